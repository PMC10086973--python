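"""Ground-truth synthetic species panels.

Emulates the toolkit's real input — long, near-identical marker sequences
(think mitochondrial genomes of sibling species) carrying localized
divergence hotspots — while keeping exact coordinate truth.  Each panel
starts from one random backbone; every species is mutated independently
inside the planted regions (i.i.d. substitutions, geometric-length indels),
and the alignment is emitted straight from the edit history rather than by
re-aligning, so the true region intervals are exact by construction.

Planted regions are guaranteed detectable: after mutation the generator
forces divergence at each region's edge columns and breaks any internal
fully-conserved run of >= ``max_conserved_run`` columns (20 by default,
safely below the 30-column flank threshold).  This models genuinely
divergent loci; without it, i.i.d. mutation leaves region edges conserved by
chance and the called interval would shrink nondeterministically.  The
repair is skipped when the substitution rate is zero so that a zero-rate
spec yields truly identical species (the degenerate control).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from pestid.seqio import Msa, SequenceRecord, write_fasta

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of a synthetic panel; defaults are the standard study conditions."""

    n_species: int = 2
    backbone_len: int = 4000
    n_regions: int = 2
    flank_len: int = 40
    vr_len_range: tuple[int, int] = (150, 300)
    vr_substitution_rate: float = 0.15
    vr_indel_rate: float = 0.02
    background_substitution_rate: float = 0.0
    max_conserved_run: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need >= 2 species")
        if not 0 <= self.vr_substitution_rate <= 1:
            raise ValueError("vr_substitution_rate must be in [0, 1]")
        if not 0 <= self.vr_indel_rate < 1:
            raise ValueError("vr_indel_rate must be in [0, 1)")
        lo, hi = self.vr_len_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid vr_len_range")


@dataclass(frozen=True)
class PlantedSite:
    """A guide window planted with a known cross-species divergence pattern."""

    kind: str
    origin_species: str
    origin_interval: tuple[int, int]  # ungapped, PAM+protospacer window, '+' strand
    region_index: int
    expected_verdict: str


@dataclass
class PanelTruth:
    """A generated panel plus its exact ground truth.

    ``segments[s][i]`` is species ``s``'s replacement string for backbone
    slot ``i`` ('' = deleted, one base = match/substitution, longer =
    insertion after the base); the alignment is deterministically derived
    from this table.
    """

    spec: PanelSpec
    backbone: str
    segments: list[list[str]]
    region_backbone: list[tuple[int, int]]
    planted: list[PlantedSite] = field(default_factory=list)
    species: list[str] = field(default_factory=list)
    msa: Msa | None = field(default=None, repr=False)
    regions_alignment: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species:
            self.species = [f"sp{i + 1}" for i in range(self.spec.n_species)]
        self._materialize()

    def _materialize(self) -> None:
        nsp = len(self.segments)
        widths = [
            max(len(self.segments[s][i]) for s in range(nsp))
            for i in range(len(self.backbone))
        ]
        col_at_slot = np.concatenate(([0], np.cumsum(widths)))
        aligned = []
        for s in range(nsp):
            parts = [
                seg + "-" * (w - len(seg))
                for seg, w in zip(self.segments[s], widths)
            ]
            aligned.append("".join(parts))
        records = [
            SequenceRecord(id=sp, residues=seq) for sp, seq in zip(self.species, aligned)
        ]
        self.msa = Msa(records=records, ncols=int(col_at_slot[-1]))
        self.regions_alignment = [
            (int(col_at_slot[a]), int(col_at_slot[b])) for a, b in self.region_backbone
        ]

    @property
    def sequences(self) -> list[SequenceRecord]:
        return [
            SequenceRecord(id=r.id, residues=r.ungapped) for r in self.msa.records
        ]

    def ungapped_pos(self, species_index: int, slot: int) -> int:
        """Ungapped position of the first base of a backbone slot in one species."""
        return sum(len(seg) for seg in self.segments[species_index][:slot])

    def truth_dict(self) -> dict:
        return {
            "spec": {
                "n_species": self.spec.n_species,
                "backbone_len": self.spec.backbone_len,
                "n_regions": self.spec.n_regions,
                "flank_len": self.spec.flank_len,
                "vr_len_range": list(self.spec.vr_len_range),
                "vr_substitution_rate": self.spec.vr_substitution_rate,
                "vr_indel_rate": self.spec.vr_indel_rate,
                "rng_seed": self.spec.rng_seed,
            },
            "species": self.species,
            "regions_alignment": [list(r) for r in self.regions_alignment],
            "regions_backbone": [list(r) for r in self.region_backbone],
            "planted_sites": [
                {
                    "kind": p.kind,
                    "origin_species": p.origin_species,
                    "origin_interval": list(p.origin_interval),
                    "region_index": p.region_index,
                    "expected_verdict": p.expected_verdict,
                }
                for p in self.planted
            ],
        }

    def write(self, out_prefix: str | Path) -> dict[str, Path]:
        """Emit <prefix>.species.fasta, <prefix>.msa.fasta and <prefix>.truth.json."""
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "species": Path(f"{prefix}.species.fasta"),
            "msa": Path(f"{prefix}.msa.fasta"),
            "truth": Path(f"{prefix}.truth.json"),
        }
        write_fasta(self.sequences, paths["species"])
        write_fasta(self.msa.records, paths["msa"])
        paths["truth"].write_text(json.dumps(self.truth_dict(), indent=2) + "\n")
        return paths


def _place_regions(spec: PanelSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    lens = rng.integers(spec.vr_len_range[0], spec.vr_len_range[1] + 1, spec.n_regions)
    slack = spec.backbone_len - int(lens.sum()) - (spec.n_regions + 1) * spec.flank_len
    if slack < 0:
        raise ValueError(
            f"infeasible spec: {spec.n_regions} regions of up to "
            f"{spec.vr_len_range[1]} plus flanks exceed backbone_len={spec.backbone_len}"
        )
    cuts = np.sort(rng.integers(0, slack + 1, spec.n_regions))
    gap_extra = np.diff(np.concatenate(([0], cuts, [slack])))
    regions = []
    pos = 0
    for k in range(spec.n_regions):
        pos += spec.flank_len + int(gap_extra[k])
        regions.append((pos, pos + int(lens[k])))
        pos += int(lens[k])
    return regions


def _mutate_region(
    segments: list[str],
    backbone: str,
    a: int,
    b: int,
    spec: PanelSpec,
    rng: np.random.Generator,
) -> None:
    """Apply i.i.d. substitutions and geometric indels to one species' slots [a,b)."""
    i = a
    while i < b:
        if segments[i] == "":  # removed by an earlier deletion
            i += 1
            continue
        base = segments[i]
        if rng.random() < spec.vr_substitution_rate:
            base = _substitute(base, rng)
        segments[i] = base
        if rng.random() < spec.vr_indel_rate:
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # deletion, clipped at the region end
                for j in range(i, min(i + length, b)):
                    segments[j] = ""
            else:  # insertion after this slot's base
                segments[i] = base + "".join(rng.choice(_BASES, length))
        i += 1


def _substitute(base: str, rng: np.random.Generator) -> str:
    alts = [c for c in "ACGT" if c != base]
    return alts[int(rng.integers(3))]


def _repair_region(
    segments: list[list[str]],
    a: int,
    b: int,
    spec: PanelSpec,
    rng: np.random.Generator,
) -> None:
    """Guarantee detectability: divergent edges, no long conserved run inside."""
    nsp = len(segments)

    def conserved(i: int) -> bool:
        first = segments[0][i]
        return len(first) == 1 and all(segments[s][i] == first for s in range(1, nsp))

    def force_divergence(i: int) -> None:
        s = int(rng.integers(1, nsp))
        segments[s][i] = _substitute(segments[s][i][0], rng)

    def first_real(i: int, step: int) -> int:
        # skip slots deleted in every species (they contribute no columns)
        while a <= i < b and all(segments[s][i] == "" for s in range(nsp)):
            i += step
        return i

    left = first_real(a, +1)
    if left < b:
        _force_first_column_divergent(segments, left, rng)
    right = first_real(b - 1, -1)
    if right >= a:
        _force_last_column_divergent(segments, right, rng)
    run = 0
    for i in range(a, b):
        run = run + 1 if conserved(i) else 0
        if run >= spec.max_conserved_run:
            force_divergence(i - run // 2)
            run = 0


def _force_first_column_divergent(
    segments: list[list[str]], i: int, rng: np.random.Generator
) -> None:
    """Make a slot's first alignment column non-conserved (insertion-aware)."""
    segs = [segments[s][i] for s in range(len(segments))]
    if all(segs) and len({seg[0] for seg in segs}) == 1:
        s = 1 + int(rng.integers(len(segments) - 1))
        segments[s][i] = _substitute(segs[s][0], rng) + segs[s][1:]


def _force_last_column_divergent(
    segments: list[list[str]], i: int, rng: np.random.Generator
) -> None:
    """Make a slot's last alignment column non-conserved (insertion-aware)."""
    segs = [segments[s][i] for s in range(len(segments))]
    lens = {len(seg) for seg in segs}
    # differing lengths already put a gap in the last column
    if 0 not in lens and len(lens) == 1 and len({seg[-1] for seg in segs}) == 1:
        s = 1 + int(rng.integers(len(segments) - 1))
        segments[s][i] = segs[s][:-1] + _substitute(segs[s][-1], rng)


def generate_panel(spec: PanelSpec) -> PanelTruth:
    """Generate a deterministic labelled panel from a :class:`PanelSpec`."""
    rng = np.random.default_rng(spec.rng_seed)
    regions = _place_regions(spec, rng)
    backbone = "".join(rng.choice(_BASES, spec.backbone_len))
    segments = [list(backbone) for _ in range(spec.n_species)]

    if spec.background_substitution_rate > 0:
        region_slots = set()
        for a, b in regions:
            region_slots.update(range(a, b))
        for s in range(spec.n_species):
            for i in range(spec.backbone_len):
                if i not in region_slots and rng.random() < spec.background_substitution_rate:
                    segments[s][i] = _substitute(segments[s][i], rng)

    for a, b in regions:
        for s in range(spec.n_species):
            _mutate_region(segments[s], backbone, a, b, spec, rng)
        if spec.vr_substitution_rate > 0:
            _repair_region(segments, a, b, spec, rng)

    return PanelTruth(
        spec=spec, backbone=backbone, segments=segments, region_backbone=regions
    )


_PLANT_PATTERNS = {
    # (PAM for non-origin species, protospacer substitution indices
    #  PAM-proximal order: 0..9 = seed, 10..19 = non-seed), expected verdict
    "identical": (None, (), "cross_reactive"),
    "pam_loss_one_base": ("TCTA", (), "specific"),
    "two_mm_one_seed": (None, (4, 14), "specific"),
    "one_mm_nonseed": (None, (14,), "unresolved"),
}


def plant_discriminating_site(
    truth: PanelTruth, kind: str, region_index: int = 0
) -> PanelTruth:
    """Inject a guide window with a controlled cross-species divergence pattern.

    The window (TTTA PAM + 20-nt protospacer, '+' strand) is written into the
    first species in the middle of the chosen planted region; every other
    species receives the same window altered per ``kind``:

    * ``identical`` — no change: the guide would recognise every species.
    * ``pam_loss_one_base`` — the PAM loses one T (TTTA -> TCTA).
    * ``two_mm_one_seed`` — two protospacer substitutions, one inside the
      10-nt PAM-proximal seed.
    * ``one_mm_nonseed`` — a single substitution outside the seed under an
      intact PAM: the pattern requiring wet-lab validation.
    """
    if kind not in _PLANT_PATTERNS:
        raise ValueError(f"unknown kind {kind!r}; one of {sorted(_PLANT_PATTERNS)}")
    alt_pam, mm_idx, expected = _PLANT_PATTERNS[kind]
    window_len = 24  # 4-nt PAM + 20-nt protospacer
    a, b = truth.region_backbone[region_index]
    margin = 2  # keep off the forced-divergent edge slots
    if b - a < window_len + 2 * margin:
        raise ValueError(f"region {region_index} too short to plant a {window_len}-nt window")
    start = a + (b - a - window_len) // 2

    rng = np.random.default_rng(truth.spec.rng_seed + 7919)
    protospacer = "".join(rng.choice(_BASES, 20))
    origin_window = "TTTA" + protospacer
    other_proto = list(protospacer)
    for idx in mm_idx:
        other_proto[idx] = _substitute(other_proto[idx], rng)
    other_window = (alt_pam or "TTTA") + "".join(other_proto)

    segments = [list(slots) for slots in truth.segments]
    nsp = len(segments)
    for s in range(nsp):
        window = origin_window if s == 0 else other_window
        for k in range(window_len):
            segments[s][start + k] = window[k]
    # the window itself may be conserved across species (kind=identical);
    # keep the columns just outside it divergent so no conserved run can
    # reach the flank threshold and absorb the window into a flank
    _force_last_column_divergent(segments, start - 1, rng)
    _force_first_column_divergent(segments, start + window_len, rng)

    planted = PanelTruth(
        spec=truth.spec,
        backbone=truth.backbone,
        segments=segments,
        region_backbone=list(truth.region_backbone),
        planted=list(truth.planted),
        species=list(truth.species),
    )
    pos = planted.ungapped_pos(0, start)
    planted.planted.append(
        PlantedSite(
            kind=kind,
            origin_species=planted.species[0],
            origin_interval=(pos, pos + window_len),
            region_index=region_index,
            expected_verdict=expected,
        )
    )
    return planted
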