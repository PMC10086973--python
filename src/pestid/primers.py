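"""RPA primer design: universal pairs in conserved flanks, specific pairs in a region.

RPA (recombinase polymerase amplification) runs isothermally at 37-42 °C, so
no melting-temperature model is applied; primers are selected by length
(30-35 nt by default, RPA favours long primers), GC fraction, homopolymer
caps and amplicon-size bounds.

*Universal* pairs sit in the conserved blocks flanking a variable region, so
their binding sites are column-identical in every panel species and one
reaction amplifies every species' region.  *Specific* pairs sit inside one
species' variable-region sequence and must differ from every other species'
mapped window by at least one mismatch or indel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pestid.nucleic import max_homopolymer, revcomp
from pestid.regions import VariableRegion
from pestid.seqio import Msa
from pestid.guides import GuideCandidate

_GC_WEIGHT = {"G": 1.0, "C": 1.0, "S": 1.0, "A": 0.0, "T": 0.0, "W": 0.0}


@dataclass(frozen=True)
class PrimerConstraints:
    """Window and amplicon constraints for RPA primer enumeration."""

    min_len: int = 30
    max_len: int = 35
    gc_min: float = 0.20
    gc_max: float = 0.70
    max_homopolymer: int = 5
    min_amplicon: int = 100
    max_amplicon: int = 600
    max_candidates_per_flank: int = 50  # windows kept per flank, closest to the region
    max_candidates_specific: int = 120  # windows paired in specific design (even coverage)

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not self.gc_min < self.gc_max:
            raise ValueError("gc_min must be < gc_max")
        if not self.min_amplicon < self.max_amplicon:
            raise ValueError("min_amplicon must be < max_amplicon")


@dataclass
class PrimerPair:
    """A forward/reverse primer pair with per-species binding evidence.

    ``rev_seq`` is the reverse complement of the bottom-strand binding site.
    Binding intervals and amplicon lengths are per species, ungapped
    half-open; for specific pairs only the target species is present.
    """

    kind: str  # 'universal' | 'specific'
    fwd_seq: str
    rev_seq: str
    target_region: str
    fwd_sites: dict[str, tuple[int, int]]
    rev_sites: dict[str, tuple[int, int]]
    amplicon_len: dict[str, int]
    covered_guides: list[str] = field(default_factory=list)
    fwd_discrimination: dict[str, str] = field(default_factory=dict)
    rev_discrimination: dict[str, str] = field(default_factory=dict)


class PrimerDesignResult(list):
    """A list of :class:`PrimerPair` carrying per-constraint diagnostics.

    When empty, ``diagnostics`` states which constraint eliminated all
    candidates.
    """

    def __init__(self, pairs=(), diagnostics: list[str] | None = None):
        super().__init__(pairs)
        self.diagnostics: list[str] = list(diagnostics or [])


def gc_fraction(seq: str) -> float:
    """GC fraction; S counts as GC, W as AT, other ambiguity codes as 0.5."""
    if not seq:
        raise ValueError("empty sequence")
    if "-" in seq or "." in seq:
        raise ValueError("gc_fraction expects a gap-free sequence")
    return sum(_GC_WEIGHT.get(c, 0.5) for c in seq) / len(seq)


def _window_ok(seq: str, constraints: PrimerConstraints, diag: dict[str, int]) -> bool:
    if not constraints.gc_min <= gc_fraction(seq) <= constraints.gc_max:
        diag["gc_out_of_bounds"] += 1
        return False
    if max_homopolymer(seq) > constraints.max_homopolymer:
        diag["homopolymer_too_long"] += 1
        return False
    return True


def _diag_lines(diag: dict[str, int]) -> list[str]:
    return [f"{name}: eliminated {count} candidate(s)" for name, count in diag.items() if count]


def window_mismatches(
    msa: Msa, species: str, interval: tuple[int, int], other: str
) -> tuple[int, bool]:
    """Column-wise mismatch count and indel flag for a window mapped onto another species."""
    c0, c1 = msa.coordinate_map(species).columns_of(*interval)
    origin = msa.record(species).residues[c0:c1]
    target = msa.record(other).residues[c0:c1]
    indel = any((o == "-") != (t == "-") for o, t in zip(origin, target))
    mm = sum(o != t for o, t in zip(origin, target) if o != "-" and t != "-")
    return mm, indel


def design_universal_primers(
    region: VariableRegion,
    msa: Msa,
    constraints: PrimerConstraints = PrimerConstraints(),
    guides: list[GuideCandidate] | None = None,
) -> PrimerDesignResult:
    """Enumerate universal pairs in the region's conserved flanks.

    Forward windows live entirely in the left flank, reverse windows in the
    right flank; because flank columns are strictly conserved, each window is
    literally identical in every species.  Pairs must satisfy GC,
    homopolymer and per-species amplicon bounds; the amplicon of any pair
    contains the whole variable region in every species by construction.
    Ranked by amplicon length (shortest first), then forward start
    descending (closest to the region).
    """
    diag: dict[str, int] = {
        "flank_too_short": 0, "gc_out_of_bounds": 0,
        "homopolymer_too_long": 0, "amplicon_out_of_bounds": 0,
    }
    ref = msa.records[0].residues
    lf, rf = region.left_flank, region.right_flank

    def flank_windows(block, reverse_primer: bool):
        wins = []
        if block.length < constraints.min_len:
            diag["flank_too_short"] += 1
            return wins
        # windows farther than max_amplicon columns from the region can never pair
        lo = max(block.start, region.start - constraints.max_amplicon) if not reverse_primer else block.start
        hi = block.end if not reverse_primer else min(block.end, region.end + constraints.max_amplicon)
        for length in range(constraints.min_len, constraints.max_len + 1):
            for c0 in range(lo, hi - length + 1):
                seq = ref[c0:c0 + length]
                if _window_ok(seq, constraints, diag):
                    wins.append((c0, c0 + length, seq))
        # keep the windows closest to the region
        wins.sort(key=lambda w: (w[0] if reverse_primer else -w[1], w[1] - w[0]))
        return wins[: constraints.max_candidates_per_flank]

    fwd_wins = flank_windows(lf, reverse_primer=False)
    rev_wins = flank_windows(rf, reverse_primer=True)

    pairs: list[PrimerPair] = []
    for fc0, fc1, fseq in fwd_wins:
        for rc0, rc1, rseq in rev_wins:
            sites_f, sites_r, amp = {}, {}, {}
            ok = True
            for sp in msa.species_ids:
                cmap = msa.coordinate_map(sp)
                sites_f[sp] = cmap.project_interval(fc0, fc1)
                sites_r[sp] = cmap.project_interval(rc0, rc1)
                length = sites_r[sp][1] - sites_f[sp][0]
                amp[sp] = length
                if not constraints.min_amplicon <= length <= constraints.max_amplicon:
                    ok = False
            if not ok:
                diag["amplicon_out_of_bounds"] += 1
                continue
            covered = _covered_guides(guides, sites_f, sites_r)
            pairs.append(
                PrimerPair(
                    kind="universal",
                    fwd_seq=fseq,
                    rev_seq=revcomp(rseq),
                    target_region=region.label,
                    fwd_sites=sites_f,
                    rev_sites=sites_r,
                    amplicon_len=amp,
                    covered_guides=covered,
                )
            )
    pairs.sort(key=lambda p: (max(p.amplicon_len.values()), -p.fwd_sites[msa.species_ids[0]][0]))
    return PrimerDesignResult(pairs, _diag_lines(diag) if not pairs else [])


def _covered_guides(
    guides: list[GuideCandidate] | None,
    sites_f: dict[str, tuple[int, int]],
    sites_r: dict[str, tuple[int, int]],
) -> list[str]:
    if not guides:
        return []
    covered = []
    for g in guides:
        sp = g.origin_species
        if sp in sites_f and sp in sites_r:
            g0, g1 = g.origin_interval
            if sites_f[sp][0] <= g0 and g1 <= sites_r[sp][1]:
                covered.append(g.guide_id)
    return covered


def design_specific_primers(
    region: VariableRegion,
    species: str,
    msa: Msa,
    constraints: PrimerConstraints = PrimerConstraints(),
    guides: list[GuideCandidate] | None = None,
) -> PrimerDesignResult:
    """Enumerate species-specific pairs inside one species' region sequence.

    Every kept primer window must differ from every other species' mapped
    window by at least one mismatch or indel (column-wise over the
    alignment), so the pair amplifies only the target species.  When guide
    candidates are supplied, a pair is kept only if its amplicon contains at
    least one of the target species' guide windows.  Ranking as for
    universal pairs.
    """
    diag: dict[str, int] = {
        "region_too_short": 0, "gc_out_of_bounds": 0, "homopolymer_too_long": 0,
        "not_species_specific": 0, "amplicon_out_of_bounds": 0, "no_guide_in_amplicon": 0,
    }
    lo, hi = region.projections[species]
    full = msa.ungapped(species)
    if hi - lo < constraints.min_len:
        diag["region_too_short"] += 1
        return PrimerDesignResult([], _diag_lines(diag))
    others = [sp for sp in msa.species_ids if sp != species]
    target_guides = [
        g for g in (guides or []) if g.origin_species == species and g.region_label == region.label
    ]

    windows = []  # (g0, g1, seq, discrimination)
    for length in range(constraints.min_len, constraints.max_len + 1):
        for g0 in range(lo, hi - length + 1):
            seq = full[g0:g0 + length]
            if "N" in seq:
                continue
            if not _window_ok(seq, constraints, diag):
                continue
            discrim: dict[str, str] = {}
            specific = True
            for other in others:
                mm, indel = window_mismatches(msa, species, (g0, g0 + length), other)
                if mm == 0 and not indel:
                    specific = False
                    break
                discrim[other] = (
                    "mismatch+indel" if mm and indel else ("indel" if indel else "mismatch")
                )
            if not specific:
                diag["not_species_specific"] += 1
                continue
            windows.append((g0, g0 + length, seq, discrim))
    windows.sort(key=lambda w: (w[0], w[1]))
    if len(windows) > constraints.max_candidates_specific:
        # thin to an evenly spaced subset so pairing stays tractable
        step = len(windows) / constraints.max_candidates_specific
        windows = [windows[int(i * step)] for i in range(constraints.max_candidates_specific)]

    pairs: list[PrimerPair] = []
    for f0, f1, fseq, fdis in windows:
        for r0, r1, rseq, rdis in windows:
            if r0 < f1:
                continue
            if r0 + constraints.min_len - f0 > constraints.max_amplicon:
                break  # starts only grow; no later window can fit
            length = r1 - f0
            if not constraints.min_amplicon <= length <= constraints.max_amplicon:
                diag["amplicon_out_of_bounds"] += 1
                continue
            covered = [
                g.guide_id for g in target_guides
                if f0 <= g.origin_interval[0] and g.origin_interval[1] <= r1
            ]
            if target_guides and not covered:
                diag["no_guide_in_amplicon"] += 1
                continue
            pairs.append(
                PrimerPair(
                    kind="specific",
                    fwd_seq=fseq,
                    rev_seq=revcomp(rseq),
                    target_region=region.label,
                    fwd_sites={species: (f0, f1)},
                    rev_sites={species: (r0, r1)},
                    amplicon_len={species: length},
                    covered_guides=covered,
                    fwd_discrimination=fdis,
                    rev_discrimination=rdis,
                )
            )
    pairs.sort(key=lambda p: (p.amplicon_len[species], -p.fwd_sites[species][0]))
    return PrimerDesignResult(pairs, _diag_lines(diag) if not pairs else [])
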