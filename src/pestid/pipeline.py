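"""End-to-end assay design: regions -> template -> guides -> primers -> report.

`run_design` composes the whole in-silico phase for one target species and
returns an :class:`AssayDesign`; `write_report` materialises it as JSON
(schema-versioned, machine-readable, byte-deterministic for fixed input and
config), TSV tables (1-based inclusive coordinates), FASTA of guide and
primer sequences and per-species BED (0-based half-open).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from pestid import seqio
from pestid.guides import (
    GuideCandidate,
    PamSpec,
    SeedSpec,
    SpecificityReport,
    VERDICT_SPECIFIC,
    VERDICT_UNRESOLVED,
    design_guides,
)
from pestid.primers import PrimerConstraints, PrimerPair, design_specific_primers, design_universal_primers
from pestid.regions import (
    DEFAULT_LINKER,
    ConservedBlock,
    VariableRegion,
    build_concatenated_template,
    conservation_profile,
    find_conserved_blocks,
    find_variable_regions,
)

SCHEMA_VERSION = "1.0"

logger = logging.getLogger("pestid")


@dataclass(frozen=True)
class Config:
    """Every tunable of the design pipeline in one validated document."""

    pam_pattern: str = "TTTV"
    protospacer_len: int = 20
    seed_len: int = 10
    min_flank: int = 30
    min_flank_identity: float = 1.0
    max_vr_len: int = 500
    min_divergence: float = 0.05
    allow_terminal_regions: bool = False
    linker: str = DEFAULT_LINKER
    mm_threshold: int = 2
    seed_threshold: int = 1
    min_primer_len: int = 30
    max_primer_len: int = 35
    gc_min: float = 0.20
    gc_max: float = 0.70
    max_homopolymer: int = 5
    min_amplicon: int = 100
    max_amplicon: int = 600

    def __post_init__(self) -> None:
        self.pam_spec()  # validates pattern and protospacer_len
        if not 1 <= self.seed_len <= self.protospacer_len:
            raise ValueError("seed_len must be in [1, protospacer_len]")
        self.primer_constraints()

    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)

    def pam_spec(self) -> PamSpec:
        return PamSpec(pattern=self.pam_pattern, protospacer_len=self.protospacer_len)

    def seed_spec(self) -> SeedSpec:
        return SeedSpec(seed_len=self.seed_len)

    def primer_constraints(self) -> PrimerConstraints:
        return PrimerConstraints(
            min_len=self.min_primer_len,
            max_len=self.max_primer_len,
            gc_min=self.gc_min,
            gc_max=self.gc_max,
            max_homopolymer=self.max_homopolymer,
            min_amplicon=self.min_amplicon,
            max_amplicon=self.max_amplicon,
        )


@dataclass
class AssayDesign:
    """The consolidated result of one design run."""

    input_digest: dict[str, str]
    target: str
    species: list[str]
    parameters: dict
    regions: list[VariableRegion]
    guides: list[GuideCandidate]
    universal_primers: list[PrimerPair]
    specific_primers: list[PrimerPair]
    warnings: list[str] = field(default_factory=list)

    @property
    def viable(self) -> bool:
        return bool(self.regions)


def _digest(path: Path) -> dict[str, str]:
    return {
        "file": path.name,
        "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
    }


def run_design(
    msa_path: str | Path, target: str, config: Config = Config()
) -> AssayDesign:
    """Run the full design for one target species against the rest of the panel."""
    msa_path = Path(msa_path)
    msa = seqio.read_alignment(msa_path)
    if target not in msa.species_ids:
        raise ValueError(f"target '{target}' not among species {msa.species_ids}")

    warnings: list[str] = []
    design = AssayDesign(
        input_digest=_digest(msa_path),
        target=target,
        species=msa.species_ids,
        parameters=asdict(config),
        regions=[],
        guides=[],
        universal_primers=[],
        specific_primers=[],
        warnings=warnings,
    )

    profile = conservation_profile(msa)
    blocks = find_conserved_blocks(
        profile, min_len=config.min_flank, min_identity=config.min_flank_identity
    )
    regions = find_variable_regions(
        profile, blocks, msa,
        max_vr_len=config.max_vr_len,
        min_divergence=config.min_divergence,
        allow_terminal=config.allow_terminal_regions,
    )
    logger.info("regions: %d conserved blocks, %d variable regions", len(blocks), len(regions))
    if not regions:
        warnings.append("no variable regions found; no design possible")
        return design
    design.regions = regions

    template = build_concatenated_template(
        regions, msa, linker=config.linker, pam_pattern=config.pam_pattern
    )
    design.guides = design_guides(
        template, msa,
        pam=config.pam_spec(),
        seed=config.seed_spec(),
        mm_threshold=config.mm_threshold,
        seed_threshold=config.seed_threshold,
    )
    logger.info("guides: %d candidates enumerated", len(design.guides))

    specific_guides = [g for g in design.guides if g.verdict == VERDICT_SPECIFIC]
    target_specific = [g for g in specific_guides if g.origin_species == target]
    unresolved = [
        g for g in design.guides
        if g.origin_species == target and g.verdict == VERDICT_UNRESOLVED
    ]
    if not target_specific:
        warnings.append(
            f"no specific-verdict guide for target '{target}'; "
            f"{len(unresolved)} unresolved candidate(s) would need wet-lab validation"
        )
    if unresolved:
        warnings.append(
            f"{len(unresolved)} unresolved guide(s) for '{target}' require experimental validation"
        )

    constraints = config.primer_constraints()
    covered_labels = {g.region_label for g in specific_guides}
    for region in regions:
        if region.label not in covered_labels:
            continue
        result = design_universal_primers(region, msa, constraints, guides=design.guides)
        if result:
            design.universal_primers.append(result[0])
        else:
            warnings.append(
                f"no universal primer pair for {region.label}: " + "; ".join(result.diagnostics)
            )
    for region in regions:
        result = design_specific_primers(
            region, target, msa, constraints,
            guides=target_specific if target_specific else None,
        )
        if result:
            design.specific_primers.append(result[0])
        else:
            warnings.append(
                f"no specific primer pair for {region.label}/{target}: "
                + "; ".join(result.diagnostics)
            )
    logger.info(
        "primers: %d universal, %d specific pair(s)",
        len(design.universal_primers), len(design.specific_primers),
    )
    return design


# ---------------------------------------------------------------------------
# serialisation

def design_to_dict(design: AssayDesign) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "input": design.input_digest,
        "target": design.target,
        "species": design.species,
        "parameters": design.parameters,
        "regions": [
            {
                "label": r.label,
                "start": r.start,
                "end": r.end,
                "divergence": round(r.divergence, 6),
                "left_flank": [r.left_flank.start, r.left_flank.end],
                "right_flank": [r.right_flank.start, r.right_flank.end],
                "projections": {sp: list(iv) for sp, iv in sorted(r.projections.items())},
            }
            for r in design.regions
        ],
        "guides": [
            {
                "guide_id": g.guide_id,
                "origin_species": g.origin_species,
                "region_label": g.region_label,
                "strand": g.strand,
                "pam_seq": g.pam_seq,
                "protospacer": g.protospacer,
                "origin_interval": list(g.origin_interval),
                "gc_fraction": round(g.gc_fraction, 6),
                "verdict": g.verdict,
                "specificity": [asdict(r) for r in g.specificity],
            }
            for g in design.guides
        ],
        "universal_primers": [_pair_to_dict(p) for p in design.universal_primers],
        "specific_primers": [_pair_to_dict(p) for p in design.specific_primers],
        "warnings": design.warnings,
    }


def _pair_to_dict(p: PrimerPair) -> dict:
    return {
        "kind": p.kind,
        "fwd_seq": p.fwd_seq,
        "rev_seq": p.rev_seq,
        "target_region": p.target_region,
        "fwd_sites": {sp: list(iv) for sp, iv in sorted(p.fwd_sites.items())},
        "rev_sites": {sp: list(iv) for sp, iv in sorted(p.rev_sites.items())},
        "amplicon_len": dict(sorted(p.amplicon_len.items())),
        "covered_guides": p.covered_guides,
        "fwd_discrimination": dict(sorted(p.fwd_discrimination.items())),
        "rev_discrimination": dict(sorted(p.rev_discrimination.items())),
    }


def design_from_dict(data: dict) -> AssayDesign:
    """Rebuild an AssayDesign from its JSON form (round-trip inverse)."""
    regions = [
        VariableRegion(
            label=r["label"],
            start=r["start"],
            end=r["end"],
            divergence=r["divergence"],
            left_flank=ConservedBlock(*r["left_flank"]),
            right_flank=ConservedBlock(*r["right_flank"]),
            projections={sp: tuple(iv) for sp, iv in r["projections"].items()},
        )
        for r in data["regions"]
    ]
    guides = [
        GuideCandidate(
            guide_id=g["guide_id"],
            origin_species=g["origin_species"],
            region_label=g["region_label"],
            strand=g["strand"],
            pam_seq=g["pam_seq"],
            protospacer=g["protospacer"],
            origin_interval=tuple(g["origin_interval"]),
            gc_fraction=g["gc_fraction"],
            specificity=[SpecificityReport(**r) for r in g["specificity"]],
            verdict=g["verdict"],
        )
        for g in data["guides"]
    ]

    def pair(p: dict) -> PrimerPair:
        return PrimerPair(
            kind=p["kind"],
            fwd_seq=p["fwd_seq"],
            rev_seq=p["rev_seq"],
            target_region=p["target_region"],
            fwd_sites={sp: tuple(iv) for sp, iv in p["fwd_sites"].items()},
            rev_sites={sp: tuple(iv) for sp, iv in p["rev_sites"].items()},
            amplicon_len=dict(p["amplicon_len"]),
            covered_guides=list(p["covered_guides"]),
            fwd_discrimination=dict(p["fwd_discrimination"]),
            rev_discrimination=dict(p["rev_discrimination"]),
        )

    return AssayDesign(
        input_digest=dict(data["input"]),
        target=data["target"],
        species=list(data["species"]),
        parameters=dict(data["parameters"]),
        regions=regions,
        guides=guides,
        universal_primers=[pair(p) for p in data["universal_primers"]],
        specific_primers=[pair(p) for p in data["specific_primers"]],
        warnings=list(data["warnings"]),
    )


def write_report(design: AssayDesign, out_prefix: str | Path) -> dict[str, Path]:
    """Write JSON + TSV + FASTA + per-species BED for a design.

    TSV coordinates are 1-based inclusive; BED stays 0-based half-open.
    Returns the mapping of artifact name to path.
    """
    prefix = Path(out_prefix)
    if prefix.parent != Path(""):
        prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["json"] = Path(f"{prefix}.design.json")
    paths["json"].write_text(
        json.dumps(design_to_dict(design), indent=2, sort_keys=True) + "\n"
    )

    paths["regions_tsv"] = Path(f"{prefix}.regions.tsv")
    with open(paths["regions_tsv"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["label", "aln_start", "aln_end", "length", "divergence"]
                   + [f"{sp}_interval" for sp in design.species])
        for r in design.regions:
            w.writerow(
                [r.label, r.start + 1, r.end, r.length, f"{r.divergence:.4f}"]
                + [f"{r.projections[sp][0] + 1}-{r.projections[sp][1]}" for sp in design.species]
            )

    paths["guides_tsv"] = Path(f"{prefix}.guides.tsv")
    with open(paths["guides_tsv"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = [
            "guide_id", "species", "region", "strand", "start", "end",
            "pam", "protospacer", "gc", "verdict",
        ]
        others = [sp for sp in design.species]
        for sp in others:
            header += [f"{sp}_mm", f"{sp}_seed_mm", f"{sp}_pam_intact", f"{sp}_indel"]
        w.writerow(header)
        for g in design.guides:
            row = [
                g.guide_id, g.origin_species, g.region_label, g.strand,
                g.origin_interval[0] + 1, g.origin_interval[1],
                g.pam_seq, g.protospacer, f"{g.gc_fraction:.2f}", g.verdict,
            ]
            by_sp = {r.species: r for r in g.specificity}
            for sp in others:
                r = by_sp.get(sp)
                row += (
                    ["", "", "", ""] if r is None
                    else [r.total_mismatches, r.seed_mismatches,
                          int(r.pam_intact), int(r.indel_in_window)]
                )
            w.writerow(row)

    paths["primers_tsv"] = Path(f"{prefix}.primers.tsv")
    with open(paths["primers_tsv"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([
            "kind", "region", "fwd_seq", "rev_seq", "species",
            "fwd_start", "fwd_end", "rev_start", "rev_end", "amplicon_len",
            "covered_guides",
        ])
        for p in design.universal_primers + design.specific_primers:
            for sp in sorted(p.fwd_sites):
                w.writerow([
                    p.kind, p.target_region, p.fwd_seq, p.rev_seq, sp,
                    p.fwd_sites[sp][0] + 1, p.fwd_sites[sp][1],
                    p.rev_sites[sp][0] + 1, p.rev_sites[sp][1],
                    p.amplicon_len[sp], ",".join(p.covered_guides),
                ])

    guide_records = [
        seqio.SequenceRecord(id=g.guide_id, residues=g.protospacer, description=g.verdict)
        for g in design.guides
    ]
    paths["guides_fasta"] = Path(f"{prefix}.guides.fasta")
    _write_fasta_or_empty(guide_records, paths["guides_fasta"])

    primer_records = []
    for i, p in enumerate(design.universal_primers + design.specific_primers):
        primer_records.append(seqio.SequenceRecord(
            id=f"{p.kind}_{p.target_region}_{i + 1}_F", residues=p.fwd_seq))
        primer_records.append(seqio.SequenceRecord(
            id=f"{p.kind}_{p.target_region}_{i + 1}_R", residues=p.rev_seq))
    paths["primers_fasta"] = Path(f"{prefix}.primers.fasta")
    _write_fasta_or_empty(primer_records, paths["primers_fasta"])

    for sp in design.species:
        bed = Path(f"{prefix}.{sp}.regions.bed")
        seqio.write_regions_bed(design.regions, sp, bed)
        paths[f"bed_{sp}"] = bed

    logger.info("report: wrote %d artifact(s) under %s.*", len(paths), prefix)
    return paths


def _write_fasta_or_empty(records, path: Path) -> None:
    if records:
        seqio.write_fasta(records, path)
    else:
        path.write_text("")
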