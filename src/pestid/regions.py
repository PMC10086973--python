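"""Conservation profiling, variable-region calling and template concatenation.

The design hotspots are *variable regions*: stretches of elevated
inter-species divergence bounded on both sides by conserved blocks long
enough (>= 30 columns by default) to host universal RPA primers.  Guide
enumeration then runs on a single template built by concatenating every
species' ungapped variable-region sequence with a PAM-free linker between
segments, so that no candidate can span an artificial junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pestid.nucleic import contains_motif, revcomp
from pestid.seqio import Msa

#: 20-nt purine repeat; contains no TTTV PAM on either strand.
DEFAULT_LINKER = "GAGAGAGAGAGAGAGAGAGA"


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation over an alignment.

    ``identity_fraction[c]`` is the count of the most frequent non-gap
    residue in column ``c`` divided by the number of sequences, so gap
    symbols count as a mismatching class.  ``is_conserved[c]`` is true only
    when every sequence carries one identical non-gap residue.
    """

    identity_fraction: np.ndarray
    is_conserved: np.ndarray
    has_gap: np.ndarray

    def __len__(self) -> int:
        return len(self.identity_fraction)


@dataclass(frozen=True)
class ConservedBlock:
    """A maximal run of fully conserved columns, 0-based half-open."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class VariableRegion:
    """A divergence hotspot between two qualifying conserved blocks.

    ``projections`` maps each species id to the half-open ungapped interval
    of the region in that species' own sequence.
    """

    label: str
    start: int
    end: int
    divergence: float
    left_flank: ConservedBlock
    right_flank: ConservedBlock
    projections: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TemplateSegment:
    """Provenance of one template stretch: which species/region it came from."""

    template_start: int
    template_end: int
    species: str
    region_label: str
    local_start: int  # ungapped coordinates in the species' full sequence
    local_end: int


@dataclass(frozen=True)
class ConcatenatedTemplate:
    """Per-species variable-region sequences joined by a fixed linker."""

    sequence: str
    junctions: list[tuple[int, int]]
    provenance: list[TemplateSegment]
    linker: str

    def segment_at(self, pos: int) -> TemplateSegment | None:
        for seg in self.provenance:
            if seg.template_start <= pos < seg.template_end:
                return seg
        return None


class LinkerError(ValueError):
    """Raised when the configured linker contains a PAM on either strand."""


def conservation_profile(msa: Msa) -> ConservationProfile:
    """Column-wise identity fractions and strict-conservation flags."""
    mat = np.array([np.frombuffer(r.residues.encode(), dtype="S1") for r in msa.records])
    nseq, ncols = mat.shape
    gap = mat == b"-"
    has_gap = gap.any(axis=0)
    identity = np.empty(ncols, dtype=float)
    conserved = np.empty(ncols, dtype=bool)
    for c in range(ncols):
        col = mat[:, c]
        bases = col[~gap[:, c]]
        if bases.size == 0:
            identity[c] = 0.0
            conserved[c] = False
            continue
        _, counts = np.unique(bases, return_counts=True)
        top = int(counts.max())
        identity[c] = top / nseq
        conserved[c] = top == nseq  # implies no gaps and a single residue
    return ConservationProfile(identity_fraction=identity, is_conserved=conserved, has_gap=has_gap)


def find_conserved_blocks(
    profile: ConservationProfile, min_len: int = 30, min_identity: float = 1.0
) -> list[ConservedBlock]:
    """All maximal conserved runs of length >= ``min_len``, in positional order.

    With the default ``min_identity=1.0`` a column qualifies only under
    strict identity (``is_conserved``); lowering it relaxes the flank
    criterion to gap-free columns of at least that identity fraction.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if min_identity >= 1.0:
        ok = profile.is_conserved
    else:
        ok = (profile.identity_fraction >= min_identity) & ~profile.has_gap
    blocks: list[ConservedBlock] = []
    n = len(profile)
    c = 0
    while c < n:
        if ok[c]:
            start = c
            while c < n and ok[c]:
                c += 1
            if c - start >= min_len:
                blocks.append(ConservedBlock(start, c))
        else:
            c += 1
    return blocks


def find_variable_regions(
    profile: ConservationProfile,
    blocks: list[ConservedBlock],
    msa: Msa,
    max_vr_len: int = 500,
    min_divergence: float = 0.05,
    allow_terminal: bool = False,
) -> list[VariableRegion]:
    """Call variable regions in the gaps between qualifying conserved blocks.

    Each gap between consecutive blocks whose length is <= ``max_vr_len``
    and whose divergence (1 - mean identity fraction) is >= ``min_divergence``
    becomes a region, labelled "VR1", "VR2", ... left to right.  Terminal
    gaps (missing one flank) are skipped unless ``allow_terminal`` is set,
    since universal amplification needs primers on both sides; a terminal
    region borrows a zero-length sentinel block on its open side.
    """
    candidates: list[tuple[int, int, ConservedBlock, ConservedBlock]] = []
    for left, right in zip(blocks, blocks[1:]):
        candidates.append((left.end, right.start, left, right))
    if allow_terminal and blocks:
        if blocks[0].start > 0:
            candidates.insert(0, (0, blocks[0].start, ConservedBlock(0, 0), blocks[0]))
        if blocks[-1].end < len(profile):
            n = len(profile)
            candidates.append((blocks[-1].end, n, blocks[-1], ConservedBlock(n, n)))
    regions: list[VariableRegion] = []
    for start, end, left, right in sorted(candidates):
        length = end - start
        if length == 0 or length > max_vr_len:
            continue
        divergence = float(1.0 - profile.identity_fraction[start:end].mean())
        if divergence < min_divergence:
            continue
        projections = {
            sp: msa.coordinate_map(sp).project_interval(start, end)
            for sp in msa.species_ids
        }
        regions.append(
            VariableRegion(
                label=f"VR{len(regions) + 1}",
                start=start,
                end=end,
                divergence=divergence,
                left_flank=left,
                right_flank=right,
                projections=projections,
            )
        )
    return regions


def build_concatenated_template(
    regions: list[VariableRegion],
    msa: Msa,
    linker: str = DEFAULT_LINKER,
    pam_pattern: str = "TTTV",
) -> ConcatenatedTemplate:
    """Join every species' ungapped region sequences with a linker.

    Order is species-major (all regions of species 1, then species 2, ...),
    deterministic given the alignment.  The linker must not contain the PAM
    on either strand, otherwise spurious junction-spanning candidates could
    acquire a valid PAM.
    """
    if not regions:
        raise ValueError("no regions to concatenate")
    if contains_motif(linker, pam_pattern) or contains_motif(revcomp(linker), pam_pattern):
        raise LinkerError(f"linker {linker!r} contains PAM {pam_pattern!r} on a strand")

    parts: list[str] = []
    junctions: list[tuple[int, int]] = []
    provenance: list[TemplateSegment] = []
    pos = 0
    first = True
    for species in msa.species_ids:
        full = msa.ungapped(species)
        for region in regions:
            lo, hi = region.projections[species]
            seg_seq = full[lo:hi]
            if not seg_seq:
                continue
            if not first:
                junctions.append((pos, pos + len(linker)))
                parts.append(linker)
                pos += len(linker)
            provenance.append(
                TemplateSegment(pos, pos + len(seg_seq), species, region.label, lo, hi)
            )
            parts.append(seg_seq)
            pos += len(seg_seq)
            first = False
    return ConcatenatedTemplate(
        sequence="".join(parts), junctions=junctions, provenance=provenance, linker=linker
    )
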