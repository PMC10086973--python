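# Methods

## The design problem

A Cas12a diagnostic assay identifies a species by three molecular
requirements: an amplifiable marker fragment, a guide RNA whose 20-nt
protospacer matches the target, and a TTTV PAM immediately 5' of the
protospacer. Discrimination between sibling species therefore reduces to a
sequence-analysis problem over a multiple sequence alignment (MSA) of their
marker sequences: find intervals divergent enough to host
species-discriminating guides, yet flanked by intervals conserved enough to
host primers that amplify every species in one isothermal (RPA) reaction.
`pestid` implements that search and the downstream guide/primer selection.
It never aligns sequences itself — alignment quality is the caller's
responsibility, and the toolkit treats the MSA as ground truth.

## Conservation profile and variable regions

For each alignment column the *identity fraction* is the count of the most
frequent non-gap residue divided by the number of sequences, so gap symbols
act as a mismatching class. A column is *conserved* only when every
sequence carries one identical non-gap residue (identity fraction 1, no
gaps). This strict default exists because universal primers must bind
every species perfectly; `min_flank_identity < 1` relaxes the flank
criterion to gap-free columns above a fractional identity, for panels where
strictness is too demanding.

*Conserved blocks* are maximal conserved runs of at least `min_flank`
columns (default 30 — the shortest stretch that can still hold an RPA
primer). A *variable region* is the gap between two consecutive qualifying
blocks, kept when its length is ≤ `max_vr_len` (default 500, an amplicon
that RPA handles comfortably) and its divergence — one minus the mean
identity fraction — is ≥ `min_divergence` (default 0.05; the floor exists
only to avoid labelling near-conserved gaps between blocks as hotspots, and
is deliberately permissive). Regions missing one flank (at the alignment
ends) are skipped by default because universal amplification needs primers
on both sides; `allow_terminal_regions` overrides this for marker panels
where a single flank suffices.

Region coordinates are alignment columns, 0-based half-open; each region
carries its projection onto every species' ungapped coordinates through a
per-species column↔position map. All internal coordinates in the package
are 0-based half-open; only human-readable TSV output converts to 1-based
inclusive, and only at the writing boundary.

## The concatenated template and the linker

Guides for all species are enumerated on a single template: every species'
ungapped variable-region sequence, species-major order, joined by a fixed
linker (default `GAGAGAGAGAGAGAGAGAGA`, a 20-nt purine repeat). The linker
must contain no PAM on either strand — verified at construction — and every
linker occurrence is an excluded interval during scanning, so no candidate
can span the artificial stitch between two biological sequences. Because
excluded junctions alternate with provenance segments, any surviving window
lies entirely inside one segment and maps 1:1 onto its origin species.
Enumerated windows containing any ambiguity code are discarded: a guide
whose target sequence is uncertain is not a usable diagnostic.

## Cross-reactivity scoring

A candidate window (PAM + protospacer) is projected onto each non-origin
species via the alignment columns of its origin positions, and scored:

* **PAM integrity** — the mapped PAM window (reverse-complemented for '−'
  strand candidates) must match the IUPAC pattern with no gap. An
  ambiguity code in the target is counted as *compatible* when its base set
  intersects the pattern's: the PAM *could* be present, which is the
  conservative reading for a diagnostic (it keeps the species on the
  recognisable side).
* **Mismatches** — column-wise Hamming distance over the protospacer: a
  target gap, an ambiguity code, or any residue other than the origin base
  counts as a mismatch. Seed mismatches are the subset in the `seed_len`
  (default 10) PAM-proximal protospacer positions.
* **Indels** — any column in the window span gapped in exactly one of the
  two species.

A species is **cross-reactive** with the candidate unless at least one
escape condition holds: broken PAM, indel in the window, or at least
`mm_threshold` (2) mismatches with at least `seed_threshold` (1) in the
seed. These thresholds reflect the empirical behaviour of LbCas12a: single
mismatches, even seed ones, are often tolerated; a missing PAM or a seed
mismatch backed by a second difference reliably abolish recognition.

The panel verdict is **specific** when every non-origin species escapes and
**cross-reactive** when any species is recognised — with one exception: a
species whose only difference is a single non-seed mismatch under an intact
PAM is evidence too weak to call either way, and such offenders downgrade
the verdict to **unresolved** (flagging the guide for wet-lab validation)
rather than to cross-reactive. The verdict is monotone: adding mismatches
or breaking a PAM in an off-species can never move a guide from specific to
cross-reactive.

Candidates are ranked by verdict, then by the worst-case escape margin over
off-species (`seed mismatches + 2·[PAM broken]`, minimised over species),
then by preferred GC (0.30–0.70) and absence of ≥ 5-base homopolymers, then
by position with '+' before '−'. The sort is stable, so identical inputs
produce identical orderings.

Specificity is defined **within the supplied panel only**. There is no
genome-wide off-target search, no on-target activity model, and no RNA
secondary-structure check; a guide reported specific here can still have
relatives outside the panel.

## Primer design

RPA is enzyme-mediated and isothermal (37–42 °C), so no melting-temperature
model applies; primers are windows of 30–35 nt (RPA favours long primers)
filtered by GC fraction (0.20–0.70), homopolymer cap (≤ 5) and amplicon
bounds (100–600 bp; 600 = a 500-column region plus two primers).

*Universal* pairs: forward windows entirely inside the left flank block,
reverse inside the right. Flank columns are strictly conserved, so each
window is literally the same sequence in every species, and any pair's
amplicon contains the whole region everywhere by construction; pairs are
additionally filtered on per-species amplicon bounds and ranked shortest
amplicon first, then forward site closest to the region. Only the
`max_candidates_per_flank` (50) windows nearest the region enter pairing —
exactly the windows the ranking prefers — keeping enumeration linear in
flank length.

*Specific* pairs: windows inside the target species' ungapped region
sequence, each required to differ from every other species' mapped window
by ≥ 1 mismatch or indel (counted column-wise exactly as for guides).
When guide candidates are supplied, a pair is kept only if its amplicon
contains at least one of them. The per-species discrimination evidence
(mismatch, indel, or both) is recorded on the pair. A single mismatch
anywhere is the default specificity bar; 3'-end-weighted placement rules
are not applied because RPA's mismatch tolerance profile is not quantified
enough to justify them. Primer-dimer and hairpin screening are likewise
omitted — RPA is tolerant of both — and empty results always carry a
diagnostic naming the constraint that eliminated the last candidate.

## The synthetic panel generator

`generate_panel` emulates the toolkit's intended input: a set of
near-identical marker sequences with localized divergence. One random
backbone (default 4 kb) receives `n_regions` (2) planted regions of
150–300 columns separated by ≥ `flank_len` (40) untouched columns; each
species is then mutated independently inside the regions with i.i.d.
substitutions (rate 0.15) and geometric-length indels (rate 0.02, mean
length 2). The MSA is emitted from the known edit history — never
re-aligned — so the true region coordinates are exact and tests are
isolated from aligner behaviour.

Two guarantees are enforced by construction after mutation: each region's
first and last alignment columns are divergent, and no fully-conserved run
of ≥ `max_conserved_run` (20) columns survives inside a region. Under pure
i.i.d. mutation a region's edge columns are conserved by chance with
substantial probability, and long chance runs can split a region; the
repair models what the generator is declaring — genuinely divergent loci —
and makes planted truth recoverable exactly for any flank threshold above
20. With a substitution rate of 0 the repair is skipped, so the degenerate
all-identical panel remains a valid negative control. The mutation model
is i.i.d. per column with no transition/transversion bias and no
tree-structured divergence between species; passing tests therefore show
coordinate and rule correctness, not robustness to phylogenetic rate
variation or alignment error in real data.

`plant_discriminating_site` injects a TTTA + 20-nt window into the first
species mid-region and writes a controlled divergence pattern into the
others: `identical` (expected verdict cross-reactive), `pam_loss_one_base`
(TTTA→TCTA; specific), `two_mm_one_seed` (two substitutions, one in the
seed; specific), or `one_mm_nonseed` (unresolved). Columns immediately
outside the window are forced divergent so an identical planted window
cannot be absorbed into a conserved flank.

## Determinism and numerical choices

Every stochastic component draws from a `numpy` generator seeded through
`PanelSpec.rng_seed`; panel files are byte-identical across runs. The
design pipeline itself contains no randomness: given the same alignment and
configuration, the JSON report is byte-identical (keys sorted, floats
rounded at serialisation to 6 decimals). Ties in every ranking are broken
positionally, '+' strand first. Degenerate inputs are first-class: an
identical-species alignment yields a structured "no design" report rather
than an error, an empty primer result carries its eliminating constraint,
and classifying a guide with no comparison species is refused.

## Problem sizes used in the test suite

Unit and acceptance tests run on the generator's default conditions
(4-kb backbones, 2–4 species, two 150–300-column regions, substitution
rate 0.15): 100 panels for region recovery, anti-stitch and primer
contracts, 200 random alignments (≤ 300 columns) for the region oracle,
200 random 1-kb sequences for the PAM-scan oracle, and ≥ 500 mapped
candidate/species pairs for the specificity oracle — sizes at which the
brute-force oracles remain exact and the whole suite completes in about a
minute on one core.
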