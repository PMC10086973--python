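# pestid

**Design toolkit for CRISPR-Cas12a species-identification assays.**

Quarantine labs intercepting insect pests (fruit fly larvae, for instance)
often cannot tell morphologically identical sibling species apart, yet the
regulatory consequences differ drastically. A Cas12a collateral-cleavage
assay solves this at the molecular level: an RPA-amplified marker fragment
is probed with a guide RNA; if the guide's protospacer and its TTTV PAM are
present, activated Cas12a shreds a fluorescent ssDNA reporter. The whole
read-out hinges on one in-silico step — choosing guides and primers that
recognise the target species and *only* the target species.

`pestid` implements that design step as a reusable library (plus a thin
CLI). Starting from a multiple sequence alignment of marker sequences
(e.g. mitochondrial genomes) of the target and its look-alike relatives, it:

1. **profiles conservation** per alignment column and calls **variable
   regions**: divergence hotspots of ≤ 500 columns flanked on both sides by
   ≥ 30 strictly conserved columns (the flanks that make universal RPA
   amplification possible);
2. **enumerates Cas12a guide candidates** (TTTV PAM, 20-nt protospacer,
   both strands) on a linker-joined concatenation of every species'
   variable-region sequence — the PAM-free linker guarantees no candidate
   spans the artificial stitch between regions;
3. **screens cross-reactivity** panel-wide: each candidate window is mapped
   onto every other species through the alignment and scored for PAM
   integrity, total protospacer mismatches, mismatches in the 10-nt
   PAM-proximal **seed**, and indels. A species escapes recognition iff

   `¬PAM ∨ indel ∨ (mm ≥ 2 ∧ mm_seed ≥ 1)`

   A guide is **specific** when every non-target species escapes,
   **cross-reactive** when one is recognised, and **unresolved** when the
   only offence is a single non-seed mismatch under an intact PAM — too
   close to call without wet-lab validation;
4. **designs RPA primers**: *universal* pairs in the conserved flanks
   (column-identical in every species, amplicon containing the whole
   region) and *species-specific* pairs inside one species' region sequence
   (≥ 1 mismatch or indel against every other species, amplicon covering a
   specific guide). RPA runs isothermally at 37–42 °C, so primers are long
   (30–35 nt) and selected by GC/homopolymer/amplicon bounds, not melting
   temperature.

A ground-truth **synthetic panel generator** emulates the real input — long
near-identical sequences with planted divergence hotspots — with exact
coordinate truth, so every step is testable without downloading a single
accession.

## Worked example

```python
from pestid import PanelSpec, generate_panel, plant_discriminating_site, run_design

truth = plant_discriminating_site(
    generate_panel(PanelSpec(n_species=3, rng_seed=42)), "pam_loss_one_base"
)
paths = truth.write("scratch/panel")
design = run_design(paths["msa"], target="sp1")
```

Running `python examples/05_full_design.py` (which does exactly this and
writes the report) prints:

```
target            : sp1 (panel: sp1, sp2, sp3)
variable regions  : 2
guide candidates  : 31 (7 specific to sp1)
universal primers : 2 pair(s)
specific primers  : 2 pair(s)
```

Two divergence hotspots were found; of 31 guide candidates across the
panel, 7 are specific to `sp1` (every other species' window is disqualified
by a broken PAM, an indel, or ≥ 2 mismatches with one in the seed); each
hotspot got one universal pair (binding sites identical in all three
species) and one `sp1`-only pair. `examples/03_design_guides.py` shows the
per-species evidence behind a verdict:

```
top guide sp1:VR1:1829:-
  PAM TTTC  protospacer CGGGCCCGCCACAGTTGGCT  GC 0.75
  vs sp2: PAM intact=False, mismatches=8 (seed 5), indel=False -> escapes
  vs sp3: PAM intact=False, mismatches=8 (seed 5), indel=False -> escapes
  verdict: specific
```

The same pipeline is available from the shell:

```bash
pestid simulate --seed 42 --n-species 3 --plant pam_loss_one_base --out-prefix panel
pestid design --msa panel.msa.fasta --target sp1 --out-prefix run1
```

`design` exits 0 when a design was produced, 3 on a structurally valid "no
viable design" outcome, ≥ 4 on errors. Output artifacts: a schema-versioned
JSON report (byte-deterministic for fixed input and config), TSV tables
(1-based inclusive coordinates), FASTA of guides and primers, and BED per
species (0-based half-open).

## Scope

The toolkit consumes a pre-computed MSA (align with MAFFT or any aligner of
your choice) and judges specificity only within the supplied species panel;
genome-wide off-target search, on-target efficiency prediction and all
wet-lab protocol concerns are out of scope. See `docs/methods.md` for the
model, parameter rationale and limitations.
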