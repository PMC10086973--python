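"""End-to-end assay design for one target species, plus the written report.

Composes the whole pipeline — region calling, template concatenation, guide
enumeration and specificity screening, universal and specific primer design —
and writes the machine-readable report artifacts.
"""

from pestid import Config, PanelSpec, generate_panel, plant_discriminating_site, run_design, write_report

truth = plant_discriminating_site(
    generate_panel(PanelSpec(n_species=3, rng_seed=42)), "pam_loss_one_base"
)
paths = truth.write("scratch/example_design_panel")

design = run_design(paths["msa"], target="sp1", config=Config())

print(f"target            : {design.target} (panel: {', '.join(design.species)})")
print(f"variable regions  : {len(design.regions)}")
n_specific = sum(g.verdict == "specific" and g.origin_species == "sp1" for g in design.guides)
print(f"guide candidates  : {len(design.guides)} ({n_specific} specific to sp1)")
print(f"universal primers : {len(design.universal_primers)} pair(s)")
print(f"specific primers  : {len(design.specific_primers)} pair(s)")
for w in design.warnings:
    print(f"warning           : {w}")

files = write_report(design, "scratch/example_run")
print("report artifacts  :")
for name, path in files.items():
    print(f"  {name:12s} {path}")

# Exit-code contract of the CLI equivalent (`pestid design`): 0 = design
# produced, 3 = no viable design, >= 4 = error.
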