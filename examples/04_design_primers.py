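"""Design universal and species-specific RPA primer pairs.

Universal pairs sit in the conserved flanks, so one isothermal reaction
amplifies every species' variable region (pooled-sample screening).
Specific pairs sit inside one species' region sequence and mismatch every
other species, amplifying the target alone.
"""

from pestid import (
    PanelSpec,
    PrimerConstraints,
    design_specific_primers,
    design_universal_primers,
    generate_panel,
)
from pestid.regions import conservation_profile, find_conserved_blocks, find_variable_regions

truth = generate_panel(PanelSpec(n_species=3, rng_seed=11))
msa = truth.msa
profile = conservation_profile(msa)
regions = find_variable_regions(profile, find_conserved_blocks(profile), msa)
region = regions[0]
constraints = PrimerConstraints()  # 30-35 nt, GC 0.20-0.70, amplicon 100-600

universal = design_universal_primers(region, msa, constraints)
print(f"{region.label}: {len(universal)} universal pair(s)")
pair = universal[0]
print(f"  fwd {pair.fwd_seq}")
print(f"  rev {pair.rev_seq}")
for sp, amp in pair.amplicon_len.items():
    print(f"  {sp}: amplicon {amp} bp (covers the whole region)")

specific = design_specific_primers(region, "sp1", msa, constraints)
print(f"\n{region.label}/sp1: {len(specific)} specific pair(s)")
pair = specific[0]
print(f"  fwd {pair.fwd_seq}")
print(f"  rev {pair.rev_seq}")
print(f"  amplicon {pair.amplicon_len['sp1']} bp")
for other, how in pair.fwd_discrimination.items():
    print(f"  fwd vs {other}: differs by {how}")

# Both primers of a specific pair differ from every non-target species by at
# least one mismatch or indel; RPA tolerates long primers, so no Tm model is
# applied — GC and homopolymer bounds stand in.
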