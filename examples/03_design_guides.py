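"""Enumerate Cas12a guide candidates and screen their cross-reactivity.

Guides are found on a linker-joined concatenation of every species' variable
regions (TTTV PAM, 20-nt protospacer) and mapped onto every other species
through the alignment.  A species escapes recognition when its PAM is
broken, an indel interrupts the window, or it carries >= 2 mismatches with
>= 1 in the 10-nt PAM-proximal seed.
"""

from pestid import PanelSpec, build_concatenated_template, generate_panel, plant_discriminating_site
from pestid.guides import design_guides
from pestid.regions import conservation_profile, find_conserved_blocks, find_variable_regions

# plant a window whose PAM is destroyed by a single T substitution in the
# non-target species: the canonical escape pattern
truth = plant_discriminating_site(
    generate_panel(PanelSpec(n_species=3, rng_seed=11)), "pam_loss_one_base"
)
msa = truth.msa
profile = conservation_profile(msa)
regions = find_variable_regions(profile, find_conserved_blocks(profile), msa)
template = build_concatenated_template(regions, msa)

guides = design_guides(template, msa)
by_verdict = {}
for g in guides:
    by_verdict.setdefault(g.verdict, []).append(g)
print(f"candidates: {len(guides)} "
      f"({', '.join(f'{k}: {len(v)}' for k, v in sorted(by_verdict.items()))})")

best = guides[0]  # ranked: specific verdicts first, widest escape margin first
print(f"\ntop guide {best.guide_id}")
print(f"  PAM {best.pam_seq}  protospacer {best.protospacer}  GC {best.gc_fraction:.2f}")
for rep in best.specificity:
    print(
        f"  vs {rep.species}: PAM intact={rep.pam_intact}, "
        f"mismatches={rep.total_mismatches} (seed {rep.seed_mismatches}), "
        f"indel={rep.indel_in_window} -> "
        f"{'cross-reactive' if rep.cross_reactive else 'escapes'}"
    )
print(f"  verdict: {best.verdict}")

site = truth.planted[0]
planted = next(
    g for g in guides
    if g.origin_species == site.origin_species and g.origin_interval == site.origin_interval
)
print(f"\nplanted PAM-loss site verdict: {planted.verdict} (expected {site.expected_verdict})")
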