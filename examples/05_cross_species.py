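"""Cross-species trend validation against two human cohort tables.

The synthetic cohorts keep the mouse fold-change sign for 75% of the
mapped significant genes, so the measured same-trend fraction should sit
near 75%, and the validated set (same sign, significant in mouse and both
cohorts) near 0.75^2 of the jointly significant genes.
"""

from fibronet import crossspecies as xs
from fibronet import differential as diff
from fibronet import simulate as sim

config = sim.SimConfig(n_genes=800, n_metabolites=10, seed=0)
counts, design, truth = sim.generate_counts(config)
mouse_d14 = diff.de_test(counts, design, "d14")

ortholog_map = sim.make_ortholog_map(counts.features)
cohort_a, cohort_b = sim.generate_cohort_tables(
    mouse_d14, ortholog_map, concordant_fraction=0.75, seed=0)

for name, cohort in [("cohort A", cohort_a), ("cohort B", cohort_b)]:
    pct, per_gene = xs.same_trend_fraction(mouse_d14, cohort, ortholog_map)
    joint = int((per_gene["mouse_sig"] & per_gene["cohort_sig"]).sum())
    print(f"{name}: {pct}% same trend over {joint} jointly significant genes")

validated, _ = xs.validated_set(mouse_d14, cohort_a, cohort_b, ortholog_map)
print(f"validated in mouse and both cohorts with one sign: {len(validated)} genes")

deg_mouse = set(mouse_d14.loc[mouse_d14["padj"] < 0.05, "feature"])
count, pct = xs.overlap_with_cohort(deg_mouse, cohort_a, ortholog_map)
print(f"mouse differential genes significant in cohort A: {count} ({pct}%)")
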