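"""Community shift under applied potential, on a synthetic pre/post survey.

Generates a Dirichlet-multinomial OTU table in which two families come to
dominate the post-treatment samples, then runs the full community pipeline:
alpha diversity (Shannon, observed species, Chao1, Faith PD), Bray-Curtis,
NMDS, PERMANOVA and per-family Welch tests with 95 % confidence intervals.
"""

import json
from pathlib import Path

from fermbal.community import (
    alpha_diversity_table,
    bray_curtis,
    family_profile,
    group_difference,
    nmds,
    permanova,
)
from fermbal.io import write_otu_table, write_taxonomy, write_tree
from fermbal.synthetic import CommunityScenario, make_community

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 20

scenario = CommunityScenario()  # 3+3 samples, 50 taxa, 12 families, 95 % dominance
counts, tree, taxonomy, metadata = make_community(scenario, seed=SEED)
write_otu_table(OUT / "otu_table.tsv", counts)
write_taxonomy(OUT / "taxonomy.tsv", taxonomy)
write_tree(OUT / "tree.nwk", tree)
metadata.to_csv(OUT / "sample_metadata.tsv", sep="\t")

alpha = alpha_diversity_table(counts, tree=tree)
alpha.to_csv(OUT / "alpha_diversity.tsv", sep="\t")
print("alpha diversity per sample:")
print(alpha.round(2).to_string())

dist = bray_curtis(counts)
ordination = nmds(dist, k=2, seed=SEED)
ordination.coordinates.to_csv(OUT / "nmds_coordinates.tsv", sep="\t")
perm = permanova(dist, metadata["group"].to_numpy(), n_permutations=9999, seed=SEED)
print(f"\nNMDS stress: {ordination.stress:.4f} ({ordination.n_iterations} iterations)")
print(
    f"PERMANOVA: R2 = {perm.r2:.3f}, pseudo-F = {perm.pseudo_f:.2f}, "
    f"p = {perm.p_value:.4f} ({perm.n_permutations} permutations)"
)

profile = family_profile(counts, taxonomy)
diffs = group_difference(profile, metadata["group"], "pre", "post").sort_values("p_value")
diffs.to_csv(OUT / "family_group_tests.tsv", sep="\t")
print("\nfamily-level pre/post differences (Welch t, 95 % CI):")
print(diffs.round(4).to_string())

dominant = profile.loc[
    metadata.index[metadata["group"] == "post"], ["family_A", "family_B"]
].sum(axis=1)
summary = {
    "nmds_stress": ordination.stress,
    "permanova_r2": perm.r2,
    "permanova_p": perm.p_value,
    "post_dominance_mean": float(dominant.mean()),
}
(OUT / "community_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
print(
    f"\nThe two shifted families hold {dominant.mean():.1%} of post-treatment reads "
    "(configured 95 %). PERMANOVA attributes "
    f"{perm.r2:.0%} of the distance variance to treatment; with triplicates the "
    "distinct 3+3 label permutations bound the attainable p at about 0.1."
)
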