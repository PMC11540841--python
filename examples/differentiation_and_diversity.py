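"""Diversity, Hardy-Weinberg, F-statistics and hierarchical AMOVA.

Produces the survey-style summary tables: per-site diversity with exact
HWE deviation counts, pairwise Weir-Cockerham FST with permutation
p-values (plus the UPGMA dendrogram over FST distances), and the
two-level AMOVA partitioning variation among habitats, among sites within
habitats, and within sites.
"""

import lanternpop as lp

gm, meta, truth = lp.simulate_dataset(lp.paper_like_preset(seed=2, scale=0.2))

div = lp.per_sample_diversity(gm, meta, by="site").table
hwe = lp.hwe_tests_per_sample(gm, meta, by="site")
q, sig = lp.bh_fdr(hwe["p"])
dev = hwe.assign(sig=sig).groupby("sample")["sig"].sum()
div["dev_hwe_fdr"] = dev
print("per-site diversity (first 6 sites):")
print(div[["n", "uhe_mean", "fis_mean", "dev_hwe_fdr"]].head(6).round(3))

h, p = lp.kruskal_wallis_groups(
    div["uhe_mean"].to_numpy(),
    [meta.group_of_site()[s] for s in div.index])
print(f"\nKruskal-Wallis uHe among habitats: H = {h:.2f}, p = {p:.2g}")

fst = lp.weir_cockerham_fst(gm, meta, by="group", n_perm=200, seed=0)
print("\npairwise habitat FST (lower triangle) / p-values (upper):")
print(fst.to_frame().round(3))

newick, order = lp.fst_dendrogram(fst)
print("\nUPGMA dendrogram:", newick)

am = lp.amova(gm, meta, by="site", groups="group", n_perm=200, seed=0)
print("\nhierarchical AMOVA:")
print(am.to_frame().round(3).to_string(index=False))
print({k: round(v, 4) for k, v in am.f_statistics.items()},
      "p:", {k: round(v, 4) for k, v in am.p_values.items()})
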