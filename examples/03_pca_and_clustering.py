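"""Correlation-matrix PCA and complete-linkage clustering of a cohort.

PC1 of the amino-acid frequency matrix tracks genomic %AT (the dominant
axis of compositional variation in prokaryotes); PC2 carries the
phylum signal.  The dendrogram provides the heatmap row order.
"""

import compbias as cb
from compbias.pipeline import AA_COLUMNS, profiles_to_frame

cohort = cb.simulate_cohort(cb.CohortConfig(
    n_phyla=10, genera_per_phylum=3, species_per_genus=2, seed=3,
))
profs, mets = cohort.profiles()
profiles = profiles_to_frame(profs, mets)
at = profiles["at_fraction"]
phylum = cohort.taxonomy.set_index("genome_id")["phylum"].reindex(profiles.index)

pca = cb.pca_correlation(profiles[AA_COLUMNS], at_vector=at)
r2_at, p_at = cb.regress_component_on_covariate(pca.scores["PC1"], at)
r2_ph, p_ph = cb.regress_component_on_covariate(pca.scores["PC2"], phylum)
print(f"PC1 explains {pca.variance_fraction[0]:.1%} of variance; "
      f"R^2(PC1, %AT) = {r2_at:.3f} (p = {p_at:.2g})")
print(f"R^2(PC2, phylum) = {r2_ph:.3f} (p = {p_ph:.2g})")

dend = cb.cluster_genomes(profiles[AA_COLUMNS])
ordered, _ = cb.export_heatmap_inputs(profiles[AA_COLUMNS], dend)
print(f"\ndendrogram: {len(dend.leaf_order)} leaves, "
      f"root height {dend.heights[-1]:.3f}")
print("first 6 leaves (heatmap row order):", dend.leaf_order[:6])
print("newick head:", cb.to_newick(dend)[:70], "...")
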