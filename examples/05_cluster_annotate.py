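"""Normalize, embed, cluster on the SNN graph, and annotate by markers.

Annotation assigns each cluster the cell type of its highest-z marker
(INS -> beta, GCG -> alpha, ...); clusters high in two hormones are flagged
as doublet suspects.
"""

from isletdeck import cluster as cl
from isletdeck.synthetic import SimulationConfig, simulate_cohort

cohort = simulate_cohort(
    SimulationConfig(seed=3, n_donors=(1, 0, 1), cells_per_donor=300,
                     n_genes=600, n_empty_droplets=500, n_variants=10)
)
filt = cohort.bundle.filtered["L00"]
norm = cl.lognormalize(filt)
hvg = cl.select_hvg(norm, n=300)
emb = cl.embed_pca(norm, hvg, n_pcs=20)
clustering = cl.snn_cluster(emb, k=20, resolution=1.0, seed=0)
ann = cl.annotate_clusters(clustering, norm)
print(ann[["cluster", "cell_type", "best_marker", "best_z", "multi_hormone"]]
      .to_string(index=False))

markers = cl.marker_de(norm, clustering.labels, target=0, family="logistic",
                       genes=hvg[:50])
top = markers.nlargest(3, "log2fc")[["gene", "log2fc", "fdr"]]
print("top markers of cluster 0:")
print(top.to_string(index=False))
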