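"""Cross-species conservation screens and kNN label transfer.

Two species-linked datasets share three matched clusters (AEC1 and AEC2
arterial populations and a VeEC venous population).  Conserved markers are
DEGs, in the same direction, in the matched contrast of both species;
conserved arterial genes must be up in all four arterial-vs-venous
comparisons.  Candidates are ranked by Fisher's combined P.
"""

import numpy as np

import avec

da, db, homologs, truth = avec.generate_two_species(avec.two_species_spec(seed=7))

def grp(ds, name):
    return list(ds.cell_meta.index[ds.cell_meta["cluster"] == name])

deg = {
    (sp, c): avec.wilcoxon_deg(d, grp(d, c), grp(d, "VeEC"))
    for sp, d in (("A", da), ("B", db)) for c in ("AEC1", "AEC2")
}

markers = avec.conserved_cluster_markers(deg[("A", "AEC1")], deg[("B", "AEC1")], homologs)
planted = truth.conserved_genes["AEC1"]
print(f"conserved AEC1 markers: {len(markers)} found, "
      f"{len(set(markers['gene']) & planted)}/{len(planted)} planted recovered")
print(markers.head(5)[["gene", "homolog", "p_a", "p_b", "combined_p"]])
# Species-specific genes (planted in only one species) never appear:
leak = set(markers["gene"]) & (truth.species_specific["A"] | truth.species_specific["B"])
print("species-specific leakage:", len(leak))

arterial = avec.conserved_arterial_genes(
    [deg[("A", "AEC1")], deg[("A", "AEC2")], deg[("B", "AEC1")], deg[("B", "AEC2")]],
    homologs,
)
print(f"\nconserved arterial genes (up in all four comparisons): {len(arterial)}")
print(arterial.head(5)[["gene", "homolog", "combined_p"]])

# transfer species-B cluster labels onto species-A cells in a shared PCA
rng = np.random.default_rng(0)
ref = avec.modified_pc_scores(db, n_top=60).to_numpy()
query = avec.modified_pc_scores(da, n_top=60).to_numpy()
pred = avec.knn_transfer(ref, db.cell_meta["cluster"].to_numpy(), query, k=15)
agree = (pred["label"].to_numpy() == da.cell_meta["cluster"].to_numpy()).mean()
print(f"\nkNN label transfer agreement in per-species PCA spaces: {agree:.2f}")
# (In practice the embedding would be a jointly integrated space; any shared
# embedding can be supplied.)
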