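# ishnet

Sparse gene-interaction networks from bags of spatially standardized
*in-situ-hybridization* (ISH) expression-pattern images.

## The problem

Whole-embryo ISH imaging (e.g. the Berkeley Drosophila Genome Project
collection) records *where* each gene is expressed, not just how much.
Two genes whose spatial patterns co-vary across the embryo are candidates
for a functional interaction — but each gene is observed as a **bag** of
one to a few images, images are not intensity-calibrated, and a naive
pairwise-correlation graph confounds direct and indirect dependence.

`ishnet` infers a **Gaussian graphical model** over genes from such data.
Each registered image is reduced to a fixed-length spatial feature vector
(median stain per triangle of a fixed Delaunay mesh over the standardized
embryo ellipse, m = 311 triangles by default). Treating the triangles as
i.i.d. spatial samples, gene similarity is computed with a
**multi-instance statistic kernel**

    K_ij = k( s(X_i), s(X_j) ),    k(u, v) = (1/m) Σ_l (u_l − ū)(v_l − v̄),

where s(·) is a per-dimension order statistic of the bag (the mean by
default; then K equals the mean pairwise covariance over all image pairs —
the normalized set kernel). The sparse precision matrix Θ is estimated by
the **graphical lasso**,

    Θ̂ = argmin_{Θ ≻ 0}  tr(K Θ) − log det Θ + λ‖Θ‖₁ ,

and the network's edges are the non-zero off-diagonals of Θ̂: gene pairs
that remain dependent after conditioning on all other genes. Downstream
analyses cover scale-free degree fits, spectral clustering with
within-cluster edge ratios, hypergeometric term enrichment (Bonferroni
corrected), hub selection, and neighbor-regression residue maps.

A fully seeded synthetic-data module generates miniature embryo image
corpora from known sparse Gaussian models, plus the dependent-sampling
study that probes how spatial correlation between samples affects network
recovery — so the entire pipeline is testable without any image downloads.

## Worked example

Generate a synthetic 40-gene corpus (8 planted modules of 5 genes, mean
degree 2, 1–5 noisy images per gene), run the full pipeline, and score it
against the known network:

```python
from ishnet import (
    planted_modules_precision, synth_embryo_dataset, run_pipeline,
    edge_precision_recall,
)

truth = planted_modules_precision(p=40)
ds = synth_embryo_dataset(truth=truth, seed=7)
res = run_pipeline(ds.manifest, config={"clusters": 8},
                   annotations=ds.annotations, images=ds.images)

net = res["network"]
index = {g: i for i, g in enumerate(ds.gene_ids)}
est = {tuple(sorted((index[a], index[b]))) for a, b in net.edges}
precision, recall = edge_precision_recall(est, truth.true_edges)
print(f"network: {net.n_genes} genes, {len(net.edges)} edges "
      f"(mean degree {net.mean_degree:.2f})")
print(f"edge recovery: precision = {precision:.3f}, recall = {recall:.3f}")
print(f"within-cluster edge ratio = {res['analysis']['within_cluster_ratio']:.3f}")
```

prints

```
network: 40 genes, 42 edges (mean degree 2.10)
edge recovery: precision = 0.667, recall = 0.700
within-cluster edge ratio = 1.000
```

That is: from 108 rendered images the pipeline selects λ by the
mean-degree rule (target 2–3), recovers 28 of the 40 planted conditional-
dependence edges with two thirds of predicted edges correct, and every
edge of the estimated network stays inside a spectral cluster — the
planted modular structure. All 8 clusters are significantly enriched for
their planted annotation term (hypergeometric test, Bonferroni-corrected
p < 0.05).

The same stages are available from the shell:

```bash
ishnet simulate --out sim --seed 7 --genes 40
ishnet run --manifest sim/manifest.tsv --annotations sim/annotations.tsv \
           --out results_dir --seed 7
# or stage by stage:
ishnet featurize --manifest sim/manifest.tsv --out features.tsv --mesh-size 311
ishnet select    --features features.tsv --tau 0.1 --out selected.tsv
ishnet kernel    --bags selected.tsv --statistic mean --out K.tsv
ishnet network   --kernel K.tsv --lambda-grid 0.5:1.0:21 --out-prefix net
ishnet analyze   --network net_edges.tsv --clusters 12 --out-prefix analysis
```

Networks are exported as edge-list TSV and Cytoscape-readable SIF.

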