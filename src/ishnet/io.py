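"""File formats, configuration, and the end-to-end pipeline driver.

Everything on disk is plain text: feature matrices, kernels, edge lists and
annotations are TSV; networks are additionally exported as SIF
(``gene_a<TAB>interacts<TAB>gene_b``) for Cytoscape; images are 8-bit
grayscale rasters.  The driver chains featurize -> normalize/select -> bags
-> kernel -> graphical lasso -> analyses, writing every intermediate
artifact, so any stage can be rerun or inspected in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .glasso import (
    GraphicalLassoPath,
    KernelGraphicalLasso,
    SparseNetwork,
)
from .kernel import KernelMatrix, MultiInstanceKernel, clip_psd
from .mesh import TriangleFeaturizer
from .netanalysis import (
    degree_ccdf_power_law,
    enrichment_test,
    select_hubs,
    spectral_cluster,
    within_cluster_edge_ratio,
)
from .preprocess import FeatureMatrix, VarianceSelector, assemble_gene_bags

logger = logging.getLogger(__name__)

__all__ = [
    "read_manifest",
    "read_image",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_kernel_matrix",
    "write_kernel_matrix",
    "write_edge_list",
    "read_edge_list",
    "write_sif",
    "read_annotations",
    "read_config",
    "default_config",
    "run_pipeline",
]


class ParseError(ValueError):
    """Malformed input file (carries the offending line number)."""


def read_manifest(path) -> pd.DataFrame:
    """TSV of (gene_id, image_path[, stage]); image paths checked at read time."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "image_path"}
    if not required <= set(df.columns):
        raise ParseError(f"manifest must have columns {sorted(required)}")
    if df.empty:
        raise ValueError("manifest is empty: nothing to analyze")
    if "stage" not in df.columns:
        df["stage"] = ""
    base = Path(path).parent
    missing = []
    resolved = []
    for i, rel in enumerate(df["image_path"]):
        p = Path(rel)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            missing.append((i + 2, rel))  # +2: header + 1-based
        resolved.append(str(p))
    if missing:
        line, rel = missing[0]
        raise ParseError(f"manifest line {line}: image not found: {rel}")
    df["image_path"] = resolved
    return df


def read_image(path) -> np.ndarray:
    """Read a raster image as 8-bit grayscale intensities (H, W) in [0, 255]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float)


def write_feature_matrix(F: FeatureMatrix, path) -> None:
    F.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_matrix(path, tau: float | None = None) -> FeatureMatrix:
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed feature TSV {path}: {exc}") from exc
    kwargs = {} if tau is None else {"tau": tau}
    return FeatureMatrix.from_frame(df, **kwargs)


def write_kernel_matrix(K: KernelMatrix, path) -> None:
    df = pd.DataFrame(K.values, index=K.gene_ids, columns=K.gene_ids)
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_kernel_matrix(path) -> KernelMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed kernel TSV {path}: {exc}") from exc
    if list(df.index) != list(df.columns):
        raise ParseError(f"kernel TSV {path}: row and column gene ids differ")
    return KernelMatrix(values=df.to_numpy(dtype=float), gene_ids=list(df.columns))


def write_edge_list(network: SparseNetwork, path) -> None:
    """TSV of (gene_a, gene_b, theta_ij), sorted for byte-stable output."""
    index = {g: i for i, g in enumerate(network.gene_ids)}
    rows = [
        {"gene_a": a, "gene_b": b, "theta_ij": network.theta[index[a], index[b]]}
        for a, b in sorted(network.edges)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "theta_ij"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_edge_list(path) -> set:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return {tuple(sorted((a, b))) for a, b in zip(df["gene_a"], df["gene_b"])}


def write_sif(network: SparseNetwork, path) -> None:
    """Cytoscape SIF export: one ``gene_a interacts gene_b`` line per edge."""
    with open(path, "w") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\tinteracts\t{b}\n")


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term"} <= set(df.columns):
        raise ParseError("annotation TSV must have columns gene_id, term")
    return df


def default_config() -> dict:
    """Every pipeline parameter with its canonical default."""
    return {
        "tau": 0.1,  # variance threshold
        "lambda": None,  # fixed penalty (overrides the grid when set)
        "lambda_grid": "0.5:1.0:21",
        "select_mean_degree": "2:3",
        "scale_by_diagonal": True,
        "penalize_diagonal": True,
        "statistic": "mean",
        "mesh_size": 311,
        "aspect_ratio": 2.0,
        "clusters": 12,
        "hub_fraction": 0.05,
        "stage": "",
        "seed": 0,
    }


_BOOL_KEYS = {"scale_by_diagonal", "penalize_diagonal"}
_INT_KEYS = {"mesh_size", "clusters", "seed"}
_FLOAT_KEYS = {"tau", "lambda", "aspect_ratio", "hub_fraction"}


def read_config(path) -> dict:
    """Flat ``key = value`` text file layered over the defaults."""
    config = default_config()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path} line {lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in config:
                raise ParseError(f"{path} line {lineno}: unknown key {key!r}")
            if key in _BOOL_KEYS:
                config[key] = value.lower() in ("1", "true", "yes")
            elif key in _INT_KEYS:
                config[key] = int(value)
            elif key in _FLOAT_KEYS:
                config[key] = float(value)
            else:
                config[key] = value
    return config


def _parse_grid(spec: str) -> np.ndarray:
    lo, hi, num = spec.split(":")
    return np.linspace(float(lo), float(hi), int(num))


def _parse_interval(spec: str) -> tuple[float, float]:
    lo, hi = spec.split(":")
    return float(lo), float(hi)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(
    manifest: pd.DataFrame | str,
    config: dict | None = None,
    outdir=None,
    annotations: pd.DataFrame | None = None,
    images: dict | None = None,
) -> dict:
    """Run the full network-inference pipeline from a manifest of images.

    Stages: featurize every image on the standard mesh; normalize and apply
    the alternating variance filter; assemble per-gene bags; compute the
    multi-instance kernel; estimate the sparse precision matrix (fixed
    lambda, or mean-degree selection along the grid); run the downstream
    analyses.  Every intermediate artifact is written under ``outdir`` when
    given.  ``images`` may supply in-memory arrays keyed by the manifest's
    image_path, bypassing disk reads (used by the synthetic corpus).

    Returns a dict of all stage products; failures raise with a
    stage-tagged message and leave earlier artifacts in place.
    """
    cfg = default_config()
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    if isinstance(manifest, (str, Path)):
        manifest = read_manifest(manifest)
    if manifest.empty:
        raise ValueError("manifest is empty: nothing to analyze")
    if cfg["stage"]:
        manifest = manifest[manifest["stage"] == cfg["stage"]]
        if manifest.empty:
            raise ValueError(f"no images with stage label {cfg['stage']!r}")
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    results: dict = {"config": dict(cfg)}
    try:
        _stage("featurize")
        key_col = "image_path" if "image_path" in manifest.columns else "image_id"
        arrays = []
        for key in manifest[key_col]:
            if images is not None and key in images:
                arrays.append(np.asarray(images[key], dtype=float))
            else:
                arrays.append(read_image(key))
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError(f"images have inconsistent shapes: {shapes}")
        featurizer = TriangleFeaturizer(
            aspect_ratio=cfg["aspect_ratio"],
            n_triangles=cfg["mesh_size"],
            frame_shape=arrays[0].shape,
        ).fit()
        values = featurizer.transform(arrays)
        image_ids = (
            manifest["image_id"]
            if "image_id" in manifest.columns
            else manifest[key_col]
        ).tolist()
        F = FeatureMatrix(
            values=values,
            image_ids=image_ids,
            gene_ids=manifest["gene_id"].tolist(),
            triangle_ids=[f"triangle_{t}" for t in range(values.shape[1])],
            tau=cfg["tau"],
        )
        results["features_raw"] = F
        results["mesh"] = featurizer.mesh_
        if out is not None:
            write_feature_matrix(F, out / "features.tsv")
    except Exception as exc:
        raise RuntimeError(f"[featurize] {exc}") from exc

    try:
        _stage("select")
        selector = VarianceSelector(tau=cfg["tau"])
        F_sel = selector.fit_transform(F)
        results["features"] = F_sel
        results["dropped_genes"] = selector.dropped_genes_
        logger.info(
            "kept %d/%d images, %d/%d features; dropped genes: %d",
            len(selector.kept_image_ids_),
            len(F.image_ids),
            len(selector.kept_triangle_ids_),
            len(F.triangle_ids),
            len(selector.dropped_genes_),
        )
        if out is not None:
            write_feature_matrix(F_sel, out / "features_selected.tsv")
            (out / "selection_log.tsv").write_text(
                "dropped_gene\n"
                + "".join(f"{g}\n" for g in selector.dropped_genes_)
            )
        bags = assemble_gene_bags(F_sel)
        results["bags"] = bags
    except Exception as exc:
        raise RuntimeError(f"[select] {exc}") from exc

    try:
        _stage("kernel")
        K = MultiInstanceKernel(statistic=cfg["statistic"]).transform(bags)
        K.values = clip_psd(K.values)
        results["kernel"] = K
        if out is not None:
            write_kernel_matrix(K, out / "kernel.tsv")
    except Exception as exc:
        raise RuntimeError(f"[kernel] {exc}") from exc

    try:
        _stage("network")
        if cfg["lambda"] is not None:
            est = KernelGraphicalLasso(
                alpha=float(cfg["lambda"]),
                penalize_diagonal=cfg["penalize_diagonal"],
            ).fit(K)
            network = est.network_
        else:
            est = GraphicalLassoPath(
                alphas=_parse_grid(cfg["lambda_grid"]),
                target_mean_degree=_parse_interval(cfg["select_mean_degree"]),
                scale_by_diagonal=cfg["scale_by_diagonal"],
                penalize_diagonal=cfg["penalize_diagonal"],
            ).fit(K)
            network = est.network_
            results["lambda_path"] = est.path_
        results["network"] = network
        logger.info(
            "network: %d genes, %d edges (lambda=%.4g)",
            network.n_genes,
            len(network.edges),
            network.lam,
        )
        if out is not None:
            write_edge_list(network, out / "network_edges.tsv")
            write_sif(network, out / "network.sif")
            pd.DataFrame(
                network.theta, index=network.gene_ids, columns=network.gene_ids
            ).to_csv(out / "theta.tsv", sep="\t", index_label="gene_id")
    except Exception as exc:
        raise RuntimeError(f"[network] {exc}") from exc

    try:
        _stage("analyze")
        analysis: dict = {}
        if network.edges:
            n_clusters = min(cfg["clusters"], network.n_genes)
            labels = spectral_cluster(network, k=n_clusters, seed=cfg["seed"])
            analysis["clusters"] = labels
            analysis["within_cluster_ratio"] = within_cluster_edge_ratio(
                network, labels
            )
            analysis["hubs"] = select_hubs(network, cfg["hub_fraction"])
            try:
                analysis["power_law"] = degree_ccdf_power_law(network)
            except ValueError:
                analysis["power_law"] = None  # degenerate degree distribution
            if annotations is not None:
                background = list(network.gene_ids)
                enrich = []
                for c in sorted(set(labels.values())):
                    members = [g for g, lab in labels.items() if lab == c]
                    enrich.extend(
                        enrichment_test(
                            members, annotations, background, cluster_id=c
                        )
                    )
                analysis["enrichment"] = enrich
            if out is not None:
                pd.DataFrame(
                    sorted(labels.items()), columns=["gene_id", "cluster"]
                ).to_csv(out / "clusters.tsv", sep="\t", index=False)
                (out / "hubs.tsv").write_text(
                    "gene_id\n" + "".join(f"{g}\n" for g in sorted(analysis["hubs"]))
                )
                if annotations is not None:
                    pd.DataFrame([vars(e) for e in analysis["enrichment"]]).to_csv(
                        out / "enrichment.tsv", sep="\t", index=False
                    )
        results["analysis"] = analysis
    except Exception as exc:
        raise RuntimeError(f"[analyze] {exc}") from exc

    if out is not None:
        run_record = {
            "ishnet_version": __version__,
            "seed": cfg["seed"],
            "config": {k: str(v) for k, v in cfg.items()},
            "config_hash": _config_hash(cfg),
            "n_images": int(len(manifest)),
            "n_genes_network": int(network.n_genes),
            "n_edges": int(len(network.edges)),
        }
        (out / "run_manifest.json").write_text(
            json.dumps(run_record, indent=2, sort_keys=True) + "\n"
        )
    return results
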