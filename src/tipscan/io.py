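"""Reading/writing counts and running the full pipeline.

On disk a dataset is either a pair of MatrixMarket matrices (one per layer,
cells x genes) with per-layer cell/gene CSVs plus an ordering CSV, or a
single ``.h5ad`` file with layers named ``"unspliced"`` and ``"spliced"``.
Cells and genes present in both layers are aligned by name intersection in
the order of the unspliced file; mismatches are dropped with a logged count.

``run_pipeline`` chains gene selection, the sliding-window scan, the
per-cell instability score and the per-window GRN/community analysis, and
writes CSV/GraphML/JSON outputs plus a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from . import __version__
from .grn import COMMUNITY_ALGORITHMS, build_grn, community_trajectory
from .model import SplicingModelFit
from .windows import (
    LineageStabilityProfile,
    SplicingCounts,
    WindowConfig,
    instability_score,
    scan_lineage,
    select_genes,
)

logger = logging.getLogger("tipscan")

__all__ = [
    "RunConfig",
    "read_counts",
    "read_counts_mtx",
    "read_counts_h5ad",
    "write_counts_mtx",
    "write_counts_h5ad",
    "write_fits",
    "read_fits",
    "write_grns",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# counts I/O
# ---------------------------------------------------------------------------


def _read_layer(prefix: str | Path):
    prefix = Path(prefix)
    raw = mmread(f"{prefix}.mtx")
    matrix = np.asarray(raw.todense() if hasattr(raw, "todense") else raw)
    cells = pd.read_csv(f"{prefix}_cells.csv")["cell_id"].astype(str).tolist()
    genes = pd.read_csv(f"{prefix}_genes.csv")["gene"].astype(str).tolist()
    if len(set(genes)) != len(genes):
        raise ValueError(f"duplicate gene names in {prefix}_genes.csv")
    if matrix.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix {prefix}.mtx has shape {matrix.shape}, expected "
            f"({len(cells)}, {len(genes)})"
        )
    return matrix, cells, genes


def read_counts_mtx(
    unspliced_prefix: str | Path,
    spliced_prefix: str | Path,
    ordering_csv: str | Path,
) -> SplicingCounts:
    """Load a dataset stored as per-layer MTX + cell/gene CSV triplets.

    Each layer consists of ``<prefix>.mtx`` (cells x genes),
    ``<prefix>_cells.csv`` (column ``cell_id``) and ``<prefix>_genes.csv``
    (column ``gene``).  ``ordering_csv`` has columns ``cell_id``,
    ``ordering`` and optionally ``branch``.  Layers are aligned on the
    intersection of cell and gene names, in unspliced-file order; dropped
    cells/genes are logged.
    """
    u_mat, u_cells, u_genes = _read_layer(unspliced_prefix)
    s_mat, s_cells, s_genes = _read_layer(spliced_prefix)

    shared_cells = [c for c in u_cells if c in set(s_cells)]
    shared_genes = [g for g in u_genes if g in set(s_genes)]
    n_dropped = (len(u_cells) - len(shared_cells)) + (len(s_cells) - len(shared_cells))
    if n_dropped:
        logger.warning("dropped %d cell(s) present in only one layer", n_dropped)
    if len(shared_genes) < len(u_genes) or len(shared_genes) < len(s_genes):
        logger.warning(
            "dropped %d gene(s) present in only one layer",
            len(u_genes) + len(s_genes) - 2 * len(shared_genes),
        )
    u_cell_idx = {c: i for i, c in enumerate(u_cells)}
    s_cell_idx = {c: i for i, c in enumerate(s_cells)}
    u_gene_idx = {g: i for i, g in enumerate(u_genes)}
    s_gene_idx = {g: i for i, g in enumerate(s_genes)}
    u_aligned = u_mat[np.ix_([u_cell_idx[c] for c in shared_cells], [u_gene_idx[g] for g in shared_genes])]
    s_aligned = s_mat[np.ix_([s_cell_idx[c] for c in shared_cells], [s_gene_idx[g] for g in shared_genes])]

    meta = (
        pd.read_csv(ordering_csv, float_precision="round_trip")
        .astype({"cell_id": str})
        .set_index("cell_id")
    )
    missing = [c for c in shared_cells if c not in meta.index]
    if missing:
        raise ValueError(f"{len(missing)} cell(s) lack an ordering value, e.g. {missing[:3]}")
    ordering = meta.loc[shared_cells, "ordering"].to_numpy(dtype=float)
    branches = (
        meta.loc[shared_cells, "branch"].to_numpy() if "branch" in meta.columns else None
    )
    return SplicingCounts(
        unspliced=u_aligned,
        spliced=s_aligned,
        gene_names=shared_genes,
        cell_ids=shared_cells,
        ordering=ordering,
        branch_labels=branches,
    )


def read_counts_h5ad(
    path: str | Path,
    ordering_key: str = "ordering",
    branch_key: str | None = "branch",
) -> SplicingCounts:
    """Load a dataset from an AnnData file with unspliced/spliced layers.

    Layers are mapped by name (``"unspliced"``/``"spliced"``), never by
    position; the ordering is taken from ``adata.obs[ordering_key]``.
    """
    adata = ad.read_h5ad(path)
    for layer in ("unspliced", "spliced"):
        if layer not in adata.layers:
            raise KeyError(f"layer {layer!r} missing from {path}")
    if ordering_key not in adata.obs:
        raise KeyError(f"obs column {ordering_key!r} missing from {path}")

    def dense(x):
        return np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)

    branches = None
    if branch_key is not None and branch_key in adata.obs:
        branches = adata.obs[branch_key].to_numpy()
    return SplicingCounts(
        unspliced=dense(adata.layers["unspliced"]),
        spliced=dense(adata.layers["spliced"]),
        gene_names=adata.var_names.tolist(),
        cell_ids=adata.obs_names.tolist(),
        ordering=adata.obs[ordering_key].to_numpy(dtype=float),
        branch_labels=branches,
    )


def read_counts(
    unspliced: str | Path | None = None,
    spliced: str | Path | None = None,
    ordering: str | Path | None = None,
    h5ad: str | Path | None = None,
) -> SplicingCounts:
    """Dispatch to the MTX-triplet or h5ad reader."""
    if h5ad is not None:
        return read_counts_h5ad(h5ad)
    if unspliced is None or spliced is None or ordering is None:
        raise ValueError("provide either h5ad= or unspliced=, spliced= and ordering=")
    return read_counts_mtx(unspliced, spliced, ordering)


def write_counts_mtx(counts: SplicingCounts, outdir: str | Path) -> dict[str, Path]:
    """Write MTX + CSV triplets (re-readable by :func:`read_counts_mtx`)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for layer, matrix in (("unspliced", counts.unspliced), ("spliced", counts.spliced)):
        prefix = outdir / layer
        mmwrite(f"{prefix}.mtx", csr_matrix(matrix), precision=17)
        pd.DataFrame({"cell_id": counts.cell_ids}).to_csv(f"{prefix}_cells.csv", index=False)
        pd.DataFrame({"gene": counts.gene_names}).to_csv(f"{prefix}_genes.csv", index=False)
        paths[layer] = prefix
    meta = pd.DataFrame({"cell_id": counts.cell_ids, "ordering": counts.ordering})
    if counts.branch_labels is not None:
        meta["branch"] = counts.branch_labels
    # %.17g keeps doubles bit-exact through the round trip
    meta.to_csv(outdir / "ordering.csv", index=False, float_format="%.17g")
    paths["ordering"] = outdir / "ordering.csv"
    return paths


def write_counts_h5ad(counts: SplicingCounts, path: str | Path) -> Path:
    """Write an AnnData file with unspliced/spliced layers (X = spliced)."""
    obs = pd.DataFrame(index=pd.Index(counts.cell_ids, name="cell_id"))
    obs["ordering"] = counts.ordering
    if counts.branch_labels is not None:
        obs["branch"] = counts.branch_labels
    adata = ad.AnnData(
        X=counts.spliced.copy(),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(counts.gene_names, name="gene")),
        layers={"unspliced": counts.unspliced.copy(), "spliced": counts.spliced.copy()},
    )
    adata.write_h5ad(path)
    return Path(path)


# ---------------------------------------------------------------------------
# fit persistence and GRN export
# ---------------------------------------------------------------------------


def write_fits(profile: LineageStabilityProfile, path: str | Path) -> Path:
    """Serialize the per-window full fits (and sender expressions) to JSON."""
    windows = []
    for w, fit in enumerate(profile.fits):
        entry: dict = {"window": w, "position": float(profile.window_positions[w])}
        if fit is not None:
            entry.update(
                genes=fit.gene_names,
                intercepts=fit.intercepts.tolist(),
                interaction_matrix=fit.interaction_matrix.tolist(),
                beta=fit.beta,
                gammas=[g if np.isfinite(g) else None for g in fit.gammas],
                shrinkage=fit.shrinkage,
                regression_kind=fit.regression_kind,
                mean_expression=profile.mean_expression[w].tolist(),
            )
        windows.append(entry)
    payload = {"gene_names": profile.gene_names, "windows": windows}
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def read_fits(path: str | Path) -> list[tuple[float, SplicingModelFit | None, np.ndarray | None]]:
    """Load fits written by :func:`write_fits` as (position, fit, mean_expression)."""
    payload = json.loads(Path(path).read_text())
    out = []
    for entry in payload["windows"]:
        if "interaction_matrix" not in entry:
            out.append((entry["position"], None, None))
            continue
        fit = SplicingModelFit(
            gene_names=entry["genes"],
            intercepts=np.asarray(entry["intercepts"]),
            interaction_matrix=np.asarray(entry["interaction_matrix"]),
            beta=entry["beta"],
            gammas=np.asarray([np.nan if g is None else g for g in entry["gammas"]]),
            shrinkage=entry["shrinkage"],
            regression_kind=entry["regression_kind"],
        )
        out.append((entry["position"], fit, np.asarray(entry["mean_expression"])))
    return out


def write_grns(
    profile: LineageStabilityProfile,
    outdir: str | Path,
    edge_threshold: float = 0.75,
) -> list[Path]:
    """Export each window's GRN as an edge-list CSV and a GraphML file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for w, fit in enumerate(profile.fits):
        if fit is None:
            continue
        usable = fit.drop_missing()
        keep = [profile.gene_names.index(g) for g in usable.gene_names]
        graph = build_grn(usable, profile.mean_expression[w][keep], edge_threshold)
        rows = [
            {"source": u, "target": v, "sign": d["sign"], "weight": d["weight"]}
            for u, v, d in graph.edges(data=True)
        ]
        csv_path = outdir / f"window_{w:03d}_edges.csv"
        pd.DataFrame(rows, columns=["source", "target", "sign", "weight"]).to_csv(
            csv_path, index=False
        )
        graphml_path = outdir / f"window_{w:03d}.graphml"
        nx.write_graphml(graph, graphml_path)
        written += [csv_path, graphml_path]
    return written


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run (JSON round-trippable)."""

    unspliced: str | None = None
    spliced: str | None = None
    ordering: str | None = None
    h5ad: str | None = None
    gene_list: str | None = None
    outdir: str = "tipscan_out"
    width: int = 100
    increment: int = 10
    n_genes: int = 10
    n_iterations: int = 10
    subsample_fraction: float = 0.9
    regression_kind: str = "linear"
    shrinkage: float = 0.0
    beta: float = 1.0
    seed: int = 0
    smoothing_sigma: float = 1.0
    edge_threshold: float = 0.75
    algorithms: tuple[str, ...] = COMMUNITY_ALGORITHMS
    log_level: str = "INFO"

    def window_config(self) -> WindowConfig:
        return WindowConfig(
            width=self.width,
            increment=self.increment,
            n_genes=self.n_genes,
            n_iterations=self.n_iterations,
            subsample_fraction=self.subsample_fraction,
            regression_kind=self.regression_kind,
            shrinkage=self.shrinkage,
            beta=self.beta,
            seed=self.seed,
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        payload["algorithms"] = list(self.algorithms)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        payload["algorithms"] = tuple(payload.get("algorithms", COMMUNITY_ALGORITHMS))
        return cls(**payload)


def _scan_one(counts: SplicingCounts, cfg: RunConfig) -> LineageStabilityProfile:
    return scan_lineage(counts, cfg.window_config())


def run_pipeline(cfg: RunConfig, counts: SplicingCounts | None = None) -> dict:
    """Execute gene selection, lineage scan, scoring and GRN analysis.

    Outputs under ``cfg.outdir``: ``profile_summary.csv`` and
    ``profile_iterations.csv`` (per branch when branch labels are present),
    ``cell_scores.csv``, ``communities.csv``, ``fits.json``, per-window GRN
    edge lists/GraphML under ``grn/`` and a JSON ``manifest.json``.
    Deterministic for a fixed config and seed.  Returns a dict with the
    in-memory results.
    """
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "read_counts"
    try:
        if counts is None:
            counts = read_counts(cfg.unspliced, cfg.spliced, cfg.ordering, cfg.h5ad)
        stage = "select_genes"
        user_list = None
        if cfg.gene_list:
            user_list = [
                line.strip() for line in Path(cfg.gene_list).read_text().splitlines() if line.strip()
            ]
            counts = select_genes(counts, user_list=user_list)
        elif cfg.n_genes < counts.n_genes:
            counts = select_genes(counts, n_genes=cfg.n_genes)

        stage = "scan_lineage"
        profiles: dict[str, LineageStabilityProfile] = {}
        if counts.branch_labels is not None:
            for branch in sorted(set(map(str, counts.branch_labels))):
                mask = np.asarray([str(b) == branch for b in counts.branch_labels])
                profiles[branch] = _scan_one(counts.subset_cells(np.flatnonzero(mask)), cfg)
        else:
            profiles["lineage"] = _scan_one(counts, cfg)

        for name, profile in profiles.items():
            prefix = f"{name}_" if len(profiles) > 1 else ""
            profile.summary.to_csv(outdir / f"{prefix}profile_summary.csv")
            profile.iterations.to_csv(outdir / f"{prefix}profile_iterations.csv", index=False)
            write_fits(profile, outdir / f"{prefix}fits.json")
            write_grns(profile, outdir / f"{prefix}grn", cfg.edge_threshold)

        stage = "instability_score"
        if counts.branch_labels is not None:
            score = instability_score(profiles, counts, cfg.smoothing_sigma)
        else:
            score = instability_score(profiles["lineage"], counts, cfg.smoothing_sigma)
        scores = pd.DataFrame(
            {"cell_id": score.cell_ids, "ordering": counts.ordering, "instability": score.global_score}
        )
        for branch, values in score.branch_scores.items():
            scores[f"instability_{branch}"] = values
        scores.to_csv(outdir / "cell_scores.csv", index=False)

        stage = "community_trajectory"
        communities = {
            name: community_trajectory(
                profile, algorithms=cfg.algorithms, edge_threshold=cfg.edge_threshold
            )
            for name, profile in profiles.items()
        }
        combined = pd.concat(communities, names=["lineage", "window"])
        combined.to_csv(outdir / "communities.csv")
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest = {
        "config": json.loads(json.dumps(dataclasses.asdict(cfg), default=list)),
        "seed": cfg.seed,
        "package_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "n_cells": counts.n_cells,
        "n_genes": counts.n_genes,
        "branches": sorted(profiles) if counts.branch_labels is not None else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "counts": counts,
        "profiles": profiles,
        "score": score,
        "communities": combined,
        "manifest": manifest,
    }
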