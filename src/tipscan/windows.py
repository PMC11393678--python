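"""Sliding-window inference of cell-state stability along a lineage.

Cells are sorted by a lineage-ordering scalar (pseudotime or experimental
time rank), a fixed-size window of cells is slid along the ordering, and in
each window the linear splicing model is fitted by regressing each gene's
unspliced counts on the spliced counts of all other genes.  The spectrum of
the per-window Jacobian yields stability metrics; repeating each fit on
random cell subsamples yields iteration error bars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.linear_model import Lasso, LinearRegression, Ridge

from .model import JacobianSpectrum, SplicingModelFit, assemble_jacobian

__all__ = [
    "SplicingCounts",
    "WindowConfig",
    "LineageStabilityProfile",
    "InstabilityScore",
    "select_genes",
    "make_windows",
    "fit_window",
    "scan_lineage",
    "smooth_profile",
    "instability_score",
    "signature_score",
]


@dataclass
class SplicingCounts:
    """Paired unspliced/spliced count matrices with a per-cell lineage ordering.

    ``unspliced`` and ``spliced`` are cells x genes arrays sharing shape and
    gene order; ``ordering`` is a finite per-cell scalar (pseudotime, or the
    rank of an experimental time label); ``branch_labels`` optionally assigns
    each cell to a branch of a multi-fate lineage.
    """

    unspliced: np.ndarray
    spliced: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    ordering: np.ndarray
    branch_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.unspliced = np.asarray(self.unspliced, dtype=float)
        self.spliced = np.asarray(self.spliced, dtype=float)
        self.ordering = np.asarray(self.ordering, dtype=float)
        self.gene_names = list(self.gene_names)
        self.cell_ids = list(self.cell_ids)
        n, m = self.unspliced.shape
        if self.spliced.shape != (n, m):
            raise ValueError(
                f"unspliced {self.unspliced.shape} and spliced "
                f"{self.spliced.shape} shapes differ"
            )
        if len(self.gene_names) != m:
            raise ValueError("gene_names length does not match matrix columns")
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match matrix rows")
        if self.ordering.shape != (n,):
            raise ValueError("ordering must be one value per cell")
        if not np.all(np.isfinite(self.ordering)):
            raise ValueError("ordering contains non-finite values")
        if n < 2:
            raise ValueError("need at least 2 cells")
        if len(set(self.gene_names)) != m:
            raise ValueError("duplicate gene names")
        if self.branch_labels is not None:
            self.branch_labels = np.asarray(self.branch_labels)
            if self.branch_labels.shape != (n,):
                raise ValueError("branch_labels must be one label per cell")

    @property
    def n_cells(self) -> int:
        return self.unspliced.shape[0]

    @property
    def n_genes(self) -> int:
        return self.unspliced.shape[1]

    def subset_cells(self, indices: np.ndarray) -> "SplicingCounts":
        idx = np.asarray(indices, dtype=int)
        return SplicingCounts(
            unspliced=self.unspliced[idx],
            spliced=self.spliced[idx],
            gene_names=self.gene_names,
            cell_ids=[self.cell_ids[i] for i in idx],
            ordering=self.ordering[idx],
            branch_labels=None if self.branch_labels is None else self.branch_labels[idx],
        )

    def subset_genes(self, indices: np.ndarray) -> "SplicingCounts":
        idx = np.asarray(indices, dtype=int)
        return SplicingCounts(
            unspliced=self.unspliced[:, idx],
            spliced=self.spliced[:, idx],
            gene_names=[self.gene_names[i] for i in idx],
            cell_ids=self.cell_ids,
            ordering=self.ordering,
            branch_labels=self.branch_labels,
        )

    def sorted_by_ordering(self) -> "SplicingCounts":
        """Cells sorted by ordering value; ties broken by cell id (stable)."""
        order = sorted(range(self.n_cells), key=lambda i: (self.ordering[i], self.cell_ids[i]))
        return self.subset_cells(np.asarray(order))


@dataclass
class WindowConfig:
    """Free parameters of the sliding-window inference scheme.

    ``width`` (cells per window) and ``increment`` (cells advanced between
    windows) control resolution along the lineage; ``n_genes`` how many
    top-expressed genes enter the model; ``n_iterations`` how many random
    subsample fits (of ``subsample_fraction`` of the window's cells) produce
    the per-window error bars.
    """

    width: int = 100
    increment: int = 10
    n_genes: int = 10
    n_iterations: int = 10
    subsample_fraction: float = 0.9
    regression_kind: str = "linear"
    shrinkage: float = 0.0
    beta: float = 1.0
    seed: int = 0
    min_cells: int = 2

    def __post_init__(self) -> None:
        if self.width < self.min_cells:
            raise ValueError("window width below minimum usable cell count")
        if self.increment < 1:
            raise ValueError("increment must be >= 1")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.regression_kind not in {"linear", "ridge", "lasso"}:
            raise ValueError(f"unknown regression_kind {self.regression_kind!r}")
        if self.shrinkage < 0:
            raise ValueError("shrinkage must be nonnegative")


@dataclass
class LineageStabilityProfile:
    """Per-window stability metrics along one lineage.

    ``iterations`` holds one row per window x iteration; ``summary`` one row
    per window with the mean and standard deviation of each spectral metric
    over iterations.  ``fits`` stores the full-window model fit used for GRN
    reconstruction, and ``mean_expression`` the per-window per-gene mean
    spliced expression (the "sender" expression used to rescale GRN edges).
    """

    window_positions: np.ndarray
    window_ranges: list[tuple[int, int]]
    iterations: pd.DataFrame
    summary: pd.DataFrame
    fits: list[SplicingModelFit | None]
    mean_expression: np.ndarray
    gene_names: list[str]
    config: WindowConfig

    @property
    def n_windows(self) -> int:
        return len(self.window_ranges)


@dataclass
class InstabilityScore:
    """Per-cell instability scores (nonnegative; 0 in stable regions)."""

    cell_ids: list[str]
    global_score: np.ndarray
    branch_scores: dict[str, np.ndarray] = field(default_factory=dict)


def select_genes(
    counts: SplicingCounts,
    n_genes: int | None = None,
    user_list: list[str] | None = None,
) -> SplicingCounts:
    """Restrict to a user gene list, or to the top genes by mean spliced expression.

    Selected genes keep their input-matrix column order; ties in mean
    expression are broken alphabetically.
    """
    if user_list is not None:
        missing = [g for g in user_list if g not in counts.gene_names]
        if missing:
            raise KeyError(f"genes not found in data: {missing}")
        keep = set(user_list)
        idx = [i for i, g in enumerate(counts.gene_names) if g in keep]
        return counts.subset_genes(np.asarray(idx))
    if n_genes is None:
        raise ValueError("either n_genes or user_list is required")
    if n_genes > counts.n_genes:
        raise ValueError(f"n_genes={n_genes} exceeds available genes ({counts.n_genes})")
    means = counts.spliced.mean(axis=0)
    ranked = sorted(range(counts.n_genes), key=lambda i: (-means[i], counts.gene_names[i]))
    chosen = sorted(ranked[:n_genes])  # back to input column order
    return counts.subset_genes(np.asarray(chosen))


def make_windows(n_cells: int, cfg: WindowConfig) -> list[tuple[int, int]]:
    """Contiguous index ranges ``[k*increment, k*increment + width)``.

    The trailing partial window is dropped, so the count is
    ``floor((N - width) / increment) + 1``.
    """
    if cfg.width > n_cells:
        raise ValueError(f"window width {cfg.width} exceeds cell count {n_cells}")
    n_windows = (n_cells - cfg.width) // cfg.increment + 1
    return [(k * cfg.increment, k * cfg.increment + cfg.width) for k in range(n_windows)]


def _regressor(cfg: WindowConfig, n_samples: int):
    if cfg.regression_kind == "linear" or cfg.shrinkage == 0:
        return LinearRegression()
    if cfg.regression_kind == "ridge":
        return Ridge(alpha=cfg.shrinkage)
    # sklearn's lasso objective is (1/2n)*RSS + alpha*L1; the model objective
    # is RSS + lambda*L1, hence alpha = lambda / (2n).
    return Lasso(alpha=cfg.shrinkage / (2 * n_samples), max_iter=10_000)


def fit_window(
    unspliced: np.ndarray,
    spliced: np.ndarray,
    gene_names: list[str],
    cfg: WindowConfig,
) -> SplicingModelFit:
    """Fit the linear splicing model on the cells of one window.

    For each gene ``i`` the production parameters solve the penalized least
    squares problem ``min sum_c (A_i0 + sum_{j!=i} A_ij S_jc - beta U_ic)^2 +
    lambda*F({A_ij})`` (the intercept is never penalized).  The degradation
    rate comes from the spliced steady state by through-origin least squares,
    ``gamma_i = beta * sum_c U_ic S_ic / sum_c S_ic^2``; a gene with all-zero
    spliced counts in the window has no estimable rate and is flagged with a
    NaN gamma (callers drop it from the Jacobian for this window).
    """
    u = np.asarray(unspliced, dtype=float)
    s = np.asarray(spliced, dtype=float)
    n, m = u.shape
    if n < 2:
        raise ValueError("window must contain at least 2 cells")
    intercepts = np.zeros(m)
    a = np.zeros((m, m))
    gammas = np.full(m, np.nan)
    for i in range(m):
        y = cfg.beta * u[:, i]
        others = np.arange(m) != i
        x = s[:, others]
        if x.shape[1] == 0:  # single-gene model: intercept only
            intercepts[i] = y.mean()
        else:
            reg = _regressor(cfg, n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # lasso convergence chatter on degenerate windows
                reg.fit(x, y)
            intercepts[i] = reg.intercept_
            a[i, others] = reg.coef_
        ss = float(s[:, i] @ s[:, i])
        if ss > 0:
            gammas[i] = cfg.beta * float(u[:, i] @ s[:, i]) / ss
    return SplicingModelFit(
        gene_names=gene_names,
        intercepts=intercepts,
        interaction_matrix=a,
        beta=cfg.beta,
        gammas=gammas,
        shrinkage=cfg.shrinkage,
        regression_kind=cfg.regression_kind,
    )


def _window_spectrum(fit: SplicingModelFit) -> JacobianSpectrum | None:
    usable = fit.drop_missing()
    if usable.n_genes == 0:
        return None
    if usable.n_genes < fit.n_genes:
        warnings.warn(
            f"excluded gene(s) with undefined degradation rate: {fit.missing_genes}",
            stacklevel=3,
        )
    return assemble_jacobian(usable)


_METRICS = ["largest_real", "n_positive", "frac_positive"]


def scan_lineage(counts: SplicingCounts, cfg: WindowConfig) -> LineageStabilityProfile:
    """Slide the inference window along the ordering and fit each window.

    Each window gets one full-window fit (stored, used downstream for GRN
    reconstruction) plus ``cfg.n_iterations`` fits on seeded random
    subsamples of ``cfg.subsample_fraction`` of its cells; the spectral
    metrics of every iteration's Jacobian are summarized as per-window mean
    and standard deviation.  Deterministic for a fixed seed.
    """
    data = counts.sorted_by_ordering()
    ranges = make_windows(data.n_cells, cfg)
    rng = np.random.default_rng(cfg.seed)
    n_sub = max(cfg.min_cells, int(round(cfg.subsample_fraction * cfg.width)))
    n_sub = min(n_sub, cfg.width)

    rows = []
    fits: list[SplicingModelFit | None] = []
    positions = np.empty(len(ranges))
    mean_expr = np.full((len(ranges), data.n_genes), np.nan)
    for w, (lo, hi) in enumerate(ranges):
        u, s = data.unspliced[lo:hi], data.spliced[lo:hi]
        positions[w] = data.ordering[lo:hi].mean()
        mean_expr[w] = s.mean(axis=0)
        try:
            full = fit_window(u, s, data.gene_names, cfg)
        except ValueError as err:
            warnings.warn(f"window {w} skipped: {err}", stacklevel=2)
            fits.append(None)
            continue
        fits.append(full)
        for it in range(cfg.n_iterations):
            sub = np.sort(rng.choice(cfg.width, size=n_sub, replace=False))
            spec = _window_spectrum(fit_window(u[sub], s[sub], data.gene_names, cfg))
            if spec is None:
                continue
            rows.append(
                {
                    "window": w,
                    "iteration": it,
                    "position": positions[w],
                    "largest_real": spec.largest_real,
                    "n_positive": spec.n_positive,
                    "frac_positive": spec.frac_positive,
                    "n_genes_used": spec.n_genes,
                }
            )

    iterations = pd.DataFrame(
        rows,
        columns=["window", "iteration", "position", *_METRICS, "n_genes_used"],
    )
    if len(iterations):
        grouped = iterations.groupby("window")
        summary = grouped[_METRICS].agg(["mean", "std"])
        summary.columns = [f"{metric}_{stat}" for metric, stat in summary.columns]
        # a single iteration has no spread, not an undefined one
        summary[[c for c in summary.columns if c.endswith("_std")]] = summary[
            [c for c in summary.columns if c.endswith("_std")]
        ].fillna(0.0)
        summary = summary.reindex(range(len(ranges)))
    else:
        summary = pd.DataFrame(
            index=range(len(ranges)),
            columns=[f"{m}_{s}" for m in _METRICS for s in ("mean", "std")],
            dtype=float,
        )
    summary.insert(0, "position", positions)
    summary.index.name = "window"
    return LineageStabilityProfile(
        window_positions=positions,
        window_ranges=ranges,
        iterations=iterations,
        summary=summary,
        fits=fits,
        mean_expression=mean_expr,
        gene_names=data.gene_names,
        config=cfg,
    )


def smooth_profile(series: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing (reflecting boundaries, unit-sum kernel).

    ``sigma`` is measured in index units of the series; ``sigma=0`` is the
    identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    arr = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    if sigma == 0:
        return arr.copy()
    return gaussian_filter1d(arr, sigma=sigma, mode="reflect")


def _per_cell_from_profile(
    profile: LineageStabilityProfile, ordering: np.ndarray, sigma: float
) -> np.ndarray:
    lam = profile.summary["largest_real_mean"].to_numpy()
    ok = np.isfinite(lam)
    pos = profile.window_positions[ok]
    lam = np.maximum(smooth_profile(lam[ok], sigma), 0.0)
    if pos.size == 0:
        return np.zeros_like(ordering)
    nearest = np.abs(ordering[:, None] - pos[None, :]).argmin(axis=1)
    return lam[nearest]


def instability_score(
    profiles: LineageStabilityProfile | dict[str, LineageStabilityProfile],
    counts: SplicingCounts,
    sigma: float = 1.0,
) -> InstabilityScore:
    """Map window-level instability back to cells.

    A cell's score along one branch is ``max(0, largest_real)`` of the
    Gaussian-smoothed profile at the window nearest the cell's ordering
    value.  With several branch profiles the global score is the maximum over
    the branches containing the cell; a cell in no branch scores 0 (with a
    warning).
    """
    if isinstance(profiles, LineageStabilityProfile):
        score = _per_cell_from_profile(profiles, counts.ordering, sigma)
        return InstabilityScore(cell_ids=list(counts.cell_ids), global_score=score)

    global_score = np.zeros(counts.n_cells)
    covered = np.zeros(counts.n_cells, dtype=bool)
    branch_scores: dict[str, np.ndarray] = {}
    labels = counts.branch_labels
    if labels is None:
        raise ValueError("branch profiles given but counts carry no branch_labels")
    for branch, profile in profiles.items():
        mask = labels == branch
        per_cell = np.zeros(counts.n_cells)
        per_cell[mask] = _per_cell_from_profile(profile, counts.ordering[mask], sigma)
        branch_scores[branch] = per_cell
        global_score[mask] = np.maximum(global_score[mask], per_cell[mask])
        covered |= mask
    if not covered.all():
        warnings.warn(
            f"{int((~covered).sum())} cell(s) belong to no branch profile; scored 0",
            stacklevel=2,
        )
    return InstabilityScore(
        cell_ids=list(counts.cell_ids),
        global_score=global_score,
        branch_scores=branch_scores,
    )


def signature_score(counts: SplicingCounts, gene_signature: list[str]) -> np.ndarray:
    """Per-cell mean of min-max-scaled spliced expression over a gene signature.

    Each signature gene is scaled to [0, 1] across cells before averaging;
    a constant-expression gene contributes 0.  Signature genes absent from
    the data are ignored, but an empty intersection is an error.
    """
    idx = [i for i, g in enumerate(counts.gene_names) if g in set(gene_signature)]
    if not idx:
        raise KeyError("gene signature has empty intersection with gene_names")
    expr = counts.spliced[:, idx]
    lo = expr.min(axis=0)
    span = expr.max(axis=0) - lo
    span_safe = np.where(span > 0, span, 1.0)
    scaled = np.where(span > 0, (expr - lo) / span_safe, 0.0)
    return scaled.mean(axis=1)
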