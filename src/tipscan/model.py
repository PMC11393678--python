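"""Multivariate splicing model: parameterization, Jacobian assembly, spectral metrics.

The model couples, for each gene ``i``, an unspliced copy number ``U_i`` and a
spliced copy number ``S_i``::

    dU_i/dt = A_i0 + sum_{j != i} A_ij * S_j - beta * U_i
    dS_i/dt = beta * U_i - gamma_i * S_i

``A`` is the cross-species interaction matrix (``A_ij`` is the effect of
spliced species ``j`` on the production of unspliced ``i``; the diagonal is
identically zero), ``beta`` a gene-independent splicing rate (time is measured
in units of ``1/beta``, so the default is 1), and ``gamma_i`` per-gene
degradation/dilution rates.

Because the model is linear, its Jacobian is state independent and has a
four-quadrant block structure (state ordering: all unspliced first, then all
spliced)::

    J = [[-beta*I,  A        ],
         [ beta*I, -diag(gamma)]]

Local stability along a lineage is judged from the spectrum of ``J``: any
eigenvalue with positive real part marks an unstable (tipping) region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplicingModelFit",
    "JacobianSpectrum",
    "assemble_jacobian",
    "spectral_metrics",
]


@dataclass
class SplicingModelFit:
    """Fitted parameters of the linear splicing model for one inference window.

    Parameters
    ----------
    gene_names
        Ordered gene identifiers (length M).
    intercepts
        Baseline unspliced production rates ``A_i0`` (counts/time), length M.
    interaction_matrix
        M x M matrix ``A`` with zero diagonal; ``A[i, j]`` is the effect of
        spliced gene ``j`` on unspliced production of gene ``i``
        (1/time per count).
    beta
        Positive scalar splicing rate shared by all genes.
    gammas
        Per-gene degradation/dilution rates (1/time).  Entries may be
        non-finite (NaN) to flag genes whose rate could not be estimated in a
        window; such genes must be dropped (``drop_missing``) before Jacobian
        assembly.
    shrinkage
        Nonnegative regularization strength ``lambda`` used in the fit.
    regression_kind
        One of ``{"linear", "ridge", "lasso"}``.
    """

    gene_names: list[str]
    intercepts: np.ndarray
    interaction_matrix: np.ndarray
    beta: float = 1.0
    gammas: np.ndarray = field(default=None)  # type: ignore[assignment]
    shrinkage: float = 0.0
    regression_kind: str = "linear"

    def __post_init__(self) -> None:
        self.gene_names = list(self.gene_names)
        m = len(self.gene_names)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.interaction_matrix = np.asarray(self.interaction_matrix, dtype=float)
        if self.gammas is None:
            self.gammas = np.full(m, np.nan)
        self.gammas = np.asarray(self.gammas, dtype=float)
        if self.interaction_matrix.shape != (m, m):
            raise ValueError(
                f"interaction_matrix has shape {self.interaction_matrix.shape}, "
                f"expected ({m}, {m})"
            )
        if self.intercepts.shape != (m,) or self.gammas.shape != (m,):
            raise ValueError("intercepts and gammas must be length-M vectors")
        diag = np.diagonal(self.interaction_matrix)
        finite_diag = diag[np.isfinite(diag)]
        if finite_diag.size and np.any(finite_diag != 0.0):
            raise ValueError("interaction_matrix must have an exactly-zero diagonal")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be a positive finite scalar, got {self.beta}")
        finite_g = self.gammas[np.isfinite(self.gammas)]
        if finite_g.size and np.any(finite_g < 0):
            raise ValueError("finite gamma entries must be nonnegative")
        if self.shrinkage < 0:
            raise ValueError("shrinkage must be nonnegative")
        if self.regression_kind not in {"linear", "ridge", "lasso"}:
            raise ValueError(f"unknown regression_kind {self.regression_kind!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def missing_genes(self) -> list[str]:
        """Genes whose degradation rate could not be estimated (non-finite)."""
        bad = ~np.isfinite(self.gammas)
        return [g for g, b in zip(self.gene_names, bad) if b]

    def subset(self, indices: np.ndarray) -> "SplicingModelFit":
        """Restrict the fit to the genes at ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return SplicingModelFit(
            gene_names=[self.gene_names[i] for i in idx],
            intercepts=self.intercepts[idx],
            interaction_matrix=self.interaction_matrix[np.ix_(idx, idx)],
            beta=self.beta,
            gammas=self.gammas[idx],
            shrinkage=self.shrinkage,
            regression_kind=self.regression_kind,
        )

    def drop_missing(self) -> "SplicingModelFit":
        """Drop genes with non-finite degradation rate or interaction entries."""
        ok_gamma = np.isfinite(self.gammas)
        ok_rows = np.all(np.isfinite(self.interaction_matrix), axis=1)
        ok_cols = np.all(np.isfinite(self.interaction_matrix), axis=0)
        ok = ok_gamma & ok_rows & ok_cols & np.isfinite(self.intercepts)
        return self.subset(np.flatnonzero(ok))


@dataclass
class JacobianSpectrum:
    """A 2M x 2M splicing-model Jacobian together with its spectrum.

    ``n_positive`` counts eigenvalues with strictly positive real part (a zero
    real part — the marginal case exactly at a bifurcation — counts as
    non-positive); ``frac_positive`` divides by the total eigenvalue count 2M.
    """

    jacobian: np.ndarray
    eigenvalues: np.ndarray
    largest_real: float
    n_positive: int
    frac_positive: float

    @property
    def n_genes(self) -> int:
        return self.jacobian.shape[0] // 2


def spectral_metrics(eigenvalues: np.ndarray) -> tuple[float, int, float]:
    """Stability metrics of an eigenvalue set.

    Returns ``(largest_real, n_positive, frac_positive)``, judging positivity
    on real parts with a strict inequality.

    Raises
    ------
    ValueError
        If ``eigenvalues`` is empty.
    """
    ev = np.asarray(eigenvalues)
    if ev.size == 0:
        raise ValueError("eigenvalue set is empty")
    real = ev.real if np.iscomplexobj(ev) else ev.astype(float)
    n_pos = int(np.count_nonzero(real > 0))
    return float(real.max()), n_pos, n_pos / ev.size


def assemble_jacobian(fit: SplicingModelFit) -> JacobianSpectrum:
    """Assemble the four-quadrant Jacobian of a fitted model and diagonalize it.

    State ordering is ``(U_1..U_M, S_1..S_M)``; the quadrants are
    ``[[-beta*I, A], [beta*I, -diag(gamma)]]``.

    Raises
    ------
    ValueError
        If any gamma or interaction entry is non-finite, naming the offending
        gene (callers should use :meth:`SplicingModelFit.drop_missing` first).
    """
    m = fit.n_genes
    if m < 1:
        raise ValueError("model must contain at least one gene")
    bad_gamma = ~np.isfinite(fit.gammas)
    if bad_gamma.any():
        names = [g for g, b in zip(fit.gene_names, bad_gamma) if b]
        raise ValueError(f"non-finite degradation rate for gene(s): {names}")
    bad_a = ~np.all(np.isfinite(fit.interaction_matrix), axis=1)
    if bad_a.any():
        names = [g for g, b in zip(fit.gene_names, bad_a) if b]
        raise ValueError(f"non-finite interaction entries for gene(s): {names}")

    eye = np.eye(m)
    jac = np.block(
        [
            [-fit.beta * eye, fit.interaction_matrix],
            [fit.beta * eye, -np.diag(fit.gammas)],
        ]
    )
    eigenvalues = np.linalg.eigvals(jac)
    largest_real, n_positive, frac_positive = spectral_metrics(eigenvalues)
    return JacobianSpectrum(
        jacobian=jac,
        eigenvalues=eigenvalues,
        largest_real=largest_real,
        n_positive=n_positive,
        frac_positive=frac_positive,
    )
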