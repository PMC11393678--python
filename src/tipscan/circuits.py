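"""Synthetic ground-truthed circuits with an explicit splicing layer.

Every circuit is a set of genes whose unspliced production is a basal rate
plus Hill activation/inhibition terms driven by spliced regulators::

    dU_i/dt = basal_i + sum_k rate_k * prod_h hill_h(S)  - beta * U_i
    dS_i/dt = beta * U_i - gamma_i * S_i

with ``hill = S^n / (K^n + S^n)`` for activation and ``K^n / (K^n + S^n)``
for repression.  One designated bifurcation parameter can be ramped in time
to drive the circuit through saddle-node transitions, and stochastic
(Euler-Maruyama) ensembles are sampled into :class:`SplicingCounts` so the
whole inference pipeline can be exercised against known ground truth.

Shipped circuits
----------------
``toggle_switch_spec``
    Two mutually repressing genes X and Y.  The ramped parameter ``beta1``
    scales the strength of X's repression of Y (it divides that Hill
    threshold), so increasing it drives a saddle-node from the low-X/high-Y
    state to the high-X state.
``toggle_bank_spec``
    Several independent toggle switches ramped together; a benchmark for
    how stability metrics scale with model dimensionality.
``emt_tristable_spec``
    A miR-like epithelial gene and a ZEB-like mesenchymal gene with staged
    self-activation; three stable states (E, I, M) at ramp start, destroyed
    in sequence (E fold then I fold) as the external signal ramps up.
    Optional reporter genes slaved to the core enrich the GRN readout.
``trifurcating_spec``
    A stem gene whose ramped-down expression releases a mutually repressing,
    self-activating triad; stochastic trajectories commit to one of three
    fates.

Ground-truth oracles (``find_fixed_points``, ``count_stable_states``,
``bifurcation_param``, ``fold_point_continuation``) locate fixed points by
seeded root search and bifurcation parameter values by bisection, and are
independent of the windowed inference they benchmark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .windows import SplicingCounts

__all__ = [
    "Hill",
    "ProductionTerm",
    "RampSchedule",
    "CircuitSpec",
    "FixedPoint",
    "DeterministicRun",
    "SimulatedLineage",
    "toggle_switch_spec",
    "toggle_bank_spec",
    "emt_tristable_spec",
    "trifurcating_spec",
    "simulate_deterministic",
    "simulate_stochastic",
    "simulate_toggle",
    "simulate_emt",
    "simulate_trifurcating",
    "find_fixed_points",
    "count_stable_states",
    "bifurcation_param",
    "fold_point_continuation",
    "label_branches",
]


@dataclass(frozen=True)
class Hill:
    """One Hill factor: ``act`` is S^n/(K^n+S^n), ``rep`` is K^n/(K^n+S^n)."""

    reg: int
    K: float
    n: float
    kind: str = "rep"

    def __post_init__(self) -> None:
        if self.kind not in {"act", "rep"}:
            raise ValueError(f"hill kind must be 'act' or 'rep', got {self.kind!r}")
        if self.K <= 0:
            raise ValueError("hill threshold K must be positive")
        if self.n < 1:
            raise ValueError("hill coefficient must be >= 1")


@dataclass(frozen=True)
class ProductionTerm:
    rate: float
    hills: tuple[Hill, ...] = ()

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("production rate must be nonnegative")


@dataclass(frozen=True)
class RampSchedule:
    """Linear ramp of the bifurcation parameter: v0 before t0, v1 after t1."""

    t0: float
    t1: float
    v0: float
    v1: float

    def value(self, t: float) -> float:
        if self.t1 <= self.t0:
            return self.v1 if t >= self.t1 else self.v0
        frac = np.clip((t - self.t0) / (self.t1 - self.t0), 0.0, 1.0)
        return self.v0 + frac * (self.v1 - self.v0)

    def rescaled(self, speedup: float) -> "RampSchedule":
        """Same parameter range traversed ``speedup`` times faster."""
        return RampSchedule(
            self.t0 / speedup, self.t0 / speedup + (self.t1 - self.t0) / speedup, self.v0, self.v1
        )


# ramp targets: ("basal", gene) sets basal[gene] = v;
# ("rate", gene, term) sets that term's rate = v;
# ("kdiv", gene, term, hill) sets that hill's threshold to K / v.
RampTarget = tuple


@dataclass
class CircuitSpec:
    genes: list[str]
    basal: np.ndarray
    terms: list[list[ProductionTerm]]
    beta: float = 1.0
    gamma: np.ndarray = field(default=None)  # type: ignore[assignment]
    sigma: float = 0.0
    noise_kind: str = "multiplicative"
    ramp: RampSchedule | None = None
    ramp_targets: tuple[RampTarget, ...] = ()

    def __post_init__(self) -> None:
        m = len(self.genes)
        self.basal = np.asarray(self.basal, dtype=float)
        if self.gamma is None:
            self.gamma = np.ones(m)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.basal.shape != (m,) or self.gamma.shape != (m,):
            raise ValueError("basal and gamma must be length-M vectors")
        if np.any(self.basal < 0) or np.any(self.gamma < 0):
            raise ValueError("rates must be nonnegative")
        if len(self.terms) != m:
            raise ValueError("terms must list production terms per gene")
        if self.sigma < 0:
            raise ValueError("noise amplitude must be nonnegative")
        if self.noise_kind not in {"multiplicative", "additive"}:
            raise ValueError("noise_kind must be 'multiplicative' or 'additive'")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def param_at(self, t: float) -> float | None:
        return None if self.ramp is None else self.ramp.value(t)

    def resolved(self, v: float | None):
        """Basal vector and production terms with the ramped value substituted."""
        basal = self.basal.copy()
        terms = [list(ts) for ts in self.terms]
        if v is not None:
            for target in self.ramp_targets:
                kind = target[0]
                if kind == "basal":
                    basal[target[1]] = v
                elif kind == "rate":
                    i, k = target[1], target[2]
                    terms[i][k] = replace(terms[i][k], rate=float(v))
                elif kind == "kdiv":
                    i, k, h = target[1], target[2], target[3]
                    term = terms[i][k]
                    hills = list(term.hills)
                    # v=0 removes the interaction entirely (infinite threshold)
                    new_k = np.inf if v == 0 else hills[h].K / float(v)
                    hills[h] = replace(hills[h], K=new_k)
                    terms[i][k] = replace(term, hills=tuple(hills))
                else:
                    raise ValueError(f"unknown ramp target {target!r}")
        return basal, terms

    # -- vector field -----------------------------------------------------

    def production(self, spliced: np.ndarray, v: float | None = None) -> np.ndarray:
        """Unspliced production rates; ``spliced`` has shape (..., M)."""
        s = np.asarray(spliced, dtype=float)
        basal, terms = self.resolved(v)
        out = np.broadcast_to(basal, s.shape).copy()
        for i in range(self.n_genes):
            for term in terms[i]:
                factor = np.full(s.shape[:-1], term.rate)
                for h in term.hills:
                    if np.isinf(h.K):  # removed interaction: no activation, no repression
                        if h.kind == "act":
                            factor = factor * 0.0
                        continue
                    x = np.maximum(s[..., h.reg], 0.0)
                    kn = h.K**h.n
                    xn = x**h.n
                    frac = xn / (kn + xn) if h.kind == "act" else kn / (kn + xn)
                    factor = factor * frac
                out[..., i] += factor
        return out

    def production_jacobian(self, spliced: np.ndarray, v: float | None = None) -> np.ndarray:
        """d production_i / d S_j at one spliced state (shape M x M)."""
        s = np.asarray(spliced, dtype=float)
        m = self.n_genes
        _, terms = self.resolved(v)
        jac = np.zeros((m, m))
        for i in range(m):
            for term in terms[i]:
                vals, grads = [], []
                for h in term.hills:
                    if np.isinf(h.K):
                        vals.append(0.0 if h.kind == "act" else 1.0)
                        grads.append(0.0)
                        continue
                    x = max(float(s[h.reg]), 0.0)
                    kn = h.K**h.n
                    xn = x**h.n
                    denom = kn + xn
                    vals.append(xn / denom if h.kind == "act" else kn / denom)
                    dx = h.n * kn * x ** (h.n - 1) / denom**2
                    grads.append(dx if h.kind == "act" else -dx)
                for a, h in enumerate(term.hills):
                    g = term.rate * grads[a]
                    for b, val in enumerate(vals):
                        if b != a:
                            g *= val
                    jac[i, h.reg] += g
        return jac

    def drift(self, state: np.ndarray, v: float | None = None) -> np.ndarray:
        """Full drift for state (..., 2M) ordered (U_1..U_M, S_1..S_M)."""
        x = np.asarray(state, dtype=float)
        m = self.n_genes
        u, s = x[..., :m], x[..., m:]
        du = self.production(s, v) - self.beta * u
        ds = self.beta * u - self.gamma * s
        return np.concatenate([du, ds], axis=-1)

    def full_jacobian(self, state: np.ndarray, v: float | None = None) -> np.ndarray:
        """Analytic 2M x 2M Jacobian of the circuit at one state."""
        m = self.n_genes
        s = np.asarray(state, dtype=float)[m:]
        eye = np.eye(m)
        return np.block(
            [
                [-self.beta * eye, self.production_jacobian(s, v)],
                [self.beta * eye, -np.diag(self.gamma)],
            ]
        )


@dataclass
class FixedPoint:
    spliced: np.ndarray
    unspliced: np.ndarray
    stable: bool
    largest_real: float

    @property
    def state(self) -> np.ndarray:
        return np.concatenate([self.unspliced, self.spliced])


@dataclass
class DeterministicRun:
    times: np.ndarray
    states: np.ndarray  # (T, 2M)
    param_values: np.ndarray
    largest_real: np.ndarray
    spec: CircuitSpec

    def spliced(self) -> np.ndarray:
        return self.states[:, self.spec.n_genes :]


@dataclass
class SimulatedLineage:
    """Stochastic ensemble sampled into counts, plus raw sampled trajectories."""

    counts: SplicingCounts
    sample_times: np.ndarray
    trajectories: np.ndarray  # (n_traj, n_samples, 2M)
    clipped_fraction: float
    spec: CircuitSpec
    branch_of_traj: np.ndarray | None = None


# ---------------------------------------------------------------------------
# circuit factories
# ---------------------------------------------------------------------------


def toggle_switch_spec(
    a: float = 2.0,
    K: float = 1.0,
    n: float = 4.0,
    basal: float = 0.1,
    beta: float = 1.0,
    gamma: float = 1.0,
    sigma: float = 0.05,
    beta1_range: tuple[float, float] = (1.0, 8.0),
    ramp_time: tuple[float, float] = (0.0, 80.0),
) -> CircuitSpec:
    """Splicing-aware toggle switch (genes "x", "y").

    ``beta1`` multiplies the effectiveness of X's repression of Y (dividing
    that Hill threshold); at ``beta1_range[0]`` the circuit is bistable, at
    ``beta1_range[1]`` only the high-X state survives, with a saddle-node
    fold in between.
    """
    spec = CircuitSpec(
        genes=["x", "y"],
        basal=np.array([basal, basal]),
        terms=[
            [ProductionTerm(a, (Hill(reg=1, K=K, n=n, kind="rep"),))],  # x <- rep by y
            [ProductionTerm(a, (Hill(reg=0, K=K, n=n, kind="rep"),))],  # y <- rep by x
        ],
        beta=beta,
        gamma=np.array([gamma, gamma]),
        sigma=sigma,
        ramp=RampSchedule(ramp_time[0], ramp_time[1], beta1_range[0], beta1_range[1]),
        ramp_targets=(("kdiv", 1, 0, 0),),
    )
    return spec


def toggle_bank_spec(
    n_pairs: int = 5,
    amplitude_decay: float = 0.05,
    **kwargs,
) -> CircuitSpec:
    """``n_pairs`` independent toggle switches sharing one ramp.

    Pair ``p`` has production amplitude ``a * (1 - amplitude_decay * p)`` so
    pairs are distinguishable by mean expression; all folds coincide, which
    makes stability metrics comparable across model dimensionality.
    """
    base = toggle_switch_spec(**kwargs)
    a = base.terms[0][0].rate
    genes, basal, terms, targets = [], [], [], []
    for p in range(n_pairs):
        scale = 1.0 - amplitude_decay * p
        ix, iy = 2 * p, 2 * p + 1
        genes += [f"x{p + 1}", f"y{p + 1}"]
        basal += [base.basal[0] * scale, base.basal[1] * scale]
        hx = base.terms[0][0].hills[0]
        hy = base.terms[1][0].hills[0]
        terms.append([ProductionTerm(a * scale, (replace(hx, reg=iy),))])
        terms.append([ProductionTerm(a * scale, (replace(hy, reg=ix),))])
        targets.append(("kdiv", iy, 0, 0))
    return CircuitSpec(
        genes=genes,
        basal=np.array(basal),
        terms=terms,
        beta=base.beta,
        gamma=np.full(2 * n_pairs, base.gamma[0]),
        sigma=base.sigma,
        ramp=base.ramp,
        ramp_targets=tuple(targets),
    )


def emt_tristable_spec(
    n_reporters: int = 3,
    sigma: float = 0.05,
    signal_range: tuple[float, float] = (0.1, 2.1),
    ramp_time: tuple[float, float] = (0.0, 100.0),
) -> CircuitSpec:
    """Tristable EMT-like circuit: epithelial "mir" and mesenchymal "zeb".

    ``zeb`` carries a two-stage self-activation (thresholds well below and
    well above the intermediate state) damped by ``mir``; ``mir`` is
    repressed by ``zeb``.  The ramped external signal enters as ``zeb``'s
    basal production and destroys first the epithelial then the intermediate
    state through two saddle-node folds.  ``n_reporters`` epithelial and as
    many mesenchymal reporter genes (activated by mir and zeb respectively)
    are slaved to the core and enrich the reconstructed GRN without changing
    the attractor structure.
    """
    genes = ["mir", "zeb"]
    basal = [0.05, signal_range[0]]
    terms: list[list[ProductionTerm]] = [
        [ProductionTerm(2.0, (Hill(reg=1, K=1.2, n=6, kind="rep"),))],
        [
            ProductionTerm(
                2.2,
                (Hill(reg=1, K=1.0, n=4, kind="act"), Hill(reg=0, K=1.5, n=2, kind="rep")),
            ),
            ProductionTerm(
                7.0,
                (Hill(reg=1, K=5.5, n=8, kind="act"), Hill(reg=0, K=1.5, n=2, kind="rep")),
            ),
        ],
    ]
    for r in range(n_reporters):
        genes.append(f"epi{r + 1}")
        basal.append(0.05)
        terms.append([ProductionTerm(1.5, (Hill(reg=0, K=1.0 + 0.3 * r, n=2, kind="act"),))])
    for r in range(n_reporters):
        genes.append(f"mes{r + 1}")
        basal.append(0.05)
        terms.append([ProductionTerm(1.5, (Hill(reg=1, K=2.0 + 1.0 * r, n=2, kind="act"),))])
    m = len(genes)
    return CircuitSpec(
        genes=genes,
        basal=np.array(basal),
        terms=terms,
        beta=1.0,
        gamma=np.ones(m),
        sigma=sigma,
        ramp=RampSchedule(ramp_time[0], ramp_time[1], signal_range[0], signal_range[1]),
        ramp_targets=(("basal", 1),),
    )


def trifurcating_spec(
    sigma: float = 0.1,
    stem_range: tuple[float, float] = (2.0, 0.0),
    ramp_time: tuple[float, float] = (10.0, 30.0),
) -> CircuitSpec:
    """Trifurcating circuit: stem gene "gS" gating a self-activating triad.

    While the stem gene is produced it represses all three fate genes (the
    starting state S).  Ramping the stem production to zero releases the
    mutually repressing triad "t1"/"t2"/"t3"; noise breaks the symmetry and
    each trajectory commits to exactly one high fate gene.
    """
    genes = ["gS", "t1", "t2", "t3"]
    basal = np.array([stem_range[0], 0.25, 0.25, 0.25])
    terms: list[list[ProductionTerm]] = [[]]
    for i in range(1, 4):
        others = [j for j in (1, 2, 3) if j != i]
        hills = (
            Hill(reg=i, K=0.6, n=4, kind="act"),
            Hill(reg=0, K=0.8, n=4, kind="rep"),
            Hill(reg=others[0], K=1.0, n=4, kind="rep"),
            Hill(reg=others[1], K=1.0, n=4, kind="rep"),
        )
        terms.append([ProductionTerm(2.5, hills)])
    return CircuitSpec(
        genes=genes,
        basal=basal,
        terms=terms,
        beta=1.0,
        gamma=np.ones(4),
        sigma=sigma,
        ramp=RampSchedule(ramp_time[0], ramp_time[1], stem_range[0], stem_range[1]),
        ramp_targets=(("basal", 0),),
    )


# ---------------------------------------------------------------------------
# fixed-point and bifurcation oracles
# ---------------------------------------------------------------------------


def _spliced_residual(spec: CircuitSpec, s: np.ndarray, v: float | None) -> np.ndarray:
    return spec.production(s, v) / spec.gamma - s


def _polish(spec: CircuitSpec, seed_s: np.ndarray, v: float | None) -> np.ndarray | None:
    sol = root(
        lambda s: _spliced_residual(spec, s, v),
        seed_s,
        jac=lambda s: spec.production_jacobian(s, v) / spec.gamma[:, None] - np.eye(spec.n_genes),
        method="hybr",
        tol=1e-12,
    )
    if not sol.success:
        return None
    s = sol.x
    if np.any(s < -1e-8):
        return None
    return np.maximum(s, 0.0)


def find_fixed_points(
    spec: CircuitSpec,
    v: float | None = None,
    s_max: float | None = None,
    n_seeds: int = 200,
    seed: int = 0,
    decimals: int = 5,
) -> list[FixedPoint]:
    """Locate fixed points by seeded root search with damped-iteration warm-up.

    Seeds cover ``[0, s_max]^M`` (a regular grid for M <= 3, quasi-random
    otherwise); each seed is first relaxed by damped fixed-point iteration
    of ``S <- production(S)/gamma`` (which drifts toward stable attractors),
    then Newton-polished; both the relaxed and the raw seed are polished so
    unstable saddles are found too.  Stability is judged from the full
    2M x 2M analytic Jacobian.
    """
    m = spec.n_genes
    if spec.ramp is not None and v is None:
        v = spec.ramp.v0
    if s_max is None:
        rates = [sum(t.rate for t in ts) for ts in spec.terms]
        s_max = 1.5 * float(np.max((spec.basal + np.asarray(rates)) / np.maximum(spec.gamma, 1e-12)))
    if m <= 3:
        axes = [np.linspace(0, s_max, 6)] * m
        seeds = np.stack(np.meshgrid(*axes), axis=-1).reshape(-1, m)
    else:
        rng = np.random.default_rng(seed)
        seeds = rng.uniform(0, s_max, size=(n_seeds, m))

    found: dict[tuple, np.ndarray] = {}
    for s0 in seeds:
        s_relaxed = s0.copy()
        for _ in range(80):
            s_new = 0.5 * s_relaxed + 0.5 * spec.production(s_relaxed, v) / spec.gamma
            if np.max(np.abs(s_new - s_relaxed)) < 1e-12:
                s_relaxed = s_new
                break
            s_relaxed = s_new
        for candidate in (s_relaxed, s0):
            s_star = _polish(spec, candidate, v)
            if s_star is not None:
                found.setdefault(tuple(np.round(s_star, decimals)), s_star)

    points = []
    for s_star in found.values():
        u_star = spec.production(s_star, v) / spec.beta
        state = np.concatenate([u_star, s_star])
        eigs = np.linalg.eigvals(spec.full_jacobian(state, v))
        lam = float(eigs.real.max())
        points.append(FixedPoint(spliced=s_star, unspliced=u_star, stable=lam < -1e-9, largest_real=lam))
    points.sort(key=lambda fp: tuple(fp.spliced))
    return points


def count_stable_states(spec: CircuitSpec, v: float | None = None, **kwargs) -> int:
    return sum(fp.stable for fp in find_fixed_points(spec, v=v, **kwargs))


def bifurcation_param(
    spec: CircuitSpec,
    v_lo: float,
    v_hi: float,
    tol: float = 1e-6,
    **fp_kwargs,
) -> float:
    """Bisect for the parameter value where the stable fixed-point count changes.

    The count at ``v_lo`` is the reference; the returned value is the first
    parameter (to within ``tol``) in ``[v_lo, v_hi]`` at which the count
    differs.  Assumes a single change inside the bracket.
    """
    n0 = count_stable_states(spec, v_lo, **fp_kwargs)
    if count_stable_states(spec, v_hi, **fp_kwargs) == n0:
        raise ValueError("stable fixed-point count does not change over the bracket")
    lo, hi = v_lo, v_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if count_stable_states(spec, mid, **fp_kwargs) == n0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fold_point_continuation(
    spec: CircuitSpec,
    v_lo: float,
    v_hi: float,
    start_spliced: np.ndarray,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Track a stable branch in the ramp parameter until it folds.

    Newton-continues the stable fixed point seeded at ``start_spliced`` from
    ``v_lo`` upward; the branch is considered lost when the polished root
    jumps away, turns unstable, or stops converging.  Returns the fold
    parameter (bisected to ``tol``) and the branch's largest Jacobian
    eigenvalue just below the fold (which approaches zero from below — the
    quasi-static stability crossing).
    """
    s_ref = _polish(spec, np.asarray(start_spliced, dtype=float), v_lo)
    if s_ref is None:
        raise ValueError("no fixed point near start_spliced at v_lo")

    def probe(v: float, s_from: np.ndarray):
        s_new = _polish(spec, s_from, v)
        if s_new is None:
            return None
        if np.linalg.norm(s_new - s_from) > 0.25 * (1.0 + np.linalg.norm(s_from)):
            return None
        u_new = spec.production(s_new, v) / spec.beta
        lam = float(
            np.linalg.eigvals(spec.full_jacobian(np.concatenate([u_new, s_new]), v)).real.max()
        )
        if lam >= 0:
            return None
        return s_new, lam

    first = probe(v_lo, s_ref)
    if first is None:
        raise ValueError("start point is not a stable fixed point at v_lo")
    s_ref, lam_ref = first
    if probe(v_hi, s_ref) is not None:
        # branch may survive a far jump check; march to be sure
        pass
    lo, hi = v_lo, v_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        res = probe(mid, s_ref)
        if res is not None:
            s_ref, lam_ref = res
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), lam_ref


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_deterministic(
    spec: CircuitSpec,
    x0: np.ndarray,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> DeterministicRun:
    """Integrate the noise-free circuit along ``t_grid`` with the ramp active.

    The analytic Jacobian is evaluated at every output state (with the
    ramped parameter at that time) and its largest eigenvalue real part is
    reported alongside the trajectory.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    def rhs(t, x):
        return spec.drift(x, spec.param_at(t))

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        np.asarray(x0, dtype=float),
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    states = sol.y.T
    params = np.array([np.nan if spec.param_at(t) is None else spec.param_at(t) for t in t_grid])
    lams = np.array(
        [
            np.linalg.eigvals(spec.full_jacobian(x, spec.param_at(t))).real.max()
            for t, x in zip(t_grid, states)
        ]
    )
    return DeterministicRun(times=t_grid, states=states, param_values=params, largest_real=lams, spec=spec)


def simulate_stochastic(
    spec: CircuitSpec,
    n_traj: int,
    t_max: float,
    dt: float,
    sample_times: np.ndarray,
    seed: int,
    x0: np.ndarray,
    burn_in: float = 0.0,
) -> SimulatedLineage:
    """Euler-Maruyama ensemble, sampled into :class:`SplicingCounts`.

    ``n_traj`` independent trajectories start from ``x0`` and are recorded
    at ``sample_times``; every (trajectory, sample time) pair becomes one
    cell whose ordering value is its sampling time.  Noise is
    ``sigma * x * dW`` (multiplicative, default) or ``sigma * dW``
    (additive); negative excursions are clipped at zero and the clipped
    fraction reported.  ``burn_in`` time units are integrated before t=0 at
    the ramp-start parameter value (unsampled), so the ensemble enters the
    lineage from its stationary spread rather than a point mass.
    Bit-reproducible for a fixed seed.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    if np.any(sample_times < 0) or np.any(sample_times > t_max + 1e-9):
        raise ValueError("sample_times must lie within [0, t_max]")
    n_steps = int(np.ceil(t_max / dt))
    sample_steps = np.minimum(np.round(sample_times / dt).astype(int), n_steps)
    rng = np.random.default_rng(seed)
    m = spec.n_genes
    x = np.tile(np.asarray(x0, dtype=float), (n_traj, 1))
    sqrt_dt = np.sqrt(dt)
    sampled = np.empty((n_traj, sample_times.size, 2 * m))
    step_to_slots: dict[int, list[int]] = {}
    for k, st in enumerate(sample_steps):
        step_to_slots.setdefault(int(st), []).append(k)
    clipped = 0
    total = 0

    def em_step(x, v):
        nonlocal clipped, total
        noise = rng.standard_normal(size=x.shape)
        if spec.noise_kind == "multiplicative":
            dw = spec.sigma * x * noise * sqrt_dt
        else:
            dw = spec.sigma * noise * sqrt_dt
        x = x + spec.drift(x, v) * dt + dw
        neg = x < 0
        n_neg = int(neg.sum())
        clipped += n_neg
        total += x.size
        # a step driving most of the state negative is Euler instability,
        # not biological noise
        if n_neg >= 0.5 * x.size:
            raise RuntimeError("stochastic integration unstable; use a smaller dt")
        np.maximum(x, 0.0, out=x)
        if not np.all(np.isfinite(x)) or x.max() > 1e9:
            raise RuntimeError("stochastic integration blew up; use a smaller dt")
        return x

    v_start = spec.param_at(0.0)
    for _ in range(int(np.ceil(burn_in / dt))):
        x = em_step(x, v_start)
    for k in step_to_slots.get(0, []):
        sampled[:, k] = x
    for step in range(1, n_steps + 1):
        x = em_step(x, spec.param_at(step * dt))
        for k in step_to_slots.get(step, []):
            sampled[:, k] = x

    cell_ids, ordering = [], []
    u_rows, s_rows = [], []
    for j in range(n_traj):
        for k, t_s in enumerate(sample_times):
            cell_ids.append(f"traj{j:04d}_t{k:03d}")
            ordering.append(t_s)
            u_rows.append(sampled[j, k, :m])
            s_rows.append(sampled[j, k, m:])
    counts = SplicingCounts(
        unspliced=np.array(u_rows),
        spliced=np.array(s_rows),
        gene_names=list(spec.genes),
        cell_ids=cell_ids,
        ordering=np.array(ordering),
    )
    frac = clipped / total if total else 0.0
    if frac > 0.01:
        warnings.warn(f"clipped fraction {frac:.3%} exceeds 1%", stacklevel=2)
    return SimulatedLineage(
        counts=counts,
        sample_times=sample_times,
        trajectories=sampled,
        clipped_fraction=frac,
        spec=spec,
    )


def _start_state(spec: CircuitSpec, pick: str) -> np.ndarray:
    """Stable fixed point at ramp start chosen by a named criterion."""
    v0 = spec.ramp.v0 if spec.ramp is not None else None
    stable = [fp for fp in find_fixed_points(spec, v=v0) if fp.stable]
    if not stable:
        raise RuntimeError("no stable fixed point at ramp start")
    if pick == "low_first_gene":
        fp = min(stable, key=lambda f: f.spliced[0])
    elif pick == "high_first_gene":
        fp = max(stable, key=lambda f: f.spliced[0])
    else:
        raise ValueError(pick)
    return fp.state


def simulate_toggle(
    n_traj: int = 50,
    n_samples: int = 40,
    seed: int = 0,
    dt: float = 0.01,
    t_max: float = 80.0,
    burn_in: float = 10.0,
    **spec_kwargs,
) -> SimulatedLineage:
    """Stochastic toggle-switch lineage starting from the low-X state."""
    spec_kwargs.setdefault("ramp_time", (0.0, t_max))
    spec = toggle_switch_spec(**spec_kwargs)
    x0 = _start_state(spec, "low_first_gene")
    sample_times = np.linspace(0.0, t_max, n_samples)
    return simulate_stochastic(spec, n_traj, t_max, dt, sample_times, seed, x0, burn_in=burn_in)


def simulate_emt(
    n_traj: int = 60,
    n_samples: int = 50,
    seed: int = 0,
    dt: float = 0.01,
    t_max: float = 100.0,
    burn_in: float = 10.0,
    **spec_kwargs,
) -> SimulatedLineage:
    """Stochastic tristable-EMT lineage starting in the epithelial state."""
    spec_kwargs.setdefault("ramp_time", (0.0, t_max))
    spec = emt_tristable_spec(**spec_kwargs)
    # epithelial = lowest zeb among the three stable states
    v0 = spec.ramp.v0
    stable = [fp for fp in find_fixed_points(spec, v=v0) if fp.stable]
    fp = min(stable, key=lambda f: f.spliced[1])
    sample_times = np.linspace(0.0, t_max, n_samples)
    return simulate_stochastic(spec, n_traj, t_max, dt, sample_times, seed, fp.state, burn_in=burn_in)


def simulate_trifurcating(
    n_traj: int = 100,
    n_samples: int = 50,
    seed: int = 0,
    dt: float = 0.005,
    t_max: float = 60.0,
    burn_in: float = 10.0,
    **spec_kwargs,
) -> SimulatedLineage:
    """Stochastic trifurcating lineage with per-trajectory branch labels."""
    spec = trifurcating_spec(**spec_kwargs)
    x0 = _start_state(spec, "high_first_gene")
    sample_times = np.linspace(0.0, t_max, n_samples)
    lineage = simulate_stochastic(spec, n_traj, t_max, dt, sample_times, seed, x0, burn_in=burn_in)
    return label_branches(lineage)


def label_branches(
    lineage: SimulatedLineage,
    marker_genes: tuple[str, ...] = ("t1", "t2", "t3"),
) -> SimulatedLineage:
    """Assign each trajectory (hence each of its cells) to a fate branch.

    The branch is the marker gene with the highest spliced expression at the
    final sample time.  Labels are written into
    ``lineage.counts.branch_labels`` and ``lineage.branch_of_traj``.
    """
    spec = lineage.spec
    m = spec.n_genes
    idx = [spec.genes.index(g) for g in marker_genes]
    final_spliced = lineage.trajectories[:, -1, m:][:, idx]
    winner = np.asarray(marker_genes)[final_spliced.argmax(axis=1)]
    n_samples = lineage.sample_times.size
    labels = np.repeat(winner, n_samples)
    lineage.counts.branch_labels = labels
    lineage.branch_of_traj = winner
    return lineage
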