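# Methods

## The splicing model and its stability readout

`tipscan` models each gene's unspliced copy number as produced at a rate
that is linear in the spliced copy numbers of the other genes
(`dU_i/dt = A_i0 + Σ_{j≠i} A_ij S_j − β U_i`) and spliced counts as
`dS_i/dt = β U_i − γ_i S_i`.  Three assumptions matter:

- **Gene-independent splicing rate.**  β is shared by all genes and set to 1
  by measuring time in units of 1/β.  This is the same simplification made
  by the standard RNA-velocity models; it is wrong in detail (splicing
  rates are gene specific) but removes an unidentifiable scale from the
  regression.
- **Local steady state.**  Within one inference window the production
  balance is assumed equilibrated, so the interaction parameters solve the
  regression of βU on S and γ comes from the spliced steady state.  The
  separation of timescales that justifies this (splicing in minutes,
  fate transitions in days) is an assumption about the data, not a
  property of the code.
- **Linearity within a window.**  The fitted model is the local
  linearization of whatever nonlinear dynamics generated the data.  Its
  Jacobian is state independent, with the four-quadrant form
  `[[−βI, A], [βI, −diag(γ)]]` (state order U₁..U_M, S₁..S_M).

Stability is judged from the spectrum: the largest real part, the count of
eigenvalues with strictly positive real part, and that count divided by 2M.
Zero real parts count as non-positive (the marginal case at a bifurcation),
and complex eigenvalues are judged by real part — the standard
linear-stability criterion.

## Sliding-window inference

Cells are sorted by the ordering value, ties broken by cell id for
determinism.  Windows contain a fixed number of cells (constant statistical
power per fit) and advance by a fixed increment; a window's coordinate is
the mean ordering of its cells, and the trailing partial window is dropped.
Each window gets one full-cell fit (stored, reused for GRN reconstruction)
plus `n_iterations = 10` fits on seeded random subsamples of 90% of its
cells; per-window means and standard deviations over these iterations give
the error bars.  The subsampling scheme is this package's choice of how to
generate iteration spread — it reproduces fit-to-fit variability without
injecting artificial noise.

The ridge/lasso penalty applies to the interaction coefficients only, never
to the intercept (standard regression convention).  The lasso strength maps
to scikit-learn's `alpha = λ / (2n)` so that the objective is
`RSS + λ·L1` exactly.  A gene whose spliced counts are identically zero in
a window has no estimable γ; it is flagged (NaN) and excluded from that
window's Jacobian, whose normalized metrics then use the realized
dimension.

Free parameters, with the defaults used on the shipped benchmarks:

| parameter | default | rationale |
|---|---|---|
| window width | 100 cells (200–300 on the benchmarks) | ≈10% of the dataset; the window must straddle the transition in ordering units for the mixture of pre/post cells to reveal the instability |
| increment | 10–60 cells | resolution along the lineage |
| n_iterations | 10 | error-bar convention |
| subsample fraction | 0.9 | mild perturbation, preserves window identity |
| shrinkage λ | 0 (linear); 20 for GRN community analysis | see below |
| smoothing σ | 1–1.5 windows | Gaussian filter with reflecting boundaries, unit-sum kernel |

The per-cell instability score is `max(0, largest_real)` of the smoothed
profile at the window nearest the cell's ordering value; for multi-branch
data each branch is scanned separately and a cell's global score is the
maximum over branches containing it.  (The exact integration rule used for
the score is an open design point; nearest-window assignment plus
max-over-branches is this package's documented choice.)

## GRN reconstruction

Edge j→i gets weight `A_ij` times the sender's min-max-scaled mean spliced
expression in the window, so unexpressed regulators contribute exactly zero
— an inactive gene cannot regulate.  Edges below the 0.75 quantile of the
remaining nonzero |weights| are dropped (the threshold is relative because
absolute interaction scales vary window to window).  Community detection
projects the directed graph to an undirected |weight| graph (the modularity
algorithms are undirected): Clauset–Newman–Moore greedy maximization, or
Girvan–Newman with distance-weighted edge betweenness, keeping the
hierarchy level of maximal weighted modularity, with the connected-component
partition as the level-0 candidate.  Isolated genes count as singleton
communities.  Betweenness rankings use shortest paths under
`distance = 1/|weight|`, ties alphabetical.

For the community-rearrangement analysis the per-window fits use ridge
shrinkage λ = 20.  With plain least squares, attractor windows contain
near-constant collinear predictors whose coefficients are arbitrarily large
noise; shrinkage (offered by the model's regression formulation with
user-defined λ) stabilizes them so that community structure reflects real
correlation structure rather than regression pathology.

## Benchmark circuits

The circuits emulate the qualitative bifurcation skeletons a method like
this must detect; their parameter values are this package's own, validated
at test time by the fixed-point oracle (the original circuit parameters
live in unpublished supplementary material and are deliberately not
reproduced).  All species carry an explicit splicing layer (U and S per
gene), β = γ = 1, Hill-type production, multiplicative noise σ·x·dW
(additive optional), Euler–Maruyama integration with per-step clipping at
zero (chemical-Langevin convention; clipped fraction reported and < 1% at
the default σ).  Ensembles are equilibrated for 10 time units at the
ramp-start parameter before sampling, so the first windows see the
stationary spread rather than a point mass.

- **Toggle switch** (genes x, y): mutual repression, basal 0.1, amplitude
  2, K = 1, n = 4.  The ramped parameter β₁ divides the threshold of x's
  repression of y (one of the two symmetric conventions; documented here).
  Bistable at β₁ = 1, fold at β₁* = 2.3905 (oracle), monostable high-x at
  β₁ = 8; default ramp 1→8 over 80 time units, σ = 0.05, 50 trajectories ×
  40 sample times = 2000 cells.
- **Toggle bank**: n independent copies of the switch, amplitudes scaled by
  (1 − 0.05p) per pair, one shared ramp — a controlled way to vary model
  dimensionality with a common instability.
- **Tristable EMT circuit** (mir, zeb + optional reporter genes): zeb
  carries a two-stage self-activation (K = 1 and K = 5.5) damped by mir;
  mir is repressed by zeb.  At signal s = 0.1 there are exactly three
  stable states (epithelial zeb ≈ 0.1, intermediate ≈ 2.2, mesenchymal
  ≈ 9.2); ramping s destroys E at s ≈ 0.553 and I at s ≈ 1.305 (oracle
  values).  Three epithelial and three mesenchymal reporter genes, slaved
  to the core, enrich the GRN readout without changing the attractors.
- **Trifurcating circuit** (gS, t1, t2, t3): a stem gene represses a
  mutually repressing, self-activating triad; ramping stem production 2→0
  (t = 10..30) releases the triad and noise (σ = 0.1) commits each
  trajectory to exactly one high fate gene.  Branch labels come from the
  terminal marker argmax.

Oracles: fixed points are located by damped-iteration warm-up plus Newton
polishing from gridded/quasi-random seeds and classified by the analytic
2M×2M Jacobian; fold parameters by bisection on the stable-state count; and
independently by Newton continuation of a branch until it disappears (its
largest eigenvalue → 0⁻).  The two fold locators agree to ~1e-7 on the
toggle switch.  Note that along a *finite-speed* ramped trajectory the
state-evaluated eigenvalue crosses zero ≈ 0.4 ramp units after the fold
(critical slowing down); only the quasi-static continuation reproduces the
fold itself.

## What the synthetic benchmarks do and do not establish

The simulated data are dense, noise-controlled, and ordered by true
simulation time.  Real scRNA-seq adds sparsity (unspliced counts are
5–10× rarer than spliced), technical noise, imperfect pseudotime, and
asynchronous transitions; a green benchmark establishes that the inference
machinery recovers instabilities it should recover, not that it will on any
given dataset.  Two observed behaviors are worth knowing: the peak of the
inferred largest eigenvalue sits up to one window width *after* the true
fold (cells take time to traverse the saddle), and its magnitude shrinks
toward zero as the per-window sample grows (on these benchmarks it
approaches zero from slightly above).

## Numerical choices

- Regressions: scikit-learn `LinearRegression`/`Ridge`/`Lasso`; ridge
  matches the centered normal-equations closed form to 1e-10.
- ODEs: `scipy.solve_ivp` (LSODA, rtol = atol = 1e-8); SDEs: fixed-step
  Euler–Maruyama (dt = 0.01 toggle/EMT, 0.005 trifurcating), with an error
  raised if a step drives half the state negative (Euler instability) or
  values exceed 1e9.
- Eigenvalues: `numpy.linalg.eigvals`; no symmetry assumed.
- Quantiles/IQR: numpy linear-interpolation percentiles.
- Gene selection ties broken alphabetically; cell sorting ties broken by
  cell id; all stochastic steps seeded — identical seeds give bit-identical
  outputs.

## Known limitations

- The linear window model attributes *statistical* association to
  regulation; confounding by shared upstream drivers produces spurious GRN
  edges (mitigated, not removed, by shrinkage).
- A constant, gene-independent splicing rate; no gene-specific β without
  additional data (e.g., metabolic labeling).
- Pseudotime is an input, not an inference target; a wrong ordering
  invalidates the scan.
- The community heuristics (greedy modularity, Girvan–Newman) can stop
  short of the global modularity optimum on degenerate symmetric graphs
  (bare paths/rings); on modular graphs they match exhaustive enumeration.
- Loom input is not supported (no loompy in the supported environment);
  use MTX+CSV or h5ad.
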