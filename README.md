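# tipscan

Tipping-point detection along single-cell lineages from unspliced/spliced
RNA counts.

Cell-fate transitions — differentiation, the epithelial–mesenchymal
transition (EMT) — are naturally described as saddle-node bifurcations on a
gene-expression landscape: a stable cell state is destroyed and cells fall
through an unstable "tipping point" toward the next attractor.  Standard
scRNA-seq snapshots hide this dynamics, but the imbalance between unspliced
(pre-mRNA) and spliced counts carries temporal information because splicing
lags transcription.  `tipscan` exploits it: given both count layers and a
per-cell lineage ordering (pseudotime or experimental time), it fits a
multivariate splicing model inside a window slid along the ordering,
diagonalizes the model's Jacobian per window, and reads off where the
lineage becomes locally unstable.  The fitted interaction matrix doubles as
a window-resolved gene regulatory network (GRN), whose community structure
and edge-weight spread show how regulation rearranges through the
transition.

The package is aimed at computational biologists who already have spliced
and unspliced matrices (from `velocyto`, `kallisto|bustools`, ...) and a
trajectory ordering, and who want a falsifiable, model-based readout of
*where* along that trajectory cells commit.

## Model

For each gene *i* with unspliced copy number *U<sub>i</sub>* and spliced
copy number *S<sub>i</sub>*,

$$\frac{dU_i}{dt} = A_{i0} + \sum_{j \ne i} A_{ij} S_j - \beta U_i,\qquad
  \frac{dS_i}{dt} = \beta U_i - \gamma_i S_i,$$

where *A* is the cross-species interaction matrix (zero diagonal;
*A<sub>ij</sub>* > 0 activation, < 0 inhibition), β the splicing rate
(gene-independent; time is measured in units of 1/β so β = 1), and
γ<sub>i</sub> the degradation/dilution rates.  Inside each window of cells
the production parameters solve a (optionally ridge- or lasso-penalized)
regression of βU<sub>i</sub> on the other genes' spliced counts, and
γ<sub>i</sub> comes from the spliced steady state by through-origin least
squares.  The Jacobian of this linear system has the four-quadrant form

$$J = \begin{pmatrix} -\beta I & A \\ \beta I & -\mathrm{diag}(\gamma) \end{pmatrix},$$

and an eigenvalue with positive real part marks a locally unstable — tipping
— region.  Per window, the scan reports the largest eigenvalue real part,
the number of positive eigenvalues, and that number normalized by 2M, with
error bars from n = 10 fits on random 90% cell subsamples.

The package also ships ground-truthed stochastic benchmark circuits (a
bistable toggle switch, a tristable EMT circuit, a trifurcating fate
decision) with fixed-point and bifurcation oracles, so the whole pipeline
is exercisable with no external data.

## Worked example

Simulate the toggle-switch benchmark and run the inference from the shell:

```bash
tipscan simulate toggle --n-cells 2000 --seed 1 --out sim/
tipscan infer --unspliced sim/unspliced --spliced sim/spliced \
    --ordering sim/ordering.csv --out out/ --width 200 --increment 50 --n-genes 2
tipscan grn --fit-dir out/ --algorithm greedy_modularity
```

or from Python:

```python
import numpy as np
from tipscan.circuits import simulate_toggle, bifurcation_param
from tipscan.windows import WindowConfig, scan_lineage

lineage = simulate_toggle(n_traj=50, n_samples=40, seed=1)   # 2000 cells
profile = scan_lineage(lineage.counts, WindowConfig(width=200, increment=50, seed=1))
lam = profile.summary["largest_real_mean"]
spec = lineage.spec
print("fold at beta1* =", round(bifurcation_param(spec, 1.0, 8.0), 4))
print("profile ends:", round(lam.iloc[0], 3), round(lam.iloc[-1], 3))
print("peak:", round(lam.max(), 3), "at ordering",
      round(profile.window_positions[int(np.argmax(lam))], 1))
```

Output:

```
fold at beta1* = 2.3905
profile ends: -0.506 -0.848
peak: 0.036 at ordering 19.5
```

Reading: the circuit's low-X state is destroyed at β₁\* = 2.39 (ramp time
≈ 15.9 of 80).  The inferred largest-eigenvalue profile is clearly negative
at both lineage ends (stable attractors) and peaks above zero at ordering
≈ 19.5 — the window where cells traverse the saddle, one window width after
the fold, as expected from the finite-speed ramp.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the toggle-switch benchmark end to end — stochastic simulation,
window scan, instability score, GRN community trajectory, and the
independent bifurcation oracle — printing a run summary.  The source
publication reports no standalone desk-scale numeric values to reproduce,
so the JSON it writes is an empty object; the scientific checks live in
`tests/test_acceptance.py`.

## Layout

- `tipscan.model` — splicing-model parameterization, Jacobian assembly, spectral metrics
- `tipscan.windows` — cell ordering, sliding-window regression, stability profiles, instability/signature scores
- `tipscan.grn` — sender-rescaled GRNs, Girvan–Newman / greedy-modularity communities, betweenness, edge-weight spread
- `tipscan.circuits` — benchmark circuits, deterministic/stochastic simulation, fixed-point and fold oracles
- `tipscan.io` / `tipscan.cli` — MTX+CSV and h5ad I/O, fit persistence, the `tipscan` command

See `docs/methods.md` for modeling assumptions, parameter choices and known
limitations.
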