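# Methods

## The design problem

A modified-release formulation is specified by a target release profile: at
each sampled time point t_q the percent of drug dissolved has a lower
specification limit LSL_q, a target T_q and an upper limit USL_q. The design
task is to choose settings of k controllable factors so that the profile of
a produced batch tracks the targets with low dispersion. `releaseopt` treats
this as a robust-parameter-design problem over four families of statistics of
the replicated dissolution experiment: the per-timepoint mean, variance and
coefficient of variation, and the covariance between time points.

All modelling is done on coded factors, x = (natural − center)/scale. Codings
are stored explicitly per factor rather than derived from the levels, because
several of the packaged case studies use codings that are not
midpoint/half-range (one codes a 93.71–234.31 mg range by (x − 93.71)/7.03,
giving coded levels 0–20). Only linear codings are supported.

## Statistics and model

Replicates are paired across time points — replicate w at time i and time j
is the same vessel — which is what makes the within-run inter-timepoint
sample covariance estimable with denominator m−1. Unpaired data is rejected
rather than guessed at, and there is no outlier rejection or imputation.

Each statistic is regressed on the coded factors by ordinary least squares
over a second-order polynomial term set (intercept, x_i, x_i², x_i x_j). Term
sets are stored per surface: published coefficient tables sometimes omit
terms, and the stepwise screener returns subsets. CV surfaces are fitted
directly to the per-run (s/ȳ) values, not derived from the fitted mean and
variance surfaces. The stepwise screener is bidirectional with
p-to-enter = p-to-remove = 0.05 by default and screens at the *factor* level
(all terms of a factor enter or leave together, judged by a partial F test),
matching how screening is used in the multi-factor case study; tie-breaks are
by smallest p-value, then canonical term order, so selection is
deterministic.

## Desirability conventions

Individual desirabilities are the Derringer–Suich piecewise-power maps with
default exponents r = s = 1 and equal weights across all components (the
weights are per-response configuration). The composite is computed as
exp(Σ w·log d / Σ w) with log 0 = −∞, so no epsilon flooring ever distorts a
component and any zero-desirability component annihilates the candidate
point exactly.

The case studies state NTB limits only for the mean-type responses. For the
dispersion statistics the package defines its own convention:

* **variance, CV**: smaller-the-better with lower ideal 0 and highest
  acceptable value equal to `dispersion_bound_factor` × the largest fitted
  value of that statistic over the coded design points (default factor: 6).
  Negative fitted values — possible from unconstrained OLS — are clamped to 0
  (desirability 1) with a logged warning. A fitted dispersion below 1e−9
  everywhere on the design is numerical noise and contributes no component.
* **covariance**: nominal-the-best with target 0 and a symmetric band of the
  same multiple of the largest fitted |covariance|; robustness of the profile
  requires inter-timepoint covariances near zero, so zero is the natural
  target.
* **scalar indices without printed limits** (the f2 similarity factor):
  larger-the-better with lowest acceptable value 50 — the conventional f2
  similarity threshold — and upper ideal 100, the value attained by identical
  profiles. t50 and mean dissolution time carry printed NTB limits and are
  treated like any NTB response.

The factor 6 deserves explanation, because the obvious convention — cap each
dispersion statistic at the worst value seen across the design (factor 1) —
fails in practice: it turns dispersion statistics into hard feasibility
constraints that the mean specifications never imposed, and under it the
halved-bound sensitivity setting leaves *no* feasible point in two of the
packaged case studies. With the looser default the dispersion components act
as soft preferences (they rank candidate settings but rarely veto them), and
the reproduced boundary optima of the diclofenac and metformin studies are
unchanged for any factor in roughly [3, 16] — in particular across the
×0.5/×1/×2 sensitivity sweep that `sensitivity_sweep` and the CLI `--sweep`
flag report. Because the bound convention is an invention of necessity, every
optimum should be read together with that sweep.

## Optimizer

Maximization over the coded box uses a dense deterministic grid (41 points
per axis for k ≤ 3, 11 for k ≤ 5, 5 above) followed by a bounded Nelder–Mead
polish started from the best grid cell; the polished point is kept only if it
improves the objective, ties on the grid are broken by the lexicographically
smallest coded point, and reruns are bit-identical. The default box is each
factor's coded level range. When every grid point has zero composite
desirability the solver raises an error naming the fraction of the grid each
component annihilates, which localizes the offending specification
immediately. No global-optimality guarantee beyond the grid resolution is
claimed; doubling the resolution can only improve the reported objective.

## Synthetic experiments

The generator draws replicate release vectors from a multivariate normal
whose mean is the vector of true surface values at the run's coded setting
and whose covariance is a user-chosen inter-timepoint matrix Σ (PSD
enforced), with m = 3 replicates by default — a typical dissolution-test
batch size; the case studies do not state their replicate counts. This
emulates the paired-replicate experimental layout exactly, which is what the
covariance statistics assume. It does *not* emulate several features of real
dissolution data: percent-released is bounded in [0, 100] and monotone in
time within a vessel, neither of which a normal draw enforces; measurement
error is typically heteroscedastic over the profile; and real designs are
often fractional rather than full factorials. Tests that pass on this
generator therefore validate the estimation and optimization machinery, not
the distributional realism of dissolution assays.

A degenerate-geometry note for test design: a true mean surface that peaks
*exactly* at its NTB target has desirability 1 on an entire level set once
any perturbation pushes the peak above target, making the maximizer
non-unique. The packaged synthetic truth therefore peaks slightly below
target, so its desirability stays on the rising side and the apex is the
unique optimum.

## The packaged case studies and what reproduces

Fixtures are verbatim transcriptions, including known defects, each flagged
in the fixture's `notes` and `coding_consistent` fields rather than silently
corrected: a garbled covariance term stored with an assumed sign split
(diclofenac), a printed coding inconsistent with its own levels (metformin,
resolved to center 1.75/scale 0.5, which reproduces that study's decode
table), and three reported coded/natural optimum pairs that contradict their
own codings (verapamil duration, ranitidine gelucire, and the last printed
digit of terazosin NaH₂PO₄).

Reproducibility of the reported optima from the published surfaces, under
the conventions above:

* **metoprolol** reproduces fully: the composite uses only mean-type
  surfaces (no dispersion convention enters) and the solver lands within
  ~0.01 coded units of the reported interior optimum.
* **diclofenac x₃ = 1** and **metformin x₃ = −1** (boundary components)
  reproduce and are stable across the sensitivity sweep; verapamil's
  x₃ = 1 boundary likewise.
* The **interior components** of the diclofenac optimum and the **metformin
  x₁ = 1** component do *not* reproduce, under this or any bound convention
  we tested: at the reported diclofenac point the fitted 6 h and 8 h means
  are 69.6 and 79.8 against targets of 60 and 72.5 (desirabilities 0.04 and
  0.02), and at the reported metformin point the fitted 0.5 h mean is 25.98
  against a USL of 26 with every dispersion surface worse than at the actual
  maximizer. Those reported points are dominated under equal weights, so
  they cannot be maxima of this composite of these surfaces. The test suite
  keeps two failing tests asserting them, as an honest record.
* **terazosin** is infeasible outright: the fitted 1 h mean surface never
  reaches its LSL of 8.8 anywhere on the coded box (its maximum is ≈ 8.36),
  so the composite is identically zero and the solver reports which
  components annihilate. The fixture is retained for coding and
  transcription regression.

## Numerical choices

* OLS via `numpy.linalg.lstsq`; rank deficiency raises an error naming the
  collinear columns (diagnosed from the R factor of a QR decomposition). The
  tests cross-check coefficients against an independent normal-equations
  solve to 1e−8.
* f1 uses absolute differences |R_t − T_t| (without them the index could be
  negative, contradicting its role as a magnitude) and f2 places the ×100
  inside the log₁₀, so identical profiles give exactly f2 = 100; both follow
  the standard regulatory definitions.
* Desirability ramp bases are clipped to [0, 1] before fractional exponents
  are applied, so no invalid-power warnings arise outside the support.
* Nelder–Mead polish runs with xatol 1e−8, fatol 1e−12, at most 2000
  iterations, clipped to the box.

## Known limitations

* The dispersion desirability bounds are a package convention, not data;
  conclusions that depend on them should cite the sensitivity sweep.
* No lack-of-fit testing, cross-validation or regularization; surfaces are
  taken at face value inside the box, and extrapolation beyond the design
  region is unguarded except by the box itself.
* The expected-total-cost formulation of the design problem (loss plus
  out-of-spec penalty costs) is out of scope: its cost coefficients and
  response densities are never available in the case studies.
* Optimization over more than ~5 factors relies on a coarse grid; the
  deterministic design favors reproducibility over large-k scalability.
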