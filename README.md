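# releaseopt

Parameter design for modified-release drug formulations. Given replicated
dissolution experiments over controllable factors (polymer content, stirring
speed, coating level, ...), `releaseopt` fits second-order response surfaces
for the time-pointwise statistics of percent drug released and finds the
factor settings whose predicted release profile best matches a prescribed
target profile, scored by a Derringer–Suich composite desirability.

## Who it is for

Formulation scientists and quality engineers designing controlled-release
dosage forms: the release profile is a *time-oriented quality
characteristic* — at each sampled time point t_q the percent released y_q has
a lower specification limit, a target and an upper specification limit — and
the design task is to choose factor settings so the whole profile sits on
target with low batch-to-batch dispersion.

## Method

1. **Summary statistics** (per design run r, from m paired replicates): mean
   ȳ_qr, sample variance s²_qr (denominator m−1), coefficient of variation
   (s/ȳ)_qr, and the inter-timepoint sample covariance s_{ij,r} across
   replicates.
2. **Response surfaces**: each statistic is regressed on the coded factors
   x = (x₁,…,x_k), coded by x = (natural − center)/scale, with a full
   second-order model (intercept, linear, quadratic, pairwise interactions)
   fitted by OLS, β̂ = (X′X)⁻¹X′y. Optional bidirectional stepwise screening
   (partial F tests, factor-level grouping) reduces the factor set first.
3. **Desirability**: each fitted statistic is mapped to [0, 1] —
   nominal-the-best for means (0 at LSL/USL, 1 at T), smaller-the-better for
   variance and CV (ideal 0), nominal-the-best with target 0 for covariances
   (robustness requires near-zero inter-timepoint covariance). The composite
   objective is the weighted geometric mean

   D_total(x) = [ Π D_μᵢ^wᵢ · Π D_s²ᵢ^w′ᵢ · Π D_cvᵢ^w″ᵢ · Π D_sᵢⱼ^w‴ᵢⱼ ]^(1/Σw)

   so a single unacceptable component (d = 0) annihilates the candidate.
4. **Optimization**: maximize D_total over the coded box with a deterministic
   dense grid scan plus bounded Nelder–Mead polish.

Also included: the regulatory profile-comparison indices
f1 = 100·Σ|R_t−T_t|/ΣR_t and f2 = 50·log₁₀(100·[1 + mean(R_t−T_t)²]^(−½)),
and the competing MSE objective Σ(μ̂_q−T_q)² + Σv̂_q for comparison.

Six published case studies (diclofenac, terazosin, verapamil, metformin,
ranitidine, metoprolol) ship as packaged fixtures: study configuration,
transcribed surface coefficients, and the originally reported optimum with
provenance notes. See `docs/methods.md` for conventions, transcription
caveats, and a reproducibility analysis of the reported optima.

## Worked example

The metoprolol matrix-tablet study has two factors (% xanthan gum, %
Methocel) and six responses: percent released at 1, 4 and 12 h (NTB limits),
t50 and mean dissolution time (NTB), and the f2 similarity factor (LTB).

```python
from releaseopt import solve_example

res = solve_example("metoprolol")
print([round(v, 4) for v in res.coded_optimum])
print([round(v, 3) for v in res.natural_optimum])
print(round(res.objective_value, 4))
for b in res.breakdown:
    print(f"{b['component']:>5s}  value={b['value']:8.3f}  d={b['desirability']:.4f}")
```

prints

```
[0.0542, 0.6669]
[30.542, 26.669]
0.7813
mu_y1  value=  17.500  d=1.0000
mu_y2  value=  33.933  d=0.6067
mu_y3  value=  64.276  d=0.8552
  t50  value=   7.128  d=0.8722
  MDT  value=   9.000  d=1.0000
   f2  value=  75.143  d=0.5029
```

i.e. 30.5 % xanthan gum and 26.7 % Methocel: the 1 h release and the mean
dissolution time sit exactly on target, the 4 h release runs 3.9 points above
its 30 % target, and the predicted f2 against the reference profile is 75.
The originally reported optimum for this study, (0.0458, 0.6726) coded, is
reproduced to within ~0.01 coded units.

The same pipeline is available from the shell:

```bash
releaseopt examples list
releaseopt optimize --example diclofenac --sweep --report report.json
releaseopt fit --data table.csv --out coeffs.yaml
releaseopt optimize --study study.yaml --surfaces coeffs.yaml --report out.json
releaseopt indices reference.csv test.csv
```

Every report echoes the conventions used (dispersion desirability bounds,
weights, exponents, grid resolution), and `--sweep` re-solves with the
dispersion bounds halved and doubled so the stability of the optimum is part
of the output.

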