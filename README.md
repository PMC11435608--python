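# ptesr

Source apportionment and human health risk assessment for **potentially
toxic elements (PTEs)** — Fe, Mn, Cu, Zn, Al, Hg, As, Se, Cd, Pb, Li, B,
Ba, Sb, Ni, Co, Mo — in surface water, built for small river-survey
datasets (tens of samples) of the kind collected around coal-mining
catchments.

The package answers two questions a water-quality scientist asks of a
samples × analytes concentration table (μg/L):

1. **Where do the elements come from?** Uncertainty-weighted positive
   matrix factorization (PMF) decomposes the concentration matrix
   `X (n×m) = G (n×p) · F (p×m) + E` into `p` non-negative source
   contributions `G` and source profiles `F` by minimizing

   `Q = Σᵢⱼ (eᵢⱼ / uᵢⱼ)²`,

   with per-cell uncertainties from the two-branch detection-limit rule:
   `u = (5/6)·MDL` when `x ≤ MDL`, else `u = √((EF·x)² + (0.5·MDL)²)`
   (MDL = method detection limit, EF = error fraction). The optimizer is
   from-scratch alternating non-negative weighted least squares with
   multi-start, exposed as a scikit-learn-style estimator (`WeightedPMF`).

2. **Do the concentrations matter for people?** The USEPA deterministic
   oral-ingestion model per sample and population group (children / men /
   women): chronic daily intake `CDI = C·10⁻³·IR·EF·ED / (BW·AT)`, hazard
   quotient `HQ = CDI/RfD`, hazard index `HI = ΣHQ` (level I ≤ 1 < level
   II), cancer risk `CR = CDI·SF` (arsenic; five bands from <10⁻⁶ to
   >10⁻³), and cumulative cancer risk `CCR = ΣCR`.

Around these sit descriptive hydrochemistry (means, coefficients of
variation, drinking-limit exceedance), a synthetic-data generator with
known factor structure for validation, and a CLI (`ptesr`) that chains the
stages into a reproducible run report.

## Worked example

```python
from ptesr import (SyntheticSpec, generate, substitute_censored,
                   build_uncertainty, fit_pmf, PMFConfig, match_factors,
                   summarize, rank, assess)

# a 41-sample survey (34 surface + 5 ground + 2 mine), 17 analytes,
# 4 true sources, 10% multiplicative noise, 5% censoring
table, truth = generate(SyntheticSpec(seed=7))

print(" > ".join(rank(summarize(table), "mean")[:6]))
# Fe > Al > Mn > Zn > Ba > B

w = substitute_censored(table.subset("surface"))
sol = fit_pmf(w.matrix(), build_uncertainty(w),
              PMFConfig(p=4, n_starts=20, seed=7))
print(f"Q = {sol.Q:.1f}, converged = {sol.converged}")
# Q = 106.9, converged = True
print([round(float(x), 1) for x in sol.factor_percent])
# [12.4, 39.0, 37.7, 10.9]         share of reconstructed mass per source
perm, cos = match_factors(sol.F, truth.F_true)
print(f"mean cosine vs true profiles: {cos:.3f}")
# mean cosine vs true profiles: 0.934

summary = assess(table).summary()["children"]
print(f"HI <= 1 for {summary['pct_hi_acceptable']:.2f}% of samples")
# HI <= 1 for 100.00% of samples
```

The factor shares say how much of the total reconstructed concentration
mass each source explains; the cosine of 0.934 shows the fitted profiles
match the generator's true source signatures closely — the residual gap
is mostly rotational ambiguity between equally valid factorizations, not
noise (see `docs/methods.md`). The hazard-index line reads: for the most
exposed group (children), every sample of this draw sits below the
non-carcinogenic threshold of 1.

The same pipeline from the shell:

```bash
ptesr synth --seed 7 --out data.csv --truth truth.json
ptesr run --input data.csv --factors 4 --starts 20 --seed 7 --out-dir results/
```

writes `summary.csv`, `G.csv`, `F.csv`, `residuals.csv`,
`pmf_diagnostics.json`, `risk.csv`, `risk_summary.json` and a Markdown/JSON
run report.

## Caveats

Bundled MDL/EF values, drinking limits beyond Hg/Cd/As/Se, and exposure
parameters are clearly labelled placeholders — override them with your
laboratory's and jurisdiction's values via the YAML configs. Only the oral
ingestion pathway is assessed (no dermal/inhalation), and the risk model is
deterministic, not Monte-Carlo. PMF rotational ambiguity is not explored
(no bootstrap/DISP); choose `p` with `scan_p` and judge profiles on domain
grounds.
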