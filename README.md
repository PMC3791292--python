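# pdmri — permeability–diffusivity modeling of multi-shell diffusion MRI decay

At diffusion weightings beyond roughly b = 1000 s/mm², the decay of the MRI
diffusion signal in brain tissue is no longer mono-exponential: it is well
described by two apparent water pools, an *unrestricted* one (far from
membranes) and a *restricted* one (near membranes). `pdmri` fits the
two-compartment decay model to shell-averaged multi-shell signal,

    S(b) = S0 · [ Mu · exp(−b·Du) + (1 − Mu) · exp(−b·Dr) ],

where `Mu` is the signal fraction of the unrestricted pool and
`Du ≥ Dr` (mm²/s) are the apparent diffusion coefficients of the
unrestricted and restricted pools. The headline scalar is the
**permeability–diffusivity index**

    PDI = Dr / Du ∈ [0, 1],

which, in the permeable-membrane account of bi-exponential decay, rises
steeply with the water permeability of cellular membranes while `Mu` moves
only modestly. The related dimensionless effective permeability is
`μ_eff = μ·d/D0` (membrane water flux μ in mm/s, compartment distance d in
mm, free-water diffusivity D0 in mm²/s); the physiological flux span
0.1–1 mm/s maps onto μ_eff = 0.01–0.1.

The package is aimed at neuroimaging researchers who want to evaluate PDI as
a white/gray-matter integrity marker (e.g. patient–control contrasts in the
corpus callosum and cingulate cortex) without access to raw scanner data. It
provides:

- **`pdmri.io`** — bval/bvec gradient tables (two-file whitespace dialect),
  b-shell grouping, long-format per-ROI signal tables as plain CSV.
- **`pdmri.decay`** — statsmodels-style `BiExponentialDecayModel` /
  `MonoExponentialDecayModel` whose `.fit()` returns results objects with
  estimates, standard errors, r², convergence/boundary diagnostics,
  `summary()` and `plot()`; plus a brute-force grid oracle for testing.
- **`pdmri.metrics`** — PDI, μ_eff and fit-quality propagation.
- **`pdmri.simulate`** — synthetic cohorts on the emulated 15-shell protocol
  (b = 250–3800 s/mm², 30 directions/shell, 16 b = 0 volumes) with group
  effects, PDI age trends, FA–PDI coupling via a Gaussian copula, gray–white
  PDI coupling, and Rician noise anchored at a configurable SNR (default 6.1
  on the highest-shell corpus-callosum signal).
- **`pdmri.stats`** — pooled-variance t-tests with Cohen's d and Bonferroni
  correction (family N = 12), age regressions, Fisher r-to-z correlation
  contrasts, the median-split analysis, and a one-call cohort report.
- **`pdmri` CLI** — `validate`, `simulate`, `fit`, `stats`, `run-all`.

## Worked example

Synthesize one corpus-callosum decay curve at the published patient-group
parameters (S0 = 1, Mu = 0.55, Du = 1.8e−3, Dr = 7.1e−5 mm²/s), corrupt it
with Rician noise near the protocol SNR, and fit it back:

```python
from pdmri import (mbi_btable, group_shells, synthesize_signal,
                   add_rician_noise, shell_average, fit_biexp,
                   metrics_from_fit, mu_eff)

shells = group_shells(mbi_btable())          # b=0 shell + 15 shells, 466 volumes
signal = synthesize_signal((1.0, 0.55, 1.8e-3, 7.1e-5), shells, mode="per-direction")
noisy  = add_rician_noise(signal, sigma=0.056, seed=20)
fit    = fit_biexp(shell_average(noisy, shells))
print(fit.summary())
print(f"PDI = {metrics_from_fit(fit).pdi:.4f}")
print(f"mu_eff span: {mu_eff(0.1, 1e-3, 1e-2):.3g} - {mu_eff(1.0, 1e-3, 1e-2):.3g}")
```

which prints

```
Two-compartment decay fit
-------------------------
  S0      0.988599   (se 0.0117)
  Mu      0.564531   (se 0.0293)  (unrestricted fraction)
  Du    0.00177101   (se 0.000152)  mm²/s (unrestricted)
  Dr   4.95879e-05   (se 2.26e-05)  mm²/s (restricted)
  r²      0.995818
  converged: True   at_bound: False   shells: 16
PDI = 0.0280
mu_eff span: 0.01 - 0.1
```

The fit recovers S0, Mu and Du tightly; Dr — and hence PDI — carries the
bulk of the noise sensitivity (one noisy curve here yields PDI 0.028 against
a generating 0.039, consistent with the ~12% median error measured across
replicates below). On noiseless input the same fit recovers all four
parameters to better than 1e−6 relative with r² = 1.

A whole cohort takes one call each:

```python
from pdmri import generate_cohort, study_config, analyze_cohort
cohort = generate_cohort(study_config(), seed=1)      # 26 patients / 26 controls
fits, report = analyze_cohort(cohort)                 # fit + full statistics
print(report.summary())
```

or, from the shell, `pdmri run-all --seed 1 --out out/`.

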