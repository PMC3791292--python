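# Methods

## The decay model

`pdmri` models the direction-averaged diffusion signal of one region of
interest as a two-compartment (bi-exponential) decay in the diffusion
weighting b,

S(b) = S0·[Mu·exp(−b·Du) + (1 − Mu)·exp(−b·Dr)],

with the unrestricted signal fraction Mu ∈ [0, 1] and apparent diffusion
coefficients Du ≥ Dr ≥ 0 (mm²/s). The "compartments" are functional, not
anatomical: the bi-exponential shape is the signature of water exchanging
across semi-permeable membranes, and within the physiological permeability
range the restricted coefficient Dr responds most strongly to membrane
permeability. The permeability–diffusivity index PDI = Dr/Du is therefore
the summary statistic of interest; it is scale-invariant and lies in [0, 1]
under the labeling convention below. PDI increases monotonically with
effective membrane permeability μ_eff = μ·d/D0 — steeply (order 1000%
across the physiological range) where the unrestricted fraction Mu moves
only ~10% — which is why group contrasts are run on PDI rather than Mu.
The model is isotropic: it carries no gradient-direction dependence, so
per-direction synthetic signals simply replicate each shell's value and the
fit consumes shell means ("the average diffusion-weighted signal for a
given b-value").

The model function is symmetric under (Mu, Du) ↔ (1 − Mu, Dr). Every
returned fit is relabeled to Du ≥ Dr (swapping Mu for 1 − Mu if the
optimizer inverted the components), so reported Mu, Du, Dr and PDI are
always comparable across subjects.

## Fitting

Fits are constrained nonlinear least squares in signal space with
unweighted residuals (no log transform, which would distort the noise at
low SNR). Bounds: S0 > 0, 0 ≤ Mu ≤ 1, 0 ≤ Dr, Du ≤ 0.05 mm²/s — the upper
bound is an order of magnitude above free water and only prevents runaway
components on degenerate input. S0 is a free parameter (initialized at the
lowest-b shell mean) rather than fixed, which keeps the fit robust to the
Rician bias of the b = 0 average.

Starting values come from exponential peeling: a log-linear fit of the
high-b tail (b ≥ 2500 s/mm²) estimates the slow component (Dr and its
amplitude), and a log-linear fit of the tail-subtracted low-b segment
(0 < b ≤ 1000) estimates the fast one; the amplitude ratio gives Mu. The
segment thresholds follow the shell design, which places seven shells at or
below 1000 and four at or above 2500 s/mm²; protocols without enough shells
in those windows fall back to a median split of the non-zero b-values, and
fully degenerate inputs fall back to (Mu, Du, Dr) = (0.5, 1.5e−3, 1e−4).

Numerical choices: scipy `least_squares` (trust-region reflective) with an
analytic Jacobian, per-parameter scaling (x_scale S0, 1, 1e−3, 1e−4), and
ftol = xtol = 1e−12. The tight tolerances cost little on a 16-point problem
and are what make noiseless recovery deterministic at the 1e−6 relative
level on Dr ~ 7e−5 mm²/s. Non-convergence never raises: the results object
carries `converged=False`. A boundary flag marks fits with any parameter at
a bound or with Du ≈ Dr (degenerate compartments); the metrics layer
propagates it as a quality warning. Goodness of fit is r² = 1 − SSR/SST in
signal space about the mean shell signal; the mono-exponential fit
S0·exp(−b·ADC) (log-linear initialization, same machinery) provides the
nested reference model, so the bi-exponential residual can never exceed the
mono residual. A brute-force grid minimizer over (S0, Mu, Du, Dr) serves as
an independent oracle in the tests — the constrained fit started from the
best grid point must end at or below the grid minimum.

The b = 0 shell enters the fit as an ordinary data point (it is not used to
normalize the curve away), and the average of its 16 volumes initializes S0.

## The synthetic cohort generator

The generator exists so that every downstream stage — fitting, metrics,
cohort statistics — is testable end to end without any acquisition. Its
defaults emulate the study conditions the published summary tables
describe.

**Protocol.** Fifteen shells at b = 250, 500, 600, 700, 800, 900, 1000,
1250, 1500, 1750, 2000, 2500, 3000, 3500, 3800 s/mm² with 30 directions per
shell (a golden-spiral isotropic set) plus 16 b = 0 volumes: 466 volumes.
Shell grouping uses a 25 s/mm² tolerance, half of the smallest inter-shell
gap.

**Subjects.** Two groups of 26 (patients/controls), ages uniform on 20–61
years, sex drawn at the published group proportions, BMI N(28, 5²),
chlorpromazine-equivalent dose for patients N(400, 200²) mg truncated at 0
and — deliberately — independent of every imaging parameter, so the
dose-correlation analysis has a true null to calibrate against.

**Decay parameters.** Per ROI and group, Mu, Du, Dr are truncated-Gaussian
draws (Mu to [0, 1], diffusivities to (0, ∞)) at the published mean ± SD
summaries for the whole corpus callosum, genu, body, splenium and cingulate
gray matter; a draw with Du < Dr is re-ordered. Age enters PDI linearly:
PDI = Dr/Du + slope·(age − 40.5), with the published decline magnitudes
(patients −3.3e−4/yr, controls −2.0e−4/yr for whole CC; −4.3e−4 and
−2.5e−4 for the genu) and Dr back-computed as PDI·Du, since the age trends
are reported on PDI, not on Du. Gray-matter Du is not published; the
generator uses 1.2e−3 mm²/s (a plausible cortical fast-pool value) and
back-computes the Dr means from the published gray-matter PDI means. A CSF
reference ROI is generated as pure mono-exponential with D = 3.0e−3 mm²/s
(free water); that diffusivity is a conventional choice, not a fitted
quantity.

**Couplings.** FA scalars are produced with a Gaussian copula on the
realized PDI: FA = mean + sd·(r·z_PDI + √(1−r²)·ε) with the published
per-group target correlations (e.g. genu r = .72 patients vs .03 controls),
clipped to [0, 1]. The cingulate–CC PDI coupling (r ≈ .7 both groups) is
induced by correlating the two ROIs' restricted-diffusivity latents.
Targets with |r| > 1 or a non-positive-definite structure raise a
configuration error.

**Noise.** Magnitude signals get Rician noise: |s + g₁ + i·g₂| with
g₁, g₂ ~ N(0, σ²). σ is anchored to the SNR of the highest-b "average
diffusion image": σ = (noiseless corpus-callosum signal at b = 3800)/SNR,
default SNR 6.1. σ = 0 (SNR = None) returns the noiseless signal exactly.
Every draw comes from one seeded generator, with ROIs and groups visited in
sorted-name order, so a config plus a seed reproduces a cohort
bit-for-bit regardless of the mapping order the config arrived in.

**What the generator does not emulate.** No anisotropy or crossing fibers
(the model itself is direction-free), no voxel images, no spatial
correlation between ROIs beyond the configured couplings, no motion/eddy
artifacts, and Gaussian parameter marginals rather than whatever the true
biological distributions are. Passing tests therefore demonstrate that the
pipeline is correct and well calibrated *under the stated generative
model* — they do not validate the biological claims on real data. One
consequence worth knowing: because the generator draws Dr and Du and forms
PDI as their ratio, the realized regional PDI group separation (mean
Cohen's d ≈ 0.6 at the genu) is smaller than the effect size implied by the
published per-subject PDI summaries (d = 1.14) — the published regional PDI
means are means of per-subject ratios and fold in the age trend, and the
published ratio-component summaries do not reproduce them exactly.

## Cohort statistics

Group differences use the pooled-variance two-tailed Student t
(df = n₁+n₂−2); with equal groups of 26 this is the conventional reading of
a "two-tail t-test". Cohen's d uses pooled SD √((s₁²+s₂²)/2) at equal n
(the (n−1)-weighted form otherwise) — this convention reproduces the
published genu effect size d = 1.14 from the printed group summaries — and
is signed like the t statistic. Multiplicity over the regional comparison
family uses Bonferroni with N = 12 exactly (4 measures × 3 subregions);
no further multiplicity layers are stacked on top. Age trends are ordinary
least squares with Pearson r and a two-tailed p from the t distribution on
n − 2 df. Differences between independent correlations use the Fisher
r-to-z contrast, z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)); on the
published genu correlation pair (.72 vs .03 at 26/26) the closed form gives
p ≈ .003. The median-split analysis ranks all subjects on corpus-callosum
PDI and splits them evenly (odd n puts the median subject in the lower
half; heavy ties produce a warning, not an error), then reports per-half
PDI–FA correlations, group composition and a between-half age comparison.
All reported p-values are two-tailed. Degenerate inputs (zero variance,
constant signal) raise typed errors rather than returning NaNs; the report
orchestrator converts missing-input analyses into explicit skip notes.

## Problem sizes and determinism

The test suite and acceptance script use: 200 noisy replicates for the
PDI-error summary, 1000 cohorts for type-I calibration and age-slope
recovery, 100 seeds for familywise control, 500 cohorts for the gray-matter
power check, 2000 permutations for the permutation oracle, and 2000
replicates for p-uniformity KS tests. These sizes put Monte-Carlo error
comfortably inside the asserted bands while keeping a full run fast on one
CPU. Statistical-calibration checks run the statistics layer on drawn true
parameters directly (signal synthesis and fitting would only add
independent noise to a property that concerns the statistics layer).
Every stochastic step is seeded; the full simulate → fit → stats chain is
byte-reproducible for a fixed seed.

## Known limitations

- No kurtosis, stretched-exponential or ≥3-compartment alternatives; model
  comparison is limited to the nested mono/bi pair.
- The PDI–permeability link is used qualitatively (monotone increase); the
  quantitative curve from the underlying membrane-permeability theory is
  not computed here.
- PDI > 1 cannot occur under the Du ≥ Dr convention; if unlabeled
  parameters are supplied directly, the raw ratio is returned with a
  warning rather than clamped.
- Fitted standard errors come from the Gauss–Newton covariance
  approximation and are indicative only at SNR ~6.
- The CSF ROI's fitted parameters at realistic SNR reflect the Rayleigh
  noise floor at high b (a small spurious slow component); this mirrors
  real magnitude data and is left as-is.
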