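# Methods

## Model and estimators

Receptor-gene expression x (RMA-normalized log2 intensity of one probe
set) is modelled as a two-component Gaussian mixture
f(x) = (1−π⁺)·N(μ⁻, σ⁻) + π⁺·N(μ⁺, σ⁺). The receptor-negative component
is by convention the lower-mean one; every fitter relabels its result so
that μ⁻ < μ⁺ before returning, which makes component identity independent
of initialization order. The three mixture estimators differ only in what
they take from IHC:

* **ParEst**: sample mean and unbiased SD per IHC class; samples with
  missing IHC are dropped from both the moments and the abundance
  λ⁺ = N⁺/(N⁺+N⁻) (the convention adopted for missing labels throughout).
* **MaxLike**: L-BFGS-B maximization of the observed-data log-likelihood
  over (μ⁻, μ⁺, σ⁻, σ⁺) with the weight fixed at λ⁺. The gradient is
  analytic (posterior-weighted per-component score) and is verified
  against central finite differences in the tests (relative error <
  1e-5). L-BFGS-B was chosen over a pure Newton iteration because the
  target is flat near the optimum and quasi-Newton steps with analytic
  gradients are robust there; the bound constraints also host the
  variance floor.
* **ExMax**: standard EM over all five parameters. E-step: posterior
  responsibilities via log-sum-exp; M-step: weighted moments and weight
  update π⁺ = (Σ γᵢ)/N. The observed log-likelihood is non-decreasing by
  construction and the loop stops when its absolute change falls below
  1e-8 or after 1,000 sweeps (then `converged=False`, never silent).

Initialization: when IHC-derived class moments are available they may be
passed as `init`; otherwise the cohort is split at its median and
half-sample moments seed the loop. Both paths are deterministic, so a
given cohort always produces the same fit.

Numerical guards: a variance floor σ ≥ 1e-3 blocks the singular
likelihood spikes a Gaussian mixture develops around single points, and a
component whose responsibility mass drops below two samples raises a
degenerate-fit error (component death) instead of returning a
one-point "cluster".

## Confidence intervals

Wald intervals come from the observed Fisher information: the Hessian of
the negative log-likelihood at the estimate, computed by central
differences of the analytic gradient (step 1e-4 per unit of parameter
scale), inverted, and scaled by 1.96. The parameter vector is the four
distribution parameters with the mixing weight held fixed — the
convention that matches reporting the four (μ, σ) intervals per receptor;
treating π⁺ as a fifth free parameter would perturb those four intervals
only in the third decimal for well-separated components but would change
what the intervals condition on. A condition number above 1e12 raises a
non-identifiability error (e.g. two coincident components) rather than
returning meaningless intervals. The tests check the intervals against a
parametric bootstrap (agreement within a factor 1.5) and the closed-form
1.96·σ/√n limit for well-separated components.

## Cut-points and the critical domain

Equating the two posteriors gives a quadratic in x:

a x² + b x + c = 0, with
a = 1/σ⁻² − 1/σ⁺²,
b = −2(μ⁻/σ⁻² − μ⁺/σ⁺²),
c = (μ⁻/σ⁻)² − (μ⁺/σ⁺)² + 2·log((σ⁻/σ⁺)·(w⁺/w⁻)).

Note the factor 2 on the log term: it follows directly from taking logs
of w⁻f⁻(x) = w⁺f⁺(x) and multiplying by 2, and it is required to
reproduce the published cut-points (without it the ER cut-point comes out
at 9.440 instead of 9.363/9.364). The root between the component means is
the cut-point; when |a| < 1e-12 (equal variances) the equation is linear
and −c/b is used. The returned threshold satisfies r⁻ = r⁺ = 0.5 to 1e-8.

The critical-domain bounds solve r⁻(x) = 1−α (lower) and r⁺(x) = 1−α
(upper). Writing g(x) = log[w⁻f⁻(x)/(w⁺f⁺(x))] (r⁻ is the logistic of g),
both are the same quadratic shifted by 2·log((1−α)/α), solved in closed
form. Root selection matters: when one component is much wider than the
other, g is non-monotone and a second, spurious root appears on the
rising branch (the PGR shape). Only roots inside (μ⁻, μ⁺) with g′ < 0
qualify; among qualifying roots the one nearest the cut-point is taken,
guaranteeing x_lower ≤ cut-point ≤ x_upper. Two consequences are
deliberate and surface as named errors rather than extrapolations:

* r⁻ may never reach 1−α between the means (PGR's r⁻ peaks at ≈0.954;
  HER2's r⁺ at ≈0.965). For α below that gap no critical domain exists at
  the requested confidence and `NoCriticalDomainError` is raised —
  the components genuinely cannot be distinguished at that level.
* The domain is closed: a value exactly on a bound is undecidable (GE0).

At α = 0.5 both equations collapse to the cut-point and the domain
degenerates to a single point, which the implementation permits.

## Agreement statistics

For a crisp 2×2 IHC×GE table: log DOR = ln[(n₋₋·n₊₊)/(n₋₊·n₊₋)] with
Woolf half-width 1.96·√(Σ 1/nᵢⱼ); Cohen's κ from the marginals;
Goodman–Kruskal γ by concordant/discordant pair counts (on a 2×2 this is
Yule's Q, and the general pair-count implementation keeps the 3×3 use
consistent). A zero off-diagonal cell flags the DOR infinite — no
continuity correction is applied by default, matching the definition
rather than a smoothed variant.

For the 3×3 table (IHC −/missing/+ against GE −/0/+): only hard
contradictions count as discordant, (n[IHC−,GE+] + n[IHC+,GE−])/N; a
sample is inconclusive when it is discordant or undecided by both assays,
so conclusive = 1 − (discordant + n[IHC0,GE0])/N; the odds-ratio-type
statistics are computed on the embedded 2×2 of crisply decided corners.
This conclusive-rate convention reproduces the published ER (92%) and
HER2 (87%) three-state rates; the published PGR value (79%) is not
reproduced by any formula consistent with the other two (the adopted
formula gives ≈83%), which is documented here rather than special-cased.

## Look-up table

The reference curve is the mean across reference samples of each sample's
r-th order statistic — the quantile-normalization reference construction,
adopted as the natural multi-sample generalization of a single sorted
profile. It is non-decreasing by construction. Projection ranks the
receptor probe among the new sample's own values (ascending ordinal
ranks, ties broken by stable probe order so results are reproducible bit
for bit) and reads the curve at that rank. Because ranks are invariant to
any monotone transformation of the new sample's scale, the projected
value is directly comparable with the critical-domain limits without
re-normalizing the new sample.

## Therapy allocation and survival

Groups over ER and PGR: (1) hormone-positive confirmed, (2) negative
confirmed, (3) positive contradicted, (4) negative contradicted, with
"contradicted" requiring a crisp opposite GE call — GE0 never triggers a
contradiction. The defining clauses overlap (one receptor can confirm
while the other contradicts); contradictions are tested first so a
warning is never suppressed by a confirmation. Patients matching no
clause (e.g. a hormone-positive IHC status whose own receptor is crisply
contradicted while the other receptor is GE0) stay unassigned.

Kaplan–Meier curves are computed by the product-limit construction with
plain Greenwood variance, Var[S] = S²·Σ d/(n(n−d)), and bands clipped to
[0, 1]. The estimator is implemented in-package because the widely used
survival libraries default to log-log (exponential-Greenwood) bands; the
tests cross-check the survival estimate against lifelines and the bands
against Greenwood's formula evaluated on lifelines' event table, keeping
the dual-route check intact.

## Synthetic cohorts

The generator draws, per sample, a latent component z ~ Bernoulli(π⁺),
expression ~ N(μ_z, σ_z), then an IHC label equal to z flipped with the
label-noise probability and blanked with the missingness probability. Its
parameter presets are the published per-receptor distribution rows, and
the default cohort size (2,269) is the ER cohort with crisp IHC in the
published agreement table. Label noise is a symmetric flip by default;
per-class rates are accepted because real discordance is asymmetric
(HER2 especially), but no value is published for them, so asymmetry is
opt-in rather than a default. A whole-chip helper adds i.i.d. Gaussian
background probes (defaults N(7, 2²) on the log2 scale, the middle of the
usual RMA intensity range) around one bimodal receptor row for look-up
tests.

What the generator emulates — and what it does not: it reproduces the
bimodal mixture, class imbalance, label noise and missingness that the
estimators assume, so passing tests show correct inference *under the
model*. It does not emulate probe saturation, batch effects between
series, correlated noise across probes, or the dependence of IHC error on
expression level (borderline tumours are likelier to be misread in
reality). Agreement rates measured on synthetic cohorts therefore
characterize the pipeline, not any clinical cohort.

## Problem sizes in the shipped tests

The test suite and the acceptance script run the published-parameter
computations exactly as printed and scale the simulation studies to
n = 2,269 (50 replicates) for parameter recovery, n = 10,000 for
end-to-end cut-point round-trips, and n = 800 with 100 replicates for the
bootstrap cross-check of the Fisher intervals — sizes chosen to keep the
Monte-Carlo error well below the tolerances being checked.

## Known limitations

* Exactly two Gaussian components; no heavier-tailed or skewed modes.
* Unsupervised EM on strongly unbalanced mixtures (HER2-like, π⁺ ≈ 0.12)
  occasionally converges from a median-split start to a local optimum a
  few percent off in the minority-component parameters; supplying
  IHC-derived initial moments removes this in practice.
* The logistic cut-point has no finite MLE under complete separation; the
  midpoint of the separating gap is returned with an explicit warning.
* The look-up projection assumes the new sample covers the reference
  probe universe; no cross-platform probe mapping is attempted.
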