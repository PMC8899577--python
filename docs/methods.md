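# Methods

This note documents the models implemented in `bclscreen`, the assumptions
behind them, the parameters that matter, and what the synthetic-data
generators do and do not emulate.

## Bioactivity curation

Records carry a relation qualifier on the reported concentration. Values
are standardized to pAffinity = −log10(value in molar); on this scale the
qualifier flips ("< 1 µM" means pAffinity > 6). Censored records receive a
label only when the bound itself settles the question (a "<" record whose
bound already clears the activity threshold is active; a ">" record whose
bound is below it is inactive); anything else is excluded rather than
guessed. The class boundary defaults to pAffinity ≥ 6 (1 µM), inclusive,
and is configurable — public bioactivity sources do not impose one.
Replicates within a (compound, assay class) group collapse to their median;
groups spanning more than one log unit are dropped whole as
irreconcilable. Both rules are conventional QSAR-curation practice; the
provenance counts let callers verify that kept + dropped = raw. Splits are
stratified on the class label and fully determined by (fraction, seed).

## QSAR ensemble

Features are "hybrid": fingerprint bits concatenated with descriptors.
In toolkit mode these are RDKit Morgan fingerprints (default radius 2,
2048 bits) plus eight standard descriptors; in precomputed mode the
feature columns are read from the table, which is how the synthetic latent
features flow through the same code path. Descriptor standardization is
fitted inside each training fold (a scaler in the logistic learner's
pipeline), so cross-validation never leaks test-fold statistics.

The committee defaults to logistic regression, a 200-tree random forest
and histogram gradient boosting; `soft_vote` averages their active-class
probabilities (optionally weighted, weights summing to 1). The decision
threshold on the averaged probability is 0.5; library ranking uses the raw
probability. MCC is computed from the confusion table with the 0/0 → 0
convention for degenerate marginals and is cross-checked against an
independent implementation in the test suite. Cross-validation is
stratified k-fold (default k = 5), shuffled with a fixed seed; each row is
scored exactly once out-of-fold.

The companion regression model is a standardized ridge regression
(α = 10⁻³) reporting out-of-fold R² and RMSE in pAffinity units. A linear
model was chosen deliberately: it makes the noiseless-linear sanity limit
(R² ≈ 1) exact, which tree ensembles cannot reach on binary features.

## Virtual-screen triage

Each class model ranks the library by predicted probability, ties broken
lexicographically by compound id so the ranking is order-invariant. The
top-k (default 30) per model are pooled, deduplicated, and tagged with
their source model(s); the pool size is ≤ 2k with equality exactly when
the lists are disjoint. Practical filters run in acquisition order —
vendor availability first, then DMSO solubility — and a compound failing
both counts once, at the first failing stage, so the stage counts always
reconcile to the final list.

## SPR kinetics

The kinetic law is a sum of independent 1:1 Langmuir sites with no
mass-transport limitation and no bulk refractive-index/DMSO jump
(solvent correction is assumed done upstream). Within each
constant-concentration segment the per-site response is the exact
mono-exponential R(t) = Req + (R₀ − Req)·e^(−kobs·t) with
kobs = ka·C + kd and Req = Rmax·C/(C + KD); states propagate exactly
across segment boundaries. The analytic solution is verified against a
high-accuracy ODE integration in the tests (agreement ≤ 10⁻⁶ relative).

Schedules are piecewise-constant. The FastStep preset encodes six doubling
steps, 0.625 → 20 µM, with contiguous boundaries at 0/30/60/90/120/150/165 s
and a buffer dissociation window after 165 s; the concentration within each
step is treated as ideally constant (no Taylor-dispersion gradient
modelling — a documented simplification of gradient injection). The
titration preset encodes 180 s association cycles at 1/3/10/30 µM
(optionally 0.3 µM first, used for Mcl-1) separated by 180 s buffer
windows; bound material carries across cycles rather than assuming surface
regeneration.

Fitting is weighted least squares in log10-parameter space
(Levenberg-Marquardt, which also enforces positivity), multi-started from
32 points drawn log-uniformly over ka ∈ [10³, 10⁷] 1/(M·s) and
kd ∈ [10⁻⁴, 1] 1/s with site capacities splitting the observed peak; the
first start is a deterministic mid-grid point and the draw is seeded. Each
site's Rmax is free (per-site capacity; whether capacities should be
shared is an open modelling choice — free capacities are the more general
default). Sites are reported in ascending-KD order and the headline KD is
the highest-affinity site's kd/ka, restricted to non-degenerate sites: a
site whose fitted Rmax falls below 1% of the peak response contributes too
little signal for its rate constants to be identifiable, so it is flagged
with a warning and skipped for the headline value (this is what makes the
nested case — one-site truth fitted with a two-site model — return the
true KD rather than an arbitrary one). Parameter uncertainties come from
the local curvature (Gauss-Newton covariance of the log10 parameters) and
are labelled approximate.

The selectivity index is KD_other/KD_reference: values above 1 mean
tighter binding to the reference target.

## Concordance

Pearson r between docking energy and affinity, computed on the pKD scale
by default (energies are log-affinity-like); the raw-KD correlation is
reported alongside, and the report carries both signed r and |r| because
the energy convention makes the expected sign negative. Constant vectors
and duplicate compounds are rejected.

## Downstream formulas and NCA

Viability, surviving fraction and sphere percentage are the standard
control-normalized ratios; all are scale-invariant. Tumor volume is the
ellipsoid estimate L·W²·π/6 from caliper length and width (longest axis
first). IC50 fitting uses the four-parameter logistic
bottom + (top − bottom)/(1 + (c/ic50)^hill) with top and bottom free by
default (fixable), optimized over log10(ic50); when the observed response
never crosses 50% of control the IC50 is reported censored as "> max
tested concentration" instead of extrapolated.

NCA takes Cmax/Tmax as the maximum observed point and AUC by the linear
trapezoid (exact for piecewise-linear curves and additive over
concatenated ranges; log-down trapezoids were deliberately not used).
The terminal slope λz is the log-linear regression over the tail of ≥ 3
post-Tmax points with the best adjusted R² ("auto" mode; a fixed count can
be forced), t½ = ln2/λz, AUC_inf = AUC_last + C_last/λz, CL = dose/AUC_inf.
If λz is not estimable or non-positive, extrapolation is refused and only
AUC_last is returned. Clearance in mL/min/kg requires the compound's
molecular weight to convert molar concentrations to mass units; without it
the raw dose/AUC figure is returned and flagged.

## Synthetic data: what it emulates, and what it does not

**Bioactivity tables.** Compounds carry d binary latent features (default
32); a sparse weight vector (default 8 informative features) gives a
standardized latent score z; noiseless pAffinity is
threshold + signal_strength·(z − cutoff) with the cutoff at the
(1 − active_fraction) quantile, plus Gaussian noise (default SD 0.4 log
units, a typical inter-assay spread); labels are recomputed from the noisy
value, so the realized active share tracks active_fraction.
signal_strength (default 3) sets the margin between typical compounds and
the class boundary relative to the noise — the dial for achievable
accuracy/MCC. With noise 0 the labels are an exactly learnable discrete
function of the features, which the perfect-CV limit test exploits. SMILES
strings are deterministic id-derived placeholders (parsable alkanols):
the generator makes no attempt to mimic real chemistry space, so passing
tests demonstrate pipeline correctness, not real-world screening power.
The benchmark conditions used in the acceptance suite are n = 1000,
active fraction 0.4, signal_strength 3, noise 0.4.

**Screening libraries.** Availability and solubility flags are independent
Bernoulli draws at configurable rates, with a deterministic fixture mode
that pins chosen ids (used for the 60 − 3 − 8 = 49 attrition chain).

**Sensorgrams.** The generator calls the package's own forward model and
adds i.i.d. Gaussian RU noise — appropriate for an averaged, referenced
sensorgram; drift, spikes and solvent mismatch are not modelled. Noiseless
output is bit-identical to the forward model, making simulate-then-fit a
clean oracle: noiseless two-site FastStep fits recover all six parameters
to well under 1%, and under 1%-of-capacity noise the headline KD is
typically recovered within a few percent (median ≈ 3–7% over 20
realizations), with worst single realizations around 15–25%.

**Plasma profiles.** One-compartment first-order absorption (Bateman):
C(t) = F·D·ka/(V·(ka − ke))·(e^(−ke·t) − e^(−ka·t)), with proportional
(constant-CV) noise. Defaults encode the studied dosing conditions:
50 mg/kg intraperitoneal, terminal t½ 11 h (ke = 0.063 h⁻¹), peak at 2 h
(ka = 1.7 h⁻¹), apparent V = 25 L/kg with MW 775 g/mol so that
AUC_inf ≈ 41 µM·h and CL ≈ 26 mL/min/kg. A single-compartment curve with
this terminal phase necessarily peaks lower (≈ 2.3 µM) than a multi-phasic
disposition would at equal AUC; the early-peak concentration is therefore
not an emulation target of this generator.

**Dose-response.** Exact 4PL curves (default 5–50 µM design) plus optional
Gaussian noise in viability percent.

**Docking energies.** Constructed with an exactly specified sample
correlation to pKD (residual orthogonalization), since real score/affinity
panels are not redistributable; the construction fixes |r| by design, so
concordance tests verify the reporting machinery, not any docking engine.

## Numerical choices and degenerate inputs

- All generators and fits are seeded; identical configs give identical
  bytes.
- Log-space optimization bounds nothing explicitly but clamps exponents to
  ±150 to avoid overflow during exploration.
- Ranking ties break lexicographically; filter stages record removals by
  rule name; empty inputs yield empty, well-formed outputs where the
  operation is total (deduplication of zero records, ranking an empty
  library) and raise a typed `InputError` where it is not.
- Problem sizes in the default test and acceptance runs (e.g. 1000-row
  benchmark, 300-compound libraries, 20 Monte-Carlo refits at 1 s sampling)
  were chosen as the smallest sizes at which the statistical checks are
  stable.

## Known limitations

- The QSAR benchmark lives in latent-feature space; toolkit-mode
  featurization is exercised on real SMILES in unit tests but the
  synthetic placeholders carry no structural signal by design.
- The SPR model omits mass transport, bulk jumps and intra-step
  concentration gradients; fits to instrument data with those artefacts
  will absorb them into apparent rate constants.
- The 2-site fit treats sites as independent and parallel; cooperative or
  sequential binding is out of scope.
- NCA assumes a single dose and a monotone terminal phase; BQL handling
  and multi-dose superposition are not implemented.
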