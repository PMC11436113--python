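# Methods

This note documents the models implemented in `soilpte`, the defaults and
the reasoning behind them, what the synthetic generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Indices and grades

For each element, PI = C/S with S the Songnen Plain background value, and
Eᵣ = Tᵣ·C/S with the Håkanson toxicity coefficients
{As 10, Cd 30, Cr 2, Cu 5, Hg 40, Ni 5, Pb 5, Zn 1}. NPI aggregates the
per-sample PI vector as √((mean² + max²)/2) and therefore always lies
between the mean and the maximum PI. RI is the plain sum of the eight Eᵣ.
All four indices are linear in concentration, so the index evaluated at
the mean concentration equals the mean per-sample index — this is how the
per-sample machinery reconciles with published study-mean figures.

Grade tables in the literature print overlapping interval bounds
("1–2", "2–3"). We use left-closed bins above the first breakpoint
(PI = 2 → moderately contaminated), the only total, monotone convention
consistent with the strict inequalities those tables also print. Two
special cases: the NPI "clean" class is right-closed at 0.7 (printed as
"≤ 0.7"), and the RI column's inconsistent printed bounds are resolved as
breakpoints 150/300/600 with four grades (slight / moderate / high /
significantly high).

Concentrations at or below the method detection limit are replaced by
MDL/2 for index and dose computation and flagged; the PMF uncertainty
model treats them separately (below).

## Health risk

Doses follow the USEPA three-route model (ingestion, inhalation via a
particulate emission factor, dermal contact), evaluated per population
group with AT = ED·365 d for non-carcinogenic risk and AT = 70·365 d for
carcinogenic risk, so each group gets its own HI and TCR. The lifetime
averaged dose (LADD), which pools the childhood and adult exposure windows
into a single lifetime quantity, is provided as a separate function; it
cannot produce per-group results, which is why the per-group HI/TCR
pipeline uses the group-wise doses.

The exposure constants are the values in wide use for Chinese soil
health-risk assessment (adult/child): IngR 100/200 mg·d⁻¹, InhR
14.5/7.63 m³·d⁻¹, EF 350 d·a⁻¹, ED 24/6 a, BW 61.8/15.9 kg, SA
5075/2448 cm², SL 0.07/0.2 mg·cm⁻²·d⁻¹, ABS 0.001, PEF 1.36×10⁹ m³·kg⁻¹.
Every constant is overridable. Because published studies rarely print
their full exposure table, exact reproduction of third-party HQ/CR tables
is a calibration exercise; the robust claims — children's HI above
adults', both below 1; TCR within 10⁻⁶–10⁻⁴; ingestion > dermal >
inhalation — hold at the shipped defaults and are what the tests assert.

Reference doses are per-route (distinct ingestion/dermal/inhalation
columns); each route's dose is divided by its own RfD and the quotients
summed. A single-RfD mode (summed dose over the ingestion RfD) is
available for comparison. Slope factors exist only for As and Cd; other
elements report CR as not-available rather than silent zero.

## Multivariate diagnostics

Pearson correlation p-values use the exact t transform with n−2 degrees
of freedom, unadjusted for multiplicity (a documented limitation matching
conventional usage). Bartlett's sphericity is
χ² = −(n−1−(2p+5)/6)·ln|R|. KMO uses the anti-image partial correlations
from R⁻¹; on an exact identity matrix the 0/0 case returns 0 with a
warning. PCA is an eigendecomposition of the correlation matrix, unrotated
(rotation is off by default), loadings scaled by √eigenvalue, retention at
eigenvalue > 1, and each component's dominant loading made positive —
signs are otherwise arbitrary.

## PMF receptor model

Uncertainties: u = 5/6·MDL for c ≤ MDL (equality counts as censored);
u = √((EF·c)² + (0.5·MDL)²) above, with error fraction EF defaulting to
0.1 and overridable per element. The additive-looking form sometimes
printed in the literature, (EF + c)², is dimensionally incoherent and is
implemented as the standard product form. Elements whose residual-based
signal-to-noise falls below 2 are flagged weak and have u tripled.

The optimizer is alternating weighted multiplicative updates with weights
1/u² and a 10⁻¹² positivity floor; Q is non-increasing across iterations
(asserted in tests). Convergence is declared when the relative ΔQ stays
below 10⁻⁹ for 20 consecutive iterations within max_iter = 5000; this is
deliberately strict, and fits that report `converged = False` at default
settings are in practice stationary to ~10⁻⁶ relative — the flag marks
slow terminal drift, not a wrong solution. A multi-start driver (default
20 starts, seeded deterministically from one root seed) keeps the solution
with the lowest robust Q, where robust Q caps each cell's contribution at
cutoff² (cutoff 4) — the conventional outlier guard. The scale
indeterminacy is fixed by normalizing each factor to unit mean sample
contribution; factor order is arbitrary, and `align_factors` matches
solutions to a reference by best-permutation cosine similarity
(linear sum assignment).

The factor-number scan fits p = 2…7 and reports Q_robust/Q_expected with
Q_expected = nm − p(n+m); `elbow` locates the largest positive curvature
of log(ratio). Selection remains with the user; the elbow is a heuristic.

Contribution tables follow the mass convention: pct[k,j] is the share of
element j's mean mass attributed to factor k (columns sum to 100%), and
the overall source share is each factor's fraction of total mean mass.
Both are invariant to the factor scale indeterminacy.

## Source-oriented risk

With F the column-stochastic source-fraction matrix, RIⱼ = Σᵢ Fⱼᵢ·Eᵣᵢ and
Dⱼ = RIⱼ/ΣRIⱼ, and identically for HQ and CR per population group. By
exchange of summation, source totals recombine exactly to the aggregate
index; every D vector is a probability vector; merging sources adds their
allocations. Cohort-level (study-mean) risk vectors are used by default.

## Synthetic surveys

The generator draws X = G·F + E: fixed profiles F (mg/kg per unit
contribution), per-source lognormal contributions with unit sample mean,
multiplicative lognormal noise with relative SD = error fraction plus an
additive N(0, 0.5·MDL) term (mirroring the uncertainty model, so PMF's
weights are well-specified on synthetic data), clipping at zero, and
MDL-censoring with MDL/2 substitution. One root seed deterministically
derives all per-stage streams. Optional Gaussian-kernel smoothing of the
contribution fields over the sampling plane produces spatially correlated
sources (off by default; used for interpolation demos).

The default scenario emulates the published 304-sample survey: four
sources — natural, irrigation, fuel, fertilizer — whose dominant elements
are (Cr,Cu,Ni,Zn), (As,Pb), (Hg), (Cd); expected element means equal to
the study's Table of descriptive statistics; expected overall mass shares
within 0.3 percentage points of the published (33.2, 29.5, 23.4, 13.9)%.
The mixing matrix pins the published fingerprint entries (irrigation owns
70% of As, fuel 72% of Hg, fertilizer 67% of Cd, natural ~36% of each
lithogenic metal and 31% of Pb) and distributes the remaining lithogenic
mass across the anthropogenic sources in near-disjoint blocks.

Two structural choices depart from a naive reading of the survey and are
essential for the factorization to be identifiable at n = 304:

1. **Episodic anthropogenic sources.** 25% of samples are background-only
   and each anthropogenic source is additionally inactive in 15/20/25% of
   the remainder, with strongly right-skewed contributions elsewhere
   (CVs 1.4–1.6; the natural source uses CV 0.15). Nonnegative
   factorizations are identified only when contributions and/or profiles
   hit zeros: with strictly positive G the weighted objective has a flat
   valley of factor rotations, and fits (even truth-initialized ones)
   wander across it. The episodic zeros pin the rotations; recovered
   profiles then match the truth at cosine ≥ 0.998 and recovered shares
   land within ~±4–5 percentage points.
2. **Dispersion is not calibrated to the survey's CVs.** Reproducing both
   the published mass shares and the published element CVs (0.05–0.36) is
   mathematically incompatible with an identifiable factorization at this
   sample size; the generator therefore reproduces means and shares
   exactly and keeps only the qualitative dispersion ordering (Cd most
   variable). Tests check empirical CVs against the scenario's analytic
   propagation, not against the survey's.

A residual ≈ −4 pp downward bias on the ubiquitous natural source's
recovered share remains even at the optimum (it persists under truth
initialization and oracle uncertainties); it is intrinsic to the
nonnegative estimator at this sample size — the anthropogenic sources'
fitted contributions cannot go below zero in their inactive samples, so
their means absorb noise upward at the natural source's expense.

What passing tests on these surveys do **not** show: performance on data
whose sources are all diffuse (never near-zero), whose noise departs from
the assumed uncertainty model, or whose spatial structure matters —
real-survey behavior on such data is expected to be worse, exactly as the
identifiability analysis above predicts.

## Problem sizes and runtime choices

Recovery experiments run at the survey's own scale (n = 304, 8 elements,
20 starts); the factor-number scan experiment uses 4 starts and
max_iter = 1500 per fit across 10 seeds, which reproduces the elbow at
the true rank in 10/10 seeds while keeping the whole suite under a minute
of PMF time. Law-of-large-numbers checks on the generator use n = 10⁴.

## IDW and pipeline

Inverse-distance weighting uses power 2 and k = 12 nearest neighbours by
default (common GIS defaults), planar distances in projected metres, and
returns a sample's exact value at coincident nodes; every interpolated
node is a convex combination of sample values. The pipeline composes the
stages in assessment order, writes each artifact with run metadata
(config digest, seed, package version), and is deterministic given
(input, config, seed); stage failures abort with the stage name while
retaining completed artifacts.

## Known limitations

* No bootstrap/displacement uncertainty estimation for PMF factor
  profiles (point estimates plus multi-start spread only).
* No rotation exploration (Fpeak-style) beyond the normalization
  convention.
* p-values unadjusted for multiple testing.
* The exposure-constant defaults are a named convention, not a
  site-specific calibration.
* Monte-Carlo (probabilistic) health risk and dietary pathways are out of
  scope.
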