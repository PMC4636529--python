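# Methods

## The outlier model

Each beat x_g is tested against a local normal model estimated from its
surrounding window: the 20 preceding and 20 subsequent beats (x_g itself
excluded), giving n = 40 window values with mean x̄ and sample standard
deviation s (n − 1 denominator).  The beat is flagged when

    |x_g − x̄| > k·|s|.

The multiplier k converts a confidence level P into a threshold while
correcting for the fact that x̄ and s are estimates:

    k = [2(n−1) / (2(n−1) − λ_b²)] · [λ_a + λ_b·√((n·λ_a² + 2(n−1) − λ_b²) / (2n(n−1)))],

where λ(P) solves Erf(λ/√2) = P, the two-sided standard-normal mass within
±λ.  With λ_b = 0 the correction vanishes (k = λ_a exactly); as n grows, k
falls to λ_a at rate λ·√((λ²+2)/(2n)) for λ_a = λ_b = λ (≈ 1.48 × 10⁻³ at
n = 10⁶).  At the defaults P = 0.75, n = 40: λ = 1.15035, k = 1.40871.

**λ_a/λ_b resolution.** The original derivation defines λ_a and λ_b
through a pair of confidence equations; this package's default
(`lambda_mode="equal"`) sets λ_a = λ_b = λ(P), which keeps the k expression
intact while isolating the one under-determined constant, and
`lambda_mode="explicit"` accepts a user-supplied pair for anyone working
from the original tables.  The equal-λ default is a documented stand-in,
not a claim about the source derivation.

**Direction of P.** Lower P narrows the tolerance band and flags *more*
beats.  This is "conservative" in the sense the method intends: a missed
artifact distorts HRV more than an erroneously deleted genuine beat, so the
default P = 0.75 deliberately over-flags and leaves the final decision to
the analyst.

**Calibration.** For a candidate independent of its window, the statistic
(x_g − x̄)/(s·√(1 + 1/n)) is exactly Student-t with n − 1 degrees of
freedom, so the null flag probability is the two-sided t tail beyond
k/√(1 + 1/n) — 0.1720 at the defaults.  The plain normal tail 1 − Erf(k/√2)
= 0.1589 underestimates this by ≈ 0.012 at n = 40: the finite-sample k only
partially compensates for estimating x̄ and s under the equal-λ stand-in.
The calibration test therefore compares the empirical rate against the
exact t-based tail.

**Degenerate windows.** s = 0 is read literally: any nonzero deviation
exceeds k·0 and flags; an exactly equal candidate does not.  No
special-casing, no epsilon.

## Scan, ordering, correction

The scan is *single-step*: every beat with sufficient context is tested
against windows computed from the ORIGINAL series, fixing the candidate set
in one pass (no iterative delete-and-rescan).  Beats with fewer than 20
neighbors on a side use a truncated window down to 10 per side; beats with
less context than that are reported as *untested*, which is deliberately
distinguishable from *clean*.

Where flagged windows overlap (indices within 2·20 of each other), the most
extreme candidate — largest |x_g − x̄|/max(s, 10⁻¹²) from the original scan
— is corrected first; remaining candidates in affected windows are
re-tested against the window re-formed after those deletions (the
recombined neighbor context) and dropped if no longer outlying.  The
emitted plan lists overlap clusters in series order, most-extreme-first
within a cluster.  Priorities always come from the original scan: a re-test
after removing the dominant spike can have s = 0, which would make any
re-tested priority infinite.

A consequence of the single-step contract worth knowing: in a paired
excursion (one huge spike followed by a moderate one), the huge spike can
inflate its neighbor's window SD enough to *mask* the partner in the same
pass.  That masked case is exactly what the visual pass is for, and the
test suite pins it.

Corrections are `delete` (surviving values form an exact subsequence of the
input) or `replace_mean` (the arithmetic mean of the 5 preceding and 5
subsequent *surviving* values — other planned beats are skipped when
collecting neighbors; at least 3 per side are required, else an error).
Every edit is recorded in a `CorrectionLog` whose replay on the source
series reproduces the corrected series exactly.  No operation can insert a
value, so corrected length ≤ source length always and a corrected trace
plotted against original beat indices shows gaps, never a shift.

Visual-inspection deletions enter as `method="visual"` edits applied
*before* the algorithmic scan (plot → analyst writes a manual-edit CSV →
`correct --manual-edits`), matching the workflow order: obvious
discontinuities first, the algorithm for unclear cases.

Recordings whose flagged fraction strictly exceeds 5 % are marked excluded
(`error_fraction > 0.05`; exactly 5 % is retained).

## HRV metrics

Standard task-force time-domain definitions, computed on the series exactly
as passed (no detrending, no interpolation):

- SDNN: sample SD (n − 1) of RR in ms;
- RMSSD: √(mean of squared successive RR differences);
- pNN50: 100 × (count of |successive difference| strictly > 50 ms)/(n − 1
  pairs).

HR mean/median/SD are computed on the bpm-converted series
(bpm = 60000/RR).  Percent changes are 100·(after − before)/before, with an
unchanged zero baseline reported as 0 % and a zero→nonzero transition as
NaN (an undefined-change marker, never an exception).

## The perturbation experiment

To compare correction strategies on error-free data, a seeded uniform draw
selects ≈ 1–5 % of beat positions (avoiding the first/last 5 beats so the
replacement mean is always well-defined); each fraction is applied once
with deletion and once with mean replacement *at the same positions*, and
the percent change of each HR/HRV parameter is tabulated.  Mean replacement
suppresses the local successive differences it touches, so it moves RMSSD
(and SDNN/pNN50) more than deletion does — at the 5 % fraction the
replacement change exceeds the deletion change in ≈ 96/100 seeded
replicates under the default generator.

## The synthetic generator

Clean series: hr_i = baseline + A·sin(2π·f·t_i + φ) + ε_i, ε_i ~ N(0, σ²),
with t_i the cumulative RR time, clipped to the Polar device range
[15, 240] bpm.  Defaults model a resting medium-size dog: baseline 90 bpm,
RSA amplitude A = 15 bpm, breathing f = 0.4 Hz, beat noise σ = 3 bpm.  The
breathing frequency and amplitude are plausibility choices for a resting
dog (no canonical values exist); the spectral peak of the generated series
sits at f to within one periodogram bin.

Two honest properties of this model:

- **Beat-sampling bias.** Beats are denser where HR is high, so the
  beatwise mean sits up to A²/(2·baseline) ≈ 1.25 bpm above baseline.
- **Threshold-straddling RSA.** A pure sinusoid has peak deviation A and
  window SD A/√2, and k(0.75, 40) ≈ 1.4087 < √2 — RSA extremes lie
  essentially on the decision boundary, so with beat noise the scan flags
  10–15 % of clean beats.  Real dog recordings show irregular, partly
  autocorrelated RSA and the reported error rates there are far lower; the
  sinusoid-plus-white-noise model is a stress test of the criterion, not a
  calibration target.  What passing tests show is therefore: spikes of
  transmission magnitude are found with sensitivity ≈ 1, the clean-series
  flag rate stays at or below the i.i.d. analytic rate, and all correction
  contracts hold — not that the 5 % exclusion rule would pass on real dog
  data.

Artifacts (all positions pairwise ≥ 2 beats apart, ≥ 21 beats from the
ends so every artifact has full window context; counts are seeded Binomial
draws):

- `spike`: the beat is replaced by median ± magnitude (default 60 bpm,
  ≈ the near-halving/doubling excursions chest-belt transmission errors
  produce; 20× the default noise SD);
- `missed_beat`: two adjacent RR merge (RR ≈ doubled, length n − 1);
- `extra_beat`: one RR splits in half (length n + 1).

Merges/splits operate in ms (the physical mechanism acts on intervals),
spikes in bpm (the displayed-value mechanism).  Ground-truth labels index
the *output* series.

## Numerical choices

- Erf via `scipy.special.erf` (machine precision); λ via bracketing
  `brentq` on [0, 40] at xtol 10⁻¹²; k cached per (λ_a, λ_b, n).
- n convention: n = number of values actually used for x̄ and s (candidate
  excluded ⇒ 40 for a full window); `include_candidate` available.
- CSV floats are written as shortest round-trip `repr` and read with
  pandas `float_precision="round_trip"`, so series and log round-trips are
  bit-exact.  HRM files store integer milliseconds (the device's 1 ms
  accuracy); writing rounds to the nearest ms.
- Problem sizes in the validation suite: calibration uses 10⁵ independent
  windows; spike recovery 50 seeds × 2000 beats; the perturbation contrast
  100 replicates × 2000 beats.  These sizes put Monte-Carlo noise well
  inside the stated tolerances while keeping a full run in seconds.

## Known limitations

- The equal-λ default is a stand-in for the original λ_a/λ_b system (see
  above); explicit mode exists for users with the original tables.
- The HRM reader supports only the RR-recording dialect (one RR per line in
  `[HRData]`); multi-channel exports are rejected, not parsed.
- HRV metric values will not numerically match analysis packages that
  detrend or interpolate before computing time-domain statistics.
- What the original workflow did at series boundaries is unstated; the
  truncated-window/untested policy here is this package's own, and
  boundary beats are never silently passed as clean.
- Frequency-domain and nonlinear HRV are out of scope.
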