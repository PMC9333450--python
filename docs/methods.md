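# Methods

## Model and procedure

The package analyses multi-antibiotic growth-inhibition screens organised
around a normalized diagonal sampling (NDS) design. Drugs are indexed by a
panel; each drug *i* has a normalization constant *N*ᵢ > 0 in μg/mL. The
tested ratios form a strictly decreasing ladder c₁ > c₂ > … > c_{m−1}
(typically cⱼ = 2^{1−j}); the design places every nonempty drug subset Ω′ at
every diagonal point (cⱼ·*N*ᵢ)_{i∈Ω′}, plus drug-free controls, and assigns
wells by a seeded uniform permutation filled row-major across plates.

Effectiveness is a thresholded scalar growth measure. The default measure
is the area under the background-subtracted OD600 curve (AUGC, OD·hours),
computed by the trapezoidal rule on the actual timestamps over a 24 h
window. An alternative measure, the maximum slope of a smoothed
log(OD − background) curve (natural log, per hour), is provided but not
used by default; in practice the two agree on which wells are inhibited.
A condition is *effective* when its replicate-aggregated measure is ≤ t
(inclusive); t defaults to 10% of the mean drug-free control AUGC and may
be given absolutely.

Scores per subset Ω:

* MECI(Ω): minimum over all nonempty Ω′ ⊆ Ω of Ω′'s smallest effective
  diagonal ratio. A subset with no effective tested condition carries a
  NOT_FOUND sentinel and is reported "indeterminate".
* TSS(Ω) = MECI(Ω) / min singleton MECI; ESS(Ω) = MECI(Ω) / min proper
  nonempty subset MECI. Subsets with NOT_FOUND are skipped in the minima;
  if nothing in a denominator is defined the score is undefined.
* Classification: ESS ≤ 0.25 synergy (inclusive), 0.25 < ESS < 1 weak
  synergy, ESS ≥ 1 none. The 0.25 cutoff corresponds to a pairwise
  checkerboard FICI of 0.5 when both drugs sit at ¼ of their MICs.
* A diagonal-restricted upper bound on the Loewe FICI — the minimum of
  Σᵢ xᵢ/MICᵢ over effective sampled points — is reported for comparability;
  it is labelled a bound because off-diagonal points are never sampled.

The correctness claim behind the design — that diagonal sampling finds the
same MECI as the m^d full factorial — holds under *non-paradoxical growth*:
for any background x₀, direction x and scalars c₃ > c₂ > c₁ ≥ 0,
r(x₀+c₂x) < r(x₀+c₁x) implies r(x₀+c₃x) ≤ r(x₀+c₂x). The oracle module
verifies the claim empirically: it solves the MECI optimization by
exhaustive enumeration over the grid built from the same ladder levels
(plus zero) and compares subset by subset, and it scans sampled rays for
fall-then-rise violations of the condition above.

## Synthetic data generator

The simulator draws dose-response surfaces from a pooled-Hill family. An
effective dose E(x) = (Σᵢ (xᵢ/Dᵢ)^p)^{1/p} + Σ_S β_S Πᵢ∈S xᵢ/Dᵢ pools
per-drug dose fractions (p = 1 Loewe-like additivity; large p approaches
highest-single-agent pooling) plus optional emergent-interaction terms, and
the response is a transform of E:

* monotone: r = r₀/(1+E^h). E is coordinatewise nondecreasing, so r is
  nonincreasing along every ray from every background — non-paradoxical by
  construction. This is the default study condition.
* hyperantagonistic: a unimodal envelope (linear rise to a peak at E = e₀,
  then Hill decline). Rise-then-fall along a ray is permitted by the
  non-paradox condition; the piecewise envelope makes that guarantee
  provable rather than parameter-dependent, which is why this mode does not
  reuse the Gaussian bump below.
* paradoxical: the monotone response times a Gaussian recovery factor
  1 + a·exp(−((E−e₀)/w)²) — an Eagle-effect-like dip-then-rise used to
  construct failure cases. The fixed demonstration surface uses Dᵢ = Nᵢ/2,
  h = 4, a = 30, e₀ = 2, w = 0.3, which makes every diagonal's effective
  dip recover above threshold before the top tested ratio, so the monotone
  reading of the diagonal misses the dip that exhaustive enumeration finds.

Synthetic plate-reader wells follow a fixed logistic shape over 24 h at
15-minute cadence (midpoint 8 h, timescale 1.5 h, background OD 0.05,
uninhibited span 0.5 OD) whose amplitude scales with r(x)/r₀, plus additive
Gaussian OD noise (default sd 0.01, one seeded stream per dataset, seed
recorded in outputs). The noiseless AUGC is therefore exactly proportional
to r(x). What this generator does *not* emulate: lag-time and growth-rate
differences between conditions (amplitude is the only dose-dependent
feature), plate-position and evaporation effects, correlated replicate
error, and partial-inhibition curve shapes. Passing tests show the
analysis pipeline is correct given the stated response model, not that any
particular laboratory screen satisfies non-paradoxical growth — that
assumption is exactly what the ray scans are for.

The injected-synergy scenario used by tests and the acceptance script
places singles' effectiveness crossing at 0.7× the top ladder ratio
(margin against noise) and chooses the pair's interaction coefficient so
its diagonal crosses threshold at ¼ of the top ratio with a 10% margin,
giving ground-truth ESS = 0.25 on a two-fold ladder.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| normalization *N*ᵢ | breakpoint if present, else MIC | μg/mL | determines the scientific meaning of synergy; echoed into every output |
| ladder | 10 two-fold steps from ratio 1 | – | resolves interactions within a factor of two over a 512-fold range |
| AUGC window | 24 | h | full incubation at 15-min cadence |
| threshold fraction | 0.1 | of control AUGC | operationalizes "complete inhibition" while tolerating reader noise |
| replicate rule | mean | – | "all"/"any" available for stricter/looser calls |
| ESS synergy cutoff | 0.25 (inclusive) | – | four-fold emergent improvement; aligns with pairwise FICI 0.5 |
| ray-check tolerance ε | 0 for noiseless, 2× replicate sd suggested for noisy data | response units | separates paradox from measurement noise |

## Numerical choices

* Background: per-well first in-window reading by default; a blank estimate
  may be supplied. Negative OD − background excursions are not clamped in
  AUGC (clamping would bias areas upward); the log-growth-rate computation
  excludes non-positive values instead.
* The moving average for the growth-rate measure uses symmetric centred
  windows truncated to 1/3/5 points at the series ends, so the smoothed
  log-curve of an exact exponential is the exact line and the recovered
  slope is exact; slopes divide by actual Δt, and duplicated timestamps are
  skipped.
* Effectiveness comparisons are inclusive (≤ t); ladder ratios compare with
  relative tolerance 1e−9; concentrations are serialized as decimal text
  with 10 significant digits.
* Diagonal reading: the default "closure" rule takes the smallest ratio
  from which every larger tested ratio is effective (the upward-closed
  reading implied by non-paradoxical growth); "raw-min" takes the smallest
  effective ratio regardless. Every non-monotone diagonal pattern is logged
  as a potential paradoxical-growth violation.
* Well-count accounting: m·2^d counts the empty subset at every step; the
  generated design de-duplicates those coincident drug-free wells to
  (m−1)(2^d−1)+1 conditions. Both counts are reported (for d = 8, m = 10:
  2,560 vs 2,296; the former needs 27 ninety-six-well plates by ceiling
  arithmetic).
* MECI over the subset lattice is computed by dynamic programming
  (each subset's value is the minimum of its own diagonal and its facets'
  values), which also yields the witness condition.

## Design decisions and limitations

* Exhaustive verification is kept to d ≤ 4–5 with 6-step ladders
  (≤ ~2,400 grid points per subset); the acceptance checks use 20 random
  monotone surfaces per dimension d ∈ {2,3,4} and ≥ 100 random rays, sizes
  chosen to give broad parameter coverage at interactive runtimes.
* The FICI reported from NDS data is always an upper bound, never "the
  FICI"; exact FICI would require the full factorial.
* Antagonism is not scored: the guarantee is asymmetric (hyperantagonism is
  allowed by the growth assumption), so a maximin "ineffective
  concentration" index would carry no analogous correctness property.
* Growth-model fitting (Gompertz/Baranyi, lag/carrying-capacity estimation)
  is out of scope; AUGC and the smoothed max slope are deliberately
  model-free.
* Real screens can violate non-paradoxical growth (notably survival-assay
  readouts of the Eagle effect); the package detects and reports such
  patterns but its MECI guarantee then no longer holds, which is precisely
  what the paradoxical simulator mode demonstrates.
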