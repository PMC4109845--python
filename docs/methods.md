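# Methods

This note documents the models, estimators and numerical choices behind
`midgeswarm`, in the order the analysis applies them.

## Velocities and collective-mode subtraction

Velocities are forward finite differences at the acquisition frame rate,
`v_i(t) = (x_i(t+1) − x_i(t))·fps`; the last frame carries none and is
excluded from per-frame statistics.  Individuals missing from either frame
of a pair are dropped from that pair (no interpolation) — the simplest
defensible handling of tracking gaps.

Three collective modes are subtracted sequentially from each frame pair,
working in the centre-of-mass frame (y_i = x_i − x_cm):

1. **translation** — subtract the mean velocity V;
2. **rotation** — the proper orthogonal matrix R minimizing
   Σ|y_i(t+1) − R y_i(t)|², computed by the standard least-squares
   superposition (SVD) solution with the determinant correction that
   excludes reflections.  The rotation axis K̂ is the invariant direction,
   with sign fixed so the angle about it is non-negative;
3. **dilatation** — the scalar α minimizing Σ|y_i(t+1) − α R y_i(t)|²,
   closed form α = Σ(R y_i)·y_i(t+1) / Σ|R y_i|².

The residual fluctuation is δv_i = v_i − V − fps·(α R y_i − y_i); the
subtraction order is fixed (translation → rotation → dilatation) and the
three fits are not jointly iterated.  Since Σy_i = 0, the identity
Σδv_i = 0 holds to round-off.  The dimensionless fluctuation divides by
the root mean square, so (1/N)Σφ_i·φ_i = 1 exactly.  Residuals that are
pure round-off of an exact rigid motion (relative magnitude below 1e−12
of the velocity scale) yield φ = 0 rather than an arbitrarily amplified
noise field.

Degenerate geometry is refused, not patched: the rotation fit raises on
N < 3 or (near-)collinear configurations (second singular value below
1e−12 of the first), and frames with N < 4 skip the rotational and
dilatational order parameters.

## Order parameters

* polarization Φ = |mean unit velocity| (zero-speed individuals excluded,
  with a warning and a count);
* rotational order: for each individual, the angular momentum of its
  translation-subtracted velocity about K̂ is L_i = y_⊥i × dv_i; with
  m_i = (L_i·K̂)/|L_i|, R = |mean m_i|.  A coherent rigid rotation gives
  R = 1 exactly; independent headings give ~1/√N.
* dilatational order Λ = mean cosine between the rotation-subtracted
  fluctuation and the radial direction: +1 for coherent expansion, −1
  for contraction.

These normalizations are the package's own choice among the forms that
satisfy the defining limits; an alternative normalization of m_i (e.g. by
|y_⊥||dv| instead of |L|) would differ only through the component of dv
along K̂ and preserves both limits.

The uncorrelated-system band is estimated by Monte Carlo: N independent
uniform random unit vectors (and uniform-in-ball positions for R and Λ),
measured by the same statistics as the data.  For large N,
E[Φ] → √(8/(3πN)).

## Correlation and susceptibility

C(r) uses contiguous bins of width δr from zero; δr defaults to
(max pair distance)/50 per frame.  Pairs are unordered (the estimator is
symmetric); empty bins are reported as *absent*, not zero, so they cannot
bias the first-zero search.  The correlation length r0 is the first zero
crossing, located by linear interpolation between the straddling populated
bin centres; a curve already negative in its first populated bin returns
that bin's lower edge, and a curve that never changes sign returns none.

Q(r) is evaluated on the bin-edge grid of the same δr (from 0 to one edge
beyond the largest pair distance), so the correspondence between the
maximum of Q and the zero of C can be checked bin for bin; the identity
holds whenever C crosses zero once and cleanly.  χ = max Q over the grid.
The normalization of φ makes Q beyond the largest pair distance equal −1
exactly; both identities are asserted in the acceptance tests to 1e−9 and
1e−12.

Per-acquisition values are means over usable frame pairs, with standard
deviations over frames as error bars.  Frames the decomposition refuses
are skipped and counted.

## Non-interacting Harmonic Swarm

Each particle independently follows the Langevin equation
m dv = (−γ v − k x)dt + σ√dt ξ with σ = √(2γT), integrated by the Euler
scheme, so the stationary positional variance per component is T/k.
Defaults: m = k = T = 1, critically damped friction γ = 2√(mk),
dt = 0.01·√(m/k) (with a stability guard γ·dt/m < 2), initial state drawn
from the stationary law.  These parameter values are chosen, not imported:
they put the ratio of per-frame displacement to nearest-neighbour distance
at the order-0.1 level typical of swarm recordings.  The analysis chain
applied to NHS frames is the identical code path used for data.

## Vicsek model in a central potential

Per unit time step, each particle averages the velocities of all particles
within rc of it (itself included), subtracts β·x_i (the harmonic pull that
replaces boundary conditions and grants cohesion; β = 0 recovers the
standard model), normalizes, applies a random rotation drawn uniformly
from the spherical cap of solid angle 4π·η around that direction — the
vectorial-cone noise convention, η = 1 being full randomization — and
moves at fixed speed v0.  The update loop is compiled (numba) with exact
O(N²) neighbour accumulation; at the system sizes used here (N ≤ 512)
this is faster and simpler than maintaining cell lists, and the neighbour
sets are exact by construction.

Sampling records position pairs around a single update, so finite
differencing recovers the exact velocities.  Defaults take one
configuration every 200 steps after the transient: fluctuation samples
taken ~40 steps apart proved strongly autocorrelated near the transition,
and decorrelated sampling is what makes per-run χ estimates usable.  This
mirrors, at reduced scale, the standard protocol of saving configurations
at long fixed intervals.

Scans vary β (density) or N; x = r1/rc is measured from the sampled
configurations, and Φ and χ are computed by the same estimators as for
data.  A drift check flags runs whose r1 trends by more than 20% of its
mean over the sampling window.  Finite-size scaling locates the χ peak
per size and requires it to be bracketed by the scan.

## Percolation

Two points are linked when their distance is strictly below λ; the largest
connected component is found by union-find over KD-tree pair enumeration.
n(λ) is non-decreasing with jumps only at pairwise distances.  λc is the
smallest λ with n(λ) ≥ θ, refined by bisection to a relative width of
1e−3.  θ defaults to 0.6 — the threshold is a configuration knob and the
result is insensitive to it in the giant-cluster regime, which the
sensitivity table in the percolation analysis script documents.  The
through-origin fit λc = s·r1 across events gives the dimensionless
threshold; for Poisson point sets s ≈ 1.6 and is constant across a 500×
density range.

## Statistics

The permutation test computes Spearman ρ (average ranks on ties) and a
two-sided P-value P = (1 + #{|ρ_perm| ≥ |ρ_obs|})/(m+1) over m random
re-pairings (default m = 10,000); the +1 correction keeps P ≥ 1/(m+1).
Under independence the P-value is uniform, which the tests verify by
Kolmogorov–Smirnov over seeded replicates.

The critical scaling fit works on log χ: for fixed x_c the amplitude and
exponent are closed-form, leaving a 1D profile over x_c (coarse geometric
grid, then bounded refinement).  Guards: the branch must be genuinely
decreasing (Spearman ρ < 0), the fitted exponent positive, and the
transition point must not run away far below the data (non-identifiable —
the expected outcome on null-model input).  The cross-event report
additionally (a) only attempts the fit when the permutation test finds a
significant decreasing dependence of χ on r1/BL, and (b) constrains
x_c ≥ 0, since x is a positive density ratio.  Confidence intervals are
95% percentile bootstrap over points.  An optional inverse-variance
weighting on log χ is available but not used by the report: the relative
χ errors are roughly uniform along the branch, so weights add noise
without improving the transition point.

The interaction-range estimate combines the fitted transition point (in
body lengths) with the percolation slope: at the transition r1 = x_c·BL,
and the alignment graph percolates when rc = s·r1, hence rc/BL = x_c·s.
Its interval is the interval image of the product, [x_lo·s_lo, x_hi·s_hi]:
the bootstrap distribution of x_c is strongly skewed (often piled against
the x_c ≥ 0 constraint), and a symmetric delta-method band around the
point product systematically understated the upper range; the endpoint
product is exact for a monotone function of positive arguments and keeps
the skew.

## Synthetic data

The generators emit exactly the structure each stage assumes, with ground
truth alongside:

* **planted-mode frame pairs** — positions uniform in a ball; the second
  frame is a translated, rotated, dilated copy plus iid Gaussian residual
  velocities re-centred to sum zero, so the planted modes are the exact
  least-squares optima at zero noise;
* **correlated fluctuation fields** — spatial blobs of radius L share a
  common random unit vector, plus isotropic noise, then re-centred and
  normalized.  The blob construction has an unambiguous planted length
  scale; its C(r) is wigglier than a smooth random field's, which is why
  the clean single-crossing checks use a long-wavelength gradient field
  instead;
* **correlated trajectories** — per-step displacements carry a fresh such
  field (no collective modes), giving a quasi-static swarm with
  spatially correlated velocity fluctuations;
* **Poisson point sets** at a requested density.

What these fixtures do *not* emulate: real flight kinematics (inertia,
speed distributions, pairwise chasing), tracking noise and identity
switches, swarm-shape anisotropy, and temporal persistence of the
fluctuation field.  Passing tests therefore validate the estimators and
the inference chain, not the biology; on real recordings the same chain
applies unchanged but the effect sizes are an empirical question.

## Problem sizes and determinism

Everything is seeded; simulators are bit-reproducible given (config,
seed), and one seed per invocation fans out to named substreams.  The test
and acceptance runs use deliberately scaled-down sizes chosen as the
package's own defaults: Vicsek scans at N = 128–512 with 50 decorrelated
samples per run, NHS runs of 10⁴–3·10⁴ steps, 300-point Poisson sets,
100-seed recovery studies for the cheap estimators and 5-seed studies for
the end-to-end report.  The end-to-end validation generates events from
Vicsek runs of known radius interpreted at different unit scales (a
"species size" proxy), so the metric-interaction test has distinct
variables to discriminate and the true rc/BL is the same for every event.

## Known limitations

* The rotational/dilatational normalizations are one defensible choice
  among near-equivalent forms (see above); absolute values of R and Λ
  should be compared only within this package.
* The critical fit is weakly identified on shallow branches — the package
  deliberately reports intervals and declines fits without a significant
  decreasing trend rather than pinning a value.
* The percolation argument is an equilibrium heuristic; in a
  self-propelled system it yields a crude range estimate, and the
  end-to-end validation accordingly checks interval coverage, not point
  accuracy.
* At these system sizes the finite-size transition point sits below its
  asymptotic location, biasing the point estimate of rc/BL low; the
  propagated interval absorbs this at the sizes tested.
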