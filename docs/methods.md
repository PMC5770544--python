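# Methods

## The problem

Flow cytometry can fingerprint a microbial community far faster than
sequencing: every sample is reduced to the relative abundances of a fixed
set of *gates* (cell subclusters in a forward-scatter × DNA-content dot
plot), giving a compositional state vector

s(t) = (s¹(t), …, sⁿ(t)),  Σᵢ sⁱ(t) = 1,

at each sampling time. `cytostability` turns such a gate-abundance time
series plus disturbance annotations into univariate ecological stability
indicators — constancy, resistance, displacement speed, resilience,
elasticity, and an online-resilience monitor — suitable for post hoc
comparison of disturbance experiments and for at-line bioprocess
monitoring.

## Distances between states

Two bounded metrics quantify the difference between compositions a and b:

* scaled Euclidean: d_e(a, b) = √(½ Σᵢ (bᵢ − aᵢ)²);
* normalized Canberra: d_c(a, b) = (1/n) Σᵢ |aᵢ − bᵢ| / (aᵢ + bᵢ).

Both are symmetric, vanish iff a = b, and lie in [0, 1] on the simplex.
The ½ factor sits *inside* the root: only there does d_e reach exactly 1
for disjoint compositions (outside the root the supremum would be √2⁄2),
which fixes an ambiguity in how the formula is sometimes typeset. A
Canberra term with aᵢ + bᵢ = 0 contributes 0 (the standard convention; it
preserves d_c(a, a) = 0 and the upper bound). No pseudocounts are added.

The Canberra distance is the default: it weighs each gate's change
relative to its summed abundance, so the doubling or extinction of a rare
population registers as strongly as an equal absolute shift in a dominant
one. The flip side, quantified below, is sensitivity to measurement noise
on rare gates.

## Reference space and deviation traces

From m reference samples (a predisturbance time series or technical
replicates), the reference state s_ref is the per-gate mean, renormalized
to the simplex (means of compositions drift off it by rounding); σ_ref is
the vector of per-gate sample standard deviations (denominator m − 1 —
m is small in practice; zero vector for m = 1); and the reference space
is the sphere around s_ref of radius

r = max over reference samples of d(s_ref, sample),

so every reference sample lies inside by construction. With m = 1 the
sample is the reference state and the radius must be supplied from prior
experience (typically precomputed from technical replicates). A constancy
check compares mean(σ_ref) to a threshold, default 0.25: intrinsic
variation of natural communities has been reported around 25%, whereas
technical replicates of a steady community sit near 0.006, so the default
separates "constant enough to define a reference" from genuinely drifting
systems.

For each annotated disturbance window the deviation trace is
d(t) = d(s(t), s_ref) over all samples with onset ≤ t ≤ window end,
prepended with the last sample before onset, whose timestamp is t_ref
(the clock zero for speeds; both t_ref and the onset are reported so the
alternative convention is one subtraction away). Windows are clipped at
the next disturbance onset and at the series end, the layout of
consecutive pulse experiments on a single run. The trace records
d_max = max d(t), its first attainment time t_max (ties resolve to the
earlier sample), and d_end at the final sample t_end. Boundary crossings
(exit when d first exceeds r, return when it first drops back) are
detected sample-by-sample; no interpolation between samples is performed,
since interpolation would invent community states between measurements.

## Stability properties

From one trace:

| property | formula | range / units |
|---|---|---|
| resistance | RS = 1 − d_max | [0, 1] |
| displacement speed | DS = d_max / (t_max − t_ref) | h⁻¹ |
| resilience | RL = 2·d_max/(d_max + d_end) − 1 | [0, 1] |
| elasticity | E = (d_max − d_end)/(t_end − t_max) | h⁻¹ |

RS is the unique affine map of the normalized maximal deviation with
RS(0) = 1 (untouched) and RS(1) = 0 (maximally displaced). RL is the
Orwin–Wardle recovery index evaluated at the trace end; because d_max is
defined as the trace maximum, d_end ≤ d_max and negative index values are
unreachable, so RL ∈ [0, 1] by construction rather than by clipping.
DS is undefined when t_max = t_ref, RL when d_max = 0; both become
explicit not-available values in reports rather than numbers. E is
defined only when recovery actually occurred (d_end < d_max and
t_end > t_max) and is otherwise reported as not-available — a zero would
read as a meaningful (null) recovery speed. RS and RL are directly
comparable across experiments; DS and E are speeds with no predefined
range, and comparisons across systems must account for their intrinsic
time scales (generation times, hydraulic retention times).

Online resilience replaces d_max by the running maximum M(t) of the
deviation encountered so far: the value is 0 wherever d(t) = M(t) (the
system is still being pushed away, including exact ties after the peak)
and 2·M(t)/(M(t)+d(t)) − 1 otherwise. Its final value equals the post hoc
RL exactly — the implementation uses literally the same arithmetic — so
the monitor can run at-line without knowing the eventual maximum.

## Synthetic trajectories

The simulator generates the canonical experiment so that every
computation can be verified against closed forms. The noise-free mean
state moves along a chord of the simplex,

s(t) = (1 − α(t))·s_base + α(t)·s_dist,

with α = 0 before onset, a linear ramp to α_max at t_peak, then
α_max·e^(−k(t−t_peak)). Convex combinations stay on the simplex, and both
metrics are monotone in α along the chord, so d_max occurs at t_peak and
d_max, d_end, RS, RL are available analytically for any metric.
Measurement noise is Dirichlet: an observation of mean state p is drawn
from Dirichlet(c·p), whose per-gate sd is √(pᵢ(1−pᵢ)/(c+1)); the single
concentration parameter c is calibrated so the mean per-gate sd matches a
target (default 0.006, the technical-replicate variability of cytometric
gate abundances) instead of hard-coding a distribution width. Gates with
pᵢ = 0 remain exactly 0.

Defaults were fixed once as the reference experimental conditions: 34
gates (the size of the study gate template); a geometric rank-abundance
baseline (ratio 0.85: dominant gate ≈ 15%, mean share 2.94%, rarest
≈ 0.07% — an uneven but not degenerate community); disturbance onset at
24 h with a 6 h ramp (pulse alterations of pH or temperature in such
experiments last 2–11 h); sampling every 3 h to 120 h (inter-disturbance
gaps of 39–117 h); recovery rate k = 0.005 h⁻¹, i.e. a partial-recovery
response, as the default scenario. Four named scenarios cover the
qualitative response taxonomy: `within_reference` (displacement only
among the two dominant gates — see the noise discussion for why a
rare-gate restructuring cannot stay inside a Canberra reference space),
`full_return` (k = 0.05 h⁻¹), `partial_recovery`, `no_recovery` (k = 0).

### What the generator does and does not emulate

It emulates steady state, a single pulse displacement with optional
exponential recovery, and technical measurement noise. It does not
emulate ecological dynamics (no species interactions, no
Lotka–Volterra-type oscillations — for oscillatory reference dynamics the
reference space becomes uninformatively large and this framework is the
wrong instrument), drift in the reference phase, multi-modal responses,
or gating artifacts. Passing recovery tests therefore demonstrates the
correctness of the computations under the stated noise model, not that
real communities follow linear-ramp/exponential trajectories.

## Noise propagation: why the two metrics behave differently

For a gate with abundance p and measurement sd τ_p, the expected Canberra
term against the true value is ≈ 0.8·τ_p/(2p), so the distance between a
noisy measurement and the truth has a floor of roughly
(0.4/n)·Σᵢ τᵢ/pᵢ — dominated by *rare* gates. At the calibrated 0.6% mean
sd on the 34-gate baseline this floor is ≈ 0.1–0.2; this is the mechanism
by which technical replicates of a perfectly steady community yield a
Canberra reference radius of the order of 0.15–0.25 despite sub-percent
per-gate noise, and it is why a replicate-derived radius (not the naive
expectation "noise is 0.6%, radius should be small") must define the
reference space. The Euclidean deviation, in contrast, aggregates
absolute noise (√(½·Σ τᵢ²) ≈ 0.03 here) and adds it roughly in
quadrature, so point recovery of RS/RL from noisy data is accurate under
d_e. The package's quantitative parameter-recovery checks therefore run
under the Euclidean metric (recovered RS within ±0.02 and RL within
±0.05 of the analytic truth across 100 simulated experiments), while the
Canberra noise floor is reported as the replicate-derived radius itself.
Even so the per-experiment RL error under d_e is the tightest of these
margins: RL's sensitivity to the final sample (|∂RL/∂d_end| ≈ 2.6 at the
default geometry) amplifies the single-sample noise of d_end by that
factor.

## Numerical choices

* Rows within the sum tolerance (default 1e-6) are silently renormalized
  to exactly 1 before any distance computation; rows outside it are
  rejected with their row index.
* Report files store values at 12 significant digits; round-trips
  reproduce deviations to well below 1e-9.
* All randomness flows through `numpy.random.default_rng(seed)` with the
  seed recorded in simulator sidecars.
* Ties: t_max takes the earliest attaining sample; running-maximum ties
  give online resilience 0.

## Known limitations

* d_end rests on a single sample; with noisy data, RL and E inherit that
  sample's noise amplified (see above). Averaging late samples would
  reduce it but would redefine s_end, so it is not done.
* Sample-based crossing detection can miss excursions shorter than the
  sampling interval.
* The workflow presumes constancy before each disturbance; it is not
  suitable for oscillatory or drifting reference dynamics.
* Persistence and domain-of-attraction are deliberately out of scope, as
  is everything upstream of gate abundances (FCS parsing, gating) and
  ordination/diversity analysis.
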