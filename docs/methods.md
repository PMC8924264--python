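# Methods

`tendrilcoil` models how the tendrils of a climbing vine (the study system
is *Cayratia japonica*, a Vitaceae vine) decide whether to coil around a
support depending on the support's diameter, and re-implements the
measurement pipeline used to quantify that behaviour from 3D marker
trajectories. This note documents the model, its parameters, the synthetic
data, and the numerical choices.

## The two-rule coiling model

The model is kinematic and planar. A tendril is an inextensible chain of
`ds`-long segments (default 2.5 mm) with an intrinsic bend angle at each
joint. Two behavioural rules drive it:

1. **Coil from the contact point.** After touching a support, the tendril
   deposits intrinsic curvature into its joints at a fixed angular rate
   (`coiling_rate`, deg/min), starting at the contact joint and progressing
   tip-ward, capped at the free-coil curvature `2 / free_coil_diameter`.
2. **Minimum coiling angle.** Once coiling starts, the contact region
   always bends by at least `theta_min`. Whether the support can keep the
   initial contact point depends on its surface curvature: contact is
   maintained iff `2 / phi >= theta_min_rad / contact_window`, i.e. iff the
   support diameter is at most
   `phi_crit = 2 * contact_window / theta_min_rad` (≈ 11.5 mm at the
   defaults). Flatter supports lose the contact once the deposited bend
   reaches `theta_min` (a *liftoff*), and the contact is re-detected
   tip-ward: the "moving contact point" response.

A subtlety is worth making explicit: `theta_min` (25°) is demanded over a
*short stimulated arc* (`contact_window`, default 2.5 mm), which transiently
requires much tighter curvature than the sustained free coil (18 mm
diameter). We model the demand and the sustained cap as separate
quantities: the stimulated spot kinks sharply at first, while long-run
curvature relaxes to the free-coil value. Tying the demand window to the
free-coil cap would force the critical diameter above 18 mm, outside the
observed 10–15 mm bifurcation band; with a 2.5 mm stimulated arc the
bifurcation lands at 11.5 mm, inside the band.

### Placement and contact resolution

The chain is pinned at the root. Each step, after depositing curvature, the
chain's placement angle at the root pin is solved (by bracketing and Brent's
method on the minimum surface clearance) so that the eligible part of the
curve rests exactly tangent to the support circle with no node penetrating
it. "Eligible" excludes the already-curled region after liftoff — the curl
hangs off the support while the straight distal section rests on it, which
is what makes the contact point migrate tip-ward. Non-penetration and
segment-length conservation therefore hold by construction (verified to
1e-6 mm in the tests).

Outcomes close the decision tree:

* **Continuous coiling** (`phi <= phi_crit`): the coil encircles the
  support; when the accumulated wrap angle (the winding of the chain around
  the support centre, net of the initial tangent-line subtension) reaches
  `detach_wrap_threshold` (360°) a `wrap_closed` event fires. Continuous
  trials never detach; trials too short to close a full wrap still count as
  success at the end of the 3-hour window, matching the observation that
  continuously coiling tendrils remain attached.
* **Tip contact**: in a moving-contact trial the contact migrates until the
  distal curvature budget is exhausted at the tip, which fires
  `tip_reached` and `detach`. With the default rate (20 deg/min) a
  mid-contacted 80–100 mm tendril detaches after roughly 10–16 minutes,
  the observed time scale for this response.
* **Clip-shape coiling**: if, during a moving-contact trial, a node of the
  root-side free segment is pressed onto the support
  (`secondary_contact_root`), the tendril re-coils from that node: the
  root arm wraps around the support with per-joint greedy clamping at
  surface tangency (it hugs supports flatter than its free coil). The clip
  succeeds if the wrap angle reaches the threshold before the arm's
  curvature budget runs out, which favours small supports and long
  tendrils; otherwise it detaches.

A lifted tendril can transiently *enclose* the support while rolling over
it; enclosure only counts as a grip (success) while the contact is held
(continuous coiling) or after a clip has formed.

### Circumnutation

The slow rotatory sweeping of the whole plant is modelled as an AR(1)
drift of the root pin: `d <- rho * d + N(0, jitter_sd^2 I2)` per 0.5-min
step, with `rho = 0.98` and `jitter_sd = 2 mm`. The stationary amplitude is
then about 10 mm with a correlation time of tens of minutes — the scale and
tempo of real circumnutation. This drift is the model's only stochastic
element; `jitter_sd = 0` gives a bit-for-bit deterministic trial. Its
mechanistic role is to occasionally press the root-side segment onto the
support, triggering clip formation: longer tendrils spend longer in the
moving-contact phase and so clip more often, reproducing the observed
length dependence through exposure time rather than through an explicit
length rule. Because drift can also slide which node of an encircling coil
touches the support, the step-1 classification reads the *liftoff event*
(did the minimum-angle rule force the contact off its initial point within
the 5-minute observation window?) rather than raw node indices.

### Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `theta_min` | 25 | deg | plateau of the measured coiling angle |
| `free_coil_diameter` | 18 | mm | centre of the 16–20 mm stop-stage coil range |
| `contact_window` | 2.5 | mm | places the step-1 bifurcation at 11.5 mm, inside the 10–15 mm band |
| `coiling_rate` | 20 | deg/min | reaches 25° in 1.25 min (inside the 5-min window) and yields ~10–16 min tip-contact detach times |
| `detach_wrap_threshold` | 360 | deg | one full turn counts as a closed grip |
| `root_contact_fraction` | 0.5 | — | with mid-tendril contact, the proximal half *is* the root-side free segment; a smaller fraction could never geometrically reach a support half a tendril-length from the root |
| `jitter_sd`, `jitter_rho` | 2 mm, 0.98 | | cm-scale, tens-of-minutes circumnutation |
| `dt`, `ds` | 0.5 min, 2.5 mm | | resolves the rapid stage in ~10 frames; two simulator segments per 5 mm marker interval |

## Measurement pipeline

The pipeline starts from tracked marker coordinates (frame, marker id,
x/y/z in mm) — camera calibration and marker identification are upstream
and out of scope.

* **Bending angle** at interior marker *i*: the interior angle
  ∠P(i−1)P(i)P(i+1), computed with the atan2 form (well conditioned near 0°
  and 180°); 180° is locally straight. For markers at arc spacing *s* on a
  circle of radius *R* it equals `180 − (180/π)(s/R)`.
* **Coiling angle**: `180° − bending angle` at the contact marker, so a
  straight tendril scores 0 and the measured rise plateaus at the minimum
  coiling angle.
* **Stage segmentation**: the stop stage starts at the first frame from
  which the per-frame angle change stays below `stop_eps` for at least
  `persistence` consecutive intervals (defaults 1°/frame and 3 frames),
  searched after the first motion. `stop_eps` must be scaled up with marker
  noise: 0.1 mm of jitter on 5 mm-spaced markers moves bending angles by a
  few degrees per frame, so noisy tracks are segmented with `stop_eps`
  around 3 times the induced angle noise.
* **Stop-stage coil diameter**: a circle is fitted to the coiled markers at
  the midpoint frame of the stop window — total-least-squares plane,
  projection, Pratt algebraic fit (on scale-normalised coordinates),
  one Gauss–Newton refinement on geometric distance. Coiled markers are
  auto-selected as those whose bending angle is within 6° of the most-bent
  marker: markers adjacent to the straight/coil junction bend visibly
  without lying on the coil circle and must stay out of the fit. Which
  markers enter the fit is also exposed as an explicit argument.

## Synthetic data

The generators are deterministic functions of (config, seed) and emulate
the two motion-capture protocols:

* `gen_free_coil_track` — touched-and-released tendril, 12 frames at 1-min
  intervals: two straight 5 mm-spaced arms hinged at the middle marker; the
  hinge rises linearly to `theta_min` over the first half of the frames and
  holds, so the recovered plateau equals `theta_min` exactly when noiseless.
* `gen_wrap_track` — a tendril tip winding onto a circle of the configured
  stop diameter with exponentially saturating coiled arc length (80% of the
  final wrap by one-third of the frames). Markers on the coiled part lie
  exactly on the circle, so the noiseless round trip recovers the diameter
  to machine precision; presets `fig5_thin` (89 mm tendril, 1 mm rod,
  20.4 mm coil) and `fig6_thick` (69 mm tendril, 40 mm rod, 16.1 mm coil)
  encode the two published tracking experiments.
* `gen_success_dataset` — Bernoulli draws from
  `logit p = β0 + βd·D + βl·L` with defaults (1.0, −0.25/mm, +0.04/mm)
  chosen so failures concentrate at large diameters and short lengths, the
  observed pattern; the default sample size is 87 trials over the
  experimental diameter grid (10–35 mm).

What the generators deliberately do **not** emulate: perspective and lens
distortion, marker mis-identification, out-of-plane coiling of real
tendrils, or tendril growth during the trial. Passing round-trip tests
therefore shows the pipeline is self-consistent and correct on clean
kinematics, not that it is robust to every artefact of real footage.

## GLM

Coiling success is modelled as Bernoulli with main effects of support
diameter and tendril length on the logit scale (interaction available
behind a flag), fitted by IRLS with a step-halving safeguard so the
log-likelihood never decreases; convergence at `max |Δβ| < 1e-8` or 100
iterations. Complete separation is detected (all fitted margins beyond the
numerical saturation point without convergence) and flagged instead of
reporting pseudo-finite estimates. Inference is Wald (standard errors from
the inverse Fisher information); the tests cross-check the estimates
against a quasi-Newton likelihood maximiser and against an independent GLM
implementation, and calibrate coverage (≥ 90/100 replicates at n = 500)
and type-I error on simulated data.

## Numerical choices and limitations

* Collinearity in the circle fit is declared scale-free (second singular
  value below 1e-6 of the largest); coincident points in angle
  computations are rejected below 1e-9 mm.
* The placement solve brackets from the previous step's angle, so
  trajectories are continuous in time; ties in contact detection resolve
  to the root-most node.
* Problem sizes: the shipped phase-diagram sweep uses 6 lengths × 9
  diameters × 20 seeds with 2.5 mm segments and 0.5-min steps, which a
  single CPU completes in well under a minute per hundred trials.
* The planar model cannot represent out-of-plane helical coiling or
  multi-wrap self-avoidance (wraps overlap in the plane); marker export
  embeds the plane in 3D with z = 0.
* The diameter dependence of the tip-versus-clip split is weaker in the
  model than in observation: clip frequency here is driven mostly by
  exposure time and by how much wrap the root arm can supply, and only the
  latter depends on diameter. The short arm of real tendrils is not
  modelled at all.
* Detach times emerge from the curvature budget and rate rather than being
  fitted: tip-contact trials detach after ~10–16 min. Failed clips detach
  tens of minutes later, qualitatively matching the observed ordering of
  the two detach time scales.
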