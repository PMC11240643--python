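# Methods

This note documents the models, conventions and design choices behind the
package, what the synthetic data does and does not emulate, and the
numerical details a user reanalysing real footage would need.

## The activity measurement

Activity is defined per consecutive frame pair as the mean optical-flow
speed over the pixels containing pigs; its unit is pixels/frame and its
scale is relative (it depends on camera geometry and resolution), so all
inference is comparative. Fixed conventions:

* The flow field for the pair `(t−1, t)` is sampled on the grid of the
  later frame: the value at pixel `p` is the displacement that brought the
  content now at `p` from the previous frame. Accordingly, the activity
  value indexed by frame `t` is averaged over the pig mask of the *later*
  frame. (Which frame's mask the original measurement averaged over is not
  determinable from the outside; a union-mask variant would differ only at
  animal boundaries.)
* The first frame of a video carries no activity value; a series over `n`
  frames has length `n − 1`, indexed from frame 1.
* All windows are half-open `[start, end)` in frame indices, so the
  collapse frame itself is excluded; this avoids double-counting the
  collapse frame between the FLOP and LLOP windows.
* "High activity" qualifies by *strict* inequality above the pooled
  median, and the pooled median is recomputed per analysed dataset (it is
  a dataset-relative threshold, not a constant of the method). The even-
  count median is the mean of the central pair. The "amount of high
  activity" is the sum of the qualifying frame values themselves, not of
  their excess above the threshold — the latter is a plausible alternative
  reading, and switching to it would only shrink all sums monotonically.

### Flow backends

The reference backend is exhaustive integer block matching: for every
pixel, the SAD over a `block_size × block_size` neighbourhood (default 5)
is minimised over integer displacements within `search_radius` (default
5, which must be at least the largest per-frame movement to be measured);
ties are broken toward the smallest displacement magnitude, then row-major
candidate order, so static content yields exactly zero flow. Box sums use
integer integral images, so the minimisation is exact — on the generator's
integer-translation scenes the recovered flow equals the ground truth on
interior pig pixels, which is the package's primary correctness oracle.
Learned estimators (the kind used on real footage) are deliberately out of
scope; any callable satisfying the backend contract can be registered, and
scikit-image's iterative Lucas–Kanade is included as a classical dense
alternative (it agrees with the reference within 0.5 px/frame on
integer-translation fixtures; scikit-image's TV-L1 was evaluated and does
not meet that tolerance, so it is not registered).

### Segmentation

Downstream computation only needs per-frame foreground masks; animals are
treated as a whole. On synthetic scenes (bright textured animals on a dark
floor) plain intensity thresholding (default 50 on gray-8) is exact up to
anti-aliasing-free edges, and serves as the reference provider. Real
footage requires a trained segmenter; its output enters through the same
provider contract (one dimension-matched mask per frame). No morphology is
applied to masks by default. An empty mask makes the frame invalid and
aborts that gondola's analysis with a diagnostic rather than silently
contributing a zero.

## The synthetic gondola model

The generator emulates the statistical structure the analysis relies on,
not the appearance of real footage:

* **Events.** Each gondola has a first-response time (default 5 s; the
  pre-response phase exists only to verify that it does not leak into the
  statistics) and one LOP time per pig, drawn i.i.d. from a normal
  distribution truncated at zero with mean 13.4 s and SD 3.8 s — the
  moments of the individually scored baseline; the truncation point lies
  3.5 SD below the mean, so the moments are preserved to ~0.003 s. The
  family is configurable (a moment-matched lognormal is included) because
  the true shape — in particular any skewness — is unknown; only the first
  two moments are calibrated. Event times are stored as integer frame
  indices (`round(t·fps)`, default 24 fps); seconds are derived views.
* **Movement.** Three-phase piecewise-constant target speeds per pig:
  resting (0.3 px/frame) before first response, induction excitation
  (3 px/frame) until the pig's own LOP, and post-collapse jitter
  (1 px/frame). Displacements are integer-rounded random-direction steps,
  so realised speeds scatter around the target — this scatter is what
  makes gondola-level mean activity a continuous statistic. A collapsed
  pig stops translating and only jitters; collapse is not rendered as a
  posture change, which keeps ground-truth flow exact at every frame and
  keeps an all-speeds-zero scenario bit-static.
* **Stocking-density effect.** Optional per-group overrides add a shift to
  the LOP mean and multiply the induction-phase speed. With zero shift and
  unit gain (the null model), per-pig LOP times are exchangeable across
  group sizes by construction.
* **Rendering vs kinematics.** The rendered path paints textured ellipses
  (semi-axes 8×5 px by default) with boundary clamping and a simple
  repulsion rule (a move into another animal's bounding box is voided), and
  emits exact masks and per-pair displacement fields. The kinematic path
  skips rendering and samples displacements in free space (no walls, no
  contacts), which makes per-pig displacement magnitudes exactly i.i.d.
  across pigs, gondolas and group sizes — the property the calibration
  experiments need — and is ~10³ times faster. Consequently the two paths
  are two variants of the model, not pixel-identical runs; flow-level
  oracles always use the rendered path.

What the generator does **not** emulate: occlusion and animal contact
(masks of real groups merge; the measurement is defined on the group as a
whole for that reason), perspective and lens distortion, lighting change,
sub-pixel motion (reserved for backend-tolerance fixtures), correlation of
LOP times within a gondola, and any behavioural repertoire beyond movement
intensity. Passing tests therefore validate the *pipeline* — segmentation
restriction, flow reduction, window bookkeeping, the resampling reference
and the test machinery — not the adequacy of any particular learned
segmenter or flow model on real videos.

## simLLOP

For group size `k` and an observed sample of `n` gondolas, the simulated
reference draws `k` baseline times uniformly *with replacement* and records
their maximum, `n` times. With replacement is the conventional bootstrap
reading (and the only one that scales past the baseline size);
without-replacement drawing is available as an option. The simulated CDF
converges to `F̂(x)^k` (verified to sup-distance < 0.02 at 10⁵ replicates).
Baseline times and observed LLOP are both measured from the first response
— the comparison is only meaningful on a shared clock origin. The baseline
pools the individual LOP times of the 3- and 4-pig gondolas, as in the
original design. One simulated dataset per group size with a recorded seed
is the implemented contract.

## Statistical machinery

Mann–Whitney U (two-sided by default, α = 0.05) with the exact null
distribution for tie-free samples with `n_x·n_y ≤ 400`, otherwise the
normal approximation with midrank tie correction and continuity
correction; the method used is recorded in every result. Exhaustive
enumeration shows the approximation is within 0.011 of the exact two-sided
p for arms of 8 and within 0.008 for arms of 12. Bonferroni correction
multiplies by the family size and caps at 1; the family is the six
pairwise comparisons within one statistic × one window (matching the
layout of the published tables), with an explicit family-size option for a
joint 12-test family. The LLOP-vs-simLLOP tests form a separate,
uncorrected family (they are reported singly). Significance letters are
maximal cliques of the non-significance graph, lettered in order of group
means.

## Calibration experiments and their design

Both experiments use the kinematic path at a reduced scale of 10 gondolas
per group size.

**Type-I calibration** (1000 null datasets) evaluates the pairwise family
on the FLOP-window *mean* activity. This choice is deliberate: under the
null, FLOP-window mean activity is the one summary whose location is
group-size invariant (all animals are in the induction phase throughout
the window). LLOP-window statistics mix induction and post-collapse phases
in proportions governed by the maximum order statistic and so differ
across group sizes *even without any density effect* — a composition
effect inherent to the measurement definition, visible in the null run of
`analysis/03_density_effect.py`, and worth keeping in mind when reading
LLOP-window comparisons on real data. High-activity sums scale with
window length (min of `k` LOP draws) and carry a milder analogue of the
same confound. Measured rates at seed 0: 5.9% (LLOP family) and 4.9%
(pairwise family), against the nominal 5%.

**Pattern recovery** (50 effect datasets) checks the full qualitative
result as a conjunction: LLOP > simLLOP significant for 7- and 8-pig
gondolas and not for 3 and 4; both activity statistics (FLOP window,
Bonferroni-adjusted) separating every 3/4-vs-7/8 pair with 3-vs-4
non-significant. The configured effect — +5 s on the LOP mean (~1.3
baseline SD) and a 1.5× induction-speed gain — was fixed a priori as a
representative strong effect. Note a structural property of any such
conjunction: it embeds four null-retention constraints whose combined
type-I mass (~11% at these test levels) bounds the expected recovery rate
near 0.89 regardless of effect size; the measured conjunction rate is
0.82 at seed 0, while each individual finding of the pattern reproduces in
≥ 95% of replicates.

## Degenerate inputs and numerical notes

* `lop_sd = 0` is a point mass at the mean; a point-mass baseline makes
  simLLOP exactly constant.
* A LOP draw landing on the first-response frame is nudged one frame out
  so the induction window is never empty.
* Identical pooled samples in the U test (zero variance) fall back to the
  asymptotic path, which reports p = 1.
* Empty windows, empty masks, empty baselines and malformed CSV rows raise
  typed errors (`AnalysisError`, `EmptyMaskError`, `DataError`,
  `SchemaError` with the offending row) rather than producing NaNs.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; identical configurations reproduce
  byte-identical CSV outputs.

## Known limitations

* The activity scale is relative; absolute thresholds (e.g. for alarms)
  would need per-installation calibration.
* The generator's three-phase constant-speed model is an invention for
  testability; real induction behaviour has richer temporal structure
  (escape attempts, gasping bouts) that the phase means only coarsely
  proxy.
* Individual-level analyses are impossible by design: animals are
  segmented as a whole.
* The simLLOP reference assumes independence of LOP times within a
  gondola; any true within-gondola correlation would widen the observed
  LLOP distribution relative to the bootstrap reference.
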