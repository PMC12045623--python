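# Methods

`neurorbit` studies how target motion modulates reach-direction coding in
motor cortex during flexible manual interception, at three levels: single-unit
tuning, population neural-state geometry, and a task-trained recurrent
network. Everything runs on synthetic data with known ground truth; real
recordings enter only through the generic population container
(`PopulationActivity`: a neurons × trials × time-bins rate tensor plus a
per-trial label table).

## Task model

A target appears on a circle of radius 15 cm (0.15 a.u. in the network world)
and either stays put or rotates at a constant angular velocity from
{−240, −120, 0, 120, 240} °/s (clockwise negative). After a delay drawn
U[400, 800] ms a GO cue is given; the subject reaches to intercept the
target. Reach direction is the endpoint angle, binned into eight half-open
45° sectors anchored at 0° (the anchor is a convention; no downstream metric
depends on it). Desired hand speed is a minimum-jerk bell profile — chosen
for its closed form (peak 1.875·D/T); any smooth unimodal profile integrating
to the displacement would serve.

## Representational model neurons

Three single-neuron mechanisms combine a Gaussian temporal profile
(200 abstract time bins, sd 30 bins, peak bin ~ N(100, 10), bin 100 = MO),
cosine direction tuning, and a sigmoidal velocity modulation with abstract
velocity code vel = 1..5:

* gain:      exp(−(t−tμ)²/(2·30²)) · (σ(g·(vel−3))·cos(θ−θpd) + 1)
* PD shift:  exp(−(t−tμ)²/(2·30²)) · (cos(θ−θpd − 90·σ(s·(vel−3))) + 1)
* additive:  exp(−(t−tμ)²/(2·30²)) · (cos(θ−θpd) + σ(g·(vel−3)) + 1)

with σ the logistic function, g ~ U[0, 1], s ~ U[0, 1.5], and preferred
directions on a deterministic uniform grid (the grid removes a variance
source; the randomized alternative changes explained variances by well under
a percentage point). A population is simulated on the 5 × 64-direction grid
(320 trials); MO-window states are the mean of bins 50–150, z-scored per
neuron, then projected by PCA. z-scoring versus plain centering changes the
explained variances by <0.3 points.

Measured explained-variance structure (20 seeds): gain ≈ 49/49/1.2,
PD-shift ≈ 49/49/1.3, additive ≈ 47/47/5.9, mixed (100 of each) ≈ 46/46/2.9
percent for PC1/PC2/PC3. Note that the additive group necessarily puts ~6%
of variance on PC3: the offset term σ(g(vel−3)) carries ~0.035 variance per
neuron against 0.5 for the cosine term, and those offsets align across
neurons into a single velocity dimension. Geometrically the three groups
behave as expected: gain and PD-shift rings tilt monotonically with velocity,
additive rings stay parallel (tilt ≈ 0) and separate vertically with a state
shift monotone in |velocity|.

## Synthetic sessions

`generate_noisy_session` emulates a recording in task units: per-cell trial
counts, endpoint angles jittered uniformly inside sectors, delays U[400, 800]
ms, tuning means from the task-unit analogues of the three mechanisms
(velocity code vel/120 inside the sigmoids, keeping slopes O(1)), a Gaussian
temporal envelope (sd 300 ms, peak jittered N(0, 100 ms) around MO), and
per-bin Poisson count noise whose variance is `noise` × the Poisson variance
(noise = 0 reproduces the deterministic means; noise = 1 is standard
Poisson). Ground-truth parameters keep baselines above the maximal tuning
excursion so rates never rectify at zero — rectification would itself convert
a pure mechanism into a mixture and defeat recovery tests. What this
generator does not emulate: spike-train timing, latency structure, slow
drifts, noise correlations between units. Recovery results therefore bound
what the statistics can do under ideal independence, not under real
recording pathologies.

## Single-unit statistics

Indices per target-motion condition, in the MO ± 100 ms window: preferred
direction (angle of the rate-weighted vector sum over the eight sector
means), tuning depth (max − min of sector means), offset (mean rate).

Modulation classification compares each moving condition with the static
condition. All three tests rest on index estimates recomputed on disjoint
trial splits (round-robin within sector, at most 5 splits), which are
independent samples — a bootstrap would let the test's effective sample size
grow with the arbitrary replicate count. Amplitude and offset are estimated
per split as sqrt(a²+b²) and c of the linear cosine model
a·cosθ + b·sinθ + c; both are exact for cosine-tuned units under any trial
angle distribution, whereas raw sector statistics pick up angle-sampling
terms proportional to the tuning amplitude and then misattribute amplitude
changes to offsets (and vice versa). The tests: PD shift — Watson–Williams
on split PDs, requiring also a ≥5° mean difference; gain and addition —
two-sided Wilcoxon rank-sum on split amplitudes / offsets, requiring a ≥2%
relative change (the floors guard the exact-null case, where discreteness
alone can otherwise reject). PD-shift and gain presuppose direction tuning
(Kruskal–Wallis across sectors, p < 0.05, any condition); a unit with no
flag and no direction tuning is "none". Flags may co-occur (mixtures). On
noiseless pure-mechanism units the procedure recovers exactly the generating
flag; under Poisson noise the per-mechanism sensitivity stays at 1.0 at
3× rate scale and 20 trials/cell while extra co-flags appear at roughly the
nominal false-positive rate of the uncorrected 4-condition comparisons (no
multiple-comparison correction is applied by design).

Parametric tuning fits (single-trial rates, nonlinear least squares,
8-point PD multi-start × 2 sigmoid-slope signs, ties by residual then
smallest |a2|): simple cosine, gain, additive, PD-shift, and a full model
combining gain, offset and shift terms. The PD-shift model uses the shift
form a1·cos(θ − θpd − a5·σ(a2·vel)); fits are canonicalized to positive
amplitude (the (−A, θpd+180°) degeneracy), and models are compared by
adjusted R² = 1 − (1−r²)(n−1)/(n−p−1) with one-tailed rank-sum tests at the
population level.

## Neural-state geometry

Pipeline: window-average → z-score per neuron (zero-variance units dropped
and logged) → PCA → per-condition 3D ellipse fit → tilt / rotation / shift
metrics → tilt-vs-velocity regression.

Ellipse fitting is plane-then-conic: the condition's best plane by total
least squares (smallest PCA direction), then the direct ellipse-specific
least-squares conic fit (Halir–Flusser) in the plane, converted to geometric
parameters through the quadratic-form eigenbasis. Fit quality is
r² = 1 − Σdᵢ²/Σ‖pᵢ−centroid‖² with dᵢ the 3D distance to the nearest ellipse
point (dense parametric sampling, 1024 points). Collinear point sets and
hyperbolic conics raise errors rather than returning nonsense.

Tilt is the angle between plane normals folded into [0°, 90°], signed by the
side of a common axis on which the normal leans; the axis is the
velocity-sign-weighted mean in-plane lean of the moving-condition normals,
which makes counter-clockwise target motion read positive by construction.
Rotation is the circular-mean PC1–PC2 angular offset of matched sector
centroids (missing sectors skipped). State shift is the RMS distance between
64 arc-length-matched points on the two ellipses, phase-anchored on the
reference major axis (or a supplied direction); the correspondence is a
convention — the convention-free quantity is the translation magnitude, which the
metric reproduces exactly for rigidly translated rings. All metrics are
invariant under proper rigid rotations of the state cloud
(`align_static_plane`, which maps the static normal to +z, is restricted to
proper rotations — no reflections).

## Recurrent network

Rate dynamics τ·dx/dt = −x + J r + B u with τ = 50 ms, r = tanh(x) for
x > 0 else 0 (rates in [0, 1)), Euler-integrated at dt = 10 ms ≪ τ, initial
state zero, read-out z = W r. Inputs (5 channels): motor intention — the 2D
interception point, present only MO−50..MO ms; target location — the moving
target's 2D coordinates all trial; GO — a 0→1 step. Trials: TO at 0, GO
after a U[400, 800] ms delay, MO = GO + 200 ms reaction time, 300 ms
movement; the target output is the minimum-jerk velocity toward the
interception point, so the analysis window MO−200..MO+120 ms always lies
inside the trial. Loss = mean squared output error + α·Σₜ Σₙ rₙ(t)²
(α = 1e−7, squared activity per the description of the penalty despite its
L1-suggestive name), optimized by Adam (lr 0.001, our NumPy implementation
with backpropagation through time, gradient clipping at norm 1; gradients
verified against finite differences to 2e−8 relative error). Defaults:
3000 steps of 32 random trials.

Initialization: J ~ N(0, (g/N)²) with g = 1.5, N = 200, taken literally
(`scale_mode="g_over_sqrt_n"` switches to the conventional g/√N); W starts
at zero. B cannot start at zero: with rectified-tanh units and zero initial
state an all-zero B leaves the network at an exact fixed point with zero
gradient everywhere, so B is drawn N(0, 1/√5).

Trained ensembles (seeds 1–3) reach a validation endpoint error of
~0.0044 ± a few 1e−3 (radius 0.15) on the fixed 500-trial validation set.
Node analyses reuse the population machinery verbatim: a balanced 5×8 grid
(5 trials per cell, endpoint jitter, delay jitter) is simulated, rates are
aligned to MO, nodes with temporal-mean rate ≤ 0.01 are excluded as
inactive, and classification, geometry, decoding, ablation (all touching
weights zeroed), connection scaling (1.5× by default), connectivity
statistics (mean |J| per class pair, Kruskal–Wallis omnibus), and CCA /
Procrustes latent comparison (first 30 PCs, 10 canonical pairs, 40 time
bins in MO−200..MO+120 ms) follow. Variants: GM (no target input), GT (no
intention input), sparse (10% nonzero initial J).

## Problem sizes and numerical choices

Simulated populations use the full published sizes (300 neurons per pure
group, 320-trial grids). Network ensembles default to 3 models rather than
100; the quantities compared (endpoint error, modulation fractions, tilt
slope) are means whose seed-to-seed spread is small (see the per-model
table the suite prints). Decoding repetitions default to 10 (temporal) and
are reduced from 1000 to ~30–100 for transfer contrasts in tests; the
contrast ordering is stable well below that. Sigmoid arguments are clipped
at ±500 to avoid overflow; PD fits report NaN adjusted R² when no start
converges; degenerate circular data (all angles equal) resolve
Watson–Williams by the limit of its F statistic.

## Known limitations

The additive model group's printed third-PC variance cannot be reconciled
with its printed generating equation (see the explained-variance note
above); we report what the equations produce. Modulation fractions of
retrained networks depend on training length and on the exact statistical
procedure, both under-determined by the published description: our networks
show more PD-shift and gain flagging than the published ensemble row while
matching its addition and none fractions and all behavioral/geometry
quantities. The Watson–Williams test assumes comparable, reasonably high
concentration across groups; with 5 splits per condition its power is
moderate, which is intentional (see the pseudo-replication argument above).
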