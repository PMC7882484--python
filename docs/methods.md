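# Methods

`mothtaxis` analyses the olfactory search behaviour of a walking male
silkmoth (*Bombyx mori*) through the lens of infotaxis: the moth's
trajectory and its odor-hit record are replayed as a probabilistic agent
that tracks a belief over candidate source locations, so that every time
step can be scored by the information it actually gained (the realized
entropy change) and by the information its movement was expected to gain.
Deviations from the stereotyped "programmed behaviour" can then be tested
for their information value. Because the reference experiment's raw
tethered-moth trajectories are not available as a machine-readable archive,
the package ships a first-class synthetic world — a stochastic puff plume
and a programmed-behaviour moth policy with a controllable deviation rate —
that emulates the study conditions and makes every downstream statistic
testable end to end.

## 1. The virtual world

**Arena and protocol.** A 350 mm (downwind, x) by 200 mm (crosswind, y)
arena with the pheromone source at the origin, wind blowing along +x at
0.1 m/s, a 35 mm goal radius, a 180 s time limit and 20 Hz sampling. The
moth starts at (180, 0) mm. All defaults live in `ArenaConfig`.

**Heading convention.** Positions are global; headings are
counter-clockwise from +x and wrapped to (−π, π]. The start heading is
stated in an "upwind" frame by default (`heading_frame="upwind"`): a start
angle of −π/6 means 30° clockwise of facing the source. This matters
because hits are only accepted when the moth faces within 90° of upwind
(see §3); with a literal +x-frame reading of the printed start tuple the
moth would face downwind, never receive a gated hit, and — being
motionless until its first hit — never move. The `"wind"` frame is
available for users who want the literal global heading.

**Plume.** Circular puffs are emitted at the source as a Poisson process
(10 puffs/s), advected downwind at the wind speed, meander laterally as a
Gaussian random walk (30 mm/√s), grow linearly (12 mm/s from a 10 mm birth
radius) and are removed after 4 s or on leaving the arena. The process
reproduces the sporadic, intermittent hit trains that the analysis needs
with five interpretable parameters; it does not model intra-puff
concentration structure, vertical transport, or the pixel statistics of a
real smoke plume. Antennae are two points offset ±3 mm perpendicular to
the heading; a hit is registered when an antenna lies strictly inside a
puff disc (the rim itself is not a hit).

**Moth policy.** The programmed behaviour is a hit-reset maneuver
sequence. Writing τ_b for the blank duration (time since the last accepted
hit):

| phase  | window                | action |
|--------|-----------------------|--------|
| wait   | before the first hit  | v = 0, ω = 0 |
| surge  | τ_b ≤ 0.5 s           | v = 24 mm/s, ω = 0 |
| zigzag | 0.5 s < τ_b ≤ 6.5 s   | v = 12 mm/s, ω = ±90 °/s, sign alternating every 2 s |
| loop   | τ_b > 6.5 s           | v = 12 mm/s, ω = 60 °/s constant sign |

With probability ε per sample (`deviation_rate`, 0 by default, 0.3 in the
study condition) the commanded action is replaced by a stationary rotation
with |ω| uniform in 30–180 °/s — the controllable source of "explorative"
deviations whose information value the pipeline measures. Pose integration
is forward Euler at 50 ms, matching the discreteness of the measured data;
the pose is clipped to the arena with heading preserved.

The surge duration and speed are behaviourally grounded (a ~0.5 s straight
run at a walking speed of ~24 mm/s). The zigzag/loop kinematics and the
plume parameters are not published for the reference setup; they were
chosen once so that the simulated experiment lands in the reported regime —
roughly half to two-thirds of 20 trials succeed within 180 s with search
times of tens of seconds and large spread — and so that pure-policy motion
satisfies the kinematic maneuver definitions (§4). Passing tests therefore
show that the *analysis* behaves correctly on data with this structure;
they do not validate the generator against real moth kinematics beyond
those summary properties.

## 2. Infotaxis observer

The belief is a probability map P(r_src | T_t) over a 5 mm lattice of
candidate source cells (70 × 40 = 2800 over the default arena — fine
enough to resolve the 10 mm agent radius, coarse enough to replay a 3600
sample trial in about a second). Its certainty is the Shannon entropy
S_t = −Σ P ln P (nats), starting at ln 2800 ≈ 7.94.

**Encounter model.** The probability that the agent receives a hit during
one 50 ms sample, if the source sat in cell r_src, is a Poisson thinning
p_hit = 1 − exp(−R(r|r_src) dt) of the classic two-dimensional mean
encounter rate for an advected, diffusing, finite-lifetime particle field:

    R(r | r0) = R / ln(λ/a) · exp(V (x − x0) / 2D) · K0(|r − r0| / λ),
    λ = sqrt(D τ / (1 + V² τ / 4D)),

with K0 the modified Bessel function of the second kind, order zero. The
distance is floored at the agent radius a to avoid the logarithmic
singularity. Defaults: a = 10 mm (half a body length), V = 100 mm/s (the
arena wind), D = 2000 mm²/s, τ = 3 s, R = 1 hit/s. D and τ were set so
the downwind e-folding length 1/(1/λ − V/2D) ≈ 320 mm spans the arena;
λ ≈ 35.5 mm keeps ln(λ/a) > 0. The closed form is cross-checked in the
test suite against an independent sparse finite-difference solution of the
steady advection–diffusion–decay equation (agreement better than 5%, and
in practice ~3%, away from the source singularity and the truncation
boundary).

**Bayes update.** On each sample the per-cell likelihood is p_hit (hit) or
1 − p_hit (no hit); cells within the agent radius of the agent are zeroed
(the source would have been discovered there) and the posterior is
renormalized. A posterior with zero total mass raises
`DegenerateBeliefError` — it means every hypothesis was excluded, which on
a small lattice simply reflects an exhaustively visited arena.

**Expected reward.** For a move to r′,

    E[ΔS(r_t → r′)] = p* ΔS* + (1 − p*) ΔS,

where p* is the belief mass within the agent radius of r′, ΔS* = −S_t
(discovery collapses the entropy to zero), and ΔS averages the entropies
of the hit/no-hit posteriors conditioned on the source *not* being at r′.
This is computed exactly (no sampling) and is verified against a
brute-force three-outcome enumeration to 1e−9.

**Replay semantics.** Hits from the two antennae are OR-ed into a single
binary event and gated by the upwind-facing capture condition
cos(π − θ + θ_src) > 0 (wing-flap-driven frontal airflow; the strictly
perpendicular heading is excluded, with a 1e−12 cosine tolerance against
floating-point rounding at right angles). Executed displacements are
snapped to the nearest lattice cell; E[ΔS_t] is reported for the executed
action (the alternative — aggregating over the whole action set — is what
a pure infotaxis controller would optimize, and a greedy closed-loop agent
using exactly that rule is provided as `run_infotaxis_episode`). The
recorded series are S_t, ΔS_t = S_{t+1} − S_t, E[ΔS_t], p*, the gated hit
indicator, cumulative hits and a trailing 1 s hit rate; a trajectory of n
samples yields n − 1 records. Entropy is *not* monotone: a detection
narrows the belief and subsequent silence broadens it again, so positive
ΔS occurs by design.

## 3. Maneuver classification

Linear and angular speeds are estimated from the pose by central
differences (one-sided at the ends); ω is reported in deg/s to match the
behavioural thresholds. Two schemes label every sample:

* **temporal** (blank duration only): Surge if τ_b ≤ 500 ms, Rotate if
  τ_b > 500 ms, Stop before the first hit;
* **kinematic** (blank duration + velocities), clauses in order:
  1. Surge if τ_b ≤ 500 ms and v > 0;
  2. Rotate if τ_b > 200 ms and |ω| > 0;
  3. Surge if τ_b > 200 ms and |ω| < 5 °/s;
  4. Stop otherwise.

Two ordering decisions shape the contingency table. Checking Rotate before
the slow-surge clause makes (temporal Rotate, kinematic Surge) possible
only when ω = 0 *exactly* — in practice a single sample at each zigzag
turn reversal, ~0.1% of samples, zero at table precision. Opening the
Rotate clause at the 200 ms bound (rather than 500 ms) is what makes the
*mismatch* class — kinematic Rotate while the temporal model predicts
Surge — reachable at all: with a 500 ms bound on both clauses the two
schemes could never disagree in that direction and the match/mismatch
dichotomy would be empty by construction. Under this ordering, mismatches
are exactly stationary rotations performed 200–500 ms after a hit, i.e.
moments where the moth rotates ("explores") when the programmed model says
it should still be surging. A sample is *matching* when both schemes agree
on a non-Stop label, *mismatching* in the kinematic-Rotate/temporal-Surge
case, and *excluded* otherwise (Stop has no information-seeking reading,
and the paper-thin ω = 0 Rotate/Surge cell is not interpretable). All
thresholds (500 ms, 200 ms, 5 °/s, and an optional minimum-speed dead-band,
default 0) are exposed in `ClassifyConfig`.

The per-trial maneuver matrix normalizes the four Surge/Rotate cells by the
*total* sample count so that cells plus the excluded fraction sum to one;
cohort output is the mean ± sd across trials.

## 4. Reward statistics

Rewards and labels are joined sample-by-sample on the shared time base
(excluded samples dropped; trials pooled by default — per-trial testing is
available by running the statistics on individual tables). The
comparisons are:

* **K-S test**: two-sided two-sample Kolmogorov–Smirnov on the ΔS (and
  E[ΔS]) samples of the match vs mismatch groups, asymptotic p-value
  (`scipy.stats.ks_2samp`). Its type-I error calibration at α = 0.05 is
  itself a test (0.05 ± 0.02 over 1000 null replicates).
* **ECDFs and histograms** per group.
* **Binned means** of ΔS and E[ΔS] against the trailing 1 s hit rate and
  the cumulative hit count (1-D binning per covariate; edges in
  `AnalysisConfig`).
* **Windowed RMSE** between realized and expected rewards,
  RMSE = sqrt(1/N Σ (ΔS_{i+1} − E[ΔS_i])²), over non-overlapping windows
  of N = 20 samples (1 s of data; overlap-free windows keep the
  per-window statistics independent for binning). Each window carries its
  mean hit rate, final cumulative hits, and a majority-vote match status
  (ties → excluded). The headline trend is the Spearman rank correlation
  of window RMSE against cumulative hits, which is reliably negative on
  synthetic cohorts: accumulated detections narrow the belief and make
  expected and realized rewards agree.

## 5. Reproducibility and numerics

Every stochastic component draws from a `numpy` Generator seeded from the
trial seed; cohort seeds derive from a base seed via `SeedSequence` and
stay below 2³¹. Equal seeds give byte-identical trajectory CSVs and
checksummed pipeline outputs (asserted in the CLI tests). Belief
normalization is enforced to 1e−9 after every update; entropies use
x·ln x with the 0 ln 0 = 0 convention via `scipy.special.xlogy`. Replay
caches the encounter-rate field per visited lattice cell, which makes a
full-trial replay roughly 100× cheaper than naive re-evaluation.

Problem sizes used by the shipped tests and the acceptance script — one
20-trial cohort per run, 5-cohort ensembles for the distributional claims,
20-cohort ensembles of 6 trials for the deviation-rate sweep — were chosen
to make each claim statistically decidable at desk scale; all sizes are
parameters of the underlying functions.

## 6. Known limitations

* The plume is parametric and two-dimensional; it reproduces hit
  intermittency but not measured smoke statistics, intra-puff
  concentration, or vertical structure.
* The synthetic moth's zigzag/loop kinematics are stylized; only the surge
  phase is quantitatively grounded.
* The likelihood parameters of the original analysis are unknown, so
  absolute entropy magnitudes (and hence absolute reward scales) are not
  comparable to the reference figures; all pipeline claims are therefore
  qualitative (signs, orderings, significance) rather than value-matching.
* The mismatch class is rare under the synthetic deviation model (~0.5% of
  included samples at ε = 0.3, because central-difference speeds smear
  single-sample deviations); the K-S comparison consequently runs with an
  unbalanced design, which the asymptotic test handles but which widens
  its run-to-run variability.
* The greedy infotaxis agent moves on the belief lattice and ignores
  orientation; it is a reference policy, not a moth model.
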