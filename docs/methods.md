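# Methods

This note documents the estimators, conventions and design decisions in
`stsa`, and what the synthetic-data tests do and do not establish about
real data.

## Data model and coordinate convention

A trial carries condition labels (device: classical key-press vs tracked
VR; N-back level 1–3; trial type Match vs non-Match), a completion time
`rt_ms` and final accuracy (absent when the response never reached a box),
and — for tracked trials — a trajectory: strictly increasing timestamps
(ms from stimulus onset, 90 Hz nominal) and a signed position `x` in
meters on the axis joining the two response boxes.

`x` is derived from the distances A (to the Match box) and B (to the
non-Match box) as `x = (B − A)/2`, so `x = 0` is the neutral start,
positive is toward the Match box *for every trial* regardless of physical
counterbalancing, and `|x|` at a box equals half the box separation.
Correctness is therefore never baked into the coordinate; it is derived
downstream from sign × trial type. The absolute spatial scale is
configuration, not fact: published displays of this paradigm use
inconsistent axis scales, so the analysis grid (total distance, default
0.20 m) is independent of the loader.

Unfinished trials are retained: they contribute to occupancy maps and to
crossing risk sets (until their last sample) but not to completed-response
survival curves. This is right-censoring by design rather than deletion.

## Discrete-time survival analysis

Time bins are left-open right-closed, `bin k = ((k−1)·w, k·w]` with
`w = 100` ms; e.g. 3,650 ms and 3,700 ms both map to bin 37. With event
counts `d_t` and at-risk counts `n_t` (trials completing in bin ≥ t) over
the *full* tail:

    h(t) = d_t / n_t        S(t) = 1 − (Σ_{i≤t} d_i)/n        ca(t) = correct_t / d_t

There is deliberately no Kaplan–Meier censoring machinery: every
completed trial has an observed time, and the 70-bin display window plus
the 5% mask (first bin with `S < .05`) only affect presentation.
`ca` is undefined (NaN, broken lines) in bins without events — never 0.

The median RT solves `S(t) = .50` by linear interpolation of S against the
bin *upper edges* (with `S = 1` at `t = 0`); an exact hit returns the
edge. Interpolating against edges rather than centers is a documented
choice; the difference is at most half a bin. When S never reaches .50
the median is reported as undefined (`None`), distinct from an error.

Curves are pooled over participants within a condition by default;
per-participant curves feed the stats module where needed.

## StSA: crossing events, H and CA

Stage 0 averages trajectories on a common time grid using only trials
whose recording extends to each grid point (no padding), reporting the
contributing `n` alongside — averages over a shrinking set are visibly
flagged rather than silently extrapolated.

Stage 2 counts trajectory visits per cell of a fine grid (default 101
spatial bins of 0.008 m over (−0.404, 0.404] m × 701 temporal bins of
10 ms over (0, 7010] ms; the published ranges do not divide evenly into
the published bin counts, so both are configurable). Default counting is
one increment per trial per cell ("how many trajectories visit"), with a
per-sample diagnostic mode; out-of-range samples are dropped and tallied.
Displays use `log10(count + 1)`.

Stage 3 reduces each trajectory to first-crossing events of 20 nested
thresholds `θ_k = k · 5% · total distance`. Detection takes the first
*sample* with `|x| ≥ θ_k` (no sub-sample interpolation: at 90 Hz the
gain would be under 12 ms against 100 ms bins), with a 1e-12 m slack so
exact ties are not lost to floating point. Event times need not be
monotone in k — a dip toward the wrong box crosses small thresholds long
before larger ones are reached on the way back, and that is the signal.

Per threshold row k, the events define an ordinary discrete-time hazard:
a trial leaves the risk set at its first crossing of θ_k, or at its last
sample if it never crosses, so

    H(k,t) = events(k,t) / at-risk(k,t)

rows are independent hazards and the product identity
`Π_{i≤t}(1 − H(k,i))` recovers the never-crossed fraction when no
recording ends early (property-tested). This "exit at first crossing or
recording end" reading of the risk set is a documented choice; the
alternative (keeping completed trials at risk indefinitely) only rescales
the tail where nothing is left to cross. `CA(k,t)` is the mean crossing
correctness per cell, NaN where no events occur. Hazard maps for a set of
conditions are scaled by their single global maximum, preserving all
orderings and making the maximum exactly 1.

No trimming is ever applied to trajectory analyses; display truncation at
70 bins never removes data from the estimates.

## Classical chain

RT trimming replicates the conventional two-stage recipe per condition:
1.5·IQR fences with type-7 (linear-interpolation) quartiles — the
convention matters, so it is pinned and tested — then mean ± 2 SD
(two-sided by default; the one-sided reading is available as an option),
then error-trial exclusion for RT analyses. Each stage's removal
percentage is reported against the count entering that stage. Cells too
small to trim pass through untrimmed rather than aborting a whole
dataset.

`rm_anova` implements the classical balanced sums-of-squares
decomposition with the participant as a random factor, for any number of
within-participant factors and optional between factors (split-plot).
Within effects are tested against their interaction with participants
(within groups); between effects against participants-within-groups.
Partial η² is `SS_effect/(SS_effect + SS_error)`. Greenhouse–Geisser
epsilon is computed from the pooled within-group covariance of the
effect's cell means under orthonormal (Helmert) contrasts — the Kronecker
product across factors for interactions — clamped to `[1/df, 1]`, with
the corrected p reported alongside the uncorrected one. Against pingouin
(which handles up to two within factors) F, p and epsilon agree to
numerical precision in the fully-within case; in the split-plot case F
and p agree while pingouin's epsilon differs slightly because it does not
pool the covariance within groups. Three fully-within factors (needed for
Device × N-back × TrialType with every participant in both devices, and
for the windowed CA model) are beyond pingouin's surface, which is why
the decomposition is implemented here and pingouin serves as an oracle in
the tests. Zero error variance yields an explicitly undefined F (NaN),
not an exception.

Windowed CA inference cuts crossing events into eight right-closed 500 ms
windows (an event at exactly 500 ms belongs to window 1) and computes CA
per participant × trial type × N-back × spatial bin × window. Each window
is analysed as a fully-within TrialType × N-back × spatial-bin ANOVA. The
error model — spatial bin as a within factor with the participant as the
random factor — is a documented choice; the alternative of averaging over
bins first is available via the emitted per-window participant means
(the display values). Sparsity is handled by an iterative selection:
within a window, participants are dropped (worst-covered first, and
logged) until some set of spatial bins is complete for everyone
remaining, and the ANOVA runs on that complete block. No correction is
applied across the eight windows (each window is reported on its own);
Holm-corrected post-hocs are available where wanted.

## Synthetic generator

The generator emulates the study design it is meant to exercise: 19
participants, both devices, three N-back levels, 76 trials per
participant × level cell (4,332 tracked trials), each trial independently
a Match with probability .33, sampling at 90 Hz, boxes at ±0.20 m.
A trial holds at 0 for a shifted-lognormal initiation delay, then moves
at constant speed toward a first target side; with probability
`early_match_bias_prob` that first leg heads toward the Match box
regardless of the truth, and any leg not aimed at the final landing side
reverses at a switch distance uniform in 30–80% of the total distance.
Per-sample hesitation pauses freeze the hand; an error probability picks
the wrong landing box, which then determines final accuracy. Participant
heterogeneity enters as lognormal multipliers on delay and speed.

Per-level defaults (delay shift 100 ms; lognormal medians 600/900/1300 ms
with σ 0.55/0.65/0.75; speeds 0.30/0.25/0.20 m/s; hesitation, self-
correction, early Match bias and error rates each increasing with N) were
chosen once so that the generated data reproduce the qualitative
structure the analyses assume: initiation concentrating around 0.7–1.4 s
and slowing with load, most N1 trials finishing under 2 s, a left tail of
early movements (roughly 10–25% of trials move within 500 ms while no
trial *completes* that early), and bias/error gradients over N. The
classical arm reuses the delay process with the motor leg compressed to
70% of the tracked movement time.

Randomness is reproducible by construction: one root seed, with each
trial (and each participant's multipliers) drawn from its own
counter-keyed substream, so output is independent of generation order.

What the generator does *not* emulate: 3-D kinematics (only the signed
box-axis projection is modelled), within-movement speed profiles
(movement is piecewise-constant velocity), learning or fatigue across
blocks, and any calibration of the device contrast to a null effect.
Passing recovery tests therefore shows the estimators are correct on data
with known structure — not that real hands move like the model.

## Numerical and testing choices

Problem sizes in the test suite and acceptance script (5,000 trials for
hazard recovery, 2,000 for bias recovery, 500 replicates for the null
rejection rate, 30 for power) were chosen to make Monte-Carlo bounds
(4·SE, [0.03, 0.07], ≥0.9) comfortably stable across seeds while keeping
a full run in minutes on one CPU. The null rejection rate pools the three
effects of each simulated table; at 1,500 draws the nominal .05 rate has
a standard error of ~0.006. Known limitations: the hazard estimator is
undefined (reported 0) in cells where no trial is at risk; the GG epsilon
for split-plot designs assumes homogeneous within-group covariance; and
the windowed ANOVA's completeness selection can legitimately return no
analysable window in very sparse data, which is reported rather than
imputed.
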