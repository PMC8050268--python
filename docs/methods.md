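# Methods

This note records the model, the synthetic study conditions, the
numerical choices and the known limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

The unit of analysis is one subject's nonnegative EMG envelope tensor
`X (S×T×K)`: S = 18 muscle channels in a fixed canonical order (9
muscles × dominant/nondominant side), T = 150 frames at 200 Hz covering
the 750 ms ending at ball release (release is the last frame; frame *j*
is `(T−1−j)·5` ms before release), K = 30 trials in three 10-trial
effort blocks (50/80/100% subjective effort). Trials always travel in
block order; files store frames and trials 1-based, memory is 0-based.

## Preprocessing

The per-trial chain is fixed: (1) subtract the per-channel mean of the
whole recording (the package's reading of "offset removal"); (2)
full-wave rectify; (3) zero-phase low-pass at 10 Hz — a Kaiser-window
FIR with ≥ 60 dB stopband attenuation and transition width 1% of the
Nyquist-to-passband span, applied forward-backward (`filtfilt`) so burst
peak timing is preserved (verified to ±1 frame); (4) decimate to 200 Hz
(the 10 Hz filter already prevents aliasing; non-integer rate ratios are
rejected rather than silently resampled); (5) keep the 150 frames ending
at the release frame, clipping filter ringing at 0.

Min-max normalization maps each muscle to [0, 1] **jointly over all
frames and trials** of a subject, not per trial: per-trial scaling would
erase the effort-dependent amplitude differences the trial components
must capture. A constant channel is an error naming the muscle.

QC: a (muscle, trial) pair is *extreme* when the trial's peak envelope
exceeds mean + 3·sd of that muscle's per-trial peaks; a muscle is
flagged with more than ten extreme trials; a subject is excluded with
more than ten flagged muscles. The per-trial-peak statistic is a design
choice (the exceedance statistic is ambiguous in the underlying
protocol); note a one-sided Chebyshev bound caps the extreme fraction
per muscle at 10% of trials, so the muscle-level flag can only fire for
recording sessions longer than ~110 trials.

## Nonnegative CP fitting

The solver minimizes `E = ½‖X − Σ_r λ_r s_r ∘ t_r ∘ u_r‖²` with
alternating multiplicative updates (the Lee–Seung rule applied to each
matricized mode), which keep all factors nonnegative and never increase
E; the objective history is retained in the diagnostics and asserted
nonincreasing in the tests. Defaults: `tol = 1e−8` (relative objective
decrease), `max_iter = 2000` sweeps, 10 restarts from uniform(0, 1]
initializations seeded per restart, best final objective kept. After
fitting, columns are normalized with scale absorbed into `λ`, zero-scale
components dropped with a warning (unless the whole model is zero, e.g.
an all-zero tensor, which legitimately yields λ = 0, E = 0), and
components sorted by λ descending with ties broken by the spatial
argmax index. Division guards use `eps = 1e−12`.

Multiplicative updates converge quickly for rank 1 (noiseless rank-1
input is reproduced to 1e−6 relative Frobenius error) but slow to a
sublinear crawl near multi-component optima (~1e−4–1e−3 relative error
after thousands of sweeps on noiseless rank-2 input); the tests assert
accordingly. Factor *recovery* is unaffected: matched cosines on the
reference scenario exceed 0.99 in all modes.

Rank selection scans ranks 1..R_max, recording the best-restart
uncentered `R² = 1 − Σ(X−X̂)²/ΣX²`, and picks the smallest rank
reaching the threshold (default 0.80). Each rank adds one warm-start
candidate — the previous rank's best factors plus one small random
column (1e−3 of the smallest λ) — so the R² curve is nondecreasing in
rank by construction; this is the package's own choice where the scan
protocol was open. When several thresholds are compared
(`criteria_robustness`), one scan is shared and each threshold reads its
rank off the same fitted curve, which both saves refits and makes the
threshold-monotonicity of the selected rank exact.

## Trial space

PCA loadings are the top-2 eigenvectors of the sample covariance of the
trial factor matrix (columns centered over trials, divisor K−1); scores
are projections of the *uncentered* trial components, so score clouds
keep their nonnegative offset — the offset is irrelevant to the
classifier (axis-aligned trees are translation invariant, asserted in
tests) but keeps plotted coordinates comparable across thresholds.

Orientation is pure sign convention: PC1 flips so the 100%-effort group
mean exceeds the 50% one, PC2 so 100% exceeds 80%. The **gate** role
goes to the PC with the larger Fisher ratio (between-group mean gap
squared over pooled within variance) for {50} vs {80, 100}; the other PC
is **fine**. The Fisher criterion is the package's explicit rule for
what the original analysis resolved by inspection, and `swap_applied`
records the atypical subject whose gate lives on the second variance
axis.

PC-associated modules are `Σ_r v_mr s_r` and `Σ_r v_mr t_r`,
renormalized to unit norm; loadings may be negative, so these modules
can carry negative entries even though the CP factors cannot. For
cross-subject averaging, a module pair flips sign only when one-sample
t-tests over its entries (S = 18 and T = 150 observations — the
package's choice of test sample) are both significant at p < 0.05 *and*
both means are negative; flipping spatial and temporal together leaves
every reconstruction invariant.

## Classification

CART with Gini impurity on the (gate, fine) scores. The minimum leaf
size is selected from 1..10 by stratified cross-validation, ties
resolved toward the larger (more regularized) leaf; the final tree is
refit on all trials. Generalization is the mean misclassification over
seeded stratified 70/30 hold-out splits (100 by default), refitting with
the selected leaf size per split. The tie rule is deliberately
conservative; on 30-trial subjects it can pick a leaf size that leaves a
21-trial training split too coarse for three classes, raising hold-out
error well above training error while still beating the 2/3 random
baseline — visible in the worked example (hold-out 0.389, training 0).
The baseline itself is `1 − Σ_c p_c/C` for a uniform guesser over the C
observed classes: exactly 2/3 for three balanced classes.

## Statistical layer

Tukey HSD (studentized range on pooled within-group variance, via
scipy), one-way ANOVA with its correct (C−1, N−C) degrees of freedom —
(2, 27) for 3×10 trials — and per-element one-sample t-tests vs 0 across
subjects with Bonferroni correction (`min(1, m·p)`) and Cohen's
d = mean/sd. A zero-variance element reports d = 0, p = 1 at mean zero
and d = ±∞, p = 0 otherwise. The familywise-error test in the suite
checks the Bonferroni guarantee with a one-sided binomial test on the
1000-rep Monte-Carlo rejection count, the statistically correct reading
of "FWER ≤ 0.05" for a finite simulation (the true FWER of the
procedure here is ≈ 0.049; the MC standard error is ≈ 0.007).

Threshold-robustness matrices hold |Pearson r| between orientation-fixed
gate (and fine) score vectors across the 70/75/80/85% criteria; the
absolute value additionally guards residual sign ambiguity.

## Synthetic study conditions

The generator's defaults are the study conditions, chosen once:

- dimensions 18 × 150 × 30, planted rank R\* = 4;
- spatial factors: 2–4 dominant muscles per component drawn without
  replacement (components occupy distinct muscle groups) with weight
  ~1 over a ~0.06 background, unit-normalized;
- temporal factors: Gaussian bursts with centers spread over frames
  0.25T–0.92T and width T/15, unit-normalized — phase-locked bursts
  tiling stride, arm-cocking and release phases;
- per-effort gains: component 2 is the gate (0.5, 1.5, 1.6 for
  50/80/100%), component 3 the fine contrast (0.8, 1.0, 1.8), the
  others effort-independent; multiplicative mean-one lognormal trial
  jitter with σ = 0.15;
- amplitudes scaled so the noiseless tensor peaks at 1 (matching
  min-max-normalized envelopes); additive Gaussian noise clipped at 0,
  with σ calibrated by closed-form truncated-normal moments so the
  planted model explains 0.85 of the rendered uncentered variance
  (a plain unclipped formula overshoots to ~0.90 because clipping
  removes noise power near zero);
- ball speeds Normal per effort with means 105/125/130 km/h, sd 2 —
  a large 50→80 step and a small 80→100 step;
- raw mode: each channel is `0.3 + envelope × carrier` at 2 kHz, with
  independent zero-mean Gaussian carriers band-limited to 20–500 Hz and
  scaled to unit rectified mean, the envelope linearly upsampled from
  the frame grid; release is the last envelope sample.

What the generator does *not* emulate: biomechanically realistic
waveforms, motion artifacts, electrode crosstalk, inter-subject
anatomical variability, or band-limited envelope noise. That last gap
matters for the raw round trip: the tensor noise is white across 200 Hz
frames, and white envelope noise cannot pass a 10 Hz filter, so
noise-dominated background channels cap at r ≈ 0.3 against the rendered
tensor. The round-trip property therefore holds channel-wise (r > 0.9,
measured ≥ 0.98) on noiseless subjects and on signal-dominated channels
under calibrated noise. Passing tests on this generator show the
pipeline recovers planted low-rank effort structure under calibrated
noise; they do not certify behavior on real EMG artifacts.

## Problem sizes in the test suite

Simulation-based tests use the reference scenario at deliberately
moderate solver settings (3 restarts, `tol 1e−7`, ≤ 400 sweeps for
single fits; 2 restarts, `tol 1e−6`, ≤ 300 sweeps inside rank scans),
which recover planted factors to cosine > 0.99; the recovery and
trial-space suites share one 20-seed session fixture, rank-scan
monotonicity uses 5 subjects, threshold robustness 10, and the
permuted-label check 25 permutations × 20 hold-out splits. These sizes
are the package's chosen defaults for its own validation.

## Known limitations

- Multiplicative updates can stagnate at rank-deficient stationary
  points; restarts plus the nested warm start mitigate but do not
  eliminate this.
- The leaf-size tie rule (larger leaf on CV ties) is conservative on
  30-trial subjects, as noted above.
- `criteria_robustness` correlates role-aligned (gate/fine) scores, so
  a role swap between thresholds compares like with like; subjects
  whose gate/fine assignment is itself unstable will show that
  instability as low fine-axis correlations.
- Tucker decompositions, smoothness-constrained temporal factors and
  missing-data handling are out of scope.
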