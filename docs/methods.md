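# Methods

`popact` re-implements, as a tested library, the population-analysis
computations used in cross-modal Go/Nogo reversal-learning two-photon
calcium-imaging experiments in auditory thalamus (MGB): behavioral
performance, per-cell stimulus-responsiveness, functional clustering,
trial-by-trial population-vector correlation (PVC), weighted co-activity
network metrics, multisensory tuning analyses, and linear population
decoding. Because the analyses are validated without any recorded dataset,
the package ships a synthetic-experiment generator whose planted structure
is the ground truth every stage is checked against.

## Task and data model

A session is a cell-by-frame fluorescence matrix `F` with a matched neuropil
matrix `Fneu` at ~30 Hz, a per-trial event table, and behavioral traces.
Each of the 140 trials per session is Go (30%), Nogo (35%) or catch (35%):
a 2 s stimulus (or blank), a 2 s delay, then a 1.5 s response window in
which licking on a Go trial is a Hit. Nogo and catch outcomes are pooled
for the false-alarm ratio. Performance is

    d' = Z(hit ratio) − Z(false-alarm ratio),

with ratios of exactly 0 or 1 replaced by 1/(2N) and 1 − 1/(2N) before the
inverse normal (the exact adjustment is unstated in the source methods; the
log-linear rule is the standard choice). A mouse is expert after three
consecutive sessions with d' > 1.5. Spout contacts within 200 ms of the
response-window onset are accidental touches, not responses.

## Signal path

Fixed order, enforced through provenance tags on the trace container:

1. neuropil correction: `corrected = F − 0.7 · Fneu`;
2. linear detrend, then zero-phase 4th-order Butterworth low-pass at 5 Hz
   (order and linear detrending are our choices; only "Butterworth, 5 Hz"
   is specified);
3. optional per-cell z-scoring against the whole-session conditioned trace
   (the z reference is unstated in the source; whole-session is our choice);
4. epoching into (trials × cells × frames) tensors under a named baseline
   convention: 0.5 s / 1 s / 2 s pre-stimulus, 150 ms pre-delay, or none.
   Window length is `round(duration × frame_rate)` frames, half-open.

Every downstream stage checks the tensor's baseline tag (PVC and the
co-activity graph require the 2 s pre-stimulus convention; decoder features
require the 1 s convention), so a tensor epoched under the wrong convention
is rejected rather than silently analyzed.

## Responsiveness classification

Two steps per cell and trial type: a two-sided Wilcoxon signed-rank test of
the per-trial mean z-score over the 2 s stimulus window against zero
(α = 0.05, uncorrected), then a median threshold (|median| > 0.2 z; sign
gives excited/inhibited). For auditory cues a 0.3 s onset window is tested
as well, to catch fast-adapting cells; passing either window counts. The
per-trial response is the mean z-score without an additional per-trial
baseline — the short-baseline variant roughly doubles per-trial noise and
pushes the null false-positive rate above 5%. Up to n = 25 the signed-rank
null is computed exactly by dynamic programming over sign assignments,
which handles midranked ties exactly (SciPy's exact mode refuses ties);
beyond that the normal approximation is used.

## Functional clustering

Matched cells' trial-averaged stimulus+delay traces are concatenated across
phases (naive‖expert; initial and reversal learning as independent rows),
reduced by PCA to the components explaining ≥ 90% of variance, and
clustered with spherical (cosine-distance) k-means, k = 30, 20 restarts,
best inertia kept, empty clusters re-seeded from the farthest point. The
source procedure merges similar clusters manually; we substitute a
reproducible surrogate — average-linkage agglomeration of cluster centroid
traces while any inter-centroid Pearson r exceeds 0.8. Merged clusters get
semantic labels by best template correlation (minimum r 0.5, else "other").
Templates are the stimulus-boxcar and delay-ramp drives convolved with the
calcium kernel: with a 1.7 s decay, a plain boxcar template misreads the
indicator's decay tail through the delay as a delay ramp, so the kernel
convolution is load-bearing. Ramp-cell ids (ramp-up ∪ ramp-down) feed the
removal controls in the PVC and network stages.

## Population-vector correlation

Per session and epoch (stimulus or delay), the population vector of a trial
is the per-cell mean of the trace baselined to the 2 s pre-stimulus mean.
PVC is the trial × trial Pearson matrix; the session summary is the mean
over distinct trial pairs. Phases are compared with a random-intercept
linear mixed model (value ~ phase, random intercept per mouse, REML, Wald
z on the phase effect; a singular fit falls back to OLS and is flagged).
Controls: stratification by anticipatory licking (sessions need more than
6 trials in each stratum), and targeted ramp-cell removal against 30 random
same-size removals. Note the trial-by-trial Pearson correlation across
cells is invariant to a global affine transform of the vectors but not to
per-cell rescaling — the tests assert the global form.

## Co-activity network

Edges are Pearson correlations `r_ij` between cells' concatenated
within-epoch time series across (filtered) trials. Positive and negative
regimes are separate graphs; the negative regime uses |r| as weight.
Metrics on the positive regime:

* hubness `H_i` = mean of `r_ij` over j ≠ i (the printed formula divides by
  m and includes the self-term; the accompanying text says "to all the
  others", so j ≠ i is the default and the literal form is a switch);
* geodesic length `L_ij` by Dijkstra on lengths `1/r_ij`; unreachable pairs
  are excluded from the mean with a reported count;
* triad clustering coefficient
  `C_i = (1/(k_i(k_i−1))) Σ_{j≠k} (ŵ_ij ŵ_ik ŵ_jk)^{1/3}` with weights
  max-normalized over the whole adjacency; `C_i = 0` for degree ≤ 1.

Condition deltas are bootstrap estimates (3000 resamples, percentile 95%
CIs), resampling nodes for hubness/C and pairs for path length — the
resampling unit is unstated in the source, only counts are printed.
The r > 0.3 threshold seen in circular plots is visualization-only and is
never applied to metrics.

## Sensory mapping, multisensory index, decoding

Mapping sessions present 5 pure tones (4–20 kHz), 4 grating directions and
all 20 combinations, 8 repetitions each (232 trials; the printed "30
stimulus types" cannot be reconciled with the enumerable 29 and the
enumerated catalog is used). Split-half responsiveness feeds the 0–1 s and
1–2 s window means of each trial as separate data points into the same
two-step classifier. Tuning matrices are cells × 20 features
(pre/post × uni/multi × 5 frequencies, multisensory responses averaged over
grating directions) and are clustered under correlation distance (row
centering + the cosine k-means core). The multisensory index is
`|AV| / |A + V|`, excluded when both A and AV are non-significant, when
`AV·(A+V) < 0`, or when `A + V = 0`; 1 indicates linear integration.
Pre/post index distributions are compared with a two-sample 2-D KS test
(Fasano–Franceschini quadrant statistic, permutation p).

Decoders are linear SVMs (C = 1, one-vs-rest, features standardized on the
training fold only) on stimulus-period activity normalized by the 1 s
pre-stimulus baseline and down-sampled to 3 Hz (cells × 6 bins per trial).
Modality decoding equalizes classes to the smallest class before a 70/30
split (27 test trials on a standard session); frequency decoding pools uni-
and multisensory trials (200 trials → 140/60). Accuracy is the mean over
50 resampled iterations. Chance is estimated by circular permutation:
the concatenated down-sampled series is rotated by one random offset,
coherently across cells, and decoders are retrained (100 surrogates by
default). A within-trial rotation cannot serve here: it preserves which
cells respond in a trial, so cell-identity-coded stimuli would still decode
perfectly; the concatenated rotation decouples activity from trial labels
while preserving all temporal and cross-cell statistics.

## Synthetic world

The generator's defaults are the stated task conditions (trial mix 30/35/35,
140 trials, 2 s/2 s/1.5 s epochs, 6–13 s ITIs, ~30 Hz). Choices the source
does not fix, made once:

* calcium kernel: difference of exponentials, rise 0.07 s, decay 1.7 s
  (GCaMP7s-like), peak-normalized; amplitudes ~ conditioned-noise units;
* noise: i.i.d. Gaussian per frame (SD 1.0) plus a per-cell linear drift
  (slope SD 0.3) — the minimal model that makes detrending consequential;
  a common slow neuropil signal contaminates F with coefficient 0.7 so the
  standard correction removes it exactly;
* per-trial response reliability 0.6 and amplitude jitter 0.3 (trial
  skipping keeps baseline PVC away from saturation, as in real data);
* cell classes: stimulus-stable, learning-enhanced/inhibited (naive
  amplitude scaled ×0.2 on the silent side), Nogo-responsive, delay
  ramp-up/ramp-down (Hit trials only), behavior-coupled, nonresponsive;
* delay coherence: on Hit trials a shared smooth latent with per-cell
  lognormal(0, 0.4) loadings and per-trial lognormal(0, 0.5) amplitude,
  scaled by the phase's coherence (default 0.4 in expert, 0 in naive).
  The positive per-trial amplitude is essential: a zero-mean latent level
  cancels across trial pairs and plants no PVC;
* lick policy: Bernoulli per trial (Go/Nogo/catch = 0.55/0.50/0.45 naive,
  0.90/0.12/0.10 expert) with Poisson anticipatory licking in the delay
  (0.3 Hz naive, 1.5 Hz expert) on licking trials;
* learning curves: logistic in session index crossing d' = 1.5 at the
  configured session (max 3.0, time constant 1.5 sessions, noise SD 0.15);
  reversal restarts the curve;
* mapping: Gaussian frequency tuning on the log-spaced tone index
  (width 1.0 by default; 0.5 in the "separable" decoding fixtures),
  direction-tuned visual amplitudes, multisensory response
  `AV = gain · (A + V)` (gain 1 = linear integration).

What the generator does not emulate: biophysical spiking, motion/bleaching
artifacts beyond linear drift, sparse nonnegative transient statistics
(noise is Gaussian), pupil video (only labeled edge points are synthesized),
or session-to-session representational drift unless planted. A green test
therefore establishes that the analysis recovers what was planted under
these assumptions — not that it would behave identically on recorded data.

Two planted worlds deserve a note. The coherence world (PVC and network
experiments) loads the expert delay latent on *every* cell, so under it all
cells legitimately merge into one delay-coherent cluster; functional
clustering is therefore validated in a coherence-free world with planted
motif classes. Conversely the clustering world plants no shared latent, so
its delay PVC carries no phase effect.

## Numerical choices and degenerate inputs

* Exact signed-rank null by DP for n ≤ 25 (ties handled exactly); all-zero
  response vectors are nonresponsive with a logged reason.
* Zero-variance cells are excluded with logged ids (z-scoring, PVC, graph).
* Empty k-means clusters re-seeded from the farthest point; identical rows
  collapse to a single occupied cluster.
* Unreachable node pairs excluded from mean path length (reported count).
* Circle fit is algebraic (Kåsa) least squares; the cited geometric fit
  differs below reporting precision at pupil noise levels. Pupil frames
  with < 3 tracked points are missing; Hampel filter uses 10 neighbors per
  side and a 1.0 scaled-MAD threshold.
* Mixed-model inference uses large-sample Wald z; Satterthwaite df are out
  of scope. Singular fits fall back to OLS and are flagged in the result.
* CLI: the library's functions and `scripts/acceptance.py` are the entry
  points; no console script is shipped.

## Known limitations

* The manual cluster merge is approximated by a threshold (r > 0.8); the
  original merge criteria are subjective and not recoverable.
* Bootstrap CIs are percentile, not BCa.
* The 2-D KS p-value is a permutation estimate, not the asymptotic form.
* Decoding chance uses a single global rotation per surrogate; per-cell
  independent rotations would additionally destroy cross-cell structure
  and are not implemented.
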