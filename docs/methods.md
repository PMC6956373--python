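# Methods

## Problem and pipeline

`eegstress` classifies single trials of multichannel EEG into calm vs
stress states. Inputs follow the layout of the DEAP emotion corpus:
per participant, 40 one-minute music-video trials recorded at 128 Hz over
40 channels (32 EEG + 8 peripheral), preprocessed with a 4–45 Hz bandpass,
8064 samples per trial including a 3-s pre-trial baseline, plus per-trial
valence/arousal self-ratings on a 1–9 scale. The pipeline is:

1. keep the 32 EEG channels; drop the 384-sample baseline (8064 → 7680);
2. annotate trials from ratings — calm iff `4 < valence < 6` and
   `arousal < 4`, stress iff `valence < 3` and `arousal > 5`, all strict;
   everything else is discarded, and a participant without both states is
   excluded;
3. compute a 19-column hybrid feature pool per (trial, channel) pair;
4. rank features with a shadow-feature wrapper (Boruta) and keep the
   confirmed set;
5. balance classes with SMOTE;
6. classify with Euclidean k-NN, k chosen by stratified 10-fold CV from
   the odd candidates 1–19;
7. compare against PCA + k-NN and all-features + k-NN baselines, with a
   one-way ANOVA across per-dataset accuracies.

## Sampling unit

Each (trial, channel) pair is one sample, giving 32 feature rows per
trial. With participants contributing as few as two trials in a class,
per-trial samples would make a 60/40 split and 10-fold CV meaningless;
per-channel rows are the only unit under which the evaluation protocol is
well defined. The cost is that rows from the same trial are statistically
dependent, so per-participant accuracies should be read as within-protocol
scores, not as generalization estimates across recordings.

## Feature pool

**Time domain (F1–F11).** RMS, square mean root, peak-to-peak of the
magnitude, kurtosis, skewness, kurtosis factor, shape factor, crest
factor, impulse factor, and the Hjorth parameters mobility and
complexity. All moments use the population (1/N) convention. The four
factor features use the canonical definitions from the statistical
parameter literature: kurtosis factor = kurtosis/RMS⁴, shape factor =
RMS/mean|x|, crest factor = peak/RMS, impulse factor = peak/mean|x|; each
lives in its own expression so an alternative reading is a one-line
change. Mobility is `sqrt(var(x′)/var(x))` (with the radical, following
the Hjorth definition) with `x′` the plain first difference — no `fs`
scaling, so F10 is in radians/sample (the ratio F11 is dimensionless
either way). For a pure sinusoid of angular frequency `w` rad/sample,
mobility → `2 sin(w/2)` and complexity → 1; both serve as analytic test
oracles. Note that F6 is not scale-invariant (it scales as `c⁻⁴` under
`x → c·x`); the other ratio features F4, F5, F7–F11 are.

**Wavelet domain (F12–F19).** A level-5 db4 wavelet packet transform in
periodization mode (orthogonal, so packet energies satisfy Parseval at
every level — verified to 1e-8 in tests). Five packets are selected to
cover theta 4–8, alpha 8–12, low beta 14–16, high beta 16–32 and gamma
32–40 Hz; because the widths differ the packets come from different tree
levels (4, 4, 5, 2, 3). Packets are indexed in frequency order with each
node's band computed explicitly — natural (Paley) ordering would scramble
the band ↔ index map. Delta (0–4 Hz) is absent from the bandpassed data
and never selected. From the five packets: F12 = total coefficient
energy, F13 = population SD of the concatenated coefficients, F14 = sum
over packets of the Shannon entropy (natural log) of each packet's
normalized squared coefficients, F15–F19 = band power per packet, i.e.
the Welch PSD of the packet's single-node reconstruction integrated
(trapezoid) over the packet band. PSD is computed on reconstructions, not
raw coefficients, because coefficients live at a decimated rate where
"power in Hz" is ill-defined. Welch settings (fixed in
`wavelet_features`): Hann window, 256-sample (2-s) segments, 50% overlap,
mean averaging. db4 packet filters are not brick-wall: a mid-band
sinusoid retains ~70% of its analytic A²/2 power in its own packet with
~15% leaking into the neighbour, and time reversal moves band powers by
up to ~10%; test tolerances reflect these measured figures.

## Feature selection

Boruta, 20 iterations by default. Each iteration appends a freshly
shuffled shadow copy of every column, fits a 100-tree random forest
(sqrt(p) features per split), and scores all columns with a permutation
Z: per tree, out-of-bag accuracy minus OOB accuracy after permuting the
column within the OOB rows; Z = mean/SD of per-tree losses. A single
importance scale is used for originals and shadows — mixing impurity
importance for shadows with permutation Z for originals would make the
"feature beats best shadow" comparison incoherent; an MDI engine is
nevertheless available behind the same interface
(`BorutaConfig(importance="mdi")`). A feature hits when its Z exceeds the
iteration's best shadow Z; after the loop a one-sided binomial test at
α = 0.05 against p = 0.5 marks features confirmed (significantly more
hits than 10/20), rejected, or tentative. Tentative features are reported
but excluded from the selected set. OOB rows per tree are recovered by
replaying the forest's documented bootstrap draw
(`RandomState(tree_seed).randint(0, n, n)`); a test cross-checks this
reconstruction against the forest's own `oob_score_`.

## Balancing and classification

SMOTE interpolates minority rows between k = 5 nearest minority
neighbours (`s = a + u·(b − a)`, `u ~ U(0,1)`), up to parity with the
majority by default. Balancing and standardization are fit on the
training split only, and Boruta/PCA likewise see only training rows — the
literal protocol (balance before the split, tune k on the test split) is
available via `smote_before_split=True` / `paper_protocol=True` for
fidelity experiments, but the leakage-free ordering is the default.
Features are z-scored with training-split statistics before selection and
distance computation; without this the wavelet energy/power columns
dominate the Euclidean metric by orders of magnitude.

k-NN tie-breaks are fixed and documented: a split vote falls back to the
class of the single nearest neighbour; equal distances at the k-th
position resolve toward the lower training-row index (stable sort).
Candidate ks are the odd integers 1–19; CV ties choose the smallest k.

## Metrics

Class-wise accuracy is `100·TP_c/(TP_c + FP_c)` with the class of
interest as positive — formally this is precision; per-class recall is
reported alongside so both conventions are visible. Average accuracy is
`100·(TP+TN)/total`. The undefined case (a class never predicted) yields
NaN rather than an exception. The three-method comparison runs a
classical one-way fixed-effects ANOVA on per-dataset average accuracies;
on the bundled 25 × 3 table of published reference accuracies this gives
F = 34.20 (df 2, 72), and the published merged-dataset accuracies give
decrements of 4.12 (all features) and 7.76 (PCA) percentage points from
the proposed method.

## Synthetic studies

The generator emulates the DEAP geometry (32 channels, 128 Hz, 63 s with
a 3-s baseline) with one sinusoidal oscillator per band per channel
(frequency uniform within the band, random phase) plus white noise.
Default relative band powers encode the alpha-suppression /
beta-gamma-enhancement stress signature: calm = {theta 1.0, alpha 2.0,
beta_low 0.4, beta_high 0.5, gamma 0.3}, stress = {0.8, 0.6, 0.9, 1.5,
0.8} (mean-squared amplitude units; oscillator amplitude = sqrt(2·power)).
Two lognormal variability terms emulate real recordings: per-oscillator
amplitude jitter (log-sd 0.2, inter-trial band-power fluctuation) and a
per-trial-per-channel gain (log-sd 0.6) applied to the whole signal,
modelling electrode-impedance and anatomical gain differences. The gain
term injects dominant but class-irrelevant variance — the structure under
which a 2-component PCA discards discriminative information while
all-relevant selection does not — and keeps accuracies in the 75–95%
range typical of calm/stress protocols instead of at saturation. Ratings
are drawn uniformly inside the open annotation regions (calm: valence
U(4.1, 5.9), arousal U(1.0, 3.9); stress: valence U(1.0, 2.9), arousal
U(5.1, 9.0)), so labelling round-trips exactly. The stress count per
participant is `round(balance·n_trials)` clamped to keep both classes.

What the generator does **not** emulate: 1/f background spectra, ERPs,
artifacts, volume conduction, non-stationarity, or inter-channel
correlation structure. Passing end-to-end tests therefore demonstrates
that the pipeline recovers band-structured class differences under
multiplicative amplitude nuisance — not that it reaches any particular
accuracy on real EEG.

## Problem sizes in tests and the acceptance script

End-to-end runs use 2 participants × 10 trials (640 feature rows) with
full-length 63-s trials; Boruta benchmarks use n = 400 rows with 5
informative columns (effect size d = 2) among 14 noise columns; unit
tests use shortened trials (8 s, 2–4 channels). These sizes were chosen
so the full suite exercises every stage at statistically meaningful n
while remaining comfortably fast.

## Known limitations

- The printed formulas for F6–F9 in the source feature table are
  typographically corrupt; the canonical definitions adopted here are a
  judgement call, isolated one-per-expression.
- Per-(trial, channel) sampling means train/test rows can come from the
  same trial; accuracies are protocol-internal (see Sampling unit).
- Headline accuracies on the real restricted corpus are not reproducible
  here; the bundled reference table supports only the ANOVA and
  decrement arithmetic.
- The Boruta binomial test is uncorrected across the 19 features, as in
  the original formulation at this iteration count.
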