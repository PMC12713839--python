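# Methods

This note documents the models, parameter choices and numerical conventions
behind `somnoscope`, and what the synthetic-data validation does and does
not establish.

## Data model and conventions

Vigilance states are coded W=0, N=1, R=2 throughout; all timing is
zeitgeber time (ZT, hours since lights-on) with half-open bins [a, b), so
ZT 12.0 belongs to the dark phase. Recordings are required to start on a
whole ZT hour so that epoch and bin grids align; epochs are 10 s by
default and never straddle hour boundaries. EDF headers carry no ZT or
light-schedule fields, so each EDF written by the package gets a JSON
sidecar with start ZT, schedule, channel roles and acquisition metadata.
The analog filter bands typical of such recordings (EEG 0.5–250 Hz) exceed
the digital Nyquist limit at 128 Hz; they are retained as metadata only
and never re-applied digitally.

## Spectral scheme

Each 10-s epoch spectrum is the mean of five consecutive, non-overlapping
2-s FFT windows (256 points at 128 Hz → 0.5 Hz bins). Windows are
mean-removed and Hann-tapered with power normalisation: per-bin powers sum
to Σw²x²/Σw², the taper-weighted mean square of the window, so
Parseval-style conservation holds to machine precision per window. Band
powers sum bins with lo ≤ f < hi; a band upper edge may extend one bin
past Nyquist so the full grid can be covered. Delta is 0.5–4 Hz (the SWA
definition); theta is fixed at 6–9 Hz, the usual rodent convention. For
between-group spectrum comparisons, per-epoch spectra are normalised to
total 0.5–30 Hz power (relative power); absolute µV² values are retained
internally. An optional 2nd-order 49–51 Hz band-stop provides parity with
mains-notched acquisitions; synthetic data does not need it and the
default is off.

Theta regularity is the power of the theta peak bin ±0.5 Hz divided by
total theta-band power: 1 for a pure rhythm, ≈0.5 for a flat spectrum
(3 of 6 half-Hz bins), 0 when the band is empty.

Sample entropy uses the standard definition (embedding m=2, Chebyshev
tolerance r = 0.2·SD, self-matches excluded) and returns an infinity
sentinel when no template pair survives at m+1. DFA integrates the
mean-removed series, linearly detrends non-overlapping windows at 8
log-spaced scales from 16 to 512 samples (suited to the 25-s, 3200-sample
staging window), and reports the log–log slope; white noise calibrates to
α ≈ 0.5 and integrated noise to α ≈ 1.5.

## Rule-based staging

The scorer mimics expert labelling: the dominant state of each 25-s window
is decided in a fixed cue order — wake if EMG tone exceeds the subject's
adaptive threshold (0.60 quantile of that subject's own EMG-tone
distribution); else NREM if the delta ratio δ/(δ+θ) ≥ 0.55; else REM if
theta regularity ≥ 0.5; else NREM. EMG is the most reliable single cue,
hence its priority; the NREM fallback reflects that ambiguous low-EMG,
low-theta windows are overwhelmingly NREM in rodents. Windows are centred
([t−12, t+13) s, clipped at record edges — the alignment is a convention,
made explicit and configurable) and slide in 1-s steps; per-second labels
aggregate to 10-s epochs by modal label with ties broken W > N > R.
Spectral window features are computed once as 1-s-hopped 2-s periodograms
and averaged over each 25-s window via prefix sums, so staging a full day
takes seconds. Manual-correction workflows are supported as an override
table (epoch index → label) applied after automated scoring.

A quantile-based wake threshold is rank-based: its error rate is governed
by how far the subject's true wake fraction sits from 1 − quantile. At the
preset's realistic wake fraction (≈0.48/24 h) the mislabelled seconds
concentrate at episode boundaries, where the 25-s window straddles a
transition; epoch-level majority voting absorbs most of them. On preset
synthetic days the scorer reaches ≈93–95% epoch accuracy with every
state's recall above 85%.

## Sleep architecture

Episodes are maximal runs with no minimum-bout smoothing (minimum episode
= 1 epoch). Conventions chosen for conservation and unambiguity: episodes
belong to the ZT bin of their onset; transitions to the bin of the
post-transition epoch; any light/dark assignment uses the event's onset
ZT. Multi-day recordings fold onto the 24-h ZT grid with time-scaling
quantities (minutes, counts) reported per day. Only five transition types
are analysed; direct W→R transitions are structurally excluded (and
impossible in the generator) but counted as a QC field if present in real
data. Conditional transition probabilities divide each count by the total
transitions leaving the pre-state.

REM latency is the time from NREM onset (a wake→NREM transition) to the
next REM onset. Wake of any length resets the clock by default — the
strictest reading of "NREM sleep onset" — via a configurable
`wake_reset_min_epochs` (default 1); REM→NREM→REM continuations without
intervening wake keep the original onset. Histograms use 50-s bins from 0
to 600 s plus an open overflow bin; REM at the recording start with no
preceding NREM onset is excluded and counted in QC, so histogram counts
plus QC equal the number of REM episodes exactly.

SWA time courses average 0.5–4 Hz power over NREM epochs per 6-h bin and
are normalised per subject to the 24-h NREM mean (=100%), which removes
between-subject amplitude differences (electrode impedance, gain) before
group comparison; bins with no NREM epochs are reported missing.

## Chi-square periodogram

For candidate period P with K = round(P/bin) columns and N complete
cycles, Qp = N·Σ_h(M_h − M̄)²/s² with s² = Σ(x − M̄)²/(KN) over the KN
bins used (trailing incomplete cycles dropped). Under an i.i.d. null each
column mean has variance s²/N, making Qp approximately χ²(K−1); the
significance line is the χ² quantile at 1−α per candidate. Candidates
step by one data bin over 20–28 h. Because the analysis package the field
uses does not document whether it reports the raw peak Qp or its excess
over the significance line, both are emitted. Note that the *maximum* Qp
over a candidate grid exceeds the pointwise threshold more often than α
even under the null (multiple comparisons across correlated candidates);
the package's calibration claim is pointwise. Activity onset detection
(first bin of the longest supra-threshold run after ≥4 h of quiescence,
threshold 20% of the daily maximum) is a QC aid only.

## Group statistics

Two-way ANOVAs are fixed-effects with interaction, Type III sums of
squares via effect coding, so unbalanced group sizes (e.g. 12 vs 11) are
handled exactly. Time-course designs are analysed as fixed-effects ANOVA
on subject×bin values rather than repeated measures; this choice is
stamped into result metadata, since validation here rests on synthetic
recovery rather than replicating any specific dataset's p-values. Sidak
adjustment is p_adj = 1 − (1−p)^m with the family size m matching the
number of bins compared (24 for 1-h profiles, 4 for 6-h bins); Fisher's
LSD uses the pooled MSE and error df of the fitted ANOVA with unadjusted
p-values. Brown-Forsythe is the Levene test on absolute deviations from
group medians. The unpaired t-test is pooled-variance by default (with
Cohen's d from the pooled SD) and offers a flagged Welch fallback for use
when Brown-Forsythe rejects. Degenerate inputs follow fixed conventions:
zero-variance equal groups give t=0, p=1; a constant response gives all
ANOVA F=0; Shapiro-Wilk is skipped with a flag below n=3.

## Synthetic-data generator

**Hypnograms.** A first-order Markov chain stepped per 10-s epoch with
separate light- and dark-phase matrices, plus an optional third matrix for
a mid-dark napping window (ZT19–21), on in the wild-type preset. First
order is the simplest structure the transition-matrix analysis can
recover, and it induces approximately geometric REM latencies — adequate
for recovery tests, though real latency distributions have more structure.
The preset matrices were chosen to give realistic murine architecture
(≈48% wake per 24 h, light-phase REM near 60 min/12 h in WT, mean NREM
bouts of 1.5–2.5 min) and to inject the mutant phenotype through the
NREM→REM rates: lower in the light phase, higher in the dark phase than
wild type, which propagates to more dark-phase REM minutes, more dark REM
bouts, and fewer short-latency light-phase REM entries.

**Signals.** Per state, narrow-band oscillations (NREM: ~2 Hz delta at
45–50 µV; REM: ~7 Hz theta at 35 µV; wake: weak broad theta) ride on 1/f
background noise (state-scaled, unit exponent); EMG is white noise at
state RMS 25/6/2.5 µV for W/N/R. Carrier frequency and phase are drawn
per episode and held continuous within it, reset at episode boundaries —
avoiding within-episode spectral leakage while keeping episodes
independent. An optional light-phase gain on NREM delta emulates
time-of-day SWA gradients. No spindles, K-complexes or artifacts are
modelled: passing staging tests shows the rule set recovers states whose
cues match its features, not robustness to real-world artifacts or
atypical EEG.

**Activity.** Counts per 1-min bin are negative-binomial (gamma-Poisson,
dispersion k=5) around a waveform allocating ~90% of activity to the
(subjective) dark phase with a boosted first-3-h peak. LD days repeat at
exactly 24 h; DD days advance at the model period (presets: 23.75 h WT,
23.68 h MUT — a small period difference with reduced, flatter activity in
the mutant). Entrainment dynamics (transients after the LD→DD switch) are
not modelled.

**Determinism.** Every generator consumes a `numpy` Generator seeded
explicitly; per-subject seeds derive from a master seed by stable hashing
of the subject id, so identical (config, seed) runs are bit-identical and
cohorts can grow without reshuffling.

## Validation scales and limitations

The test suite and acceptance script use problem sizes chosen as the
smallest that make each claim statistically meaningful: one simulated day
for staging accuracy and oracle equivalence (8,640 epochs), 30-day
hypnograms × 3 seeds for kinetics recovery (the family of binomial checks
is assessed at a family-wise 95% level, Sidak-corrected), 10 DD days at
6-min bins for period recovery, 20 replicates for DFA calibration, 12
subjects per genotype × 2 days for effect-direction recovery, and 200
null replicates for type-I calibration.

Known limitations: the stager is tuned to the three-state rodent problem
and a fixed cue ordering — it does not output probabilities or handle
artifacts; REM-latency generation is geometric by construction; the
periodogram assumes stationary period and waveform across the folded
days; and the fixed-effects ANOVA understates within-subject correlation
in time-course designs relative to a repeated-measures model.
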