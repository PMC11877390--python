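# Methods

## Physical model

A defocused imaging system viewing a laser-illuminated rough surface turns
surface tilt into a rigid lateral translation of the observed speckle
pattern. We model the recording chain in two stages.

**Master speckle field.** A fully developed speckle intensity pattern is
synthesized as the squared modulus of the inverse FFT of a random-phase
screen supported on a centred circular frequency-domain aperture of diameter
`size/grain_px`. This yields the canonical negative-exponential intensity
statistics (contrast ≈ 1; the test suite asserts coefficient of variation
> 0.3) and a controllable mean grain size. The field is scaled so its mean
sits at one quarter of full scale; the exponential tail then clips at the
top grey level for roughly 2% of pixels, as a real camera would saturate.

**Frame rendering.** Each frame is a crop of the master field displaced by
the cumulative ground-truth shift. The integer part of the shift is applied
by array indexing — so integer-shift ground truth survives rendering *bit
exactly*, enabling an exact recovery test — and the fractional part by
bilinear interpolation. Additive Gaussian sensor noise and quantization to
`bit_depth` bits (default 8, the common machine-vision class) follow. The
master margin (default 16 px around a 64 px frame) bounds the admissible
trajectory; exceeding it raises an error naming the offending frame.

## Cardiac displacement model

The displacement waveform is a pulse train: one raised-cosine (Hann) lobe
of width `pulse_width_s` per heartbeat, with inter-beat intervals drawn from
Normal(1/`heart_rate_hz`, `hrv_sd_s`) truncated positive (first beat at half
an interval). A sub-0.5 Hz sinusoidal drift with random phase models motion
artifacts, and white displacement noise models residual jitter. The scalar
waveform drives a fixed unit direction (1, 0.4)/|·| so both image axes carry
correlated signal, as both axes do in practice.

The default lobe width is 0.5 s. A Hann lobe of width W has its spectral
energy concentrated below ≈ 2/W; at W = 0.25 s the pulse train's third and
higher harmonics (≥ 3.3 Hz at 1.1 Hz rate) would carry >20% of the non-DC
power, leaking outside the 0.5–3 Hz physiological band. At W = 0.5 s the
first two harmonics dominate and >95% of non-DC power stays in band, while
individual beats remain resolved for rates up to ~1.5 Hz.

### Alcohol-state parameterization

The five measurement labels map to cardiac parameters with baseline
`heart_rate_hz = 1.1`, `pulse_amplitude_px = 2.0`, `hrv_sd_s = 0.05`;
post-consumption states scale amplitude by {1.5, 1.4, 1.25, 1.15} and rate
by {1.25, 1.2, 1.12, 1.06} at 0/30/60/90 min — a monotone return toward
baseline mirroring a blood alcohol level that falls roughly linearly over
the session. These are stated modelling assumptions, not measured effects;
the true quantitative imprint of alcohol on a speckle-derived waveform is
not specified anywhere, so the simulator's job is to provide a *plausible,
controllable* class structure, not a physiological digital twin.

Each simulated subject applies a small deterministic multiplier
(0.95–1.05) to all of their heart rates. Without it, all subjects would be
statistically identical and holding one out would be no harder than a random
split; with it, the held-out subject genuinely differs from the training
subjects, and the between-state rate differences (6–25%) partially overlap
the between-subject differences — which is what makes the hardest label
boundaries (e.g. "0 min" vs "30 min") hard, as they should be.

### What the simulator does not emulate

Speckle decorrelation (the real pattern slowly boils as skin deforms),
non-rigid motion, illumination fluctuations, physiological waveform shape
changes beyond rate/amplitude/HRV, breathing, and any pharmacokinetic
realism beyond the monotone schedule. Passing tests therefore demonstrate
that the *pipeline* recovers and classifies the signal it is pointed at;
they say nothing about detection performance on real skin recordings.

## Displacement tracking

Consecutive frame pairs are correlated — not each frame against a fixed
reference — because slow decorrelation in real data would degrade a fixed
reference; cumulative position is reconstructed by summation. The
correlation is circular (frequency-domain) on zero-mean frames, valid here
because true shifts (a few px) are far below the frame size; the argmax is
mapped to a signed shift in (−N/2, N/2], ties broken at the smallest
row-major index. Sub-pixel refinement fits a parabola through the three
samples around the peak per axis, clamped to ±0.5 px; refinement is skipped
when the three points are not concave. Per-pair sub-pixel errors are
oscillatory in the fractional part of the true shift and largely cancel
over a zero-mean cardiac trajectory, which is why the summed trajectory
stays within 0.25 px RMSE over 3000 frames at 2 grey levels of noise.

An optional Hann window is available for edge-dominated scenes; it is off
by default since the synthetic scenes are statistically homogeneous.

## Chunking and splitting

Windows of 256 frames with stride 32 (86 windows per 3000-frame recording)
give the classifier ~0.5 s of waveform per element. Channels 1–2 are the
cumulative position re-zeroed to the window start (removing inter-window
offsets); channels 3–4 are their first differences, which coincide with the
per-pair shifts. The difference channels have 255 natural samples; the
first value is repeated once to keep a rectangular 4×256 array.

Splitting is by subject. Overlapping windows make chunk-wise random splits
leak near-duplicates across the boundary; `split_random` exists for
comparison studies and warns when used.

## Features and selection

The registry holds 18 descriptors per channel: mean, median, standard
deviation, skewness, kurtosis, minimum, maximum, range, quantiles
{0.1, 0.25, 0.75, 0.9} (linear interpolation between order statistics, for
bit-reproducibility), RMS, mean absolute change, lag-1 autocorrelation,
energy, dominant periodogram frequency and the fraction of non-DC power in
0.5–3 Hz. Variance is deliberately absent: it is a deterministic function
of the standard deviation and would add a perfectly collinear column.
Degenerate values (e.g. skewness of a constant channel) are imputed to 0
with a logged warning so the table never contains missing values.

Selection is univariate and rank-based — Mann–Whitney U for binary targets,
Kruskal–Wallis for three or more classes — robust to the heavy-tailed
distributions displacement features produce. The default rule keeps raw
p ≤ 0.05; Benjamini–Hochberg FDR adjustment is available
(`correction="fdr"`) and is never more permissive. Selection is computed on
training rows only and recomputed per label scheme (the labels under test
change with the merging); applying a `SelectionResult` to validation data
only subsets columns.

## Classification and tuning

XGBoost (`hist` tree method, logistic objective for binary schemes, softmax
otherwise) with a seeded random search of 50 trials by default over
`n_trees ∈ [50, 500]`, `max_depth ∈ [2, 8]`, `learning_rate ∈ [0.01, 0.3]`
(log-uniform). The objective is accuracy on the single held-out subject —
the study's own validation design — not cross-validation; ties break toward
fewer trees, then shallower depth, so the smallest equally-good model wins
deterministically. The winner is refit on the full training table.

## Evaluation

Binary metrics follow the standard contingency definitions above, with
explicit `None` for zero-denominator cases. Percentages are rounded
half-up to integers for reporting; full-precision values stay in the JSON.
ROC curves sweep thresholds over the unique scores with trapezoidal AUC;
multiclass schemes are evaluated one-vs-rest per class with an unweighted
macro average. Row-normalized confusion percentages are per-class recall;
reports keep that distinction explicit.

## Reproducibility

One master seed fans out through `stage_seed(master, stage_name, index)`
(a SeedSequence over the master seed, a CRC32 of the stage name, and an
index), so stages are independently reproducible and never share streams.
Identical configuration + seed reproduces every artifact bit-identically;
the run configuration is hashed into each report's provenance block.

## Problem sizes

The end-to-end synthetic study used by the test suite and the acceptance
script runs 5 subjects × 5 states × 2 recordings per state (50 rendered
3000-frame videos, 4300 chunks) with 20 search trials per scheme — a size
chosen so the whole study executes in minutes on a single core while
keeping ≥ 500 validation chunks per scheme. The full 5-recordings default
(125 videos) is the simulator's study-design default and runs the same way,
just longer.

## Known limitations

- The simulator's class structure is an assumption; absolute accuracies on
  synthetic data do not transfer to human recordings.
- Sub-pixel refinement is a 3-point parabolic fit; at very low SNR a 2D
  Gaussian peak fit would be more accurate.
- The random search is not adaptive; with large budgets a Bayesian
  optimizer would find equally good parameters in fewer trials.
- Recording-level aggregation (majority vote over a recording's chunks) is
  not implemented as a primary metric; chunk-level accuracy is reported.
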