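# Methods

## Analysis model

`osaconnect` treats a cohort of 4-channel sleep-EEG recordings as draws
from two populations (OSA-like and healthy-like) that differ in the
band-wise statistical coupling between scalp derivations. The fitted
quantity per subject and band is the channel × channel Pearson correlation
of absolute wavelet-packet coefficients; group structure is then summarized
by positive-correlation extremes, positive-edge graphs with node degrees,
rank tests on per-subject summaries, and Welch t-maps of degree.

The chain, per subject:

1. **Notch, band-pass.** A second-order IIR notch at 50 Hz with quality
   factor Q = 30, then a 4th-order Butterworth band-pass 0.5–35 Hz. Both
   are applied forward–backward (`filtfilt` with its default odd-reflection
   padding of 3× the filter length), so the pass band is traversed twice
   (magnitudes below quote the squared response) and the net phase is zero
   — important because connectivity is an instantaneous correlation and any
   differential lag would depress it. A causal mode (`zero_phase=False`)
   exists for streaming-like use.
2. **Epoching.** Non-overlapping 30 s epochs, the standard polysomnography
   scoring window; trailing samples are discarded. Correlations are
   computed per epoch and averaged over epochs (plain mean by default;
   Fisher-z averaging is a config switch). Epoch-wise estimation makes the
   estimator robust to slow nonstationarity across the night and gives a
   natural unit for excluding degenerate (constant) stretches.
3. **Wavelet packet decomposition.** Full binary filter-bank tree of depth
   5 with the Daubechies-4 (8-tap) filter pair, periodization boundary
   mode. Periodization keeps the total coefficient count equal to the
   sample count and preserves energy (Parseval) up to the orthogonality of
   the filter bank; symmetric/zero padding are available via
   `WaveletSpec(boundary_mode=...)`. Reconstruction seeds the inverse tree
   with a zero signal of the original length so per-level padding is
   reproduced exactly; inversion is then accurate to machine precision for
   arbitrary (non-dyadic) lengths.
4. **Frequency ordering and band mapping.** Leaves indexed by filter path
   are not in spectral order: each decimated high-pass stage mirrors its
   branch's spectrum. The ascending-frequency permutation is the
   binary-reflected Gray code `k ^ (k >> 1)`, validated in the tests
   against a swept-sine oracle (for a sine at each leaf's center frequency,
   the predicted leaf must capture maximal energy) at every level 1–5.
   Each leaf (width fs/64 = 3.125 Hz at 200 Hz) is assigned to the band
   containing its center frequency: δ → leaf 0, θ → 1–2, α → 3,
   β → 4–9, γ → 10. Band edges are the conventional clinical
   definitions (δ 0.5–4, θ 4–8, α 8–13, β 13–30 Hz) with γ capped at the
   35 Hz band-pass corner.
5. **Connectivity.** For each band and epoch, the product-moment
   correlation between channels' absolute coefficient vectors
   (concatenated over the band's leaves in frequency order); constant
   vectors raise rather than silently yielding 0, and an epoch containing
   one is excluded with a warning. Per-subject matrices are the mean over
   epochs.
6. **Graphs and group statistics.** Edges are strictly positive
   correlations (threshold configurable); degree is the incident-edge
   count. Group summaries take min/max over all positive off-diagonals
   across a group's subjects. Group tests are two-sided
   Mann–Whitney–Wilcoxon on per-subject scalars — either the mean positive
   correlation (`mean_pos_r`) or the mean absolute coefficient
   (`mean_abs_coeff`) per band; both are computed and reported. Degree
   contrasts use Welch's t per node, kept deliberately separate from the
   nonparametric band tests. Raw p-values are reported without multiplicity
   correction (a Benjamini–Hochberg helper exists but is off by default);
   with four bands and four nodes this is a real caveat for interpretation.

## Mann–Whitney implementation

U is computed from midranks. For tie-free samples with n₁·n₂ ≤ 400 the
exact two-sided p doubles the lower tail of the enumerated null
distribution of U (counting recurrence f(a,b,u) = f(a−1,b,u−b) + f(a,b−1,u);
counts stay below 2⁵³ so float64 arithmetic is exact). Otherwise the
normal approximation with tie-corrected variance
n₁n₂/12 · [(n+1) − Σ(t³−t)/(n(n−1))] and a 0.5 continuity correction is
used. The suite cross-checks both paths against brute-force enumeration
and against an independent library implementation, and verifies the 5%
type-I error rate of the asymptotic path by simulation.

## Spectral leakage of db4 at level 5

Daubechies-4 filters are short and far from brick-wall. Any conjugate
quadrature pair satisfies |H(ω)|² + |G(ω)|² = 2 with |H|² = 1 at DC and
|H(π/2)|² = 1/2, so a tone near a dyadic split frequency sends almost half
its energy down the mirror branch at that stage. Measured consequence at
fs = 200, level 5: a sine at a leaf's center concentrates between 55% and
99% of its coefficient energy in that leaf (only the outermost leaves
exceed 90%), and single-leaf bands are porous — a 10 Hz sine leaves ~65%
of its energy in the α leaf, the rest mostly in the adjacent θ and β
leaves. Multi-leaf bands (θ, β) retain ≥ 99% for tones at their centers.
Two practical corollaries, visible in the worked example: the α band at
this decomposition depth is a single 3.125 Hz leaf and its estimates are
coarse; and a δ-band group contrast partially surfaces in θ because the
3.125–6.25 Hz leaf straddles the 4 Hz edge. These are properties of the
chosen wavelet and depth, documented rather than patched; a deeper tree or
longer wavelet would sharpen bands at the cost of temporal resolution.

## Synthetic cohort generator

Each subject is built per band as x = L·n, where n are four independent
unit-variance band-limited noises (white noise through a zero-phase
4th-order Butterworth band-pass, restandardized) and L is the Cholesky
factor of the target 4×4 correlation matrix; band components are summed
with relative amplitudes δ 1.0, θ 0.6, α 0.5, β 0.4, γ 0.2 (slow-wave
dominant, as in sleep EEG), plus an independent 1/f floor per channel
contributing 20% of total variance, scaled to 20 µV overall. Per-subject
random streams derive from `SeedSequence([seed, group, index])`, so cohorts
are reproducible and extensible without regeneration.

The default contrast (`paper_contrast_spec`) draws each case-like
subject's delta equicorrelation uniformly from [0.75, 0.90] and each
control-like subject's from [0.45, 0.65]; θ/α/β/γ couplings (0.45, 0.40,
0.35, 0.30) are identical across groups. Only the delta coupling differs
between groups; per-channel band power does not. The group tests in the
acceptance checks and the acceptance script therefore use the
`mean_pos_r` feature, which measures the contrasted quantity; the
`mean_abs_coeff` feature answers a different question (band power) and has
no power against a pure coupling contrast by construction.

Coupling is induced on band *signals*. Because every preprocessing and
band-extraction step is the same linear operator applied to each channel,
the correlation of reconstructed band signals recovers the generating
coupling essentially exactly (the parameter-recovery check demands ±0.05
at 300 s). The correlation of *absolute* coefficients is a different,
attenuated functional — for jointly Gaussian coefficients with correlation
ρ, corr(|X|,|Y|) ≈ 0.64 at ρ = 0.83 — so only strict monotonicity in the
ground truth is required of it. The generator emulates stationary
band-specific coupling only: no sleep-stage dynamics, apnea event
morphology, artifacts, or non-Gaussianity. Passing tests demonstrate that
the pipeline measures what it claims on signals with known structure, not
that clinical recordings behave like the generator.

## Problem sizes and numerical choices

- Reconstruction and additivity tolerances: 1e-8 relative (machine
  precision leaves ample margin).
- Group-contrast replication uses 50 cohorts of 10+10 subjects at 120 s
  each; at the preset effect size the per-subject δ estimates separate
  almost completely, so 120 s already gives near-complete power while
  keeping the whole check around a minute. Parameter recovery uses the
  300 s, 200 Hz single-subject setting its tolerance was stated for.
- The acceptance script's cohort (10+10 × 120 s) mirrors the replication
  setting; all of its randomness derives from `--seed`.
- EDF fixtures are written by a minimal internal 16-bit writer (1 s
  records, per-channel physical scaling from the data range) and read back
  through an independent reader; round-trip tolerance is the per-channel
  quantization step (range/65535).
- Degenerate inputs raise explicit errors: constant vectors in Pearson,
  empty bands (e.g. γ after a lower band-pass corner), recordings shorter
  than one epoch, non-PSD coupling targets (reporting the smallest
  eigenvalue), mixed per-channel EDF sampling rates.

## Known limitations

- Four channels give 4-node graphs; degree ∈ {0..3} is a very coarse
  statistic, and Welch t on it is reported for completeness, not as a
  recommended inference.
- α and γ each map to a single 3.125 Hz leaf at level 5 (see leakage
  section).
- Min/max positive correlation across subjects is an extreme-value summary
  and rises with cohort size; compare groups of equal size.
- No artifact rejection; recordings are assumed already referenced
  (F4-A1 etc. as delivered).
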