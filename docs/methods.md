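# Methods

## Problem and model

Wheezes are pitched, sustained adventitious lung sounds (fundamental roughly
100–1000 Hz, duration > 100 ms) superimposed on the broadband noise of normal
respiration (energy concentrated in 60–1000 Hz).  Given a single-channel
auscultation recording, the package separates the wheeze component w[n] from
the respiratory component r[n].

The mixture's magnitude spectrogram is divided into respiratory stages
(inspirations/expirations), each labeled wheezing (1) or non-wheezing (0) by
an external detector or a human annotator.  Every segment X(l) (F×T(l)) is
modeled as

    X(l) ≈ U_R diag(D_xR(l)) V_R(l)  +  U_W(l) diag(D_xW(l)) V_W(l)

with a single respiratory dictionary U_R (F×K_R) shared across all L
segments and per-segment wheeze dictionaries U_W(l) (F×K_W).  Optionally a
respiratory-only training spectrogram Y is co-factorized with the same U_R:
Y ≈ U_R diag(D_yR) H_R.  All factors are non-negative.

The objective is a weighted sum of generalized Kullback–Leibler data terms
plus squared-Frobenius penalties on the dictionaries:

    Γ = Σ_l λ_{C(l)} KL(X(l) | X̂(l)) + L·‖U_R‖²_F + Σ_l ‖U_W(l)‖²_F
        + α·KL(Y | Ŷ) + ‖U_R‖²_F

The informed inter-segment weighting is the core idea: non-wheezing segments
get weight λ_R0 and wheezing segments λ_R1 in the terms that shape U_R, with
λ_R0 > λ_R1 > λ_W, so the shared respiratory bases are learned predominantly
from wheeze-free evidence.  The wheeze data weight λ_W is common to all
segments (wheezes are never observed in isolation, so no segment is a
privileged wheeze exemplar).

Minimization uses multiplicative updates derived from the KL gradient split
(one sweep = shared basis, per-segment wheeze bases, all activations).  The
penalty gradient contributes (2L+2)·U_R to the shared-basis denominator —
the exact gradient of the (L+1)·‖U_R‖²_F total — and 2·U_W(l) to the wheeze
denominators.  After every sweep each basis column and activation row is
rescaled to unit L2 norm with the removed norms folded into the gain vectors
D, which leaves every reconstruction unchanged.  Zero columns/rows are left
at zero with gain 0 (they are multiplicative fixed points).

Separation finishes with per-segment Wiener soft masks built from the squared
magnitude reconstructions, applied to the mixture's complex STFT (mixture
phase reused for both sources), concatenation over segments, and weighted
overlap-add synthesis.  The two complex estimates sum to the mixture
spectrogram exactly, so the reconstruction is conservative by construction.

## Objective descent and the renormalization caveat

Each update sweep is a descent step: on random small instances (F ≤ 16,
T ≤ 32, L ≤ 3, 100 seeds, 50 sweeps each) the objective evaluated before vs
after a sweep never increases (tolerance 1e-8; measured increases are all
negative).  The per-sweep L2 renormalization, however, preserves every
reconstruction and KL term but re-expresses the Frobenius penalties at their
unit-norm value, undoing the norm shrinkage the penalized updates produce.
The objective trace recorded *after* renormalization therefore oscillates
slightly instead of decreasing monotonically.  This is a property of the
norm-penalized multiplicative scheme with per-sweep rescaling, not an
implementation artifact; the descent property at fixed normalization state is
the meaningful monotonicity invariant and is what the acceptance suite
asserts.

## Parameters

| parameter | default | meaning |
|---|---|---|
| fs | 2048 Hz | sampling rate of the analysis front end |
| N | 256 | Hamming window length (samples) |
| hop | 64 | frame hop = N/4, 31.25 ms |
| DFT size | 512 | 2N-point DFT → 4 Hz bin spacing, F = 257 |
| K_W / K_R | 64 / 32 | wheeze / respiratory components |
| λ_R0, λ_R1, λ_W, α | 10, 0.1, 0.01, 1 | informed weighting |
| M | 50 | update sweeps |
| eps | 1e-12 | floor for divisions and logs |

The STFT uses left-aligned frames with no centering padding; the N-sample
window is zero-padded to the 2N-point DFT.  The stated hop resolves an
ambiguity between "25% overlap" and the printed 31.3 ms temporal resolution
in favour of the latter (hop = N/4).  Magnitude (not power) spectrograms are
normalized to unit mean (the divisor is retained and multiplied back before
Wiener masking).  The training spectrogram Y is normalized by its own
divisor.  Synthesis compensates by the summed squared window, so
analysis–synthesis round trips are exact to float precision wherever frames
overlap fully; with the default hop the first/last N samples are edge
regions.

Weight admissibility (λ_R0 ≥ λ_R1 ≥ λ_W) is advisory: violations warn rather
than error, because the equal-weight configurations are themselves meaningful
(they recover conventional unweighted NMPCF).

## Baseline family

All NMPCF variants are configurations of the same core: ST = equal λ with
training; T = equal λ without training; 1S = single segment with training;
IIS0 = informed weights, α = 0.  The supervised 2S variant extends ST with a
wheeze-training branch: because the wheeze dictionary is per-segment, the
tonal template Z is co-factorized with each U_W(l) through its own
activations (Z ≈ U_W(l) diag(D_zW(l)) H_W(l), weight β, default α); its
update rules follow from the same KL gradient recipe.  Plain NMF, SNMF
(both dictionaries pre-trained and frozen) and SSNMF (respiratory dictionary
frozen) operate on the whole spectrogram without segments.  The wheeze
template z[n] concatenates Hamming-windowed N-sample sinusoids from 100 to
1000 Hz at the 4 Hz model spacing (226 pitches).

Per-method hyperparameters were calibrated once on a held-out batch of
generator seeds (mirroring tuning on material disjoint from the evaluation
data) and then frozen: T-NMPCF uses k_W=8, k_R=64 with unweighted data terms
(inter-segment separation needs scarce per-segment capacity — with K_W
comparable to the segment length the per-segment dictionary can absorb an
entire segment and the shared/specific split becomes unidentifiable); the
training-coupled variants (1S/ST/2S) operate at equal λ = 0.01 where the
training branch dominates; the NMF family uses the standard ranks.

## Synthetic data

The generator emulates the statistical structure of auscultation mixtures:

- **Wheezes**: harmonic tones (default 2 harmonics) with constant or gently
  chirped fundamental in 100–1000 Hz, duration 0.15 s up to most of a stage,
  raised-cosine fades.
- **Respiration**: band-limited Gaussian noise (60–1000 Hz) with a smooth
  1/f^t tilt, amplitude-modulated per stage.  Two realism features matter for
  the baseline comparisons: (i) *subject resonances* — 2–4 Gaussian spectral
  bumps (gain 0.5–2, width 30–120 Hz) shared by all stages of a recording
  but drawn fresh per recording, emulating the airway/chest transfer
  function; they limit how well respiratory material from other subjects can
  serve as training data.  (ii) *stage contrast* — alternating
  inspiration/expiration stages with a steeper tilt, reduced upper band edge
  and lower level on expirations, so no single clean stage fully
  characterizes a recording's noise.
- **Mixing**: the higher-power signal is fixed and the other scaled to the
  requested wheeze-to-respiratory SNR (ties fixed toward the wheeze); truth
  signals sum to the mixture exactly.
- **Benchmark suites**: 16 mixtures per SNR ∈ {+5, 0, −5} dB, 4–8 stages of
  2 s, 1–5 wheezes confined to a strict subset of stages (at least one stage
  always wheeze-free), exact per-stage labels.
- **Training signal**: concatenated wheeze-free stages drawn pairwise
  (inspiration + expiration) from distinct synthetic subjects; defaults
  128 s / 54 stages.  Benchmark runs use a scaled 24 s / 12 stages draw, and
  each mixture is separated with two random restarts whose scores are
  averaged (a scaled version of the four-restart protocol).

What the generator does *not* emulate: heart sounds and friction artifacts,
imperfect segment boundaries or labels, sensor/coupling variation, and the
full diversity of real wheeze morphologies.  Passing benchmarks on this data
demonstrates the mechanism of informed inter-segment weighting, not clinical
performance.

An honest consequence, visible in the shipped benchmark: with exact labels
and statistically complete within-recording evidence, the *marginal* value
of the respiratory training branch on top of informed weighting is about
zero (±1 dB).  The informed configurations dominate every unweighted or
blind baseline by a wide margin in median wheeze SDR at all three SNRs, and
the lower ladder (blind NMF worst, then pre-trained NMF flavours, then
conventional NMPCF) reproduces; but the fine ordering between the
training-augmented and training-free informed variants (and between 1S and T
at high SNR) is within noise and can invert — on real recordings the
training branch earns its keep against label errors and artifacts that the
generator does not model.

## Evaluation

SDR/SIR/SAR follow the standard error decomposition: the estimate is split
into the projection onto the true target source, the additional component
lying in the span of all true sources (interference), and the residual
(artifacts); the spatial term is identically zero for mono two-source
evaluation.  Projections use time-invariant gains — no allowed-distortion
filter — which realizes the printed energy-ratio definitions exactly and
keeps SDR ≤ min(SIR, SAR).  Infinite ratios (zero denominators) are capped
at +120 dB for aggregation, with the raw value retained.  Estimates and
truths are trimmed to their common length before scoring.

## Numerical choices

- eps = 1e-12 floors every elementwise divisor and the KL log argument;
  0·log 0 ≡ 0.
- Initialization: uniform(0,1) + eps for all factors, gains set by the first
  renormalization; the RNG seed is mandatory, so equal seeds give bitwise
  identical runs.  Replicate r of a case derives its seed as seed + offset·r.
- Update order within a sweep: shared basis, wheeze bases per segment,
  activations (V_R(l) then V_W(l) with refreshed reconstructions, then H_R),
  then renormalization — sequential coordinate updates, each evaluated at
  the current state.
- Convergence: fixed M = 50 sweeps; an optional early stop on relative
  objective change < tol is available but off by default.
- Degenerate inputs: all-zero spectrograms are rejected at normalization;
  zero-power signals are rejected at mixing; segments shorter than one
  window are rejected at analysis.

## Known limitations

- The fallback energy-valley segmenter and narrowband-dominance labeler are
  plumbing for unannotated input; their threshold is calibrated to tolerate
  subject resonances and misses weak wheezes.  The separation claims assume
  externally provided boundaries and labels.
- The factorization is non-convex; different seeds give different local
  minima (hence the replicate-averaging protocol).
- Absolute benchmark dB values are properties of the synthetic generator and
  are not comparable to results on clinical recordings.
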