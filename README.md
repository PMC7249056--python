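# wheezesep

Separation of wheezes from normal respiratory sounds in single-channel lung
auscultation recordings, by informed inter-segment non-negative matrix
partial co-factorization (IIS-NMPCF).

Wheezes — pitched, sustained adventitious sounds with fundamental around
100–1000 Hz — overlap the broadband breath noise (60–1000 Hz) produced in
every respiratory cycle, which degrades both listening and automatic
analysis.  This package is for researchers in biomedical acoustics who want
to isolate the wheeze component w[n] and the respiratory component r[n] from
a mono recording, given the recording's respiratory-stage boundaries and
per-stage wheeze/non-wheeze labels.

## Method

The mixture magnitude spectrogram is split into L labeled stage segments
X(1)…X(L).  Each segment is modeled as

    X(l) ≈ U_R diag(D_xR(l)) V_R(l) + U_W(l) diag(D_xW(l)) V_W(l)

with the respiratory dictionary U_R shared across all segments (breath noise
repeats every cycle) and per-segment wheeze dictionaries U_W(l); optionally a
respiratory-only training spectrogram Y is co-factorized with the same U_R
(Y ≈ U_R diag(D_yR) H_R).  The factors minimize

    Σ_l λ_{C(l)} KL(X(l)|X̂(l)) + L‖U_R‖²_F + Σ_l ‖U_W(l)‖²_F
      + α KL(Y|Ŷ) + ‖U_R‖²_F ,

by KL multiplicative updates with per-sweep L2 renormalization.  The key
idea is the informed weighting λ_R0 > λ_R1 > λ_W: segments labeled
non-wheezing (C(l)=0, weight λ_R0 = 10) dominate the learning of U_R because
they are guaranteed free of wheeze energy, while wheezing segments (λ_R1 =
0.1) and the wheeze data term (λ_W = 0.01) contribute weakly.  Equal weights
recover conventional NMPCF; the package ships that and the rest of the
baseline ladder (NMF, SNMF, SSNMF, 1S/2S/T/ST-NMPCF) as configurations of
the same core.  Sources are reconstructed with per-segment Wiener soft masks
on the mixture complex STFT (mixture phase reused) and overlap-add
synthesis; the two estimates sum to the mixture exactly.

Quality is measured with the standard BSS error decomposition: SDR, SIR and
SAR in dB per source.  A synthetic-data module generates labeled benchmark
mixtures (harmonic wheezes over stage-modulated, subject-colored breath
noise) at +5/0/−5 dB wheeze-to-respiratory SNR with exact ground truth.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
import wheezesep as ws

# one synthetic 0 dB mixture with ground truth and stage labels
case = ws.build_benchmark(n_cases=1, snr_db=0.0, seed=7)[0]
config = ws.StftConfig()          # fs 2048 Hz, N=256, hop 64, 512-pt DFT
n_frames = (len(case.mixture.samples) - config.window_length) // config.hop + 1
ann = ws.SegmentAnnotation.from_sample_boundaries(
    case.stage_edges, case.labels, config, n_frames)
y = ws.generate_training_y(total_duration=24.0, n_stages=12, seed=999)

res = ws.separate(case.mixture, ann=ann, y=y,
                  hp=ws.HyperParams(seed=0), w=ws.WeightScheme())
sw, sr, mean = ws.evaluate_pair(res, case.wheeze, case.respiratory)
print(f"labels {case.labels}")
print(f"wheeze      SDR {sw.sdr:5.2f}  SIR {sw.sir:5.2f}  SAR {sw.sar:5.2f} dB")
print(f"respiratory SDR {sr.sdr:5.2f}  SIR {sr.sir:5.2f}  SAR {sr.sar:5.2f} dB")
```

prints

```
labels [0, 0, 0, 0, 1]
wheeze      SDR  9.23  SIR 16.32  SAR 10.27 dB
respiratory SDR  9.07  SIR 26.85  SAR  9.15 dB
```

A wheeze SDR of 9.2 dB means the recovered wheeze waveform carries about 8×
more target energy than total distortion; SIR ≈ 16 dB says little
respiratory noise leaks into it.  Running the same mixture with the
equal-weight scheme (`ws.WeightScheme.equal(0.01, 1.0)`) drops the wheeze
SDR to 2.27 dB — the informed weighting is what buys the margin.

The same pipeline is scriptable from the shell:

```
wheezesep simulate --suite t1m --n 4 --seed 7 --out-dir data/
wheezesep separate --in data/case000/mixture.wav \
    --segments data/case000/segments.json --train y.wav --out-dir out/
wheezesep evaluate --est-dir out/ --truth-dir data/case000/ --out report.json
```

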