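# cidn — deep-learning noise reduction workbench for cochlear-implant research

Cochlear-implant (CI) listeners understand speech well in quiet but poorly in
noise, and conventional single-microphone noise reduction only helps against
stationary maskers — not against the multi-talker babble of real social
settings. Deep-learning enhancement closes that gap: a network learns a
time–frequency **soft mask** (gains in [0, 1]) that suppresses the masker and
keeps the target, or separates the mixture into foreground and background
sources outright. `cidn` implements that whole research pipeline end to end
at desk scale, so every stage — data, models, metrics, statistics — can be
run, tested, and audited on one CPU with no external corpora.

What's inside:

* **`synthgen`** — seeded parametric audio: speech-like targets (harmonic
  source, formant resonators, syllabic gating), speech-shaped stationary
  noise (CCITT-like spectrum), sparse environmental noise, N-talker babble
  from distinct synthetic talkers.
* **`mixer`** — SNR-exact mixture construction with an active-speech-level
  anchor (−29 dBFS), equal-SNR-representation training manifests, and the
  13-condition behavioral test plan (3 processings × 2 maskers × 2 SNRs + quiet).
* **`spectral`** — STFT/iSTFT (Hamming 512/256/512 at 16 kHz, exact
  weighted-overlap-add inverse), hard-typed [0, 1] masks, ideal ratio mask
  |S|/(|S|+|N|) as an oracle upper bound.
* **`rnn_enhancer`** — bidirectional-LSTM mask estimator on add-one-log
  magnitude features, logistic-bounded gains, spectral-MSE training with Adam.
* **`sepformer_lite`** — a dimension-reduced dual-path transformer separator:
  conv encoder, chunked intra/inter-chunk attention, two bounded mask heads
  (m1/m2), overlap-add, transposed-conv decoder.
* **`metrics`** — SI-SDR from its defining projection, STOI from the
  published third-octave/384 ms-segment correlation pipeline, and a PESQ
  adapter contract (score absent unless an external backend is registered).
* **`evalgrid`** — the masker × SNR × processing evaluation grid, paired
  Wilcoxon signed-rank tests (exact for n ≤ 25), Benjamini–Hochberg FDR over
  the 54 planned comparisons.
* **`behavioral`** — linear mixed models of percent-correct and quality
  scores (participant random intercept), Type-III Wald F tables, estimated
  marginal means (EMMs) with delta-method CIs, Tukey-adjusted pairwise
  contrasts, stepwise-AIC selection over demographics, and a seeded
  behavioral-score simulator.
* **`workbench`** — the end-to-end demo (`cidn demo`) tying it all together
  with a fully seeded run manifest.

Both trainable models run on a small numpy reverse-mode autodiff engine
written for this package (`cidn.autodiff`), so training is dependency-light
and bit-reproducible; gradients are verified against central differences.

## Worked example

Train the tiny recurrent enhancer on 64 synthetic speech-in-stationary-noise
mixtures and measure the held-out SI-SDR improvement against the
ideal-ratio-mask oracle:

```python
import numpy as np
from cidn import metrics, mixer, rnn_enhancer, spectral

train = mixer.make_mixture_batch(64, 5.0, "stationary", 1.0, seed=11)
val   = mixer.make_mixture_batch(8,  5.0, "stationary", 1.0, seed=12)
test  = mixer.make_mixture_batch(12, 5.0, "stationary", 1.0, seed=13)

cfg = rnn_enhancer.EnhancerConfig(recurrent_layers=1, recurrent_units=32,
                                  projection_units=32, epochs=5,
                                  learning_rate=3e-3, seed=0)
model = rnn_enhancer.train_enhancer(rnn_enhancer.init_enhancer(cfg), train, val)

def improvement(estimate, tr):
    return (metrics.si_sdr_db(tr.target, estimate)
            - metrics.si_sdr_db(tr.target, tr.mixture))

imps = [improvement(rnn_enhancer.enhance(model, tr.mixture), tr) for tr in test]
oracle = []
for tr in test:
    tf, nf, mf = map(spectral.stft, (tr.target, tr.noise, tr.mixture))
    irm = spectral.ideal_ratio_mask(tf, nf)
    oracle.append(improvement(spectral.istft(spectral.apply_mask(mf, irm)), tr))

print(f"val loss: {model.history[0]['val_loss']:.4f} -> "
      f"{model.history[-1]['val_loss']:.4f}")
print(f"mean SI-SDR improvement: {np.mean(imps):+.2f} dB")
print(f"IRM oracle bound:        {np.mean(oracle):+.2f} dB")
```

Output:

```
val loss: 0.0488 -> 0.0245
mean SI-SDR improvement: +3.93 dB
IRM oracle bound:        +11.17 dB
```

The validation loss halves in five epochs, the trained mask buys ~4 dB of
SI-SDR on held-out +5 dB mixtures, and the ideal-ratio-mask oracle shows
~11 dB of headroom — the expected picture for a one-layer model after ~300
gradient steps.

The same pipeline from the shell:

```bash
cidn demo --seed 7 --out run1/    # data -> both models -> metrics -> stats
cidn behavioral simulate --participants 13 --seed 11 --out scores.csv
cidn behavioral analyze --scores scores.csv --out results/
```

`cidn demo` writes six report files (training manifest, metric table,
Wilcoxon/FDR summary, EMM/contrast/ANOVA tables) plus a run manifest with
every stage seed and file hash; two runs with the same seed are identical.

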