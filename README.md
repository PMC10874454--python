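# sigfate

Single-cell signaling histories and the integral control of cell fate.

BMP4 drives human pluripotent stem cells (hPSCs) toward an amnion-like
fate, read out through nuclear translocation of SMAD4. `sigfate`
implements the complete computational pipeline for asking *which feature
of a cell's signaling history decides its fate*: division-aware
single-cell tracking, reduction of each nuclear:cytoplasmic (N:C) SMAD4
time series to interpretable sigmoid features, MAGIC-style
graph-diffusion denoising, fate calling from seven immunofluorescence
markers, Bayes-optimal threshold classification, micropattern-colony
fate maps, an RNA-seq screen for integrator genes, and a two-gene ODE
model in which SOX2 integrates BMP signaling. A synthetic-data module
generates every input with known ground truth, so the full analysis is
testable end to end.

It is written for quantitative developmental biologists analyzing
live-imaging signaling data linked to fixed-cell fate readouts, and for
modelers studying temporal integration of morphogen signals.

## The model

Each cell's signaling history is summarized by a descending sigmoid

```
s(t) = L + (H − L) / (1 + exp((t − d)/τ))
```

with initial plateau `H`, final plateau `L`, duration `d` (midpoint
time) and transition timescale `τ`, plus the baseline-subtracted time
integral `Σ = ∫ (s(t) − s₀) dt`. Fate is predicted by a single threshold
per feature — the Bayes-optimal rule when fate is monotone in the
feature — and the central empirical property is *integral control*:
differentiation curves measured at different signaling levels or
durations collapse onto one threshold on the `Σ` axis, so level and
duration are interchangeable.

Mechanistically, the package implements the SOX2/ISL1 integrator model

```
dS/dt = α · max(0, 1 − βB(t)) · f_auto(S) · f_repI(I) − γ_S S
dI/dt = α_I · f_repS(S) − γ_I I
```

where `B(t)` is the idealized SMAD4 input, `f_auto` is positive SOX2
autoregulation, and the Hill terms `f_repI`, `f_repS` encode mutual
SOX2/ISL1 repression. With slow turnover, the SOX2 deficit equals
`α·β` times the exponentially weighted signaling integral
`∫ B(t′) e^{−γ_S(t−t′)} dt′`, which tends to the plain integral as
`γ_S → 0`. The decay rate `γ_S` is constrained independently by a FRAP
recovery fit `A₀ + A(1 − e^{−λt})`, half-life `ln 2 / λ`.

## Worked example

```python
from sigfate import synthgen, histfeat, fatecall, fatepredict

params = synthgen.HistoryGenParams(n_cells=500, seed=11)   # 42 h, 10-min frames
histories, truth = synthgen.gen_histories(params)
markers = synthgen.gen_fates(truth, synthgen.FateGenParams(seed=12))

feats = histfeat.feature_table(histories, baseline=params.baseline)
labels = fatecall.fate_score(markers)["fate_label"]        # log(ISL1/NANOG) > 0
clf = fatepredict.bayes_threshold(feats["integral"], labels, feature="integral")
cv = fatepredict.history_classifier(histories, labels, model="linear_sigmoid", seed=0)
print(f"integral threshold {clf.threshold:.1f} ratio·h, "
      f"Bayes accuracy {100*clf.accuracy:.1f}%")
print(f"full-history CV accuracy {100*cv['cv_accuracy']:.1f}%")
```

prints

```
integral threshold 26.3 ratio·h, Bayes accuracy 86.0%
full-history CV accuracy 85.0%
```

The fitted threshold sits at the generator's planted integral threshold
(26 ratio·h), and a classifier trained on the complete 253-point history
does not beat the one-number integral — the history carries no fate
information beyond `Σ`.

The same pipeline runs from the shell:

```bash
sigfate run-all --seed 0 --outdir demo_run   # all stages + manifest
sigfate simulate --n-cells 500 --out h.csv
sigfate features --histories h.csv --out features.csv
```

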