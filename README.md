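# rarliver

Rest–activity rhythm (RAR) analysis of minute-level wrist actigraphy and
survey-weighted association models linking rhythm characteristics to
liver-function biomarkers (ALT, AST, ALP, GGT, albumin, bilirubin).

The package is aimed at epidemiologists working with accelerometer cohorts
of the NHANES 2011–2014 kind: minute-epoch activity summaries carrying a
wake/sleep/non-wear/unknown state label per epoch, a participant table of
serum liver biomarkers and covariates, and positive examination survey
weights. A fully synthetic data generator with known ground truth is a
first-class component, so every stage — rhythm estimation, quality
filtering, scoring and the weighted regression battery — can be validated
by parameter and odds-ratio recovery without any restricted data.

## The model

Mean activity at clock time $t$ (hours) follows a sigmoidally-transformed
("anti-logistic") extended cosine:

$$ E[y(t)] = \min + A \cdot \frac{e^{\beta(c(t)-\alpha)}}{1+e^{\beta(c(t)-\alpha)}},
\qquad c(t) = \cos\!\left(\frac{(t-\phi)\pi}{12}\right) $$

with nadir level $\min$, amplitude parameter $A$, acrophase $\phi$ (clock
time of peak activity), width $\alpha \in (-1,1)$ and steepness $\beta > 0$
(large $\beta$ approaches a square wave). Derived quantities: reported
amplitude = fitted peak − nadir, mesor = minimum + amplitude/2,
amplitude:mesor ratio, and the **pseudo-F statistic**

$$ F = \frac{(RSS_0 - RSS)/(k-1)}{RSS/(n-k)}, \qquad k = 5, $$

comparing the fit to a flat-mean model — higher F, more robust overall
rhythmicity. Nonparametric metrics: interdaily stability (IS), intradaily
variability (IV), and the L5 midpoint (centre of the least-active 5
consecutive hours), whose circular 2-SD rule proxies night-shift work.

Participants are filtered (valid day = ≥ 20 h wake+sleep data; ≥ 4 valid
days), parameters are grouped into survey-weighted quintiles, and
associations with sex-specific biomarker abnormality (e.g. ALT > 47 IU/L in
men, > 30 IU/L in women; albumin < 3.7 g/dL) are estimated by
survey-weighted logistic, log-linear and proportional-odds models with
sandwich variance, Wald trend tests and Rao–Scott-corrected working
likelihood-ratio interaction tests.

## Worked example

```python
import numpy as np
from rarliver import (RhythmTruth, simulate_actigraphy,
                      classify_valid_days, aggregate_5min, ExtendedCosineModel)

truth = RhythmTruth.with_nadir_sleep(minimum=10, amplitude=100, acrophase=14,
                                     alpha=0.0, beta=8.0, noise_sd=5, n_days=7)
epochs = simulate_actigraphy(truth, participant_id=1, seed=42)
bins = aggregate_5min(epochs, classify_valid_days(epochs))
res = ExtendedCosineModel.from_bins(bins).fit()
print(res.summary())
```

prints

```
Extended cosine fit
======================================
pseudo F                   213056.9537
amplitude (peak - nadir)       99.9506
mesor                          60.0486
amplitude:mesor                 1.6645
acrophase (h)                  14.0167
minimum (nadir)                10.0733
alpha (width)                   0.0026
beta (steepness)                7.9340
n obs                             2016
converged                         True
```

— the fit recovers the planted acrophase (14 h) to about a minute and the
planted amplitude (100) to 0.05%, and the very large pseudo-F reflects the
high amplitude-to-noise ratio of this simulated participant. Downstream,
`derive_rar_profiles` produces the per-participant seven-parameter table,
`score_participants` adds weighted quintiles and abnormality composites,
and `run_full_analysis` emits the tidy odds-ratio battery. A thin CLI
(`rarliver simulate | derive-rhythms | associate | full-run`) wraps the
same functions.

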