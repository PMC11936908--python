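# immersim

Session-level analytics for neurophysiologic **Immersion** in retail service
encounters: can the physiology of the *sales associate* predict the purchase
behaviour of the *customer* they are serving?

The package targets the study design of a two-store luxury-retail field
experiment (a women's-clothing arm, WS, n = 31 sessions, and a
men's-clothing arm, MS, n = 25). During each encounter the associate wears a
PPG sensor whose cardiac signal is converted by a commercial platform into a
1 Hz Immersion index (arbitrary positive scale, session means ≈ 4.4). From
that trace, per-session statistics are derived and fed through a full
analysis chain — classical tests, synthetic-data expansion, mediation, and
ensemble classification — all exercisable on simulated cohorts with no data
download.

## The quantities at the core

**Peak Immersion.** For a session running from the greeting at *t* = 0 to
departure at *T*, with associate Immersion *n(t)* sampled at 1 Hz, let

```
M = median(n) + 0.5 · sd(n)          (session threshold)
Peak = ( Σ_{t : n(t) > M} n(t) ) / ( Σ_t n(t) )   ∈ [0, 1)
```

the fraction of total session Immersion contributed by samples strictly
above the threshold. Because the brain returns to basal activity, this
peak-over-threshold fraction tracks the value of an experience better than
the session mean.

**Procedural utility.** A shopper splits income *M* between two stores at
the same price *p*; store 1 additionally yields an experience multiplier
*e*:

```
max  e·ln c₁ + ln c₂   s.t.  p·c₁ + p·c₂ ≤ M
⇒    p·c₁* = M·e/(1+e)      (expenditure share; a literal M·e/(p+e)
                              variant is also exposed — they coincide at p=1)
```

Spend in the experience store and dwell time (assumed proportional to *e*)
are both increasing in *e*; Immersion enters through *e = e(Im)*, *e′ > 0*.

**The causal chain.** Peak Immersion → dwell time → purchase amount, tested
as a linear mediation (paths *a*, *b*, direct *c′*, indirect *a·b* with
percentile-bootstrap CIs), and as an ensemble purchase classifier (random
forest + two gradient-boosting learners, tuned by nested grid search and
evaluated by stratified 5-fold CV).

## Worked example

```python
from immersim.pipeline import PipelineConfig, run_pipeline, summarize_results

cfg = PipelineConfig(out_dir="demo", seed=1969, n_synthetic=10000)
print(summarize_results(run_pipeline(cfg)))
```

or equivalently `immersim run-all --seed 1969 --out demo`, followed by
`immersim report --out demo`. Output (abridged):

```
## Store comparisons (pooled t)
| label          | group_a | group_b |        t |  df |     p_value |
| dwell_min      | WS      | MS      |  2.35826 |  54 | 0.0220114   |
| purchase_usd   | WS      | MS      |  0.852787|  54 | 0.397544    |
| avg_immersion  | WS      | MS      | -5.15443 |  54 | 3.70061e-06 |
| peak_immersion | WS      | MS      | -1.8245  |  54 | 0.0736105   |

## Mediation (WS, n=10000)
a (peak->dwell): 346.5 (p=0)
b (dwell->purchase): 6.231 (p=1.59e-60)
indirect a*b: 2159 [1735, 2624]

## Purchase prediction (pooled CV)
MS: acc 0.746, sens 0.878, spec 0.462, AUC 0.775, MSE 0.1717
WS: acc 0.707, sens 0.899, spec 0.316, AUC 0.723, MSE 0.1907
```

Reading it: the simulated WS cohort dwells longer than MS (t ≈ 2.36 on 54
df) while peak Immersion runs slightly higher in MS; on the n = 10,000
synthetic expansion both mediation paths (peak → dwell, slope *a*, and
dwell → purchase given peak, slope *b*) are positive and strongly
significant, so the indirect effect *a·b* is positive with a bootstrap CI
excluding zero; and the tuned ensemble separates purchasers from
non-purchasers well above chance (AUC ≈ 0.72–0.78), with the
high-sensitivity / low-specificity profile typical of a majority-purchase
cohort at a 0.5 threshold.

The stages are also available individually (`simulate`, `metrics`,
`synthesize`, `stats`, `mediate`, `predict`), each reading the previous
stage's CSV/JSON artifacts, and everything is reproducible from
(config, seed).

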