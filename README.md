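# shiftdetect

Break-point ("dynamic shift") detection for density-dependent population
time series.

Ecological populations are governed by internal rules — density dependence,
growth rates, carrying capacities — that external perturbations can push to
new values abruptly: an invasion, a management change, a resource collapse.
`shiftdetect` takes an annual abundance series (trap counts, census areas,
individuals — units are opaque) and asks *whether, when, and how strongly*
the parameters governing its dynamics shifted, without any break points
being nominated in advance.

## Method

Dynamics within each regime follow the Ricker map

```
N_{t+1} = N_t · exp(r · (1 − N_t / K)) + ε_t,   ε_t ~ Normal(0, σ²)
```

with intrinsic growth rate `r` and carrying capacity `K`. The detector:

1. enumerates **every** partition of the series into contiguous segments of
   at least four data points ("break after year y" semantics; the no-break
   partition included);
2. fits `(r, K)` to each segment's transition pairs by bounded
   nonlinear least squares with an analytic Jacobian;
3. scores each segment with a small-sample information criterion
   (AICc; plain AIC available for higher sensitivity) and sums the scores
   across a partition's segments;
4. ranks all partitions, forms the **equivalence set** of partitions within
   2 IC units of the best, and converts scores to Akaike weights
   `w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2)`;
5. reports each candidate break year's **break weight** — the summed weight
   of every retained partition containing it — classified as supported
   (> 0.8), ambiguous, or erroneous (< 0.2).

The package also ships the full simulation benchmark used to characterise
the detector: Ricker series with step changes in `r` and `K` at randomly
placed breaks under multiplicative noise, a 94-scenario parameter grid, and
an evaluation harness computing detection accuracy and true-vs-erroneous
break-weight separation.

## Worked example

Simulate a 20-year series with one hidden parameter shift, then detect it:

```sh
$ shiftdetect simulate --seed 11 --n-breaks 1 --out demo
series -> demo.csv
truth  -> demo.truth.json (breaks after [5])

$ shiftdetect detect demo.csv
Series: 20 points, years 1-20  (criterion: AICc)
Best combination: break(s) after 5  (total IC 189.35)
Candidates: 95 enumerated, 26 unscorable, 64 pruned

Equivalence set (delta IC < 2):
  breaks 5            IC    189.35  delta 0.00  weight 0.992

Break weights:
  after 5: weight 1.000 (supported)
  after 11: weight 0.002 (erroneous)
  after 12: weight 0.003 (erroneous)
  after 13: weight 0.002 (erroneous)
  after 14: weight 0.001 (erroneous)

Best-combination segments:
  1-5: r = 2.01 ± 0.028, K = 2.01e+03 ± 14 (n_obs 4)
  5-20: r = 1.47 ± 0.064, K = 3.5e+03 ± 12 (n_obs 15)
```

The planted break (after year 5) is the sole member of the equivalence set
and carries a break weight of 1.0 — every retained partition contains it —
while the stray candidates the noise suggests all sit far below the 0.2
"erroneous" threshold. The per-segment table recovers the generating
parameters on each side of the shift (`r` 2 → 1.47, `K` 2000 → 3500, i.e. a
+75% carrying-capacity shift).

The same analysis is available as a library call:

```python
import shiftdetect as sd

series = sd.read_series_csv("demo.csv")
report = sd.run_dsd(series)          # dict: ranking, weights, segments
print(report["best"]["breaks"])      # [5]
```

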