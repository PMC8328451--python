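# snowsel

Winter habitat-selection analysis for alpine ungulates: map snow-free
forage patches from spectral and terrain indices, test whether GPS-collared
animals use those patches more than a proportional-availability null
predicts, and model the selection with resource-selection probability
functions (RSPF).

## The problem

Wild mountain reindeer wintering on high alpine plateaus face a choice
between digging feeding craters through deep snow and travelling to
wind-blown, snow-free ridges where ground lichen is directly accessible.
Whether (and how strongly) animals select those snow-free patches is a
use-versus-availability question: overlay GPS positions on a map of
snow-free cells and compare observed use with what a "random walk"
(use proportional to areal availability) would produce.

The snow-free map itself must be built: a fine (1 m) snow reference —
cells are snow-free when depth ≤ 35 cm — exists only along sampling
transects, so a regression calibrated there (mean multi-scene NDSI plus the
Topographic Position Index as predictors, flexible learners scored by 5-fold
cross-validation repeated 5 times and the two best averaged) predicts the
snow-free fraction of every 30 m cell area-wide. Thresholding that fraction
at 80/50/30 % delineates snow-free patches.

## The statistics

For a 2×2 used/available × on/off-patch table (a, b, c, d):

    OR = (a/b) / (c/d),   SE(ln OR) = sqrt(1/a + 1/b + 1/c + 1/d)
    95 % CI = exp(ln OR ± 1.96 SE)

together with the selection ratio observed/expected, where
expected = N_used × availability fraction. Diel stratification uses
morning/day/evening/night windows anchored ±1 h on local sunrise and sunset.

RSPF models are binary ML regressions with the complementary log-log
response P(used = 1 | x) = 1 − exp(−exp(x′β)) on z-score standardized
predictors (snow depth, distance to snow-free areas, lichen cover,
elevation and its square, TPI, easting), ranked by AIC with a caution flag
inside 2 units, checked with Hosmer–Lemeshow deciles and variance inflation
factors.

Because collar data and imagery are external, the package ships a
first-class synthetic generator (`snowsel.synthetic`): fractal terrain, snow
scoured off ridges into depressions with a west→east thinning gradient,
NDSI scenes coherent with true snow cover, and 3-hourly tracks whose step
choice prefers snow-free cells with a known log-odds strength — so every
stage is testable against known truth.

## Worked example

```bash
snowsel run --seed 2 --out runs/demo
```

runs the whole chain on a synthetic 600 × 600 m landscape (four animals,
500 steps at 3 h, snow-free preference β = 2) and prints

```
30% threshold: OR = 2.03 (95% CI 1.622-2.535)
report written to runs/demo/report.json
```

i.e. the simulated animals' odds of being on a snow-free cell are about
twice the landscape's availability odds, and the CI excludes 1 — the
built-in preference is detected. `report.json` also holds the calibration
CV R², patch statistics per threshold, diel excess-use percentages, the
AIC model ranking, coefficients of the best model, Hosmer–Lemeshow and VIF
diagnostics. The same statistics are available as library calls:

```python
from snowsel.selection import ContingencyTable, odds_ratio
res = odds_ratio(ContingencyTable(56378, 132564, 17383, 171559))
print(f"{res.odds_ratio:.2f} ({res.ci_low:.4f}-{res.ci_high:.4f})")
# 4.20 (4.1206-4.2755)
```

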