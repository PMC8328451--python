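"""Snow-fraction calibration: NDSI mean + TPI -> snow-free fraction.

The fine-grid snow reference only covers sampling transects, so a regression
is calibrated there and then predicts the snow-free fraction of every coarse
cell area-wide.  Both predictors relate to the response curvilinearly and TPI
shows a threshold effect, so the learners are flexible regressors behind a
minimal fit/predict contract: a penalized-spline regressor and
gradient-boosted stumps are built in (plus a plain linear model and a
constant-mean baseline, mainly for testing).  Reference cells are sampled in
a balanced way across ten snow-fraction bins, learners are scored by 5-fold
cross-validation repeated 5 times (25 resamples, out-of-fold R^2), and the
final predictor is the unweighted average of the two best learners, clipped
to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer

from .grid import Grid, aligned

FEATURES = ["ndsi_mean", "tpi"]


@dataclass(frozen=True)
class LearnerSpec:
    """Name + hyperparameters of a regressor honoring fit/predict."""

    name: str
    params: dict = field(default_factory=dict)

    def make(self, seed: int):
        p = dict(self.params)
        if self.name == "pspline":
            n_knots = p.pop("n_knots", 8)
            alpha = p.pop("alpha", 1.0)
            return make_pipeline(
                SplineTransformer(n_knots=n_knots, degree=3),
                Ridge(alpha=alpha, **p),
            )
        if self.name == "gbstumps":
            return GradientBoostingRegressor(
                max_depth=p.pop("max_depth", 1),
                n_estimators=p.pop("n_estimators", 300),
                learning_rate=p.pop("learning_rate", 0.05),
                random_state=seed,
                **p,
            )
        if self.name == "linear":
            return LinearRegression(**p)
        if self.name == "mean":
            return DummyRegressor(strategy="mean")
        raise ValueError(f"unknown learner {self.name!r}")


DEFAULT_LEARNERS = [LearnerSpec("pspline"), LearnerSpec("gbstumps")]


@dataclass
class CalibrationResult:
    cv_r2: pd.DataFrame            # one row per (learner, resample)
    mean_r2: pd.Series             # per learner
    chosen: list[LearnerSpec]      # the two best, by mean CV R^2
    predictor_correlations: pd.Series  # Pearson r of each feature vs y
    estimators: list = field(default_factory=list)  # refit on all data

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.mean([est.predict(X) for est in self.estimators], axis=0)
        return np.clip(preds, 0.0, 1.0)


def make_calibration_set(
    ndsi_mean: Grid, tpi: Grid, reference: Grid, coverage: np.ndarray | None = None
) -> pd.DataFrame:
    """Calibration rows from coarse cells holding a fine-grid reference.

    ``reference`` is the true snow-free fraction (coarse); ``coverage``
    optionally restricts rows to reference-covered cells (e.g. ALS transect
    bands).  Rows with any nodata are dropped.
    """
    aligned(ndsi_mean, tpi, reference)
    sel = np.isfinite(reference.values)
    if coverage is not None:
        sel &= coverage.astype(bool)
    rows, cols = np.nonzero(sel)
    df = pd.DataFrame(
        {
            "cell_row": rows,
            "cell_col": cols,
            "ndsi_mean": ndsi_mean.values[rows, cols],
            "tpi": tpi.values[rows, cols],
            "y": reference.values[rows, cols],
        }
    ).dropna()
    if ((df["y"] < 0) | (df["y"] > 1)).any():
        raise ValueError("reference fractions must lie in [0, 1]")
    return df.reset_index(drop=True)


def transect_coverage(coarse: Grid, n_transects: int = 6, width_cells: int = 2) -> np.ndarray:
    """Boolean coverage mask of uniformly spaced east-west transect bands."""
    cov = np.zeros(coarse.shape, dtype=bool)
    nr = coarse.nrows
    starts = np.linspace(0, nr - width_cells, n_transects).round().astype(int)
    for s in starts:
        cov[s : s + width_cells, :] = True
    return cov


def balanced_sample(data: pd.DataFrame, quota_per_bin: int, seed: int) -> pd.DataFrame:
    """Draw about the same number of rows per 10%-wide snow-fraction bin.

    The response is partitioned into [0,0.1), ..., [0.9,1.0] and
    ``min(quota, bin size)`` rows are sampled without replacement per bin,
    so the calibration set is not dominated by fully snow-covered cells.
    """
    if len(data) == 0:
        raise ValueError("empty calibration set")
    if quota_per_bin < 1:
        raise ValueError("quota_per_bin must be >= 1")
    rng = np.random.default_rng(seed)
    bins = np.minimum((data["y"].to_numpy() * 10).astype(int), 9)
    keep = []
    for b in range(10):
        idx = np.nonzero(bins == b)[0]
        if len(idx) == 0:
            continue
        take = min(quota_per_bin, len(idx))
        keep.append(rng.choice(idx, size=take, replace=False))
    keep = np.sort(np.concatenate(keep))
    return data.iloc[keep].reset_index(drop=True)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels stratified on deciles of y (mirrors the balanced design)."""
    n = len(y)
    deciles = np.searchsorted(np.quantile(y, np.linspace(0.1, 0.9, 9)), y, side="right")
    fold = np.empty(n, dtype=int)
    offset = 0
    for d in np.unique(deciles):
        idx = np.nonzero(deciles == d)[0]
        rng.shuffle(idx)
        fold[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)
    return fold


def cv_score(
    learner: LearnerSpec,
    data: pd.DataFrame,
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold R^2 for each of k x repeats resamples.

    R^2 = 1 - SSE/SST on the held-out rows; a held-out fold with zero
    response variance has an undefined R^2, flagged as NaN.
    """
    if len(data) < 2 * k:
        raise ValueError(f"need at least {2*k} rows for {k}-fold CV")
    X = data[FEATURES].to_numpy(dtype=float)
    y = data["y"].to_numpy(dtype=float)
    scores = []
    for rep in range(repeats):
        rng = np.random.default_rng([seed, rep])
        folds = _stratified_folds(y, k, rng)
        for f in range(k):
            test = folds == f
            est = learner.make(seed)
            est.fit(X[~test], y[~test])
            pred = est.predict(X[test])
            sst = ((y[test] - y[test].mean()) ** 2).sum()
            if sst == 0:
                scores.append(np.nan)
                continue
            sse = ((y[test] - pred) ** 2).sum()
            scores.append(1.0 - sse / sst)
    return np.asarray(scores)


def fit_ensemble(
    data: pd.DataFrame,
    learners: list[LearnerSpec] | None = None,
    seed: int = 0,
    k: int = 5,
    repeats: int = 5,
) -> CalibrationResult:
    """Score learners by repeated CV, refit the two best, average them.

    Learners are ranked by mean out-of-fold R^2 (ties broken in favor of
    fewer hyperparameters); the top two are refit on all rows and the
    calibrated predictor is their unweighted mean, clipped to [0, 1].
    """
    if learners is None:
        learners = list(DEFAULT_LEARNERS)
    if len(learners) < 2:
        raise ValueError("need at least 2 learners to build the ensemble")
    records = []
    means = []
    for spec in learners:
        r2 = cv_score(spec, data, k=k, repeats=repeats, seed=seed)
        means.append(float(np.nanmean(r2)))
        for i, v in enumerate(r2):
            records.append({"learner": spec.name, "resample": i, "r2": v})
    order = sorted(
        range(len(learners)),
        key=lambda i: (-means[i], len(learners[i].params)),
    )
    chosen = [learners[i] for i in order[:2]]
    X = data[FEATURES].to_numpy(dtype=float)
    y = data["y"].to_numpy(dtype=float)
    estimators = [spec.make(seed).fit(X, y) for spec in chosen]
    corr = pd.Series(
        {f: float(np.corrcoef(data[f], data["y"])[0, 1]) for f in FEATURES},
        name="pearson_r",
    )
    return CalibrationResult(
        cv_r2=pd.DataFrame(records),
        mean_r2=pd.Series({s.name: m for s, m in zip(learners, means)}),
        chosen=chosen,
        predictor_correlations=corr,
        estimators=estimators,
    )


def predict_fraction(result: CalibrationResult, ndsi_mean: Grid, tpi: Grid) -> Grid:
    """Cellwise ensemble snow-free fraction prediction; nodata propagates."""
    aligned(ndsi_mean, tpi)
    valid = np.isfinite(ndsi_mean.values) & np.isfinite(tpi.values)
    out = np.full(ndsi_mean.shape, np.nan)
    if valid.any():
        X = np.column_stack([ndsi_mean.values[valid], tpi.values[valid]])
        out[valid] = result.predict(X)
    return ndsi_mean.like(out)
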