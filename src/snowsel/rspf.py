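"""Resource-selection probability function (RSPF) modeling.

Used (animal) versus available (random landscape) fine cells are contrasted
with a binary maximum-likelihood regression using the complementary log-log
response, ``P(used = 1 | x) = 1 - exp(-exp(eta))``.  Candidate predictors are
snow depth (SNOW, cm), distance to snow-free areas (DIST, m), lichen cover
(LICHEN, %), elevation and its square (DEM, DEM2), the topographic position
index (TPI) and the easting (XCOORD, proxy for the west-east climate
gradient); all are z-score standardized over the pooled design before
fitting.  Models are compared by AIC, with caution flagged for models within
2 AIC units of the best; goodness of fit uses the Hosmer-Lemeshow decile
statistic and collinearity is screened with variance inflation factors.

This is the plain used/available GLM formulation; a weighted-distribution
RSPF estimator is deliberately not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grid import Grid

PREDICTORS = ["SNOW", "DIST", "LICHEN", "DEM", "DEM2", "TPI", "XCOORD"]

FULL_MODEL = "DIST + SNOW + XCOORD + DEM2 + DEM + TPI + LICHEN + SNOW:LICHEN"


@dataclass
class RSPFFit:
    terms: list[str]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    log_likelihood: float
    aic: float
    link: str = "cloglog"
    n_used: int = 0
    n_avail: int = 0
    fitted: np.ndarray | None = None
    model_spec: str = ""

    @property
    def k(self) -> int:
        return len(self.coefficients)


def parse_terms(spec: str) -> list[str]:
    """Split a model-spec string like "DIST + SNOW + SNOW:LICHEN" into terms."""
    terms = [t.strip() for t in spec.split("+")]
    if any(not t for t in terms):
        raise ValueError(f"malformed model spec: {spec!r}")
    return terms


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    if ":" in term:
        parts = [p.strip() for p in term.split(":")]
        col = np.ones(len(df))
        for p in parts:
            col = col * df[p].to_numpy(dtype=float)
        return col
    return df[term].to_numpy(dtype=float)


def design_matrix(df: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Intercept + one column per term; interactions built as products."""
    cols = [np.ones(len(df))] + [_term_column(df, t) for t in terms]
    return np.column_stack(cols)


# -- design construction ------------------------------------------------------


def snap_position(
    x: float, y: float, depth_fine: Grid, buffer: float = 5.0
) -> tuple[int, int]:
    """Snap a GPS position to the lowest-snow-depth fine cell within a buffer.

    GPS fixes carry a few meters of error, so among fine cells whose centers
    lie within ``buffer`` meters of the position the one with minimum snow
    depth is taken as the animal's cell.  Ties go to the cell nearest the
    original position, then row-major order.  With no cell center in the
    buffer (including buffer 0) the containing cell is returned.
    """
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    row0, col0 = depth_fine.cell_at(x, y)
    row0, col0 = int(row0), int(col0)
    r_cells = int(np.floor(buffer / depth_fine.cell)) + 1
    rows = np.arange(max(0, row0 - r_cells), min(depth_fine.nrows, row0 + r_cells + 1))
    cols = np.arange(max(0, col0 - r_cells), min(depth_fine.ncols, col0 + r_cells + 1))
    if len(rows) == 0 or len(cols) == 0:
        return row0, col0
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    cx = depth_fine.origin_x + (cc + 0.5) * depth_fine.cell
    cy = depth_fine.origin_y - (rr + 0.5) * depth_fine.cell
    dist = np.hypot(cx - x, cy - y)
    ok = (dist <= buffer) & np.isfinite(depth_fine.values[rr, cc])
    if not ok.any():
        return row0, col0
    depths = depth_fine.values[rr, cc]
    # lexicographic: depth, then distance to the fix, then row-major
    order = np.lexsort(
        (cc[ok].ravel(), rr[ok].ravel(), dist[ok].ravel(), depths[ok].ravel())
    )
    flat_idx = np.argwhere(ok)
    pick = flat_idx[order[0]]
    return int(rr[pick[0], pick[1]]), int(cc[pick[0], pick[1]])


def sample_available(
    depth_fine: Grid, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random fine cells without replacement (rows, cols), seeded."""
    valid = np.argwhere(np.isfinite(depth_fine.values))
    if n > len(valid):
        raise ValueError("not enough valid cells to sample availability")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(valid), size=n, replace=False)
    return valid[idx, 0], valid[idx, 1]


def build_design(
    used_xy: np.ndarray,
    layers: dict[str, Grid],
    n_available: int,
    seed: int,
    buffer: float = 5.0,
) -> pd.DataFrame:
    """Assemble a used/available design table from predictor rasters.

    ``layers`` must contain fine-grid 'SNOW' (cm), 'DIST' (m), 'DEM' (m),
    'TPI' (m) and a 'LICHEN' grid (any resolution, sampled by coordinate).
    Each used position is snapped to the minimum-depth cell within the GPS
    buffer; available rows are uniform random fine cells.  DEM2 is the square
    of DEM; XCOORD the cell-center easting.  Rows with any missing predictor
    are dropped.
    """
    depth = layers["SNOW"]
    rows_u, cols_u = [], []
    for x, y in np.asarray(used_xy, dtype=float):
        if not depth.contains(x, y):
            continue
        r, c = snap_position(x, y, depth, buffer=buffer)
        rows_u.append(r)
        cols_u.append(c)
    rows_a, cols_a = sample_available(depth, n_available, seed)
    rows = np.concatenate([rows_u, rows_a]).astype(int)
    cols = np.concatenate([cols_u, cols_a]).astype(int)
    used = np.concatenate([np.ones(len(rows_u)), np.zeros(len(rows_a))])
    cx = depth.origin_x + (cols + 0.5) * depth.cell
    cy = depth.origin_y - (rows + 0.5) * depth.cell
    df = pd.DataFrame(
        {
            "used": used,
            "SNOW": depth.values[rows, cols],
            "DIST": layers["DIST"].values[rows, cols],
            "DEM": layers["DEM"].values[rows, cols],
            "TPI": layers["TPI"].values[rows, cols],
            "LICHEN": layers["LICHEN"].sample(cx, cy),
            "XCOORD": cx,
        }
    )
    df["DEM2"] = df["DEM"] ** 2
    df = df.dropna().reset_index(drop=True)
    return df


def standardize(
    design: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Z-score predictor columns over all rows (used and available pooled).

    Uses the sample standard deviation (n-1).  Returns the standardized copy
    plus the means and sds needed for an exact back-transform.  A constant
    column is an error naming the column.
    """
    if columns is None:
        columns = [c for c in design.columns if c != "used"]
    means = design[columns].mean()
    sds = design[columns].std(ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise ValueError(f"constant predictor column(s): {list(zero.index)}")
    out = design.copy()
    out[columns] = (design[columns] - means) / sds
    return out, means, sds


# -- fitting ------------------------------------------------------------------


def fit_rspf(
    design: pd.DataFrame, terms: list[str] | str, link: str = "cloglog"
) -> RSPFFit:
    """Maximum-likelihood binary fit of used-vs-available with a cloglog link.

    ``P(used=1 | x) = 1 - exp(-exp(x'beta))`` (or logistic with
    ``link='logit'``).  Standard errors come from the observed information
    matrix; AIC = 2k - 2 logL.  Raises on rank-deficient designs and on
    non-convergence (e.g. complete separation).
    """
    if isinstance(terms, str):
        terms = parse_terms(terms)
    y = design["used"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("design needs at least one used and one available row")
    X = design_matrix(design, terms)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    links = {"cloglog": sm.families.links.CLogLog(), "logit": sm.families.links.Logit()}
    model = sm.GLM(y, X, family=sm.families.Binomial(link=links[link]))
    res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise RuntimeError(
            f"IRLS did not converge in {res.fit_history['iteration']} iterations"
        )
    names = ["(Intercept)"] + terms
    return RSPFFit(
        terms=terms,
        coefficients=dict(zip(names, res.params)),
        std_errors=dict(zip(names, res.bse)),
        p_values=dict(zip(names, res.pvalues)),
        log_likelihood=float(res.llf),
        aic=float(res.aic),
        link=link,
        n_used=int(y.sum()),
        n_avail=int(len(y) - y.sum()),
        fitted=np.asarray(res.fittedvalues),
        model_spec=" + ".join(terms),
    )


def rank_models(fits: list[RSPFFit] | list[tuple[str, float]]) -> pd.DataFrame:
    """Rank models by AIC ascending with ΔAIC versus the best.

    Accepts fitted models or bare ``(name, AIC)`` pairs.  Models with ΔAIC
    under 2 are flagged for cautious interpretation (extra parameters may not
    be earning their keep).
    """
    if not len(fits):
        raise ValueError("no models to rank")
    rows = []
    for f in fits:
        if isinstance(f, RSPFFit):
            rows.append({"model": f.model_spec, "aic": f.aic})
        else:
            name, aic = f
            rows.append({"model": name, "aic": float(aic)})
    df = pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    df["within_2_aic"] = df["delta_aic"] < 2.0
    df.index = np.arange(1, len(df) + 1)
    df.index.name = "rank"
    return df


def hosmer_lemeshow(
    fitted: np.ndarray, y: np.ndarray, groups: int = 10
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit on deciles of fitted probability.

    X^2 sums ``(O-E)^2/E`` over events and non-events in each group;
    df = groups - 2.  Tied fitted values can empty a group; such groups are
    merged into their neighbor and df adjusted.  All-identical fitted
    probabilities leave nothing to group and raise.
    """
    if groups < 3:
        raise ValueError("need at least 3 groups")
    fitted = np.asarray(fitted, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(fitted) == 0:
        raise ValueError("all fitted probabilities identical; grouping degenerate")
    edges = np.unique(np.quantile(fitted, np.linspace(0, 1, groups + 1)))
    if len(edges) - 1 < 3:
        raise ValueError("too many ties in fitted probabilities to form groups")
    bins = np.clip(np.searchsorted(edges, fitted, side="right") - 1, 0, len(edges) - 2)
    x2 = 0.0
    n_groups = 0
    for g in range(len(edges) - 1):
        sel = bins == g
        n_g = sel.sum()
        if n_g == 0:
            continue
        o = y[sel].sum()
        e = fitted[sel].sum()
        if e <= 0 or e >= n_g:
            # degenerate expected count; fold into the chi-square with the
            # complement guard to avoid division by zero
            e = min(max(e, 1e-10), n_g - 1e-10)
        x2 += (o - e) ** 2 / e + ((n_g - o) - (n_g - e)) ** 2 / (n_g - e)
        n_groups += 1
    df = n_groups - 2
    from scipy import stats

    p = float(stats.chi2.sf(x2, df))
    return float(x2), int(df), p


def vif(design: pd.DataFrame, terms: list[str]) -> pd.Series:
    """Variance inflation factor per term: 1 / (1 - R^2_j).

    Each term (with an intercept) is regressed on the remaining terms;
    perfect collinearity yields ``inf``.
    """
    if len(terms) < 2:
        raise ValueError("need at least 2 terms for VIF")
    cols = {t: _term_column(design, t) for t in terms}
    out = {}
    for t in terms:
        yj = cols[t]
        X = np.column_stack([np.ones(len(yj))] + [cols[o] for o in terms if o != t])
        beta, *_ = np.linalg.lstsq(X, yj, rcond=None)
        resid = yj - X @ beta
        sst = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / sst if sst > 0 else 1.0
        out[t] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
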