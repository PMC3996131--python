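"""Statistical procedures over the unit-level table.

Implements the correlation-mining screen (16 metrics x 5 radii with
Bonferroni correction), standardized-coefficient OLS models, stratified
regression by deprivation tertile, and the HullR radius sweep.

Model-fitting classes follow the scikit-learn estimator protocol
(``fit``, ``get_params``/``set_params``, fitted attributes with a
trailing underscore); the module-level functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .aggregation import DEFAULT_BUFFER_M, aggregate, assign_links
from .network import ArealUnit, SpatialNetwork
from .radial import DEFAULT_RADII, METRIC_NAMES, hullr_profile, metric_column

__all__ = [
    "ScreenResult",
    "RegressionResult",
    "TertileResult",
    "CorrelationScreen",
    "StandardizedOLS",
    "zscore",
    "pearson_screen",
    "ols_standardized",
    "tertile_split",
    "tertile_models",
    "radius_sweep",
]

#: the paper-style alternative correction factor when the five radii are
#: treated as calibration of a single test per metric
RELAXED_BONFERRONI_FACTOR = 16


def zscore(x: np.ndarray) -> np.ndarray:
    """Sample z-score with ddof=1 (the scale used for standardized coefficients)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance column cannot be standardized")
    return (x - x.mean()) / sd


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pairwise-complete Pearson r with two-sided p; NaN r on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return float("nan"), float("nan"), n
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return float("nan"), float("nan"), n
    r, p = sps.pearsonr(xs, ys)
    return float(r), float(p), n


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Outcome of the (metric x radius) correlation-mining screen."""

    table: pd.DataFrame          # long: metric, radius_m, r, p, p_adj, n
    bonferroni_factor: int       # cells actually tested (80 by default)
    relaxed_factor: int          # metadata: per-metric calibration reading
    best: dict                   # metric, radius_m, r, p, p_adj of max |r|

    def r_grid(self) -> pd.DataFrame:
        return self.table.pivot(index="metric", columns="radius_m", values="r")


class CorrelationScreen(BaseEstimator):
    """Screen every (metric, radius) column against an areal outcome.

    Parameters
    ----------
    metrics, radii : the screened grid; defaults to all 16 metrics at the
        five walking-scale radii.
    outcome : outcome column name, default ``cohesion``.
    continuous : whether the table's columns carry the continuous-space
        ``c`` suffix.
    bonferroni_factor : multiplier for adjusted p values; ``None`` means
        the number of cells actually tested.
    """

    def __init__(
        self,
        metrics: Sequence[str] = METRIC_NAMES,
        radii: Sequence[float] = DEFAULT_RADII,
        outcome: str = "cohesion",
        continuous: bool = True,
        bonferroni_factor: int | None = None,
    ):
        self.metrics = metrics
        self.radii = radii
        self.outcome = outcome
        self.continuous = continuous
        self.bonferroni_factor = bonferroni_factor

    def fit(self, table: pd.DataFrame, y=None):
        rows = []
        y_col = table[self.outcome].to_numpy(dtype=float)
        n_tested = 0
        for m in self.metrics:
            for r in self.radii:
                col = metric_column(m, r, self.continuous)
                if col not in table.columns:
                    continue
                n_tested += 1
                rr, p, n = _pearson(table[col].to_numpy(dtype=float), y_col)
                rows.append(
                    {"metric": m, "radius_m": float(r), "r": rr, "p": p, "n": n}
                )
        if not rows:
            raise ValueError("no screened columns found in table")
        long = pd.DataFrame(rows)
        factor = self.bonferroni_factor or n_tested
        long["p_adj"] = np.minimum(1.0, long["p"] * factor)
        valid = long.dropna(subset=["r"])
        if valid.empty:
            raise ValueError("every screened cell was degenerate")
        best_row = valid.loc[valid["r"].abs().idxmax()]
        self.result_ = ScreenResult(
            table=long,
            bonferroni_factor=factor,
            relaxed_factor=RELAXED_BONFERRONI_FACTOR,
            best=best_row[["metric", "radius_m", "r", "p", "p_adj"]].to_dict(),
        )
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.result_.table


def pearson_screen(
    table: pd.DataFrame,
    metrics: Sequence[str] = METRIC_NAMES,
    radii: Sequence[float] = DEFAULT_RADII,
    outcome: str = "cohesion",
    continuous: bool = True,
    bonferroni_factor: int | None = None,
) -> ScreenResult:
    """Functional wrapper over :class:`CorrelationScreen`."""
    est = CorrelationScreen(metrics, radii, outcome, continuous, bonferroni_factor)
    return est.fit(table).result_


# ---------------------------------------------------------------------------
# standardized OLS
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """Standardized-coefficient OLS output."""

    predictors: list
    coef: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    n: int
    dropped: list = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )


class StandardizedOLS(BaseEstimator):
    """OLS on z-scored outcome and predictors (standardized coefficients).

    Both outcome and predictors — including 0/1 indicator columns, unless
    ``standardize_binary=False`` — are z-scored by sample mean and SD
    (ddof=1), so every reported coefficient is on the standardized scale
    and, with a single predictor, equals the Pearson correlation.  The fit
    absorbs the intercept; residual degrees of freedom are n - p - 1.
    """

    def __init__(self, standardize_binary: bool = True):
        self.standardize_binary = standardize_binary

    @staticmethod
    def _is_binary(x: np.ndarray) -> bool:
        vals = np.unique(x[np.isfinite(x)])
        return len(vals) <= 2 and np.isin(vals, (0.0, 1.0)).all()

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        names = [str(c) for c in X.columns]
        y = np.asarray(y, dtype=float)
        Xv = X.to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(Xv).all(axis=1)  # listwise deletion
        y, Xv = y[ok], Xv[ok]
        n, p = Xv.shape
        if n <= p + 1:
            raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")

        cols = []
        for j, name in enumerate(names):
            col = Xv[:, j]
            if col.std(ddof=1) == 0:
                raise ValueError(f"predictor {name!r} has zero variance")
            if not self.standardize_binary and self._is_binary(col):
                cols.append(col)
            else:
                cols.append(zscore(col))
        Z = np.column_stack(cols)
        zy = zscore(y)

        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), Z]))
        if rank < p + 1:
            _, _, vt = np.linalg.svd(Z - Z.mean(axis=0))
            null = vt[-1]
            involved = [names[j] for j in np.nonzero(np.abs(null) > 1e-8)[0]]
            raise ValueError(f"exactly collinear predictors: {involved}")

        model = sm.OLS(zy, sm.add_constant(Z, has_constant="add")).fit()
        idx = pd.Index(names)
        self.feature_names_in_ = names
        self.coef_ = pd.Series(model.params[1:], index=idx)
        self.bse_ = pd.Series(model.bse[1:], index=idx)
        self.tvalues_ = pd.Series(model.tvalues[1:], index=idx)
        self.pvalues_ = pd.Series(model.pvalues[1:], index=idx)
        self.rsquared_ = float(model.rsquared)
        self.rsquared_adj_ = float(model.rsquared_adj)
        self.nobs_ = n
        self.result_ = RegressionResult(
            predictors=names,
            coef=self.coef_,
            bse=self.bse_,
            tvalues=self.tvalues_,
            pvalues=self.pvalues_,
            r2=self.rsquared_,
            adj_r2=self.rsquared_adj_,
            n=n,
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        # prediction on the standardized scale; mainly for pipeline use
        Z = np.column_stack([zscore(np.asarray(X[c], dtype=float)) for c in self.feature_names_in_])
        return Z @ self.coef_.to_numpy()


def ols_standardized(
    y, X: pd.DataFrame, standardize_binary: bool = True
) -> RegressionResult:
    """Functional wrapper over :class:`StandardizedOLS`."""
    return StandardizedOLS(standardize_binary).fit(X, y).result_


# ---------------------------------------------------------------------------
# deprivation tertiles
# ---------------------------------------------------------------------------

@dataclass
class TertileResult:
    models: list                 # RegressionResult per tertile, least deprived first
    boundaries: list             # (min, max) deprivation per tertile
    bivariate_r: list            # Pearson r of outcome vs main predictor per tertile
    assignments: pd.Series       # tertile index per unit_id


def tertile_split(
    table: pd.DataFrame, deprivation: str = "deprivation"
) -> list[pd.DataFrame]:
    """Equal-size thirds by deprivation rank, least deprived first.

    Ties in deprivation are broken by unit id so the partition is stable
    and reproducible; every unit lands in exactly one tertile.
    """
    if len(table) < 9:
        raise ValueError("need at least 9 units for a tertile split")
    ranked = table.sort_values(
        [deprivation, "unit_id"],
        key=lambda s: s.astype(str) if s.name == "unit_id" else s,
    ).reset_index(drop=True)
    return [ranked.loc[idx] for idx in np.array_split(ranked.index.to_numpy(), 3)]


def tertile_models(
    table: pd.DataFrame,
    outcome: str = "cohesion",
    predictor: str = "HullR600c",
    deprivation: str = "deprivation",
    urban: str = "urban",
    standardize_binary: bool = True,
) -> TertileResult:
    """Re-run the multivariate model within each tertile of deprivation.

    Units are split with :func:`tertile_split`; within each third, the
    outcome is regressed on the main predictor, deprivation and urban
    status with coefficients standardized within-tertile.  A predictor
    with zero within-tertile variance is dropped and flagged.
    """
    if len(table) < 30:
        raise ValueError("need at least 30 units to fit tertile models")
    models, bounds, biv = [], [], []
    assign = {}
    for t, part in enumerate(tertile_split(table, deprivation)):
        for uid in part["unit_id"]:
            assign[uid] = t
        bounds.append(
            (float(part[deprivation].min()), float(part[deprivation].max()))
        )
        cols, dropped = [], []
        for c in (predictor, deprivation, urban):
            vals = part[c].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0 or np.std(vals, ddof=0) == 0:
                dropped.append(c)
            else:
                cols.append(c)
        res = ols_standardized(
            part[outcome], part[cols], standardize_binary=standardize_binary
        )
        res.dropped = dropped
        models.append(res)
        r, _, _ = _pearson(part[predictor], part[outcome])
        biv.append(r)
    return TertileResult(
        models=models,
        boundaries=bounds,
        bivariate_r=biv,
        assignments=pd.Series(assign, name="tertile"),
    )


# ---------------------------------------------------------------------------
# radius sweep
# ---------------------------------------------------------------------------

def radius_sweep(
    net: SpatialNetwork,
    units: list[ArealUnit],
    radii: Iterable[float],
    outcome: str = "cohesion",
    metric: str = "HullR",
    buffer_m: float = DEFAULT_BUFFER_M,
    continuous: bool = True,
    outcomes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, float]:
    """Bivariate correlation of a recomputed metric with the outcome, per radius.

    The metric is recomputed at every radius, re-aggregated with a fixed
    30 m-buffer assignment, and correlated with the outcome.  Returns the
    curve (radius_m, r, p, n) and the radius of maximum |r|.
    """
    radii = sorted(float(r) for r in radii)
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    if metric == "HullR" and continuous:
        rows = hullr_profile(net, radii, continuous=continuous)
    else:
        from .radial import compute_link_metrics

        rows = compute_link_metrics(net, radii, continuous=continuous)
    mapping = assign_links(units, net, buffer_m)
    table = aggregate(mapping, rows, continuous)
    if outcomes is not None:
        y_by_unit = outcomes.set_index("unit_id")[outcome]
    else:
        y_by_unit = pd.Series(
            {u.id: u.attributes.get(outcome) for u in units}, name=outcome
        )
    y = table["unit_id"].map(y_by_unit).to_numpy(dtype=float)
    curve = []
    for r in radii:
        col = metric_column(metric, r, continuous)
        rr, p, n = _pearson(table[col].to_numpy(dtype=float), y)
        curve.append({"radius_m": r, "r": rr, "p": p, "n": n})
    curve = pd.DataFrame(curve)
    valid = curve.dropna(subset=["r"])
    best = float(valid.loc[valid["r"].abs().idxmax(), "radius_m"])
    return curve, best
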