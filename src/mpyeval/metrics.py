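"""Agreement and bias statistics for observed-vs-predicted evaluation.

Implements the metric suite standard in feed-evaluation-model assessment:
root mean square error (RMSE) and its normalization by the observed mean
(NRMSE), Pearson correlation, Lin's concordance correlation coefficient
(CCC) with its bias-correction factor Cb, and the decomposition of mean
square error into central-tendency bias (mean shift), regression bias
(slope) and disturbance bias (random scatter).

Population (divide-by-n) moments are the default, which makes the MSE
decomposition an exact identity and matches Lin's original CCC definition;
sample moments (divide-by-n−1) are available via ``moments="sample"``.
Residuals follow the ``obs − pred`` sign convention throughout.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .types import InvalidInputError

__all__ = [
    "PairedSeries",
    "EvaluationReport",
    "rmse",
    "nrmse",
    "ccc_cb",
    "mse_decomposition",
    "residual_correlation",
    "evaluate",
]


class DegenerateInputError(InvalidInputError):
    """Raised when a statistic is undefined (e.g. zero variance)."""


@dataclass(frozen=True)
class PairedSeries:
    """Paired observed and predicted milk protein yields (g/d)."""

    obs: np.ndarray
    pred: np.ndarray
    labels: Optional[Sequence] = None  # optional herd ids per element

    def __post_init__(self) -> None:
        obs = np.asarray(self.obs, dtype=float)
        pred = np.asarray(self.pred, dtype=float)
        object.__setattr__(self, "obs", obs)
        object.__setattr__(self, "pred", pred)
        if obs.ndim != 1 or pred.ndim != 1 or obs.shape != pred.shape:
            raise InvalidInputError("obs and pred must be 1-D of equal length")
        if obs.size < 3:
            raise InvalidInputError(f"need at least 3 pairs, got {obs.size}")
        if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
            raise InvalidInputError("obs and pred must be finite")
        if self.labels is not None and len(self.labels) != obs.size:
            raise InvalidInputError("labels length must match series length")

    @property
    def n(self) -> int:
        return self.obs.size

    @property
    def residuals(self) -> np.ndarray:
        """Residuals, obs − pred."""
        return self.obs - self.pred


@dataclass(frozen=True)
class EvaluationReport:
    """All agreement/bias metrics for one prediction set.

    Bias components (``ctb``, ``rb``, ``db``) are in g²/d² and sum exactly
    to ``mse``; their shares of MSE are in ``ctb_pct``/``rb_pct``/``db_pct``.
    ``slope``/``intercept`` describe the pred-on-obs regression;
    ``slope_obs_on_pred``/``intercept_obs_on_pred`` the reverse fit drawn
    through observed-vs-predicted scatter plots.
    """

    n: int
    mean_obs: float
    mean_pred: float
    rmse: float
    nrmse: float          # fraction of observed mean
    mse: float
    r: float
    ccc: float
    cb: float
    ctb: float
    rb: float
    db: float
    ctb_pct: float
    rb_pct: float
    db_pct: float
    slope: float
    intercept: float
    slope_obs_on_pred: float
    intercept_obs_on_pred: float
    n_negative_pred: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _moments(series: PairedSeries, moments: str):
    if moments not in ("population", "sample"):
        raise InvalidInputError(f"moments must be 'population' or 'sample', got {moments!r}")
    ddof = 0 if moments == "population" else 1
    o, p = series.obs, series.pred
    mo, mp = o.mean(), p.mean()
    var_o = o.var(ddof=ddof)
    var_p = p.var(ddof=ddof)
    cov_op = ((o - mo) * (p - mp)).sum() / (o.size - ddof)
    return mo, mp, var_o, var_p, cov_op


def rmse(series: PairedSeries) -> float:
    """Root mean square error of prediction, g/d."""
    return float(np.sqrt(np.mean(series.residuals**2)))


def nrmse(series: PairedSeries) -> float:
    """RMSE as a fraction of the observed mean (multiply by 100 for %)."""
    mean_obs = series.obs.mean()
    if mean_obs == 0:
        raise InvalidInputError("observed mean is zero; NRMSE undefined")
    return rmse(series) / mean_obs


def ccc_cb(series: PairedSeries, moments: str = "population"):
    """Pearson r, Lin's concordance correlation coefficient, and the bias
    correction factor Cb = CCC / r.

    CCC = 2·s_op / (s_o² + s_p² + (mean_obs − mean_pred)²); r measures
    precision, Cb accuracy (how far the fit sits from the identity line).
    """
    mo, mp, var_o, var_p, cov_op = _moments(series, moments)
    if var_o == 0 or var_p == 0:
        raise DegenerateInputError("zero variance; correlation undefined")
    r = cov_op / np.sqrt(var_o * var_p)
    ccc = 2.0 * cov_op / (var_o + var_p + (mo - mp) ** 2)
    return float(r), float(ccc), float(ccc / r)


def mse_decomposition(series: PairedSeries, moments: str = "population"):
    """Split MSE into central tendency bias (mean shift), regression bias
    (slope) and disturbance bias (random scatter).

    With population moments the identity CTB + RB + DB = MSE is exact:
    CTB = (mean_pred − mean_obs)², RB = (s_p − r·s_o)², DB = (1 − r²)·s_o².

    Returns ``(ctb, rb, db, (ctb_pct, rb_pct, db_pct))`` with the
    percentages relative to their sum.
    """
    if series.n < 2:
        raise InvalidInputError("need at least 2 pairs for the decomposition")
    mo, mp, var_o, var_p, cov_op = _moments(series, moments)
    ctb = (mp - mo) ** 2
    s_o, s_p = np.sqrt(var_o), np.sqrt(var_p)
    if s_o == 0 or s_p == 0:
        r = 0.0
    else:
        r = cov_op / (s_o * s_p)
    rb = (s_p - r * s_o) ** 2
    db = (1.0 - r**2) * var_o
    total = ctb + rb + db
    if total == 0:
        pcts = (0.0, 0.0, 0.0)
    else:
        pcts = (100.0 * ctb / total, 100.0 * rb / total, 100.0 * db / total)
    return float(ctb), float(rb), float(db), pcts


def residual_correlation(residuals, covariate):
    """Pearson correlation of residuals (obs − pred) with a covariate such
    as days in milk or the rolling herd average, with the two-sided
    p-value from the t distribution on n − 2 df.

    A negative correlation with DIM flags efficiency decline over the
    lactation not captured by the predictor; a positive correlation with
    RHA flags under-adjustment to herd production level.
    """
    residuals = np.asarray(residuals, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if residuals.shape != covariate.shape or residuals.ndim != 1:
        raise InvalidInputError("residuals and covariate must be 1-D of equal length")
    if residuals.size < 3:
        raise InvalidInputError("need at least 3 pairs")
    if residuals.std() == 0 or covariate.std() == 0:
        raise DegenerateInputError("zero variance; correlation undefined")
    res = sps.pearsonr(residuals, covariate)
    return float(res.statistic), float(res.pvalue)


def evaluate(series: PairedSeries, moments: str = "population") -> EvaluationReport:
    """Compute the full metric suite for one prediction set."""
    mo, mp, var_o, var_p, cov_op = _moments(series, moments)
    mse = float(np.mean(series.residuals**2))
    _rmse = float(np.sqrt(mse))
    _nrmse = nrmse(series)
    if var_o == 0 or var_p == 0:
        raise DegenerateInputError("zero variance; agreement metrics undefined")
    r, ccc, cb = ccc_cb(series, moments)
    ctb, rb, db, (ctb_pct, rb_pct, db_pct) = mse_decomposition(series, moments)
    slope = cov_op / var_o            # pred on obs
    intercept = mp - slope * mo
    slope_op = cov_op / var_p         # obs on pred
    intercept_op = mo - slope_op * mp
    return EvaluationReport(
        n=series.n, mean_obs=float(mo), mean_pred=float(mp),
        rmse=_rmse, nrmse=float(_nrmse), mse=mse,
        r=r, ccc=ccc, cb=cb,
        ctb=ctb, rb=rb, db=db,
        ctb_pct=ctb_pct, rb_pct=rb_pct, db_pct=db_pct,
        slope=float(slope), intercept=float(intercept),
        slope_obs_on_pred=float(slope_op), intercept_obs_on_pred=float(intercept_op),
        n_negative_pred=int(np.sum(series.pred < 0)),
    )
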