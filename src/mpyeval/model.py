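"""Model/Results interface for evaluating MPY predictors against data.

:class:`MPYEvaluation` is built from a cow table and a supply table (real
files or the synthetic generator); :meth:`MPYEvaluation.fit` applies the
requested predictors under the requested DMI scenarios and returns an
:class:`MPYEvaluationResults` carrying per-set agreement metrics, per-cow
predictions, residual-covariate correlations, and a ``summary()`` table.

    >>> model = MPYEvaluation.from_synthetic(seed=42)
    >>> results = model.fit()
    >>> print(results.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import metrics, prediction
from .metrics import EvaluationReport, PairedSeries
from .types import InvalidInputError, Scenario

__all__ = ["MPYEvaluation", "MPYEvaluationResults", "PREDICTORS"]

PREDICTORS = ("multi", "eff")

COW_COLUMNS = ["cow_id", "herd_id", "parity", "bw", "dim", "mpy_obs", "rha"]
SUPPLY_COLUMNS = ["cow_id", "scenario", "dmi", "mp_supply", "his", "ile", "leu",
                  "lys", "met", "oaa", "eaa_sq", "de_intake", "de_np", "dndf_kg",
                  "tpuri", "tpfecal_mp", "tpscurf_mp", "tpgrowth_mp"]


@dataclass
class MPYEvaluationResults:
    """Results of one evaluation run.

    ``reports`` maps (scenario, predictor) to an
    :class:`~mpyeval.metrics.EvaluationReport`; ``predictions`` holds one
    row per evaluated cow × scenario with both predictors' values and
    residuals (obs − pred); ``residual_correlations`` maps
    (scenario, predictor, covariate) to (r, p).
    """

    reports: Dict[Tuple[Scenario, str], EvaluationReport]
    predictions: pd.DataFrame
    residual_correlations: Dict[Tuple[Scenario, str, str], Tuple[float, float]]
    n_rha_imputed: Dict[Scenario, int]
    n_excluded: Dict[Scenario, int]
    excluded_ids: Dict[Scenario, List[str]] = field(default_factory=dict)
    rha_adjustment: str = "none"
    rha_multiplier: float = 1.0

    @property
    def n_sets(self) -> int:
        return len(self.reports)

    def metrics_frame(self) -> pd.DataFrame:
        """All metrics, one row per scenario × predictor."""
        rows = []
        for (scenario, predictor), rep in self.reports.items():
            row = {"scenario": scenario.value, "predictor": predictor}
            row.update(rep.to_dict())
            for cov in ("dim", "rha"):
                r, p = self.residual_correlations[(scenario, predictor, cov)]
                row[f"resid_corr_{cov}"] = r
                row[f"resid_corr_{cov}_p"] = p
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable metric table in the style of a model-evaluation
        results section."""
        lines = ["Milk protein yield prediction — evaluation summary",
                 "=" * 78]
        hdr = (f"{'set':<16}{'n':>5}{'obs':>8}{'pred':>8}{'RMSE':>8}"
               f"{'NRMSE%':>8}{'r':>7}{'Cb':>7}{'CCC':>7}"
               f"{'CTB%':>7}{'RB%':>7}{'DB%':>7}")
        lines.append(hdr)
        lines.append("-" * 78)
        for (scenario, predictor), rep in self.reports.items():
            name = f"{scenario.value}/{predictor}"
            lines.append(
                f"{name:<16}{rep.n:>5d}{rep.mean_obs:>8.0f}{rep.mean_pred:>8.0f}"
                f"{rep.rmse:>8.1f}{100 * rep.nrmse:>8.1f}{rep.r:>7.2f}"
                f"{rep.cb:>7.2f}{rep.ccc:>7.2f}"
                f"{rep.ctb_pct:>7.1f}{rep.rb_pct:>7.1f}{rep.db_pct:>7.1f}")
        lines.append("-" * 78)
        lines.append("Residual correlations (obs − pred vs covariate):")
        for (scenario, predictor, cov), (r, p) in self.residual_correlations.items():
            lines.append(f"  {scenario.value}/{predictor} vs {cov.upper():<4}"
                         f" r = {r:+.2f} (p = {p:.3g})")
        for scenario, k in self.n_rha_imputed.items():
            if k:
                lines.append(f"RHA imputed for {k} cows under {scenario.value}")
        for scenario, k in self.n_excluded.items():
            if k:
                lines.append(f"{k} cows excluded under {scenario.value} (no supplies)")
        negs = {f"{s.value}/{p}": rep.n_negative_pred
                for (s, p), rep in self.reports.items() if rep.n_negative_pred}
        if negs:
            lines.append(f"Negative predictions: {negs}")
        return "\n".join(lines)

    def plot_observed_vs_predicted(self, outfile: Optional[str] = None):
        """Observed-vs-predicted scatter per prediction set, with the
        bisector and the overall regression line."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        keys = list(self.reports)
        n = len(keys)
        ncols = min(n, 2)
        nrows = (n + ncols - 1) // ncols
        fig, axes = plt.subplots(nrows, ncols, figsize=(5 * ncols, 4.5 * nrows),
                                 squeeze=False)
        for ax, (scenario, predictor) in zip(axes.ravel(), keys):
            sub = self.predictions[self.predictions["scenario"] == scenario.value]
            pred = sub[f"mpy_{predictor}"].to_numpy()
            obs = sub["mpy_obs"].to_numpy()
            ax.scatter(pred, obs, s=8, alpha=0.5)
            lo, hi = min(pred.min(), obs.min()), max(pred.max(), obs.max())
            ax.plot([lo, hi], [lo, hi], "k-", lw=0.8)
            rep = self.reports[(scenario, predictor)]
            xs = np.array([lo, hi])
            ax.plot(xs, rep.intercept_obs_on_pred + rep.slope_obs_on_pred * xs,
                    "k-", lw=2)
            ax.set_title(f"{scenario.value} / MPY_{predictor}  "
                         f"CCC={rep.ccc:.2f} RMSE={rep.rmse:.0f}")
            ax.set_xlabel("predicted MPY, g/d")
            ax.set_ylabel("observed MPY, g/d")
        for ax in axes.ravel()[n:]:
            ax.set_visible(False)
        fig.tight_layout()
        if outfile:
            fig.savefig(outfile, dpi=120)
            plt.close(fig)
        return fig


class MPYEvaluation:
    """Evaluation model: observed milk protein yields paired with predicted
    nutrient supplies under one or two DMI scenarios.

    Parameters
    ----------
    cows : DataFrame
        Columns ``cow_id, herd_id, parity, bw, dim, mpy_obs, rha``
        (``rha`` may contain NaN for missing records).
    supplies : DataFrame
        Columns ``cow_id, scenario, dmi, mp_supply, his…met, oaa, eaa_sq,
        de_intake, de_np, dndf_kg, tpuri, tpfecal_mp, tpscurf_mp,
        tpgrowth_mp`` keyed by cow × scenario.
    """

    def __init__(self, cows: pd.DataFrame, supplies: pd.DataFrame,
                 target_eff: float = 0.69):
        for col in COW_COLUMNS:
            if col not in cows.columns:
                raise InvalidInputError(f"cow table missing column {col!r}")
        for col in SUPPLY_COLUMNS:
            if col not in supplies.columns:
                raise InvalidInputError(f"supply table missing column {col!r}")
        self.cows = cows.reset_index(drop=True).copy()
        self.supplies = supplies.reset_index(drop=True).copy()
        self.target_eff = float(target_eff)
        self.supplies["scenario"] = [Scenario.parse(s).value
                                     for s in self.supplies["scenario"]]

    # ------------------------------------------------------------------ #
    @classmethod
    def from_tables(cls, cow_path, supply_path, **kwargs) -> "MPYEvaluation":
        """Build from delimited-text cow and supply tables (see
        :mod:`mpyeval.pipeline` for the formats)."""
        from . import pipeline
        cows = pipeline.read_cow_frame(cow_path)
        supplies = pipeline.read_supply_frame(supply_path)
        return cls(cows, supplies, **kwargs)

    @classmethod
    def from_synthetic(cls, config=None, seed: int = 0, **kwargs) -> "MPYEvaluation":
        """Build from the synthetic multi-herd generator."""
        from . import pipeline, simulate
        config = config or simulate.GeneratorConfig()
        herd_set = simulate.generate_herd_set(config, seed)
        return cls.from_herd_set(herd_set, **kwargs)

    @classmethod
    def from_herd_set(cls, herd_set, **kwargs) -> "MPYEvaluation":
        from . import pipeline
        cows, supplies = pipeline.herd_set_to_frames(herd_set)
        kwargs.setdefault("target_eff",
                          herd_set.config.target_eff if herd_set.config else 0.69)
        model = cls(cows, supplies, **kwargs)
        model.herd_set = herd_set
        return model

    # ------------------------------------------------------------------ #
    def available_scenarios(self) -> List[Scenario]:
        return sorted({Scenario(s) for s in self.supplies["scenario"]},
                      key=lambda s: s.value)

    def _merged(self, scenario: Scenario) -> Tuple[pd.DataFrame, List[str]]:
        sup = self.supplies[self.supplies["scenario"] == scenario.value]
        merged = self.cows.merge(sup, on="cow_id", how="inner",
                                 suffixes=("", "_sup"))
        excluded = sorted(set(self.cows["cow_id"]) - set(merged["cow_id"]))
        if merged.empty:
            raise InvalidInputError(
                f"no cows with supplies under scenario {scenario.value}")
        return merged, excluded

    def predict(self, scenario: Scenario, rha_adjustment: str = "none",
                rha_multiplier: float = 1.0) -> pd.DataFrame:
        """Per-cow predictions for one scenario: columns ``mpy_multi``,
        ``ratio``, ``eff``, ``mpy_eff`` plus identity/covariate columns.

        ``rha_adjustment='scalar'`` multiplies the supply-response terms of
        the multivariate equation by (RHA × ``rha_multiplier``) / 280; the
        default leaves the coefficients unadjusted.
        """
        scenario = Scenario.parse(scenario)
        if rha_adjustment not in ("none", "scalar"):
            raise InvalidInputError("rha_adjustment must be 'none' or 'scalar'")
        merged, excluded = self._merged(scenario)

        rha_imputed = np.array([prediction.impute_rha(None if pd.isna(v) else v)
                                for v in merged["rha"]])
        n_imputed = int(merged["rha"].isna().sum())
        if rha_adjustment == "scalar":
            rha_scalar = rha_imputed * rha_multiplier / prediction.RHA_DEFAULT
        else:
            rha_scalar = np.ones(len(merged))

        dndf_pct = prediction.dndf_percent(merged["dndf_kg"].to_numpy(),
                                           merged["dmi"].to_numpy())
        mpy_multi = prediction.predict_mpy_multi(
            None, merged["bw"].to_numpy(), dndf_pct, rha_scalar,
            his=merged["his"].to_numpy(), ile=merged["ile"].to_numpy(),
            leu=merged["leu"].to_numpy(), lys=merged["lys"].to_numpy(),
            met=merged["met"].to_numpy(), oaa=merged["oaa"].to_numpy(),
            eaa_sq=merged["eaa_sq"].to_numpy(), de_np=merged["de_np"].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # negative-ratio stress draws
            ratio = prediction.compute_ratio(
                merged["mp_supply"].to_numpy(), merged["tpuri"].to_numpy(),
                prediction.mcal_to_mj(merged["de_intake"].to_numpy()))
        eff = prediction.predict_efficiency(ratio, merged["dim"].to_numpy())
        mpy_eff = prediction.predict_mpy_eff(
            merged["mp_supply"].to_numpy(), None, eff,
            tpuri=merged["tpuri"].to_numpy(),
            tpfecal_mp=merged["tpfecal_mp"].to_numpy(),
            tpscurf_mp=merged["tpscurf_mp"].to_numpy(),
            tpgrowth_mp=merged["tpgrowth_mp"].to_numpy(),
            target_eff=self.target_eff)

        out = pd.DataFrame({
            "cow_id": merged["cow_id"], "herd_id": merged["herd_id"],
            "scenario": scenario.value, "dim": merged["dim"],
            "rha_imputed": rha_imputed, "mpy_obs": merged["mpy_obs"],
            "mpy_multi": mpy_multi, "ratio": ratio, "eff": eff,
            "mpy_eff": mpy_eff,
            "resid_multi": merged["mpy_obs"].to_numpy() - mpy_multi,
            "resid_eff": merged["mpy_obs"].to_numpy() - mpy_eff,
        })
        out.attrs["n_rha_imputed"] = n_imputed
        out.attrs["excluded_ids"] = excluded
        return out

    def fit(self, scenarios: Optional[Sequence] = None,
            predictors: Sequence[str] = PREDICTORS,
            rha_adjustment: str = "none",
            rha_multiplier: float = 1.0) -> MPYEvaluationResults:
        """Evaluate the requested predictors under the requested scenarios.

        Each scenario × predictor pair yields one agreement report
        (pooled across herds) plus residual correlations with days in
        milk and with the (imputed) rolling herd average.
        """
        scenarios = ([Scenario.parse(s) for s in scenarios]
                     if scenarios is not None else self.available_scenarios())
        predictors = tuple(predictors)
        if not scenarios or not predictors:
            raise InvalidInputError("need at least one scenario and one predictor")
        for p in predictors:
            if p not in PREDICTORS:
                raise InvalidInputError(f"unknown predictor {p!r}")

        reports: Dict[Tuple[Scenario, str], EvaluationReport] = {}
        corrs: Dict[Tuple[Scenario, str, str], Tuple[float, float]] = {}
        n_imputed: Dict[Scenario, int] = {}
        n_excluded: Dict[Scenario, int] = {}
        excluded_ids: Dict[Scenario, List[str]] = {}
        frames = []
        for scenario in scenarios:
            preds = self.predict(scenario, rha_adjustment, rha_multiplier)
            frames.append(preds)
            n_imputed[scenario] = preds.attrs["n_rha_imputed"]
            excluded_ids[scenario] = preds.attrs["excluded_ids"]
            n_excluded[scenario] = len(excluded_ids[scenario])
            for predictor in predictors:
                series = PairedSeries(obs=preds["mpy_obs"].to_numpy(),
                                      pred=preds[f"mpy_{predictor}"].to_numpy(),
                                      labels=list(preds["herd_id"]))
                reports[(scenario, predictor)] = metrics.evaluate(series)
                resid = preds[f"resid_{predictor}"].to_numpy()
                for cov, values in (("dim", preds["dim"].to_numpy()),
                                    ("rha", preds["rha_imputed"].to_numpy())):
                    try:
                        corrs[(scenario, predictor, cov)] = (
                            metrics.residual_correlation(resid, values))
                    except metrics.DegenerateInputError:
                        # e.g. a perfect fit leaves zero-variance residuals
                        corrs[(scenario, predictor, cov)] = (np.nan, np.nan)
        predictions = pd.concat(frames, ignore_index=True)
        return MPYEvaluationResults(
            reports=reports, predictions=predictions,
            residual_correlations=corrs, n_rha_imputed=n_imputed,
            n_excluded=n_excluded, excluded_ids=excluded_ids,
            rha_adjustment=rha_adjustment, rha_multiplier=rha_multiplier)
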