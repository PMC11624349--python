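"""End-to-end orchestration and file formats.

Reads delimited-text cow and supply tables (comma or tab, auto-detected
from the header line), runs the 2 predictors × up-to-2 DMI scenarios
evaluation, the rolling-herd-average sensitivity analysis, and writes
metric/prediction/log files. The exchange formats are plain CSV/TSV —
the lingua franca of on-farm nutrition work.

Cow table columns
    ``cow_id, herd_id, parity, bw_kg, dim_d, mpy_obs_g_d`` and optional
    ``rha_kg_305d`` (empty cell = missing, imputed downstream).

Supply table columns (one row per cow × scenario)
    ``cow_id, scenario, dmi, mp_supply, his, ile, leu, lys, met, oaa,
    de_intake, de_np, dndf_kg, tpuri, tpfecal_mp, tpscurf_mp,
    tpgrowth_mp`` and optional ``eaa_sq`` (computed when absent).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import MPYEvaluation, MPYEvaluationResults, PREDICTORS
from .simulate import GeneratorConfig, SyntheticHerdSet
from .types import (CowRecord, ExpenditureProfile, InvalidInputError, Scenario,
                    SupplyProfile)

__all__ = [
    "FormatError",
    "RunConfig",
    "RunReport",
    "read_cow_frame",
    "read_supply_frame",
    "read_cow_table",
    "read_supply_table",
    "write_cow_table",
    "write_supply_table",
    "herd_set_to_frames",
    "run_pipeline",
    "rha_sensitivity",
    "write_report",
]

logger = logging.getLogger("mpyeval")

COW_FILE_COLUMNS = {"cow_id": "cow_id", "herd_id": "herd_id",
                    "parity": "parity", "bw_kg": "bw", "dim_d": "dim",
                    "mpy_obs_g_d": "mpy_obs"}
COW_OPTIONAL = {"rha_kg_305d": "rha"}
SUPPLY_FILE_COLUMNS = ["cow_id", "scenario", "dmi", "mp_supply", "his", "ile",
                       "leu", "lys", "met", "oaa", "de_intake", "de_np",
                       "dndf_kg", "tpuri", "tpfecal_mp", "tpscurf_mp",
                       "tpgrowth_mp"]


class FormatError(InvalidInputError):
    """Malformed input table."""


# --------------------------------------------------------------------- #
# reading

def _detect_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _numeric(frame: pd.DataFrame, columns: Sequence[str], path) -> pd.DataFrame:
    for col in columns:
        # float() is correctly rounded, so written tables re-read exactly
        values = []
        for idx, raw in frame[col].items():
            if pd.isna(raw) or str(raw).strip() == "":
                values.append(np.nan)
                continue
            try:
                values.append(float(raw))
            except ValueError:
                # +2: one for the header line, one for 0- vs 1-based
                raise FormatError(f"{path}: non-numeric value {raw!r} in "
                                  f"column {col!r} at line {int(idx) + 2}") from None
        frame[col] = values
    return frame


def read_cow_frame(path) -> pd.DataFrame:
    """Read a cow table into the model's internal frame layout."""
    frame = pd.read_csv(path, sep=_detect_sep(path), dtype=str,
                        skipinitialspace=True)
    missing = [c for c in COW_FILE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    keep = dict(COW_FILE_COLUMNS)
    for col, name in COW_OPTIONAL.items():
        if col in frame.columns:
            keep[col] = name
    frame = frame[list(keep)].rename(columns=keep)
    frame = _numeric(frame, [c for c in frame.columns
                             if c not in ("cow_id", "herd_id")], path)
    if "rha" not in frame.columns:
        frame["rha"] = np.nan
    return frame


def read_supply_frame(path) -> pd.DataFrame:
    """Read a supply/expenditure table into the internal frame layout;
    ``eaa_sq`` is computed from the five EAA columns when absent."""
    frame = pd.read_csv(path, sep=_detect_sep(path), dtype=str,
                        skipinitialspace=True)
    missing = [c for c in SUPPLY_FILE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    cols = list(SUPPLY_FILE_COLUMNS) + (["eaa_sq"] if "eaa_sq" in frame.columns else [])
    frame = frame[cols]
    frame = _numeric(frame, [c for c in cols if c not in ("cow_id", "scenario")], path)
    frame["scenario"] = [Scenario.parse(s).value for s in frame["scenario"]]
    if "eaa_sq" not in frame.columns:
        frame["eaa_sq"] = np.nan
    computed = (frame["his"]**2 + frame["ile"]**2 + frame["leu"]**2
                + frame["lys"]**2 + frame["met"]**2)
    frame["eaa_sq"] = frame["eaa_sq"].fillna(computed)
    return frame


def read_cow_table(path) -> List[CowRecord]:
    """Read and validate a cow table as typed records."""
    frame = read_cow_frame(path)
    records = []
    for _, row in frame.iterrows():
        records.append(CowRecord(
            cow_id=str(row["cow_id"]), herd_id=str(row["herd_id"]),
            parity=int(row["parity"]), bw=float(row["bw"]),
            dim=float(row["dim"]), mpy_obs=float(row["mpy_obs"]),
            rha=None if pd.isna(row["rha"]) else float(row["rha"])))
    return records


def read_supply_table(path, target_eff: float = 0.69,
                      ) -> Dict[Tuple[str, Scenario],
                                Tuple[SupplyProfile, ExpenditureProfile]]:
    """Read and validate a supply table as typed profiles keyed by
    (cow_id, scenario)."""
    frame = read_supply_frame(path)
    out = {}
    for _, row in frame.iterrows():
        scenario = Scenario(row["scenario"])
        supply = SupplyProfile(
            scenario=scenario, dmi=row["dmi"], mp_supply=row["mp_supply"],
            his=row["his"], ile=row["ile"], leu=row["leu"], lys=row["lys"],
            met=row["met"], oaa=row["oaa"], de_intake=row["de_intake"],
            de_np=row["de_np"], dndf_kg=row["dndf_kg"], eaa_sq=row["eaa_sq"])
        exp = ExpenditureProfile(
            tpuri=row["tpuri"], tpfecal_mp=row["tpfecal_mp"],
            tpscurf_mp=row["tpscurf_mp"], tpgrowth_mp=row["tpgrowth_mp"],
            target_eff=target_eff)
        out[(str(row["cow_id"]), scenario)] = (supply, exp)
    return out


# --------------------------------------------------------------------- #
# writing

def write_cow_table(cows, path) -> None:
    """Write cow records (or an internal cow frame) as CSV."""
    if isinstance(cows, pd.DataFrame):
        frame = cows.copy()
    else:
        frame = pd.DataFrame([{
            "cow_id": c.cow_id, "herd_id": c.herd_id, "parity": c.parity,
            "bw": c.bw, "dim": c.dim, "mpy_obs": c.mpy_obs, "rha": c.rha,
        } for c in cows])
    inv = {v: k for k, v in {**COW_FILE_COLUMNS, **COW_OPTIONAL}.items()}
    frame = frame.rename(columns=inv)
    frame.to_csv(path, index=False)


def write_supply_table(supplies_frame: pd.DataFrame, path) -> None:
    cols = SUPPLY_FILE_COLUMNS + ["eaa_sq"]
    supplies_frame[cols].to_csv(path, index=False)


def herd_set_to_frames(herd_set: SyntheticHerdSet) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a synthetic herd set into the cow and supply frames the
    evaluation model consumes."""
    cows = pd.DataFrame([{
        "cow_id": c.cow_id, "herd_id": c.herd_id, "parity": c.parity,
        "bw": c.bw, "dim": c.dim, "mpy_obs": c.mpy_obs,
        "rha": np.nan if c.rha is None else c.rha,
    } for c in herd_set.cows])
    rows = []
    for (cow_id, scenario), sup in herd_set.supplies.items():
        exp = herd_set.expenditures[(cow_id, scenario)]
        rows.append({
            "cow_id": cow_id, "scenario": scenario.value, "dmi": sup.dmi,
            "mp_supply": sup.mp_supply, "his": sup.his, "ile": sup.ile,
            "leu": sup.leu, "lys": sup.lys, "met": sup.met, "oaa": sup.oaa,
            "eaa_sq": sup.eaa_sq, "de_intake": sup.de_intake,
            "de_np": sup.de_np, "dndf_kg": sup.dndf_kg, "tpuri": exp.tpuri,
            "tpfecal_mp": exp.tpfecal_mp, "tpscurf_mp": exp.tpscurf_mp,
            "tpgrowth_mp": exp.tpgrowth_mp,
        })
    return cows, pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# orchestration

@dataclass
class RunConfig:
    """One evaluation run: inputs (files or generator), which scenario ×
    predictor combinations to evaluate, RHA handling, and outputs."""

    cow_table: Optional[str] = None
    supply_table: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    scenarios: Sequence[str] = (Scenario.DMI_Ao.value, Scenario.DMI_AR.value)
    predictors: Sequence[str] = PREDICTORS
    rha_adjustment: str = "none"
    rha_delta: float = 0.15
    outdir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scenarios or not self.predictors:
            raise InvalidInputError("need at least one scenario and one predictor")
        if not 0 <= self.rha_delta < 1:
            raise InvalidInputError("rha_delta must be in [0, 1)")
        if self.rha_adjustment not in ("none", "scalar"):
            raise InvalidInputError("rha_adjustment must be 'none' or 'scalar'")

    def build_model(self) -> MPYEvaluation:
        if self.cow_table and self.supply_table:
            return MPYEvaluation.from_tables(self.cow_table, self.supply_table)
        config = self.generator or GeneratorConfig()
        return MPYEvaluation.from_synthetic(config=config, seed=self.seed)


@dataclass
class RunReport:
    """Evaluation results plus the RHA sensitivity table."""

    results: MPYEvaluationResults
    sensitivity: Optional[pd.DataFrame] = None

    def summary(self) -> str:
        text = self.results.summary()
        if self.sensitivity is not None:
            text += "\n\nRHA sensitivity (NRMSE % of observed mean, MPY_multi):\n"
            text += self.sensitivity.to_string(index=False)
        return text


def run_pipeline(config: RunConfig) -> RunReport:
    """Read (or generate) the inputs, evaluate every requested scenario ×
    predictor pair, run the RHA sensitivity analysis, and optionally write
    the report files. Deterministic given inputs + config."""
    model = config.build_model()
    results = model.fit(scenarios=config.scenarios,
                        predictors=config.predictors,
                        rha_adjustment=config.rha_adjustment)
    for scenario, k in results.n_rha_imputed.items():
        if k:
            logger.info("imputed RHA for %d cows (%s)", k, scenario.value)
    for scenario, ids in results.excluded_ids.items():
        if ids:
            logger.warning("excluded %d cows without supplies (%s): %s",
                           len(ids), scenario.value, ", ".join(ids[:10]))
    sens = rha_sensitivity_from_model(model, config)
    report = RunReport(results=results, sensitivity=sens)
    if config.outdir:
        write_report(report, config.outdir)
    return report


def rha_sensitivity_from_model(model: MPYEvaluation, config: RunConfig) -> pd.DataFrame:
    """NRMSE (percentage points) of the multivariate predictor when every
    cow's RHA is scaled by 1−δ, 1, 1+δ.

    With ``rha_adjustment='none'`` the equation ignores RHA, the three
    columns are identical, and the table records the no-op."""
    delta = config.rha_delta
    rows = []
    for scenario in [Scenario.parse(s) for s in config.scenarios]:
        row = {"scenario": scenario.value, "rha_adjustment": config.rha_adjustment}
        for mult, label in [(1 - delta, f"nrmse_pct_rha_x{1 - delta:g}"),
                            (1.0, "nrmse_pct_rha_x1"),
                            (1 + delta, f"nrmse_pct_rha_x{1 + delta:g}")]:
            res = model.fit(scenarios=[scenario], predictors=["multi"],
                            rha_adjustment=config.rha_adjustment,
                            rha_multiplier=mult)
            row[label] = 100.0 * res.reports[(scenario, "multi")].nrmse
        cols = [c for c in row if c.startswith("nrmse")]
        row["max_abs_delta_pct"] = max(abs(row[c] - row["nrmse_pct_rha_x1"])
                                       for c in cols)
        rows.append(row)
    return pd.DataFrame(rows)


def rha_sensitivity(config: RunConfig, delta: Optional[float] = None) -> pd.DataFrame:
    """Standalone entry point for the RHA sensitivity analysis."""
    if delta is not None:
        config = dataclasses.replace(config, rha_delta=delta)
    return rha_sensitivity_from_model(config.build_model(), config)


def write_report(report: RunReport, outdir) -> None:
    """Write metrics, per-cow predictions, sensitivity table, a summary
    and the imputation/exclusion log under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.results.metrics_frame().to_csv(out / "metrics.csv", index=False)
    report.results.predictions.to_csv(out / "predictions.csv", index=False)
    if report.sensitivity is not None:
        report.sensitivity.to_csv(out / "rha_sensitivity.csv", index=False)
    (out / "summary.txt").write_text(report.summary() + "\n")
    log_lines = []
    for scenario, k in report.results.n_rha_imputed.items():
        log_lines.append(f"rha_imputed\t{scenario.value}\t{k}")
    for scenario, ids in report.results.excluded_ids.items():
        log_lines.append(f"excluded\t{scenario.value}\t{len(ids)}\t{';'.join(ids)}")
    for (scenario, predictor), rep in report.results.reports.items():
        log_lines.append(f"negative_predictions\t{scenario.value}\t{predictor}"
                         f"\t{rep.n_negative_pred}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
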