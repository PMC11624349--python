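"""Milk protein yield (MPY) predictors.

Two predictors are implemented, both operating on nutrient supplies
estimated by a NASEM-style feed evaluation run (the supply sub-model itself
is out of scope; supplies arrive as inputs):

* the **multivariate equation** — an empirical regression of MPY on the
  digested flows of the five most-limiting essential amino acids (His, Ile,
  Leu, Lys, Met), the grouped remaining amino acids (OAA), the sum of
  squared EAA flows, non-protein digestible energy intake, digestible NDF
  concentration and body weight;

* the **variable-efficiency equation** — MPY derived from a predicted
  efficiency of metabolizable protein (MP) utilization, itself a quadratic
  in the ratio of (MP supply − urinary endogenous loss) to digestible
  energy intake, declining with days in milk.

All functions accept scalars or NumPy arrays and broadcast elementwise.
Predictions are never clamped: negative values are returned as-is so that
downstream agreement statistics stay unbiased (callers count negatives).
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import ExpenditureProfile, InvalidInputError, SupplyProfile

__all__ = [
    "RHA_DEFAULT",
    "MCAL_TO_MJ",
    "impute_rha",
    "dndf_percent",
    "mcal_to_mj",
    "predict_mpy_multi",
    "compute_ratio",
    "predict_efficiency",
    "tp_from_mp",
    "predict_mpy_eff",
    "predict_cow",
]

#: Rolling herd average substituted when a cow has no DHI record, kg/305 d.
RHA_DEFAULT = 280.0

#: Thermochemical calorie conversion, MJ per Mcal.
MCAL_TO_MJ = 4.184

# Multivariate equation coefficients (response g MPY/d).
_MULTI_INTERCEPT = -97.0
_COEF_HIS = 1.68
_COEF_ILE = 0.885
_COEF_LEU = 0.466
_COEF_LYS = 1.15
_COEF_MET = 1.84
_COEF_OAA = 0.077
_COEF_EAASQ = -0.00215
_COEF_DEINP = 10.8
_COEF_DNDF = -4.6
_DNDF_CENTER = 17.06   # % of DM
_COEF_BW = -0.42
_BW_CENTER = 612.0     # kg

# Variable-efficiency equation coefficients (response %).
_EFF_INTERCEPT = 176.0
_EFF_RATIO = -21.2
_EFF_RATIO_SQ = 0.87
_EFF_DIM = -0.041


def _check_finite(**kwargs: object) -> None:
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(f"{name} must be finite, got {value}")


def impute_rha(rha: float | None) -> float:
    """Return the rolling herd average, substituting the standard default
    of 280 kg protein/305 d when the record is missing.

    Raises :class:`InvalidInputError` for a non-positive value.
    """
    if rha is None:
        return RHA_DEFAULT
    if not np.isfinite(rha) or rha <= 0:
        raise InvalidInputError(f"rha must be > 0 when present, got {rha}")
    return float(rha)


def dndf_percent(dndf_kg, dmi):
    """Digestible NDF concentration, % of dietary DM, from the daily
    digestible NDF flow (kg/d) and dry matter intake (kg/d)."""
    dndf_kg = np.asarray(dndf_kg, dtype=float)
    dmi = np.asarray(dmi, dtype=float)
    if np.any(dmi <= 0):
        raise InvalidInputError("dmi must be > 0")
    if np.any(dndf_kg < 0):
        raise InvalidInputError("dndf_kg must be >= 0")
    out = 100.0 * dndf_kg / dmi
    return float(out) if out.ndim == 0 else out


def mcal_to_mj(x):
    """Convert Mcal to MJ at exactly 4.184 MJ/Mcal."""
    x = np.asarray(x, dtype=float)
    out = MCAL_TO_MJ * x
    return float(out) if out.ndim == 0 else out


def predict_mpy_multi(supply: SupplyProfile | None, bw, dndf_pct=None,
                      rha_scalar=1.0, *, his=None, ile=None, leu=None,
                      lys=None, met=None, oaa=None, eaa_sq=None, de_np=None):
    """Milk protein yield (g/d) from the multivariate supply/BW equation.

    Parameters
    ----------
    supply
        A :class:`SupplyProfile`; alternatively pass the individual flows
        as keyword arrays (``his`` … ``de_np``) for vectorized use.
    bw
        Body weight, kg.
    dndf_pct
        Digestible NDF as % of dietary DM (derived from the profile's
        kg/d flow and DMI when a profile is given and this is None).
    rha_scalar
        Multiplicative adjustment applied to the supply-response terms
        (the five EAA, OAA and DEInp terms). The default 1 means no
        herd-average adjustment; see :mod:`mpyeval.pipeline` for the
        optional rha/280 scaling hook.

    Predictions may be negative; no clamping is applied.
    """
    if supply is not None:
        his, ile, leu, lys, met = supply.his, supply.ile, supply.leu, supply.lys, supply.met
        oaa, eaa_sq, de_np = supply.oaa, supply.eaa_sq, supply.de_np
        if dndf_pct is None:
            dndf_pct = dndf_percent(supply.dndf_kg, supply.dmi)
    if dndf_pct is None:
        raise InvalidInputError("dndf_pct is required when no SupplyProfile is given")
    _check_finite(his=his, ile=ile, leu=leu, lys=lys, met=met, oaa=oaa,
                  eaa_sq=eaa_sq, de_np=de_np, bw=bw, dndf_pct=dndf_pct,
                  rha_scalar=rha_scalar)
    rha_scalar = np.asarray(rha_scalar, dtype=float)
    if np.any(rha_scalar <= 0):
        raise InvalidInputError("rha_scalar must be > 0")
    supply_terms = (_COEF_HIS * np.asarray(his, float)
                    + _COEF_ILE * np.asarray(ile, float)
                    + _COEF_LEU * np.asarray(leu, float)
                    + _COEF_LYS * np.asarray(lys, float)
                    + _COEF_MET * np.asarray(met, float)
                    + _COEF_OAA * np.asarray(oaa, float)
                    + _COEF_DEINP * np.asarray(de_np, float))
    out = (_MULTI_INTERCEPT
           + rha_scalar * supply_terms
           + _COEF_EAASQ * np.asarray(eaa_sq, float)
           + _COEF_DNDF * (np.asarray(dndf_pct, float) - _DNDF_CENTER)
           + _COEF_BW * (np.asarray(bw, float) - _BW_CENTER))
    return float(out) if out.ndim == 0 else out


def compute_ratio(mp_supply, tpuri, de_mj):
    """Energy-normalized net MP supply, g/MJ:
    (MP supply − urinary endogenous MP loss) / DE intake.

    A supply below the urinary endogenous loss is physiologically odd but
    tolerated with a warning (stress inputs), yielding a negative ratio.
    """
    mp_supply = np.asarray(mp_supply, dtype=float)
    tpuri = np.asarray(tpuri, dtype=float)
    de_mj = np.asarray(de_mj, dtype=float)
    _check_finite(mp_supply=mp_supply, tpuri=tpuri, de_mj=de_mj)
    if np.any(de_mj <= 0):
        raise InvalidInputError("de_mj must be > 0")
    if np.any(mp_supply < tpuri):
        warnings.warn("MP supply below urinary endogenous loss; ratio is negative",
                      stacklevel=2)
    out = (mp_supply - tpuri) / de_mj
    return float(out) if out.ndim == 0 else out


def predict_efficiency(ratio, dim):
    """Predicted efficiency of MP utilization, %, as a convex quadratic in
    the supply/energy ratio with a linear decline over days in milk."""
    ratio = np.asarray(ratio, dtype=float)
    dim = np.asarray(dim, dtype=float)
    _check_finite(ratio=ratio, dim=dim)
    out = (_EFF_INTERCEPT + _EFF_RATIO * ratio + _EFF_RATIO_SQ * ratio**2
           + _EFF_DIM * dim)
    return float(out) if out.ndim == 0 else out


def tp_from_mp(exp_mp, target_eff=0.69):
    """True-protein flow corresponding to an MP-basis expenditure, g/d:
    the expenditure times the target efficiency of utilization."""
    exp_mp = np.asarray(exp_mp, dtype=float)
    if np.any(exp_mp < 0):
        raise InvalidInputError("exp_mp must be >= 0")
    if not (0 < target_eff <= 1):
        raise InvalidInputError(f"target_eff must be in (0, 1], got {target_eff}")
    out = exp_mp * target_eff
    return float(out) if out.ndim == 0 else out


def predict_mpy_eff(mp_supply, exp: ExpenditureProfile, eff, *,
                    tpuri=None, tpfecal_mp=None, tpscurf_mp=None,
                    tpgrowth_mp=None, target_eff=None):
    """Milk protein yield (g/d) through the variable efficiency:

        MPY = (MP supply − TPuri) · Eff/100 − (TPfecal + TPscurf + TPgrowth)

    where the three export expenditures are converted from their MP basis
    to true protein via the target efficiency. ``exp`` may be an
    :class:`ExpenditureProfile` or None with the flows passed as keyword
    arrays. Predictions may be negative; no clamping is applied.
    """
    if exp is not None:
        tpuri, tpfecal_mp = exp.tpuri, exp.tpfecal_mp
        tpscurf_mp, tpgrowth_mp = exp.tpscurf_mp, exp.tpgrowth_mp
        target_eff = exp.target_eff
    if target_eff is None:
        target_eff = 0.69
    _check_finite(mp_supply=mp_supply, eff=eff, tpuri=tpuri,
                  tpfecal_mp=tpfecal_mp, tpscurf_mp=tpscurf_mp,
                  tpgrowth_mp=tpgrowth_mp)
    exports_tp = (tp_from_mp(tpfecal_mp, target_eff)
                  + tp_from_mp(tpscurf_mp, target_eff)
                  + tp_from_mp(tpgrowth_mp, target_eff))
    out = ((np.asarray(mp_supply, float) - np.asarray(tpuri, float))
           * np.asarray(eff, float) / 100.0 - exports_tp)
    return float(out) if out.ndim == 0 else out


def predict_cow(cow_id: str, supply: SupplyProfile, exp: ExpenditureProfile,
                bw: float, dim: float, rha_scalar: float = 1.0):
    """Run both predictors for one cow × scenario; returns a
    :class:`~mpyeval.types.PredictionResult`."""
    from .types import PredictionResult

    mpy_multi = predict_mpy_multi(supply, bw, rha_scalar=rha_scalar)
    ratio = compute_ratio(supply.mp_supply, exp.tpuri, mcal_to_mj(supply.de_intake))
    eff = predict_efficiency(ratio, dim)
    mpy_eff = predict_mpy_eff(supply.mp_supply, exp, eff)
    return PredictionResult(cow_id=cow_id, scenario=supply.scenario,
                            mpy_multi=mpy_multi, eff=eff, ratio=ratio,
                            mpy_eff=mpy_eff)
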