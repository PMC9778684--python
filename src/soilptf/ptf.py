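"""Pedotransfer functions for antibiotic sorption coefficients.

A pedotransfer function (PTF) here is a multiple linear regression that
maps readily measured soil properties — and optionally species fractions
and batch-experiment conditions — to a sorption affinity coefficient
(Freundlich Kf or linear Kd) of one antibiotic.  The module ships three
built-in coefficient collections:

* ``table4`` — the 14 main PTFs (one Kf and one Kd model per antibiotic)
  using edaphic predictors only (OC, pH, CEC, sand/silt/clay);
* ``table5`` — 8 improved models that add non-edaphic predictors:
  species fractions (alpha_plus/zero/minus, entered as fractions in
  [0, 1]), solid/liquid ratio SLR (kg/L) and maximal initial
  concentration Cimax (mg/L);
* ``table6`` — 4 previously published regional models used as
  comparators.  The OTC comparator regresses on 1/CEC with CEC in
  cmol kg^-1 (its source reports CEC in that unit); the set carries a
  ``cec_unit`` annotation and ``predict`` converts from the package's
  canonical mmol kg^-1 automatically.

It also provides the machinery to fit new PTFs (ordinary least squares
with intercept, adjusted r^2 and coefficient t-tests) and a greedy
forward-selection wrapper.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

from .compounds import get_compound, species_fractions
from .dataset import SoilSample, SorptionRecord
from .exceptions import InputError, UnknownModelError

__all__ = [
    "PREDICTOR_NAMES",
    "TRAINING_RANGES",
    "CoefficientSet",
    "PredictionResult",
    "FitResult",
    "builtin_models",
    "get_builtin_model",
    "predict",
    "fit_mlr",
    "forward_select",
    "coefficient_sets_to_json",
    "coefficient_sets_from_json",
]

#: Closed vocabulary of predictor names.  ``CEC_inv`` (1/CEC) appears only
#: in one published comparator model.
PREDICTOR_NAMES = (
    "OC", "pH", "CEC", "Sand", "Silt", "Clay", "SLR", "Cimax",
    "alpha_plus", "alpha_zero", "alpha_minus", "CEC_inv",
)

#: Property ranges of the training dataset, used for the extrapolation
#: flag: pH 2.75-9.40, OC 0.1-21.3 %, CEC 3.40-740 mmol/kg.
TRAINING_RANGES: Dict[str, Tuple[float, float]] = {
    "pH": (2.75, 9.40),
    "OC": (0.1, 21.3),
    "CEC": (3.40, 740.00),
}


@dataclass(frozen=True)
class CoefficientSet:
    """One pedotransfer function: intercept plus named linear terms."""

    antibiotic: str
    response: str  # "Kf" or "Kd"
    intercept: float
    terms: Mapping[str, float]
    provenance: str = "fitted"
    r2: Optional[float] = None
    n_obs: Optional[int] = None
    cec_unit: str = "mmol_kg"  # unit the CEC/CEC_inv terms expect

    def __post_init__(self):
        if self.response not in ("Kf", "Kd"):
            raise InputError(f"response must be 'Kf' or 'Kd', got {self.response!r}")
        if not self.terms:
            raise InputError("a coefficient set needs at least one term")
        unknown = set(self.terms) - set(PREDICTOR_NAMES)
        if unknown:
            raise InputError(f"unknown predictor name(s) {sorted(unknown)}; "
                             f"valid: {PREDICTOR_NAMES}")
        if self.cec_unit not in ("mmol_kg", "cmol_kg"):
            raise InputError(f"cec_unit must be 'mmol_kg' or 'cmol_kg', got {self.cec_unit!r}")
        object.__setattr__(self, "terms", dict(self.terms))

    def equation(self) -> str:
        """Human-readable equation, e.g. ``Kf = 4.198 + 1.666*OC - 0.735*pH``."""
        parts = [f"{self.response} = {self.intercept:g}"]
        for name, coef in self.terms.items():
            sign = "-" if coef < 0 else "+"
            parts.append(f"{sign} {abs(coef):g}*{name}")
        return " ".join(parts)

    def to_dict(self) -> dict:
        return {
            "antibiotic": self.antibiotic, "response": self.response,
            "provenance": self.provenance, "intercept": self.intercept,
            "terms": dict(self.terms), "r2": self.r2, "n_obs": self.n_obs,
            "cec_unit": self.cec_unit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientSet":
        return cls(
            antibiotic=d["antibiotic"], response=d["response"],
            intercept=d["intercept"], terms=d["terms"],
            provenance=d.get("provenance", "fitted"), r2=d.get("r2"),
            n_obs=d.get("n_obs"), cec_unit=d.get("cec_unit", "mmol_kg"),
        )


@dataclass(frozen=True)
class PredictionResult:
    """Raw PTF prediction plus advisory flags.

    ``negative_prediction`` marks a raw value below zero (never clamped
    here — a sorption coefficient cannot be negative, so downstream users
    decide how to floor it).  ``extrapolation:<name>`` marks a predictor
    outside the training ranges.
    """

    value: float
    flags: Tuple[str, ...] = ()


def _t4(ab, resp, intercept, terms, r2, n_obs):
    return CoefficientSet(ab, resp, intercept, terms, "table4", r2, n_obs)


_TABLE4 = [
    _t4("SCP", "Kf", 4.198, {"OC": 1.666, "pH": -0.735}, 0.616, 68),
    _t4("SCP", "Kd", 2.769, {"OC": 1.668, "pH": -0.689}, 0.689, 80),
    _t4("SMT", "Kf", 0.820, {"OC": 0.818}, 0.565, 107),
    _t4("SMT", "Kd", 0.099, {"OC": 0.789}, 0.510, 114),
    _t4("SDZ", "Kf", 1.951, {"OC": 0.239, "Sand": -0.018}, 0.380, 53),
    _t4("SDZ", "Kd", -0.480, {"OC": 0.484, "pH": 0.201}, 0.507, 83),
    _t4("SMX", "Kf", 4.717, {"OC": 0.464, "pH": -0.565, "CEC": 0.006, "Silt": -0.027}, 0.666, 49),
    _t4("SMX", "Kd", 3.208, {"OC": 0.519, "pH": -0.457}, 0.525, 57),
    _t4("OTC", "Kf", 4428.177, {"OC": 330.323, "pH": -543.318}, 0.606, 104),
    _t4("OTC", "Kd", 182.875, {"OC": 239.030}, 0.444, 94),
    _t4("TC", "Kf", 2740.451, {"OC": 215.512, "pH": -363.881, "CEC": 3.331}, 0.509, 84),
    _t4("TC", "Kd", 274.636, {"CEC": 1.151, "Sand": -5.607, "Clay": 14.741}, 0.607, 67),
    _t4("CTC", "Kf", 2345.591, {"OC": 1205.573, "pH": -281.455}, 0.524, 73),
    _t4("CTC", "Kd", -588.94, {"OC": 561.887, "Clay": 38.582}, 0.371, 72),
]

_TABLE5 = [
    CoefficientSet("SCP", "Kf", -0.807, {"OC": 1.657, "alpha_zero": 2.023}, "table5", 0.619),
    CoefficientSet("SCP", "Kd", -1.149, {"OC": 1.657, "alpha_plus": 183.089}, "table5", 0.695),
    CoefficientSet("SDZ", "Kd", 0.980, {"OC": 0.398, "Clay": 0.200, "alpha_zero": -0.949}, "table5", 0.579),
    CoefficientSet("SMX", "Kd", 1.652, {"OC": 0.485, "alpha_minus": -1.91}, "table5", 0.552),
    CoefficientSet("OTC", "Kf", 4595.375,
                   {"pH": -701.271, "OC": 397.550, "SLR": 16589.89, "alpha_minus": 5204.082},
                   "table5", 0.647),
    CoefficientSet("TC", "Kf", 2863.937, {"OC": 288.648, "pH": -265.391, "SLR": -20202.101},
                   "table5", 0.545),
    CoefficientSet("TC", "Kd", 325.965,
                   {"OC": 51.147, "Sand": -6.099, "Clay": 15.714, "alpha_plus": -1058.792},
                   "table5", 0.633),
    CoefficientSet("CTC", "Kf", -256.377, {"OC": 1219.651, "Cimax": 6.639}, "table5", 0.549),
]

_TABLE6 = [
    CoefficientSet("SCP", "Kf", 8.810, {"OC": 1.967, "pH": -2.028}, "table6", 0.829, 50),
    CoefficientSet("SMT", "Kd", 0.38, {"OC": 0.81}, "table6", 0.92, 5),
    CoefficientSet("SDZ", "Kf", 3.493, {"OC": 0.780, "pH": -0.819}, "table6", 0.675, 50),
    # Published OTC comparator: regresses on 1/CEC with CEC in cmol/kg.
    CoefficientSet("OTC", "Kf", 96.924, {"OC": 701.607, "CEC_inv": 8118.902}, "table6",
                   0.349, 63, cec_unit="cmol_kg"),
]

_BUILTIN = {"table4": _TABLE4, "table5": _TABLE5, "table6": _TABLE6}


def builtin_models(provenance: str) -> List[CoefficientSet]:
    """All built-in coefficient sets of one collection (table4/table5/table6)."""
    try:
        return list(_BUILTIN[provenance])
    except KeyError:
        raise UnknownModelError(
            f"unknown provenance {provenance!r}; valid: {', '.join(_BUILTIN)}"
        ) from None


def get_builtin_model(provenance: str, antibiotic: str, response: str) -> CoefficientSet:
    """Look up one built-in model by collection, antibiotic and response."""
    antibiotic = antibiotic.strip().upper()
    for m in builtin_models(provenance):
        if m.antibiotic == antibiotic and m.response == response:
            return m
    raise UnknownModelError(
        f"no {provenance} model for {antibiotic}/{response}; available: "
        + ", ".join(f"{m.antibiotic}/{m.response}" for m in builtin_models(provenance))
    )


def _resolve_predictor(name: str, model: CoefficientSet, soil: SoilSample,
                       compound, conditions: Optional[dict]) -> float:
    conditions = conditions or {}
    if name == "pH":
        return soil.pH
    if name in ("OC", "CEC", "Sand", "Silt", "Clay"):
        attr = {"OC": "OC", "CEC": "CEC", "Sand": "sand", "Silt": "silt", "Clay": "clay"}[name]
        value = getattr(soil, attr)
        if value is None:
            raise InputError(f"model needs soil predictor {name!r} but it is missing")
        if name == "CEC" and model.cec_unit == "cmol_kg":
            value = value / 10.0  # canonical mmol/kg -> the model's cmol/kg
        return value
    if name == "CEC_inv":
        cec = _resolve_predictor("CEC", model, soil, compound, conditions)
        if cec == 0:
            raise InputError("CEC is zero; 1/CEC predictor undefined")
        return 1.0 / cec
    if name in ("alpha_plus", "alpha_zero", "alpha_minus"):
        if compound is None:
            compound = get_compound(model.antibiotic)
        return getattr(species_fractions(compound, soil.pH), name)
    if name in ("SLR", "Cimax"):
        key = {"SLR": "slr", "Cimax": "cimax"}[name]
        value = conditions.get(key)
        if value is None:
            raise InputError(f"model needs experiment condition {name!r} "
                             f"(pass conditions={{'{key}': ...}})")
        return float(value)
    raise InputError(f"unknown predictor {name!r}")  # pragma: no cover


def predict(model: CoefficientSet, soil: SoilSample, compound=None,
            conditions: Optional[dict] = None) -> PredictionResult:
    """Evaluate a pedotransfer function for one soil.

    Species-fraction terms are computed from the compound's pKa ladder at
    the soil's pH; SLR (kg/L) and Cimax (mg/L) come from ``conditions``.
    The raw regression value is always returned; a negative value is
    flagged, never clamped, and predictors outside the training ranges
    raise an ``extrapolation:<name>`` flag.
    """
    flags: List[str] = []
    value = model.intercept
    for name, coef in model.terms.items():
        x = _resolve_predictor(name, model, soil, compound, conditions)
        value += coef * x
        check = "CEC" if name == "CEC_inv" else name
        if check in TRAINING_RANGES:
            raw = 1.0 / x if name == "CEC_inv" else x
            if check == "CEC" and model.cec_unit == "cmol_kg":
                raw *= 10.0  # back to canonical mmol/kg for the range check
            lo, hi = TRAINING_RANGES[check]
            if not lo <= raw <= hi:
                flags.append(f"extrapolation:{check}")
    if value < 0:
        flags.append("negative_prediction")
    return PredictionResult(float(value), tuple(flags))


@dataclass(frozen=True)
class FitResult:
    """Fitted pedotransfer function plus inference summary."""

    coefficients: CoefficientSet
    adj_r2: float
    coefficient_p_values: Dict[str, float]
    residual_sd: float
    n_obs: int
    conf_int: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    trace: Tuple[str, ...] = ()  # forward-selection history, if any


def _design_from_records(records: Sequence[SorptionRecord], response: str,
                         predictors: Sequence[str]):
    """Rows = complete records; returns (X without intercept, y)."""
    xs, ys = [], []
    for r in records:
        y = r.Kf if response == "Kf" else r.Kd
        if y is None:
            continue
        try:
            stub = CoefficientSet(r.antibiotic, response, 0.0, {p: 0.0 for p in predictors}) \
                if predictors else None
            row = [
                _resolve_predictor(p, stub, r.soil, None,
                                   {"slr": r.slr, "cimax": r.Cimax})
                for p in predictors
            ]
        except InputError:
            continue
        xs.append(row)
        ys.append(y)
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


def fit_mlr(records: Sequence[SorptionRecord], response: str,
            predictors: Sequence[str]) -> FitResult:
    """Ordinary least squares fit of ``response ~ intercept + predictors``.

    Only records with the response and every predictor available enter
    the fit.  Raises on rank deficiency (naming constant or collinear
    predictors) and when fewer than ``len(predictors) + 2`` complete
    records remain.
    """
    predictors = list(predictors)
    unknown = set(predictors) - set(PREDICTOR_NAMES)
    if unknown:
        raise InputError(f"unknown predictor name(s) {sorted(unknown)}")
    if len(set(predictors)) != len(predictors):
        raise InputError(f"duplicated predictors in {predictors}")
    antibiotic = records[0].antibiotic if records else "?"

    X, y = _design_from_records(records, response, predictors)
    n_obs = len(y)
    if n_obs < len(predictors) + 2:
        raise InputError(
            f"need at least {len(predictors) + 2} complete records, got {n_obs}"
        )

    if not predictors:  # intercept-only model
        resid = y - y.mean()
        sd = float(np.sqrt(resid @ resid / (n_obs - 1)))
        coeffs = CoefficientSet(antibiotic, response, float(y.mean()),
                                {"OC": 0.0}, "fitted", 0.0, n_obs)
        return FitResult(coeffs, 0.0, {}, sd, n_obs)

    constant = [p for p, col in zip(predictors, X.T) if np.ptp(col) == 0.0]
    if constant:
        raise InputError(f"predictor(s) constant across records: {constant}")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        collinear = _name_collinear(predictors, X)
        raise InputError(f"rank-deficient design; collinear predictors: {collinear}")

    res = sm.OLS(y, design).fit()
    terms = {p: float(b) for p, b in zip(predictors, res.params[1:])}
    pvals = {p: float(v) for p, v in zip(predictors, res.pvalues[1:])}
    ci = res.conf_int(alpha=0.05)
    conf = {"intercept": (float(ci[0][0]), float(ci[0][1]))}
    conf.update({p: (float(lo), float(hi)) for p, (lo, hi) in zip(predictors, ci[1:])})
    coeffs = CoefficientSet(antibiotic, response, float(res.params[0]), terms,
                            "fitted", float(res.rsquared_adj), n_obs)
    return FitResult(coeffs, float(res.rsquared_adj), pvals,
                     float(np.sqrt(res.mse_resid)), n_obs, conf)


def _name_collinear(predictors, X) -> List[str]:
    """Best-effort naming of linearly dependent predictor columns."""
    flagged = set()
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    k = len(predictors)
    for i in range(k):
        for j in range(i + 1, k):
            if abs(corr[i, j]) > 1 - 1e-10:
                flagged.update((predictors[i], predictors[j]))
    if not flagged:
        flagged = set(predictors)
    return sorted(flagged)


def forward_select(records: Sequence[SorptionRecord], response: str,
                   candidates: Sequence[str], alpha_enter: float = 0.05) -> FitResult:
    """Greedy forward selection of predictors by entry p-value.

    At each step the candidate with the smallest coefficient p-value in
    the augmented model enters, provided p < ``alpha_enter``; ties break
    deterministically by candidate name order.  Returns the final fit
    with the selection history in ``trace``.
    """
    selected: List[str] = []
    remaining = sorted(set(candidates))
    trace: List[str] = []
    while remaining:
        best = None  # (p, name)
        for name in remaining:
            try:
                fit = fit_mlr(records, response, selected + [name])
            except InputError:
                continue
            p = fit.coefficient_p_values[name]
            if best is None or p < best[0]:
                best = (p, name)
        if best is None or not best[0] < alpha_enter:
            break
        selected.append(best[1])
        remaining.remove(best[1])
        trace.append(f"+{best[1]} (p={best[0]:.3g})")
    final = fit_mlr(records, response, selected)
    return FitResult(final.coefficients, final.adj_r2, final.coefficient_p_values,
                     final.residual_sd, final.n_obs, final.conf_int, tuple(trace))


def coefficient_sets_to_json(models: Sequence[CoefficientSet], path=None) -> str:
    """Serialize coefficient sets to JSON (bit-exact round trip)."""
    text = json.dumps([m.to_dict() for m in models], indent=2)
    if path is not None:
        from pathlib import Path
        Path(path).write_text(text)
    return text


def coefficient_sets_from_json(source) -> List[CoefficientSet]:
    """Inverse of :func:`coefficient_sets_to_json` (accepts path or text)."""
    from pathlib import Path
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and source.strip().endswith(".json")):
        source = Path(source).read_text()
    return [CoefficientSet.from_dict(d) for d in json.loads(source)]
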