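"""Model-evaluation metrics for sorption-parameter predictions.

Implements the validation statistics used for pedotransfer functions:
Nash-Sutcliffe efficiency (NSE = 1 - SSE/SST; 1 = perfect, 0 = no better
than the mean of the measurements), root-mean-square error, the RMSE as
a percentage of the measurements' standard deviation, and the
per-observation absolute relative error AE = |M - E| / |M|.  Also
provides Pearson correlation screening of sorption parameters against
soil properties (with 0.05/0.01 significance stars) and AE summaries
binned by OC or pH.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SorptionRecord, records_to_frame
from .exceptions import InputError, UndefinedMetricError

__all__ = [
    "EvaluationReport",
    "BinnedAEReport",
    "nse",
    "rmse",
    "abs_error",
    "rmse_sd_ratio",
    "evaluate",
    "pearson_screen",
    "binned_ae",
    "DEFAULT_OC_EDGES",
    "DEFAULT_PH_EDGES",
]

#: Default interior bin boundaries for AE-by-range reports (4 bins each).
DEFAULT_OC_EDGES = (1.0, 3.0, 5.0)
DEFAULT_PH_EDGES = (5.0, 6.5, 8.0)


def _pair(measured, estimated, min_len=1):
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.shape != e.shape:
        raise InputError(f"length mismatch: {m.shape} vs {e.shape}")
    if m.size < min_len:
        raise InputError(f"need at least {min_len} value pairs, got {m.size}")
    return m, e


def nse(measured: Sequence[float], estimated: Sequence[float]) -> float:
    """Nash-Sutcliffe efficiency, 1 - SSE/SST."""
    m, e = _pair(measured, estimated, min_len=2)
    sst = float(np.sum((m - m.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedMetricError("NSE undefined: measured values have zero variance")
    sse = float(np.sum((m - e) ** 2))
    return 1.0 - sse / sst


def rmse(measured: Sequence[float], estimated: Sequence[float]) -> float:
    """Root-mean-square error."""
    m, e = _pair(measured, estimated)
    return float(np.sqrt(np.mean((m - e) ** 2)))


def abs_error(measured: float, estimated: float) -> float:
    """Absolute relative error |M - E| / |M| of one observation."""
    measured = float(measured)
    if measured == 0.0:
        raise UndefinedMetricError("AE undefined for a measured value of 0")
    return abs(measured - float(estimated)) / abs(measured)


def rmse_sd_ratio(measured: Sequence[float], estimated: Sequence[float]) -> float:
    """RMSE as a percentage of the measurements' sample (N-1) standard deviation."""
    m, e = _pair(measured, estimated, min_len=2)
    sd = float(np.std(m, ddof=1))
    if sd == 0.0:
        raise UndefinedMetricError("RMSE/SD undefined: zero standard deviation")
    return 100.0 * rmse(m, e) / sd


@dataclass(frozen=True)
class EvaluationReport:
    """Joint NSE/RMSE/RMSE-SD/AE summary for one prediction-vs-measurement set.

    ``n_ae_excluded`` counts observations dropped from the AE statistics
    because their measured value was 0 (AE is undefined there).
    """

    nse: float
    rmse: float
    rmse_sd_pct: float
    ae: Tuple[float, ...]
    mean_ae: float
    n: int
    n_ae_excluded: int = 0


def evaluate(measured: Sequence[float], estimated: Sequence[float]) -> EvaluationReport:
    """Compute the full metric suite for one comparison."""
    m, e = _pair(measured, estimated, min_len=2)
    ae = tuple(abs_error(mi, ei) for mi, ei in zip(m, e) if mi != 0.0)
    excluded = int(np.sum(m == 0.0))
    return EvaluationReport(
        nse=nse(m, e), rmse=rmse(m, e), rmse_sd_pct=rmse_sd_ratio(m, e),
        ae=ae, mean_ae=float(np.mean(ae)) if ae else float("nan"),
        n=int(m.size), n_ae_excluded=excluded,
    )


_SOIL_PROPERTIES = {"pH": "ph", "OC": "oc", "CEC": "cec_mmol_kg",
                    "Sand": "sand", "Silt": "silt", "Clay": "clay"}


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_screen(records: Sequence[SorptionRecord], response: str) -> pd.DataFrame:
    """Pearson correlations of a sorption parameter with soil properties.

    One row per antibiotic x property, using pairwise-complete
    observations; cells with fewer than 3 pairs or a constant column are
    reported with missing r.  Stars follow the usual convention:
    ``*`` p < 0.05, ``**`` p < 0.01 (two-sided).
    """
    if response not in ("Kf", "n", "Kd"):
        raise InputError(f"response must be 'Kf', 'n' or 'Kd', got {response!r}")
    frame = records_to_frame(records)
    resp_col = response.lower()
    rows = []
    for code, grp in frame.groupby("antibiotic", sort=True):
        for prop, col in _SOIL_PROPERTIES.items():
            pair = grp[[col, resp_col]].dropna()
            if len(pair) < 3 or pair[col].nunique() == 1 or pair[resp_col].nunique() == 1:
                rows.append({"antibiotic": code, "property": prop, "r": np.nan,
                             "p_value": np.nan, "stars": "", "n": len(pair)})
                continue
            r, p = stats.pearsonr(pair[col], pair[resp_col])
            rows.append({"antibiotic": code, "property": prop, "r": float(r),
                         "p_value": float(p), "stars": _stars(p), "n": len(pair)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BinnedAEReport:
    """Mean absolute error by ranges of one soil variable."""

    variable: str  # "OC" or "pH"
    bin_edges: Tuple[float, ...]
    mean_ae_per_bin: Tuple[float, ...]
    counts_per_bin: Tuple[int, ...]


def binned_ae(records: Sequence[SorptionRecord], predictions: Sequence[float],
              variable: str, edges: Optional[Sequence[float]] = None,
              response: str = "Kf", statistic: str = "mean") -> BinnedAEReport:
    """AE distribution of predictions across OC or pH ranges.

    ``edges`` are the interior boundaries; outer edges extend to the
    observed extremes.  Bins are half-open [lo, hi) with the last bin
    closed.  ``statistic`` may be ``"mean"`` (default) or ``"median"``.
    """
    if variable not in ("OC", "pH"):
        raise InputError(f"variable must be 'OC' or 'pH', got {variable!r}")
    if statistic not in ("mean", "median"):
        raise InputError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    if len(records) != len(predictions):
        raise InputError("records and predictions differ in length")
    if not records:
        raise InputError("no records to bin")

    attr = "OC" if variable == "OC" else "pH"
    xs, aes = [], []
    for rec, pred in zip(records, predictions):
        x = getattr(rec.soil, attr)
        measured = rec.Kf if response == "Kf" else rec.Kd
        if x is None or measured is None or measured == 0.0:
            continue
        xs.append(x)
        aes.append(abs_error(measured, pred))
    if not xs:
        raise InputError(f"no records carry both {variable} and a nonzero measured {response}")
    xs = np.asarray(xs)
    aes = np.asarray(aes)

    interior = list(edges) if edges is not None else list(
        DEFAULT_OC_EDGES if variable == "OC" else DEFAULT_PH_EDGES)
    if any(b <= a for a, b in zip(interior, interior[1:])):
        raise InputError(f"bin edges must be strictly increasing: {interior}")
    full = [min(xs.min(), interior[0] if interior else xs.min())]
    full.extend(interior)
    full.append(max(xs.max(), full[-1] + np.finfo(float).eps))
    full = np.asarray(full, dtype=float)
    if xs.min() < full[0] or xs.max() > full[-1]:
        raise InputError("a record lies outside all bins")

    # half-open [lo, hi), last bin closed
    idx = np.clip(np.searchsorted(full, xs, side="right") - 1, 0, len(full) - 2)
    agg = np.mean if statistic == "mean" else np.median
    means, counts = [], []
    for b in range(len(full) - 1):
        mask = idx == b
        counts.append(int(mask.sum()))
        means.append(float(agg(aes[mask])) if mask.any() else float("nan"))
    return BinnedAEReport(variable, tuple(full.tolist()), tuple(means), tuple(counts))
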