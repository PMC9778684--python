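"""Record schema for literature sorption observations and dataset plumbing.

A :class:`SorptionRecord` joins one soil's properties with the sorption
parameters reported (or re-fitted) for one antibiotic, plus the batch
experiment metadata that can modulate measured sorption (maximal initial
concentration, solid/liquid ratio).  The module also handles the unit
conventions used throughout:

* organic matter is converted to organic carbon with %OM = 1.724 x %OC;
* cation exchange capacity is stored in mmol kg^-1 (an explicit ingest
  flag converts from cmol kg^-1, x10 — never auto-guessed);
* solid/liquid ratios are stored in kg L^-1 ("1:10" -> 0.1);
* the Freundlich exponent column may hold n or 1/n in source papers; an
  explicit flag normalizes to n.

Training/validation bookkeeping follows the four-way convention: capital
splits ("A" for Kf, "B" for Kd) train pedotransfer functions, lowercase
splits ("a", "b") validate them.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .compounds import get_compound
from .exceptions import ConfigError, DomainError, InputError
from .isotherms import parse_slr

__all__ = [
    "OM_TO_OC_FACTOR",
    "SoilSample",
    "SorptionRecord",
    "IngestOptions",
    "IngestReport",
    "om_to_oc",
    "oc_to_om",
    "read_records",
    "write_records",
    "records_to_frame",
    "split_dataset",
    "describe",
    "CSV_COLUMNS",
]

#: Van Bemmelen-type conversion: %OM = 1.724 x %OC.
OM_TO_OC_FACTOR = 1.724

SPLITS = ("A", "a", "B", "b", "unassigned")

CSV_COLUMNS = [
    "antibiotic", "ph", "oc", "om", "cec_mmol_kg", "sand", "silt", "clay",
    "kf", "n", "kd", "cimax_mg_l", "slr", "source_id", "split", "kd_origin",
]


def om_to_oc(om: float) -> float:
    """Convert % organic matter to % organic carbon (OC = OM / 1.724)."""
    om = float(om)
    if om < 0:
        raise DomainError(f"organic matter must be non-negative, got {om}")
    return om / OM_TO_OC_FACTOR


def oc_to_om(oc: float) -> float:
    """Convert % organic carbon to % organic matter (OM = 1.724 x OC)."""
    oc = float(oc)
    if oc < 0:
        raise DomainError(f"organic carbon must be non-negative, got {oc}")
    return oc * OM_TO_OC_FACTOR


@dataclass(frozen=True)
class SoilSample:
    """Edaphic properties of one soil.

    CEC is in mmol kg^-1; texture fractions in % mass.  When all three
    texture fractions are present their sum must fall in [95, 105]
    (tolerance for rounding in literature tables).
    """

    pH: float
    OC: Optional[float] = None
    CEC: Optional[float] = None
    sand: Optional[float] = None
    silt: Optional[float] = None
    clay: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.pH <= 14.0:
            raise DomainError(f"soil pH must be in [0, 14], got {self.pH}")
        if self.OC is not None and self.OC < 0:
            raise InputError(f"OC must be non-negative, got {self.OC}")
        if self.CEC is not None and self.CEC < 0:
            raise InputError(f"CEC must be non-negative, got {self.CEC}")
        texture = (self.sand, self.silt, self.clay)
        for name, v in zip(("sand", "silt", "clay"), texture):
            if v is not None and not 0.0 <= v <= 100.0:
                raise InputError(f"{name} must be in [0, 100] %, got {v}")
        if all(v is not None for v in texture):
            total = self.sand + self.silt + self.clay
            if not 95.0 <= total <= 105.0:
                raise InputError(f"sand+silt+clay must be within [95, 105] %, got {total:.2f}")


@dataclass(frozen=True)
class SorptionRecord:
    """One literature observation of antibiotic sorption in one soil."""

    antibiotic: str
    soil: SoilSample
    Kf: Optional[float] = None
    n: Optional[float] = None
    Kd: Optional[float] = None
    Cimax: Optional[float] = None
    slr: Optional[float] = None
    source_id: str = ""
    split: str = "unassigned"
    kd_origin: str = "reported"

    def __post_init__(self):
        get_compound(self.antibiotic)  # validates the code
        object.__setattr__(self, "antibiotic", self.antibiotic.strip().upper())
        has_freundlich = self.Kf is not None and self.n is not None
        if self.Kf is not None and self.n is None:
            raise InputError(f"{self.antibiotic}: Kf given without its linearity index n")
        if self.n is not None and self.Kf is None:
            raise InputError(f"{self.antibiotic}: n given without Kf")
        if not has_freundlich and self.Kd is None:
            raise InputError(f"{self.antibiotic}: record needs (Kf, n) or Kd")
        for name in ("Kf", "n", "Kd", "Cimax", "slr"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InputError(f"{self.antibiotic}: {name} must be positive, got {v}")
        if self.split not in SPLITS:
            raise InputError(f"split must be one of {SPLITS}, got {self.split!r}")
        if self.kd_origin not in ("reported", "refit"):
            raise InputError(f"kd_origin must be 'reported' or 'refit', got {self.kd_origin!r}")


@dataclass(frozen=True)
class IngestOptions:
    """Flags controlling CSV ingest.

    ``exponent_is_inverse``: the Freundlich exponent column holds 1/n and
    must be inverted.  ``cec_in_cmol``: the CEC column is in cmol kg^-1
    and is multiplied by 10.  ``strict``: any invalid row aborts the read
    instead of being collected in the error report.
    """

    exponent_is_inverse: bool = False
    cec_in_cmol: bool = False
    strict: bool = False


@dataclass
class IngestReport:
    """Valid records plus per-row errors from one CSV read."""

    records: List[SorptionRecord] = field(default_factory=list)
    errors: List[tuple] = field(default_factory=list)  # (row_number, message)


def _get(row: dict, key: str):
    v = row.get(key)
    if v is None:
        return None
    v = str(v).strip()
    return v if v else None


def _float_or_none(row: dict, key: str):
    v = _get(row, key)
    return None if v is None else float(v)


def _parse_row(row: dict, options: IngestOptions) -> SorptionRecord:
    antibiotic = _get(row, "antibiotic")
    ph = _get(row, "ph")
    if antibiotic is None or ph is None:
        raise InputError("columns 'antibiotic' and 'ph' are required")
    oc = _float_or_none(row, "oc")
    om = _float_or_none(row, "om")
    if oc is None and om is not None:
        oc = om_to_oc(om)
    cec = _float_or_none(row, "cec_mmol_kg")
    if cec is not None and options.cec_in_cmol:
        cec *= 10.0
    soil = SoilSample(
        pH=float(ph), OC=oc, CEC=cec,
        sand=_float_or_none(row, "sand"),
        silt=_float_or_none(row, "silt"),
        clay=_float_or_none(row, "clay"),
    )
    n = _float_or_none(row, "n")
    if n is not None and options.exponent_is_inverse:
        if n == 0:
            raise InputError("exponent column holds 1/n but the value is 0")
        n = 1.0 / n
    slr_raw = _get(row, "slr")
    return SorptionRecord(
        antibiotic=antibiotic,
        soil=soil,
        Kf=_float_or_none(row, "kf"),
        n=n,
        Kd=_float_or_none(row, "kd"),
        Cimax=_float_or_none(row, "cimax_mg_l"),
        slr=None if slr_raw is None else parse_slr(slr_raw),
        source_id=_get(row, "source_id") or "",
        split=_get(row, "split") or "unassigned",
        kd_origin=_get(row, "kd_origin") or "reported",
    )


def read_records(source, options: Optional[IngestOptions] = None) -> IngestReport:
    """Read sorption records from CSV (path or text).

    Required columns: ``antibiotic``, ``ph``, and at least one sorption
    parameter column (``kf``+``n`` or ``kd``).  An ``om`` column is
    converted to OC when ``oc`` is absent.  Invalid rows are collected in
    the report (with 1-based data row numbers) unless ``strict``.
    """
    options = options or IngestOptions()
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    else:
        text = str(source)
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        raise InputError("CSV is empty: no header row")
    fields = set(reader.fieldnames)
    if "antibiotic" not in fields or "ph" not in fields:
        raise InputError("CSV must have 'antibiotic' and 'ph' columns")
    if not ({"kf", "kd"} & fields):
        raise InputError("CSV needs at least one sorption-parameter column ('kf' or 'kd')")

    report = IngestReport()
    for i, row in enumerate(reader, start=1):
        try:
            report.records.append(_parse_row(row, options))
        except (InputError, ValueError) as exc:
            if options.strict:
                raise InputError(f"row {i}: {exc}") from exc
            report.errors.append((i, str(exc)))
    return report


def write_records(records: Sequence[SorptionRecord], path=None) -> str:
    """Emit records as RFC-4180 CSV in the canonical column order."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    writer.writerow(CSV_COLUMNS)
    for r in records:
        s = r.soil
        writer.writerow([
            r.antibiotic, _fmt(s.pH), _fmt(s.OC), "", _fmt(s.CEC), _fmt(s.sand),
            _fmt(s.silt), _fmt(s.clay), _fmt(r.Kf), _fmt(r.n), _fmt(r.Kd),
            _fmt(r.Cimax), _fmt(r.slr), r.source_id, r.split, r.kd_origin,
        ])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, newline="")
    return text


def _fmt(v) -> str:
    if v is None:
        return ""
    return repr(float(v))


def records_to_frame(records: Sequence[SorptionRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (one row per record)."""
    rows = []
    for r in records:
        rows.append({
            "antibiotic": r.antibiotic, "ph": r.soil.pH, "oc": r.soil.OC,
            "cec_mmol_kg": r.soil.CEC, "sand": r.soil.sand, "silt": r.soil.silt,
            "clay": r.soil.clay, "kf": r.Kf, "n": r.n, "kd": r.Kd,
            "cimax_mg_l": r.Cimax, "slr": r.slr, "source_id": r.source_id,
            "split": r.split, "kd_origin": r.kd_origin,
        })
    return pd.DataFrame(rows)


def split_dataset(records: Sequence[SorptionRecord], fraction: float = 0.75,
                  seed: int = 0) -> List[SorptionRecord]:
    """Assign training/validation split labels, stratified per antibiotic.

    Records carrying Freundlich parameters enter the Kf pools ("A" train /
    "a" validation); records carrying a Kd enter the Kd pools ("B"/"b").
    A record with both parameter sets receives a Kf label (it still
    contributes its Kd downstream through the same partition).  Within
    each antibiotic, round(fraction * N) records train; the split is a
    seeded permutation, so the same seed reproduces identical labels.
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigError(f"split fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    out: List[Optional[SorptionRecord]] = list(records)

    def assign(indices: List[int], train_label: str, valid_label: str) -> None:
        idx = np.array(indices)
        n_train = int(np.floor(fraction * len(idx) + 0.5))
        perm = rng.permutation(len(idx))
        for rank, j in enumerate(perm):
            label = train_label if rank < n_train else valid_label
            out[idx[j]] = replace(out[idx[j]], split=label)

    for code in sorted({r.antibiotic for r in records}):
        kf_idx = [i for i, r in enumerate(records) if r.antibiotic == code and r.Kf is not None]
        kd_idx = [i for i, r in enumerate(records)
                  if r.antibiotic == code and r.Kf is None and r.Kd is not None]
        if kf_idx:
            assign(kf_idx, "A", "a")
        if kd_idx:
            assign(kd_idx, "B", "b")
    return out


def describe(records: Sequence[SorptionRecord]) -> pd.DataFrame:
    """Descriptive statistics (max/min/mean/median/N) per antibiotic and parameter."""
    if not records:
        raise InputError("describe needs at least one record")
    frame = records_to_frame(records)
    rows = []
    for code, grp in frame.groupby("antibiotic", sort=True):
        for param in ("kf", "n", "kd"):
            vals = grp[param].dropna()
            if vals.empty:
                continue
            rows.append({
                "antibiotic": code, "parameter": param,
                "max": vals.max(), "min": vals.min(), "mean": vals.mean(),
                "median": vals.median(), "n_obs": int(vals.size),
            })
    return pd.DataFrame(rows)
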