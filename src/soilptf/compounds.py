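"""Physicochemical constants of the seven target antibiotics and pH speciation.

The registry holds four sulfonamides (SCP, SMT, SDZ, SMX) and three
tetracyclines (OTC, TC, CTC).  Sulfonamides are diprotic acids (two pKa
values); tetracyclines are amphoteric triprotic compounds (three pKa
values).  :func:`species_fractions` maps the sequential deprotonation
ladder onto the three macro-species classes used throughout the package:
cationic (``alpha_plus``), neutral/zwitterionic (``alpha_zero``) and
anionic (``alpha_minus``).  For tetracyclines the mono- and di-anion are
pooled into ``alpha_minus`` so that all compounds expose the same three
classes.  Zwitterion and true-neutral microspecies are not distinguished.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np

from .exceptions import DomainError, InputError, UnknownCompoundError

__all__ = [
    "Compound",
    "SpeciesFractions",
    "get_compound",
    "list_compounds",
    "species_fractions",
    "registry_to_csv",
    "registry_from_csv",
]


@dataclass(frozen=True)
class Compound:
    """Physicochemical constants of one antibiotic.

    Attributes
    ----------
    code : str
        Short identifier, e.g. ``"SMX"``.
    antibiotic_class : str
        ``"SA"`` (sulfonamide) or ``"TC"`` (tetracycline).
    molecular_formula : str
    mw : float
        Molar mass, g mol^-1.
    solubility : float
        Aqueous solubility, mg L^-1.
    log_kow : float
        Octanol-water partition coefficient, log10.
    pka : tuple[float, ...]
        Acid dissociation constants, strictly increasing; two values for
        sulfonamides, three for tetracyclines.
    """

    code: str
    antibiotic_class: str
    molecular_formula: str
    mw: float
    solubility: float
    log_kow: float
    pka: tuple

    def __post_init__(self):
        if self.antibiotic_class not in ("SA", "TC"):
            raise InputError(f"antibiotic_class must be 'SA' or 'TC', got {self.antibiotic_class!r}")
        expected = 2 if self.antibiotic_class == "SA" else 3
        if len(self.pka) != expected:
            raise InputError(
                f"{self.code}: {self.antibiotic_class} compounds need {expected} pKa values, got {len(self.pka)}"
            )
        if any(b <= a for a, b in zip(self.pka, self.pka[1:])):
            raise InputError(f"{self.code}: pKa values must be strictly increasing: {self.pka}")


@dataclass(frozen=True)
class SpeciesFractions:
    """Macro-species fractions at one pH; they sum to 1."""

    alpha_plus: float
    alpha_zero: float
    alpha_minus: float

    def as_dict(self) -> dict:
        return {
            "alpha_plus": self.alpha_plus,
            "alpha_zero": self.alpha_zero,
            "alpha_minus": self.alpha_minus,
        }


_REGISTRY = {
    c.code: c
    for c in (
        Compound("SCP", "SA", "C10H9ClN4O2S", 284.72, 7000.00, -0.80, (1.87, 5.45)),
        Compound("SMT", "SA", "C12H14N4O2S", 278.34, 1500.00, 0.14, (2.07, 7.49)),
        Compound("SDZ", "SA", "C10H10N4O2S", 250.30, 77.00, -1.05, (2.10, 6.28)),
        Compound("SMX", "SA", "C10H11N3O3S", 253.28, 370.00, 0.89, (1.83, 5.62)),
        Compound("OTC", "TC", "C22H24N2O9", 460.40, 1000.00, -0.12, (3.30, 7.30, 9.10)),
        Compound("TC", "TC", "C22H24N2O8", 444.43, 231.00, -1.37, (3.20, 7.80, 9.60)),
        Compound("CTC", "TC", "C22H23ClN2O8", 479.00, 4120.00, 2.07, (3.30, 7.44, 9.27)),
    )
}


def list_compounds() -> list:
    """All registered compound codes, sulfonamides first."""
    return list(_REGISTRY)


def get_compound(code: str) -> Compound:
    """Look up a compound by its (case-insensitive) code.

    Raises
    ------
    UnknownCompoundError
        If ``code`` is not one of the seven registered antibiotics.
    """
    key = str(code).strip().upper()
    try:
        return _REGISTRY[key]
    except KeyError:
        raise UnknownCompoundError(
            f"unknown compound {code!r}; valid codes: {', '.join(_REGISTRY)}"
        ) from None


def _ladder_fractions(pka, pH: float) -> np.ndarray:
    """Fractions of the k-times-deprotonated species for a sequential ladder.

    Species k (k = 0 .. len(pka)) has relative abundance
    10^(k*pH - sum(pka[:k])); computed with the maximum exponent factored
    out for numerical stability.
    """
    pka = np.asarray(pka, dtype=float)
    k = np.arange(len(pka) + 1)
    exponents = k * pH - np.concatenate(([0.0], np.cumsum(pka)))
    rel = np.power(10.0, exponents - exponents.max())
    return rel / rel.sum()


def species_fractions(compound: Union[Compound, str], pH: float) -> SpeciesFractions:
    """Macro-species fractions of an antibiotic at a given pH.

    For sulfonamides the three ladder species map directly to
    (cation, neutral/zwitterion, anion).  For tetracyclines the fully
    protonated species is the cation, the first deprotonation the
    neutral/zwitterion, and the last two steps are pooled into the anion
    fraction.

    Parameters
    ----------
    compound : Compound or str
        Compound record or its code.
    pH : float
        Must lie in [0, 14].
    """
    if isinstance(compound, str):
        compound = get_compound(compound)
    pH = float(pH)
    if not 0.0 <= pH <= 14.0:
        raise DomainError(f"pH must be in [0, 14], got {pH}")
    frac = _ladder_fractions(compound.pka, pH)
    if compound.antibiotic_class == "SA":
        a_plus, a_zero, a_minus = frac[0], frac[1], frac[2]
    else:
        a_plus, a_zero, a_minus = frac[0], frac[1], frac[2] + frac[3]
    return SpeciesFractions(float(a_plus), float(a_zero), float(a_minus))


_CSV_HEADER = ["code", "class", "formula", "mw", "solubility", "logkow", "pka1", "pka2", "pka3"]


def registry_to_csv(path=None) -> str:
    """Export the registry as CSV (``pka3`` empty for sulfonamides).

    Returns the CSV text; also writes it to ``path`` when given.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_CSV_HEADER)
    for c in _REGISTRY.values():
        pka3 = f"{c.pka[2]}" if len(c.pka) == 3 else ""
        writer.writerow(
            [c.code, c.antibiotic_class, c.molecular_formula, c.mw, c.solubility,
             c.log_kow, c.pka[0], c.pka[1], pka3]
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def registry_from_csv(source) -> dict:
    """Read a compound table in the export schema; returns code -> Compound."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    else:
        text = str(source)
    reader = csv.DictReader(io.StringIO(text))
    missing = set(_CSV_HEADER) - set(reader.fieldnames or [])
    if missing:
        raise InputError(f"compound CSV missing columns: {sorted(missing)}")
    out = {}
    for row in reader:
        pka = [float(row["pka1"]), float(row["pka2"])]
        if row.get("pka3", "").strip():
            pka.append(float(row["pka3"]))
        c = Compound(
            row["code"].strip().upper(), row["class"].strip().upper(), row["formula"],
            float(row["mw"]), float(row["solubility"]), float(row["logkow"]), tuple(pka),
        )
        out[c.code] = c
    return out
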