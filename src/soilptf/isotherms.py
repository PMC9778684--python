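"""Sorption isotherm models, batch mass balance and Freundlich-to-Kd re-fitting.

The linear model is Qe = Kd * Ce and the Freundlich model
Qe = Kf * Ce^(1/n), with Qe in mg kg^-1, Ce in mg L^-1, Kd in L kg^-1 and
Kf in mg^(1-1/n) L^(1/n) kg^-1.  n close to 1 means near-linear sorption;
n > 1 indicates saturation of sorption sites at high concentration.

For literature studies that report only Freundlich parameters, a linear
Kd is recovered by simulating a batch experiment: each initial
concentration Ci is propagated through the mass balance
Ci - Ce = slr * Qe(Ce) (slr = soil mass per solution volume, kg L^-1),
and the through-origin line Qe = Kd * Ce is fitted to the resulting
(Ce, Qe) points.  Only re-fits with a significant slope (p < 0.05) are
normally retained downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .exceptions import DomainError, InputError, NumericalError

__all__ = [
    "IsothermParams",
    "BatchConditions",
    "RefitResult",
    "linear",
    "freundlich",
    "sorbed_amount",
    "solve_equilibrium",
    "refit_kd",
    "parse_slr",
    "DEFAULT_CI_GRID",
    "DEFAULT_SLR",
]

#: Default initial-concentration grid (mg/L) used when a source study's
#: batch design is unknown: 5 log-spaced points spanning 0.1-10 mg/L.
DEFAULT_CI_GRID: Tuple[float, ...] = tuple(np.logspace(-1, 1, 5))

#: Default solid/liquid ratio, the common 1:10 batch convention (kg/L).
DEFAULT_SLR: float = 0.1

#: Significance threshold for retaining a re-fitted Kd.
REFIT_P_THRESHOLD: float = 0.05


@dataclass(frozen=True)
class IsothermParams:
    """Parameters of a linear or Freundlich isotherm.

    Exactly the fields of the chosen kind are set: ``Kd`` for
    ``kind="linear"``; ``Kf`` and ``n`` for ``kind="freundlich"``.
    """

    kind: str
    Kd: Optional[float] = None
    Kf: Optional[float] = None
    n: Optional[float] = None

    def __post_init__(self):
        if self.kind == "linear":
            if self.Kd is None or self.Kd <= 0:
                raise InputError(f"linear isotherm needs Kd > 0, got {self.Kd}")
            if self.Kf is not None or self.n is not None:
                raise InputError("linear isotherm must not set Kf or n")
        elif self.kind == "freundlich":
            if self.Kf is None or self.Kf <= 0 or self.n is None or self.n <= 0:
                raise InputError(f"freundlich isotherm needs Kf > 0 and n > 0, got Kf={self.Kf}, n={self.n}")
            if self.Kd is not None:
                raise InputError("freundlich isotherm must not set Kd")
        else:
            raise InputError(f"kind must be 'linear' or 'freundlich', got {self.kind!r}")


def linear(Kd: float) -> IsothermParams:
    """Linear isotherm Qe = Kd * Ce."""
    return IsothermParams("linear", Kd=Kd)


def freundlich(Kf: float, n: float) -> IsothermParams:
    """Freundlich isotherm Qe = Kf * Ce^(1/n)."""
    return IsothermParams("freundlich", Kf=Kf, n=n)


def parse_slr(value) -> float:
    """Normalize a solid/liquid ratio to kg L^-1.

    Accepts a number (already kg/L) or a ``"1:X"`` string, the common
    way batch studies report soil mass : solution volume (g : mL), so
    ``"1:10"`` parses to 0.1.
    """
    if isinstance(value, str):
        text = value.strip()
        if ":" in text:
            left, right = text.split(":", 1)
            try:
                num, den = float(left), float(right)
            except ValueError:
                raise InputError(f"cannot parse solid/liquid ratio {value!r}") from None
            if num <= 0 or den <= 0:
                raise InputError(f"solid/liquid ratio parts must be positive: {value!r}")
            return num / den
        try:
            value = float(text)
        except ValueError:
            raise InputError(f"cannot parse solid/liquid ratio {value!r}") from None
    slr = float(value)
    if slr <= 0:
        raise InputError(f"solid/liquid ratio must be positive, got {slr}")
    return slr


@dataclass(frozen=True)
class BatchConditions:
    """Batch experiment design: initial concentrations and solid/liquid ratio."""

    Ci_list: Tuple[float, ...] = DEFAULT_CI_GRID
    slr: float = DEFAULT_SLR

    def __post_init__(self):
        object.__setattr__(self, "Ci_list", tuple(float(c) for c in self.Ci_list))
        object.__setattr__(self, "slr", parse_slr(self.slr))
        if not self.Ci_list:
            raise InputError("Ci_list must not be empty")
        if any(c <= 0 for c in self.Ci_list):
            raise InputError(f"all initial concentrations must be positive: {self.Ci_list}")


@dataclass(frozen=True)
class RefitResult:
    """Result of the Freundlich-to-Kd re-fit."""

    Kd: float
    p_value: float
    points: tuple  # (Ce, Qe) pairs used in the through-origin fit

    @property
    def significant(self) -> bool:
        """True when the through-origin slope passes the p < 0.05 filter."""
        return self.p_value < REFIT_P_THRESHOLD


def sorbed_amount(params: IsothermParams, Ce) -> float:
    """Equilibrium sorbed amount Qe (mg/kg) at aqueous concentration Ce (mg/L)."""
    Ce = np.asarray(Ce, dtype=float)
    if np.any(Ce < 0):
        raise DomainError(f"Ce must be non-negative, got {Ce}")
    if params.kind == "linear":
        q = params.Kd * Ce
    else:
        q = params.Kf * np.power(Ce, 1.0 / params.n)
    return float(q) if q.ndim == 0 else q


def solve_equilibrium(params: IsothermParams, Ci: float, slr: float) -> float:
    """Equilibrium aqueous concentration Ce for a batch experiment.

    Solves the mass balance Ci - Ce = slr * Qe(Ce) for the unique root in
    (0, Ci].  The residual g(Ce) = Ci - Ce - slr*Qe(Ce) is strictly
    decreasing, so a bracketed Brent search on [0, Ci] always converges.

    Parameters
    ----------
    params : IsothermParams
    Ci : float
        Initial aqueous concentration, mg/L (> 0).
    slr : float or str
        Solid/liquid ratio, kg/L; ``"1:X"`` strings accepted.
    """
    Ci = float(Ci)
    slr = parse_slr(slr)
    if Ci <= 0:
        raise DomainError(f"Ci must be positive, got {Ci}")

    def residual(ce: float) -> float:
        return Ci - ce - slr * sorbed_amount(params, ce)

    try:
        # xtol far below float spacing: iterate to machine precision so the
        # mass-balance residual stays < 1e-9*Ci even for steep isotherms
        ce, info = optimize.brentq(residual, 0.0, Ci, xtol=1e-300, rtol=8.9e-16,
                                   maxiter=300, full_output=True)
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - defensive
        raise NumericalError(
            f"equilibrium solver failed for Ci={Ci}, slr={slr}, params={params}: {exc}"
        ) from exc
    if not info.converged:
        raise NumericalError(
            f"equilibrium solver did not converge for Ci={Ci}, slr={slr}: "
            f"iterations={info.iterations}, flag={info.flag}"
        )
    return float(ce)


def refit_kd(Kf: float, n: float, conditions: Optional[BatchConditions] = None) -> RefitResult:
    """Re-fit a linear Kd from reported Freundlich parameters.

    Simulates a batch series at the given conditions: each Ci is pushed
    through the mass balance to get Ce, the sorbed amount follows as
    Qe = (Ci - Ce)/slr, and the through-origin least-squares slope
    Kd = sum(Qe*Ce)/sum(Ce^2) is returned with the two-sided t-test
    p-value of the slope (N - 1 degrees of freedom, no intercept).

    When n == 1 the Freundlich model is already linear and the returned
    Kd equals Kf for any conditions.
    """
    if Kf <= 0 or n <= 0:
        raise InputError(f"need Kf > 0 and n > 0, got Kf={Kf}, n={n}")
    if conditions is None:
        conditions = BatchConditions()
    if len(conditions.Ci_list) < 3:
        raise InputError(
            f"re-fitting needs at least 3 initial concentrations, got {len(conditions.Ci_list)}"
        )
    params = freundlich(Kf, n)
    ce = np.array([solve_equilibrium(params, ci, conditions.slr) for ci in conditions.Ci_list])
    qe = (np.array(conditions.Ci_list) - ce) / conditions.slr

    sxx = float(np.dot(ce, ce))
    if sxx == 0.0:
        raise NumericalError("all equilibrium concentrations are zero; cannot fit slope")
    kd = float(np.dot(qe, ce)) / sxx

    n_pts = len(ce)
    rss = float(np.sum((qe - kd * ce) ** 2))
    dof = n_pts - 1
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / sxx)
    if se == 0.0:
        p = np.finfo(float).tiny  # exact fit: perfectly significant
    else:
        t_stat = kd / se
        p = max(2.0 * stats.t.sf(abs(t_stat), dof), np.finfo(float).tiny)
    return RefitResult(Kd=kd, p_value=float(p), points=tuple(zip(ce.tolist(), qe.tolist())))
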