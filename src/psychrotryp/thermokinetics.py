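"""Arrhenius/Eyring analysis of enzyme activity-temperature data.

The module turns activity-versus-temperature series into transition-state
thermodynamics and compares a psychrophilic enzyme against a mesophilic
homolog at a shared reference temperature.

Model
-----
Below the thermal optimum an enzyme's rate follows the Arrhenius law
``k(T) = A * exp(-Ea/(R*T))``; a least-squares line of ln k on 1/T over the
ascending limb yields the activation energy Ea = -slope*R. Above the optimum
the apparent slope is dominated by inactivation/unfolding and is reported
signed, without a transition-state reading.

Transition-state parameters come from the Eyring equation
``k = kappa*(k_B*T/h)*exp(-dG/(R*T))``, with the solution-phase convention
``dH = Ea - R*T`` and ``dS = (dH - dG)/T``. Psychrophile-minus-mesophile
differentials (ddG, ddH, T*ddS) at a shared reference temperature quantify
cold adaptation: a negative ddG is an activity advantage of
``exp(-ddG/(R*T))``-fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .constants import CODATA, PhysicalConstants

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityTemperatureSeries",
    "ArrheniusFit",
    "EyringState",
    "DifferentialActivation",
    "ProfileSummary",
    "CalciumProfile",
    "fit_arrhenius",
    "fit_arrhenius_two_sided",
    "predict_rate",
    "eyring_from_rate",
    "rate_from_eyring",
    "arrhenius_to_eyring",
    "differential_activation",
    "differential_from_rates",
    "activity_ratio_from_ddg",
    "summarize_profile",
    "characterize_calcium_profile",
]


@dataclass(frozen=True)
class ActivityTemperatureSeries:
    """Rates across temperature for one enzyme/substrate pair.

    Temperatures are Kelvin and strictly increasing; rates share one unit
    (``unit_tag``), typically ``s^-1`` for k_cat or ``U/mg`` for specific
    activity — Arrhenius slopes are invariant to the constant scaling between
    the two.
    """

    enzyme_label: str
    substrate_label: str
    temperatures: tuple[float, ...]
    rates: tuple[float, ...]
    unit_tag: str = "s^-1"

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if t.size != r.size:
            raise ValueError("temperatures and rates must have equal length")
        if t.size < 3:
            raise ValueError("a series needs at least 3 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("rates must be non-negative")

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.temperatures, dtype=float)

    @property
    def k(self) -> np.ndarray:
        return np.asarray(self.rates, dtype=float)

    def rate_at(self, temperature: float, rtol: float = 1e-9) -> float:
        """Rate at a grid temperature (exact lookup, no interpolation)."""
        t = self.t
        idx = np.argmin(np.abs(t - temperature))
        if abs(t[idx] - temperature) > rtol * max(1.0, abs(temperature)):
            raise ValueError(
                f"temperature {temperature} K is not a grid point of the series"
            )
        return float(self.k[idx])


@dataclass(frozen=True)
class ArrheniusFit:
    """One log-linear limb of an Arrhenius plot.

    ``Ea`` is in J/mol; for the ascending limb it is positive for physically
    sensible data, for the descending limb it is the signed apparent slope
    parameter (usually negative) with no transition-state meaning.
    """

    Ea: float
    lnA: float
    r_squared: float
    window: tuple[float, float]
    limb: str  # "ascending" | "descending"
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.limb not in ("ascending", "descending"):
            raise ValueError("limb must be 'ascending' or 'descending'")
        if not (-1e-9 <= self.r_squared <= 1.0 + 1e-9):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class EyringState:
    """Transition-state parameters of one enzyme at ``T_ref`` (J/mol units).

    The defining identity dG = dH - T_ref*dS is enforced at construction.
    """

    dG: float
    dH: float
    dS: float
    T_ref: float

    def __post_init__(self) -> None:
        lhs, rhs = self.dG, self.dH - self.T_ref * self.dS
        scale = max(abs(lhs), abs(rhs), 1.0)
        if abs(lhs - rhs) > 1e-6 * scale:
            raise ValueError("EyringState violates dG = dH - T*dS")


@dataclass(frozen=True)
class DifferentialActivation:
    """Psychrophile-minus-mesophile activation differentials at ``T_ref``."""

    ddG: float
    ddH: float
    TddS: float
    T_ref: float

    def __post_init__(self) -> None:
        lhs, rhs = self.ddG, self.ddH - self.TddS
        scale = max(abs(lhs), abs(rhs), 1.0)
        if abs(lhs - rhs) > 1e-6 * scale:
            raise ValueError("DifferentialActivation violates ddG = ddH - TddS")

    @property
    def ddS(self) -> float:
        return self.TddS / self.T_ref


@dataclass(frozen=True)
class ProfileSummary:
    """Optimum and (optional) plateau of an activity profile."""

    x_opt: float
    y_max: float
    plateau: tuple[float, float] | None
    plateau_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.plateau_fraction < 1.0):
            raise ValueError("plateau_fraction must lie in (0, 1)")
        if self.plateau is not None:
            lo, hi = self.plateau
            if not (lo <= self.x_opt <= hi):
                raise ValueError("plateau must contain x_opt")


@dataclass(frozen=True)
class CalciumProfile:
    """Descriptive summary of activity vs Ca2+/enzyme molar ratio."""

    ratio_at_max: float
    activity_fraction_at_zero: float | None


# ---------------------------------------------------------------------------
# Arrhenius fitting


def _trim_edge_zeros(t: np.ndarray, k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nz = np.nonzero(k > 0)[0]
    if nz.size == 0:
        raise ValueError("nonpositive rate: no positive rates in limb")
    lo, hi = nz[0], nz[-1]
    if lo > 0 or hi < k.size - 1:
        logger.warning(
            "trimmed %d zero-rate point(s) at the range edges before log fit",
            (lo + (k.size - 1 - hi)),
        )
    t, k = t[lo : hi + 1], k[lo : hi + 1]
    if np.any(k <= 0):
        raise ValueError("nonpositive rate inside limb; cannot log-transform")
    return t, k


def fit_arrhenius(
    temperatures: Sequence[float],
    rates: Sequence[float],
    limb: str = "ascending",
    constants: PhysicalConstants = CODATA,
) -> ArrheniusFit:
    """Ordinary least squares of ln(rate) on 1/T over one limb.

    Zero rates at the edges of the window are trimmed (with a warning);
    interior zeros are an error. Needs >=3 usable points.
    """
    t = np.asarray(temperatures, dtype=float)
    k = np.asarray(rates, dtype=float)
    t, k = _trim_edge_zeros(t, k)
    if t.size < 3:
        raise ValueError("insufficient limb data: need at least 3 points per limb")
    res = stats.linregress(1.0 / t, np.log(k))
    ea = -res.slope * constants.R
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0
    return ArrheniusFit(
        Ea=float(ea),
        lnA=float(res.intercept),
        r_squared=min(r2, 1.0),
        window=(float(t.min()), float(t.max())),
        limb=limb,
        n_points=int(t.size),
    )


def fit_arrhenius_two_sided(
    series: ActivityTemperatureSeries,
    constants: PhysicalConstants = CODATA,
) -> tuple[ArrheniusFit, ArrheniusFit, float]:
    """Fit both limbs of a peaked Arrhenius plot.

    The maximal-rate point terminates the ascending limb and starts the
    descending limb (it belongs to both). Ties on the maximum break toward
    the lower temperature, with a warning.
    """
    t, k = series.t, series.k
    kmax = k.max()
    idx_candidates = np.nonzero(k == kmax)[0]
    if idx_candidates.size > 1:
        logger.warning(
            "tie for maximal rate at %d temperatures; using the lowest",
            idx_candidates.size,
        )
    i_max = int(idx_candidates[0])
    if i_max + 1 < 3 or t.size - i_max < 3:
        raise ValueError("insufficient limb data: need >=3 points on each side of the maximum")
    asc = fit_arrhenius(t[: i_max + 1], k[: i_max + 1], "ascending", constants)
    desc = fit_arrhenius(t[i_max:], k[i_max:], "descending", constants)
    return asc, desc, float(t[i_max])


def predict_rate(fit: ArrheniusFit, temperature: float, constants: PhysicalConstants = CODATA) -> float:
    """Rate implied by a fitted limb at ``temperature`` (K)."""
    return math.exp(fit.lnA - fit.Ea / (constants.R * temperature))


# ---------------------------------------------------------------------------
# Eyring decomposition


def eyring_from_rate(k: float, T: float, constants: PhysicalConstants = CODATA) -> float:
    """Free energy of activation dG (J/mol) from a first-order rate.

    dG = R*T*ln(kappa*k_B*T/(h*k)).
    """
    if k <= 0 or T <= 0:
        raise ValueError("invalid kinetic input: k and T must be positive")
    c = constants
    return c.R * T * math.log(c.kappa * c.k_B * T / (c.h * k))


def rate_from_eyring(dG: float, T: float, constants: PhysicalConstants = CODATA) -> float:
    """Inverse of :func:`eyring_from_rate`."""
    if T <= 0:
        raise ValueError("invalid kinetic input: T must be positive")
    c = constants
    return c.kappa * c.k_B * T / c.h * math.exp(-dG / (c.R * T))


def arrhenius_to_eyring(
    fit: ArrheniusFit,
    k_at_Tref: float,
    T_ref: float,
    constants: PhysicalConstants = CODATA,
) -> EyringState:
    """Transition-state parameters at ``T_ref`` from an ascending-limb fit.

    Solution-phase convention: dH = Ea - R*T_ref; dG from the Eyring relation
    at the supplied rate; dS = (dH - dG)/T_ref.
    """
    if fit.limb != "ascending":
        raise ValueError("descending limb has no TST interpretation")
    if k_at_Tref <= 0:
        raise ValueError("invalid kinetic input: k_at_Tref must be positive")
    dH = fit.Ea - constants.R * T_ref
    dG = eyring_from_rate(k_at_Tref, T_ref, constants)
    dS = (dH - dG) / T_ref
    return EyringState(dG=dG, dH=dH, dS=dS, T_ref=T_ref)


def differential_activation(psychro: EyringState, meso: EyringState) -> DifferentialActivation:
    """Psychrophile-minus-mesophile differentials at the shared T_ref."""
    if psychro.T_ref != meso.T_ref:
        raise ValueError("reference temperature mismatch")
    T = psychro.T_ref
    return DifferentialActivation(
        ddG=psychro.dG - meso.dG,
        ddH=psychro.dH - meso.dH,
        TddS=T * (psychro.dS - meso.dS),
        T_ref=T,
    )


def differential_from_rates(
    psychro: ActivityTemperatureSeries,
    meso: ActivityTemperatureSeries,
    T1: float,
    T2: float,
    constants: PhysicalConstants = CODATA,
) -> DifferentialActivation:
    """Recover (ddG, ddH, T*ddS) at T_ref = ``T1`` from rate ratios at two
    grid temperatures.

    Uses ddG(T) = -R*T*ln(k_p/k_m) and the linearity ddG(T) = ddH - T*ddS to
    solve the two-point system; exact on noiseless data because any common
    inactivation factor cancels in the ratio.
    """
    if T1 == T2:
        raise ValueError("two distinct temperatures required")
    R = constants.R

    def ddg(T: float) -> float:
        return -R * T * math.log(psychro.rate_at(T) / meso.rate_at(T))

    g1, g2 = ddg(T1), ddg(T2)
    ddS = (g1 - g2) / (T2 - T1)
    ddH = g1 + T1 * ddS
    return DifferentialActivation(ddG=g1, ddH=ddH, TddS=T1 * ddS, T_ref=T1)


def activity_ratio_from_ddg(ddG: float, T: float, constants: PhysicalConstants = CODATA) -> float:
    """Rate ratio k_p/k_m implied by a ddG at temperature T.

    Returns exp(-ddG/(R*T)); > 1 iff ddG < 0 (psychrophile advantage).
    """
    if T <= 0:
        raise ValueError("invalid temperature")
    return math.exp(-ddG / (constants.R * T))


# ---------------------------------------------------------------------------
# Descriptive profile summaries


def summarize_profile(
    xs: Sequence[float],
    ys: Sequence[float],
    plateau_fraction: float = 0.9,
) -> ProfileSummary:
    """Optimum position and near-maximal plateau of an activity profile.

    The plateau is the maximal contiguous run around the optimum with
    activity >= plateau_fraction * max, reported only when it spans at least
    two grid steps (a single-point maximum is a peak, not a plateau).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("profile needs >=3 (x, y) points")
    if not np.all(np.diff(x) > 0):
        raise ValueError("profile positions must be strictly increasing")
    if np.all(y == 0):
        raise ValueError("empty profile: all activities are zero")
    y_max = float(y.max())
    idx_max = np.nonzero(y == y_max)[0]
    if idx_max.size > 1:
        logger.warning("tie for maximal activity; reporting the lowest position")
    i = int(idx_max[0])
    thr = plateau_fraction * y_max
    lo = i
    while lo > 0 and y[lo - 1] >= thr:
        lo -= 1
    hi = i
    while hi < y.size - 1 and y[hi + 1] >= thr:
        hi += 1
    plateau = (float(x[lo]), float(x[hi])) if hi - lo >= 2 else None
    return ProfileSummary(
        x_opt=float(x[i]), y_max=y_max, plateau=plateau, plateau_fraction=plateau_fraction
    )


def characterize_calcium_profile(
    ratios: Sequence[float],
    activities: Sequence[float],
) -> CalciumProfile:
    """Descriptive summary of a Ca2+-dependence curve.

    Reports the molar ratio at maximal activity and, when a zero-calcium
    point exists, activity(0)/max. Absence of a zero point is reported as
    ``None`` rather than interpolated.
    """
    r = np.asarray(ratios, dtype=float)
    a = np.asarray(activities, dtype=float)
    if r.size != a.size or r.size == 0:
        raise ValueError("ratios and activities must be non-empty and equal length")
    if np.any(r < 0) or not np.all(np.diff(r) > 0):
        raise ValueError("ratios must be non-negative and strictly increasing")
    if np.any(a < 0):
        raise ValueError("activities must be non-negative")
    a_max = float(a.max())
    ratio_at_max = float(r[int(np.argmax(a))])
    frac0 = float(a[0] / a_max) if r[0] == 0 and a_max > 0 else None
    return CalciumProfile(ratio_at_max=ratio_at_max, activity_fraction_at_zero=frac0)
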