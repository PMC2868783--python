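"""Single-species host binding of UCB and midpoint-pH analysis.

A pH-insensitive host (vesicle, micelle, cyclodextrin) that takes up one
ionization species with distribution ratio K = mols bound / mols free
binds the fraction

    F(pH) = K*f(pH) / (K*f(pH) + 1)

of total UCB, where f is that species' unbound fraction.  As f -> 1 the
curve approaches its asymptote F_max = K/(K+1); the midpoint pH is the pH
at which F = F_max/2, i.e. f = 1/(K+2).  For diacid binding F falls with
pH and the midpoint lies *above* the aqueous pKa's, shifting up with K;
for dianion binding F rises with pH and the midpoint lies *below* them,
shifting down with K — a general result independent of the pKa values
chosen.  Midpoints are computed in closed form (quadratic in 10**pH) and
cross-checked by bisection.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import NumericalError, ValidationError
from .speciation import HIGH_PKA, IonizationConstants, species_fractions

__all__ = [
    "Species",
    "HostBindingModel",
    "BindingCurve",
    "MidpointResult",
    "bound_fraction",
    "binding_curve",
    "midpoint_ph",
    "limiting_midpoint",
]


class Species(enum.Enum):
    """Which ionization species a host binds."""

    H2B = "H2B"
    HB = "HB"
    B = "B"


@dataclass(frozen=True)
class HostBindingModel:
    """A host binding one UCB species with distribution ratio ``k`` (bound/free)."""

    species: Species
    k: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k) and self.k >= 0):
            raise ValidationError("distribution ratio must be finite and >= 0")

    @property
    def f_max(self) -> float:
        """Asymptotic maximum of the bound fraction, K/(K+1)."""
        return self.k / (self.k + 1.0)


@dataclass(frozen=True)
class BindingCurve:
    """F(pH) sampled on a grid; F = [UCB]bound/[UCB]total."""

    ph_grid: tuple[float, ...]
    f_values: tuple[float, ...]


@dataclass(frozen=True)
class MidpointResult:
    ph: float
    f_max: float
    method: str  # "closed_form" or "bisection"


def _species_fraction(ph: float, species: Species, ks: IonizationConstants) -> float:
    fr = species_fractions(ph, ks)
    return {Species.H2B: fr.fh2b, Species.HB: fr.fhb, Species.B: fr.fb}[species]


def bound_fraction(
    ph: float, model: HostBindingModel, ks: IonizationConstants = HIGH_PKA
) -> float:
    """F = K*f/(K*f + 1) with f the unbound fraction of the bound species."""
    f = _species_fraction(ph, model.species, ks)
    kf = model.k * f
    return kf / (kf + 1.0)


def binding_curve(
    model: HostBindingModel,
    ks: IonizationConstants = HIGH_PKA,
    ph_grid: Sequence[float] = (),
) -> BindingCurve:
    """Element-wise bound fraction over a sorted pH grid."""
    grid = np.asarray(list(ph_grid), dtype=float)
    if grid.size == 0:
        raise ValidationError("pH grid must be non-empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValidationError("pH grid must be strictly increasing")
    vals = tuple(bound_fraction(ph, model, ks) for ph in grid)
    return BindingCurve(tuple(grid), vals)


def _solve_fraction_equals(
    species: Species, target: float, ks: IonizationConstants
) -> float:
    """Closed-form pH at which the species fraction equals ``target``.

    Let z = 10**pH.  For H2B: 1/D = t gives K1*K2*z**2 + K1*z - (1/t - 1) = 0.
    For B=: y/D = t gives (1/t - 1)*K1*K2*z**2 - K1*z - 1 = 0.  Each has a
    single positive root.  For HB- the fraction is not monotone; the
    ascending (low-pH) branch is returned:
    (x/D = t) -> t*K1*K2*z**2 + (t-1)*K1*z + t = 0, smaller root.
    """
    k1, k2 = ks.k1, ks.k2
    t = target
    if species is Species.H2B:
        a, b, c = k1 * k2, k1, -(1.0 / t - 1.0)
        z = (-b + math.sqrt(b * b - 4.0 * a * c)) / (2.0 * a)
    elif species is Species.B:
        a, b, c = (1.0 / t - 1.0) * k1 * k2, -k1, -1.0
        z = (-b + math.sqrt(b * b - 4.0 * a * c)) / (2.0 * a)
    else:
        a, b, c = t * k1 * k2, (t - 1.0) * k1, t
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise NumericalError("target exceeds the maximum monoanion fraction")
        # stable smaller root (b < 0 for t < 1)
        z = 2.0 * c / (-b + math.sqrt(disc))
    if z <= 0:
        raise NumericalError("no positive root for the requested fraction")
    return math.log10(z)


def _max_fraction(species: Species, ks: IonizationConstants) -> float:
    """Supremum of the species fraction over pH."""
    if species in (Species.H2B, Species.B):
        return 1.0
    # fHB peaks at pH = (pKa1+pKa2)/2 with value 1/(1 + 2*sqrt(K2/K1))
    return 1.0 / (1.0 + 2.0 * math.sqrt(ks.k2 / ks.k1))


def midpoint_ph(
    model: HostBindingModel,
    ks: IonizationConstants = HIGH_PKA,
    method: str = "closed_form",
) -> MidpointResult:
    """pH at which binding reaches half its asymptotic maximum.

    Solves F(pH) = F_peak/2 where F_peak is the maximum of F over pH.
    For diacid and dianion hosts the bound species' fraction approaches 1
    so F_peak = K/(K+1) and the condition reduces to f = 1/(K+2); for a
    monoanion host, whose fraction peaks below 1 at f_peak, the general
    condition f = f_peak/(K*f_peak + 2) is used (same formula with
    f_peak = 1), and the ascending (low-pH) branch is returned.
    ``method`` selects the closed-form quadratic root or a bisection
    cross-check; they agree to ~1e-10.
    """
    if model.k <= 0:
        raise ValidationError("midpoint requires a positive distribution ratio")
    f_peak = _max_fraction(model.species, ks)
    target = f_peak / (model.k * f_peak + 2.0)
    f_max = model.k * f_peak / (model.k * f_peak + 1.0)
    if method == "closed_form":
        ph = _solve_fraction_equals(model.species, target, ks)
    elif method == "bisection":
        func = lambda p: _species_fraction(p, model.species, ks) - target
        lo = -5.0
        # for the monoanion stay on the ascending branch left of the peak
        hi = (ks.pka1 + ks.pka2) / 2.0 if model.species is Species.HB else 25.0
        if func(lo) * func(hi) > 0:
            raise NumericalError("no sign change in bisection bracket")
        ph = brentq(func, lo, hi, xtol=1e-12)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return MidpointResult(ph=ph, f_max=f_max, method=method)


def limiting_midpoint(species: Species, ks: IonizationConstants = HIGH_PKA) -> float:
    """Midpoint pH in the weak-binding limit K -> 0.

    As K vanishes the midpoint condition f = 1/(K+2) tends to f equal to
    half the species' own maximum over pH (1 for H2B and B=).
    """
    return _solve_fraction_equals(species, _max_fraction(species, ks) / 2.0, ks)
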