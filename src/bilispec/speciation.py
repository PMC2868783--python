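"""Diprotic-acid equilibria of unconjugated bilirubin (UCB).

UCB is a sparingly soluble diprotic tetrapyrrole acid.  Its unbound,
monomeric pool is distributed over three ionization species — the diacid
H2B, the monoanions HB- and the dianion B= — according to two successive
acid dissociation constants.  Writing [H+] = 10**-pH, K1 = 10**-pKa1 and
K2 = 10**-pKa2, the total monomer concentration is

    Bm = [H2B] * (1 + K1/[H+] + K1*K2/[H+]**2)

so the species fractions depend on pH and the pKa pair alone.  On top of
the monomer equilibria this module carries the two self-association /
saturation phenomena the downstream binding models need:

* dimerization of the dianion, 2 B= <-> (B=)2, with a per-micromolar
  equilibrium constant KD (default 0.26 uM**-1), and
* the pH-dependent equilibrium solubility of the diacid-saturated
  solution, St(pH) = S_H2B * (1 + 10**(pH-pKa1) + 10**(2*pH-pKa_sum)),
  whose ratio to the actual free concentration is the supersaturation
  ratio R.

All concentrations are micromolar and all logarithms base 10.  Ionic
strength and temperature are not modeled; every constant is a conditional
constant valid for the medium in which it was determined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "IonizationConstants",
    "SpeciesFractions",
    "DimerizationModel",
    "SolubilityModel",
    "MonomerComposition",
    "HIGH_PKA",
    "LOW_PKA",
    "species_fractions",
    "fraction_table",
    "monomer_composition_from_total",
    "total_solubility",
    "dianion_saturation",
    "saturation_ratio",
]


@dataclass(frozen=True)
class IonizationConstants:
    """The pKa pair of a diprotic acid.

    ``pka1`` governs H2B -> HB- and ``pka2`` HB- -> B=.  The pair is not
    required to be ordered: both the partition-derived high values
    (8.12, 8.44) and the literature low values (4.2, 4.9) are accepted.
    """

    pka1: float
    pka2: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pka1) and math.isfinite(self.pka2)):
            raise ValidationError("pKa values must be finite")

    @property
    def k1(self) -> float:
        return 10.0 ** (-self.pka1)

    @property
    def k2(self) -> float:
        return 10.0 ** (-self.pka2)

    @property
    def pka_sum(self) -> float:
        return self.pka1 + self.pka2


#: Solvent-partition-derived pKa pair for UCB.
HIGH_PKA = IonizationConstants(8.12, 8.44)
#: Low pKa pair advocated elsewhere in the literature; used as a counterfactual.
LOW_PKA = IonizationConstants(4.2, 4.9)


@dataclass(frozen=True)
class SpeciesFractions:
    """Fractions of unbound *monomeric* UCB: diacid, monoanion, dianion."""

    fh2b: float
    fhb: float
    fb: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.fh2b, self.fhb, self.fb)


@dataclass(frozen=True)
class DimerizationModel:
    """Dianion self-association 2 B= <-> (B=)2, KD in uM**-1 (default 0.26)."""

    kd: float = 0.26

    def __post_init__(self) -> None:
        if not (math.isfinite(self.kd) and self.kd >= 0):
            raise ValidationError("dimerization constant must be finite and >= 0")


#: Convenience instance that switches self-association off.
NO_DIMER = DimerizationModel(0.0)


@dataclass(frozen=True)
class SolubilityModel:
    """Equilibrium solubility of the diacid and the pKa sum that scales it.

    ``s_h2b`` is the aqueous solubility of H2B in uM (default 0.051, i.e.
    51 nM) and ``pka_sum`` the sum pKa1 + pKa2 (default 16.56), which
    controls the dianion term 10**(2*pH - pka_sum).
    """

    s_h2b: float = 0.051
    pka_sum: float = 16.56

    def __post_init__(self) -> None:
        if not (math.isfinite(self.s_h2b) and self.s_h2b > 0):
            raise ValidationError("diacid solubility must be finite and > 0")


@dataclass(frozen=True)
class MonomerComposition:
    """Concentrations (uM) of the free species and the dianion dimer.

    Mass balance counts each dimer as two monomer units:
    ``ch2b + chb + cb + 2*cdimer == total_free``.
    """

    ch2b: float
    chb: float
    cb: float
    cdimer: float

    @property
    def total_free(self) -> float:
        return self.ch2b + self.chb + self.cb + 2.0 * self.cdimer


def _ratio_terms(ph: float, ks: IonizationConstants) -> tuple[float, float]:
    """Return (x, y) = ([HB-]/[H2B], [B=]/[H2B]) at ``ph``."""
    x = 10.0 ** (ph - ks.pka1)
    y = 10.0 ** (2.0 * ph - ks.pka1 - ks.pka2)
    return x, y


def species_fractions(ph: float, ks: IonizationConstants) -> SpeciesFractions:
    """Fractions of unbound monomeric UCB at one pH.

    With x = 10**(pH-pKa1) and y = 10**(2*pH-pKa1-pKa2) the denominator is
    D = 1 + x + y and the fractions are (1/D, x/D, y/D); they always sum
    to one.
    """
    if not math.isfinite(ph):
        raise ValidationError("pH must be finite")
    x, y = _ratio_terms(ph, ks)
    if math.isinf(x) or math.isinf(y):
        # far-alkaline limit: everything is dianion
        return SpeciesFractions(0.0, 0.0, 1.0)
    d = 1.0 + x + y
    return SpeciesFractions(1.0 / d, x / d, y / d)


def fraction_table(ph_grid: Sequence[float], ks: IonizationConstants):
    """Species fractions over a strictly increasing pH grid.

    Returns a pandas DataFrame with columns ``pH, fH2B, fHB, fB``.
    Values are carried at full precision; rounding (4 d.p. in the printed
    reference tables) is presentation-layer only.
    """
    import pandas as pd

    grid = np.asarray(list(ph_grid), dtype=float)
    if grid.size == 0:
        raise ValidationError("pH grid must be non-empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValidationError("pH grid must be strictly increasing")
    rows = [species_fractions(ph, ks).as_tuple() for ph in grid]
    arr = np.array(rows)
    return pd.DataFrame(
        {"pH": grid, "fH2B": arr[:, 0], "fHB": arr[:, 1], "fB": arr[:, 2]}
    )


def monomer_composition_from_total(
    total_free: float,
    ph: float,
    ks: IonizationConstants,
    dim: DimerizationModel = DimerizationModel(),
) -> MonomerComposition:
    """Split a total free UCB concentration into monomer species + dimer.

    Solves the mass balance

        total_free = cH2B*(1 + x + y) + 2*KD*cB**2,   cB = y*cH2B,

    a quadratic in cB:  2*KD*cB**2 + (D/y)*cB - total_free = 0 with
    D = 1 + x + y.  The unique non-negative root is taken with the
    numerically stable q-form  cB = 2*total / (b + sqrt(b**2 + 8*KD*total))
    (b = D/y), which avoids cancellation when KD*cB << 1.  With KD = 0
    this reduces exactly to the fraction split.
    """
    if not (math.isfinite(total_free) and total_free >= 0):
        raise ValidationError("total_free must be finite and >= 0")
    fr = species_fractions(ph, ks)
    if dim.kd == 0.0 or fr.fb == 0.0 or total_free == 0.0:
        return MonomerComposition(
            total_free * fr.fh2b, total_free * fr.fhb, total_free * fr.fb, 0.0
        )
    x, y = _ratio_terms(ph, ks)
    d = 1.0 + x + y
    b = d / y  # total monomer per unit of cB
    cb = 2.0 * total_free / (b + math.sqrt(b * b + 8.0 * dim.kd * total_free))
    ch2b = cb / y
    chb = ch2b * x
    cdimer = dim.kd * cb * cb
    return MonomerComposition(ch2b, chb, cb, cdimer)


def total_solubility(
    ph: float,
    sol: SolubilityModel = SolubilityModel(),
    ks: IonizationConstants = HIGH_PKA,
) -> float:
    """Total monomeric solubility St(pH) in uM with [H2B] pinned at S_H2B.

    St = S_H2B * (1 + 10**(pH - pKa1) + 10**(2*pH - pKa_sum)).  The
    monoanion term uses pKa1 from ``ks``; the dianion term uses the
    (independently better-determined) pKa sum from ``sol``.
    """
    if not math.isfinite(ph):
        raise ValidationError("pH must be finite")
    return sol.s_h2b * (
        1.0 + 10.0 ** (ph - ks.pka1) + 10.0 ** (2.0 * ph - sol.pka_sum)
    )


def dianion_saturation(ph: float, sol: SolubilityModel = SolubilityModel()) -> float:
    """Free dianion concentration (uM) of a saturated solution.

    [B=]sat = S_H2B * 10**(2*pH - pKa_sum); the excess forms a suspension.
    """
    if not math.isfinite(ph):
        raise ValidationError("pH must be finite")
    return sol.s_h2b * 10.0 ** (2.0 * ph - sol.pka_sum)


def saturation_ratio(
    free_total: float,
    ph: float,
    sol: SolubilityModel = SolubilityModel(),
    ks: IonizationConstants = HIGH_PKA,
) -> float:
    """Supersaturation ratio R = free UCB / equilibrium solubility at pH.

    R > 1 marks a metastable, kinetically trapped (supersaturated)
    solution.
    """
    if not (math.isfinite(free_total) and free_total >= 0):
        raise ValidationError("free_total must be finite and >= 0")
    return free_total / total_solubility(ph, sol, ks)
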