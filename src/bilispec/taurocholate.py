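"""UCB in 50 mM taurocholate (TC) micelles: partition, apparent pKa, CD.

Taurine-conjugated bile salts are fully ionized across pH 4-10, so the
pH dependence of UCB uptake into 50 mM TC micelles reflects the pigment
alone.  Each species partitions with its own micelle/water distribution
ratio (bound/free), at 50 mM TC: 1.41 for H2B, 12.9 for HB- and 730 for
B=.  With x = 10**(pH-pKa1) and y = 10**(2*pH-pKa1-pKa2) the fraction of
*total* UCB bound as each species is

    fs_i = K_i * w_i / T,  w = (1, x, y),  T = sum_i (1 + K_i) * w_i

Preferential uptake of the more ionized species shifts the apparent pKa
down from its aqueous value by the log ratio of adjacent distribution
ratios:  pKa_app = pKa_aq + log10(K_upstream / K_downstream), giving 7.16
and 6.69 (sum 13.85) against the aqueous 8.12 and 8.44.

The chloroform -> aqueous-TC partition ratio of total UCB follows

    log10 P = log10 Po - log10(1 + 10**(pH-A) + 10**(2*pH-B))

with A = 7.36 and B = 14.08 the apparent pKa's of the whole TC system.
(The source equation was printed without the logarithm on the bracket,
which is dimensionally inconsistent; the -log10 form is the one that
matches the monotone decrease of partition with pH.)

The CD signal at 458 nm is modeled as a two-coefficient combination of
the bound-species fractions, 10^3*theta = A* fs_HB + B* fs_B, fitted by
no-intercept least squares; bound monoanion contributes a large negative
ellipticity (A* ~ -98.7) and bound dianion a modest positive one
(B* ~ 5.24).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from .errors import ValidationError
from .regression import FitStats, lstsq_no_intercept
from .speciation import HIGH_PKA, IonizationConstants

__all__ = [
    "MicelleDistribution",
    "TcPartitionParams",
    "BoundSpeciesFractions",
    "EllipticityModel",
    "bound_species_fractions",
    "apparent_pka",
    "log_partition",
    "predict_ellipticity",
    "fit_ellipticity",
    "scale_ellipticity",
    "load_reference_table",
]


@dataclass(frozen=True)
class MicelleDistribution:
    """Per-species micelle/water distribution ratios (bound/free) at 50 mM TC."""

    k_h2b: float = 1.41
    k_hb: float = 12.9
    k_b: float = 730.0

    def __post_init__(self) -> None:
        if min(self.k_h2b, self.k_hb, self.k_b) < 0:
            raise ValidationError("distribution ratios must be >= 0")


@dataclass(frozen=True)
class TcPartitionParams:
    """Parameters of the chloroform/aqueous-TC partition profile.

    ``a`` and ``b`` are the apparent first pKa and pKa sum of the whole
    50 mM TC system (defaults 7.36 and 14.08); ``log_po`` the low-pH
    plateau log partition ratio of the diacid.
    """

    log_po: float = 0.0
    a: float = 7.36
    b: float = 14.08

    def __post_init__(self) -> None:
        for name in ("log_po", "a", "b"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")


@dataclass(frozen=True)
class BoundSpeciesFractions:
    """Fractions of total UCB bound to micelles as each species (rest is free)."""

    fs_h2b: float
    fs_hb: float
    fs_b: float

    @property
    def total_bound(self) -> float:
        return self.fs_h2b + self.fs_hb + self.fs_b


@dataclass(frozen=True)
class EllipticityModel:
    """Coefficients of 10^3*theta = A* fs_HB + B* fs_B with fit statistics."""

    a_star: float = -98.7
    b_star: float = 5.24
    r: float = float("nan")
    sd: float = float("nan")
    n: int = 0
    stderr: tuple[float, float] = (float("nan"), float("nan"))


def bound_species_fractions(
    ph: float,
    dist: MicelleDistribution = MicelleDistribution(),
    ks: IonizationConstants = HIGH_PKA,
) -> BoundSpeciesFractions:
    """Fractions of total UCB present as each micelle-bound species at one pH."""
    if not math.isfinite(ph):
        raise ValidationError("pH must be finite")
    x = 10.0 ** (ph - ks.pka1)
    y = 10.0 ** (2.0 * ph - ks.pka1 - ks.pka2)
    t = (1.0 + dist.k_h2b) + (1.0 + dist.k_hb) * x + (1.0 + dist.k_b) * y
    return BoundSpeciesFractions(
        dist.k_h2b / t, dist.k_hb * x / t, dist.k_b * y / t
    )


def apparent_pka(pka_aq: float, k_upstream: float, k_downstream: float) -> float:
    """Apparent pKa of a micelle-solubilized acid.

    Preferential uptake of the more ionized (downstream) species shifts
    the step down:  pKa_app = pKa_aq + log10(K_upstream / K_downstream).
    Also valid for the pKa *sum* with the diacid and dianion ratios.
    """
    if k_upstream <= 0 or k_downstream <= 0:
        raise ValidationError("distribution ratios must be positive")
    return pka_aq + math.log10(k_upstream / k_downstream)


def log_partition(ph: float, p: TcPartitionParams = TcPartitionParams()) -> float:
    """log10 of the chloroform/aqueous partition ratio of total UCB at ``ph``."""
    if not math.isfinite(ph):
        raise ValidationError("pH must be finite")
    return p.log_po - math.log10(
        1.0 + 10.0 ** (ph - p.a) + 10.0 ** (2.0 * ph - p.b)
    )


def predict_ellipticity(
    frac: BoundSpeciesFractions, m: EllipticityModel = EllipticityModel()
) -> float:
    """10^3*theta = A* fs_HB + B* fs_B."""
    return m.a_star * frac.fs_hb + m.b_star * frac.fs_b


def fit_ellipticity(
    points: Sequence[tuple[float, float, float]]
) -> EllipticityModel:
    """No-intercept least squares of theta on (fs_HB, fs_B).

    ``points`` are (fs_HB, fs_B, theta) triples on a common concentration
    basis.  Residual SD uses an n-2 denominator and r is the Pearson
    correlation of observed vs fitted.
    """
    if len(points) < 2:
        raise ValidationError("at least two points are required")
    x = [[p[0], p[1]] for p in points]
    y = [p[2] for p in points]
    stats: FitStats = lstsq_no_intercept(x, y)
    return EllipticityModel(
        a_star=stats.coefficients[0],
        b_star=stats.coefficients[1],
        r=stats.r,
        sd=stats.sd,
        n=stats.n,
        stderr=(stats.stderr[0], stats.stderr[1]),
    )


def scale_ellipticity(theta: float, from_conc: float, to_conc: float) -> float:
    """Rescale a CD reading to a different total UCB concentration basis."""
    if from_conc <= 0:
        raise ValidationError("from_conc must be positive")
    return theta * to_conc / from_conc


def load_reference_table():
    """Packaged reference dataset: CD of UCB in 50 mM sodium taurocholate.

    Seven (pH, theta) observations at 458 nm with the bound-species
    fractions from the partition analysis.  Readings taken at 4.6 uM
    total UCB are already scaled to the 34 uM basis (factor 34/4.6).
    Returns a pandas DataFrame with columns
    ``pH, conc_uM, theta_exp, fs_hb, fs_b, theta_calc``.
    """
    import pandas as pd

    path = resources.files("bilispec.data").joinpath("tc_ellipticity_50mM.csv")
    with resources.as_file(path) as fp:
        return pd.read_csv(fp, comment="#")
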