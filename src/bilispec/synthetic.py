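"""Synthetic titration datasets for end-to-end and parameter-recovery tests.

Each generator evaluates the deterministic model curve of one analysis
stage on a pH grid and adds independent Gaussian noise of configurable
SD, seeded through ``numpy.random.default_rng`` — a pure function of
(parameters, seed).  Noise SD defaults mirror the residual scales of the
corresponding published fits (0.002 on nbar, 1.1 on 10^3*theta).
Observables with hard physical bounds (vesicle nbar) are clipped to
them, a deliberate slight deviation from pure Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cyclodextrin import CdxSystem, predict_ellipticity as _cdx_ellipticity
from .errors import ValidationError
from .io import TitrationDataset
from .speciation import HIGH_PKA, DimerizationModel, IonizationConstants
from .taurocholate import (
    EllipticityModel,
    MicelleDistribution,
    bound_species_fractions,
    predict_ellipticity as _tc_ellipticity,
)
from .vesicle import VesicleSystem, predict_nbar

__all__ = [
    "NoiseSpec",
    "gen_vesicle_dataset",
    "gen_tc_dataset",
    "gen_cdx_dataset",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: standard deviation (observable units) and seed."""

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sd) and self.sd >= 0):
            raise ValidationError("noise SD must be finite and >= 0")


def _check_grid(ph_grid: Sequence[float]) -> np.ndarray:
    grid = np.asarray(list(ph_grid), dtype=float)
    if grid.size == 0:
        raise ValidationError("pH grid must be non-empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValidationError("pH grid must be strictly increasing")
    if grid.min() < 4.0 or grid.max() > 12.0:
        raise ValidationError("pH grid must lie within [4, 12]")
    return grid


def _noisy(clean: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    if noise.sd == 0.0:
        return clean.copy()
    rng = np.random.default_rng(noise.seed)
    return clean + rng.normal(0.0, noise.sd, size=clean.shape)


def gen_vesicle_dataset(
    k_dblprime: float,
    ph_grid: Sequence[float],
    sys: VesicleSystem = VesicleSystem(),
    ks: IonizationConstants = HIGH_PKA,
    dim: DimerizationModel = DimerizationModel(),
    noise: NoiseSpec = NoiseSpec(),
) -> TitrationDataset:
    """nbar titration from the vesicle partition model.

    Noise is clipped only at the upper physical bound Bt/PC (beyond which
    the free pool would be negative).  Small negative nbar readings are
    kept: where the model curve lies below the noise floor, truncating at
    zero would bias the mean-of-ratios K'' estimator upward.
    """
    grid = _check_grid(ph_grid)
    clean = np.array([predict_nbar(ph, k_dblprime, sys, ks, dim) for ph in grid])
    vals = np.minimum(_noisy(clean, noise), sys.nbar_max)
    return TitrationDataset(
        observable_kind="nbar",
        ph=tuple(grid),
        values=tuple(vals),
        metadata={
            "generator": "gen_vesicle_dataset",
            "k_dblprime": k_dblprime,
            "total_ucb_uM": sys.total_ucb,
            "total_pc_uM": sys.total_pc,
            "noise_sd": noise.sd,
            "seed": noise.seed,
        },
    )


def gen_tc_dataset(
    a_star: float,
    b_star: float,
    ph_grid: Sequence[float],
    dist: MicelleDistribution = MicelleDistribution(),
    ks: IonizationConstants = HIGH_PKA,
    noise: NoiseSpec = NoiseSpec(),
) -> TitrationDataset:
    """10^3*theta titration from the two-coefficient bile-salt CD model."""
    grid = _check_grid(ph_grid)
    model = EllipticityModel(a_star=a_star, b_star=b_star)
    clean = np.array(
        [_tc_ellipticity(bound_species_fractions(ph, dist, ks), model) for ph in grid]
    )
    vals = _noisy(clean, noise)
    return TitrationDataset(
        observable_kind="theta",
        ph=tuple(grid),
        values=tuple(vals),
        metadata={
            "generator": "gen_tc_dataset",
            "a_star": a_star,
            "b_star": b_star,
            "noise_sd": noise.sd,
            "seed": noise.seed,
        },
    )


def gen_cdx_dataset(
    q: float,
    ph_grid: Sequence[float],
    sys: CdxSystem = CdxSystem(),
    ks: IonizationConstants = HIGH_PKA,
    dim: DimerizationModel = DimerizationModel(),
    noise: NoiseSpec = NoiseSpec(),
) -> TitrationDataset:
    """delta_eps titration from the cyclodextrin dianion-signal model."""
    grid = _check_grid(ph_grid)
    cdx = CdxSystem(
        affinity=sys.affinity, cdx_conc=sys.cdx_conc, total_ucb=sys.total_ucb, q=q
    )
    clean = np.array([_cdx_ellipticity(ph, cdx, ks, dim) for ph in grid])
    vals = _noisy(clean, noise)
    return TitrationDataset(
        observable_kind="delta_eps",
        ph=tuple(grid),
        values=tuple(vals),
        metadata={
            "generator": "gen_cdx_dataset",
            "q": q,
            "noise_sd": noise.sd,
            "seed": noise.seed,
        },
    )
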