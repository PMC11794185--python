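"""Low-frequency conductivity from CTI maps and the high-frequency atlas.

The position-wise scale factor relating extracellular diffusivity to
conductivity is

    eta = alpha * sigma_H / (alpha * de + beta * (1 - alpha) * di)

and the effective isotropic low-frequency conductivity is
``sigma_L = eta * de``. ``beta`` is the ratio of intracellular to
extracellular ionic concentrations; it cannot be estimated from diffusion
data and defaults to 0.41 after the CTI literature this pipeline follows.

With nonnegative inputs ``0 <= sigma_L <= sigma_H`` holds voxelwise, with
equality when ``alpha = 1`` or ``di = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BETA_DEFAULT, DENOMINATOR_FLOOR
from .volumes import AlignmentError

__all__ = ["CtiConfig", "ConductivityVolume", "sigma_low"]


@dataclass(frozen=True)
class CtiConfig:
    """Tunables of the diffusion-to-conductivity relation."""

    beta: float = BETA_DEFAULT
    denominator_floor: float = DENOMINATOR_FLOOR

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.denominator_floor < 0:
            raise ValueError("denominator_floor must be >= 0")


@dataclass
class ConductivityVolume:
    """sigma_L (S/m) and the scale factor eta, with a validity mask."""

    sigma_l: np.ndarray
    eta: np.ndarray
    valid_mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    model: str = ""


def sigma_low(cti, sigma_h, cfg: CtiConfig = CtiConfig()) -> ConductivityVolume:
    """Voxelwise sigma_L from CTI maps and a sigma_H volume.

    Parameters
    ----------
    cti : CtiMaps
        Adapter output (alpha, di, de, valid_mask).
    sigma_h : SigmaHAtlas or ndarray
        High-frequency conductivity volume, S/m, on the same grid.
    cfg : CtiConfig
        beta and the denominator floor below which a voxel is masked.

    Voxels are masked (sigma_L = 0, valid False) where the denominator
    ``alpha*de + beta*(1-alpha)*di`` falls below the floor, where
    sigma_H = 0 (background), or where the adapter already masked them.
    """
    sh_arr = np.asarray(getattr(sigma_h, "sigma_h", sigma_h), dtype=float)
    if sh_arr.shape != cti.alpha.shape:
        raise AlignmentError(
            f"sigma_H grid {sh_arr.shape} does not match CTI grid {cti.alpha.shape}"
        )
    sh_affine = getattr(sigma_h, "affine", None)
    if sh_affine is not None and not np.allclose(sh_affine, cti.affine, atol=1e-6):
        raise AlignmentError("sigma_H affine does not match CTI affine")

    alpha, di, de = cti.alpha, cti.di, cti.de
    denom = alpha * de + cfg.beta * (1.0 - alpha) * di
    valid = cti.valid_mask & (denom >= cfg.denominator_floor) & (sh_arr > 0)
    safe = np.where(valid, denom, 1.0)
    eta = np.where(valid, alpha * sh_arr / safe, 0.0)
    sigma_l = np.where(valid, eta * de, 0.0)
    return ConductivityVolume(
        sigma_l=sigma_l, eta=eta, valid_mask=valid, affine=cti.affine, model=cti.model
    )
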