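"""Convert fitted micro-structure parameter maps to the CTI triplet (alpha, di, de).

Each diffusion model (NODDI, SANDI, SMT) is reduced to the three scalar
quantities the conductivity relation needs per voxel:

* ``alpha`` — extracellular volume fraction,
* ``di``   — intracellular (direction-averaged) diffusivity, mm^2/s,
* ``de``   — extracellular (direction-averaged) diffusivity, mm^2/s.

The NODDI route goes through the Watson-distribution orientation machinery:
the orientation dispersion index maps to a concentration parameter
``kappa = 1 / tan(pi * ODI / 2)``, which maps to the orientation coherence
``tau = E[cos^2 theta]`` of stick orientations, used in the extracellular
tortuosity expressions.

Two published conventions exist for the NODDI tortuosity step and both are
supported through ``noddi_scaling``:

* ``"scaled"`` (default) — the parallel diffusivity entering the
  tortuosity expressions is pre-scaled by ``fi * (1 - fiso)``;
* ``"canonical"`` — the tortuosity uses the unscaled intrinsic stick
  diffusivity, as in the original NODDI extracellular model.

The scaled form compresses extracellular diffusivities wherever the neurite
fraction is small; it is kept as the default because it is the convention
this pipeline's reference analysis used, and the switch makes the
difference auditable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import dawsn

from .constants import DECW, KAPPA_CAP, NODDI_D_ISO, NODDI_D_PAR, SANDI_D_IS

logger = logging.getLogger(__name__)

__all__ = [
    "CtiMaps",
    "kappa_from_odi",
    "odi_from_kappa",
    "tau_from_kappa",
    "noddi_to_cti",
    "sandi_to_cti",
    "smt_to_cti",
    "cti_alpha_de",
]


@dataclass
class CtiMaps:
    """Aligned alpha / di / de maps — the common currency of all adapters.

    ``valid_mask`` is False where a conversion was degenerate (for example a
    voxel with no extracellular space, where ``de`` is undefined) or where an
    input was NaN; masked voxels are excluded from all downstream statistics.
    """

    alpha: np.ndarray
    di: np.ndarray
    de: np.ndarray
    valid_mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    model: str = ""


class DomainError(ValueError):
    """Input outside the mathematical domain of an adapter function."""


def _clip_with_warning(x: np.ndarray, lo: float, hi: float, name: str) -> np.ndarray:
    """Clip to [lo, hi]; fitted real maps routinely contain small violations."""
    x = np.asarray(x, dtype=float)
    bad = np.count_nonzero((x < lo) | (x > hi) & ~np.isnan(x))
    if bad:
        warnings.warn(
            f"{name}: {bad} voxel(s) outside [{lo}, {hi}] clipped", stacklevel=3
        )
    return np.clip(x, lo, hi)


def kappa_from_odi(odi, cap: float = KAPPA_CAP):
    """Watson concentration parameter from the orientation dispersion index.

    ``kappa = 1 / tan(pi * ODI / 2)``: ODI = 1 is fully dispersed
    (kappa = 0), ODI -> 0 is perfectly coherent (kappa -> infinity, capped
    at ``cap``).

    Raises :class:`DomainError` for ODI outside [0, 1]. ODI = 0 returns the
    cap rather than raising: fitted maps legitimately reach 0 in coherent
    white matter.
    """
    odi_arr = np.asarray(odi, dtype=float)
    if np.any((odi_arr < 0) | (odi_arr > 1)):
        raise DomainError("ODI must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        k = 1.0 / np.tan(np.pi * odi_arr / 2.0)
    k = np.where(odi_arr <= 0, cap, np.minimum(k, cap))
    # tan(pi/2) is finite-but-huge in floating point; pin the ODI=1 endpoint
    k = np.where(odi_arr >= 1, 0.0, k)
    return k if k.ndim else float(k)


def odi_from_kappa(kappa):
    """Inverse of :func:`kappa_from_odi` (used for round-trip checking)."""
    k = np.asarray(kappa, dtype=float)
    if np.any(k < 0):
        raise DomainError("kappa must be >= 0")
    odi = 2.0 / np.pi * np.arctan2(1.0, k)
    return odi if odi.ndim else float(odi)


_TAU_SERIES_CUTOFF = 1e-6


def tau_from_kappa(kappa):
    """Orientation coherence tau = E[cos^2 theta] under the Watson density.

    Computed as ``tau(k) = -1/(2k) + 1/(2*sqrt(k)*D(sqrt(k)))`` with ``D``
    the Dawson function; tau runs from 1/3 (isotropic, kappa -> 0) to 1
    (perfectly coherent, kappa -> infinity). Below ``kappa = 1e-6`` the
    Taylor expansion ``1/3 + 4*kappa/45`` is used to avoid cancellation.
    """
    k = np.asarray(kappa, dtype=float)
    if np.any(k < 0):
        raise DomainError("kappa must be >= 0")
    small = k < _TAU_SERIES_CUTOFF
    ks = np.where(small, 1.0, k)  # placeholder to keep sqrt/division finite
    s = np.sqrt(ks)
    tau = -1.0 / (2.0 * ks) + 1.0 / (2.0 * s * dawsn(s))
    tau = np.where(small, 1.0 / 3.0 + 4.0 * k / 45.0, tau)
    tau = np.clip(tau, 1.0 / 3.0, 1.0)
    return tau if tau.ndim else float(tau)


def noddi_to_cti(
    fi,
    odi,
    fiso,
    d_par: float = NODDI_D_PAR,
    d_iso: float = NODDI_D_ISO,
    noddi_scaling: str = "scaled",
    affine: np.ndarray | None = None,
) -> CtiMaps:
    """NODDI (fi, ODI, fiso) maps to CTI (alpha, di, de).

    Per voxel, with ``tau = tau(kappa(ODI))``::

        di_par = fi * (1 - fiso) * d_par      ("scaled"; "canonical": d_par)
        di     = di_par / 3                   (di_perp = 0, sticks)
        de_par = di_par * (1 - fi * (1 - tau))
        de_perp= di_par * (1 - fi * (1 + tau) / 2)
        decm   = (de_par + 2 * de_perp) / 3
        alpha  = fiso + (1 - fiso) * (1 - fi)
        de     = [(1-fiso)(1-fi) * decm + fiso * d_iso] / alpha

    ``alpha = 0`` (a purely intracellular voxel, fi = 1 and fiso = 0) leaves
    ``de`` undefined and is masked rather than raised.
    """
    if noddi_scaling not in ("scaled", "canonical"):
        raise ValueError(f"unknown noddi_scaling {noddi_scaling!r}")
    fi = _clip_with_warning(fi, 0.0, 1.0, "fi")
    fiso = _clip_with_warning(fiso, 0.0, 1.0, "fiso")
    odi = _clip_with_warning(odi, 0.0, 1.0, "odi")

    tau = tau_from_kappa(kappa_from_odi(odi))
    di_par_scaled = fi * (1.0 - fiso) * d_par
    tort_base = di_par_scaled if noddi_scaling == "scaled" else np.broadcast_to(
        float(d_par), np.shape(di_par_scaled)
    )
    di = di_par_scaled / 3.0
    de_par = tort_base * (1.0 - fi * (1.0 - tau))
    de_perp = tort_base * (1.0 - fi * (1.0 + tau) / 2.0)
    decm = (de_par + 2.0 * de_perp) / 3.0

    alpha = fiso + (1.0 - fiso) * (1.0 - fi)
    num = (1.0 - fiso) * (1.0 - fi) * decm + fiso * d_iso
    with np.errstate(divide="ignore", invalid="ignore"):
        de = np.where(alpha > 0, num / np.where(alpha > 0, alpha, 1.0), 0.0)

    valid = (alpha > 0) & np.isfinite(alpha) & np.isfinite(di) & np.isfinite(de)
    return _finish(alpha, di, de, valid, affine, "noddi")


def sandi_to_cti(
    fe,
    fin,
    Din,
    Dec,
    Dis: float = SANDI_D_IS,
    affine: np.ndarray | None = None,
) -> CtiMaps:
    """SANDI (fe, fin, Din, Dec) maps to CTI (alpha, di, de).

    ``alpha = fe``; ``di = (1 - fe) * (fin * Din + (1 - fin) * Dis)``;
    ``de = fe * Dec``. The soma diffusivity ``Dis`` is the model's fixed
    3e-3 mm^2/s unless overridden. The ``(1 - fe)`` scaling of ``di`` is a
    convention of the source analysis and is applied as stated.
    """
    fe = _clip_with_warning(fe, 0.0, 1.0, "fe")
    fin = _clip_with_warning(fin, 0.0, 1.0, "fin")
    Din = _clip_with_warning(Din, 0.0, np.inf, "Din")
    Dec = _clip_with_warning(Dec, 0.0, np.inf, "Dec")

    alpha = fe
    di = (1.0 - fe) * (fin * Din + (1.0 - fin) * Dis)
    de = fe * Dec
    valid = np.isfinite(alpha) & np.isfinite(di) & np.isfinite(de)
    return _finish(alpha, di, de, valid, affine, "sandi")


def smt_to_cti(fin, Din, De, affine: np.ndarray | None = None) -> CtiMaps:
    """SMT (fin, Din, De) maps to CTI (alpha, di, de).

    The intra-neurite fraction is the intracellular fraction:
    ``alpha = 1 - fin``, ``di = fin * Din``, and the extra-neurite
    microscopic mean diffusivity is taken directly as ``de = De``.
    """
    fin = _clip_with_warning(fin, 0.0, 1.0, "fin")
    Din = _clip_with_warning(Din, 0.0, np.inf, "Din")
    De = _clip_with_warning(De, 0.0, np.inf, "De")

    alpha = 1.0 - fin
    di = fin * Din
    de = np.asarray(De, dtype=float).copy()
    valid = np.isfinite(alpha) & np.isfinite(di) & np.isfinite(de)
    return _finish(alpha, di, de, valid, affine, "smt")


def cti_alpha_de(fecm, fecw, fi, decm, decw: float = DECW):
    """Extracellular fraction and volume-weighted extracellular diffusivity.

    From the three-compartment decomposition (extracellular matrix,
    extracellular water, intracellular)::

        alpha = (fecm + fecw) / (fecm + fecw + fi)
        de    = (fecm * decm + fecw * decw) / (fecm + fecw)

    Voxels with no extracellular space (``fecm + fecw = 0``) leave ``de``
    undefined and come back masked (NaN ``de``, alpha = 0).
    """
    fecm = np.asarray(fecm, dtype=float)
    fecw = np.asarray(fecw, dtype=float)
    fi = np.asarray(fi, dtype=float)
    decm = np.asarray(decm, dtype=float)
    if np.any(fecm < 0) or np.any(fecw < 0) or np.any(fi < 0):
        raise DomainError("compartment fractions must be >= 0")
    fe = fecm + fecw
    total = fe + fi
    if np.any(total <= 0):
        raise DomainError("compartment fractions must not all be zero")
    alpha = fe / total
    with np.errstate(divide="ignore", invalid="ignore"):
        de = np.where(fe > 0, (fecm * decm + fecw * decw) / np.where(fe > 0, fe, 1.0), np.nan)
    if alpha.ndim == 0:
        return float(alpha), float(de)
    return alpha, de


def _finish(alpha, di, de, valid, affine, model) -> CtiMaps:
    alpha = np.asarray(alpha, dtype=float)
    shape = alpha.shape
    logger.info("%s adapter: %d/%d voxels valid", model, int(np.sum(valid)), alpha.size)
    return CtiMaps(
        alpha=alpha,
        di=np.broadcast_to(np.asarray(di, dtype=float), shape).copy(),
        de=np.broadcast_to(np.asarray(de, dtype=float), shape).copy(),
        valid_mask=np.broadcast_to(np.asarray(valid, dtype=bool), shape).copy(),
        affine=np.eye(4) if affine is None else np.asarray(affine, dtype=float),
        model=model,
    )
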