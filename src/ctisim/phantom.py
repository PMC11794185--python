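"""Synthetic multi-subject phantom cohorts.

The phantom stands in for a registered, atlas-labeled human cohort: a
mirror-symmetric head volume with CSF / gray-matter / white-matter shells,
a set of blocky region-of-interest analogues of the structures a
conductivity comparison would examine (corpus-callosum segments, cingulum,
cerebellar peduncles, bilateral subcortical nuclei with hippocampal
subfields, paired cortical strips), and per-subject micro-structure
parameter maps drawn from per-tissue-class truncated normal distributions.

What it emulates is the *statistical* structure of fitted parameter maps —
tissue-class contrast, bilateral symmetry, controllable left-right offsets
— not anatomy, diffusion signal formation, or scanner noise.

Subject ``k`` of a cohort depends only on ``(seed, k, spec)``: the master
seed and the subject index are combined into an independent substream, so
cohorts of different sizes share their leading subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .volumes import ParameterVolume, default_affine

__all__ = [
    "TissueAtlas",
    "TruncNormSpec",
    "CohortSpec",
    "PhantomSizingError",
    "ConfigurationError",
    "build_default_atlas",
    "generate_cohort",
    "generate_subject",
    "DEFAULT_TISSUE_PARAMS",
    "MODEL_PARAMS",
]

BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
TISSUE_NAMES = {CSF: "CSF", GM: "GM", WM: "WM"}


class PhantomSizingError(ValueError):
    """Grid too small to place a region of interest."""


class ConfigurationError(ValueError):
    """Cohort specification incomplete or inconsistent."""


@dataclass
class TissueAtlas:
    """Tissue-class and ROI label volumes with the ROI dictionary.

    ``roi_table`` has one row per ROI code with columns
    ``code, name, tissue, pair_code`` (pair_code 0 for unpaired ROIs).
    ``composites`` maps a name (e.g. ``hippocampus_left``) to the list of
    codes whose union it denotes.
    """

    labels: np.ndarray
    roi_labels: np.ndarray
    affine: np.ndarray
    roi_table: pd.DataFrame
    composites: dict[str, list[int]] = field(default_factory=dict)

    def code_for(self, name: str) -> int:
        row = self.roi_table[self.roi_table["name"] == name]
        if row.empty:
            raise KeyError(f"unknown ROI name {name!r}")
        return int(row["code"].iloc[0])

    def roi_mask(self, roi: int | str) -> np.ndarray:
        """Boolean mask for an ROI code, name, or composite name."""
        if isinstance(roi, str):
            if roi in self.composites:
                return np.isin(self.roi_labels, self.composites[roi])
            roi = self.code_for(roi)
        return self.roi_labels == roi

    @property
    def roi_names(self) -> list[str]:
        return list(self.roi_table["name"])


# ROI layout in fractional grid coordinates. Each entry:
# name -> (tissue, (x0, x1, y0, y1, z0, z1), pair_name or None, side)
# side "L" boxes live in x < 0.5 and are mirrored to build their partner;
# side "M" boxes straddle the midline and are symmetrised in place.
_LAYOUT: list[tuple[str, int, tuple[float, float, float, float, float, float], str | None]] = [
    ("cc_genu", WM, (0.42, 0.58, 0.62, 0.72, 0.56, 0.66), None),
    ("cc_body", WM, (0.42, 0.58, 0.45, 0.55, 0.56, 0.66), None),
    ("cc_splenium", WM, (0.42, 0.58, 0.28, 0.38, 0.56, 0.66), None),
    ("cingulum_left", WM, (0.33, 0.40, 0.35, 0.65, 0.60, 0.67), "cingulum_right"),
    ("cerebellar_peduncle_inferior", WM, (0.42, 0.58, 0.30, 0.42, 0.12, 0.18), "cerebellar_peduncle_superior"),
    ("cerebellar_peduncle_superior", WM, (0.42, 0.58, 0.30, 0.42, 0.20, 0.26), "cerebellar_peduncle_inferior"),
    ("amygdala_left", GM, (0.26, 0.34, 0.64, 0.72, 0.30, 0.38), "amygdala_right"),
    ("ca1_left", GM, (0.28, 0.36, 0.30, 0.38, 0.34, 0.42), "ca1_right"),
    ("ca23_left", GM, (0.28, 0.36, 0.38, 0.46, 0.34, 0.42), "ca23_right"),
    ("ca4dg_left", GM, (0.28, 0.36, 0.46, 0.54, 0.34, 0.42), "ca4dg_right"),
    ("pallidum_left", GM, (0.30, 0.36, 0.50, 0.60, 0.42, 0.50), "pallidum_right"),
    ("putamen_left", GM, (0.22, 0.28, 0.48, 0.62, 0.40, 0.52), "putamen_right"),
    ("thalamus_left", GM, (0.38, 0.48, 0.40, 0.54, 0.42, 0.54), "thalamus_right"),
    ("cingulate_anterior", GM, (0.42, 0.58, 0.58, 0.68, 0.70, 0.78), "cingulate_posterior"),
    ("cingulate_posterior", GM, (0.42, 0.58, 0.32, 0.42, 0.70, 0.78), "cingulate_anterior"),
    ("precentral", GM, (0.35, 0.65, 0.52, 0.58, 0.74, 0.82), "postcentral"),
    ("postcentral", GM, (0.35, 0.65, 0.44, 0.50, 0.74, 0.82), "precentral"),
]

# Head shells as concentric ellipsoid semi-axes (fractional coordinates).
_SHELLS = {"outer": (0.46, 0.48, 0.46), "gm": (0.42, 0.44, 0.42), "wm": (0.34, 0.38, 0.34)}


def _box_mask(shape, box, name) -> np.ndarray:
    idx = []
    for ax, (f0, f1) in enumerate(zip(box[0::2], box[1::2])):
        lo = int(round(f0 * shape[ax]))
        hi = int(round(f1 * shape[ax]))
        if hi - lo < 2:
            raise PhantomSizingError(
                f"grid {tuple(shape)} too small to place ROI {name!r} "
                f"(axis {ax} span {hi - lo} < 2 voxels)"
            )
        idx.append((lo, hi))
    m = np.zeros(shape, dtype=bool)
    m[idx[0][0]:idx[0][1], idx[1][0]:idx[1][1], idx[2][0]:idx[2][1]] = True
    return m


def _ellipsoid(shape, semi) -> np.ndarray:
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) / n - 0.5 for n in shape], indexing="ij", sparse=True
    )
    r2 = sum((g / s) ** 2 for g, s in zip(grids, semi))
    return r2 <= 1.0


def build_default_atlas(grid_shape=(64, 64, 64), voxel_mm: float = 1.0) -> TissueAtlas:
    """Build the mirror-symmetric default phantom atlas.

    The head is three nested ellipsoids (CSF shell, gray-matter shell,
    white-matter core); ROI boxes are then painted on, overriding the
    tissue class inside each ROI so every ROI voxel carries its structure's
    tissue. Left/right ROIs are exact mirror images along the first axis
    (hence voxel-count-equal); midline ROIs are symmetrised in place.

    Raises :class:`PhantomSizingError` if any axis has fewer than 16 voxels
    or any ROI would span fewer than 2 voxels along some axis.
    """
    shape = tuple(int(n) for n in grid_shape)
    if len(shape) != 3 or min(shape) < 16:
        raise PhantomSizingError(
            f"grid {shape} too small: at least 16 voxels per axis required"
        )

    labels = np.zeros(shape, dtype=np.int16)
    labels[_ellipsoid(shape, _SHELLS["outer"])] = CSF
    labels[_ellipsoid(shape, _SHELLS["gm"])] = GM
    labels[_ellipsoid(shape, _SHELLS["wm"])] = WM

    roi = np.zeros(shape, dtype=np.int16)
    rows = []
    name_to_code = {name: 10 + i for i, (name, *_rest) in enumerate(_LAYOUT)}
    mirrored: dict[str, int] = {}
    for name, tissue, box, pair in _LAYOUT:
        mask = _box_mask(shape, box, name)
        if name.endswith("_left"):
            # left member defines the geometry; the right partner is its
            # exact mirror image, guaranteeing equal voxel counts
            rmask = mask[::-1, :, :]
            rname = name[:-5] + "_right"
            mirrored[rname] = len(rows) + 1
        else:
            mask = mask | mask[::-1, :, :]  # symmetrise midline boxes
            rmask, rname = None, None
        for nm, msk in ((name, mask), (rname, rmask)):
            if nm is None:
                continue
            code = name_to_code.get(nm)
            if code is None:
                code = max(name_to_code.values()) + 1
                name_to_code[nm] = code
            if np.any(roi[msk]):
                raise PhantomSizingError(f"ROI {nm!r} overlaps a previously placed ROI")
            roi[msk] = code
            labels[msk] = tissue
            rows.append({"code": code, "name": nm, "tissue": TISSUE_NAMES[tissue]})

    table = pd.DataFrame(rows)
    pair_of = {}
    for name, _t, _b, pair in _LAYOUT:
        if pair is not None:
            pair_of[name] = pair
            if name.endswith("_left"):
                pair_of[pair] = name
    table["pair_code"] = [
        name_to_code.get(pair_of.get(nm, ""), 0) for nm in table["name"]
    ]
    if table["code"].duplicated().any():
        raise RuntimeError("duplicate ROI codes in atlas table")

    composites = {
        "hippocampus_left": [name_to_code[n] for n in ("ca1_left", "ca23_left", "ca4dg_left")],
        "hippocampus_right": [name_to_code[n] for n in ("ca1_right", "ca23_right", "ca4dg_right")],
    }
    return TissueAtlas(
        labels=labels,
        roi_labels=roi,
        affine=default_affine(shape, voxel_mm),
        roi_table=table,
        composites=composites,
    )


@dataclass(frozen=True)
class TruncNormSpec:
    """Truncated normal (mean, sd, lower, upper) for one parameter."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower < self.upper):
            raise ConfigurationError(f"empty truncation interval [{self.lower}, {self.upper}]")
        if self.sd <= 0:
            raise ConfigurationError("sd must be > 0")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        # inverse-CDF sampling: exact, vectorised, and reproducible
        a = ndtr((self.lower - self.mean) / self.sd)
        b = ndtr((self.upper - self.mean) / self.sd)
        u = rng.uniform(a, b, size)
        return self.mean + self.sd * ndtri(u)


#: Parameter names each diffusion model requires (diffusivities in mm^2/s).
MODEL_PARAMS = {
    "noddi": ("fi", "odi", "fiso"),
    "sandi": ("fe", "fin", "Din", "Dec"),
    "smt": ("fin", "Din", "De"),
}

_FRACTIONS = {"fi", "odi", "fiso", "fe", "fin"}


def _t(mean, sd, lo, hi):
    return TruncNormSpec(mean, sd, lo, hi)


#: Default per-tissue-class parameter distributions. These are plausible
#: stand-ins chosen to make WM/GM separable — they are not calibrated to
#: any fitted human cohort — and every one can be overridden in the config.
DEFAULT_TISSUE_PARAMS: dict[str, dict[str, dict[str, TruncNormSpec]]] = {
    "noddi": {
        "WM": {"fi": _t(0.60, 0.05, 0, 1), "odi": _t(0.20, 0.05, 1e-3, 1), "fiso": _t(0.05, 0.02, 0, 1)},
        "GM": {"fi": _t(0.40, 0.05, 0, 1), "odi": _t(0.55, 0.10, 1e-3, 1), "fiso": _t(0.10, 0.05, 0, 1)},
        "CSF": {"fi": _t(0.02, 0.01, 0, 1), "odi": _t(0.50, 0.10, 1e-3, 1), "fiso": _t(0.95, 0.03, 0, 1)},
    },
    "sandi": {
        "WM": {"fe": _t(0.35, 0.05, 0, 1), "fin": _t(0.70, 0.05, 0, 1),
               "Din": _t(2.0e-3, 0.2e-3, 0, 3e-3), "Dec": _t(1.2e-3, 0.2e-3, 0, 3e-3)},
        "GM": {"fe": _t(0.45, 0.05, 0, 1), "fin": _t(0.45, 0.05, 0, 1),
               "Din": _t(2.0e-3, 0.2e-3, 0, 3e-3), "Dec": _t(1.2e-3, 0.2e-3, 0, 3e-3)},
        "CSF": {"fe": _t(0.90, 0.03, 0, 1), "fin": _t(0.10, 0.05, 0, 1),
                "Din": _t(2.8e-3, 0.1e-3, 0, 3e-3), "Dec": _t(2.8e-3, 0.1e-3, 0, 3e-3)},
    },
    "smt": {
        "WM": {"fin": _t(0.65, 0.05, 0, 1), "Din": _t(2.0e-3, 0.2e-3, 0, 3e-3), "De": _t(1.1e-3, 0.2e-3, 0, 3e-3)},
        "GM": {"fin": _t(0.35, 0.05, 0, 1), "Din": _t(2.0e-3, 0.2e-3, 0, 3e-3), "De": _t(1.1e-3, 0.2e-3, 0, 3e-3)},
        "CSF": {"fin": _t(0.05, 0.02, 0, 1), "Din": _t(2.0e-3, 0.2e-3, 0, 3e-3), "De": _t(2.8e-3, 0.1e-3, 0, 3e-3)},
    },
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of one synthetic cohort for one diffusion model.

    ``asymmetry`` is a list of ``(roi_name, parameter, offset)`` triples:
    the additive offset is applied to that ROI's voxels after sampling and
    re-clipped to the parameter's physical range — the mechanism for
    injecting controlled left-right conductivity differences.
    """

    model: str
    n_subjects: int = 30
    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    tissue_params: dict[str, dict[str, TruncNormSpec]] | None = None
    asymmetry: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.model not in MODEL_PARAMS:
            raise ConfigurationError(
                f"unknown model {self.model!r}; expected one of {sorted(MODEL_PARAMS)}"
            )
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")

    def resolved_params(self) -> dict[str, dict[str, TruncNormSpec]]:
        params = self.tissue_params or DEFAULT_TISSUE_PARAMS[self.model]
        required = MODEL_PARAMS[self.model]
        for cls in ("WM", "GM", "CSF"):
            missing = [p for p in required if p not in params.get(cls, {})]
            if missing:
                raise ConfigurationError(
                    f"model {self.model!r}: tissue class {cls} is missing "
                    f"distribution(s) for {missing}"
                )
        for cls, spec in params.items():
            for pname, tn in spec.items():
                if pname in _FRACTIONS and not (0 <= tn.lower and tn.upper <= 1):
                    raise ConfigurationError(
                        f"{pname} in {cls}: truncation bounds must lie in [0, 1]"
                    )
                if pname not in _FRACTIONS and tn.lower < 0:
                    raise ConfigurationError(f"{pname} in {cls}: diffusivity must be >= 0")
        return params


def _param_range(pname: str) -> tuple[float, float]:
    return (0.0, 1.0) if pname in _FRACTIONS else (0.0, np.inf)


def generate_subject(
    spec: CohortSpec, atlas: TissueAtlas, subject: int
) -> dict[str, ParameterVolume]:
    """Parameter volumes for one subject; depends only on (seed, subject, spec)."""
    params = spec.resolved_params()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(subject,)))
    shape = atlas.labels.shape
    out: dict[str, np.ndarray] = {
        p: np.zeros(shape, dtype=np.float64) for p in MODEL_PARAMS[spec.model]
    }
    # draw order is fixed (tissue class, then parameter name) so results are
    # independent of dict insertion order
    for code, cls in sorted(TISSUE_NAMES.items()):
        vox = atlas.labels == code
        n = int(np.count_nonzero(vox))
        if n == 0:
            continue
        for pname in MODEL_PARAMS[spec.model]:
            out[pname][vox] = params[cls][pname].sample(rng, n)
    for roi_name, pname, offset in spec.asymmetry:
        if pname not in out:
            raise ConfigurationError(
                f"asymmetry on {pname!r}: not a parameter of model {spec.model!r}"
            )
        mask = atlas.roi_mask(roi_name)
        lo, hi = _param_range(pname)
        out[pname][mask] = np.clip(out[pname][mask] + offset, lo, hi)
    return {p: ParameterVolume(p, arr, atlas.affine) for p, arr in out.items()}


def generate_cohort(spec: CohortSpec, atlas: TissueAtlas) -> list[dict[str, ParameterVolume]]:
    """One ParameterVolume set per subject; bit-identical for equal (seed, spec)."""
    spec.resolved_params()  # validate before doing any work
    return [generate_subject(spec, atlas, k) for k in range(spec.n_subjects)]


def with_asymmetry(spec: CohortSpec, *injections: tuple[str, str, float]) -> CohortSpec:
    """Copy of ``spec`` with additional asymmetry injections."""
    return replace(spec, asymmetry=spec.asymmetry + tuple(injections))
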