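"""Per-subject, per-ROI summaries of sigma_L and cohort-level tables.

Each subject contributes one median (and interquartile range) per ROI and
model; cohort-level descriptive statistics and the equivalence tests
operate on those per-subject medians. Quartiles use linear interpolation
between order statistics. CSF is excluded from cohort tables: low-frequency
CSF conductivity is outside this pipeline's scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RoiSummary",
    "EmptyRoiError",
    "summarize_roi",
    "build_cohort_table",
    "normality_screen",
    "normality_table",
    "boxplot_summary",
]


class EmptyRoiError(ValueError):
    """ROI contains no valid voxels (or does not exist)."""


@dataclass(frozen=True)
class RoiSummary:
    subject: int
    roi: str
    model: str
    n_voxels: int
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def summarize_roi(sigma, atlas, roi, subject: int = 0) -> RoiSummary:
    """Median and quartiles of sigma_L over an ROI's valid voxels.

    ``roi`` may be a code, a name, or a composite name (e.g. a hippocampus
    made of its subfields). Masked voxels never contribute; an ROI with no
    valid voxels raises :class:`EmptyRoiError`.
    """
    mask = atlas.roi_mask(roi)
    if not mask.any():
        raise EmptyRoiError(f"ROI {roi!r} has no voxels in this atlas")
    vals = sigma.sigma_l[mask & sigma.valid_mask]
    if vals.size == 0:
        raise EmptyRoiError(f"ROI {roi!r} has no valid voxels")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
    name = roi if isinstance(roi, str) else str(roi)
    return RoiSummary(
        subject=subject,
        roi=name,
        model=sigma.model,
        n_voxels=int(vals.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def default_roi_list(atlas) -> list[str]:
    """All named ROIs plus composites, excluding any CSF-class ROI."""
    names = [
        nm
        for nm, tis in zip(atlas.roi_table["name"], atlas.roi_table["tissue"])
        if tis != "CSF"
    ]
    return names + sorted(atlas.composites)


def build_cohort_table(
    sigmas: list, atlas, model: str | None = None, rois: list[str] | None = None
) -> pd.DataFrame:
    """One row per (subject, ROI): per-subject sigma_L medians and IQRs.

    ``sigmas`` is one :class:`~ctisim.cti_core.ConductivityVolume` per
    subject, in subject order.
    """
    rois = default_roi_list(atlas) if rois is None else rois
    rows = []
    for k, sig in enumerate(sigmas):
        for roi in rois:
            s = summarize_roi(sig, atlas, roi, subject=k)
            rows.append(
                {
                    "subject": k,
                    "roi": s.roi,
                    "model": model or sig.model,
                    "n_voxels": s.n_voxels,
                    "median": s.median,
                    "q1": s.q1,
                    "q3": s.q3,
                    "iqr": s.iqr,
                }
            )
    return pd.DataFrame(rows)


def normality_screen(values) -> tuple[float, float, str, bool]:
    """Shapiro-Wilk screen of per-subject ROI medians.

    Returns ``(W, p, verdict, degenerate)`` with verdict ``"non-normal"``
    iff p < 0.05. A zero-variance sample cannot be tested; it is reported
    as non-normal with the ``degenerate`` flag set (a point mass is as
    non-Gaussian as a sample gets). Requires n >= 3.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got n = {x.size}")
    if np.ptp(x) == 0:
        return float("nan"), 0.0, "non-normal", True
    w, p = stats.shapiro(x)
    return float(w), float(p), ("non-normal" if p < 0.05 else "normal"), False


def normality_table(table: pd.DataFrame) -> pd.DataFrame:
    """Shapiro-Wilk screen per (ROI, model) over per-subject medians."""
    rows = []
    for (roi, model), grp in table.groupby(["roi", "model"], sort=True):
        w, p, verdict, degen = normality_screen(grp["median"].to_numpy())
        rows.append(
            {"roi": roi, "model": model, "W": w, "p": p, "verdict": verdict, "degenerate": degen}
        )
    return pd.DataFrame(rows)


def boxplot_summary(table: pd.DataFrame) -> dict:
    """Box-plot statistics per (ROI, model) over per-subject medians.

    Whiskers use 1.5*IQR fences (most extreme data point inside the fence),
    which is what the box height / whisker convention here means.
    """
    out: dict = {}
    for (roi, model), grp in table.groupby(["roi", "model"], sort=True):
        x = grp["median"].to_numpy()
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = x[(x >= lo_fence) & (x <= hi_fence)]
        out.setdefault(roi, {})[model] = {
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(inside.min()),
            "whisker_high": float(inside.max()),
            "n_subjects": int(x.size),
            "whisker_rule": "1.5*IQR",
        }
    return out
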