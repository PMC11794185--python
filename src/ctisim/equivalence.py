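"""Paired ROI comparisons: Wilcoxon signed-rank difference and TOST equivalence.

For each pair of partner ROIs (left/right, anterior/posterior,
inferior/superior, or corpus-callosum sub-segments) and each diffusion
model, two questions are asked of the per-subject sigma_L medians:

* *different?* — a two-sided Wilcoxon signed-rank test of zero median
  difference at level alpha;
* *equivalent?* — two one-sided Wilcoxon signed-rank tests (TOST) against
  the equivalence bounds, by default +/- 0.05 S/m: equivalence is declared
  when both one-sided tests reject at level alpha.

The two verdicts are not mutually exclusive: a tiny but consistent offset
can be detectably nonzero yet still within the equivalence bounds.

The signed-rank machinery is implemented here: exact tail probabilities by
dynamic programming over the rank-sum distribution for n <= 25 (midranks
handled exactly via doubled ranks), and a tie-corrected normal
approximation above that. Zero differences are dropped before ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WilcoxonResult",
    "EquivalenceResult",
    "DegenerateSampleError",
    "wilcoxon_signed_rank",
    "tost_equivalence",
    "run_comparison_roster",
    "DEFAULT_ROSTER",
]

EXACT_MAX_N = 25


class DegenerateSampleError(ValueError):
    """All differences equal the hypothesised shift; no test possible."""


class PairingError(ValueError):
    """Paired samples of unequal length."""


class RosterError(KeyError):
    """A roster ROI is absent from the cohort table."""


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    n_used: int  # sample size after dropping zeros
    p_greater: float  # H1: location > shift
    p_less: float  # H1: location < shift
    p_two_sided: float
    method: str  # "exact" or "approx"


def _exact_tail_probs(w_plus: float, double_ranks: np.ndarray) -> tuple[float, float]:
    """P(W+ >= w) and P(W+ <= w) by DP over all 2^n sign assignments.

    ``double_ranks`` are midranks times two, hence integers even with ties;
    the distribution of the doubled rank sum is built by convolution.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    p_ge = float(counts[w2:].sum())
    p_le = float(counts[: w2 + 1].sum())
    return p_ge, p_le


def wilcoxon_signed_rank(diffs, shift: float = 0.0) -> WilcoxonResult:
    """One- and two-sided signed-rank p-values for a location shift.

    The test is applied to ``diffs - shift``. Exact distribution for
    n <= 25 (after zero-dropping), tie-corrected normal approximation (no
    continuity correction) otherwise. The two-sided p is twice the smaller
    one-sided tail, capped at 1.

    Raises
    ------
    DegenerateSampleError
        If every difference equals the shift.
    ValueError
        If fewer than 5 nonzero differences remain.
    """
    d = np.asarray(diffs, dtype=float) - shift
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateSampleError("all differences equal the hypothesised shift")
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences after shift, got {n}")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        p_ge, p_le = _exact_tail_probs(w_plus, np.round(2.0 * ranks))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        ties = counts[counts > 1].astype(float)
        if ties.size:
            var -= (ties**3 - ties).sum() / 48.0
        sd = np.sqrt(var)
        z = (w_plus - mean) / sd
        p_ge = float(stats.norm.sf(z))
        p_le = float(stats.norm.cdf(z))
        method = "approx"
    return WilcoxonResult(
        statistic=w_plus,
        n_used=n,
        p_greater=p_ge,
        p_less=p_le,
        p_two_sided=min(1.0, 2.0 * min(p_ge, p_le)),
        method=method,
    )


def _rank_sum_one_sided(a, b, shift: float, alternative: str) -> float:
    """Mann-Whitney one-sided p for location(a) - location(b) vs shift."""
    res = stats.mannwhitneyu(np.asarray(a) - shift, b, alternative=alternative)
    return float(res.pvalue)


@dataclass(frozen=True)
class EquivalenceResult:
    roi_pair: tuple[str, str]
    model: str
    n: int
    median_diff: float
    p_diff: float
    p_lower: float  # H1: median difference > lower bound
    p_upper: float  # H1: median difference < upper bound
    equivalent: bool
    different: bool
    bounds: tuple[float, float]
    alpha: float
    mode: str = "paired"

    @property
    def p_tost(self) -> float:
        """The TOST p-value: the larger of the two one-sided p-values."""
        return max(self.p_lower, self.p_upper)


def tost_equivalence(
    a,
    b,
    bounds: tuple[float, float] = (-0.05, 0.05),
    alpha: float = 0.05,
    mode: str = "paired",
    roi_pair: tuple[str, str] = ("a", "b"),
    model: str = "",
) -> EquivalenceResult:
    """Wilcoxon TOST equivalence plus a two-sided difference test.

    ``mode="paired"`` (default) treats ``a`` and ``b`` as per-subject
    paired samples and uses the signed-rank test on their differences;
    ``mode="pooled"`` treats them as independent groups and uses the
    rank-sum test. Paired is the appropriate reading for within-subject
    left/right and sub-compartment comparisons.
    """
    low, high = bounds
    if not low < high:
        raise ValueError(f"bounds must satisfy low < high, got {bounds}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mode == "paired":
        if a.size != b.size:
            raise PairingError(f"paired samples differ in length: {a.size} vs {b.size}")
        d = a - b
        median_diff = float(np.median(d))
        r_diff = wilcoxon_signed_rank(d, 0.0)
        p_diff = r_diff.p_two_sided
        p_lower = wilcoxon_signed_rank(d, low).p_greater
        p_upper = wilcoxon_signed_rank(d, high).p_less
        n = r_diff.n_used
    elif mode == "pooled":
        median_diff = float(np.median(a) - np.median(b))
        p_diff = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        p_lower = _rank_sum_one_sided(a, b, low, "greater")
        p_upper = _rank_sum_one_sided(a, b, high, "less")
        n = min(a.size, b.size)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return EquivalenceResult(
        roi_pair=roi_pair,
        model=model,
        n=n,
        median_diff=median_diff,
        p_diff=p_diff,
        p_lower=p_lower,
        p_upper=p_upper,
        equivalent=bool(max(p_lower, p_upper) < alpha),
        different=bool(p_diff < alpha),
        bounds=(float(low), float(high)),
        alpha=alpha,
        mode=mode,
    )


#: The default comparison roster: corpus-callosum sub-segment pairs, the
#: cerebellar peduncle, paired cortical strips, bilateral subcortical
#: nuclei, and the hippocampal subfields.
DEFAULT_ROSTER: tuple[tuple[str, str], ...] = (
    ("cc_body", "cc_genu"),
    ("cc_body", "cc_splenium"),
    ("cerebellar_peduncle_inferior", "cerebellar_peduncle_superior"),
    ("cingulate_anterior", "cingulate_posterior"),
    ("precentral", "postcentral"),
    ("pallidum_left", "pallidum_right"),
    ("hippocampus_left", "hippocampus_right"),
    ("amygdala_left", "amygdala_right"),
    ("thalamus_left", "thalamus_right"),
    ("putamen_left", "putamen_right"),
    ("ca1_left", "ca1_right"),
    ("ca23_left", "ca23_right"),
    ("ca4dg_left", "ca4dg_right"),
)

#: Roster pairs that are left/right mirror comparisons.
BILATERAL_PAIRS = tuple(
    p for p in DEFAULT_ROSTER if p[0].endswith("_left") and p[1].endswith("_right")
)


def run_comparison_roster(
    table: pd.DataFrame,
    roster: tuple[tuple[str, str], ...] = DEFAULT_ROSTER,
    bounds: tuple[float, float] = (-0.05, 0.05),
    alpha: float = 0.05,
    mode: str = "paired",
) -> list[EquivalenceResult]:
    """Run the TOST roster on a cohort table (one result per pair per model).

    ``table`` is the output of :func:`ctisim.roi_stats.build_cohort_table`
    (columns subject / roi / model / median). Missing ROIs raise
    :class:`RosterError` naming the ROI.
    """
    results = []
    available = set(table["roi"])
    for model, grp in table.groupby("model", sort=True):
        pivot = grp.pivot(index="subject", columns="roi", values="median")
        for roi_a, roi_b in roster:
            for roi in (roi_a, roi_b):
                if roi not in available:
                    raise RosterError(f"ROI {roi!r} missing from cohort table")
            results.append(
                tost_equivalence(
                    pivot[roi_a].to_numpy(),
                    pivot[roi_b].to_numpy(),
                    bounds=bounds,
                    alpha=alpha,
                    mode=mode,
                    roi_pair=(roi_a, roi_b),
                    model=str(model),
                )
            )
    return results


def results_frame(results: list[EquivalenceResult]) -> pd.DataFrame:
    """Tabulate equivalence results (one row per pair x model)."""
    return pd.DataFrame(
        [
            {
                "roi_a": r.roi_pair[0],
                "roi_b": r.roi_pair[1],
                "model": r.model,
                "n": r.n,
                "median_diff": r.median_diff,
                "p_diff": r.p_diff,
                "p_lower": r.p_lower,
                "p_upper": r.p_upper,
                "p_tost": r.p_tost,
                "equivalent": r.equivalent,
                "different": r.different,
                "mode": r.mode,
            }
            for r in results
        ]
    )


def verdict_matrix(results: list[EquivalenceResult]) -> dict:
    """Nested {pair: {model: {equivalent, different}}} verdict summary."""
    out: dict = {}
    for r in results:
        key = f"{r.roi_pair[0]} vs {r.roi_pair[1]}"
        out.setdefault(key, {})[r.model] = {
            "equivalent": r.equivalent,
            "different": r.different,
        }
    return out
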