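"""Paired model comparison machinery.

Bootstrap confidence intervals for mean AUCs, paired t-tests with
t-distribution CIs over fold-wise differences, exact Wilcoxon signed-rank
tests (full null enumeration for small n, normal approximation beyond),
Holm-Bonferroni step-down correction across a comparison family, and
common-subset pairing of per-image faithfulness results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, ValidationError

EXACT_WILCOXON_MAX_N = 25


@dataclass
class PairedComparison:
    """One model-vs-model contrast on paired scalars."""

    name_a: str
    name_b: str
    n: int
    delta: float
    ci_low: float
    ci_high: float
    p_t: float
    p_wilcoxon: float
    p_holm: float | None = None


# ----------------------------------------------------------------------
def bootstrap_mean_ci(sample, n_boot: int = 10_000, alpha: float = 0.05,
                      seed: int = 0) -> tuple[float, float, float]:
    """Percentile bootstrap CI for the mean; (mean, low, high)."""
    x = np.asarray(sample, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValidationError("bootstrap requires a non-empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(x.mean()), float(lo), float(hi)


def paired_t_test(a, b, alpha: float = 0.05) -> tuple[float, float, float, float]:
    """Two-sided paired t-test with a t-distribution CI on the mean difference."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("paired t-test needs two equal-length samples, n >= 2")
    d = a - b
    if np.ptp(d) == 0.0:
        raise DegenerateInputError("all paired differences identical; t-test undefined")
    n = d.size
    delta = d.mean()
    se = d.std(ddof=1) / np.sqrt(n)
    t = delta / se
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    crit = sps.t.ppf(1 - alpha / 2, df=n - 1)
    return float(delta), float(delta - crit * se), float(delta + crit * se), float(p)


def _exact_wilcoxon_p(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided p for signed-rank statistic via sum-distribution DP.

    ``ranks2`` are doubled ranks (integers even with mid-rank ties); ``w2``
    the doubled positive-rank sum.  Enumerates the 2^n sign assignments by
    dynamic programming over achievable sums.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w2))
    p_low = counts[:w2 + 1].sum()
    p_high = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p; zeros dropped, ties mid-ranked.

    Exact null enumeration for n <= 25 pairs; normal approximation above.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("Wilcoxon needs two equal-length samples, n >= 2")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        raise DegenerateInputError("all paired differences are zero; Wilcoxon undefined")
    ranks = sps.rankdata(np.abs(d))
    if d.size <= EXACT_WILCOXON_MAX_N:
        w_pos = ranks[d > 0].sum()
        return _exact_wilcoxon_p(np.round(2 * ranks), 2 * w_pos)
    return float(sps.wilcoxon(d, zero_method="wilcox", method="approx").pvalue)


def holm_adjust(pvals) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValidationError("empty p-value family")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ----------------------------------------------------------------------
def compare_paired(a, b, name_a: str = "a", name_b: str = "b",
                   alpha: float = 0.05) -> PairedComparison:
    delta, lo, hi, p_t = paired_t_test(a, b, alpha=alpha)
    return PairedComparison(name_a, name_b, n=len(np.ravel(a)), delta=delta,
                            ci_low=lo, ci_high=hi, p_t=p_t,
                            p_wilcoxon=wilcoxon_signed_rank(a, b))


def holm_family(comparisons: list[PairedComparison]) -> list[PairedComparison]:
    """Fill p_holm across one family of contrasts (e.g. the four baselines)."""
    adj = holm_adjust([c.p_t for c in comparisons])
    for c, ph in zip(comparisons, adj):
        c.p_holm = float(ph)
    return comparisons


def common_subset_pairing(results_a, results_b):
    """Intersect two per-image result lists by image_id (included only).

    Returns a dict with the sorted shared ids, paired metric arrays
    ('insertion_auc', 'deletion_auc', 'one_minus_deletion') of shape (2, n),
    and the pair count n.
    """
    def index(results):
        out = {}
        for r in results:
            if not getattr(r, "included", True):
                continue
            if r.image_id in out:
                raise ValidationError(f"duplicate image_id {r.image_id!r}")
            out[r.image_id] = r
        return out

    ia, ib = index(results_a), index(results_b)
    shared = sorted(set(ia) & set(ib))
    if not shared:
        raise ValidationError("no common image_ids between the two result sets")
    paired = {"image_ids": shared, "n": len(shared)}
    for key in ("insertion_auc", "deletion_auc", "one_minus_deletion"):
        paired[key] = np.array([[getattr(ia[i], key) for i in shared],
                                [getattr(ib[i], key) for i in shared]])
    return paired
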