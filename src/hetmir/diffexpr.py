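"""Differential miRNA expression on pooled counts.

The DE model treats each pooled group's read count for a miRNA as a
binomial draw from the pooled library: under the null of equal relative
abundance, the count in group 1 conditioned on the two-group total is
Binomial(k1+k2, n1/(n1+n2)) where n1, n2 are the pooled library totals.
The two-sided p-value follows the minimum-likelihood rule (sum the
probabilities of all outcomes no more likely than the observed one).
Calls are gated conjunctively: q < 0.05 (Benjamini-Hochberg) AND
|log2 fold change| >= 1 on the CPM scale.

A synthetic mid-parent group A with per-pseudo-replicate profiles
A_i = (P1_i + P2_i) / 2 on the CPM scale supports hybrid-vs-mid-parent
contrasts, the basis of the additivity call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .config import DEThresholds, log

__all__ = [
    "cpm",
    "filter_low_expression",
    "synthesize_midparent",
    "with_midparent",
    "binomial_exact_test",
    "bh_adjust",
    "de_contrast",
    "DECall",
]

# relative slack when comparing outcome probabilities in the
# minimum-likelihood rule, so exact ties survive floating-point noise
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class DECall:
    """One miRNA's result in one ordered contrast (group1 vs group2)."""

    mirna_id: str
    contrast: tuple[str, str]
    log2fc: float
    p: float
    q: float
    status: str  # up | down | ns


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------

def library_totals(counts: pd.DataFrame) -> pd.Series:
    """Per-sample library totals (column sums)."""
    return counts.sum(axis=0)


def cpm(counts: pd.DataFrame, totals: pd.Series | None = None) -> pd.DataFrame:
    """Counts-per-million normalization.

    Parameters
    ----------
    counts
        miRNA x sample integer matrix.
    totals
        Optional explicit library totals; defaults to column sums.

    Raises
    ------
    ValueError
        If any library total is zero (named in the message).
    """
    if (counts.values < 0).any():
        raise ValueError("count matrix contains negative entries")
    tot = library_totals(counts) if totals is None else totals.reindex(counts.columns)
    zero = tot.index[tot <= 0].tolist()
    if zero:
        raise ValueError(f"zero-total library: {zero}")
    return counts.div(tot, axis=1) * 1e6


def filter_low_expression(
    norm: pd.DataFrame, threshold: float = 10.0
) -> tuple[list[str], list[str]]:
    """Drop miRNAs below ``threshold`` CPM in *every* library.

    A miRNA is kept as soon as one library reaches the threshold;
    the comparison is strict (< threshold everywhere => dropped), so a
    miRNA at exactly 10.0 CPM in all libraries is kept.
    """
    low_everywhere = (norm < threshold).all(axis=1)
    dropped = norm.index[low_everywhere].tolist()
    kept = norm.index[~low_everywhere].tolist()
    log.info("filter_low_expression: kept %d, dropped %d miRNAs", len(kept), len(dropped))
    return kept, dropped


# ---------------------------------------------------------------------------
# mid-parent synthesis
# ---------------------------------------------------------------------------

def _parent_samples(samples: pd.DataFrame, genotype: str) -> pd.DataFrame:
    sub = samples[samples["genotype"] == genotype].sort_values("replicate")
    if sub.empty:
        raise ValueError(f"parent genotype {genotype!r} absent from sample table")
    return sub


def synthesize_midparent(
    norm: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Mid-parent CPM profiles A_i = (P1_i + P2_i) / 2.

    Parental replicates are paired by replicate index; the number of
    pseudo-replicates is the smaller parental replicate count.  Returns a
    miRNA x pseudo-replicate CPM matrix with columns ``A_1 .. A_k``.
    """
    p1 = _parent_samples(samples, "P1")
    p2 = _parent_samples(samples, "P2")
    k = min(len(p1), len(p2))
    cols = {}
    for i in range(k):
        s1 = p1.iloc[i]["sample_id"]
        s2 = p2.iloc[i]["sample_id"]
        cols[f"A_{i + 1}"] = (norm[s1] + norm[s2]) / 2.0
    return pd.DataFrame(cols, index=norm.index)


def with_midparent(
    counts: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Augment a count matrix with mid-parent pseudo-libraries.

    Each pseudo-replicate's CPM profile is converted back to integer
    pseudo-counts at the rounded mean parental library size, so the same
    pooled binomial machinery applies to hybrid-vs-A contrasts.

    Returns (augmented counts, augmented samples, explicit library totals).
    The pseudo-libraries' totals are the conversion denominator, not their
    column sums.
    """
    totals = library_totals(counts)
    norm = cpm(counts)
    a_cpm = synthesize_midparent(norm, samples)
    parents = samples[samples["genotype"].isin(("P1", "P2"))]["sample_id"]
    mean_lib = int(round(totals[parents].mean()))
    a_counts = (a_cpm * mean_lib / 1e6).round().astype(np.int64)
    aug_counts = pd.concat([counts, a_counts], axis=1)
    extra = pd.DataFrame(
        {
            "sample_id": a_cpm.columns,
            "genotype": "A",
            "replicate": range(1, len(a_cpm.columns) + 1),
        }
    )
    aug_samples = pd.concat([samples, extra], ignore_index=True)
    aug_totals = pd.concat(
        [totals, pd.Series(mean_lib, index=a_cpm.columns, dtype=np.int64)]
    )
    return aug_counts, aug_samples, aug_totals


# ---------------------------------------------------------------------------
# the exact binomial test
# ---------------------------------------------------------------------------

def _minlike_two_sided(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value by the minimum-likelihood rule.

    Sums P(X = x) over every x whose probability does not exceed that of
    the observed k (with a tiny relative slack for exact ties).  Small
    totals are enumerated directly; large totals use the unimodality of
    the binomial pmf: the observed tail is a cdf/sf call and the opposite
    tail's boundary is located by binary search over the monotone flank,
    which is exact to floating precision at any n.
    """
    d = binom.pmf(k, n, p0)
    thresh = d * (1.0 + _TIE_RTOL)
    if n <= 2000:
        x = np.arange(n + 1)
        pmf = binom.pmf(x, n, p0)
        mask = pmf <= thresh
        if mask.all():
            return 1.0
        return float(min(1.0, pmf[mask].sum()))
    mode = min(int(math.floor((n + 1) * p0)), n)
    if k == mode or binom.pmf(mode, n, p0) <= thresh:
        return 1.0
    if k < mode:
        left = binom.cdf(k, n, p0)
        # pmf non-increasing on [mode, n]: first j with pmf(j) <= thresh
        lo, hi = mode, n + 1
        while lo < hi:
            mid = (lo + hi) // 2
            if binom.pmf(mid, n, p0) <= thresh:
                hi = mid
            else:
                lo = mid + 1
        right = binom.sf(lo - 1, n, p0) if lo <= n else 0.0
    else:
        right = binom.sf(k - 1, n, p0)
        # pmf non-decreasing on [0, mode]: last j with pmf(j) <= thresh
        lo, hi = -1, mode
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if binom.pmf(mid, n, p0) <= thresh:
                lo = mid
            else:
                hi = mid - 1
        left = binom.cdf(lo, n, p0) if lo >= 0 else 0.0
    return float(min(1.0, left + right))


def binomial_exact_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Conditional exact test of equal relative abundance in two libraries.

    Under H0, k1 | (k1 + k2) ~ Binomial(k1 + k2, n1 / (n1 + n2)).
    Returns the two-sided minimum-likelihood p-value in (0, 1];
    k1 + k2 = 0 returns 1 by convention (no signal).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    n = k1 + k2
    if n == 0:
        return 1.0
    return max(_minlike_two_sided(int(k1), int(n), n1 / (n1 + n2)), 5e-324)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    Standard step-up with monotone enforcement; stable sort keeps tied
    p-values in input order. q in [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def _pool(counts: pd.DataFrame, totals: pd.Series, sample_ids) -> tuple[pd.Series, int]:
    pooled = counts[list(sample_ids)].sum(axis=1)
    return pooled, int(totals[list(sample_ids)].sum())


def de_contrast(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    group1: str,
    group2: str,
    thresholds: DEThresholds = DEThresholds(),
    totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Pairwise differential expression between two genotype groups.

    Counts and library totals are pooled within each group; each miRNA
    gets an exact binomial p, BH q over all miRNAs in this contrast, a
    log2 fold change log2((CPM1 + c) / (CPM2 + c)) with pseudocount c,
    and a status: up / down when q < q_max and |log2fc| >= min_abs_log2fc
    (sign giving the direction), ns otherwise.

    Apply after :func:`filter_low_expression`; rows enter the BH family
    as given.
    """
    for g in (group1, group2):
        if g not in set(samples["genotype"]):
            raise ValueError(f"unknown group {g!r}")
    if totals is None:
        totals = library_totals(counts)
    ids1 = samples.loc[samples["genotype"] == group1, "sample_id"]
    ids2 = samples.loc[samples["genotype"] == group2, "sample_id"]
    k1, n1 = _pool(counts, totals, ids1)
    k2, n2 = _pool(counts, totals, ids2)

    pvals = np.array(
        [binomial_exact_test(int(a), n1, int(b), n2) for a, b in zip(k1, k2)]
    )
    qvals = bh_adjust(pvals)

    c = thresholds.pseudocount
    cpm1 = k1 / n1 * 1e6
    cpm2 = k2 / n2 * 1e6
    log2fc = np.log2((cpm1 + c) / (cpm2 + c))

    sig = (qvals < thresholds.q_max) & (
        np.abs(log2fc) >= thresholds.min_abs_log2fc
    )
    status = np.where(sig & (log2fc > 0), "up", np.where(sig, "down", "ns"))

    out = pd.DataFrame(
        {
            "mirna_id": counts.index,
            "log2fc": log2fc.values,
            "p": pvals,
            "q": qvals,
            "status": status,
        }
    )
    out.attrs["contrast"] = (group1, group2)
    log.info(
        "de_contrast %s vs %s: %d tested, %d up, %d down",
        group1, group2, len(out), (status == "up").sum(), (status == "down").sum(),
    )
    return out
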