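"""Shannon diversity of dominant (binary) markers and the associated tests.

For a dominant marker with band-presence frequency f the Shannon index is
S = -(f ln f + (1-f) ln(1-f)), bounded by ln 2 ~ 0.693.  Group-level
summaries average S over loci; MSL-vs-NML and field-vs-micro contrasts use
the Wilcoxon rank-sum test on per-locus values and a paired t-test on
matched summary pairs.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["shannon_locus", "group_diversity", "wilcoxon_rank_sum", "paired_t"]


def shannon_locus(presence_freq, base: float = math.e):
    """Shannon diversity of a binary locus from its presence frequency.

    Vectorised; 0*log(0) is taken as 0 so monomorphic loci score 0.
    """
    f = np.asarray(presence_freq, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("presence frequency must be in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        s = -(f * np.log(f) + (1 - f) * np.log(1 - f))
    s = np.where((f == 0) | (f == 1), 0.0, s) / math.log(base)
    return float(s) if np.isscalar(presence_freq) else s


def group_diversity(
    binary: pd.DataFrame,
    groups: Mapping[str, str],
    loci: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-group per-locus Shannon values and the per-group mean over loci.

    Frequencies are computed over non-missing cells within each group; a
    locus with no calls in a group is skipped in that group's mean (logged).
    Returns ``(per_locus, means)`` where ``per_locus`` has loci as rows and
    groups as columns.
    """
    sub = binary if loci is None else binary[list(loci)]
    if sub.shape[1] == 0:
        raise ValueError("empty locus subset")
    cols = {}
    for g in sorted(set(groups.values())):
        members = [s for s in sub.index if groups.get(s) == g]
        block = sub.loc[members]
        freq = block.mean(axis=0, skipna=True)
        n_called = block.notna().sum(axis=0)
        if (n_called == 0).any():
            skipped = freq.index[n_called == 0].tolist()
            logger.warning("group %r: %d all-missing loci skipped: %s",
                           g, len(skipped), skipped[:5])
        s = pd.Series(np.nan, index=freq.index)
        ok = n_called > 0
        s[ok] = shannon_locus(freq[ok].to_numpy())
        cols[g] = s
    per_locus = pd.DataFrame(cols)
    per_locus.index.name = "locus_id"
    return per_locus, per_locus.mean(axis=0, skipna=True)


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    continuity: bool = True,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both samples have <= 10
    observations and the pooled values are tie-free; otherwise the normal
    approximation with mid-ranks, tie correction and a 0.5 continuity
    correction.  Returns (W, p) with W the rank-sum U statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= 10 and y.size <= 10 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=continuity,
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on matched values.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y and df = n - 1.  A
    zero-variance difference vector has no defined t and is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired_t requires two equal-length samples of size >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("differences have zero variance; paired t undefined")
    n = d.size
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)
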