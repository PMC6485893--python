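"""Per-locus differential methylation, FDR control, UPGMA and heatmaps.

Each methylation-susceptible locus yields a 2 x k contingency table of
methylation-state counts (field vs micropropagated); significance comes
from the Freeman-Halton generalisation of Fisher's exact test, with
Benjamini-Hochberg adjustment across the loci of one genotype/primer
family.  Significant loci feed a categorical heatmap whose rows are
ordered by UPGMA clustering on Gower distances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .amova import DistanceMatrix
from .meth_states import STATES, LocusPartition, MethylationStateMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_exact",
    "bh_adjust",
    "test_all_msl",
    "Dendrogram",
    "upgma",
    "heatmap_export",
]

# relative tolerance for "point probability <= observed" ties
_FH_EPS = 1e-10


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact(table) -> float:
    """Two-sided exact test on a 2 x k contingency table (Freeman-Halton).

    Enumerates every table with the observed margins under the multivariate
    hypergeometric null and sums the point probabilities not exceeding the
    observed table's (to within a tiny relative tolerance, so exact ties are
    included despite floating point).  For 2 x 2 this reduces to the
    classical two-sided Fisher test.  Columns that are entirely zero are
    dropped; a zero row margin makes the table degenerate (p = 1).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("table must be 2 x k")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[1] <= 1:
        return 1.0
    if (t.sum(axis=1) == 0).any():
        logger.warning("fisher_exact: zero row margin; p = 1")
        return 1.0
    r1 = int(t[0].sum())
    cols = t.sum(axis=0)
    n = int(cols.sum())
    log_denom = _log_comb(np.array(n, dtype=float), np.array(r1, dtype=float))

    # grid over the first k-1 columns of row 1; the last is forced by r1
    grids = np.meshgrid(*[np.arange(c + 1) for c in cols[:-1]], indexing="ij")
    a_last = r1 - sum(g for g in grids)
    valid = (a_last >= 0) & (a_last <= cols[-1])
    logp = -log_denom * np.ones(valid.shape)
    for j, g in enumerate(grids):
        logp = logp + _log_comb(float(cols[j]), g.astype(float))
    logp = logp + np.where(
        valid, _log_comb(float(cols[-1]), np.clip(a_last, 0, cols[-1]).astype(float)), -np.inf
    )
    obs_logp = -log_denom + sum(
        _log_comb(float(c), float(a)) for c, a in zip(cols, t[0])
    )
    include = valid & (logp <= obs_logp + _FH_EPS)
    p = float(np.exp(logp[include]).sum())
    return min(p, 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_all_msl(
    states: MethylationStateMatrix,
    partition: LocusPartition,
    groups: Mapping[str, str],
    fdr: float = 0.05,
    binary: bool = False,
) -> pd.DataFrame:
    """Exact tests of state composition between the two groups at every MSL.

    For each MSL a 2 x k table of group x state counts is built over the
    states actually observed there (``binary=True`` collapses II/III/IV to a
    single methylated class first), tested with :func:`fisher_exact`, and
    the p-values are BH-adjusted across all MSL of this family.  Returns a
    DataFrame with per-group state counts, p, q and the significance flag.
    """
    levels = sorted({groups[s] for s in states.samples})
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    members = {g: [s for s in states.samples if groups[s] == g] for g in levels}
    sub = states.values[partition.msl_ids]
    cats = ("unmeth", "meth") if binary else STATES

    rows = []
    for locus in partition.msl_ids:
        col = sub[locus]
        counts = np.zeros((2, len(cats)), dtype=np.int64)
        for gi, g in enumerate(levels):
            vals = col.loc[members[g]].dropna()
            if binary:
                vals = vals.map(lambda s: "unmeth" if s == "I" else "meth")
            vc = vals.value_counts()
            for ci, c in enumerate(cats):
                counts[gi, ci] = int(vc.get(c, 0))
        p = fisher_exact(counts)
        row = {"locus_id": locus, "p": p}
        for gi, g in enumerate(levels):
            for ci, c in enumerate(cats):
                row[f"n_{g}_{c}"] = counts[gi, ci]
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr
        out = out.sort_values(["q", "p", "locus_id"], kind="stable").reset_index(drop=True)
    else:
        out = pd.DataFrame(columns=["locus_id", "p", "q", "significant"])
    return out


@dataclass
class Dendrogram:
    """UPGMA merge tree; ultrametric node heights (merge distance / 2).

    ``merges`` rows are (left, right, height, size) where left/right index
    leaves (0..n-1) or earlier merges (n + row).
    """

    merges: list[tuple[int, int, float, int]]
    leaves: list[str]

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the tree."""
        n = len(self.leaves)

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            left, right, _, _ = self.merges[node - n]
            return walk(left) + walk(right)

        root = n + len(self.merges) - 1 if self.merges else 0
        return [self.leaves[i] for i in walk(root)]

    def cophenetic(self) -> pd.DataFrame:
        """Matrix of tree distances: 2 x height of the lowest common merge."""
        n = len(self.leaves)
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        out = np.zeros((n, n))
        for k, (a, b, h, _) in enumerate(self.merges):
            for i in members[a]:
                for j in members[b]:
                    out[i, j] = out[j, i] = 2.0 * h
            members[n + k] = members[a] + members[b]
        return pd.DataFrame(out, index=self.leaves, columns=self.leaves)

    def to_newick(self) -> str:
        """Newick string with branch lengths from the ultrametric heights."""
        n = len(self.leaves)
        height = {i: 0.0 for i in range(n)}
        for k, (_, _, h, _) in enumerate(self.merges):
            height[n + k] = h

        def walk(node: int, parent_h: float) -> str:
            bl = parent_h - height[node]
            if node < n:
                return f"{self.leaves[node]}:{bl:.10g}"
            left, right, h, _ = self.merges[node - n]
            return f"({walk(left, h)},{walk(right, h)}):{bl:.10g}"

        if not self.merges:
            return f"({self.leaves[0]}:0);"
        root = n + len(self.merges) - 1
        left, right, h, _ = self.merges[-1]
        return f"({walk(left, h)},{walk(right, h)});"


def upgma(D: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration with deterministic tie-breaking.

    Cluster distances are size-weighted means of member pairwise distances;
    merge height is half the merge distance so leaf-to-leaf tree distance
    equals the cluster distance (ultrametric).  Ties are broken toward the
    pair whose clusters contain the smallest original leaf indices.
    """
    n = D.n
    if n < 2:
        raise ValueError("UPGMA needs at least two samples")
    dist = {frozenset((i, j)): float(D.values[i, j]) for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    minleaf = {i: i for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(sorted(active, key=lambda c: minleaf[c]), 2):
            d = dist[frozenset((a, b))]
            key = (d, minleaf[a] if minleaf[a] < minleaf[b] else minleaf[b],
                   max(minleaf[a], minleaf[b]))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        d_ab = dist[frozenset((a, b))]
        new = next_id
        next_id += 1
        for c in active - {a, b}:
            d_new = (
                size[a] * dist[frozenset((a, c))] + size[b] * dist[frozenset((b, c))]
            ) / (size[a] + size[b])
            dist[frozenset((new, c))] = d_new
        size[new] = size[a] + size[b]
        minleaf[new] = min(minleaf[a], minleaf[b])
        # left child = the one holding the smaller leaf index
        left, right = (a, b) if minleaf[a] <= minleaf[b] else (b, a)
        merges.append((left, right, d_ab / 2.0, size[new]))
        active -= {a, b}
        active.add(new)
    return Dendrogram(merges=merges, leaves=list(D.ids))


_STATE_COLORS = {"I": "#2c7bb6", "II": "#abd9e9", "III": "#fdae61", "IV": "#d7191c"}
_GROUP_COLORS = {"field": "#1a9641", "micro": "#d73027"}


def heatmap_export(
    states: MethylationStateMatrix,
    significant_loci: Sequence[str],
    groups: Mapping[str, str],
    dendrogram: Dendrogram | None,
    tsv_path,
    image_path=None,
):
    """Categorical heatmap of significant MSL states, plus its TSV twin.

    Rows are samples in dendrogram leaf order with a propagation-system
    colour strip; columns are the significant loci; cells use one colour per
    methylation state.  The TSV is always written; with zero significant
    loci only a header-only TSV is produced (warning, no image).
    """
    loci = list(significant_loci)
    order = dendrogram.leaf_order() if dendrogram is not None else states.samples
    sub = states.values.loc[order, loci] if loci else states.values.loc[order, []]
    with open(tsv_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["sample_id", "group", *loci]) + "\n")
        if loci:
            for sid in order:
                cells = ["NA" if pd.isna(v) else str(v) for v in sub.loc[sid]]
                fh.write("\t".join([sid, str(groups.get(sid, "")), *cells]) + "\n")
    if not loci:
        logger.warning("heatmap_export: zero significant loci; TSV header only, no image")
        return None
    if image_path is None:
        return None

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    code = np.full(sub.shape, np.nan)
    for k, s in enumerate(STATES):
        code[(sub == s).to_numpy()] = k
    fig, (ax_strip, ax) = plt.subplots(
        1, 2, figsize=(max(4, 0.25 * len(loci) + 2), max(3, 0.12 * len(order))),
        gridspec_kw={"width_ratios": [0.04, 1]}, constrained_layout=True,
    )
    cmap = ListedColormap([_STATE_COLORS[s] for s in STATES])
    cmap.set_bad("#eeeeee")
    ax.imshow(np.ma.masked_invalid(code), aspect="auto", cmap=cmap, vmin=-0.5, vmax=3.5,
              interpolation="nearest")
    ax.set_xticks(range(len(loci)))
    ax.set_xticklabels(loci, rotation=90, fontsize=5)
    ax.set_yticks([])
    strip = np.array(
        [[list(_GROUP_COLORS).index(groups.get(s, "field")) for s in order]]
    ).T
    ax_strip.imshow(strip, aspect="auto",
                    cmap=ListedColormap(list(_GROUP_COLORS.values())), vmin=-0.5, vmax=1.5,
                    interpolation="nearest")
    ax_strip.set_xticks([])
    ax_strip.set_yticks(range(len(order)))
    ax_strip.set_yticklabels(order, fontsize=4)
    handles = [
        Patch(color=_STATE_COLORS[s], label=f"Type {s}") for s in STATES
    ] + [Patch(color=c, label=g) for g, c in _GROUP_COLORS.items()]
    ax.legend(handles=handles, loc="upper left", bbox_to_anchor=(1.01, 1), fontsize=6)
    fig.savefig(image_path, dpi=150)
    plt.close(fig)
    return image_path
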