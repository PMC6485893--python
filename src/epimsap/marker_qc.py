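"""Primer-screening QC: marker reproducibility and discriminatory alleles.

Selective primer combinations are screened on a small pilot panel before the
full study: the metrics are the percentage of markers scored identically in
technical duplicates, the number of loci amplified, and the number of loci
whose presence frequency separates the two propagation systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_profiles import SampleRecord, ScoreMatrix

__all__ = ["PrimerQCReport", "reproducibility", "count_discriminatory",
           "replicate_pairs", "primer_qc_report"]


@dataclass
class PrimerQCReport:
    primer: str
    n_loci: int
    reproducibility_pct: dict  # per enzyme name, plus "mean"
    n_discriminatory: dict  # per enzyme name
    discriminatory_loci: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for enzyme in self.n_discriminatory:
            rows.append(
                {
                    "primer": self.primer,
                    "enzyme": enzyme,
                    "n_loci": self.n_loci,
                    "reproducibility_pct": self.reproducibility_pct[enzyme],
                    "n_discriminatory": self.n_discriminatory[enzyme],
                }
            )
        return pd.DataFrame(rows)


def replicate_pairs(records: Sequence[SampleRecord]) -> list[tuple[str, str]]:
    """(source, duplicate) pairs from metadata ``replicate_of`` links."""
    return [(r.replicate_of, r.sample_id) for r in records if r.replicate_of]


def reproducibility(profile: ScoreMatrix, pairs: Sequence[tuple[str, str]]) -> float:
    """Percent of markers called identically in technical duplicate pairs.

    For each pair the fraction of loci with the same 0/1 call is computed
    over loci where both calls are non-missing; the mean over pairs is
    returned as a percentage.
    """
    if not pairs:
        raise ValueError("no replicate pairs supplied")
    scores = []
    for a, b in pairs:
        for sid in (a, b):
            if sid not in profile.values.index:
                raise KeyError(f"replicate sample {sid!r} not in score matrix")
        x = profile.values.loc[a].to_numpy()
        y = profile.values.loc[b].to_numpy()
        both = ~np.isnan(x) & ~np.isnan(y)
        if not both.any():
            raise ValueError(f"pair ({a!r}, {b!r}) shares no scored loci")
        scores.append(float(np.mean(x[both] == y[both])))
    return 100.0 * float(np.mean(scores))


def count_discriminatory(
    profile: ScoreMatrix,
    groups: Mapping[str, str],
    min_freq_diff: float = 1.0,
) -> tuple[int, list[str]]:
    """Count loci whose presence frequency differs between the two groups.

    A locus is discriminatory when |freq(A) - freq(B)| >= ``min_freq_diff``;
    the default 1.0 counts only fixed differences, the only robust call at
    pilot sample sizes.  Missing cells are excluded from the frequencies.
    """
    levels = sorted(set(groups.values()))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    masks = {
        g: [s for s in profile.samples if groups.get(s) == g] for g in levels
    }
    for g, members in masks.items():
        if not members:
            raise ValueError(f"group {g!r} has no samples in the matrix")
    fa = profile.values.loc[masks[levels[0]]].mean(axis=0, skipna=True)
    fb = profile.values.loc[masks[levels[1]]].mean(axis=0, skipna=True)
    diff = (fa - fb).abs()
    hits = diff.index[diff >= min_freq_diff].tolist()
    return len(hits), hits


def primer_qc_report(
    hpa: ScoreMatrix,
    msp: ScoreMatrix,
    pairs: Sequence[tuple[str, str]],
    groups: Mapping[str, str],
    min_freq_diff: float = 1.0,
) -> PrimerQCReport:
    """QC summary for one primer combination over both digests.

    Reproducibility is reported per enzyme and averaged, since published
    summaries do not always say which convention they used.
    """
    rep = {
        "HpaII": reproducibility(hpa, pairs),
        "MspI": reproducibility(msp, pairs),
    }
    rep["mean"] = float(np.mean([rep["HpaII"], rep["MspI"]]))
    n_disc, loci = {}, {}
    for name, m in (("HpaII", hpa), ("MspI", msp)):
        # duplicates are excluded from group frequencies
        core = {s: g for s, g in groups.items() if s in m.values.index}
        n, ids = count_discriminatory(
            ScoreMatrix(m.enzyme, m.primer, m.values.loc[list(core)]),
            core,
            min_freq_diff,
        )
        n_disc[name], loci[name] = n, ids
    return PrimerQCReport(
        primer=hpa.primer,
        n_loci=len(hpa.loci),
        reproducibility_pct=rep,
        n_discriminatory=n_disc,
        discriminatory_loci=loci,
    )
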