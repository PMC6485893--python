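"""Methylation-state calling from isoschizomer band pairs and MSL/NML partition.

HpaII and MspI both cut CCGG but differ in methylation sensitivity, so the
four (HpaII band, MspI band) combinations map onto four cytosine-methylation
states of the restriction site:

=========  =========  =========  =================================
HpaII      MspI       state      interpretation
=========  =========  =========  =================================
1          1          I          unmethylated
0          1          II         internal-cytosine methylation
1          0          III        hemimethylation (outer cytosine)
0          0          IV         fully methylated (or site absent)
=========  =========  =========  =================================

Loci where the two digests disagree (states II/III) in more samples than
scoring error can explain are Methylation-Susceptible Loci (MSL, epigenetic
signal); concordant loci are Non-Methylated Loci (NML, genetic
presence/absence signal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_profiles import PairedProfile

logger = logging.getLogger(__name__)

STATES = ("I", "II", "III", "IV")
STATE_LABELS = {
    "I": "unmethylated",
    "II": "internal methylation",
    "III": "hemimethylated",
    "IV": "fully methylated",
}
_PAIR_TO_STATE = {(1, 1): "I", (0, 1): "II", (1, 0): "III", (0, 0): "IV"}
_STATE_TO_PAIR = {v: k for k, v in _PAIR_TO_STATE.items()}

__all__ = [
    "STATES",
    "STATE_LABELS",
    "classify_state",
    "band_pair",
    "MethylationStateMatrix",
    "LocusPartition",
    "call_states",
    "partition_loci",
    "recode_msl_binary",
    "recode_nml_binary",
    "state_frequencies",
]


def classify_state(hpa_band: int, msp_band: int) -> str:
    """Map one (HpaII, MspI) band pair to its methylation state I-IV."""
    try:
        return _PAIR_TO_STATE[(int(hpa_band), int(msp_band))]
    except KeyError:
        raise ValueError(f"band calls must be 0 or 1, got ({hpa_band}, {msp_band})")


def band_pair(state: str) -> tuple[int, int]:
    """Inverse of :func:`classify_state`: state -> (HpaII, MspI) bands."""
    try:
        return _STATE_TO_PAIR[state]
    except KeyError:
        raise ValueError(f"unknown state {state!r}")


@dataclass
class MethylationStateMatrix:
    """Categorical samples x loci matrix over states I-IV (NaN = missing)."""

    values: pd.DataFrame  # object dtype: "I".."IV" or NaN
    primer: str

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def loci(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class LocusPartition:
    """The MSL/NML split of loci at a given scoring-error threshold."""

    msl_ids: list[str]
    nml_ids: list[str]
    error_rate: float
    discordance: pd.Series  # per-locus fraction of samples in states II/III
    low_call_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.msl_ids) & set(self.nml_ids):
            raise ValueError("MSL and NML sets overlap")


def call_states(profile: PairedProfile) -> MethylationStateMatrix:
    """Call the methylation state of every cell of a paired profile.

    A cell is missing iff either enzyme's call is missing.
    """
    h = profile.hpa.values.to_numpy(float)
    m = profile.msp.values.to_numpy(float)
    missing = np.isnan(h) | np.isnan(m)
    code = np.where(missing, 0, 2 * np.nan_to_num(h) + np.nan_to_num(m)).astype(int)
    lookup = np.array(["IV", "II", "III", "I"], dtype=object)  # index 2h+m
    out = lookup[code]
    out[missing] = np.nan
    return MethylationStateMatrix(
        values=pd.DataFrame(out, index=profile.samples, columns=profile.loci),
        primer=profile.primer,
    )


def suggest_error_threshold(error_rate: float, n_samples: int) -> float:
    """MSL discordance threshold clearing the scoring-error floor.

    Independent per-cell mis-scoring at rate e makes a truly concordant
    locus look discordant in a sample with probability 2e(1-e) (exactly one
    of the two enzyme calls flipped).  A partition threshold below that
    floor misclassifies concordant loci systematically, so the suggested
    threshold is the floor plus two binomial standard deviations at the
    study's sample count.
    """
    floor = 2.0 * error_rate * (1.0 - error_rate)
    sd = float(np.sqrt(floor * (1.0 - floor) / max(n_samples, 1)))
    return floor + 2.0 * sd


def partition_loci(
    states: MethylationStateMatrix,
    error_rate: float = 0.05,
    min_call_rate: float = 0.5,
) -> LocusPartition:
    """Split loci into MSL and NML by enzyme-discordance frequency.

    A locus is MSL iff the fraction of its non-missing samples in the
    discordant states {II, III} strictly exceeds ``error_rate``.  Loci with
    fewer than ``min_call_rate`` non-missing calls (including all-missing
    loci) carry too little evidence and are assigned NML with a warning;
    they are listed in ``low_call_ids``.
    """
    if not 0 <= error_rate < 1:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")
    arr = states.values.to_numpy(dtype=object)
    present = pd.notna(states.values).to_numpy()
    discordant = (arr == "II") | (arr == "III")
    n_called = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_called > 0, discordant.sum(axis=0) / np.maximum(n_called, 1), 0.0)
    disc = pd.Series(frac, index=states.values.columns, name="discordance")
    low = n_called < min_call_rate * states.values.shape[0]
    if low.any():
        ids = disc.index[low].tolist()
        logger.warning(
            "partition_loci: %d loci with <%.0f%% non-missing calls assigned NML: %s",
            len(ids), 100 * min_call_rate, ids[:10],
        )
    is_msl = (frac > error_rate) & ~low
    return LocusPartition(
        msl_ids=disc.index[is_msl].tolist(),
        nml_ids=disc.index[~is_msl].tolist(),
        error_rate=error_rate,
        discordance=disc,
        low_call_ids=disc.index[low].tolist(),
    )


def recode_msl_binary(
    states: MethylationStateMatrix,
    partition: LocusPartition,
    uninformative_policy: str = "fully_methylated",
) -> pd.DataFrame:
    """Recode MSL states to a binary methylated/unmethylated matrix.

    Under the default ``fully_methylated`` policy, states II/III/IV score 1
    (some methylation at the site) and state I scores 0.  The ``missing``
    policy instead treats state IV as uninformative (the (0,0) pattern can
    also mean the restriction site is absent) and sets it missing.
    """
    if uninformative_policy not in ("fully_methylated", "missing"):
        raise ValueError(f"unknown policy {uninformative_policy!r}")
    sub = states.values[partition.msl_ids]
    arr = sub.to_numpy(dtype=object)
    out = np.full(arr.shape, np.nan)
    out[arr == "I"] = 0.0
    out[(arr == "II") | (arr == "III")] = 1.0
    if uninformative_policy == "fully_methylated":
        out[arr == "IV"] = 1.0
    return pd.DataFrame(out, index=sub.index, columns=sub.columns)


def recode_nml_binary(profile: PairedProfile, partition: LocusPartition) -> pd.DataFrame:
    """Recode NML to genetic band presence/absence.

    Presence (1) requires the band in both digests (state I); (0,0) is
    absence (0).  Residual discordant cells at NML — within the scoring-error
    allowance that produced the partition — are set missing rather than
    guessed.
    """
    h = profile.hpa.values[partition.nml_ids].to_numpy(float)
    m = profile.msp.values[partition.nml_ids].to_numpy(float)
    out = np.full(h.shape, np.nan)
    out[(h == 1) & (m == 1)] = 1.0
    out[(h == 0) & (m == 0)] = 0.0
    return pd.DataFrame(out, index=profile.samples, columns=partition.nml_ids)


def state_frequencies(
    states: MethylationStateMatrix,
    partition: LocusPartition,
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Percentage of MSL cells in each state I-IV, per group and overall.

    Percentages are over non-missing MSL cells and each row sums to 100.
    """
    sub = states.values[partition.msl_ids]
    missing_groups = [s for s in sub.index if s not in groups]
    if missing_groups:
        raise ValueError(f"samples without a group: {missing_groups[:5]}")
    rows: dict[str, pd.Series] = {}

    def _pct(block: pd.DataFrame) -> pd.Series:
        counts = pd.Series(
            {s: (block.to_numpy(dtype=object) == s).sum() for s in STATES}, dtype=float
        )
        total = counts.sum()
        if total == 0:
            raise ValueError("no non-missing MSL cells in group")
        return 100.0 * counts / total

    for g in sorted(set(groups.values())):
        members = [s for s in sub.index if groups[s] == g]
        if not members:
            raise ValueError(f"group {g!r} is empty")
        rows[g] = _pct(sub.loc[members])
    rows["overall"] = _pct(sub)
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    return out
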