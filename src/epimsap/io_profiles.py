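"""Reading, validation and pairing of MSAP score matrices.

MSAP fingerprints are scored as binary presence/absence matrices, one per
restriction digest (HpaII/EcoRI or MspI/EcoRI) and selective-primer
combination.  Rows are samples, columns are anonymous loci (fragment bins);
cells are 0, 1 or NA.  The two isoschizomer digests of the same primer
combination are paired into a :class:`PairedProfile` with identical sample
and locus order, which is the unit every downstream analysis consumes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENZYMES = ("HpaII", "MspI")
PROPAGATION_LEVELS = ("field", "micro")

__all__ = [
    "SampleRecord",
    "ScoreMatrix",
    "PairedProfile",
    "read_score_matrix",
    "write_score_matrix",
    "read_metadata",
    "write_metadata",
    "metadata_frame",
    "pair_profiles",
]


@dataclass(frozen=True)
class SampleRecord:
    """One plant sample: a ramet of a genotype under one propagation system.

    ``replicate_of`` links a technical duplicate (re-run of the same DNA)
    to its source sample, used for marker-reproducibility QC.
    """

    sample_id: str
    genotype: str
    propagation: str
    block: str | None = None
    replicate_of: str | None = None

    def __post_init__(self) -> None:
        if self.propagation not in PROPAGATION_LEVELS:
            raise ValueError(
                f"sample {self.sample_id!r}: propagation must be one of "
                f"{PROPAGATION_LEVELS}, got {self.propagation!r}"
            )
        if self.replicate_of == self.sample_id:
            raise ValueError(f"sample {self.sample_id!r} cannot replicate itself")


class ScoreMatrix:
    """Binary samples x loci presence/absence matrix for one digest.

    ``values`` is a float DataFrame with entries 0.0, 1.0 or NaN (missing),
    indexed by sample id with locus ids as columns.
    """

    def __init__(self, enzyme: str, primer: str, values: pd.DataFrame):
        if enzyme not in ENZYMES:
            raise ValueError(f"enzyme must be one of {ENZYMES}, got {enzyme!r}")
        values = values.astype(float)
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if values.columns.has_duplicates:
            dupes = values.columns[values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate locus ids: {dupes}")
        arr = values.to_numpy()
        bad = ~(np.isnan(arr) | (arr == 0.0) | (arr == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at row {i + 1}, column {j + 1} "
                f"(sample {values.index[i]!r}, locus {values.columns[j]!r}): "
                f"{arr[i, j]!r}"
            )
        self.enzyme = enzyme
        self.primer = primer
        self.values = values

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def loci(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreMatrix):
            return NotImplemented
        return (
            self.enzyme == other.enzyme
            and self.primer == other.primer
            and self.values.equals(other.values)
        )

    def __repr__(self) -> str:
        return (
            f"ScoreMatrix(enzyme={self.enzyme!r}, primer={self.primer!r}, "
            f"{len(self.samples)} samples x {len(self.loci)} loci)"
        )


@dataclass(frozen=True)
class PairedProfile:
    """HpaII and MspI score matrices aligned sample-for-sample, locus-for-locus."""

    hpa: ScoreMatrix
    msp: ScoreMatrix
    primer: str

    def __post_init__(self) -> None:
        if self.hpa.enzyme != "HpaII" or self.msp.enzyme != "MspI":
            raise ValueError("hpa must be a HpaII matrix and msp a MspI matrix")
        if self.hpa.primer != self.primer or self.msp.primer != self.primer:
            raise ValueError("both matrices must carry the profile's primer token")
        if self.hpa.samples != self.msp.samples:
            raise ValueError("sample lists differ between HpaII and MspI matrices")
        if self.hpa.loci != self.msp.loci:
            raise ValueError("locus lists differ between HpaII and MspI matrices")

    @property
    def samples(self) -> list[str]:
        return self.hpa.samples

    @property
    def loci(self) -> list[str]:
        return self.hpa.loci


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_score_matrix(
    path: str | Path,
    enzyme: str,
    primer: str,
    delimiter: str | None = None,
    transpose: bool = False,
) -> ScoreMatrix:
    """Read a 0/1/NA score matrix from CSV/TSV.

    The first column must be ``sample_id``; remaining header tokens become
    locus ids.  ``transpose=True`` accepts the loci-as-rows orientation some
    scoring exports use.  Any cell outside {0, 1, NA} is a hard error naming
    the offending row and column.
    """
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    if raw.columns[0] != "sample_id":
        raise ValueError(
            f"{path}: first header token must be 'sample_id', got {raw.columns[0]!r}"
        )
    raw = raw.set_index("sample_id")
    if transpose:
        raw = raw.T
        raw.index.name = "sample_id"
    cells = raw.to_numpy(dtype=object)
    out = np.empty(cells.shape, dtype=float)
    for (i, j), cell in np.ndenumerate(cells):
        tok = str(cell).strip()
        if tok in ("", "NA", "NaN", "nan"):
            out[i, j] = np.nan
        elif tok == "0":
            out[i, j] = 0.0
        elif tok == "1":
            out[i, j] = 1.0
        else:
            raise ValueError(
                f"{path}: invalid cell {tok!r} at row {i + 1}, column {j + 1}"
            )
    values = pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return ScoreMatrix(enzyme=enzyme, primer=primer, values=values)


def write_score_matrix(matrix: ScoreMatrix, path: str | Path, delimiter: str = ",") -> None:
    """Write the matrix in the exact dialect ``read_score_matrix`` accepts."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(delimiter.join(["sample_id", *matrix.loci]) + "\n")
        arr = matrix.values.to_numpy()
        for i, sid in enumerate(matrix.samples):
            cells = ["NA" if np.isnan(v) else str(int(v)) for v in arr[i]]
            fh.write(delimiter.join([sid, *cells]) + "\n")


_META_HEADER = ["sample_id", "genotype", "propagation", "block", "replicate_of"]


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the sample-metadata CSV and validate record invariants."""
    path = Path(path)
    records: list[SampleRecord] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or reader.fieldnames[:3] != _META_HEADER[:3]:
            raise ValueError(
                f"{path}: metadata header must start with "
                f"{','.join(_META_HEADER[:3])}, got {reader.fieldnames}"
            )
        for row in reader:
            records.append(
                SampleRecord(
                    sample_id=row["sample_id"].strip(),
                    genotype=row["genotype"].strip(),
                    propagation=row["propagation"].strip(),
                    block=(row.get("block") or "").strip() or None,
                    replicate_of=(row.get("replicate_of") or "").strip() or None,
                )
            )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    known = set(ids)
    for r in records:
        if r.replicate_of is not None and r.replicate_of not in known:
            raise ValueError(
                f"{path}: sample {r.sample_id!r} replicates unknown sample "
                f"{r.replicate_of!r}"
            )
    return records


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_META_HEADER) + "\n")
        for r in records:
            fh.write(
                ",".join(
                    [r.sample_id, r.genotype, r.propagation, r.block or "", r.replicate_of or ""]
                )
                + "\n"
            )


def metadata_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by sample_id (convenience view)."""
    return pd.DataFrame(
        {
            "genotype": [r.genotype for r in records],
            "propagation": [r.propagation for r in records],
            "block": [r.block for r in records],
            "replicate_of": [r.replicate_of for r in records],
        },
        index=pd.Index([r.sample_id for r in records], name="sample_id"),
    )


def pair_profiles(hpa: ScoreMatrix, msp: ScoreMatrix) -> PairedProfile:
    """Align the two digests on their common samples and loci.

    Samples and loci are intersected and sorted lexicographically so the
    paired order is deterministic regardless of input order; dropped rows
    and columns are logged.
    """
    if hpa.primer != msp.primer:
        raise ValueError(
            f"primer mismatch: HpaII={hpa.primer!r} vs MspI={msp.primer!r}"
        )
    samples = sorted(set(hpa.samples) & set(msp.samples))
    loci = sorted(set(hpa.loci) & set(msp.loci))
    if not samples:
        raise ValueError("no samples shared between the two digests")
    if not loci:
        raise ValueError("no loci shared between the two digests")
    for name, m in (("HpaII", hpa), ("MspI", msp)):
        drop_s = sorted(set(m.samples) - set(samples))
        drop_l = sorted(set(m.loci) - set(loci))
        if drop_s:
            logger.info("pair_profiles: dropping %d %s-only samples: %s", len(drop_s), name, drop_s)
        if drop_l:
            logger.info("pair_profiles: dropping %d %s-only loci: %s", len(drop_l), name, drop_l)
    return PairedProfile(
        hpa=ScoreMatrix("HpaII", hpa.primer, hpa.values.loc[samples, loci]),
        msp=ScoreMatrix("MspI", msp.primer, msp.values.loc[samples, loci]),
        primer=hpa.primer,
    )
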