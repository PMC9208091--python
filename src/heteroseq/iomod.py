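"""Readers, writers and shared domain types.

All tabular files are UTF-8 TSV with a header row and "." as the decimal
mark. SNP positions are 1-based. Missing counts are hard errors, never
imputed as zeros: a silently absent sample usually means an upstream
bookkeeping problem that should surface immediately.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("heteroseq")

#: Genotype labels for the hybrid/parent trio design. P1 is the maternal
#: inbred (Z58 in the motivating maize study), P2 the paternal inbred (C72),
#: F1a and F1b the two reciprocal F1 hybrids (Z58xC72 and C72xZ58).
GENOTYPES = ("P1", "P2", "F1a", "F1b")
PARENTS = ("P1", "P2")
HYBRIDS = ("F1a", "F1b")

ALLELE_COLUMNS = ["gene_id", "snp_id", "chrom", "pos", "sample_id", "count_p1", "count_p2"]


class HeteroseqError(ValueError):
    """Base class for validation and pipeline errors."""


@dataclasses.dataclass(frozen=True)
class SampleDesign:
    """One sequencing library: its id, genotype and replicate number."""

    sample_id: str
    genotype: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise HeteroseqError(
                f"unknown genotype {self.genotype!r} for sample {self.sample_id!r}; "
                f"expected one of {GENOTYPES}"
            )
        if self.replicate < 1:
            raise HeteroseqError(f"replicate must be >= 1 (sample {self.sample_id!r})")


def validate_design(design: Sequence[SampleDesign], require_all_genotypes: bool = False) -> None:
    """Check sample-id uniqueness and, optionally, full trio coverage."""
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise HeteroseqError(f"duplicate sample ids in design: {dup}")
    if require_all_genotypes:
        present = {d.genotype for d in design}
        missing = [g for g in GENOTYPES if g not in present]
        if missing:
            raise HeteroseqError(f"design missing genotypes required for the full pipeline: {missing}")


def design_samples(design: Sequence[SampleDesign], genotype: str) -> list[str]:
    """Sample ids of one genotype, in design order."""
    return [d.sample_id for d in design if d.genotype == genotype]


class CountMatrix:
    """Gene x sample matrix of raw, non-negative integer read counts.

    Thin wrapper over a pandas DataFrame (genes as index, samples as
    columns) that enforces the integrality/non-negativity invariants once,
    at construction.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise HeteroseqError(f"duplicate gene ids: {dup[:5]}")
        if counts.columns.has_duplicates:
            raise HeteroseqError("duplicate sample ids in count matrix")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            # accept float input only if exactly integral
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere((~np.isfinite(arr)) | (arr != np.floor(arr)))[0]
                raise HeteroseqError(
                    f"non-integer count at gene {counts.index[bad[0]]!r}, "
                    f"sample {counts.columns[bad[1]]!r}"
                )
            arr = arr.astype(np.int64)
        if arr.size and arr.min() < 0:
            bad = np.argwhere(arr < 0)[0]
            raise HeteroseqError(
                f"negative count at gene {counts.index[bad[0]]!r}, sample {counts.columns[bad[1]]!r}"
            )
        self.df = pd.DataFrame(arr.astype(np.int64), index=counts.index, columns=counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.df.equals(other.df)


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Per-gene ground truth attached to a simulated dataset."""

    gene_id: str
    true_class: str
    true_hybrid_allele_prop: float
    true_regulation: str
    base_mean: float
    dispersion: float


# ---------------------------------------------------------------------------
# readers


def read_design(path: str | Path) -> list[SampleDesign]:
    """Read a YAML design file mapping sample_id -> {genotype, replicate}."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "samples" not in raw:
        raise HeteroseqError(f"design file {path} must contain a top-level 'samples' mapping")
    design = [
        SampleDesign(sample_id=str(sid), genotype=str(spec["genotype"]), replicate=int(spec["replicate"]))
        for sid, spec in raw["samples"].items()
    ]
    validate_design(design)
    return design


def write_design(design: Sequence[SampleDesign], path: str | Path) -> None:
    payload = {
        "samples": {
            d.sample_id: {"genotype": d.genotype, "replicate": d.replicate} for d in design
        }
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_counts(path: str | Path, design: Sequence[SampleDesign]) -> CountMatrix:
    """Read a TSV count table (first column gene id) restricted to the design.

    Columns are reordered to follow the design; a design sample missing from
    the file is a hard error naming the sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    wanted = [d.sample_id for d in design]
    missing = [s for s in wanted if s not in df.columns]
    if missing:
        raise HeteroseqError(f"count table {path} is missing design sample(s): {missing}")
    df = df[wanted]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise HeteroseqError(
            f"non-numeric count {df.iat[r, c]!r} at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return CountMatrix(numeric)


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read a SNP-level allele-count TSV and validate it.

    Expected columns: gene_id, snp_id, chrom, pos, sample_id, count_p1,
    count_p2. (gene_id, snp_id, sample_id) must be unique; pos is 1-based.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "snp_id": str, "chrom": str, "sample_id": str})
    return validate_allele_counts(df)


def validate_allele_counts(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ALLELE_COLUMNS if c not in df.columns]
    if missing:
        raise HeteroseqError(f"allele-count table missing column(s): {missing}")
    df = df[ALLELE_COLUMNS].copy()
    key = ["gene_id", "snp_id", "sample_id"]
    if df.duplicated(subset=key).any():
        dup = df.loc[df.duplicated(subset=key), key].iloc[0].tolist()
        raise HeteroseqError(f"duplicate (gene_id, snp_id, sample_id) row: {dup}")
    if len(df) and int(df["pos"].min()) < 1:
        raise HeteroseqError("SNP positions are 1-based; found pos < 1")
    if len(df) and (int(df["count_p1"].min()) < 0 or int(df["count_p2"].min()) < 0):
        raise HeteroseqError("negative allele counts")
    return df


# ---------------------------------------------------------------------------
# writers


def write_results(records: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV, floats at 6 significant digits.

    Column order is the DataFrame's order, which every producer in this
    package fixes deterministically; an empty table still gets its header.
    """
    path = Path(path)
    records.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")


def truth_to_frame(truth: Iterable[SyntheticTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(t) for t in truth],
        columns=["gene_id", "true_class", "true_hybrid_allele_prop", "true_regulation", "base_mean", "dispersion"],
    )
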