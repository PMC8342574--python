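"""Reading, validation and assembly of twin-cohort inputs.

Two tabular inputs drive an analysis:

* a sample-by-taxon table of 16S read counts (or proportions) in the
  style of a species-level read-classification pipeline, one row per
  vaginal sample, with a per-sample total read count;
* a participant metadata CSV carrying pair ID, zygosity (MZ/DZ),
  self-reported ancestry, age and optional reproductive-health
  covariates.

This module applies the per-sample read-depth screen, converts counts
to relative abundances, and joins metadata to samples to form complete
twin pairs.  Participants whose co-twin lacks a retained sample are
singletons and are excluded before any downstream statistic is
computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxaCountTable",
    "TaxaProportionTable",
    "ParticipantRecord",
    "TwinPair",
    "TwinCohort",
    "MalformedInputError",
    "DuplicateKeyError",
    "InconsistentMetadataError",
    "EmptyResultError",
    "read_taxa_table",
    "write_taxa_table",
    "read_metadata",
    "write_metadata",
    "depth_filter",
    "to_proportions",
    "assemble_pairs",
]

ZYGOSITIES = ("MZ", "DZ")

#: optional per-participant covariates recognised in metadata files
COVARIATE_COLUMNS = (
    "bmi",
    "bacterial_vaginosis",
    "pregnant",
    "nulliparous",
    "hormone_therapy",
    "hormonal_birth_control",
    "ph",
    "current_smoking",
)


class MalformedInputError(ValueError):
    """An input file violates the format contract (e.g. negative count)."""


class DuplicateKeyError(ValueError):
    """A sample, participant or pair identifier is not unique."""


class InconsistentMetadataError(ValueError):
    """Twin metadata contradicts itself (e.g. discordant zygosity in a pair)."""


class EmptyResultError(ValueError):
    """A filter removed every record."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxaCountTable:
    """Sample-by-taxon read counts with per-sample total read counts.

    ``total_reads`` may exceed the row sum of ``counts``: reads that the
    classifier left unassigned still count toward sequencing depth.
    """

    sample_ids: tuple
    taxon_names: tuple
    counts: np.ndarray  # (n_samples, n_taxa) nonnegative integers
    total_reads: np.ndarray  # (n_samples,) nonnegative integers

    def __post_init__(self):
        counts = np.asarray(self.counts)
        totals = np.asarray(self.total_reads)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "total_reads", totals)
        if counts.shape != (len(self.sample_ids), len(self.taxon_names)):
            raise MalformedInputError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_names)} taxa"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateKeyError("duplicate sample ids")
        if len(set(self.taxon_names)) != len(self.taxon_names):
            raise DuplicateKeyError("duplicate taxon names")
        if counts.size and counts.min() < 0:
            i, j = np.unravel_index(int(np.argmin(counts)), counts.shape)
            raise MalformedInputError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_names[j]!r}"
            )
        if totals.size and totals.min() < 0:
            i = int(np.argmin(totals))
            raise MalformedInputError(
                f"negative total_reads for sample {self.sample_ids[i]!r}"
            )
        row_sums = counts.sum(axis=1) if counts.size else np.zeros(len(self.sample_ids))
        over = row_sums > totals
        if np.any(over):
            i = int(np.argmax(over))
            raise MalformedInputError(
                f"assigned reads exceed total_reads for sample {self.sample_ids[i]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, keep: Sequence[int]) -> "TaxaCountTable":
        keep = list(keep)
        return TaxaCountTable(
            sample_ids=tuple(self.sample_ids[i] for i in keep),
            taxon_names=self.taxon_names,
            counts=self.counts[keep],
            total_reads=self.total_reads[keep],
        )


@dataclass(frozen=True)
class TaxaProportionTable:
    """Sample-by-taxon relative abundances in [0, 1]."""

    sample_ids: tuple
    taxon_names: tuple
    proportions: np.ndarray

    ROW_SUM_TOL = 1e-6

    def __post_init__(self):
        props = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", props)
        if props.shape != (len(self.sample_ids), len(self.taxon_names)):
            raise MalformedInputError("proportions shape mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateKeyError("duplicate sample ids")
        if props.size:
            if props.min() < 0 or props.max() > 1:
                i, j = np.unravel_index(int(np.argmax((props < 0) | (props > 1))), props.shape)
                raise MalformedInputError(
                    f"proportion outside [0, 1] at sample {self.sample_ids[i]!r}, "
                    f"taxon {self.taxon_names[j]!r}: {props[i, j]}"
                )
            sums = props.sum(axis=1)
            if sums.max() > 1.0 + self.ROW_SUM_TOL:
                i = int(np.argmax(sums))
                raise MalformedInputError(
                    f"proportions sum to {sums[i]} > 1 for sample {self.sample_ids[i]!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, taxon: str) -> np.ndarray:
        return self.proportions[:, self.taxon_names.index(taxon)]


@dataclass(frozen=True)
class ParticipantRecord:
    """One study participant joined to her twin-pair membership."""

    participant_id: str
    pair_id: str
    zygosity: str  # "MZ" | "DZ"
    ancestry: str  # e.g. "African" | "European"
    age: float | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.zygosity not in ZYGOSITIES:
            raise InconsistentMetadataError(
                f"participant {self.participant_id!r}: zygosity must be MZ or DZ, "
                f"got {self.zygosity!r}"
            )
        if self.age is not None and self.age < 0:
            raise MalformedInputError(
                f"participant {self.participant_id!r}: negative age"
            )


@dataclass(frozen=True)
class TwinPair:
    pair_id: str
    zygosity: str
    ancestry: str
    member_1: str  # participant_id, lexicographically first
    member_2: str


@dataclass(frozen=True)
class TwinCohort:
    """Complete twin pairs retained for analysis."""

    pairs: tuple  # of TwinPair
    singletons_excluded: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_participants(self) -> int:
        return 2 * len(self.pairs)

    def stratum(self, ancestry: str | None = None, zygosity: str | None = None) -> "TwinCohort":
        kept = tuple(
            p
            for p in self.pairs
            if (ancestry is None or p.ancestry == ancestry)
            and (zygosity is None or p.zygosity == zygosity)
        )
        return TwinCohort(pairs=kept, singletons_excluded=0)

    def ancestries(self) -> tuple:
        seen = []
        for p in self.pairs:
            if p.ancestry not in seen:
                seen.append(p.ancestry)
        return tuple(sorted(seen))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_taxa_table(path, dialect: str = "counts"):
    """Read a tab-separated sample-by-taxon table.

    The counts dialect expects a header ``sample_id <tab> total_reads
    <tab> taxon...``; the proportions dialect omits ``total_reads``.
    Parsing is locale-independent (dot decimal separator).
    """
    if dialect not in ("counts", "proportions"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.columns[0] != "sample_id":
        raise MalformedInputError(
            f"first column must be 'sample_id', got {df.columns[0]!r}"
        )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DuplicateKeyError(f"duplicate sample id {dup!r}")
    sample_ids = tuple(df["sample_id"])
    if dialect == "counts":
        if "total_reads" not in df.columns[:2]:
            raise MalformedInputError("counts dialect requires a 'total_reads' column")
        taxa = tuple(df.columns[2:])
        counts = df.iloc[:, 2:].to_numpy()
        if not np.issubdtype(counts.dtype, np.number):
            raise MalformedInputError("non-numeric value in counts matrix")
        return TaxaCountTable(
            sample_ids=sample_ids,
            taxon_names=taxa,
            counts=counts.astype(np.int64),
            total_reads=df["total_reads"].to_numpy(np.int64),
        )
    taxa = tuple(df.columns[1:])
    props = df.iloc[:, 1:].to_numpy(dtype=float)
    return TaxaProportionTable(sample_ids=sample_ids, taxon_names=taxa, proportions=props)


def write_taxa_table(table, path) -> None:
    """Write a table in the dialect matching its type (inverse of read)."""
    if isinstance(table, TaxaCountTable):
        df = pd.DataFrame(table.counts, columns=list(table.taxon_names))
        df.insert(0, "total_reads", table.total_reads)
    else:
        df = pd.DataFrame(table.proportions, columns=list(table.taxon_names))
    df.insert(0, "sample_id", list(table.sample_ids))
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> list:
    """Read a participant metadata CSV into validated records.

    Required columns: ``participant_id,pair_id,zygosity,ancestry``.
    ``age`` and any of the recognised covariate columns are optional;
    empty fields are missing values.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "pair_id": str})
    required = ["participant_id", "pair_id", "zygosity", "ancestry"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedInputError(f"metadata missing columns: {missing}")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise DuplicateKeyError(f"duplicate participant id {dup!r}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        age = d.get("age")
        covs = {
            c: d[c]
            for c in COVARIATE_COLUMNS
            if c in d and not _is_missing(d[c])
        }
        records.append(
            ParticipantRecord(
                participant_id=d["participant_id"],
                pair_id=d["pair_id"],
                zygosity=str(d["zygosity"]).strip(),
                ancestry=str(d["ancestry"]).strip(),
                age=None if _is_missing(age) else float(age),
                covariates=covs,
            )
        )
    return records


def write_metadata(records: Iterable[ParticipantRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "pair_id": r.pair_id,
            "zygosity": r.zygosity,
            "ancestry": r.ancestry,
            "age": r.age,
        }
        row.update(r.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _is_missing(v) -> bool:
    if v is None:
        return True
    try:
        return bool(pd.isna(v))
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def depth_filter(table: TaxaCountTable, min_reads: int = 5000) -> TaxaCountTable:
    """Retain samples with ``total_reads >= min_reads`` (inclusive).

    The read-depth screen controls for detection: shallow samples
    cannot distinguish a truly absent taxon from an unsampled one.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be nonnegative")
    keep = np.flatnonzero(np.asarray(table.total_reads) >= min_reads)
    if keep.size == 0:
        raise EmptyResultError(
            f"depth filter at {min_reads} reads removed all {table.n_samples} samples"
        )
    return table.subset_samples(keep)


def to_proportions(
    table: TaxaCountTable, denominator: str = "total_reads"
) -> TaxaProportionTable:
    """Convert counts to relative abundances.

    ``denominator="total_reads"`` divides by per-sample sequencing depth
    (unassigned reads dilute every taxon); ``"assigned"`` renormalizes
    over the listed taxa only.
    """
    if denominator == "total_reads":
        denom = np.asarray(table.total_reads, dtype=float)
    elif denominator == "assigned":
        denom = table.counts.sum(axis=1).astype(float)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    zero = denom == 0
    if np.any(zero):
        i = int(np.argmax(zero))
        raise ZeroDivisionError(
            f"sample {table.sample_ids[i]!r} has zero {denominator}; "
            "apply depth_filter first"
        )
    return TaxaProportionTable(
        sample_ids=table.sample_ids,
        taxon_names=table.taxon_names,
        proportions=table.counts / denom[:, None],
    )


def assemble_pairs(
    records: Sequence[ParticipantRecord],
    phenotype_samples: Iterable[str] | None = None,
) -> TwinCohort:
    """Join participants into complete twin pairs.

    ``phenotype_samples`` is the set of participant/sample identifiers
    that survived the depth screen; participants without a retained
    sample are dropped, and any pair left with fewer than two members
    contributes its remaining member to ``singletons_excluded``.  Pair
    members are ordered lexicographically by participant id so the
    output is independent of input record order.
    """
    ids = [r.participant_id for r in records]
    if len(set(ids)) != len(ids):
        raise DuplicateKeyError("duplicate participant id in records")

    if phenotype_samples is not None:
        retained = set(phenotype_samples)
        records = [r for r in records if r.participant_id in retained]

    by_pair: dict = {}
    for r in records:
        by_pair.setdefault(r.pair_id, []).append(r)

    pairs = []
    singletons = 0
    for pair_id in sorted(by_pair):
        members = sorted(by_pair[pair_id], key=lambda r: r.participant_id)
        if len(members) > 2:
            raise DuplicateKeyError(
                f"pair {pair_id!r} has {len(members)} members"
            )
        if len(members) == 1:
            singletons += 1
            continue
        a, b = members
        if a.zygosity != b.zygosity:
            raise InconsistentMetadataError(
                f"pair {pair_id!r}: discordant zygosity {a.zygosity}/{b.zygosity}"
            )
        if a.ancestry != b.ancestry:
            raise InconsistentMetadataError(
                f"pair {pair_id!r}: discordant ancestry {a.ancestry}/{b.ancestry}"
            )
        pairs.append(
            TwinPair(
                pair_id=pair_id,
                zygosity=a.zygosity,
                ancestry=a.ancestry,
                member_1=a.participant_id,
                member_2=b.participant_id,
            )
        )
    return TwinCohort(pairs=tuple(pairs), singletons_excluded=singletons)
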