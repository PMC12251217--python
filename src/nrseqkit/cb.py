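"""Counts-Binomial (cB) table and sample-metadata I/O.

The cB table is the compressed read-level mutational summary produced by
NR-seq preprocessing pipelines: one row per unique combination of
(sample, feature assignment(s), mutation counts, mutable-nucleotide counts),
with a column ``n`` counting the identical reads sharing that signature.

Mutation types are two-letter reference->alternative codes ("TC" for T-to-C,
"GA" for G-to-A).  For a type ``t`` the table carries a pair of columns:
``n<ref>`` (e.g. ``nT``) with the number of mutable reference nucleotides in
the read, and ``t`` itself (e.g. ``TC``) with the number of observed
mutations.  Feature columns hold string labels; reads overlapping no feature
carry the sentinel ``__no_feature`` and reads overlapping several features
carry their names joined by "+".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

NO_FEATURE = "__no_feature"

__all__ = [
    "NO_FEATURE",
    "CBTable",
    "CBValidationError",
    "CBFormatError",
    "mutation_columns",
    "read_cb",
    "write_cb",
    "filter_features",
    "read_meta",
    "validate_meta",
]


class CBFormatError(ValueError):
    """A cB / metadata file is missing a required column."""


class CBValidationError(ValueError):
    """A cB table violates a structural invariant (e.g. nM > nN)."""


def mutation_columns(mutation_type: str) -> tuple[str, str]:
    """Return the (nN, nM) column names for a mutation-type code.

    >>> mutation_columns("TC")
    ('nT', 'TC')
    """
    if len(mutation_type) != 2 or not mutation_type.isalpha():
        raise ValueError(f"invalid mutation-type code: {mutation_type!r}")
    return "n" + mutation_type[0], mutation_type


@dataclass
class CBTable:
    """Canonical cB table.

    ``data`` holds one row per unique (sample, features..., counts) key with
    the read multiplicity in column ``n``.  Constructing a CBTable validates
    and canonicalizes (aggregates duplicate keys, summing ``n``).
    """

    data: pd.DataFrame
    mutation_types: tuple[str, ...]
    feature_cols: tuple[str, ...] = ("feature",)

    def __post_init__(self) -> None:
        self.mutation_types = tuple(self.mutation_types)
        self.feature_cols = tuple(self.feature_cols)
        self.data = _canonicalize(
            self.data, self.mutation_types, self.feature_cols
        )

    # -- convenience accessors -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample"].unique())

    @property
    def count_cols(self) -> list[str]:
        cols: list[str] = []
        for t in self.mutation_types:
            cols.extend(mutation_columns(t))
        return cols

    @property
    def key_cols(self) -> list[str]:
        return ["sample", *self.feature_cols, *self.count_cols]

    def total_reads(self) -> int:
        return int(self.data["n"].sum())

    def reads_per_feature(self, feature_col: str | None = None) -> pd.DataFrame:
        """Total read count per (sample, feature)."""
        fc = feature_col or self.feature_cols[0]
        return (
            self.data.groupby(["sample", fc], as_index=False)["n"]
            .sum()
            .rename(columns={fc: "feature"})
        )

    def __eq__(self, other: object) -> bool:  # canonical-form equality
        if not isinstance(other, CBTable):
            return NotImplemented
        if self.mutation_types != other.mutation_types:
            return False
        if self.feature_cols != other.feature_cols:
            return False
        a = self.data.sort_values(self.key_cols).reset_index(drop=True)
        b = other.data.sort_values(self.key_cols).reset_index(drop=True)
        return a.equals(b)


def _canonicalize(
    df: pd.DataFrame,
    mutation_types: Sequence[str],
    feature_cols: Sequence[str],
) -> pd.DataFrame:
    required = ["sample", *feature_cols, "n"]
    for t in mutation_types:
        required.extend(mutation_columns(t))
    for col in required:
        if col not in df.columns:
            raise CBFormatError(f"cB table is missing required column {col!r}")
    df = df.loc[:, required].copy()

    for col in ["sample", *feature_cols]:
        df[col] = df[col].astype(str) if len(df) else df[col].astype(object)

    count_cols = [c for t in mutation_types for c in mutation_columns(t)]
    for col in [*count_cols, "n"]:
        vals = df[col].to_numpy()
        if not np.issubdtype(np.asarray(vals).dtype, np.integer):
            as_float = np.asarray(vals, dtype=float)
            if not np.all(as_float == np.floor(as_float)):
                raise CBValidationError(f"column {col!r} contains non-integer values")
            vals = as_float.astype(np.int64)
        df[col] = np.asarray(vals, dtype=np.int64)

    if len(df) and (df["n"] < 1).any():
        bad = df.index[df["n"] < 1][0]
        raise CBValidationError(f"read count n < 1 at row {bad}")
    for t in mutation_types:
        nn, nm = mutation_columns(t)
        viol = df[nm] > df[nn]
        if viol.any():
            bad = df.index[viol][0]
            raise CBValidationError(
                f"{nm} > {nn} (more mutations than mutable nucleotides) at row {bad}"
            )
        if (df[nm] < 0).any() or (df[nn] < 0).any():
            raise CBValidationError(f"negative counts in columns {nn}/{nm}")

    key = ["sample", *feature_cols, *count_cols]
    out = df.groupby(key, as_index=False, sort=True)["n"].sum()
    return out.reset_index(drop=True)


def read_cb(
    path: str | Path,
    mutation_types: Sequence[str] = ("TC",),
    feature_cols: Sequence[str] | None = None,
) -> CBTable:
    """Read a (optionally gzipped) TSV cB file into canonical form.

    If ``feature_cols`` is None, every column other than ``sample``, ``n``
    and the mutation-count pairs is treated as a feature column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", compression="infer")
    count_cols = {c for t in mutation_types for c in mutation_columns(t)}
    if feature_cols is None:
        feature_cols = [
            c for c in df.columns if c not in count_cols | {"sample", "n"}
        ]
    return CBTable(df, tuple(mutation_types), tuple(feature_cols))


def write_cb(cb: CBTable, path: str | Path) -> Path:
    """Write a canonical cB table as TSV (gzipped iff the suffix is .gz)."""
    path = Path(path)
    cb.data.to_csv(path, sep="\t", index=False, compression="infer")
    return path


def filter_features(
    cb: CBTable,
    feature_col: str | None = None,
    drop_no_feature: bool = False,
    min_reads: int = 0,
) -> CBTable:
    """Subset a cB table by feature.

    Rows whose ``feature_col`` value is the ``__no_feature`` sentinel are
    dropped when ``drop_no_feature`` is set.  Features whose total read count
    in any sample falls below ``min_reads`` are removed entirely.  Counts in
    retained rows are unchanged.
    """
    fc = feature_col or cb.feature_cols[0]
    if fc not in cb.data.columns:
        raise CBFormatError(f"feature column {fc!r} not present in cB table")
    df = cb.data
    if drop_no_feature:
        df = df[df[fc] != NO_FEATURE]
    if min_reads > 0 and len(df):
        per_sample = df.groupby([fc, "sample"])["n"].sum()
        keep = per_sample.groupby(level=0).min() >= min_reads
        df = df[df[fc].map(keep).fillna(False)]
    return replace(cb, data=df.reset_index(drop=True))


# -- sample metadata ----------------------------------------------------------

def read_meta(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV.

    Must contain a ``sample`` column plus label-time columns named ``tl``
    (single label) or ``tl_<type>`` (multi-label, e.g. ``tl_TC``); any other
    columns are free experimental factors.  ``tl == 0`` marks an unlabeled
    control for that label.
    """
    meta = pd.read_csv(Path(path), sep="\t")
    validate_meta(meta)
    return meta


def validate_meta(meta: pd.DataFrame, cb: CBTable | None = None) -> None:
    if "sample" not in meta.columns:
        raise CBFormatError("metadata is missing required column 'sample'")
    if meta["sample"].duplicated().any():
        dup = meta["sample"][meta["sample"].duplicated()].iloc[0]
        raise CBValidationError(f"sample {dup!r} appears more than once in metadata")
    tl_cols = [c for c in meta.columns if c == "tl" or c.startswith("tl_")]
    for c in tl_cols:
        if (meta[c] < 0).any():
            raise CBValidationError(f"negative label time in column {c!r}")
    if cb is not None:
        missing = set(cb.samples) - set(meta["sample"])
        if missing:
            raise CBValidationError(
                f"samples present in cB but absent from metadata: {sorted(missing)}"
            )
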