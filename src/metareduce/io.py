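"""Reading, validating and writing GWAS summary-statistics tables.

A summary-statistics table is one header row plus one marker per line with
an effect size (log-odds or linear beta), its standard error, and usually
alleles, a p-value and a sample size. Files are parsed with pandas (gzip
handled transparently by extension), renamed to canonical columns via a
:class:`~metareduce.dialects.ColumnDialect`, and validated record by
record: retained records always have a non-empty unique marker id and
finite ``beta`` with ``se > 0``. Rows failing validation are dropped,
counted per reason, and logged — never silently discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .dialects import CANONICAL_FIELDS, ColumnDialect, METAL, get_dialect

logger = logging.getLogger("metareduce")

_VALID_BASES = frozenset("ACGT")


class MarkerStats(NamedTuple):
    """One marker's summary estimate from one source table."""

    marker_id: str
    effect_allele: str | None
    other_allele: str | None
    beta: float
    se: float
    pvalue: float | None
    n: float | None


@dataclass
class SumstatsTable:
    """A validated collection of per-marker summary statistics.

    The records live in ``df`` with the canonical columns
    ``marker_id, effect_allele, other_allele, beta, se, pvalue, n``
    (optional fields are NaN where absent). Invariants guaranteed after
    construction through :func:`read_sumstats` or :func:`validate_frame`:
    unique non-empty marker ids, finite beta, ``se > 0``.
    """

    df: pd.DataFrame
    source_label: str = ""
    dialect: ColumnDialect = METAL
    #: per-reason counts of rows rejected during validation
    rejections: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def marker_ids(self) -> pd.Series:
        return self.df["marker_id"]

    @property
    def n_rejected(self) -> int:
        return sum(self.rejections.values())

    def records(self) -> Iterator[MarkerStats]:
        """Iterate records as typed tuples (alleles/pvalue/n None if absent)."""
        for row in self.df.itertuples(index=False):
            yield MarkerStats(
                marker_id=row.marker_id,
                effect_allele=None if pd.isna(row.effect_allele) else row.effect_allele,
                other_allele=None if pd.isna(row.other_allele) else row.other_allele,
                beta=float(row.beta),
                se=float(row.se),
                pvalue=None if pd.isna(row.pvalue) else float(row.pvalue),
                n=None if pd.isna(row.n) else float(row.n),
            )

    def has_alleles(self) -> bool:
        """True when at least one record carries both alleles."""
        return bool(
            (self.df["effect_allele"].notna() & self.df["other_allele"].notna()).any()
        )


def empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker_id": pd.Series(dtype=object),
            "effect_allele": pd.Series(dtype=object),
            "other_allele": pd.Series(dtype=object),
            "beta": pd.Series(dtype=float),
            "se": pd.Series(dtype=float),
            "pvalue": pd.Series(dtype=float),
            "n": pd.Series(dtype=float),
        }
    )


def validate_frame(
    df: pd.DataFrame, source_label: str = ""
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Enforce record invariants on a canonical-column frame.

    Returns the retained rows and a per-reason rejection tally. Reasons:
    ``missing_marker_id``, ``unparseable_beta``, ``unparseable_se``,
    ``nonpositive_se``, ``duplicate_marker_id`` (first occurrence kept).
    Rows in = rows retained + rows rejected, exactly.
    """
    df = df.copy()
    for col in CANONICAL_FIELDS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(CANONICAL_FIELDS)]

    rejections: dict[str, int] = {}

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        count = int(mask.sum())
        if count:
            rejections[reason] = rejections.get(reason, 0) + count
            logger.warning(
                "%s: dropped %d row(s): %s", source_label or "<table>", count, reason
            )
            df = df.loc[~mask]

    ids = df["marker_id"].astype("string")
    drop(ids.isna() | (ids.str.strip() == ""), "missing_marker_id")
    df["marker_id"] = df["marker_id"].astype(str)

    # coerce through Python's strtod: correctly rounded, unlike the fast
    # pandas parser, so printed tables round-trip bit-for-bit
    def _coerce(x):
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan

    for col in ("beta", "se", "pvalue", "n"):
        df[col] = df[col].map(_coerce).astype(float)

    drop(~np.isfinite(df["beta"]), "unparseable_beta")
    drop(~np.isfinite(df["se"]), "unparseable_se")
    drop(df["se"] <= 0, "nonpositive_se")

    # alleles upper-cased; non-ACGT single chars and indels are retained
    # as-is (harmonization decides flippability), blanks become missing
    for col in ("effect_allele", "other_allele"):
        al = df[col].astype("string").str.strip().str.upper()
        al = al.where(al.notna() & (al != ""), other=pd.NA)
        df[col] = al.astype(object).where(al.notna(), np.nan)

    drop(df["marker_id"].duplicated(keep="first"), "duplicate_marker_id")

    return df.reset_index(drop=True), rejections


def read_sumstats(
    path: str | Path, dialect: str | Path | ColumnDialect = METAL
) -> SumstatsTable:
    """Read one summary-statistics file into a validated table.

    ``dialect`` may be a :class:`ColumnDialect`, a built-in name
    (``"metal"``, ``"plink"``) or the path of a YAML/TOML dialect config.
    A mandatory column missing from the header is a hard error; invalid
    rows are dropped with a logged per-reason tally (see
    ``SumstatsTable.rejections``). Gzipped files are decompressed by
    extension.
    """
    path = Path(path)
    dialect = get_dialect(dialect)
    raw = pd.read_csv(
        path,
        sep=dialect.sep if dialect.sep is not None else r"\s+",
        engine="python" if dialect.sep is None else "c",
        dtype=str,
        na_values=list(dialect.na_values),
        keep_default_na=False,
    )
    missing = [c for c in dialect.mandatory_columns() if c not in raw.columns]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s) {missing}; header has {list(raw.columns)}"
        )
    present = {f: c for f, c in dialect.mapping().items() if c in raw.columns}
    df = raw[list(present.values())].rename(
        columns={c: f for f, c in present.items()}
    )
    df, rejections = validate_frame(df, source_label=str(path))
    table = SumstatsTable(
        df=df, source_label=path.name, dialect=dialect, rejections=rejections
    )
    logger.info(
        "%s: %d record(s) retained, %d rejected", path, len(table), table.n_rejected
    )
    return table


def write_sumstats(
    table: SumstatsTable,
    path: str | Path,
    dialect: str | Path | ColumnDialect | None = None,
    extra_columns: tuple[str, ...] = (),
) -> None:
    """Write a table under a dialect's column names (tab-delimited).

    Floats are printed with 17 significant digits so that a write/read
    round trip reproduces every retained value bit-for-bit. ``extra_columns``
    names additional columns of ``table.df`` (e.g. ``z``, ``status``) to
    append verbatim after the dialect columns.
    """
    path = Path(path)
    dialect = get_dialect(dialect) if dialect is not None else table.dialect
    mapping = dialect.mapping()
    out = table.df[list(mapping)].rename(columns=mapping)
    for col in extra_columns:
        out[col] = table.df[col].to_numpy()
    sep = dialect.sep if dialect.sep not in (None, r"\s+") else "\t"
    out.to_csv(
        path,
        sep=sep,
        index=False,
        float_format="%.17g",
        na_rep=dialect.na_values[0] if dialect.na_values else "NA",
    )
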