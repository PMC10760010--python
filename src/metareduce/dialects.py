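"""Column dialects for GWAS summary-statistics tables.

Published summary files share a de-facto shape — one header row, one marker
per line, whitespace- or tab-delimited — but column names differ by tool.
A :class:`ColumnDialect` maps the canonical fields (marker id, effect size,
standard error, alleles, p-value, sample size) onto the names used by a
particular file. Two dialects ship built in (METAL- and PLINK-style); any
other naming can be described in a small YAML or TOML file.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

import yaml

#: Canonical field names used internally, in canonical column order.
CANONICAL_FIELDS = (
    "marker_id",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "n",
)

MANDATORY_FIELDS = ("marker_id", "beta", "se")


@dataclass(frozen=True)
class ColumnDialect:
    """Mapping from canonical summary-statistics fields to file columns.

    Parameters
    ----------
    marker_id, beta, se
        Column names for the mandatory fields.
    effect_allele, other_allele, pvalue, n
        Column names for the optional fields; ``None`` means the file does
        not carry that field.
    sep
        Field separator; ``None`` means any run of whitespace (files are
        always written tab-delimited).
    na_values
        Tokens treated as missing on read; the first is used on write.
    """

    marker_id: str
    beta: str
    se: str
    effect_allele: str | None = None
    other_allele: str | None = None
    pvalue: str | None = None
    n: str | None = None
    sep: str | None = None
    na_values: tuple[str, ...] = ("NA", ".", "")

    def mapping(self) -> dict[str, str]:
        """Canonical-field -> file-column mapping, skipping absent fields."""
        out = {}
        for f in CANONICAL_FIELDS:
            col = getattr(self, f)
            if col is not None:
                out[f] = col
        return out

    def mandatory_columns(self) -> tuple[str, ...]:
        return tuple(getattr(self, f) for f in MANDATORY_FIELDS)


#: METAL output naming (MarkerName/Allele1/Allele2/Effect/StdErr/P-value).
METAL = ColumnDialect(
    marker_id="MarkerName",
    effect_allele="Allele1",
    other_allele="Allele2",
    beta="Effect",
    se="StdErr",
    pvalue="P-value",
    n="Weight",
)

#: PLINK association-output naming (SNP/A1/A2/BETA/SE/P/N).
PLINK = ColumnDialect(
    marker_id="SNP",
    effect_allele="A1",
    other_allele="A2",
    beta="BETA",
    se="SE",
    pvalue="P",
    n="N",
)

BUILTIN_DIALECTS: dict[str, ColumnDialect] = {"metal": METAL, "plink": PLINK}


def get_dialect(name_or_path: str | Path | ColumnDialect) -> ColumnDialect:
    """Resolve a dialect from a built-in name, a config file path, or pass through."""
    if isinstance(name_or_path, ColumnDialect):
        return name_or_path
    key = str(name_or_path).lower()
    if key in BUILTIN_DIALECTS:
        return BUILTIN_DIALECTS[key]
    path = Path(name_or_path)
    if path.exists():
        return load_dialect(path)
    raise KeyError(
        f"unknown dialect {name_or_path!r}: not a built-in "
        f"({', '.join(sorted(BUILTIN_DIALECTS))}) and no such config file"
    )


def load_dialect(path: str | Path) -> ColumnDialect:
    """Load a dialect from a YAML (.yaml/.yml) or TOML (.toml) mapping.

    The file holds a flat mapping of canonical field names to column names,
    plus optional ``sep`` and ``na_values`` entries, e.g.::

        marker_id: variant
        beta: effect_size
        se: stderr
        effect_allele: EA
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        data = tomllib.loads(path.read_text())
    else:
        data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ValueError(f"dialect config {path} must be a mapping")
    known = set(CANONICAL_FIELDS) | {"sep", "na_values"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"dialect config {path}: unknown keys {sorted(unknown)}")
    for f in MANDATORY_FIELDS:
        if f not in data:
            raise ValueError(f"dialect config {path}: missing mandatory key {f!r}")
    if "na_values" in data:
        data["na_values"] = tuple(str(v) for v in data["na_values"])
    return ColumnDialect(**data)
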