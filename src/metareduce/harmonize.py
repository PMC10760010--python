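"""Allele harmonization between a meta-analysis table and a cohort table.

Before the cohort's contribution can be subtracted from the pooled
estimate, both effect sizes must refer to the same effect allele. Markers
are matched on marker id; where both sides carry alleles, the cohort
record is reconciled to the meta orientation by one of four actions:

``exact``
    alleles already agree as written;
``swapped``
    effect/other alleles are reversed — the cohort beta is negated;
``strand_flipped``
    the cohort reported the opposite strand (A<->T, C<->G complement) —
    sign unchanged;
``strand_flipped_swapped``
    complement and reversal — beta negated.

Only the sign of the cohort beta ever changes; |beta| and se are
preserved. Palindromic (A/T, C/G) markers are strand-ambiguous: under the
default ``drop-if-flip`` policy they are kept only when the alleles match
as written, since any other configuration cannot be distinguished from its
strand flip. Indel (multi-base) alleles are never strand-complemented.
Markers that no action reconciles are excluded and counted, never guessed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import MarkerStats, SumstatsTable

logger = logging.getLogger("metareduce")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTIONS = ("exact", "swapped", "strand_flipped", "strand_flipped_swapped")
EXCLUSION_REASONS = (
    "not_in_cohort",
    "not_in_meta",
    "allele_mismatch",
    "ambiguous_palindromic",
    "indel_unresolvable",
)
PALINDROMIC_POLICIES = ("drop-if-flip", "keep", "drop")


class HarmonizedPair(NamedTuple):
    """A meta/cohort record pair matched on marker with alleles aligned."""

    marker_id: str
    meta: MarkerStats
    cohort: MarkerStats
    action: str


@dataclass
class HarmonizationReport:
    """Per-action match counts and per-reason exclusion counts.

    ``matched + excluded`` equals the size of the union of marker ids of
    the two input tables. ``not_in_cohort`` markers are not lost: the
    adjustment passes them through unchanged (a cohort that never measured
    a marker contributed zero weight to it).
    """

    actions: Counter = field(default_factory=Counter)
    exclusions: Counter = field(default_factory=Counter)
    allele_free_matching: bool = False

    @property
    def n_matched(self) -> int:
        return sum(self.actions.values())

    @property
    def n_excluded(self) -> int:
        return sum(self.exclusions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("matched", a, self.actions.get(a, 0)) for a in ACTIONS]
        rows += [("excluded", r, self.exclusions.get(r, 0)) for r in EXCLUSION_REASONS]
        return pd.DataFrame(rows, columns=["category", "label", "count"])


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """A/T and C/G pairs are their own strand complement (ambiguous)."""
    return _COMPLEMENT.get(effect_allele) == other_allele


def _complement_series(alleles: pd.Series, flippable: np.ndarray) -> pd.Series:
    out = alleles.map(_COMPLEMENT)
    return out.where(flippable, other=pd.NA)


def harmonize_tables(
    meta: SumstatsTable,
    cohort: SumstatsTable,
    policy: str = "drop-if-flip",
) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Match markers and align the cohort effect allele to the meta's.

    Parameters
    ----------
    meta, cohort
        Validated summary tables. The meta side keeps its orientation;
        only the cohort beta sign may change.
    policy
        Palindromic-marker policy: ``"drop-if-flip"`` (default — keep only
        when alleles match as written), ``"keep"`` (treat like any marker,
        strand flips disabled), or ``"drop"`` (exclude all palindromic).

    Returns
    -------
    pairs : pandas.DataFrame
        One row per matched marker, meta order, with columns ``marker_id,
        effect_allele, other_allele`` (meta orientation), ``B, SE``
        (meta), ``beta, se`` (cohort, beta sign-resolved), ``pvalue, n``
        (cohort), ``action``.
    report : HarmonizationReport
    """
    if policy not in PALINDROMIC_POLICIES:
        raise ValueError(f"unknown palindromic policy {policy!r}; choose from {PALINDROMIC_POLICIES}")

    report = HarmonizationReport()
    meta_df = meta.df
    cohort_df = cohort.df

    merged = meta_df.merge(
        cohort_df, on="marker_id", how="inner", suffixes=("_meta", "_cohort"), sort=False
    )
    report.exclusions["not_in_cohort"] = len(meta_df) - len(merged)
    report.exclusions["not_in_meta"] = len(cohort_df) - len(merged)

    if len(merged) == 0:
        pairs = pd.DataFrame(
            columns=["marker_id", "effect_allele", "other_allele", "B", "SE",
                     "beta", "se", "pvalue", "n", "action"]
        )
        return pairs, report

    m_ea = merged["effect_allele_meta"].astype("string")
    m_oa = merged["other_allele_meta"].astype("string")
    c_ea = merged["effect_allele_cohort"].astype("string")
    c_oa = merged["other_allele_cohort"].astype("string")

    have_alleles = (m_ea.notna() & m_oa.notna() & c_ea.notna() & c_oa.notna()).to_numpy()

    if not have_alleles.any():
        if meta.has_alleles() or cohort.has_alleles():
            logger.warning(
                "harmonize: no marker carries alleles on both sides; matching by "
                "marker id only — effect-direction mismatches cannot be detected"
            )
        else:
            logger.warning(
                "harmonize: neither table carries allele columns; matching by "
                "marker id only — effect-direction mismatches cannot be detected"
            )
        report.allele_free_matching = True

    is_base = lambda s: s.isin(list(_COMPLEMENT))  # single-char ACGT
    acgt = (is_base(m_ea) & is_base(m_oa) & is_base(c_ea) & is_base(c_oa)).fillna(False).to_numpy()
    flippable = acgt  # indels / non-ACGT codes are never strand-complemented

    c_ea_f = _complement_series(c_ea, flippable)
    c_oa_f = _complement_series(c_oa, flippable)

    exact = ((c_ea == m_ea) & (c_oa == m_oa)).fillna(False).to_numpy()
    swapped = ((c_ea == m_oa) & (c_oa == m_ea)).fillna(False).to_numpy()
    flipped = ((c_ea_f == m_ea) & (c_oa_f == m_oa)).fillna(False).to_numpy()
    flip_swapped = ((c_ea_f == m_oa) & (c_oa_f == m_ea)).fillna(False).to_numpy()

    palindromic = np.zeros(len(merged), dtype=bool)
    pal_mask = acgt.copy()
    if pal_mask.any():
        palindromic[pal_mask] = [
            is_palindromic(a, b) for a, b in zip(m_ea[pal_mask], m_oa[pal_mask])
        ]

    action = np.full(len(merged), "", dtype=object)
    exclude_reason = np.full(len(merged), "", dtype=object)

    # markers without alleles on both sides: match by id, assume aligned
    no_alleles = ~have_alleles
    action[no_alleles] = "exact"
    if no_alleles.any() and have_alleles.any():
        logger.warning(
            "harmonize: %d marker(s) lack alleles on one side; matched by id "
            "only and assumed aligned", int(no_alleles.sum())
        )
        report.allele_free_matching = True

    full = have_alleles
    # precedence: as-written matches before strand flips
    for name, mask in (
        ("exact", exact),
        ("swapped", swapped),
        ("strand_flipped", flipped),
        ("strand_flipped_swapped", flip_swapped),
    ):
        sel = full & mask & (action == "")
        if name.startswith("strand"):
            sel &= flippable
        action[sel] = name

    unresolved = full & (action == "")
    multi = (~acgt) & ((c_ea.str.len() > 1) | (c_oa.str.len() > 1)
                       | (m_ea.str.len() > 1) | (m_oa.str.len() > 1)).fillna(False).to_numpy()
    exclude_reason[unresolved & multi] = "indel_unresolvable"
    exclude_reason[unresolved & ~multi] = "allele_mismatch"

    # palindromic overlay
    if policy == "drop":
        sel = full & palindromic & (exclude_reason == "")
        action[sel] = ""
        exclude_reason[sel] = "ambiguous_palindromic"
    elif policy == "drop-if-flip":
        # keep only if alleles match as written; any swap/flip is
        # indistinguishable from its strand complement
        sel = full & palindromic & (action != "exact") & (exclude_reason == "")
        action[sel] = ""
        exclude_reason[sel] = "ambiguous_palindromic"
    # policy == "keep": as-written precedence already resolved palindromic
    # pairs to exact/swapped (a palindromic pair's strand complement IS its
    # swap, so the flip branches can never be reached for them)

    keep = action != ""
    for name in ACTIONS:
        report.actions[name] = int((action[keep] == name).sum())
    for reason in ("allele_mismatch", "ambiguous_palindromic", "indel_unresolvable"):
        cnt = int((exclude_reason == reason).sum())
        if cnt:
            report.exclusions[reason] += cnt

    negate = np.isin(action, ["swapped", "strand_flipped_swapped"])
    beta = merged["beta_cohort"].to_numpy(dtype=float).copy()
    beta[negate] = -beta[negate]

    pairs = pd.DataFrame(
        {
            "marker_id": merged["marker_id"],
            "effect_allele": merged["effect_allele_meta"],
            "other_allele": merged["other_allele_meta"],
            "B": merged["beta_meta"].to_numpy(),  # dtype preserved (pooled
            "SE": merged["se_meta"].to_numpy(),   # tables carry longdouble)
            "beta": beta,
            "se": merged["se_cohort"].to_numpy(dtype=float),
            "pvalue": merged["pvalue_cohort"].to_numpy(dtype=float),
            "n": merged["n_cohort"].to_numpy(dtype=float),
            "action": action,
        }
    )[keep].reset_index(drop=True)

    excluded_matched = int((~keep).sum())
    if excluded_matched:
        logger.warning(
            "harmonize: excluded %d matched marker(s): %s",
            excluded_matched,
            {k: v for k, v in report.exclusions.items()
             if k in ("allele_mismatch", "ambiguous_palindromic", "indel_unresolvable") and v},
        )
    return pairs, report


def pairs_as_records(pairs: pd.DataFrame) -> list[HarmonizedPair]:
    """Typed per-record view of the pairs frame (convenience for small tables)."""
    out = []
    for row in pairs.itertuples(index=False):
        ea = None if pd.isna(row.effect_allele) else row.effect_allele
        oa = None if pd.isna(row.other_allele) else row.other_allele
        out.append(
            HarmonizedPair(
                marker_id=row.marker_id,
                meta=MarkerStats(row.marker_id, ea, oa, float(row.B), float(row.SE), None, None),
                cohort=MarkerStats(
                    row.marker_id, ea, oa, float(row.beta), float(row.se),
                    None if pd.isna(row.pvalue) else float(row.pvalue),
                    None if pd.isna(row.n) else float(row.n),
                ),
                action=row.action,
            )
        )
    return out
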