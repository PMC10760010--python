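"""Fixed-effect inverse-variance-weighted (IVW) meta-analysis.

Each cohort's estimate is weighted by the inverse of its sampling
variance, w_i = 1/se_i^2, the minimum-variance fixed-effect combination:

    B  = sum_i beta_i * w_i / sum_i w_i
    SE = sqrt(1 / sum_i w_i)

The pooled effect is a convex combination of the inputs (so it lies
between their min and max) and the pooled SE never exceeds the smallest
input SE. Besides serving as a standalone command, ``leave_one_out_meta``
is the brute-force oracle against which the closed-form meta-reductive
adjustment is verified.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import SumstatsTable
from .stats import normal_two_sided_p


class MetaResult(NamedTuple):
    """Pooled estimate for one marker."""

    B: float
    SE: float
    W: float  # total weight sum_i 1/se_i^2, units 1/se^2
    k: int  # number of cohorts contributing


def ivw_pool(estimates: Iterable[tuple[float, float]]) -> MetaResult:
    """Pool (beta, se) estimates with inverse-variance weights.

    Raises ``ValueError`` on an empty collection, a non-positive se, or a
    non-finite input (the offending cohort index is named).
    """
    pairs = list(estimates)
    if not pairs:
        raise ValueError("no estimates to pool")
    betas = np.asarray([p[0] for p in pairs], dtype=float)
    ses = np.asarray([p[1] for p in pairs], dtype=float)
    bad = ~(np.isfinite(betas) & np.isfinite(ses) & (ses > 0))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"cohort {i}: invalid estimate (beta={betas[i]}, se={ses[i]}); "
            "need finite beta and se > 0"
        )
    # extended precision guards the near-cancellations that arise when
    # these pooled values are later algebraically decomposed
    w = 1.0 / ses.astype(np.longdouble) ** 2
    W = w.sum()
    B = (betas.astype(np.longdouble) * w).sum() / W
    return MetaResult(B=float(B), SE=float(np.sqrt(1.0 / W)), W=float(W), k=len(pairs))


def meta_analyze(
    tables: Sequence[SumstatsTable],
    marker_policy: str = "union",
) -> SumstatsTable:
    """Per-marker IVW meta-analysis across cohort tables.

    Tables must already be harmonized to a common effect allele per
    marker. Under the default ``union`` policy every marker seen in any
    cohort is pooled over the cohorts that report it; ``intersection``
    keeps only markers present in all cohorts. The output table carries
    the pooled ``beta``/``se``, a recomputed two-sided normal ``pvalue``,
    the summed sample size ``n`` (where reported), and extra columns ``W``
    (total weight) and ``k`` (cohorts contributing). Marker order follows
    first appearance across the input tables.
    """
    if len(tables) < 2:
        raise ValueError("meta-analysis needs at least 2 tables")
    if marker_policy not in ("union", "intersection"):
        raise ValueError(f"unknown marker policy {marker_policy!r}")

    cat = pd.concat(
        [t.df[["marker_id", "effect_allele", "other_allele", "beta", "se", "n"]]
         for t in tables],
        ignore_index=True,
    )
    # pooled sums accumulated in extended precision: the adjustment later
    # subtracts one cohort's term back out of these, and the residual must
    # survive the cancellation (see the adjust module)
    w = 1.0 / cat["se"].to_numpy(dtype=np.longdouble) ** 2
    bw = cat["beta"].to_numpy(dtype=np.longdouble) * w

    codes, uniques = pd.factorize(cat["marker_id"], sort=False)  # first-appearance order
    W = np.zeros(len(uniques), dtype=np.longdouble)
    BW = np.zeros(len(uniques), dtype=np.longdouble)
    np.add.at(W, codes, w)
    np.add.at(BW, codes, bw)
    k = np.bincount(codes, minlength=len(uniques))
    n_sum = np.zeros(len(uniques))
    np.add.at(n_sum, codes, np.nan_to_num(cat["n"].to_numpy(dtype=float), nan=0.0))

    firsts = cat.drop_duplicates("marker_id")

    B = BW / W
    SE = np.sqrt(1.0 / W)
    df = pd.DataFrame(
        {
            "marker_id": np.asarray(uniques, dtype=object),
            "effect_allele": firsts["effect_allele"].to_numpy(),
            "other_allele": firsts["other_allele"].to_numpy(),
            "beta": B,
            "se": SE,
            "pvalue": normal_two_sided_p(np.asarray(B / SE, dtype=float)),
            "n": n_sum,
            "W": W,
            "k": k,
        }
    )
    if marker_policy == "intersection":
        df = df[df["k"] == len(tables)].reset_index(drop=True)
        if len(df) == 0:
            raise ValueError("no markers shared by all cohorts under intersection policy")
    return SumstatsTable(
        df=df,
        source_label=f"ivw_meta({len(tables)} cohorts, {marker_policy})",
        dialect=tables[0].dialect,
    )


def leave_one_out_meta(
    tables: Sequence[SumstatsTable],
    excluded_index: int,
    marker_policy: str = "union",
) -> SumstatsTable:
    """Brute-force re-pooling with one cohort excluded.

    Recomputes the meta-analysis over the K-1 remaining tables; this is
    the oracle the closed-form adjustment must reproduce. With a single
    remaining cohort the output is that cohort's own (beta, se).
    """
    if len(tables) < 2:
        raise ValueError("nothing left after exclusion: need at least 2 tables")
    if not 0 <= excluded_index < len(tables):
        raise IndexError(f"excluded_index {excluded_index} out of range 0..{len(tables) - 1}")
    rest = [t for i, t in enumerate(tables) if i != excluded_index]
    if len(rest) == 1:
        only = rest[0]
        df = only.df.copy()
        df["W"] = 1.0 / df["se"].to_numpy() ** 2
        df["k"] = 1
        return SumstatsTable(
            df=df, source_label=f"loo(exclude {excluded_index})", dialect=only.dialect
        )
    out = meta_analyze(rest, marker_policy=marker_policy)
    out.source_label = f"loo(exclude {excluded_index})"
    return out
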