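"""The meta-reductive adjustment: remove one cohort from IVW meta statistics.

Given the pooled fixed-effect estimate (B, SE) of an inverse-variance-
weighted meta-analysis and the estimate (beta_n, se_n) of one contributing
cohort, the cohort's contribution can be subtracted in closed form, without
access to any other cohort's data. With w_n = 1/se_n^2 the remaining weight
is (1 - SE^2 * w_n)/SE^2, and

    B_adj  = (B - SE^2 * beta_n * w_n) / (1 - SE^2 * w_n)
    SE_adj = SE / sqrt(1 - SE^2 * w_n)

which is algebraically identical to re-running the meta-analysis with the
cohort left out. Equivalently B_adj = B + SE^2 (B w_n - beta_n w_n) /
(1 - SE^2 w_n): the pooled effect shifted away from the removed cohort's
estimate in proportion to its weight share.

Degeneracies are reported, never glossed over. When the removed cohort
carries (nearly) all the weight, the denominator d = 1 - SE^2 w_n vanishes
and nothing remains to estimate (``dominant_cohort``). When rounding in
published inputs makes w_n exceed the total weight (d < 0), the inputs are
mutually inconsistent (``inconsistent_inputs``); clamping would fabricate
precision. Markers absent from the cohort pass through with the meta
values verbatim — zero contribution means zero adjustment.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

from .harmonize import HarmonizationReport, harmonize_tables
from .io import SumstatsTable
from .stats import normal_two_sided_p

logger = logging.getLogger("metareduce")

STATUSES = (
    "adjusted",
    "passthrough_not_in_cohort",
    "dominant_cohort",
    "inconsistent_inputs",
)

#: default degeneracy threshold on d = 1 - SE^2 * w_n
DEFAULT_EPS = 1e-12


class AdjustmentResult(NamedTuple):
    """Per-marker output of the adjustment.

    ``B_adj``/``SE_adj``/``z_adj``/``p_adj`` are NaN unless
    ``status == "adjusted"`` (or passthrough, where they carry the meta
    values). ``w_n`` is the removed cohort's weight 1/se_n^2 and ``denom``
    the remaining weight fraction d = 1 - SE^2 * w_n.
    """

    marker_id: str
    B_adj: float
    SE_adj: float
    z_adj: float
    p_adj: float
    w_n: float
    denom: float
    status: str


def recompute_significance(B_adj: float, SE_adj: float) -> tuple[float, float]:
    """z and two-sided normal p for an adjusted estimate.

    Input p-values refer to the unadjusted estimate and are never carried
    over; downstream PRS tools get a p consistent with (B_adj, SE_adj).
    """
    if not SE_adj > 0:
        raise ValueError(f"SE_adj must be positive, got {SE_adj}")
    z = B_adj / SE_adj
    return float(z), float(normal_two_sided_p(z))


def adjust_marker(
    B: float,
    SE: float,
    beta_n: float,
    se_n: float,
    eps: float = DEFAULT_EPS,
    marker_id: str = "",
) -> AdjustmentResult:
    """Remove one cohort's (beta_n, se_n) from one marker's pooled (B, SE).

    Status ``adjusted`` requires d = 1 - SE^2/se_n^2 > eps; d in [-eps, eps]
    is ``dominant_cohort`` (the cohort holds essentially the whole weight),
    d < -eps is ``inconsistent_inputs`` (the cohort claims more weight than
    the entire meta-analysis, which exact IVW arithmetic cannot produce).
    """
    vals = np.array([B, SE, beta_n, se_n], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite input for marker {marker_id!r}: "
                         f"B={B}, SE={SE}, beta_n={beta_n}, se_n={se_n}")
    if SE <= 0 or se_n <= 0:
        raise ValueError(f"standard errors must be positive (SE={SE}, se_n={se_n})")

    L = np.longdouble
    w_n = 1.0 / L(se_n) ** 2
    d = 1.0 - L(SE) ** 2 * w_n
    nan = float("nan")
    if d > eps:
        B_adj = (L(B) - L(SE) ** 2 * L(beta_n) * w_n) / d
        SE_adj = L(SE) / np.sqrt(d)
        z, p = recompute_significance(float(B_adj), float(SE_adj))
        return AdjustmentResult(marker_id, float(B_adj), float(SE_adj), z, p,
                                float(w_n), float(d), "adjusted")
    if d >= -eps:
        return AdjustmentResult(marker_id, nan, nan, nan, nan, float(w_n), float(d),
                                "dominant_cohort")
    return AdjustmentResult(marker_id, nan, nan, nan, nan, float(w_n), float(d),
                            "inconsistent_inputs")


def _adjust_arrays(B, SE, beta_n, se_n, eps=DEFAULT_EPS):
    """Vectorized core: returns (B_adj, SE_adj, z, p, w_n, d, status).

    Arithmetic runs at extended precision (longdouble): subtracting the
    cohort's term back out of the pooled sums is a near-cancellation
    whenever the remaining effect is close to zero, and the residual must
    agree with a from-scratch leave-one-out pooling well below 1e-10
    relative. Inputs already at longdouble (a meta table straight from
    the pooling engine) pass through without rounding.
    """
    L = np.longdouble
    B = np.asarray(B, dtype=L)
    SE = np.asarray(SE, dtype=L)
    beta_n = np.asarray(beta_n, dtype=L)
    se_n = np.asarray(se_n, dtype=L)

    w_n = 1.0 / se_n**2
    d = 1.0 - SE**2 * w_n

    status = np.full(B.shape, "adjusted", dtype=object)
    status[d <= eps] = "dominant_cohort"
    status[d < -eps] = "inconsistent_inputs"
    ok = status == "adjusted"

    B_adj = np.full(B.shape, np.nan, dtype=L)
    SE_adj = np.full(B.shape, np.nan, dtype=L)
    with np.errstate(invalid="ignore", divide="ignore"):
        B_adj[ok] = (B[ok] - SE[ok] ** 2 * beta_n[ok] * w_n[ok]) / d[ok]
        SE_adj[ok] = SE[ok] / np.sqrt(d[ok])
    z = np.full(B.shape, np.nan, dtype=L)
    p = np.full(B.shape, np.nan)
    z[ok] = B_adj[ok] / SE_adj[ok]
    p[ok] = normal_two_sided_p(np.asarray(z[ok], dtype=float))
    return B_adj, SE_adj, z, p, w_n, d, status


def adjust_table(
    meta: SumstatsTable,
    cohort: SumstatsTable,
    policy: str = "drop-if-flip",
    eps: float = DEFAULT_EPS,
) -> tuple[SumstatsTable, HarmonizationReport]:
    """Adjust a whole meta-analysis table for one contributing cohort.

    Harmonizes the cohort to the meta effect alleles first (see
    :func:`metareduce.harmonize.harmonize_tables`), then applies
    :func:`adjust_marker` to every matched marker. Output rows follow the
    meta-table order: matched markers carry the adjusted values, meta-only
    markers pass through verbatim with status ``passthrough_not_in_cohort``,
    degenerate markers keep their status with NaN values. Cohort-only
    markers are excluded via the harmonization report.

    The output table's ``beta``/``se``/``pvalue`` columns are the adjusted
    values, with extra columns ``z``, ``w_n``, ``denom`` and ``status``.
    """
    pairs, report = harmonize_tables(meta, cohort, policy=policy)

    out = meta.df[["marker_id", "effect_allele", "other_allele", "beta", "se"]].copy()
    out = out.rename(columns={"beta": "B"})

    matched = pairs.set_index("marker_id")
    idx = out["marker_id"]
    in_cohort = idx.isin(matched.index).to_numpy()

    B = out["B"].to_numpy()  # dtype preserved: longdouble straight from pooling
    SE = out["se"].to_numpy()
    beta_n = np.full(len(out), np.nan)
    se_n = np.full(len(out), np.nan)
    aligned = matched.reindex(idx[in_cohort])
    beta_n[in_cohort] = aligned["beta"].to_numpy(dtype=float)
    se_n[in_cohort] = aligned["se"].to_numpy(dtype=float)

    B_adj = B.astype(np.longdouble)
    SE_adj = SE.astype(np.longdouble)
    z = B_adj / SE_adj
    status = np.full(len(out), "passthrough_not_in_cohort", dtype=object)
    w_n = np.full(len(out), np.nan)
    d = np.full(len(out), np.nan)

    if in_cohort.any():
        (B_a, SE_a, z_a, _p, w_a, d_a, st) = _adjust_arrays(
            B[in_cohort], SE[in_cohort], beta_n[in_cohort], se_n[in_cohort], eps=eps
        )
        B_adj[in_cohort] = B_a
        SE_adj[in_cohort] = SE_a
        z[in_cohort] = z_a
        status[in_cohort] = st
        w_n[in_cohort] = w_a
        d[in_cohort] = d_a

    z64 = np.asarray(z, dtype=float)
    with np.errstate(invalid="ignore"):
        pvalue = np.where(np.isnan(z64), np.nan,
                          normal_two_sided_p(np.nan_to_num(z64)))

    result = pd.DataFrame(
        {
            "marker_id": out["marker_id"],
            "effect_allele": out["effect_allele"],
            "other_allele": out["other_allele"],
            "beta": B_adj,
            "se": SE_adj,
            "pvalue": pvalue,
            "n": np.nan,
            "z": z,
            "w_n": w_n,
            "denom": d,
            "status": status,
        }
    )

    counts = pd.Series(status).value_counts().to_dict()
    logger.info("adjust_table: per-status counts %s", counts)
    degenerate = {k: v for k, v in counts.items()
                  if k in ("dominant_cohort", "inconsistent_inputs")}
    if degenerate:
        logger.warning("adjust_table: degenerate markers not adjusted: %s", degenerate)

    table = SumstatsTable(
        df=result,
        source_label=f"mra_adjust({meta.source_label} - {cohort.source_label})",
        dialect=meta.dialect,
    )
    return table, report
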