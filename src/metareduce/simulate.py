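"""Seeded generator of synthetic multi-cohort GWAS summary statistics.

Emulates the situation the adjustment is built for: K independent cohorts
measuring the same M markers, each publishing per-marker (beta, se), later
pooled by fixed-effect IVW meta-analysis. Defaults mirror a four-study,
100,000-marker validation with unequal cohort sizes.

Generative model, marker j and cohort i:

    p_j        ~ Uniform(maf_low, maf_high)            effect-allele frequency
    beta_true,j = 0  with prob 1 - causal_fraction,
                  else ~ Normal(0, effect_sd^2)         sparse polygenic effects
    se_ij      = 1 / sqrt(2 p_j (1 - p_j) n_i)          quantitative-trait,
                                                        unit-variance approx.
    beta_hat_ij ~ Normal(beta_true,j, se_ij^2)

All cohorts share marker ids and effect alleles (pre-aligned); alleles are
drawn from the non-palindromic ACGT pairs by default, as strand-ambiguous
markers are conventionally excluded from PRS pipelines. Cohorts are
independent (no overlapping individuals), matching the fixed-effect IVW
assumption. One global seed drives everything; per-cohort substreams are
spawned deterministically from it, so identical config gives bit-identical
output.

``perturb_alleles`` deliberately mis-orients a table (allele swaps with
negated beta, strand complements) to exercise harmonization, recording the
ground-truth action per marker so recovery can be verified exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dialects import METAL
from .harmonize import _COMPLEMENT
from .io import SumstatsTable

#: ordered non-palindromic ACGT pairs (effect, other)
_NONPALINDROMIC_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and _COMPLEMENT[a] != b
]
_ALL_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for the synthetic multi-cohort study.

    Defaults are the validation conditions: 4 cohorts of unequal size,
    100,000 markers, 1% causal markers with effect s.d. 0.02, effect-allele
    frequencies uniform on (0.01, 0.5).
    """

    K: int = 4
    M: int = 100_000
    causal_fraction: float = 0.01
    effect_sd: float = 0.02
    n_per_cohort: tuple[int, ...] = (20_000, 8_000, 45_000, 6_000)
    maf_range: tuple[float, float] = (0.01, 0.5)
    seed: int = 0
    allow_palindromic: bool = False

    def validate(self) -> None:
        if self.K < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise ValueError(f"causal_fraction must be in [0, 1], got {self.causal_fraction}")
        if not self.effect_sd > 0:
            raise ValueError(f"effect_sd must be positive, got {self.effect_sd}")
        if len(self.n_per_cohort) != self.K:
            raise ValueError(
                f"n_per_cohort has {len(self.n_per_cohort)} entries for K={self.K} cohorts"
            )
        if any(n <= 0 for n in self.n_per_cohort):
            raise ValueError(f"n_per_cohort entries must be positive, got {self.n_per_cohort}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")


@dataclass
class GroundTruth:
    """Per-marker generative truth: effect, allele frequency, causal flag."""

    df: pd.DataFrame  # marker_id, effect_allele, other_allele, maf, beta_true, causal

    def __len__(self) -> int:
        return len(self.df)


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[list[SumstatsTable], GroundTruth]:
    """Draw K pre-aligned cohort summary tables plus the generating truth."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    marker_ss, *cohort_ss = root.spawn(1 + config.K)
    rng = np.random.default_rng(marker_ss)

    M, K = config.M, config.K
    marker_id = np.array([f"rs{j + 1}" for j in range(M)], dtype=object)
    pairs = _ALL_PAIRS if config.allow_palindromic else _NONPALINDROMIC_PAIRS
    pair_idx = rng.integers(0, len(pairs), size=M)
    ea = np.array([pairs[i][0] for i in pair_idx], dtype=object)
    oa = np.array([pairs[i][1] for i in pair_idx], dtype=object)

    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=M)
    causal = rng.random(M) < config.causal_fraction
    beta_true = np.zeros(M)
    beta_true[causal] = rng.normal(0.0, config.effect_sd, size=int(causal.sum()))

    truth = GroundTruth(
        df=pd.DataFrame(
            {
                "marker_id": marker_id,
                "effect_allele": ea,
                "other_allele": oa,
                "maf": maf,
                "beta_true": beta_true,
                "causal": causal,
            }
        )
    )

    tables = []
    for i, (n_i, ss) in enumerate(zip(config.n_per_cohort, cohort_ss)):
        crng = np.random.default_rng(ss)
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_i)
        beta_hat = crng.normal(beta_true, se)
        df = pd.DataFrame(
            {
                "marker_id": marker_id,
                "effect_allele": ea,
                "other_allele": oa,
                "beta": beta_hat,
                "se": se,
                "pvalue": np.nan,
                "n": float(n_i),
            }
        )
        tables.append(
            SumstatsTable(df=df, source_label=f"cohort_{i + 1}", dialect=METAL)
        )
    return tables, truth


def perturb_alleles(
    table: SumstatsTable,
    fraction_swapped: float = 0.0,
    fraction_strand_flipped: float = 0.0,
    seed: int = 0,
) -> tuple[SumstatsTable, pd.DataFrame]:
    """Mis-orient a seeded random subset of a table's markers.

    Swapping reverses effect/other alleles and negates beta (the estimate
    now refers to the other allele); strand flipping complements both
    alleles and leaves beta untouched. The two subsets are drawn
    independently, so a marker can receive both. Returns the perturbed
    table and a per-marker record (``swapped``, ``strand_flipped``
    booleans) so harmonization can be verified against ground truth.
    """
    for name, frac in (("fraction_swapped", fraction_swapped),
                       ("fraction_strand_flipped", fraction_strand_flipped)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")

    rng = np.random.default_rng(seed)
    df = table.df.copy()
    m = len(df)
    swap = rng.random(m) < fraction_swapped
    flip = rng.random(m) < fraction_strand_flipped

    ea = df["effect_allele"].to_numpy(dtype=object).copy()
    oa = df["other_allele"].to_numpy(dtype=object).copy()
    beta = df["beta"].to_numpy(dtype=float).copy()

    ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
    beta[swap] = -beta[swap]

    comp = np.vectorize(lambda a: _COMPLEMENT.get(a, a), otypes=[object])
    if flip.any():
        ea[flip] = comp(ea[flip])
        oa[flip] = comp(oa[flip])

    df["effect_allele"] = ea
    df["other_allele"] = oa
    df["beta"] = beta

    record = pd.DataFrame(
        {"marker_id": df["marker_id"], "swapped": swap, "strand_flipped": flip}
    )
    out = SumstatsTable(
        df=df, source_label=f"{table.source_label}+perturbed", dialect=table.dialect
    )
    return out, record
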