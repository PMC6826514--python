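"""Expression coordination: replicate-level Pearson correlation of gene
pairs, redundancy-aware significance, classification and reversal detection.

Two genes are *coordinated* in a condition when their (log2) expression
levels co-vary across the biological replicates of that condition.  The
significance of the Pearson coefficient rho is judged by a two-tailed t-test
whose degrees of freedom grow with probe redundancy:

    df = n_replicates * R - 2

with R the number of spots probing each of the two transcripts (the minimum
of the two redundancies by default when they differ).  With 4 replicates and
single spots, df = 2 and |rho| must exceed 0.95 for p < 0.05; with two spots
each, df = 6 and the threshold drops to 0.71 — redundant probing buys
statistical power.

Each pair is classified as POS (significantly positive), NEG (significantly
negative), IND (near-zero |rho|, operationalized as |rho| below a
configurable independence cutoff) or UNCLASSIFIED (everything in between,
including undefined correlations from constant profiles).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "POS",
    "NEG",
    "IND",
    "UNCLASSIFIED",
    "ClassificationConfig",
    "CorrelationRecord",
    "pair_key",
    "pearson_rho",
    "pair_df",
    "critical_rho",
    "rho_p_value",
    "classify_pair",
    "enumerate_pairs",
    "pair_count",
    "replicate_profiles",
    "correlate_pairs",
    "coordination_profile",
    "detect_reversals",
    "records_to_frame",
]

POS = "POS"
NEG = "NEG"
IND = "IND"
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class ClassificationConfig:
    """Significance level, independence cutoff and redundancy handling.

    ``independence_threshold`` operationalizes "significantly uncorrelated"
    as |rho| below the cutoff (default 0.05).  ``unequal_redundancy_rule`` is
    ``"min"`` (df from the smaller redundancy; conservative default) or
    ``"all_pairings"`` (df from all R_i x R_j spot pairings; overstates df).
    ``use_log2`` controls whether profiles are log2-transformed upstream.
    """

    alpha: float = 0.05
    independence_threshold: float = 0.05
    use_log2: bool = True
    unequal_redundancy_rule: str = "min"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.independence_threshold < 1:
            raise ValueError("independence_threshold must be in [0, 1)")
        if self.unequal_redundancy_rule not in ("min", "all_pairings"):
            raise ValueError(f"unknown rule {self.unequal_redundancy_rule!r}")


@dataclass
class CorrelationRecord:
    """One gene pair in one condition: rho, its df/p, and the class."""

    gene_a: str
    gene_b: str
    condition: str
    rho: float
    df: int
    p_value: float
    classification: str

    @property
    def pair(self) -> tuple[str, str]:
        return pair_key(self.gene_a, self.gene_b)


def pair_key(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Canonical unordered pair key (lexicographic)."""
    if gene_a == gene_b:
        raise ValueError(f"self-pair {gene_a!r}")
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


def pearson_rho(x, y) -> float:
    """Pearson product-moment correlation of two equal-length profiles.

    Returns NaN (undefined) when either profile is constant; the caller maps
    that to UNCLASSIFIED.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def pair_df(
    redundancy_a: int,
    redundancy_b: int,
    replicates: int = 4,
    rule: str = "min",
) -> int:
    """Degrees of freedom for a pair's correlation test.

    Equal redundancies R give df = replicates * R - 2; unequal redundancies
    follow ``rule`` ("min" or "all_pairings").
    """
    if redundancy_a < 1 or redundancy_b < 1:
        raise ValueError("redundancy must be >= 1")
    if rule == "min":
        r_eff = min(redundancy_a, redundancy_b)
        return replicates * r_eff - 2
    if rule == "all_pairings":
        return replicates * redundancy_a * redundancy_b - 2
    raise ValueError(f"unknown rule {rule!r}")


def critical_rho(df: int, alpha: float = 0.05) -> float:
    """Minimal |rho| significant at ``alpha`` for ``df`` degrees of freedom.

    Inverts the two-tailed t-test: t* = t_{1-alpha/2}(df), threshold =
    t* / sqrt(t*^2 + df).  Strictly decreasing in df, increasing as alpha
    shrinks.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t_star = stats.t.ppf(1 - alpha / 2, df)
    return float(t_star / math.sqrt(t_star**2 + df))


def rho_p_value(rho: float, df: int) -> float:
    """Two-tailed p-value of a Pearson coefficient at the given df."""
    if math.isnan(rho):
        return float("nan")
    r = min(max(rho, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * math.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df))


def classify_pair(rho: float, df: int, config: ClassificationConfig | None = None) -> str:
    """POS / NEG / IND / UNCLASSIFIED for one correlation estimate."""
    config = config or ClassificationConfig()
    if rho is None or (isinstance(rho, float) and math.isnan(rho)):
        return UNCLASSIFIED
    thr = critical_rho(df, config.alpha)
    if rho > thr:
        return POS
    if rho < -thr:
        return NEG
    if abs(rho) < config.independence_threshold:
        return IND
    return UNCLASSIFIED


def pair_count(n_a: int, n_b: int | None = None) -> int:
    """Number of distinct pairs: C(n, 2) within a set, n x m across sets."""
    if n_b is None:
        return n_a * (n_a - 1) // 2
    return n_a * n_b


def enumerate_pairs(set_a, set_b=None):
    """(iterator over pairs, exact count) within a set or across two sets.

    Within a set: unordered pairs, self-pairs excluded, each counted once.
    Across sets: all A x B ordered pairs; overlapping membership is refused
    because a symbol in both sets would create ambiguous self-pairs.
    """
    genes_a = list(set_a)
    if not genes_a:
        raise ValueError("empty gene set")
    if set_b is None:
        return itertools.combinations(genes_a, 2), pair_count(len(genes_a))
    genes_b = list(set_b)
    if not genes_b:
        raise ValueError("empty gene set")
    overlap = set(genes_a) & set(genes_b)
    if overlap:
        raise ValueError(f"gene sets overlap: {sorted(overlap)[:5]}")
    return itertools.product(genes_a, genes_b), pair_count(len(genes_a), len(genes_b))


def replicate_profiles(
    normalized: pd.DataFrame, condition: str, use_log2: bool = True
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene, per-replicate expression profiles for one condition.

    Each gene's profile is the mean over its redundant spots of the
    normalized value in each replicate (optionally log2-transformed), the
    quantity whose co-variation across replicates defines coordination.
    Returns (genes x replicates frame, per-gene redundancy map).
    """
    sub = normalized[normalized["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no data for condition {condition!r}")
    prof = sub.pivot_table(
        index="transcript_id", columns="replicate", values="value", aggfunc="mean"
    )
    if use_log2:
        prof = np.log2(prof)
    redundancy = (
        sub.groupby("transcript_id")["spot_id"].nunique().astype(int).to_dict()
    )
    return prof, redundancy


def correlate_pairs(
    profiles: pd.DataFrame,
    redundancy: dict[str, int],
    pairs,
    condition: str,
    config: ClassificationConfig | None = None,
    replicates: int | None = None,
) -> list[CorrelationRecord]:
    """Correlation records for every requested pair (no silent drops).

    Pairs with a gene missing from the profiles, or with a constant profile,
    yield UNCLASSIFIED records with NaN rho.
    """
    config = config or ClassificationConfig()
    n_rep = replicates or profiles.shape[1]
    records = []
    values = {g: profiles.loc[g].to_numpy() for g in profiles.index}
    for a, b in pairs:
        if a not in values or b not in values:
            rho, df = float("nan"), 1
        else:
            rho = pearson_rho(values[a], values[b])
            df = pair_df(
                redundancy.get(a, 1),
                redundancy.get(b, 1),
                replicates=n_rep,
                rule=config.unequal_redundancy_rule,
            )
        records.append(
            CorrelationRecord(
                gene_a=a,
                gene_b=b,
                condition=condition,
                rho=rho,
                df=df,
                p_value=rho_p_value(rho, df),
                classification=classify_pair(rho, df, config),
            )
        )
    return records


def coordination_profile(records: list[CorrelationRecord]) -> dict[str, float]:
    """Percentages of POS / NEG / IND pairs among all records.

    The three percentages need not sum to 100; the remainder is the
    UNCLASSIFIED fraction (pairs meeting no statistical criterion).
    """
    n = len(records)
    if n == 0:
        return {POS: 0.0, NEG: 0.0, IND: 0.0}
    counts = {POS: 0, NEG: 0, IND: 0}
    for r in records:
        if r.classification in counts:
            counts[r.classification] += 1
    return {k: 100.0 * v / n for k, v in counts.items()}


def detect_reversals(
    records_a: list[CorrelationRecord], records_b: list[CorrelationRecord]
) -> pd.DataFrame:
    """Pairs significantly positive in one condition and significantly
    negative in the other, with both rho values attached.

    Only POS<->NEG flips count: a pair significant in one condition but
    IND/UNCLASSIFIED in the other is not a reversal.
    """
    by_pair_b = {r.pair: r for r in records_b}
    rows = []
    for ra in records_a:
        rb = by_pair_b.get(ra.pair)
        if rb is None:
            continue
        flip = (ra.classification == POS and rb.classification == NEG) or (
            ra.classification == NEG and rb.classification == POS
        )
        if flip:
            rows.append(
                {
                    "gene_a": ra.pair[0],
                    "gene_b": ra.pair[1],
                    "condition_a": ra.condition,
                    "condition_b": rb.condition,
                    "rho_a": ra.rho,
                    "rho_b": rb.rho,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "condition_a", "condition_b", "rho_a", "rho_b"]
    ).sort_values(["gene_a", "gene_b"], ignore_index=True)


def records_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    """Edge-list view (gene_a, gene_b, condition, rho, df, p_value, class)."""
    return pd.DataFrame(
        [
            {
                "gene_a": r.gene_a,
                "gene_b": r.gene_b,
                "condition": r.condition,
                "rho": r.rho,
                "df": r.df,
                "p_value": r.p_value,
                "classification": r.classification,
            }
            for r in records
        ]
    )
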