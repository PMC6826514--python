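"""Per-transcript expression summaries, the REV variability statistic,
regulation calls and group-level comparisons.

The central quantity is the Relative Expression Variability (REV): a
redundancy-corrected, chi-square mid-interval estimate of the pooled
coefficient of variation of a transcript's expression across biological
replicates,

    REV_i = C(R_i) * 100 * sqrt( (1/R_i) * sum_k (s_ik / mu_ik)^2 )

where spot k = 1..R_i probes transcript i, mu_ik and s_ik are the mean and
sample SD of that spot's normalized expression over the replicates, and
C(R) is the mid chi-square interval factor for 4R - 1 degrees of freedom at
significance level epsilon.  Pooling over the R redundant spots and shrinking
C(R) with R gives more credit to transcripts probed by many spots.  Low REV
marks transcripts whose abundance is tightly controlled by homeostatic
mechanisms; high REV marks loosely controlled ones.

The exact convention by which the two chi-square quantiles enter C(R) is
configurable (see :class:`REVConfig`): standard conventions do not reproduce
the endpoint values quoted in some of the methodology literature, so the
chosen convention is carried in output metadata rather than silently
absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REVConfig",
    "TranscriptSummary",
    "FabricSummary",
    "RegulationCall",
    "summarize_transcript",
    "summarize_all",
    "coefficient_of_variation",
    "redundancy_correction",
    "rev",
    "regulation_call",
    "group_summary",
    "compare_rev_distributions",
    "fabric_summary",
    "summaries_to_frame",
]

#: supported chi-square quantile conventions for the redundancy correction
QUANTILE_CONVENTIONS = ("sigma_ci", "variance_ci")


@dataclass(frozen=True)
class REVConfig:
    """Parameters of the REV estimator.

    epsilon
        Significance level of the chi-square interval (default 0.05, i.e.
        quantiles at cumulative 0.025 and 0.975).
    replicates_per_spot
        Biological replicates per spot; degrees of freedom are
        ``replicates_per_spot * R - 1``.
    quantile_convention
        ``"sigma_ci"`` (default): C = (sqrt(df/chi2_hi) + sqrt(df/chi2_lo))/2,
        the midpoint of the confidence interval for a standard deviation.
        ``"variance_ci"``: same without square roots (variance interval).
        Both are positive and monotone non-increasing in R.
    """

    epsilon: float = 0.05
    replicates_per_spot: int = 4
    quantile_convention: str = "sigma_ci"

    def __post_init__(self):
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must be in (0, 1)")
        if self.replicates_per_spot < 2:
            raise ValueError("need at least 2 replicates per spot")
        if self.quantile_convention not in QUANTILE_CONVENTIONS:
            raise ValueError(f"unknown quantile convention {self.quantile_convention!r}")


@dataclass
class TranscriptSummary:
    """Per-transcript, per-condition summary over redundant spots.

    ``spot_means[k]`` / ``spot_sds[k]`` are the mean and sample SD (n-1
    denominator) of spot k's normalized expression over the biological
    replicates; ``redundancy`` is the number of spots R; ``combined_mean``
    the mean of spot means.  ``replicate_values`` (R x n) retains the
    underlying values for downstream tests; ``rev`` is filled by
    :func:`rev`.
    """

    transcript_id: str
    condition: str
    spot_means: np.ndarray
    spot_sds: np.ndarray
    redundancy: int
    combined_mean: float
    rev: float | None = None
    replicate_values: np.ndarray | None = None

    def __post_init__(self):
        self.spot_means = np.asarray(self.spot_means, dtype=float)
        self.spot_sds = np.asarray(self.spot_sds, dtype=float)
        if len(self.spot_means) != len(self.spot_sds):
            raise ValueError("spot_means and spot_sds must have equal length")
        if len(self.spot_means) != self.redundancy:
            raise ValueError("redundancy must equal the number of spots")


@dataclass(frozen=True)
class FabricSummary:
    """Condition-wide means over all N quantified unigenes (used by PWR)."""

    condition: str
    n_unigenes: int
    mean_expression: float
    mean_rev: float


@dataclass
class RegulationCall:
    """Surrogate regulation call: fold change, Welch t-test p-value and a
    Bonferroni correction restricted to the transcript's redundancy group.

    ``fold_change`` uses the signed convention: ratios below 1 are reported
    as the negative reciprocal (2-fold down = -2.0).
    """

    transcript_id: str
    fold_change: float
    p_value: float
    corrected_p: float
    status: str  # UP | DOWN | NC
    method: str = "surrogate: Welch t on pooled spot-replicate values, redundancy-group Bonferroni"


def summarize_transcript(values: pd.DataFrame, condition: str) -> TranscriptSummary:
    """Summarize one transcript in one condition from normalized spot values.

    ``values`` holds columns (spot_id, replicate, value) for a single
    transcript; every spot needs >= 2 replicate values.
    """
    tid = str(values["transcript_id"].iloc[0]) if "transcript_id" in values else ""
    counts = values.groupby("spot_id")["value"].size()
    if (counts < 2).any():
        raise ValueError(
            f"transcript {tid!r}: spot(s) with fewer than 2 replicate values"
        )
    per_spot = values.groupby("spot_id")["value"]
    means = per_spot.mean().to_numpy()
    sds = per_spot.std(ddof=1).to_numpy()
    wide = values.pivot_table(index="spot_id", columns="replicate", values="value")
    return TranscriptSummary(
        transcript_id=tid,
        condition=condition,
        spot_means=means,
        spot_sds=sds,
        redundancy=len(means),
        combined_mean=float(means.mean()),
        replicate_values=wide.to_numpy(dtype=float),
    )


def summarize_all(
    normalized: pd.DataFrame, config: REVConfig | None = None
) -> dict[tuple[str, str], TranscriptSummary]:
    """Summaries for every (transcript, condition) in a normalized table,
    with REV filled in when a config is given."""
    config = config or REVConfig()
    out: dict[tuple[str, str], TranscriptSummary] = {}
    for (cond, tid), sub in normalized.groupby(["condition", "transcript_id"], sort=False):
        s = summarize_transcript(sub, condition=cond)
        s.transcript_id = str(tid)
        s.rev = rev(s, config)
        out[(str(tid), str(cond))] = s
    return out


def coefficient_of_variation(values) -> float:
    """Sample coefficient of variation, in percent (n-1 denominator SD)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


def redundancy_correction(redundancy: int, config: REVConfig | None = None) -> float:
    """Mid chi-square interval factor C(R) for 4R - 1 degrees of freedom.

    Monotone non-increasing in R under every supported convention; tends to
    1 as R grows (the pooled CV then needs no interval widening).
    """
    config = config or REVConfig()
    if redundancy < 1:
        raise ValueError("redundancy must be >= 1")
    df = config.replicates_per_spot * redundancy - 1
    lo = stats.chi2.ppf(config.epsilon / 2, df)
    hi = stats.chi2.ppf(1 - config.epsilon / 2, df)
    if config.quantile_convention == "sigma_ci":
        return float(0.5 * (np.sqrt(df / hi) + np.sqrt(df / lo)))
    return float(0.5 * (df / hi + df / lo))


def rev(summary: TranscriptSummary, config: REVConfig | None = None) -> float:
    """REV of a transcript: redundancy correction x pooled CV, in percent.

    Invariant under global rescaling of the transcript's values; zero iff
    every spot SD is zero; reduces to C(1) x CV for a single spot.
    """
    config = config or REVConfig()
    mu = summary.spot_means
    if np.any(mu == 0):
        raise ValueError("REV undefined when a spot mean is zero")
    pooled = np.sqrt(np.mean((summary.spot_sds / mu) ** 2))
    return float(redundancy_correction(summary.redundancy, config) * 100.0 * pooled)


def regulation_call(
    summary_cond: TranscriptSummary,
    summary_ctrl: TranscriptSummary,
    fold_threshold: float = 1.5,
    alpha: float = 0.05,
) -> RegulationCall:
    """Surrogate regulation call of a transcript versus a reference condition.

    Fold change is the ratio of combined means (negative-reciprocal
    convention below 1).  The p-value comes from a heteroscedastic (Welch)
    two-sample t-test on the pooled spot x replicate values, Bonferroni
    corrected by the redundancy R only (the same transcript is tested once
    per redundant spot, distinct transcripts are not treated as repeats).
    """
    if summary_cond.transcript_id != summary_ctrl.transcript_id:
        raise ValueError("summaries refer to different transcripts")
    if summary_cond.replicate_values is None or summary_ctrl.replicate_values is None:
        raise ValueError("summaries lack replicate-level values")
    ratio = summary_cond.combined_mean / summary_ctrl.combined_mean
    fold = ratio if ratio >= 1 else -1.0 / ratio
    res = stats.ttest_ind(
        summary_cond.replicate_values.ravel(),
        summary_ctrl.replicate_values.ravel(),
        equal_var=False,
    )
    p = float(res.pvalue)
    r_group = max(summary_cond.redundancy, summary_ctrl.redundancy)
    corrected = min(1.0, r_group * p)
    if abs(fold) >= fold_threshold and corrected < alpha:
        status = "UP" if fold > 0 else "DOWN"
    else:
        status = "NC"
    return RegulationCall(
        transcript_id=summary_cond.transcript_id,
        fold_change=float(fold),
        p_value=p,
        corrected_p=float(corrected),
        status=status,
    )


def group_summary(
    summaries: list[TranscriptSummary],
    group: str = "",
    reference_median: float | None = None,
) -> tuple[float, float]:
    """(average REV, median combined expression) of a gene set in one condition.

    When ``reference_median`` (the unstimulated-condition median) is given,
    the median expression is reported relative to it.
    """
    if not summaries:
        raise ValueError(f"empty group {group!r}")
    conds = {s.condition for s in summaries}
    if len(conds) > 1:
        raise ValueError("group_summary mixes conditions")
    revs = [s.rev for s in summaries]
    if any(r is None for r in revs):
        raise ValueError("REV not computed for all summaries")
    med = float(np.median([s.combined_mean for s in summaries]))
    if reference_median is not None:
        med /= reference_median
    return float(np.mean(revs)), med


def compare_rev_distributions(revs_a, revs_b) -> float:
    """Two-tailed heteroscedastic (Welch) t-test p-value for equality of the
    mean REV of two distributions."""
    a = np.asarray(revs_a, dtype=float)
    b = np.asarray(revs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 REV values per group")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def fabric_summary(summaries: list[TranscriptSummary], condition: str) -> FabricSummary:
    """Condition-wide arithmetic means of expression and REV over all N
    quantified unigenes — the denominators of the PWR score."""
    subset = [s for s in summaries if s.condition == condition]
    if not subset:
        raise ValueError(f"no summaries for condition {condition!r}")
    if any(s.rev is None for s in subset):
        raise ValueError("REV not computed for all summaries")
    return FabricSummary(
        condition=condition,
        n_unigenes=len(subset),
        mean_expression=float(np.mean([s.combined_mean for s in subset])),
        mean_rev=float(np.mean([s.rev for s in subset])),
    )


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Tabular view (transcript_id, condition, redundancy, combined_mean, rev)."""
    items = summaries.values() if isinstance(summaries, dict) else summaries
    return pd.DataFrame(
        [
            {
                "transcript_id": s.transcript_id,
                "condition": s.condition,
                "redundancy": s.redundancy,
                "combined_mean": s.combined_mean,
                "rev": s.rev,
            }
            for s in items
        ]
    )
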