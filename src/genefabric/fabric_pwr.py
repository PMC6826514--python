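"""Pair-wise relevance (PWR) scoring and landscape extraction.

PWR ranks gene pairs by how prominent they are within a condition's
transcriptome ("genomic fabric"): a pair scores highly when both genes are
highly expressed relative to the fabric average, strongly coordinated, and
tightly controlled (low REV relative to the fabric average):

    PWR_ij = (mu_i * mu_j / mu_bar^2) * rho_ij^2 * (REV_bar^2 / (REV_i * REV_j))

where mu_bar and REV_bar are the arithmetic means over all N quantified
unigenes of the condition.  The score is symmetric in the two genes and
invariant under global rescaling of all expression levels or of all REVs, so
it carries no directionality and no units — only relative prominence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_stats import FabricSummary, TranscriptSummary

__all__ = ["PWRRecord", "pwr_score", "pwr_records", "pwr_landscape", "top_pairs"]


@dataclass
class PWRRecord:
    """A scored pair with its factor decomposition.

    ``factors`` = (expression term, correlation term, control term);
    ``pwr`` is their product.  NaN signals an undefined correlation.
    """

    gene_a: str
    gene_b: str
    condition: str
    pwr: float
    factors: tuple[float, float, float]


def pwr_score(
    mu_i: float,
    mu_j: float,
    rev_i: float,
    rev_j: float,
    rho_ij: float,
    fabric: FabricSummary,
    gene_a: str = "",
    gene_b: str = "",
) -> PWRRecord:
    """PWR of one pair against the fabric-wide means.

    No significance gate is applied to rho: the squared correlation enters
    whatever its class.  Zero REV is a domain error (the control term would
    be infinite); an undefined rho propagates as NaN rather than a silent 0.
    """
    if rev_i <= 0 or rev_j <= 0:
        raise ValueError("PWR requires strictly positive REV values")
    if fabric.mean_expression <= 0 or fabric.mean_rev <= 0:
        raise ValueError("fabric means must be positive")
    expr_term = (mu_i * mu_j) / fabric.mean_expression**2
    control_term = fabric.mean_rev**2 / (rev_i * rev_j)
    if rho_ij is None or (isinstance(rho_ij, float) and math.isnan(rho_ij)):
        corr_term = float("nan")
    else:
        corr_term = float(rho_ij) ** 2
    return PWRRecord(
        gene_a=gene_a,
        gene_b=gene_b,
        condition=fabric.condition,
        pwr=expr_term * corr_term * control_term,
        factors=(float(expr_term), float(corr_term), float(control_term)),
    )


def pwr_records(
    summaries: dict[tuple[str, str], TranscriptSummary],
    rho: dict[tuple[str, str], float],
    pairs,
    fabric: FabricSummary,
) -> list[PWRRecord]:
    """Score every requested pair; ``rho`` maps canonical pair keys (or the
    given ordered pair) to correlation estimates."""
    out = []
    cond = fabric.condition
    for a, b in pairs:
        sa = summaries.get((a, cond))
        sb = summaries.get((b, cond))
        key = (a, b) if (a, b) in rho else ((b, a) if (b, a) in rho else None)
        if (
            sa is None
            or sb is None
            or key is None
            or not sa.rev
            or not sb.rev
            or sa.rev <= 0
            or sb.rev <= 0
        ):
            # missing gene data or degenerate (zero) REV: flagged, not scored
            out.append(PWRRecord(a, b, cond, float("nan"), (float("nan"),) * 3))
            continue
        out.append(
            pwr_score(
                sa.combined_mean,
                sb.combined_mean,
                sa.rev,
                sb.rev,
                rho[key],
                fabric,
                gene_a=a,
                gene_b=b,
            )
        )
    return out


def pwr_landscape(records: list[PWRRecord], set_a, set_b) -> pd.DataFrame:
    """Dense PWR matrix over set A (rows) x set B (columns).

    Entries with no record, or with undefined correlation, are NaN —
    flagged, never silently zero.
    """
    mat = pd.DataFrame(np.nan, index=list(set_a), columns=list(set_b))
    for r in records:
        if r.gene_a in mat.index and r.gene_b in mat.columns:
            mat.at[r.gene_a, r.gene_b] = r.pwr
        elif r.gene_b in mat.index and r.gene_a in mat.columns:
            mat.at[r.gene_b, r.gene_a] = r.pwr
    return mat


def top_pairs(records: list[PWRRecord], k: int) -> list[PWRRecord]:
    """The k highest-PWR pairs ("medallion" pairs), ties broken
    lexicographically by pair key; stable under record order; NaN-scored
    records never rank.  Asking for more pairs than exist returns all."""
    if k < 1:
        raise ValueError("k must be >= 1")
    scored = [r for r in records if not math.isnan(r.pwr)]
    scored.sort(key=lambda r: (-r.pwr, min(r.gene_a, r.gene_b), max(r.gene_a, r.gene_b)))
    return scored[:k]
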