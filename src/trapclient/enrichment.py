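"""Annotation-category enrichment of affected protein sets.

For a binary category (signal peptide, membrane, N-glycosylated, secretory
pathway, ...) the enrichment factor of an affected set against the quantified
background is (k/n)/(K/N): the category's frequency among the n affected
proteins over its frequency among the N background proteins. Significance is
an upper-tail hypergeometric probability (the chance of drawing >= k
annotated proteins in n draws without replacement), with Benjamini-Hochberg
correction across a report table. The background is the set of proteins
quantified in all samples, i.e. the statistically analyzed universe, not the
whole proteome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import AnnotationTable


@dataclass
class EnrichmentRecord:
    category: str
    affected_set: str  # e.g. "negative" / "positive"
    k: int  # annotated among affected
    n: int  # affected set size
    K: int  # annotated among background
    N: int  # background size
    factor: float  # (k/n) / (K/N); NaN when K == 0
    p_value: float  # upper-tail hypergeometric


def enrichment_factor(
    affected_ids, background_ids, annotations: AnnotationTable, category: str,
    set_name: str = "affected",
) -> EnrichmentRecord:
    affected = set(affected_ids)
    background = set(background_ids)
    if not affected or not background:
        raise ValidationError("affected and background sets must be non-empty")
    if not affected <= background:
        raise ValidationError(
            f"affected set is not a subset of the background "
            f"({sorted(affected - background)[:5]} ...)"
        )
    members = annotations.members(category)
    k = len(affected & members)
    n = len(affected)
    K = len(background & members)
    N = len(background)
    if K == 0:
        return EnrichmentRecord(category, set_name, k, n, K, N, np.nan, 1.0)
    factor = (k / n) / (K / N)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentRecord(category, set_name, k, n, K, N, factor, min(p, 1.0))


def enrichment_report(
    affected_sets: dict[str, set],
    background_ids,
    annotations: AnnotationTable,
    categories: list[str] | None = None,
) -> pd.DataFrame:
    """One record per category per affected set, with BH-adjusted p-values.

    The hypergeometric test is an addition of this implementation; published
    depletion screens of this kind report only the fold factors.
    """
    categories = categories or annotations.categories
    records = []
    for set_name, ids in affected_sets.items():
        for category in categories:
            records.append(
                enrichment_factor(ids, background_ids, annotations, category, set_name)
            )
    df = pd.DataFrame(
        [
            {
                "affected_set": r.affected_set, "category": r.category,
                "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "factor": r.factor, "p_value": r.p_value,
            }
            for r in records
        ]
    )
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
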