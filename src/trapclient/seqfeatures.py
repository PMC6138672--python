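"""Physicochemical scoring of signal peptides and transmembrane helices.

TRAP (the translocon-associated protein complex) assists Sec61-mediated ER
import of a subset of precursor proteins. The distinguishing features of its
clients are carried by the signal peptide (SP): a high combined glycine+proline
content (a proxy for low helix propensity) and a low mean Kyte-Doolittle
hydropathy. This module computes those two scores, classifies sequences by the
15% GP threshold, and compares feature distributions between a client set and
a background set with the Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .errors import ValidationError

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class HydropathyScale:
    """Residue -> hydropathy map covering the 20 standard amino acids."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.values)
        if missing:
            raise ValidationError(
                f"hydropathy scale {self.name!r} lacks residues {sorted(missing)}"
            )

    @property
    def min(self) -> float:
        return min(self.values.values())

    @property
    def max(self) -> float:
        return max(self.values.values())


#: Kyte & Doolittle hydropathy propensities.
KYTE_DOOLITTLE = HydropathyScale(
    name="kyte-doolittle",
    values={
        "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
        "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
        "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
        "R": -4.5,
    },
)


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValidationError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - STANDARD_AA
    if bad:
        raise ValidationError(
            f"non-standard residue(s) {sorted(bad)} in sequence {sequence!r}"
        )
    return seq


def gp_content(sequence: str) -> float:
    """Percent of residues that are glycine or proline: 100*(#G+#P)/length."""
    seq = _check_sequence(sequence)
    return 100.0 * (seq.count("G") + seq.count("P")) / len(seq)


def hydrophobicity(sequence: str, scale: HydropathyScale = KYTE_DOOLITTLE) -> float:
    """Mean per-residue hydropathy over the full sequence length."""
    seq = _check_sequence(sequence)
    return sum(scale.values[aa] for aa in seq) / len(seq)


#: GP threshold (percent) above which an SP is considered a putative TRAP client.
GP_THRESHOLD = 15.0


def classify_gp(gp_percent: float, threshold: float = GP_THRESHOLD) -> str:
    """Classify by GP content; strictly above the threshold counts as high."""
    return "high_gp" if gp_percent > threshold else "low_gp"


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at `ndigits` decimals (table conventions)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FeatureComparison:
    """Two-group comparison of one physicochemical feature."""

    feature: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    statistic: float  # rank-sum W of group a (average ranks for ties)
    p_value: float  # two-sided
    mean_ratio: float = field(default=np.nan)  # mean_a / mean_b


def wilcoxon_rank_sum(
    values_a, values_b, group_a: str = "a", group_b: str = "b",
    feature: str = "value",
) -> FeatureComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The p-value is exact (full enumeration of rank splits) when the pooled
    sample is small (n_a+n_b <= 12) and tie-free, otherwise the normal
    approximation with tie and continuity correction is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("wilcoxon_rank_sum requires two non-empty groups")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 12 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank sum
    mean_b = float(np.mean(b))
    return FeatureComparison(
        feature=feature, group_a=group_a, group_b=group_b,
        n_a=int(a.size), n_b=int(b.size),
        mean_a=float(np.mean(a)), mean_b=mean_b,
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        statistic=w, p_value=float(res.pvalue),
        mean_ratio=float(np.mean(a)) / mean_b if mean_b != 0 else np.nan,
    )


FEATURES = ("gp_percent", "hydrophobicity")


def feature_report(records_clients, records_background, feature: str) -> FeatureComparison:
    """Compare a feature between client records and background records.

    `mean_ratio` is clients/background; e.g. a ratio of ~1.5 reproduces the
    observation that TRAP-dependent SPs carry ~50% more G+P than average SPs.
    """
    if feature not in FEATURES:
        raise ValidationError(f"unknown feature {feature!r}; expected one of {FEATURES}")
    va = [getattr(r, feature) for r in records_clients]
    vb = [getattr(r, feature) for r in records_background]
    return wilcoxon_rank_sum(va, vb, group_a="clients", group_b="background",
                             feature=feature)
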