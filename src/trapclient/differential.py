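"""Per-contrast differential abundance testing with permutation FDR.

Each targeting-siRNA group is tested against the control group on the
normalized log2 matrix. The per-protein effect is the mean log2 difference
(targeting - control), which equals the log2-transformed intensity ratio.
Two statistics are available:

* ``student_t`` — the classical two-sample pooled-variance t;
* ``moderated_d`` — the significance-analysis-of-microarrays d-statistic
  d = (mean_b - mean_a) / (s + s0), where s is the pooled standard error and
  the exchangeability constant s0 damps the small-denominator tail that
  otherwise dominates triplicate designs. s0 is auto-selected by the standard
  coefficient-of-variation criterion over percentiles of s.

Multiple testing is handled by a permutation FDR: group labels of the
contrast's samples are relabelled (exhaustively for small designs), null
statistics are pooled across proteins, and the q-value of each protein is the
estimated false-call fraction at the threshold set by its own |statistic|,
scaled by an estimate of the true-null proportion pi0 and monotonized.
Proteins significant (q < alpha) with a concordant sign in *every* targeting
contrast form the intersected affected sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StateError, ValidationError
from .io import LOG2, AbundanceMatrix, SampleDesign

logger = logging.getLogger(__name__)

STATISTICS = ("student_t", "moderated_d")


@dataclass
class TestConfig:
    alpha: float = 0.05
    statistic: str = "moderated_d"
    s0: float | None = None  # fixed s0; None -> auto-select
    permutations: str = "exhaustive"  # or "sampled"
    n_sampled: int = 10000
    seed: int | None = None
    pool_null: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.statistic not in STATISTICS:
            raise ValidationError(f"statistic must be one of {STATISTICS}")
        if self.permutations not in ("exhaustive", "sampled"):
            raise ValidationError("permutations must be 'exhaustive' or 'sampled'")
        if self.permutations == "sampled" and self.seed is None:
            raise ValidationError("sampled permutations require a seed")


@dataclass
class ContrastResult:
    contrast: str  # targeting group label
    table: pd.DataFrame  # index protein_id: mean_diff, statistic, p_value, q_value, direction
    n_permutations: int
    pi0: float
    s0: float | None = None

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != "none"]


@dataclass
class AffectedSets:
    negatively_affected: set[str]
    positively_affected: set[str]
    per_contrast: dict[str, pd.DataFrame] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _group_stats(values: np.ndarray, axis_b: np.ndarray, axis_a: np.ndarray):
    """Vectorized mean difference and pooled standard error (2-D input)."""
    a = values[:, axis_a]
    b = values[:, axis_b]
    na, nb = a.shape[1], b.shape[1]
    diff = b.mean(axis=1) - a.mean(axis=1)
    ssq = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    sp = np.sqrt(ssq / (na + nb - 2))
    se = sp * np.sqrt(1.0 / na + 1.0 / nb)
    return diff, se


def unpaired_t(group_a, group_b) -> tuple[float, float]:
    """Student's pooled-variance two-sample t with two-sided p (df na+nb-2).

    The statistic is (mean_a - mean_b) / se. Identical zero-variance groups
    return (0, 1); a zero-variance mean gap returns (+-inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 values")
    diff, se = _group_stats(np.concatenate([a, b])[None, :],
                            np.arange(a.size, a.size + b.size),
                            np.arange(a.size))
    diff, se = -float(diff[0]), float(se[0])
    df = a.size + b.size - 2
    if se == 0:
        if diff == 0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    t = diff / se
    return t, float(2.0 * stats.t.sf(abs(t), df))


def moderated_d(group_a, group_b, s0: float = 0.0) -> float:
    """SAM d-statistic (mean_a - mean_b) / (se + s0); reduces to t at s0=0."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 values")
    if s0 < 0:
        raise ValidationError("s0 must be >= 0")
    diff, se = _group_stats(np.concatenate([a, b])[None, :],
                            np.arange(a.size, a.size + b.size),
                            np.arange(a.size))
    diff_ab = -float(diff[0])
    denom = float(se[0]) + s0
    if denom == 0:
        return 0.0 if diff_ab == 0 else float(np.sign(diff_ab) * np.inf)
    return float(diff_ab / denom)


def select_s0(diff: np.ndarray, se: np.ndarray) -> float:
    """Auto-select s0 by the standard coefficient-of-variation criterion.

    Candidate s0 values are percentiles (0, 5, ..., 95) of the standard
    errors. For each candidate the proteins are binned into 100 quantile
    slices of se; the candidate minimizing the coefficient of variation of the
    per-bin median absolute d-statistic is chosen.
    """
    se = np.asarray(se, dtype=float)
    ok = se > 0
    if ok.sum() < 10:
        return float(np.median(se))
    qs = np.percentile(se[ok], np.arange(0, 100, 5))
    n_bins = min(100, max(2, ok.sum() // 20))
    bins = pd.qcut(se[ok], n_bins, labels=False, duplicates="drop")
    best_s0, best_cv = qs[0], np.inf
    for s0 in qs:
        d = np.abs(diff[ok]) / (se[ok] + s0)
        spread = pd.Series(d).groupby(bins).apply(
            lambda v: float(np.median(np.abs(v - np.median(v))))
        )
        mu = spread.mean()
        if mu == 0:
            continue
        cv = spread.std(ddof=1) / mu
        if cv < best_cv:
            best_cv, best_s0 = cv, s0
    return float(best_s0)


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

def _splits(n_total: int, n_b: int, config: TestConfig) -> list[np.ndarray]:
    """Pseudo-targeting column index sets used as the permutation null.

    Sampled mode draws n_sampled label splits and keeps the distinct ones
    with uniform weight, so it converges to the exhaustive enumeration as the
    sample grows.
    """
    if config.permutations == "exhaustive":
        return [np.array(c) for c in combinations(range(n_total), n_b)]
    rng = np.random.default_rng(config.seed)
    drawn = np.sort(
        np.stack([
            rng.choice(n_total, size=n_b, replace=False)
            for _ in range(config.n_sampled)
        ]),
        axis=1,
    )
    return list(np.unique(drawn, axis=0))


def _statistics(values: np.ndarray, cols_b: np.ndarray, n_total: int,
                s0: float, use_s0: bool) -> np.ndarray:
    cols_a = np.setdiff1d(np.arange(n_total), cols_b)
    diff, se = _group_stats(values, cols_b, cols_a)
    denom = se + s0 if use_s0 else se
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / denom
    d[np.isnan(d)] = 0.0  # 0/0: no effect, no variance
    return d


def permutation_fdr(
    matrix: AbundanceMatrix,
    design: SampleDesign,
    contrast: str,
    config: TestConfig | None = None,
) -> ContrastResult:
    """Test one targeting group against the control with permutation FDR.

    Returns a per-protein table with the log2 mean difference, the configured
    statistic, the Student-t p-value, the permutation q-value and the call
    direction at config.alpha.
    """
    config = config or TestConfig()
    matrix.require_scale(LOG2, "permutation_fdr")
    if matrix.n_missing:
        raise StateError("matrix has missing cells; impute before testing")
    design.validate_against(matrix)
    if contrast not in design.targeting_groups:
        raise ValidationError(f"{contrast!r} is not a targeting group")

    ctrl_samples = design.samples_of(design.control)
    tgt_samples = design.samples_of(contrast)
    cols = ctrl_samples + tgt_samples
    values = matrix.values[cols].to_numpy()
    n_ctrl, n_tgt = len(ctrl_samples), len(tgt_samples)
    n_total = n_ctrl + n_tgt

    splits = _splits(n_total, n_tgt, config)
    if len(splits) < 2:
        raise ValidationError("fewer than 2 distinct permutations available")

    # observed statistic and p-value
    obs_b = np.arange(n_ctrl, n_total)
    diff, se = _group_stats(values, obs_b, np.arange(n_ctrl))
    use_s0 = config.statistic == "moderated_d"
    s0 = 0.0
    if use_s0:
        s0 = config.s0 if config.s0 is not None else select_s0(diff, se)
    d_obs = _statistics(values, obs_b, n_total, s0, use_s0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    p = 2.0 * stats.t.sf(np.abs(t_obs), n_total - 2)

    # pooled permutation null
    null = np.stack([
        _statistics(values, np.asarray(b), n_total, s0, use_s0) for b in splits
    ])  # (B, m)

    abs_obs = np.abs(d_obs)
    m = abs_obs.size
    order = np.argsort(abs_obs)
    # observed exceedance count R(c) for each protein's own threshold
    r = m - np.searchsorted(abs_obs[order], abs_obs, side="left")
    if config.pool_null:
        # per-permutation exceedance counts at every threshold, then median
        v = np.stack([
            b.size - np.searchsorted(np.sort(np.abs(b)), abs_obs, side="left")
            for b in null
        ])
        v_med = np.median(v, axis=0)
    else:
        # audit mode: each protein's own permutation tail probability, scaled
        v_med = (np.abs(null) >= abs_obs[None, :]).mean(axis=0) * m

    # pi0 from the fraction of observed statistics inside the central 50% of the null
    q25, q75 = np.percentile(null.ravel(), [25, 75])
    pi0 = min(1.0, ((d_obs >= q25) & (d_obs <= q75)).sum() / (0.5 * m))

    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.minimum(1.0, pi0 * v_med / np.maximum(r, 1))
    # monotonize: q non-decreasing as |statistic| decreases. In ascending
    # |statistic| order a running minimum assigns each protein the smallest
    # raw q among proteins at or below its own significance rank.
    q_final = np.empty_like(q)
    q_final[order] = np.minimum.accumulate(q[order])

    direction = np.where(
        (q_final < config.alpha) & (diff < 0), "negative",
        np.where((q_final < config.alpha) & (diff > 0), "positive", "none"),
    )
    table = pd.DataFrame(
        {
            "mean_diff": diff,
            "statistic": d_obs,
            "p_value": p,
            "q_value": q_final,
            "direction": direction,
        },
        index=pd.Index(matrix.protein_ids, name="protein_id"),
    )
    logger.info(
        "contrast %s: %d negative, %d positive at q<%g (pi0=%.3f, s0=%s)",
        contrast, int((direction == "negative").sum()),
        int((direction == "positive").sum()), config.alpha, pi0,
        f"{s0:.4g}" if use_s0 else "n/a",
    )
    return ContrastResult(
        contrast=contrast, table=table, n_permutations=len(splits), pi0=pi0,
        s0=s0 if use_s0 else None,
    )


def call_affected(contrast_results: list[ContrastResult], alpha: float = 0.05) -> AffectedSets:
    """Intersect per-contrast calls: membership in an affected set requires
    q < alpha with the same sign of the mean difference in every contrast."""
    if not contrast_results:
        raise ValidationError("need at least one contrast result")
    universe = set(contrast_results[0].table.index)
    for res in contrast_results[1:]:
        if set(res.table.index) != universe:
            raise ValidationError("contrast results cover different protein universes")
    neg = universe.copy()
    pos = universe.copy()
    for res in contrast_results:
        t = res.table
        sig = t["q_value"] < alpha
        neg &= set(t.index[sig & (t["mean_diff"] < 0)])
        pos &= set(t.index[sig & (t["mean_diff"] > 0)])
    return AffectedSets(
        negatively_affected=neg,
        positively_affected=pos,
        per_contrast={r.contrast: r.table for r in contrast_results},
    )


def volcano_table(result: ContrastResult, n_proteins: int | None = None) -> pd.DataFrame:
    """Per-protein (mean_diff, -log10 q) pairs; q floored to avoid infinities."""
    t = result.table
    m = n_proteins if n_proteins is not None else len(t)
    floor = 1.0 / (result.n_permutations * m)
    q = np.maximum(t["q_value"].to_numpy(), floor)
    return pd.DataFrame(
        {
            "protein_id": t.index,
            "mean_diff": t["mean_diff"].to_numpy(),
            "neg_log10_q": -np.log10(q),
        }
    )
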