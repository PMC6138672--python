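"""Missing-value imputation for log2 LFQ intensity matrices.

Label-free MS intensities are missing not at random: low-abundance proteins
preferentially drop below the detection limit. Two cases are distinguished,
following common practice for LFQ data:

* proteins with no valid data point in any sample get values drawn from a
  down-shifted Gaussian in the bottom tail of each sample's observed log2
  distribution (mean - 1.8 sd, width 0.3 sd, the canonical defaults of the
  Perseus-style strategy);
* proteins with at least one valid data point are completed by local least
  squares (LLS): the k most correlated fully-observed neighbour proteins are
  used as regressors to predict the missing cells.

Observed cells are never modified, and a report partitions the imputed cells
by mechanism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import StateError, ValidationError
from .io import LOG2, AbundanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class ImputationConfig:
    downshift: float = 1.8  # sd units below the per-sample mean
    width: float = 0.3  # sd units, spread of the imputed distribution
    k: int = 10  # LLS neighbour count
    min_overlap: int = 3  # observed samples a target needs for LLS
    seed: int = 0
    pooled_tail: bool = False  # one matrix-wide tail instead of per-sample

    def __post_init__(self) -> None:
        if self.downshift < 0:
            raise ValidationError("downshift must be >= 0")
        if self.width <= 0:
            raise ValidationError("width must be > 0")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.min_overlap < 2:
            raise ValidationError("min_overlap must be >= 2")


@dataclass
class ImputationReport:
    n_bottom_tail_cells: int = 0
    n_lls_cells: int = 0
    n_fallback_cells: int = 0
    tail_params: dict = field(default_factory=dict)  # sample -> (mean, sd)

    @property
    def n_imputed(self) -> int:
        return self.n_bottom_tail_cells + self.n_lls_cells + self.n_fallback_cells


def _observed_stats(col: np.ndarray, label: str) -> tuple[float, float]:
    obs = col[~np.isnan(col)]
    if obs.size < 2:
        raise ValidationError(
            f"sample {label!r} has {obs.size} observed values; "
            "bottom-tail distribution undefined"
        )
    return float(obs.mean()), float(obs.std(ddof=1))


def impute_bottom_tail(
    matrix: AbundanceMatrix,
    config: ImputationConfig | None = None,
    rng: np.random.Generator | None = None,
    rows: np.ndarray | None = None,
) -> tuple[AbundanceMatrix, ImputationReport]:
    """Fill missing cells of fully-missing proteins with bottom-tail draws.

    For a target cell in sample j the draw is
    Normal(mean_j - downshift*sd_j, (width*sd_j)^2) where mean_j/sd_j come
    from sample j's observed log2 values. `rows` restricts the operation to a
    boolean row subset (defaults to rows with zero observed values).
    """
    config = config or ImputationConfig()
    matrix.require_scale(LOG2, "impute_bottom_tail")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = matrix.values.to_numpy().copy()
    missing = np.isnan(X)
    if rows is None:
        rows = missing.all(axis=1)
    report = ImputationReport()
    if config.pooled_tail:
        pool = X[~missing]
        if pool.size < 2:
            raise ValidationError("matrix has <2 observed values; tail undefined")
        stats = [(float(pool.mean()), float(pool.std(ddof=1)))] * X.shape[1]
    else:
        stats = [
            _observed_stats(X[:, j], matrix.sample_ids[j]) for j in range(X.shape[1])
        ]
    for j, (mean_j, sd_j) in enumerate(stats):
        report.tail_params[matrix.sample_ids[j]] = (mean_j, sd_j)
        target = rows & missing[:, j]
        n = int(target.sum())
        if n:
            X[target, j] = rng.normal(
                mean_j - config.downshift * sd_j, config.width * sd_j, size=n
            )
            report.n_bottom_tail_cells += n
    out = AbundanceMatrix(
        matrix.values.copy(), LOG2
    )
    out.values.iloc[:, :] = X
    return out, report


def _lls_impute_row(
    X: np.ndarray, i: int, neighbour_pool: np.ndarray,
    protein_ids: np.ndarray, config: ImputationConfig
) -> tuple[np.ndarray, str]:
    """Return imputed values for row i's missing cells and the mechanism used."""
    row = X[i]
    obs = ~np.isnan(row)
    mis = ~obs
    obs_vals = row[obs]
    fallback = np.full(int(mis.sum()), obs_vals.mean())
    if obs.sum() < config.min_overlap:
        return fallback, "fallback"
    # eligible neighbours: complete in every column the fit or prediction needs
    eligible = neighbour_pool & ~np.isnan(X).any(axis=1)
    eligible[i] = False
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return fallback, "fallback"
    y = obs_vals
    yc = y - y.mean()
    y_sd = yc.std()
    if y_sd == 0:  # flat target row carries no correlation signal
        return fallback, "fallback"
    N = X[idx][:, obs]
    Nc = N - N.mean(axis=1, keepdims=True)
    n_sd = Nc.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Nc @ yc) / (len(y) * n_sd * y_sd)
    corr = np.nan_to_num(np.abs(corr), nan=0.0)
    # top-k by |r|; ties broken by protein id, lexicographically. When k
    # exceeds the observed-column count the system is underdetermined and
    # lstsq returns the minimum-norm solution, which spreads weight across
    # the correlated neighbours instead of interpolating noise.
    k_eff = min(config.k, idx.size)
    order = np.lexsort((protein_ids[idx], -corr))[:k_eff]
    chosen = idx[order]
    # least squares with intercept on the observed columns
    A = np.column_stack([np.ones(obs.sum()), X[chosen][:, obs].T])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    P = np.column_stack([np.ones(mis.sum()), X[chosen][:, mis].T])
    return P @ coef, "lls"


def impute_lls(
    matrix: AbundanceMatrix,
    config: ImputationConfig | None = None,
    neighbour_pool: np.ndarray | None = None,
    leave_unserved: bool = False,
) -> tuple[AbundanceMatrix, ImputationReport]:
    """LLS-impute every protein with at least one observed and one missing cell.

    Neighbours are ranked by absolute Pearson correlation with the target
    over the target's observed columns; the top-k enter an intercepted
    least-squares fit. Targets with too few observed columns (< min_overlap),
    a flat observed profile, or no eligible neighbour cannot be served by the
    regression; they fall back to their observed row mean, or are left
    missing when `leave_unserved` is set (the combined `impute` then hands
    them to the bottom-tail mechanism).
    """
    config = config or ImputationConfig()
    matrix.require_scale(LOG2, "impute_lls")
    X = matrix.values.to_numpy().copy()
    missing = np.isnan(X)
    if neighbour_pool is None:
        neighbour_pool = np.ones(X.shape[0], dtype=bool)
    report = ImputationReport()
    targets = np.flatnonzero(missing.any(axis=1) & ~missing.all(axis=1))
    filled = X.copy()
    protein_ids = np.asarray(matrix.protein_ids, dtype=str)
    for i in targets:
        values, mechanism = _lls_impute_row(X, i, neighbour_pool, protein_ids, config)
        n = int(missing[i].sum())
        if mechanism == "lls":
            filled[i, missing[i]] = values
            report.n_lls_cells += n
        elif leave_unserved:
            continue
        else:
            filled[i, missing[i]] = values
            report.n_fallback_cells += n
    out = matrix.copy()
    out.values.iloc[:, :] = filled
    return out, report


def impute(
    matrix: AbundanceMatrix, config: ImputationConfig | None = None
) -> tuple[AbundanceMatrix, ImputationReport]:
    """Two-case imputation: bottom tail for fully-missing proteins, LLS for
    partially-missing ones. The output has no missing cells.

    Bottom-tail rows are excluded from the LLS neighbour pool so random draws
    never serve as regressors. Cells the LLS regression cannot serve (too few
    observed columns, flat profile, or no eligible neighbour) receive
    bottom-tail draws as the final fallback: under missing-not-at-random
    dropout an uninformative missing cell is most plausibly below the
    detection limit.
    """
    config = config or ImputationConfig()
    matrix.require_scale(LOG2, "impute")
    missing = matrix.values.isna().to_numpy()
    fully_missing = missing.all(axis=1)
    rng = np.random.default_rng(config.seed)
    step1, tail_report = impute_bottom_tail(matrix, config, rng=rng, rows=fully_missing)
    step2, lls_report = impute_lls(
        step1, config, neighbour_pool=~fully_missing, leave_unserved=True
    )
    unserved = step2.values.isna().to_numpy().any(axis=1)
    step3, fb_report = impute_bottom_tail(step2, config, rng=rng, rows=unserved)
    report = ImputationReport(
        n_bottom_tail_cells=tail_report.n_bottom_tail_cells,
        n_lls_cells=lls_report.n_lls_cells,
        n_fallback_cells=fb_report.n_bottom_tail_cells,
        tail_params=tail_report.tail_params,
    )
    if step3.n_missing:
        raise StateError("imputation left missing cells; this is a bug")
    logger.info(
        "imputed %d cells (%d bottom-tail, %d LLS, %d fallback)",
        report.n_imputed, report.n_bottom_tail_cells, report.n_lls_cells,
        report.n_fallback_cells,
    )
    return step3, report
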