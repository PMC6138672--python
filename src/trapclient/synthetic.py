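"""Seeded synthetic LFQ datasets with known ground truth.

The generator emulates the statistical structure of a triplicate
siRNA-depletion screen: one control group and two targeting groups, three
replicates each. Per protein, a log2 baseline is drawn once from a broad
between-protein distribution; replicate values add a group effect (additive
in log2 space, i.e. multiplicative in intensity) and Gaussian replicate
noise. Missingness is missing-not-at-random: the probability that a cell
drops out decays logistically with its log2 intensity, the regime that
bottom-tail imputation assumes. Planted effect classes:

* ``client_negative`` — knocked down (default -1 log2FC) in BOTH targeting
  groups: the true clients the intersection should recover;
* ``compensatory_positive`` — up-regulated (default +0.5 log2FC) in both
  targeting groups, emulating compensatory components such as the SRP
  receptor subunits;
* ``offtarget_g1`` / ``offtarget_g2`` — knocked down in only one targeting
  group: single-siRNA artifacts the intersection must reject.

A companion generator draws synthetic signal-peptide cohorts with a
controllable G+P content, and ``end_to_end_fixture`` writes a complete file
bundle (matrix, design, annotations, SP table, truth, YAML run config).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import io
from .errors import ValidationError
from .io import AbundanceMatrix, AnnotationTable, SampleDesign, SignalPeptideRecord

CLASSES = (
    "null", "client_negative", "compensatory_positive", "offtarget_g1", "offtarget_g2",
)


@dataclass
class SynthConfig:
    n_proteins: int = 2000
    control_group: str = "control"
    targeting_groups: tuple[str, ...] = ("siRNA1", "siRNA2")
    n_replicates: int = 3
    baseline_mean: float = 25.0  # log2 units, typical LFQ magnitude
    baseline_sd: float = 2.0  # between-protein spread
    noise_sd: float = 0.25  # replicate noise, log2 units
    n_clients: int = 100
    client_log2fc: float = -1.0  # shared knockdown effect
    n_positive: int = 50
    positive_log2fc: float = 0.5  # compensatory up-regulation
    n_offtarget: int = 25  # per targeting group
    offtarget_log2fc: float = -1.0
    mnar: bool = True
    missing_midpoint: float | None = None  # default: baseline_mean - 2*baseline_sd
    missing_slope: float = 1.0  # logistic steepness per log2 unit
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_clients, self.n_positive, self.n_offtarget)
        if any(c < 0 for c in counts):
            raise ValidationError("effect-class counts must be non-negative")
        planted = self.n_clients + self.n_positive + self.n_offtarget * len(self.targeting_groups)
        if planted > self.n_proteins:
            raise ValidationError("planted classes exceed n_proteins")
        if self.baseline_sd <= 0 or self.noise_sd <= 0:
            raise ValidationError("standard deviations must be > 0")
        if self.n_replicates < 2:
            raise ValidationError("need >= 2 replicates per group")
        if len(self.targeting_groups) < 1:
            raise ValidationError("need >= 1 targeting group")

    @property
    def midpoint(self) -> float:
        if self.missing_midpoint is not None:
            return self.missing_midpoint
        return self.baseline_mean - 2.0 * self.baseline_sd


@dataclass
class GroundTruth:
    table: pd.DataFrame  # index protein_id: class, lfc_<group> per targeting group

    def ids_of(self, cls: str) -> set[str]:
        if cls not in CLASSES:
            raise ValidationError(f"unknown class {cls!r}")
        return set(self.table.index[self.table["class"] == cls])


def missing_probability(log2_intensity, config: SynthConfig) -> np.ndarray:
    """Logistic MNAR dropout probability at a given log2 intensity."""
    x = np.asarray(log2_intensity, dtype=float)
    if not config.mnar:
        return np.zeros_like(x)
    return expit(-config.missing_slope * (x - config.midpoint))


def generate_lfq_dataset(
    config: SynthConfig | None = None,
) -> tuple[AbundanceMatrix, SampleDesign, GroundTruth]:
    """Simulate a linear-scale LFQ matrix plus design and ground truth."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    groups = [config.control_group, *config.targeting_groups]
    samples = [
        f"{g}_r{r + 1}" for g in groups for r in range(config.n_replicates)
    ]
    group_of = np.repeat(np.arange(len(groups)), config.n_replicates)

    m = config.n_proteins
    width = len(str(m))
    protein_ids = [f"P{i + 1:0{width}d}" for i in range(m)]

    classes = np.array(["null"] * m, dtype=object)
    pos = 0
    classes[pos:pos + config.n_clients] = "client_negative"
    pos += config.n_clients
    classes[pos:pos + config.n_positive] = "compensatory_positive"
    pos += config.n_positive
    for g_idx in range(len(config.targeting_groups)):
        classes[pos:pos + config.n_offtarget] = f"offtarget_g{g_idx + 1}"
        pos += config.n_offtarget

    # per-protein true log2 fold change in each group (control = 0)
    lfc = np.zeros((m, len(groups)))
    for g_idx in range(1, len(groups)):
        lfc[classes == "client_negative", g_idx] = config.client_log2fc
        lfc[classes == "compensatory_positive", g_idx] = config.positive_log2fc
        lfc[classes == f"offtarget_g{g_idx}", g_idx] = config.offtarget_log2fc

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=m)
    log2_values = (
        baseline[:, None]
        + lfc[:, group_of]
        + rng.normal(0.0, config.noise_sd, size=(m, len(samples)))
    )
    drop = rng.random(log2_values.shape) < missing_probability(log2_values, config)
    linear = np.exp2(log2_values)
    linear[drop] = np.nan

    matrix = AbundanceMatrix(
        pd.DataFrame(linear, index=pd.Index(protein_ids, name="protein_id"),
                     columns=samples),
        scale=io.LINEAR,
    )
    design = SampleDesign(
        pd.DataFrame(
            {
                "group": [groups[g] for g in group_of],
                "replicate": [r + 1 for _ in groups for r in range(config.n_replicates)],
            },
            index=pd.Index(samples, name="sample_id"),
        ),
        control=config.control_group,
    )
    truth_table = pd.DataFrame(
        {"class": classes}, index=pd.Index(protein_ids, name="protein_id")
    )
    for g_idx, g in enumerate(groups):
        if g != config.control_group:
            truth_table[f"lfc_{g}"] = lfc[:, g_idx]
    return matrix, design, GroundTruth(truth_table)


# background residue frequencies for non-G/P positions, loosely following
# average membrane-targeting sequence composition (hydrophobics enriched)
_BACKGROUND_AA = np.array(list("ACDEFHIKLMNQRSTVWY"))
_BACKGROUND_FREQ = np.array([
    0.14, 0.03, 0.01, 0.01, 0.06, 0.01, 0.05, 0.01, 0.24, 0.03,
    0.01, 0.02, 0.03, 0.08, 0.05, 0.12, 0.05, 0.05,
])
_BACKGROUND_FREQ = _BACKGROUND_FREQ / _BACKGROUND_FREQ.sum()


def generate_sp_cohort(
    n: int,
    gp_target_percent: float,
    length_range: tuple[int, int] = (15, 40),
    seed: int = 0,
    prefix: str = "SYN",
) -> list[SignalPeptideRecord]:
    """Draw synthetic SP records with per-position G/P probability
    gp_target_percent/100; remaining positions use a fixed hydrophobic-rich
    background frequency."""
    if not 0 <= gp_target_percent <= 100:
        raise ValidationError("gp_target_percent must be in [0, 100]")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p_gp = gp_target_percent / 100.0
    records = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        is_gp = rng.random(length) < p_gp
        gp_chars = rng.choice(np.array(["G", "P"]), size=length)
        bg_chars = rng.choice(_BACKGROUND_AA, size=length, p=_BACKGROUND_FREQ)
        seq = "".join(np.where(is_gp, gp_chars, bg_chars))
        records.append(
            SignalPeptideRecord(
                protein_id=f"{prefix}{i + 1:05d}", gene=f"{prefix.lower()}{i + 1}",
                sequence=seq, kind="SP",
            )
        )
    return records


SCENARIOS = ("null", "default_knockdown", "offtarget_stress")


def scenario_config(scenario: str, seed: int = 0) -> SynthConfig:
    if scenario == "null":
        return SynthConfig(n_clients=0, n_positive=0, n_offtarget=0, seed=seed)
    if scenario == "default_knockdown":
        return SynthConfig(seed=seed)
    if scenario == "offtarget_stress":
        return SynthConfig(n_offtarget=150, seed=seed)
    raise ValidationError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


def _annotations_for_truth(truth: GroundTruth, rng: np.random.Generator) -> AnnotationTable:
    """Binary categories correlated with client status, so enrichment of the
    recovered set against the background is expected by construction."""
    classes = truth.table["class"].to_numpy()
    m = len(classes)
    is_client = classes == "client_negative"
    prob = {
        "signal_peptide": np.where(is_client, 0.65, 0.10),
        "membrane": np.where(is_client, 0.50, 0.15),
        "nglyc": np.where(is_client, 0.55, 0.10),
        "secretory_pathway": np.where(is_client, 0.70, 0.25),
    }
    table = pd.DataFrame(
        {cat: rng.random(m) < p for cat, p in prob.items()},
        index=truth.table.index,
    )
    return AnnotationTable(table)


def end_to_end_fixture(scenario: str, out_dir, seed: int = 0) -> dict[str, Path]:
    """Write a complete pipeline input bundle for a named scenario."""
    config = scenario_config(scenario, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, design, truth = generate_lfq_dataset(config)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9151]))
    annotations = _annotations_for_truth(truth, rng)

    # SP records reuse matrix protein ids so the feature stage can relate
    # affected proteins to sequences: clients get a high-GP cohort (the ~1.5x
    # enrichment regime), a sample of the remaining proteins gets a 15% cohort
    client_ids = sorted(truth.ids_of("client_negative"))
    others = sorted(set(truth.table.index) - set(client_ids))
    bg_ids = list(rng.choice(others, size=min(200, len(others)), replace=False))
    sp_records = []
    if client_ids:
        sp_records += generate_sp_cohort(
            len(client_ids), gp_target_percent=22.5, seed=seed, prefix="CLI"
        )
    sp_records += generate_sp_cohort(
        len(bg_ids), gp_target_percent=15.0, seed=seed + 1, prefix="BG"
    )
    for record, pid in zip(sp_records, client_ids + bg_ids):
        record.protein_id = pid

    paths = {
        "matrix": out_dir / "matrix.tsv",
        "design": out_dir / "design.tsv",
        "annotations": out_dir / "annotations.tsv",
        "sp_table": out_dir / "sp_table.tsv",
        "truth": out_dir / "truth.tsv",
        "config": out_dir / "run.yaml",
    }
    io.write_abundance_table(matrix, paths["matrix"])
    io.write_design(design, paths["design"])
    io.write_annotations(annotations, paths["annotations"])
    io.write_sp_table(sp_records, paths["sp_table"])
    truth.table.to_csv(paths["truth"], sep="\t")
    # paths are kept relative to the bundle directory so regenerated
    # bundles are byte-identical wherever they are written
    run_config = {
        "seed": seed,
        "out_dir": "results",
        "inputs": {
            "matrix": "matrix.tsv",
            "design": "design.tsv",
            "annotations": "annotations.tsv",
            "sp_table": "sp_table.tsv",
        },
        "impute": {"downshift": 1.8, "width": 0.3, "k": 10, "min_overlap": 3},
        "normalize": {"mode": "sample_quantile", "reference": "mean_of_sorted"},
        "diff": {"alpha": 0.05, "statistic": "moderated_d", "permutations": "exhaustive"},
    }
    with paths["config"].open("w") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=True)
    return paths
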