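"""End-to-end orchestration: (synth|load) -> impute -> normalize -> diff ->
features -> enrich, with a reproducible manifest.

A run is described by a nested configuration (usually a YAML file): a global
seed, either a synthetic scenario or input file paths, and per-stage
sections mirroring the module configs. Per-stage seeds are derived
deterministically from the global seed by hashing the stage name, so any
stage can be re-run in isolation and identical (config, seed) pairs produce
identical outputs and manifest hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import pandas as pd

from . import differential, enrichment, imputation, io, normalization, seqfeatures, synthetic
from .errors import TrapClientError, ValidationError

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2 ** 31)


def _dataclass_from(section: dict | None, cls, **extra):
    section = dict(section or {})
    section.update(extra)
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(section) - fields
    if unknown:
        raise ValidationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**section)


def run_pipeline(config: dict) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    The manifest records the resolved configuration, per-stage counts, every
    output file with row count and content hash, and an overall run hash.
    """
    seed = int(config.get("seed", 0))
    base_dir = Path(config.get("base_dir", "."))
    out_dir = base_dir / Path(config.get("out_dir", "trapclient_results"))
    out_dir.mkdir(parents=True, exist_ok=True)

    def _resolve(p):
        return base_dir / Path(p)

    counts: dict[str, object] = {}

    # ------------------------------------------------------------------ input
    annotations = None
    sp_records = None
    if "scenario" in config:
        scenario = config["scenario"]
        paths = synthetic.end_to_end_fixture(
            scenario, out_dir / "inputs", seed=stage_seed(seed, "synth")
        )
        matrix = io.read_abundance_table(paths["matrix"])
        design = io.read_design(paths["design"])
        annotations = io.read_annotations(paths["annotations"])
        sp_records = io.read_sp_table(paths["sp_table"])
    else:
        inputs = config.get("inputs", {})
        if "matrix" not in inputs or "design" not in inputs:
            raise ValidationError("config needs a scenario or inputs.matrix/inputs.design")
        matrix = io.read_abundance_table(_resolve(inputs["matrix"]))
        design = io.read_design(_resolve(inputs["design"]), control=inputs.get("control"))
        if inputs.get("annotations"):
            annotations = io.read_annotations(_resolve(inputs["annotations"]))
        if inputs.get("sp_table"):
            sp_records = io.read_sp_table(_resolve(inputs["sp_table"]))
    design.validate_against(matrix)
    counts["proteins_loaded"] = len(matrix.protein_ids)
    counts["samples_loaded"] = len(matrix.sample_ids)
    counts["missing_cells"] = matrix.n_missing
    logger.info("loaded %d proteins x %d samples (%d missing cells)",
                counts["proteins_loaded"], counts["samples_loaded"],
                counts["missing_cells"])

    # ------------------------------------------------- impute + normalize
    log2m = normalization.log2_transform(matrix)
    impute_cfg = _dataclass_from(
        config.get("impute"), imputation.ImputationConfig,
        seed=stage_seed(seed, "impute"),
    )
    imputed, impute_report = imputation.impute(log2m, impute_cfg)
    counts["imputed_bottom_tail"] = impute_report.n_bottom_tail_cells
    counts["imputed_lls"] = impute_report.n_lls_cells
    counts["imputed_fallback"] = impute_report.n_fallback_cells

    norm_cfg = _dataclass_from(config.get("normalize"), normalization.NormalizationConfig)
    normalized = normalization.quantile_normalize(imputed, norm_cfg)

    # --------------------------------------------------------------- testing
    diff_section = dict(config.get("diff") or {})
    if diff_section.get("permutations") == "sampled":
        diff_section.setdefault("seed", stage_seed(seed, "diff"))
    test_cfg = _dataclass_from(diff_section, differential.TestConfig)
    results = [
        differential.permutation_fdr(normalized, design, contrast, test_cfg)
        for contrast in design.targeting_groups
    ]
    affected = differential.call_affected(results, alpha=test_cfg.alpha)
    counts["negatively_affected"] = len(affected.negatively_affected)
    counts["positively_affected"] = len(affected.positively_affected)
    for res in results:
        t = res.table
        counts[f"contrast_{res.contrast}_negative"] = int(
            ((t["direction"] == "negative")).sum())
        counts[f"contrast_{res.contrast}_positive"] = int(
            ((t["direction"] == "positive")).sum())
    logger.info("intersected calls: %d negative, %d positive",
                counts["negatively_affected"], counts["positively_affected"])

    tables: dict[str, pd.DataFrame] = {}
    for res in results:
        tables[f"contrast_{res.contrast}"] = res.table.reset_index()
        tables[f"volcano_{res.contrast}"] = differential.volcano_table(res)
    tables["affected"] = pd.DataFrame(
        [
            {"protein_id": pid, "set": name}
            for name, ids in (
                ("negative", sorted(affected.negatively_affected)),
                ("positive", sorted(affected.positively_affected)),
            )
            for pid in ids
        ],
        columns=["protein_id", "set"],
    )

    # -------------------------------------------------------------- features
    if sp_records:
        feature_cfg = dict(config.get("features") or {})
        threshold = float(feature_cfg.get("threshold", seqfeatures.GP_THRESHOLD))
        by_id = {r.protein_id: r for r in sp_records}
        client_records = [
            by_id[p] for p in sorted(affected.negatively_affected) if p in by_id
        ]
        rows = [
            {
                "id": r.protein_id, "gene": r.gene, "kind": r.kind,
                "gp_percent": r.gp_percent, "hydrophobicity": r.hydrophobicity,
                "gp_class": seqfeatures.classify_gp(r.gp_percent, threshold),
                "client": r.protein_id in affected.negatively_affected,
            }
            for r in sp_records
        ]
        tables["sp_features"] = pd.DataFrame(rows)
        if client_records and len(client_records) < len(sp_records):
            comparisons = [
                seqfeatures.feature_report(client_records, sp_records, feat)
                for feat in seqfeatures.FEATURES
            ]
            tables["feature_comparison"] = pd.DataFrame(
                [vars(c) for c in comparisons]
            )
            counts["sp_clients_compared"] = len(client_records)

    # ------------------------------------------------------------ enrichment
    if annotations is not None:
        sets = {
            name: ids
            for name, ids in (
                ("negative", affected.negatively_affected),
                ("positive", affected.positively_affected),
            )
            if ids
        }
        if sets:
            tables["enrichment"] = enrichment.enrichment_report(
                sets, matrix.protein_ids, annotations
            )

    # --------------------------------------------------------------- outputs
    file_manifest = io.write_results(tables, out_dir)
    manifest = {
        "config": _jsonable(config),
        "seed": seed,
        "counts": counts,
        "files": file_manifest.to_dict(orient="records"),
    }
    payload = json.dumps(manifest, sort_keys=True).encode()
    manifest["run_hash"] = hashlib.sha256(payload).hexdigest()
    with (out_dir / "run_manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
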