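"""End-to-end orchestration: curate -> cluster -> down-sample ->
augment -> split, as one configured, logged, atomic run.

All stage outputs are written into a staging directory and moved into
place only after every stage succeeds, so a failed run never leaves a
partial bundle. Every source of randomness flows from the single global
seed through :func:`cpidebias._seeds.derive_seed`.
"""

from __future__ import annotations

import json
import logging
import shutil
import tempfile
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from ._errors import ConfigError, InputError
from ._seeds import derive_seed
from .clustering import assign_cluster, fingerprint_matrix, fit_cluster_model, stratified_sample
from .curation import curate, druglike_mask, read_blocklist
from .downsampling import SamplingCaps, run_downsampling
from .metrics import positive_prevalence
from .putative_negatives import BalanceParams, balance_dataset
from .scenario_split import scenario_split

logger = logging.getLogger("cpidebias")

__all__ = ["CurationConfig", "ClusteringConfig", "RunConfig", "run_pipeline", "load_config"]


class CurationConfig(BaseModel):
    threshold: float = 6.0
    min_confidence: Optional[int] = None
    allowed_assay_types: Optional[list[str]] = None
    max_mw: float = 1000.0
    min_heavy: int = 12
    frequent_hitters_positives_only: bool = False


class ClusteringConfig(BaseModel):
    K: int = Field(default=50, ge=1)
    variance_target: float = Field(default=0.95, gt=0, le=1)
    n_classes: int = Field(default=100, ge=1)
    fit_sample: Optional[int] = None  # stratified subsample size for fitting
    max_iter: int = Field(default=300, ge=1)


class RunConfig(BaseModel):
    """Full pipeline configuration; validates before any work starts."""

    activity_path: str
    compounds_path: str
    out_dir: str
    blocklist_path: Optional[str] = None
    curation: CurationConfig = CurationConfig()
    clustering: ClusteringConfig = ClusteringConfig()
    caps: SamplingCaps = SamplingCaps()
    balance: BalanceParams = BalanceParams()
    cutoff_year_by_family: dict[str, int] = {"default": 2015}
    seed: int = 0
    log_level: str = "INFO"


def load_config(path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} did not parse to a mapping")
    return RunConfig(**raw)


def _prevalence_table(interactions: pd.DataFrame, stage: str) -> pd.DataFrame:
    frames = []
    for by in ("target", "cluster"):
        prev = positive_prevalence(interactions, by=by)
        frames.append(
            pd.DataFrame(
                {"entity": prev.index.astype(str), "level": by, "stage": stage,
                 "positive_prevalence": prev.to_numpy()}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _histogram(prev: pd.Series, bin_width: float = 0.05) -> dict[str, int]:
    edges = np.arange(0, 1 + bin_width, bin_width)
    counts, _ = np.histogram(prev.to_numpy(), bins=edges)
    return {f"{lo:.2f}-{lo + bin_width:.2f}": int(c) for lo, c in zip(edges[:-1], counts)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the dataset bundle.

    Returns the machine-readable report. Output files:
    ``curated.csv``, ``cluster_model.json``, ``compound_clusters.csv``,
    ``downsampled.csv``, ``balanced.csv``, ``splits/``, ``report.json``,
    ``prevalence.csv``.
    """
    logging.basicConfig(level=config.log_level)
    records = pd.read_csv(config.activity_path)
    compounds = pd.read_csv(config.compounds_path, dtype={"fingerprint": str})
    blocklist = read_blocklist(config.blocklist_path) if config.blocklist_path else set()

    out_dir = Path(config.out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix=".cpidebias-", dir=out_dir.parent))
    try:
        report = _run_stages(config, records, compounds, blocklist, staging)
        if out_dir.exists():
            shutil.rmtree(out_dir)
        staging.replace(out_dir)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    logger.info("bundle written to %s", out_dir)
    return report


def _run_stages(config, records, compounds, blocklist, out: Path) -> dict:
    cur = config.curation
    logger.info("curation: %d raw records", len(records))
    curated = curate(
        records,
        props=compounds,
        blocklist=blocklist,
        threshold=cur.threshold,
        min_confidence=cur.min_confidence,
        allowed_assay_types=cur.allowed_assay_types,
        max_mw=cur.max_mw,
        min_heavy=cur.min_heavy,
        frequent_hitters_positives_only=cur.frequent_hitters_positives_only,
    )
    if curated.empty:
        raise InputError("curation produced an empty table; nothing to process")
    curated.to_csv(out / "curated.csv", index=False)

    druglike = compounds.loc[
        druglike_mask(compounds, cur.max_mw, cur.min_heavy)
    ].reset_index(drop=True)
    cl = config.clustering
    fit_pool = druglike
    if cl.fit_sample is not None and cl.fit_sample < len(druglike):
        ids = stratified_sample(
            druglike, cl.fit_sample, n_classes=cl.n_classes,
            seed=derive_seed(config.seed, "stratified_sample") % (2**32),
        )
        fit_pool = druglike.loc[druglike["compound_id"].isin(set(ids))]
    logger.info("clustering: fitting K=%d on %d compounds", cl.K, len(fit_pool))
    model = fit_cluster_model(
        fingerprint_matrix(fit_pool),
        K=cl.K,
        seed=derive_seed(config.seed, "clustering") % (2**32),
        variance_target=cl.variance_target,
        max_iter=cl.max_iter,
    )
    model.save(out / "cluster_model.json")

    cluster_ids = assign_cluster(fingerprint_matrix(druglike), model)
    cluster_map = dict(zip(druglike["compound_id"], (int(c) for c in cluster_ids)))
    pd.DataFrame(
        {"compound_id": druglike["compound_id"], "cluster_id": cluster_ids}
    ).to_csv(out / "compound_clusters.csv", index=False)

    clustered = curated.copy()
    clustered["cluster_id"] = clustered["compound_id"].map(cluster_map)
    if clustered["cluster_id"].isna().any():
        raise InputError("curated interactions reference compounds without cluster ids")
    clustered["cluster_id"] = clustered["cluster_id"].astype(int)

    caps = config.caps.model_copy(update={"seed": derive_seed(config.seed, "downsampling")})
    downsampled = run_downsampling(clustered, caps).reset_index(drop=True)
    downsampled.to_csv(out / "downsampled.csv", index=False)
    logger.info("down-sampling: %d -> %d rows", len(clustered), len(downsampled))

    pool = druglike[["compound_id"]].copy()
    pool["cluster_id"] = [cluster_map[c] for c in pool["compound_id"]]
    params = config.balance.model_copy(update={"seed": derive_seed(config.seed, "balance")})
    balanced = balance_dataset(downsampled, cluster_map, pool, params)
    balanced.to_csv(out / "balanced.csv", index=False)
    logger.info("augmentation: %d -> %d rows", len(downsampled), len(balanced))

    split = scenario_split(balanced, config.cutoff_year_by_family)
    split.write(out / "splits")

    prevalence = pd.concat(
        [_prevalence_table(downsampled, "before"), _prevalence_table(balanced, "after")],
        ignore_index=True,
    )
    prevalence.to_csv(out / "prevalence.csv", index=False)

    before_t = positive_prevalence(downsampled, by="target")
    after_t = positive_prevalence(balanced, by="target")
    n_pos = int((balanced["label"] == "positive").sum())
    report = {
        "seed": config.seed,
        "rows": {
            "raw": int(len(records)),
            "curated": int(len(curated)),
            "downsampled": int(len(downsampled)),
            "putative_added": int(len(balanced) - len(downsampled)),
            "balanced": int(len(balanced)),
        },
        "final_positive_fraction": n_pos / len(balanced),
        "final_negative_fraction": 1.0 - n_pos / len(balanced),
        "targets_prevalence_gt_0.8": {
            "before": int((before_t > 0.8).sum()),
            "after": int((after_t > 0.8).sum()),
        },
        "prevalence_histogram_target": {
            "before": _histogram(before_t),
            "after": _histogram(after_t),
        },
        "split_counts": split.counts(),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
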