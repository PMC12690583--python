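"""Time-based train/validation splitting and the four seen/unseen
validation scenarios.

Measured rows dated before their family's cutoff year train the model;
later rows validate it. Putative rows (sentinel year) always go to
training. Validation rows are then cross-classified by whether their
target and their compound's cluster occur in training:

* seen target, seen cluster        — drug repurposing
* seen target, unseen cluster      — novel lead discovery
* unseen target, seen cluster      — target generalization
* unseen target, unseen cluster    — hardest generalization
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from ._errors import ConfigError, InputError
from .putative_negatives import AUGMENTED_YEAR

__all__ = ["SCENARIOS", "ScenarioSplit", "time_split", "assign_scenarios", "scenario_split"]

SCENARIOS = (
    "val_seen_seen",
    "val_seen_unseen_cluster",
    "val_unseen_target_seen_cluster",
    "val_unseen_unseen",
)


@dataclass
class ScenarioSplit:
    train: pd.DataFrame
    val_seen_seen: pd.DataFrame
    val_seen_unseen_cluster: pd.DataFrame
    val_unseen_target_seen_cluster: pd.DataFrame
    val_unseen_unseen: pd.DataFrame
    cutoff_year_by_family: dict

    def partitions(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in ("train",) + SCENARIOS}

    def counts(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.partitions().items()}

    def write(self, out_dir) -> None:
        """Five CSV files plus a JSON manifest of counts and cutoffs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.partitions().items():
            df.to_csv(out / f"{name}.csv", index=False)
        manifest = {
            "counts": self.counts(),
            "cutoff_year_by_family": {str(k): int(v) for k, v in self.cutoff_year_by_family.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _cutoff_for(family: str, cutoffs: Mapping[str, int]) -> int:
    if family in cutoffs:
        return int(cutoffs[family])
    if "default" in cutoffs:
        return int(cutoffs["default"])
    raise ConfigError(f"no cutoff year configured for family {family!r} and no default")


def time_split(
    interactions: pd.DataFrame, cutoff_year_by_family: Mapping[str, int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measured rows with year < family cutoff train; the rest validate.
    Putative rows are training-only."""
    for col in ("year", "family", "provenance"):
        if col not in interactions.columns:
            raise InputError(f"interactions missing column {col!r}")
    cutoffs = interactions["family"].map(lambda f: _cutoff_for(f, cutoff_year_by_family))
    putative = interactions["provenance"] == "putative"
    is_train = putative | (interactions["year"] < cutoffs)
    if ((interactions["year"] == AUGMENTED_YEAR) & ~putative).any():
        raise InputError("measured rows carry the augmented sentinel year")
    return interactions.loc[is_train].copy(), interactions.loc[~is_train].copy()


def assign_scenarios(
    train: pd.DataFrame, val: pd.DataFrame, cutoff_year_by_family: Mapping[str, int] | None = None
) -> ScenarioSplit:
    """Cross-classify validation rows by train membership of target and
    cluster. Seen-ness is computed on the given training set as-is, so
    putative rows count toward seen targets/clusters."""
    if "cluster_id" not in val.columns or "cluster_id" not in train.columns:
        raise InputError("both partitions need cluster_id for scenario assignment")
    seen_targets = set(train["target_id"])
    seen_clusters = set(train["cluster_id"])
    seen_t = val["target_id"].isin(seen_targets)
    seen_c = val["cluster_id"].isin(seen_clusters)
    return ScenarioSplit(
        train=train.copy(),
        val_seen_seen=val.loc[seen_t & seen_c].copy(),
        val_seen_unseen_cluster=val.loc[seen_t & ~seen_c].copy(),
        val_unseen_target_seen_cluster=val.loc[~seen_t & seen_c].copy(),
        val_unseen_unseen=val.loc[~seen_t & ~seen_c].copy(),
        cutoff_year_by_family=dict(cutoff_year_by_family or {}),
    )


def scenario_split(
    interactions: pd.DataFrame, cutoff_year_by_family: Mapping[str, int]
) -> ScenarioSplit:
    """Time split followed by scenario assignment."""
    train, val = time_split(interactions, cutoff_year_by_family)
    return assign_scenarios(train, val, cutoff_year_by_family)
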