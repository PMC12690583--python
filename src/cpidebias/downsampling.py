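"""Cluster-aware down-sampling of curated interactions.

Two passes: records of multi-target compounds are capped per
(target, cluster) pair; the remaining records are capped per
(target, cluster, label) combination. Within a group the retained rows
are a seeded uniform draw; the draw is a prefix of a seeded permutation
of the group's content-sorted rows, so it is independent of input row
order and monotone in the cap (raising the cap never drops a
previously retained row).
"""

from __future__ import annotations

import hashlib
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from ._errors import InputError

__all__ = ["SamplingCaps", "split_multitarget", "downsample", "run_downsampling"]


class SamplingCaps(BaseModel):
    """Caps for the two down-sampling passes (defaults: three records
    per group in both)."""

    cap_multitarget: int = Field(default=3, ge=1)
    cap_rest: int = Field(default=3, ge=1)
    seed: int = 0
    multitarget_label_aware: bool = False


def split_multitarget(interactions: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition rows into (multi, single) by whether the compound
    appears with at least two distinct targets."""
    degree = interactions.groupby("compound_id")["target_id"].transform("nunique")
    multi = interactions.loc[degree >= 2].copy()
    single = interactions.loc[degree < 2].copy()
    return multi, single


def _group_seed(seed: int, key: tuple) -> np.random.Generator:
    digest = hashlib.sha256(repr((int(seed),) + tuple(map(str, key))).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def downsample(
    interactions: pd.DataFrame, key_fields: Sequence[str], cap: int, seed: int = 0
) -> pd.DataFrame:
    """Retain at most ``cap`` rows per group keyed by ``key_fields``."""
    missing = [k for k in key_fields if k not in interactions.columns]
    if missing:
        raise InputError(f"down-sampling key fields missing from table: {missing}")
    if interactions.empty:
        return interactions.copy()
    # Content-sort so the permutation is independent of input row order.
    ordered = interactions.sort_values(
        list(interactions.columns), kind="mergesort"
    )
    keep_index = []
    for key, group in ordered.groupby(list(key_fields), sort=True):
        if len(group) <= cap:
            keep_index.extend(group.index)
            continue
        key_t = key if isinstance(key, tuple) else (key,)
        perm = _group_seed(seed, key_t).permutation(len(group))
        keep_index.extend(group.index[perm[:cap]])
    return interactions.loc[sorted(keep_index)].copy()


def run_downsampling(interactions: pd.DataFrame, caps: SamplingCaps) -> pd.DataFrame:
    """Both passes joined: multi-target rows capped per (target, cluster),
    the rest per (target, cluster, label). Output is a subset of the
    input with no field mutation."""
    if "cluster_id" not in interactions.columns:
        raise InputError("interactions must carry cluster_id before down-sampling")
    multi, single = split_multitarget(interactions)
    multi_key = ["target_id", "cluster_id"]
    if caps.multitarget_label_aware:
        multi_key = multi_key + ["label"]
    kept_multi = downsample(multi, multi_key, caps.cap_multitarget, caps.seed)
    kept_single = downsample(
        single, ["target_id", "cluster_id", "label"], caps.cap_rest, caps.seed
    )
    out = pd.concat([kept_multi, kept_single])
    return out.loc[sorted(out.index)]
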