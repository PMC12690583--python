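"""Putative-negative (PN) augmentation to balance label distributions.

Stage 1 balances targets: a target whose positives outnumber negatives
past a skew trigger (or that has no negatives at all) receives PN
compounds drawn from chemical clusters with no recorded interaction
against it. Stage 2 balances compounds: a compound touching fewer than
all six protein families receives PN targets from the untouched
families. Both quotas come from the rectified half sigmoid

    alpha(x) = max(x, (2 - 2m) / (1 + exp(-g * (x - 1))) + m)

applied to the entity's imbalance ``x`` and the clamped difference

    quota = max(0, round(alpha * N_P - N_N)).

For targets ``x`` is the negative prevalence N_N / (N_P + N_N); for
compounds it is the negative-to-positive ratio N_N / N_P. Entities that
are already negative-dominant get quota 0 and are left untouched; no
putative positives are ever generated. Measured rows are never modified
or removed — balancing only appends rows with provenance ``"putative"``
and the sentinel year -1, which keeps them out of time-based
validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from ._errors import InputError
from ._seeds import derive_seed
from .curation import FAMILIES, INTERACTION_COLUMNS

__all__ = [
    "AUGMENTED_YEAR",
    "BalanceParams",
    "ClusterEligibility",
    "rectified_half_sigmoid",
    "pn_quota",
    "target_profiles",
    "compound_profiles",
    "eligible_clusters",
    "eligible_families",
    "sample_pn_compounds",
    "sample_pn_targets",
    "augment_targets",
    "augment_compounds",
    "balance_dataset",
]

#: Sentinel year carried by putative rows so time-splitting can never
#: mistake them for measured validation data.
AUGMENTED_YEAR = -1


class BalanceParams(BaseModel):
    """Knobs of the augmentation stage (defaults follow the reference
    settings: g=3, m=0.4, skew trigger 2:1, three PN compounds per
    cluster)."""

    g: float = Field(default=3.0, gt=0)
    m: float = Field(default=0.4, gt=0, lt=1)
    skew_trigger: float = Field(default=2.0, ge=1)
    max_per_cluster: int = Field(default=3, ge=1)
    seed: int = 0
    eligibility_mode: str = Field(default="tiered", pattern="^(tiered|interaction_free)$")
    compound_trigger: float | None = None  # None: every eligible compound


def rectified_half_sigmoid(x: float, g: float = 3.0, m: float = 0.4) -> float:
    """Map an imbalance measure to a post-sampling negative ratio.

    Identity above its sigmoid branch (so balanced entities stay
    unchanged), smoothly upweighted below; fixed point alpha(1) = 1.
    """
    xf = float(x)
    if not math.isfinite(xf):
        raise InputError(f"x must be finite, got {x!r}")
    if xf < 0:
        raise InputError(f"x must be non-negative, got {x!r}")
    sig = (2.0 - 2.0 * m) / (1.0 + math.exp(-g * (xf - 1.0))) + m
    return max(xf, sig)


def pn_quota(alpha: float, n_pos: int, n_neg: int) -> int:
    """Number of putative negatives needed: round-half-up of
    ``alpha * N_P - N_N``, clamped at zero."""
    if n_pos < 0 or n_neg < 0:
        raise InputError("counts must be non-negative")
    raw = float(alpha) * n_pos - n_neg
    return max(0, int(math.floor(raw + 0.5)))


def target_profiles(
    interactions: pd.DataFrame, g: float = 3.0, m: float = 0.4
) -> pd.DataFrame:
    """Per-target label counts, negative prevalence x, alpha and PN quota.

    Targets with no records are absent; the quota is zero whenever
    negatives already match or outnumber positives.
    """
    grouped = interactions.groupby("target_id")["label"]
    n_pos = grouped.apply(lambda s: int((s == "positive").sum()))
    n_neg = grouped.apply(lambda s: int((s == "negative").sum()))
    prof = pd.DataFrame({"N_P": n_pos, "N_N": n_neg})
    total = prof["N_P"] + prof["N_N"]
    prof = prof.loc[total > 0]
    prof["x"] = prof["N_N"] / (prof["N_P"] + prof["N_N"])
    prof["alpha"] = [rectified_half_sigmoid(x, g, m) for x in prof["x"]]
    prof["N_PN"] = [
        pn_quota(a, p, n) for a, p, n in zip(prof["alpha"], prof["N_P"], prof["N_N"])
    ]
    return prof.reset_index()


def compound_profiles(
    interactions: pd.DataFrame, g: float = 3.0, m: float = 0.4
) -> pd.DataFrame:
    """Per-compound counts with x = negative-to-positive ratio.

    Compounds without a positive record are excluded (their ratio is
    undefined and they never receive PN targets).
    """
    grouped = interactions.groupby("compound_id")["label"]
    n_pos = grouped.apply(lambda s: int((s == "positive").sum()))
    n_neg = grouped.apply(lambda s: int((s == "negative").sum()))
    prof = pd.DataFrame({"N_P": n_pos, "N_N": n_neg})
    prof = prof.loc[prof["N_P"] > 0]
    prof["x"] = prof["N_N"] / prof["N_P"]
    prof["alpha"] = [rectified_half_sigmoid(x, g, m) for x in prof["x"]]
    prof["N_PN"] = [
        pn_quota(a, p, n) for a, p, n in zip(prof["alpha"], prof["N_P"], prof["N_N"])
    ]
    return prof.reset_index()


@dataclass(frozen=True)
class ClusterEligibility:
    """Clusters a target may draw PN compounds from, split into a
    preferred tier (clusters whose recorded interactions are all
    positive) and the remaining interaction-free-for-this-target tier."""

    tier1: frozenset
    tier2: frozenset

    @property
    def all_eligible(self) -> frozenset:
        return self.tier1 | self.tier2

    def __contains__(self, cluster_id) -> bool:
        return cluster_id in self.tier1 or cluster_id in self.tier2


def eligible_clusters(
    target_id: str,
    interactions: pd.DataFrame,
    cluster_of_compound: Mapping,
    all_clusters,
    mode: str = "tiered",
) -> ClusterEligibility:
    """Clusters with zero recorded interactions against ``target_id``.

    ``mode="tiered"`` prefers clusters whose dataset-wide records are
    all positive (tier 1) over merely target-free clusters (tier 2);
    ``mode="interaction_free"`` restricts eligibility to clusters with
    no recorded interactions at all.
    """
    clusters = pd.Series(
        [cluster_of_compound[c] for c in interactions["compound_id"]],
        index=interactions.index,
    )
    touched = set(clusters[interactions["target_id"] == target_id])
    free = set(all_clusters) - touched
    by_cluster = interactions.groupby(clusters)["label"]
    has_negative = set(by_cluster.apply(lambda s: bool((s == "negative").any()))
                       .loc[lambda s: s].index)
    has_any = set(by_cluster.size().index)
    if mode == "interaction_free":
        return ClusterEligibility(frozenset(free - has_any), frozenset())
    if mode != "tiered":
        raise InputError(f"unknown eligibility mode {mode!r}")
    tier1 = {c for c in free if c in has_any and c not in has_negative}
    tier2 = free - tier1
    return ClusterEligibility(frozenset(tier1), frozenset(tier2))


def eligible_families(compound_id: str, interactions: pd.DataFrame) -> set[str]:
    """Protein families with no recorded interaction for the compound."""
    touched = set(interactions.loc[interactions["compound_id"] == compound_id, "family"])
    return set(FAMILIES) - touched


def _pn_row(compound_id, target_id, cluster_id, family) -> dict:
    return {
        "compound_id": compound_id,
        "target_id": target_id,
        "label": "negative",
        "provenance": "putative",
        "year": AUGMENTED_YEAR,
        "family": family,
        "cluster_id": cluster_id,
    }


def sample_pn_compounds(
    target_id: str,
    quota: int,
    eligibility: ClusterEligibility,
    compound_pool: pd.DataFrame,
    target_family: str,
    max_per_cluster: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw up to ``quota`` PN compounds for one target.

    Clusters are visited round-robin in seeded random order (tier-1
    clusters ahead of tier 2) taking one compound per cluster per round,
    at most ``max_per_cluster`` from any cluster — cluster diversity
    first, depth second. A shortfall emits a warning, not an error.
    """
    if quota < 0:
        raise InputError("quota must be non-negative")
    cols = INTERACTION_COLUMNS + ["cluster_id"]
    if quota == 0:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(seed)
    pool = compound_pool.sort_values("compound_id", kind="mergesort")
    members: dict = {}
    for cid, grp in pool.groupby("cluster_id"):
        if cid in eligibility:
            ids = grp["compound_id"].to_numpy()
            members[cid] = ids[rng.permutation(len(ids))]
    order = [c for c in sorted(members) if c in eligibility.tier1]
    order += [c for c in sorted(members) if c in eligibility.tier2]
    order = list(np.asarray(order, dtype=object)[rng.permutation(len(order))]) if order else []
    # Stable partition back into tiers after the shuffle.
    order = [c for c in order if c in eligibility.tier1] + [
        c for c in order if c in eligibility.tier2
    ]
    rows: list[dict] = []
    for round_i in range(max_per_cluster):
        if len(rows) >= quota:
            break
        for cid in order:
            if len(rows) >= quota:
                break
            bucket = members[cid]
            if round_i < len(bucket):
                rows.append(_pn_row(bucket[round_i], target_id, cid, target_family))
    if len(rows) < quota:
        warnings.warn(
            f"PN shortfall for target {target_id!r}: wanted {quota}, sampled {len(rows)}",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=cols)


def sample_pn_targets(
    compound_id: str,
    quota: int,
    interactions: pd.DataFrame,
    family_of_target: Mapping[str, str],
    cluster_id,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw up to ``quota`` PN targets for one compound, restricted to
    protein families the compound has no recorded interaction with."""
    cols = INTERACTION_COLUMNS + ["cluster_id"]
    families = eligible_families(compound_id, interactions)
    if quota == 0 or not families:
        return pd.DataFrame(columns=cols)
    candidates = sorted(
        t for t, fam in family_of_target.items() if fam in families
    )
    if not candidates:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(seed)
    take = min(quota, len(candidates))
    picked = rng.choice(np.asarray(candidates, dtype=object), size=take, replace=False)
    if take < quota:
        warnings.warn(
            f"PN-target shortfall for compound {compound_id!r}: wanted {quota}, sampled {take}",
            stacklevel=2,
        )
    return pd.DataFrame(
        [_pn_row(compound_id, t, cluster_id, family_of_target[t]) for t in picked],
        columns=cols,
    )


def augment_targets(
    interactions: pd.DataFrame,
    cluster_of_compound: Mapping,
    compound_pool: pd.DataFrame,
    params: BalanceParams,
    family_of_target: Mapping[str, str],
) -> pd.DataFrame:
    """Stage 1: PN-compound rows for skewed targets (returned separately,
    not yet appended).

    A target qualifies when it has no negatives at all or its
    positive:negative ratio reaches ``params.skew_trigger``; its quota
    comes from the rectified half sigmoid of its negative prevalence.
    """
    all_clusters = sorted(set(cluster_of_compound.values()))
    prof = target_profiles(interactions, params.g, params.m).set_index("target_id")
    additions: list[pd.DataFrame] = []
    for tid, row in prof.sort_index().iterrows():
        if row["N_PN"] <= 0:
            continue
        skewed = row["N_N"] == 0 or (
            row["N_N"] > 0 and row["N_P"] / row["N_N"] >= params.skew_trigger
        )
        if not skewed:
            continue
        elig = eligible_clusters(
            tid, interactions, cluster_of_compound, all_clusters,
            mode=params.eligibility_mode,
        )
        pns = sample_pn_compounds(
            tid,
            int(row["N_PN"]),
            elig,
            compound_pool,
            target_family=family_of_target.get(tid, "Others"),
            max_per_cluster=params.max_per_cluster,
            seed=derive_seed(params.seed, f"pn_compounds:{tid}") % (2**32),
        )
        if not pns.empty:
            additions.append(pns)
    cols = INTERACTION_COLUMNS + ["cluster_id"]
    if not additions:
        return pd.DataFrame(columns=cols)
    return pd.concat(additions, ignore_index=True)[cols]


def augment_compounds(
    interactions: pd.DataFrame,
    cluster_of_compound: Mapping,
    params: BalanceParams,
    family_of_target: Mapping[str, str],
) -> pd.DataFrame:
    """Stage 2: PN-target rows for compounds holding a positive record,
    drawn from protein families the compound never touched (returned
    separately, not yet appended)."""
    cprof = compound_profiles(interactions, params.g, params.m).set_index("compound_id")
    additions: list[pd.DataFrame] = []
    for cid, row in cprof.sort_index().iterrows():
        if row["N_PN"] <= 0:
            continue
        if params.compound_trigger is not None:
            skewed = row["N_N"] == 0 or row["N_P"] / row["N_N"] >= params.compound_trigger
            if not skewed:
                continue
        pns = sample_pn_targets(
            cid,
            int(row["N_PN"]),
            interactions,
            family_of_target,
            cluster_id=cluster_of_compound.get(cid),
            seed=derive_seed(params.seed, f"pn_targets:{cid}") % (2**32),
        )
        if not pns.empty:
            additions.append(pns)
    cols = INTERACTION_COLUMNS + ["cluster_id"]
    if not additions:
        return pd.DataFrame(columns=cols)
    return pd.concat(additions, ignore_index=True)[cols]


def balance_dataset(
    interactions: pd.DataFrame,
    cluster_of_compound: Mapping,
    compound_pool: pd.DataFrame,
    params: BalanceParams | None = None,
    family_of_target: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Append PN rows in two stages; measured rows pass through untouched.

    Stage 1 (:func:`augment_targets`) uses ``compound_pool`` (columns
    ``compound_id``/``cluster_id``; pass the drug-like pool) as the PN
    compound source. Stage 2 (:func:`augment_compounds`) recomputes
    compound quotas on the stage-1-augmented table, so target-level
    corrections are not double-counted.
    """
    params = params or BalanceParams()
    if "cluster_id" not in interactions.columns:
        raise InputError("interactions must carry cluster_id before balancing")
    base = interactions.copy()
    if family_of_target is None:
        family_of_target = dict(zip(base["target_id"], base["family"]))

    stage1_added = augment_targets(
        base, cluster_of_compound, compound_pool, params, family_of_target
    )
    stage1 = (
        pd.concat([base, stage1_added], ignore_index=True) if len(stage1_added) else base
    )
    stage2_added = augment_compounds(stage1, cluster_of_compound, params, family_of_target)
    out = (
        pd.concat([stage1, stage2_added], ignore_index=True) if len(stage2_added) else stage1
    )
    return out.reset_index(drop=True)
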