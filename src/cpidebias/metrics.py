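"""Bias diagnostics and virtual-screening evaluation metrics.

Includes per-entity positive prevalence, the Truchon-Bayly early
recognition metric BEDROC, enrichment factors at a top fraction,
top-decile score summaries, and coverage/IoU of high-attention residues
against binding-pocket masks.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from ._errors import DegenerateInputError, InputError

__all__ = [
    "positive_prevalence",
    "rank_actives",
    "bedroc",
    "enrichment_factor",
    "top_decile_scores",
    "attention_pocket_eval",
]


def positive_prevalence(interactions: pd.DataFrame, by: str = "target") -> pd.Series:
    """Fraction of positive rows per target (``by="target"``) or per
    compound cluster (``by="cluster"``)."""
    key = {"target": "target_id", "cluster": "cluster_id"}.get(by)
    if key is None:
        raise InputError(f"'by' must be 'target' or 'cluster', got {by!r}")
    pos = interactions["label"] == "positive"
    return pos.groupby(interactions[key]).mean()


def _validated_screen(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise InputError("scores and labels must be 1-D vectors of equal length")
    if not np.isfinite(s).all():
        raise InputError("scores must be finite")
    y = y.astype(int)
    if not np.isin(y, (0, 1)).all():
        raise InputError("labels must be binary (0/1)")
    if y.sum() == 0 or y.sum() == len(y):
        raise DegenerateInputError("need at least one active and one inactive")
    return s, y


def rank_actives(scores, labels, seed: int = 0) -> np.ndarray:
    """1-based ranks of the actives after sorting by descending score.

    Ties are broken by a seeded random shuffle applied before the stable
    sort, so tied items get an unbiased yet reproducible order.
    """
    s, y = _validated_screen(scores, labels)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(s))
    order = perm[np.argsort(-s[perm], kind="stable")]
    ranked_labels = y[order]
    return np.flatnonzero(ranked_labels == 1) + 1


def _rie_numerator(ranks: np.ndarray, n_total: int, alpha: float) -> float:
    return float(np.exp(-alpha * ranks / n_total).sum())


def bedroc(scores, labels, alpha: float = 80.5, seed: int = 0) -> float:
    """Boltzmann-enhanced discrimination of ROC.

    The exponentially weighted active-rank sum (the RIE numerator) is
    min-max normalized between its value for the worst possible ranking
    (actives last) and the best (actives first), so a perfect screen
    scores exactly 1 and the worst scores exactly 0.
    """
    ranks = rank_actives(scores, labels, seed=seed)
    n_total = len(np.asarray(scores))
    n_act = len(ranks)
    observed = _rie_numerator(ranks, n_total, alpha)
    best = _rie_numerator(np.arange(1, n_act + 1), n_total, alpha)
    worst = _rie_numerator(np.arange(n_total - n_act + 1, n_total + 1), n_total, alpha)
    return (observed - worst) / (best - worst)


def enrichment_factor(scores, labels, fraction: float = 0.01, seed: int = 0) -> float:
    """Actives captured in the top ``fraction`` of the ranked list,
    relative to random expectation at the global active rate."""
    if not (0 < fraction <= 1):
        raise InputError(f"fraction must be in (0, 1], got {fraction!r}")
    s, y = _validated_screen(scores, labels)
    n = len(s)
    top_n = math.ceil(fraction * n)
    ranks = rank_actives(s, y, seed=seed)
    hits = int((ranks <= top_n).sum())
    expected_rate = y.sum() / n
    return (hits / top_n) / expected_rate


def top_decile_scores(
    scores: pd.DataFrame,
    entity_col: str = "entity",
    score_col: str = "score",
    decile: float = 0.10,
    min_items: int = 10,
) -> pd.DataFrame:
    """Per-entity median and quartiles of the top ``decile`` of scores.

    Entities with fewer than ``min_items`` scored items are skipped with
    a warning. Returns one row per surviving entity with columns
    ``entity, n_top, q1, median, q3``.
    """
    rows = []
    for entity, grp in scores.groupby(entity_col):
        vals = np.sort(grp[score_col].to_numpy(dtype=float))
        if len(vals) < min_items:
            warnings.warn(f"entity {entity!r} has {len(vals)} < {min_items} scores; skipped",
                          stacklevel=2)
            continue
        k = max(1, int(math.floor(decile * len(vals))))
        top = vals[-k:]
        q1, med, q3 = np.percentile(top, [25, 50, 75])
        rows.append({"entity": entity, "n_top": k, "q1": q1, "median": med, "q3": q3})
    return pd.DataFrame(rows, columns=["entity", "n_top", "q1", "median", "q3"])


def attention_pocket_eval(
    weights,
    pocket_mask,
    rule: str = "top_k",
    k: int | None = None,
    quantile: float | None = None,
) -> tuple[float, float]:
    """Coverage and IoU of high-attention residues vs a pocket mask.

    ``rule="top_k"`` selects the ``k`` highest-attention residues
    (default k = pocket size); ``rule="quantile"`` selects residues at
    or above the given weight quantile. Coverage is the fraction of
    pocket residues selected; IoU is intersection over union.
    """
    w = np.asarray(weights, dtype=float)
    mask = np.asarray(pocket_mask).astype(bool)
    if w.shape != mask.shape or w.ndim != 1:
        raise InputError("weights and pocket_mask must be 1-D vectors of equal length")
    if (w < 0).any() or not np.isfinite(w).all():
        raise InputError("attention weights must be finite and non-negative")
    if w.sum() == 0:
        raise DegenerateInputError("all-zero attention weights")
    if not mask.any():
        raise InputError("pocket mask selects no residues")

    if rule == "top_k":
        k_eff = int(mask.sum()) if k is None else int(k)
        # Stable index order on ties: lower residue index wins.
        selected = np.zeros_like(mask)
        selected[np.argsort(-w, kind="stable")[:k_eff]] = True
    elif rule == "quantile":
        if quantile is None:
            raise InputError("rule='quantile' needs a quantile")
        selected = w >= np.quantile(w, quantile)
    else:
        raise InputError(f"unknown selection rule {rule!r}")

    inter = int((selected & mask).sum())
    union = int((selected | mask).sum())
    coverage = inter / int(mask.sum())
    iou = inter / union if union else 0.0
    return coverage, iou
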