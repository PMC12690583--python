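"""Seeded synthetic compound-protein activity data.

Emulates the structure every pipeline stage assumes — compounds grouped
into planted chemical clusters (cluster-biased fingerprints recoverable
by k-means), targets spread over the six protein families, per-target
positive prevalence drawn from a skewed Beta distribution, record years
spanning a cutoff, plus injectable duplicate and conflicting records —
so the whole pipeline is testable without any external downloads.

Compounds carry explicit property fields and fingerprints rather than
SMILES, keeping chemistry toolkits out of the test path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .curation import FAMILIES

__all__ = ["SynthConfig", "generate_compounds", "generate_activity_table", "write_bundle"]


class SynthConfig(BaseModel):
    """Generator knobs; everything is driven by ``seed``."""

    n_targets: int = Field(default=200, ge=1)
    n_compounds: int = Field(default=5000, ge=1)
    n_clusters: int = Field(default=10, ge=1)
    fingerprint_len: int = Field(default=881, ge=8)
    prevalence_a: float = Field(default=5.0, gt=0)
    prevalence_b: float = Field(default=1.0, gt=0)
    records_per_target: tuple[int, int] = (50, 150)
    year_range: tuple[int, int] = (2000, 2020)
    conflict_rate: float = Field(default=0.0, ge=0, lt=1)
    duplicate_rate: float = Field(default=0.0, ge=0, lt=1)
    druglike_violation_rate: float = Field(default=0.0, ge=0, lt=1)
    signature_on_prob: float = 0.9
    background_on_prob: float = 0.05
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.n_clusters > self.n_compounds:
            raise ValueError("n_clusters must not exceed n_compounds")
        for lo, hi in (self.records_per_target, self.year_range):
            if lo > hi:
                raise ValueError("interval bounds out of order")
        return self


def generate_compounds(config: SynthConfig) -> pd.DataFrame:
    """Compound property table with planted cluster structure.

    Each cluster owns a disjoint block of signature bits switched on
    with high probability; background bits fire rarely, so the planted
    partition is recoverable from the fingerprints. The returned frame
    has columns ``compound_id, mol_weight, heavy_atoms, contains_metal,
    complexity_bits, fingerprint, planted_cluster`` (the last is ground
    truth for tests, not consumed by the pipeline).
    """
    rng = np.random.default_rng(config.seed)
    n, p, k = config.n_compounds, config.fingerprint_len, config.n_clusters
    planted = rng.integers(0, k, size=n)
    block = max(1, p // (2 * k))
    probs = np.full((n, p), config.background_on_prob)
    for c in range(k):
        start = c * block
        probs[planted == c, start : start + block] = config.signature_on_prob
    bits = (rng.random((n, p)) < probs).astype(np.uint8)

    mw = rng.uniform(200, 800, size=n)
    heavy = rng.integers(15, 61, size=n)
    metal = np.zeros(n, dtype=bool)
    n_bad = int(round(config.druglike_violation_rate * n))
    if n_bad:
        bad = rng.choice(n, size=n_bad, replace=False)
        kinds = rng.integers(0, 3, size=n_bad)
        metal[bad[kinds == 0]] = True
        mw[bad[kinds == 1]] = rng.uniform(1000, 1500, size=int((kinds == 1).sum()))
        heavy[bad[kinds == 2]] = rng.integers(1, 13, size=int((kinds == 2).sum()))

    width = len(str(n - 1))
    return pd.DataFrame(
        {
            "compound_id": [f"C{i:0{width}d}" for i in range(n)],
            "mol_weight": np.round(mw, 3),
            "heavy_atoms": heavy,
            "contains_metal": metal,
            "complexity_bits": bits.sum(axis=1).astype(int),
            "fingerprint": ["".join(map(str, row)) for row in bits],
            "planted_cluster": planted,
        }
    )


def generate_activity_table(config: SynthConfig, compounds: pd.DataFrame) -> pd.DataFrame:
    """Raw activity records consistent with the curation contract.

    Per-target positive prevalence is Beta(a, b); activity values are
    placed on the matching side of 1000 nM so generated labels and
    values never contradict each other — except for deliberately
    injected conflicts (opposite-label duplicates of existing pairs) and
    duplicates (same-label re-measurements in a different year), at the
    configured rates.
    """
    rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.records_per_target
    y0, y1 = config.year_range
    comp_ids = compounds["compound_id"].to_numpy()
    width = len(str(config.n_targets - 1))

    rows: list[dict] = []
    for t in range(config.n_targets):
        target_id = f"T{t:0{width}d}"
        family = FAMILIES[t % len(FAMILIES)]
        prevalence = rng.beta(config.prevalence_a, config.prevalence_b)
        n_rec = int(rng.integers(lo, hi + 1))
        n_rec = min(n_rec, len(comp_ids))
        chosen = rng.choice(comp_ids, size=n_rec, replace=False)
        positive = rng.random(n_rec) < prevalence
        # pChEMBL in [6.05, 10] for positives, [3, 5.95] for negatives:
        # clear of the 6.0 boundary so float round-trips cannot flip labels.
        pchembl = np.where(
            positive, rng.uniform(6.05, 10.0, n_rec), rng.uniform(3.0, 5.95, n_rec)
        )
        years = rng.integers(y0, y1 + 1, size=n_rec)
        for cid, pc, yr in zip(chosen, pchembl, years):
            rows.append(
                {
                    "compound_id": cid,
                    "target_id": target_id,
                    "family": family,
                    "activity_unit": "IC50",
                    "value_nM": float(10.0 ** (9.0 - pc)),
                    "year": int(yr),
                    "source": "synth",
                }
            )
    df = pd.DataFrame(rows)

    if config.duplicate_rate > 0:
        n_dup = int(round(config.duplicate_rate * len(df)))
        dup = df.sample(n=n_dup, random_state=np.random.RandomState(config.seed + 2)).copy()
        dup["source"] = "synth-dup"
        dup["year"] = rng.integers(y0, y1 + 1, size=len(dup))
        df = pd.concat([df, dup], ignore_index=True)

    if config.conflict_rate > 0:
        n_conf = int(round(config.conflict_rate * len(df)))
        conf = df.sample(n=n_conf, random_state=np.random.RandomState(config.seed + 3)).copy()
        was_positive = conf["value_nM"] <= 1000.0
        flipped = np.where(
            was_positive,
            10.0 ** (9.0 - rng.uniform(3.0, 5.95, len(conf))),
            10.0 ** (9.0 - rng.uniform(6.05, 10.0, len(conf))),
        )
        conf["value_nM"] = flipped
        conf["source"] = "synth-conflict"
        df = pd.concat([df, conf], ignore_index=True)

    return df.reset_index(drop=True)


def write_bundle(config: SynthConfig, out_dir) -> dict[str, Path]:
    """Generate and write ``compounds.csv`` and ``activity.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    compounds = generate_compounds(config)
    records = generate_activity_table(config, compounds)
    paths = {
        "compounds": out / "compounds.csv",
        "activity": out / "activity.csv",
        "config": out / "synth_config.json",
    }
    compounds.to_csv(paths["compounds"], index=False)
    records.to_csv(paths["activity"], index=False)
    paths["config"].write_text(config.model_dump_json(indent=2))
    return paths
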