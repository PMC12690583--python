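"""Curation of raw activity tables into deduplicated, conflict-free,
binary-labeled compound-protein interactions.

The raw input is one row per assay record with at least
``compound_id, target_id, family, activity_unit, value_nM, year, source``
and optionally ``smiles, assay_type, confidence``. Values must already be
in nanomolar; unit conversion is deliberately not silent (use
:func:`read_activity_table` options).

The curated output is one row per (compound, target) pair with columns
``compound_id, target_id, label, provenance, year, family`` where
``label`` is ``"positive"``/``"negative"`` and ``provenance`` is
``"measured"`` (putative rows are added later by the augmentation
stage).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._errors import InputError

__all__ = [
    "FAMILIES",
    "DEFAULT_ALLOWED_UNITS",
    "INTERACTION_COLUMNS",
    "compute_pchembl",
    "label_activity",
    "label_records",
    "filter_records",
    "filter_druglike",
    "druglike_mask",
    "remove_frequent_hitters",
    "resolve_conflicts",
    "curate",
    "compound_props_from_smiles",
    "read_activity_table",
    "read_blocklist",
]

#: Closed six-family vocabulary for protein targets.
FAMILIES = (
    "Kinase",
    "Nonkinase Enzyme",
    "Nuclear Receptor",
    "Membrane Receptor",
    "Ion Channel",
    "Others",
)

#: Activity units comparable on the pChEMBL scale.
DEFAULT_ALLOWED_UNITS = frozenset(
    {"Potency", "Ki", "Kd", "IC50", "AC50", "EC50", "ED50", "XC50"}
)

#: Canonical column order of a curated interaction table.
INTERACTION_COLUMNS = ["compound_id", "target_id", "label", "provenance", "year", "family"]

_REQUIRED_RAW = ["compound_id", "target_id", "family", "activity_unit", "value_nM", "year"]


def compute_pchembl(value_nM: float) -> float:
    """Negative base-10 log of a molar activity value given in nM.

    1000 nM maps to 6.0; 1 nM maps to 9.0.
    """
    v = float(value_nM)
    if not math.isfinite(v) or v <= 0:
        raise InputError(f"value_nM must be a positive finite number, got {value_nM!r}")
    return 9.0 - math.log10(v)


def label_activity(pchembl: float, threshold: float = 6.0) -> str:
    """Binary activity label; the threshold itself counts as positive."""
    p = float(pchembl)
    if not math.isfinite(p):
        raise InputError(f"pchembl must be finite, got {pchembl!r}")
    return "positive" if p >= threshold else "negative"


def label_records(records: pd.DataFrame, threshold: float = 6.0) -> pd.DataFrame:
    """Vectorized labeling: adds ``pchembl`` and ``label`` columns."""
    values = pd.to_numeric(records["value_nM"], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(values) | (values <= 0)):
        raise InputError("value_nM column contains non-positive or non-finite entries")
    out = records.copy()
    out["pchembl"] = 9.0 - np.log10(values)
    out["label"] = np.where(out["pchembl"] >= threshold, "positive", "negative")
    return out


def filter_records(
    records: pd.DataFrame,
    allowed_units: Iterable[str] = DEFAULT_ALLOWED_UNITS,
    min_confidence: int | None = None,
    allowed_assay_types: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Keep records whose unit is on the pChEMBL-comparable whitelist and,
    when the metadata columns exist, whose confidence / assay type pass.

    Records lacking the optional metadata columns pass those checks;
    unknown unit strings are silently dropped.
    """
    mask = records["activity_unit"].isin(set(allowed_units))
    if min_confidence is not None and "confidence" in records.columns:
        conf = pd.to_numeric(records["confidence"], errors="coerce")
        mask &= conf.isna() | (conf >= min_confidence)
    if allowed_assay_types is not None and "assay_type" in records.columns:
        at = records["assay_type"]
        mask &= at.isna() | at.isin(set(allowed_assay_types))
    return records.loc[mask].copy()


def filter_druglike(
    mol_weight: float,
    heavy_atoms: int,
    contains_metal: bool,
    max_mw: float = 1000.0,
    min_heavy: int = 12,
) -> bool:
    """Drug-likeness rule: no metal, MW strictly below ``max_mw`` Da and
    heavy-atom count strictly above ``min_heavy``."""
    for name, v in (("mol_weight", mol_weight), ("heavy_atoms", heavy_atoms),
                    ("contains_metal", contains_metal)):
        if v is None or (isinstance(v, float) and not math.isfinite(v)):
            raise InputError(f"missing or non-finite property {name!r}")
    return (not bool(contains_metal)) and float(mol_weight) < max_mw and int(heavy_atoms) > min_heavy


def druglike_mask(props: pd.DataFrame, max_mw: float = 1000.0, min_heavy: int = 12) -> pd.Series:
    """Vectorized :func:`filter_druglike` over a compound-properties table."""
    for col in ("mol_weight", "heavy_atoms", "contains_metal"):
        if col not in props.columns:
            raise InputError(f"compound properties missing column {col!r}")
        if props[col].isna().any():
            raise InputError(f"compound properties column {col!r} has missing values")
    return (
        ~props["contains_metal"].astype(bool)
        & (props["mol_weight"].astype(float) < max_mw)
        & (props["heavy_atoms"].astype(int) > min_heavy)
    )


def remove_frequent_hitters(
    records: pd.DataFrame,
    blocklist: Iterable[str],
    positives_only: bool = False,
) -> pd.DataFrame:
    """Drop records of blocklisted compounds (known aggregators /
    luciferase inhibitors) that have at least one positive record.

    By default every record of such a compound is removed, so that
    suspect negatives of the same compound do not survive either. With
    ``positives_only=True`` only the positive records are dropped.
    Requires a ``label`` column (run :func:`label_records` first).
    """
    block = set(blocklist)
    if not block:
        return records.copy()
    blocked = records["compound_id"].isin(block)
    positive = records["label"] == "positive"
    if positives_only:
        drop = blocked & positive
    else:
        suspects = set(records.loc[blocked & positive, "compound_id"])
        drop = records["compound_id"].isin(suspects)
    return records.loc[~drop].copy()


def resolve_conflicts(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse labeled records into one row per (compound, target) pair.

    Pairs observed with both labels across any sources are removed
    entirely. Duplicates with a single label collapse to one row
    retaining the earliest year (stable for later time-splitting). The
    result is independent of input row order.
    """
    df = records
    n_labels = df.groupby(["compound_id", "target_id"])["label"].transform("nunique")
    df = df.loc[n_labels == 1]
    sort_cols = ["compound_id", "target_id", "year"] + [
        c for c in ("source", "value_nM") if c in df.columns
    ]
    df = df.sort_values(sort_cols, kind="mergesort")
    df = df.drop_duplicates(subset=["compound_id", "target_id"], keep="first")
    out = df[["compound_id", "target_id", "label", "year", "family"]].copy()
    out["provenance"] = "measured"
    return out[INTERACTION_COLUMNS].reset_index(drop=True)


def curate(
    records: pd.DataFrame,
    props: pd.DataFrame | None = None,
    blocklist: Iterable[str] = (),
    allowed_units: Iterable[str] = DEFAULT_ALLOWED_UNITS,
    threshold: float = 6.0,
    min_confidence: int | None = None,
    allowed_assay_types: Iterable[str] | None = None,
    max_mw: float = 1000.0,
    min_heavy: int = 12,
    frequent_hitters_positives_only: bool = False,
) -> pd.DataFrame:
    """Full curation chain: unit/assay filter, drug-likeness filter,
    labeling, frequent-hitter removal, conflict resolution.

    ``props`` is an optional compound-properties table indexed by
    ``compound_id``; when absent the drug-likeness filter is skipped
    (properties are then assumed pre-filtered upstream).
    """
    missing = [c for c in _REQUIRED_RAW if c not in records.columns]
    if missing:
        raise InputError(f"raw activity table missing columns: {missing}")
    bad_family = set(records["family"]) - set(FAMILIES)
    if bad_family:
        raise InputError(f"unknown protein families: {sorted(bad_family)}")
    years = pd.to_numeric(records["year"], errors="coerce")
    if years.isna().any() or (years < 1900).any() or (years > 2100).any():
        raise InputError("year column must be integers in [1900, 2100]")

    df = filter_records(records, allowed_units, min_confidence, allowed_assay_types)
    if props is not None:
        keep = druglike_mask(props, max_mw=max_mw, min_heavy=min_heavy)
        druglike_ids = set(props.loc[keep, "compound_id"])
        df = df.loc[df["compound_id"].isin(druglike_ids)]
    df = label_records(df, threshold=threshold)
    df = remove_frequent_hitters(df, blocklist, positives_only=frequent_hitters_positives_only)
    return resolve_conflicts(df)


# -- optional chemistry adapter ---------------------------------------------

_METALS = frozenset(
    {3, 4, 11, 12, 13, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31,
     37, 38, 39, 40, 41, 42, 43, 44, 45, 46, 47, 48, 49, 50, 55, 56, 57, 72,
     73, 74, 75, 76, 77, 78, 79, 80, 81, 82, 83}
)


def compound_props_from_smiles(
    compound_id: str, smiles: str, n_bits: int = 881
) -> dict:
    """Compute a properties row (including a folded circular-substructure
    fingerprint) from a SMILES string. Requires RDKit."""
    from rdkit import Chem
    from rdkit.Chem import Descriptors, rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparseable SMILES for {compound_id!r}: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    wide = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048).GetFingerprint(mol)
    return {
        "compound_id": compound_id,
        "mol_weight": float(Descriptors.MolWt(mol)),
        "heavy_atoms": int(mol.GetNumHeavyAtoms()),
        "contains_metal": any(a.GetAtomicNum() in _METALS for a in mol.GetAtoms()),
        "complexity_bits": int(wide.GetNumOnBits()),
        "fingerprint": "".join(map(str, bits)),
    }


# -- I/O ---------------------------------------------------------------------

_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "µM": 1e3, "mM": 1e6, "pM": 1e-3, "M": 1e9}


def read_activity_table(
    path, sep: str = ",", convert_units_from: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Read a raw activity table from delimited text.

    ``convert_units_from`` optionally maps a ``value_unit`` column's
    molar units to nM multipliers (e.g. ``{"uM": 1e3}``); conversion is
    explicit, never guessed.
    """
    df = pd.read_csv(path, sep=sep)
    if convert_units_from is not None:
        if "value_unit" not in df.columns:
            raise InputError("unit conversion requested but no value_unit column present")
        factors = df["value_unit"].map(dict(convert_units_from))
        if factors.isna().any():
            unknown = sorted(set(df.loc[factors.isna(), "value_unit"]))
            raise InputError(f"no conversion factor for units: {unknown}")
        df["value_nM"] = df["value_nM"].astype(float) * factors
    return df


def read_blocklist(path) -> set[str]:
    """One compound id per line; blank lines and ``#`` comments ignored."""
    with open(path) as fh:
        return {
            line.strip() for line in fh
            if line.strip() and not line.lstrip().startswith("#")
        }
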