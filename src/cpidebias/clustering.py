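"""Chemical-space partitioning: complexity-stratified sampling, a
variance-targeted linear projection of bit fingerprints, and k-means.

Fingerprints are fixed-length bit vectors stored either as a dense
0/1 matrix or, in compound tables, as strings of '0'/'1' in a
``fingerprint`` column (text-friendly; see :func:`fingerprint_matrix`).
Any fixed-length substructure-key fingerprint works; nothing here
assumes a particular chemistry backend.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from ._errors import DegenerateInputError, InputError
from ._seeds import derive_seed

__all__ = [
    "ClusterModel",
    "fingerprint_matrix",
    "stratified_sample",
    "fit_projection",
    "fit_kmeans",
    "fit_cluster_model",
    "assign_cluster",
]

MODEL_FORMAT_VERSION = 1


def fingerprint_matrix(compounds: pd.DataFrame) -> np.ndarray:
    """Decode the ``fingerprint`` bit-string column into a uint8 matrix."""
    if "fingerprint" not in compounds.columns:
        raise InputError("compound table has no 'fingerprint' column")
    strings = compounds["fingerprint"].astype(str).to_numpy()
    lengths = {len(s) for s in strings}
    if len(lengths) != 1:
        raise InputError(f"inconsistent fingerprint lengths: {sorted(lengths)}")
    n_bits = lengths.pop()
    flat = np.frombuffer("".join(strings).encode("ascii"), dtype=np.uint8) - ord("0")
    return flat.reshape(len(strings), n_bits)


@dataclass
class ClusterModel:
    """Fitted projection basis plus K centroids.

    ``projection`` has shape (n_bits, d) with orthonormal columns;
    ``mean`` is the training column mean subtracted before projecting;
    ``centroids`` has shape (K, d).
    """

    mean: np.ndarray
    projection: np.ndarray
    explained_variance_fraction: float
    centroids: np.ndarray
    K: int
    seed: int
    variance_target: float = 0.95
    version: int = field(default=MODEL_FORMAT_VERSION)

    @property
    def n_bits(self) -> int:
        return self.projection.shape[0]

    @property
    def d(self) -> int:
        return self.projection.shape[1]

    def project(self, fingerprints: np.ndarray) -> np.ndarray:
        fp = np.asarray(fingerprints, dtype=float)
        if fp.ndim == 1:
            fp = fp[None, :]
        if fp.shape[1] != self.n_bits:
            raise InputError(
                f"fingerprint length {fp.shape[1]} does not match model basis {self.n_bits}"
            )
        return (fp - self.mean) @ self.projection

    def save(self, path) -> None:
        """Serialize to a single JSON archive (text, versioned)."""
        payload = {
            "version": self.version,
            "K": self.K,
            "seed": self.seed,
            "variance_target": self.variance_target,
            "explained_variance_fraction": self.explained_variance_fraction,
            "mean": self.mean.tolist(),
            "projection": self.projection.tolist(),
            "centroids": self.centroids.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ClusterModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("version") != MODEL_FORMAT_VERSION:
            raise InputError(f"unsupported cluster-model version: {payload.get('version')!r}")
        return cls(
            mean=np.asarray(payload["mean"], dtype=float),
            projection=np.asarray(payload["projection"], dtype=float),
            explained_variance_fraction=float(payload["explained_variance_fraction"]),
            centroids=np.asarray(payload["centroids"], dtype=float),
            K=int(payload["K"]),
            seed=int(payload["seed"]),
            variance_target=float(payload["variance_target"]),
        )


def stratified_sample(
    pool: pd.DataFrame, n_sample: int, n_classes: int = 100, seed: int = 0
) -> list[str]:
    """Sample compound ids preserving the substructure-complexity histogram.

    The pool is cut into ``n_classes`` equal-width classes over the
    observed range of ``complexity_bits`` (on-bit counts); empty classes
    simply draw nothing. Per-class draws follow largest-remainder
    proportional allocation, so each class's sampled count differs from
    the exact proportional share by less than one.
    """
    if n_sample > len(pool):
        raise InputError(f"n_sample={n_sample} exceeds pool size {len(pool)}")
    if "complexity_bits" not in pool.columns:
        raise InputError("pool has no 'complexity_bits' column")
    complexity = pool["complexity_bits"].astype(float)
    if complexity.nunique() == 1:
        classes = pd.Series(0, index=pool.index)
    else:
        classes = pd.cut(complexity, bins=n_classes, labels=False, include_lowest=True)
    counts = classes.value_counts().sort_index()
    exact = counts.to_numpy() * n_sample / len(pool)
    base = np.floor(exact).astype(int)
    remainder = n_sample - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:remainder]] += 1

    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    pool_ids = pool["compound_id"].to_numpy()
    for cls_idx, take in zip(counts.index, base):
        members = np.sort(pool_ids[(classes == cls_idx).to_numpy()])
        picked = rng.choice(members, size=take, replace=False)
        chosen.extend(picked.tolist())
    return chosen


def fit_projection(
    fingerprints: np.ndarray, variance_target: float = 0.95
) -> tuple[np.ndarray, np.ndarray, float]:
    """PCA basis truncated at the smallest dimension reaching the
    variance target.

    Returns ``(mean, projection, explained_variance_fraction)`` where
    ``projection`` is (n_bits, d). A numerically-zero spectrum (constant
    matrix) is rejected.
    """
    X = np.asarray(fingerprints, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("fit_projection needs a 2-D matrix with at least 2 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD directly: deterministic, and the spectrum gives exact variance ratios.
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 1e-12:
        raise DegenerateInputError("fingerprint matrix is constant; nothing to project")
    ratios = var / total
    cum = np.cumsum(ratios)
    # Tolerance so variance_target=1.0 lands on the numerical rank.
    d = int(np.searchsorted(cum, variance_target - 1e-9) + 1)
    return mean, vt[:d].T.copy(), float(cum[d - 1])


def fit_kmeans(
    projected: np.ndarray, K: int, seed: int = 0, max_iter: int = 300, n_init: int = 1
) -> tuple[np.ndarray, np.ndarray, float]:
    """Seeded k-means (k-means++ init, Lloyd iterations).

    Returns ``(centroids, labels, inertia)``. Deterministic under a
    fixed seed; empty clusters are re-seeded at high-cost points by the
    backend.
    """
    X = np.asarray(projected, dtype=float)
    if K > X.shape[0]:
        raise InputError(f"K={K} exceeds number of rows {X.shape[0]}")
    km = KMeans(n_clusters=K, random_state=seed, max_iter=max_iter, n_init=n_init)
    labels = km.fit_predict(X)
    return km.cluster_centers_, labels, float(km.inertia_)


def fit_cluster_model(
    fingerprints: np.ndarray,
    K: int,
    seed: int = 0,
    variance_target: float = 0.95,
    max_iter: int = 300,
) -> ClusterModel:
    """Projection + k-means in one step, on the same fingerprint sample."""
    mean, basis, evf = fit_projection(fingerprints, variance_target)
    km_seed = derive_seed(seed, "kmeans") % (2**32)
    centroids, _, _ = fit_kmeans(
        (np.asarray(fingerprints, dtype=float) - mean) @ basis, K, seed=km_seed, max_iter=max_iter
    )
    return ClusterModel(
        mean=mean,
        projection=basis,
        explained_variance_fraction=evf,
        centroids=centroids,
        K=K,
        seed=seed,
        variance_target=variance_target,
    )


def assign_cluster(fingerprints: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Nearest-centroid cluster ids in projected space; ties go to the
    lowest cluster id."""
    proj = model.project(fingerprints)
    # Squared Euclidean distances; argmin picks the lowest index on ties.
    d2 = (
        (proj**2).sum(axis=1)[:, None]
        - 2.0 * proj @ model.centroids.T
        + (model.centroids**2).sum(axis=1)[None, :]
    )
    return np.argmin(np.round(d2, 9), axis=1)
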