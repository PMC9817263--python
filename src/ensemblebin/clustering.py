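"""Length-weighted k-means++ with partial-seed initialization.

Seed contigs (carriers of a chosen single-copy gene) fix the first l
initial centers; the remaining K - l centers come from weighted D²
sampling. Seeds constrain initialization only — centers move freely
during Lloyd iterations. One bin number K, selected by silhouette on the
combined matrix, is shared by all twelve component runs (three
partial-seed runs plus one plain k-means++ run per feature track).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

from ensemblebin.features import FeatureSet
from ensemblebin.markers import SeedPlan

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 300
SILHOUETTE_SUBSAMPLE = 2000

FEATURE_TRACKS = ("combo", "cov", "com")
INIT_NAMES = ("Q1", "Q2", "Q3", "plain")


@dataclass
class Binning:
    """A disjoint labeling of (a subset of) contigs into bins."""

    assignment: dict[str, str]
    provenance: dict = field(default_factory=dict)

    @property
    def bins(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for contig, bin_id in self.assignment.items():
            out.setdefault(bin_id, set()).add(contig)
        return out

    @property
    def n_bins(self) -> int:
        return len(set(self.assignment.values()))

    def without_contigs(self, contigs: set[str]) -> "Binning":
        return Binning(
            assignment={c: b for c, b in self.assignment.items() if c not in contigs},
            provenance=dict(self.provenance),
        )


@dataclass
class KMeansResult:
    labels: np.ndarray
    centers: np.ndarray
    inertia: float
    n_iter: int
    inertia_history: list[float] = field(default_factory=list)


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from one master seed."""
    return np.random.default_rng([master_seed, zlib.crc32(name.encode("utf-8"))])


def weighted_kmeanspp_init(
    X: np.ndarray,
    weights: np.ndarray,
    K: int,
    fixed_centers: list[int] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """k-means++ initial centers with optional fixed (seeded) rows.

    The first l = len(fixed_centers) centers are exactly the indicated
    rows; the remaining K - l are drawn by D² sampling with probability
    proportional to weight × squared distance to the nearest chosen
    center. Points at distance 0 (or weight 0) are never sampled.
    """
    X = np.asarray(X, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n = X.shape[0]
    fixed = list(fixed_centers or [])
    if len(set(fixed)) != len(fixed):
        raise ValueError("fixed_centers must be distinct")
    if any(i < 0 or i >= n for i in fixed):
        raise ValueError("fixed center row index out of range")
    if K > n:
        raise ValueError(f"K={K} exceeds number of points {n}")
    if len(fixed) > K:
        raise ValueError("more fixed centers than K")
    if rng is None:
        rng = np.random.default_rng()

    chosen: list[int] = list(fixed)
    if not chosen:
        p = weights / weights.sum() if weights.sum() > 0 else np.full(n, 1.0 / n)
        chosen.append(int(rng.choice(n, p=p)))
    d2 = cdist(X, X[chosen], metric="sqeuclidean").min(axis=1)
    while len(chosen) < K:
        mass = weights * d2
        mass[chosen] = 0.0
        total = mass.sum()
        if total <= 0:
            # all remaining D² mass zero: uniform weighted fallback
            avail = np.ones(n, dtype=bool)
            avail[chosen] = False
            w = weights * avail
            if w.sum() <= 0:
                w = avail.astype(float)
            idx = int(rng.choice(n, p=w / w.sum()))
        else:
            idx = int(rng.choice(n, p=mass / total))
        chosen.append(idx)
        d2 = np.minimum(d2, cdist(X, X[[idx]], metric="sqeuclidean")[:, 0])
    return X[chosen].copy()


def _weighted_inertia(X, weights, centers, labels) -> float:
    diffs = X - centers[labels]
    return float(np.sum(weights * np.einsum("ij,ij->i", diffs, diffs)))


def weighted_lloyd(
    X: np.ndarray,
    weights: np.ndarray,
    init_centers: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> KMeansResult:
    """Weighted Lloyd iterations from the given initial centers.

    Alternates nearest-center assignment and weighted-mean updates until
    the maximum center displacement falls below ``tol``. An emptied
    cluster is re-seeded at the point with the largest weighted squared
    distance to its current center.
    """
    X = np.asarray(X, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(weights))):
        raise ValueError("non-finite entries in data or weights")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be >= 0 with positive sum")
    centers = np.array(init_centers, dtype=float, copy=True)
    k = centers.shape[0]
    labels = np.zeros(X.shape[0], dtype=int)
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = cdist(X, centers, metric="sqeuclidean")
        labels = d2.argmin(axis=1)
        # re-seed empty clusters at the worst-fit point
        for j in range(k):
            if not np.any(labels == j):
                resid = weights * d2[np.arange(len(labels)), labels]
                worst = int(np.argmax(resid))
                centers[j] = X[worst]
                labels[worst] = j
                d2[:, j] = cdist(X, centers[[j]], metric="sqeuclidean")[:, 0]
        history.append(_weighted_inertia(X, weights, centers, labels))
        new_centers = centers.copy()
        for j in range(k):
            mask = labels == j
            wsum = weights[mask].sum()
            if wsum > 0:
                new_centers[j] = np.average(X[mask], axis=0, weights=weights[mask])
            elif mask.any():
                new_centers[j] = X[mask].mean(axis=0)
        shift = np.abs(new_centers - centers).max() if k else 0.0
        centers = new_centers
        if shift < tol:
            break
    d2 = cdist(X, centers, metric="sqeuclidean")
    labels = d2.argmin(axis=1)
    inertia = _weighted_inertia(X, weights, centers, labels)
    history.append(inertia)
    return KMeansResult(
        labels=labels, centers=centers, inertia=inertia, n_iter=n_iter,
        inertia_history=history,
    )


def _run_kmeans(X, weights, K, fixed_rows, rng) -> KMeansResult:
    centers = weighted_kmeanspp_init(X, weights, K, fixed_rows, rng)
    return weighted_lloyd(X, weights, centers)


def select_bin_number(
    features: FeatureSet,
    plan: SeedPlan,
    rng: np.random.Generator,
) -> int:
    """Pick the candidate bin number with the best mean silhouette.

    Each candidate k is clustered on X_combo with plain weighted
    k-means++; the silhouette is computed unweighted on one shared
    uniform subsample of at most 2000 contigs. Ties break to the
    smallest k.
    """
    X = features.X_combo
    n = X.shape[0]
    candidates = [k for k in plan.candidate_ks if k < n]
    if not candidates:
        raise ValueError("no usable bin-number candidate below N")
    if len(candidates) == 1:
        return candidates[0]
    sub = np.arange(n)
    if n > SILHOUETTE_SUBSAMPLE:
        sub = np.sort(rng.choice(n, size=SILHOUETTE_SUBSAMPLE, replace=False))
    best_k, best_sil = None, -np.inf
    for k in candidates:
        result = _run_kmeans(X, features.lengths, k, None, rng)
        sub_labels = result.labels[sub]
        if len(set(sub_labels.tolist())) < 2:
            sil = -1.0
        else:
            sil = float(silhouette_score(X[sub], sub_labels, metric="euclidean"))
        logger.debug("bin-number candidate k=%d silhouette=%.4f", k, sil)
        if sil > best_sil:
            best_k, best_sil = k, sil
    return int(best_k)


def partial_seed_kmeans(
    X: np.ndarray,
    weights: np.ndarray,
    K: int,
    seed_contig_rows: list[int],
    rng: np.random.Generator,
    contig_ids: list[str],
    provenance: dict | None = None,
) -> Binning:
    """Cluster with the seed rows as fixed initial centers.

    With l seed rows and l >= K the run degenerates to seed k-means
    (K := l, nothing sampled); with l = 0 it reduces to plain weighted
    k-means++. Seeds only fix initialization — Lloyd moves all centers.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n = X.shape[0]
    if any(i < 0 or i >= n for i in seed_contig_rows):
        raise ValueError("seed contig row out of range")
    l = len(seed_contig_rows)
    k_eff = max(K, l)
    if k_eff > n:
        k_eff = n
    result = _run_kmeans(X, weights, k_eff, list(seed_contig_rows)[:k_eff], rng)
    assignment = {
        contig_ids[i]: f"k{int(label)}" for i, label in enumerate(result.labels)
    }
    prov = dict(provenance or {})
    prov.setdefault("K", k_eff)
    prov["n_seeds"] = l
    return Binning(assignment=assignment, provenance=prov)


def generate_component_binnings(
    features: FeatureSet,
    plan: SeedPlan,
    K: int,
    master_seed: int,
    length_weights: bool = True,
) -> list[Binning]:
    """The twelve component binnings: {combo, cov, com} × {Q1, Q2, Q3, plain}.

    Each run draws from its own named RNG substream of the master seed so
    ablations do not perturb one another. ``length_weights=False``
    reproduces the unweighted ablation (all contigs weigh 1).
    """
    row_of = features.row_index()
    weights = features.lengths if length_weights else np.ones(len(features.contig_ids))
    binnings: list[Binning] = []
    for track in FEATURE_TRACKS:
        X = features.matrix(track)
        for init, marker_q in zip(INIT_NAMES[:3], plan.seed_markers):
            rows = [row_of[c] for c in plan.seed_contigs[marker_q] if c in row_of]
            binning = partial_seed_kmeans(
                X,
                weights,
                K,
                rows,
                substream(master_seed, f"{track}/{init}"),
                features.contig_ids,
                provenance={
                    "feature": track,
                    "init": init,
                    "seed_marker": marker_q,
                    "seed": master_seed,
                },
            )
            binnings.append(binning)
        plain = partial_seed_kmeans(
            X,
            weights,
            K,
            [],
            substream(master_seed, f"{track}/plain"),
            features.contig_ids,
            provenance={"feature": track, "init": "plain", "seed": master_seed},
        )
        binnings.append(plain)
    return binnings
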