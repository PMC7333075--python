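"""DTW dissimilarity, k-medoids clustering and membership features.

The featurization pipeline for zone behaviour: standardize the four
channels of every subinterval in a zone, compute all pairwise dynamic
time warping (DTW) dissimilarities, cluster with k-medoids under restarts,
and represent each drive by its dissimilarity to every elected medoid —
a soft-clustering feature vector of width k per zone (k blanks where the
drive never visited the zone).

DTW here uses the classic dynamic program with steps (i-1,j), (i,j-1),
(i-1,j-1), Euclidean local cost across the four channels, and no warping
window.  By default the optimal warp cost is divided by the warping path
length so transit duration does not dominate the dissimilarity; pass
``normalized=False`` for the raw cost.  Ties in optimal cost are broken
toward the shorter path, making the normalized value well defined.

DTW does not satisfy the triangle inequality; nothing here assumes it.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .zone_partition import SUBINTERVAL_CHANNELS, Subinterval

__all__ = [
    "DissimilarityMatrix",
    "ClusterModel",
    "dtw",
    "dissimilarity_matrix",
    "standardize_subintervals",
    "k_medoids",
    "best_clustering",
    "cluster_zones",
    "membership_features",
    "summarize_clusters",
    "save_models",
    "load_models",
]


# ---------------------------------------------------------------------------
# DTW core

@njit(cache=True)
def _dtw_core(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Accumulated optimal warp cost and its path length (shortest on ties)."""
    n, m = a.shape[0], b.shape[0]
    nch = a.shape[1]
    acc = np.empty((n, m))
    plen = np.empty((n, m), dtype=np.int64)
    for i in range(n):
        for j in range(m):
            d = 0.0
            for c in range(nch):
                diff = a[i, c] - b[j, c]
                d += diff * diff
            d = math.sqrt(d)
            if i == 0 and j == 0:
                best = 0.0
                bl = 0
            elif i == 0:
                best = acc[0, j - 1]
                bl = plen[0, j - 1]
            elif j == 0:
                best = acc[i - 1, 0]
                bl = plen[i - 1, 0]
            else:
                best = acc[i - 1, j - 1]
                bl = plen[i - 1, j - 1]
                if acc[i - 1, j] < best or (acc[i - 1, j] == best and plen[i - 1, j] < bl):
                    best = acc[i - 1, j]
                    bl = plen[i - 1, j]
                if acc[i, j - 1] < best or (acc[i, j - 1] == best and plen[i, j - 1] < bl):
                    best = acc[i, j - 1]
                    bl = plen[i, j - 1]
            acc[i, j] = d + best
            plen[i, j] = bl + 1
    return acc[n - 1, m - 1], plen[n - 1, m - 1]


@njit(cache=True)
def _pairwise_dtw(stack: np.ndarray, lengths: np.ndarray,
                  normalized: bool) -> np.ndarray:
    """Condensed all-pairs DTW over a padded (n, Lmax, C) stack."""
    n = stack.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cost, pl = _dtw_core(stack[i, :lengths[i]], stack[j, :lengths[j]])
            v = cost / pl if normalized else cost
            out[i, j] = v
            out[j, i] = v
    return out


def dtw(a: Subinterval | np.ndarray, b: Subinterval | np.ndarray,
        normalized: bool = True) -> float:
    """DTW dissimilarity between two channel matrices.

    Symmetric, non-negative, and zero for identical sequences.  With
    ``normalized=True`` (default) the optimal aggregate cost is divided by
    the warping path length.
    """
    am = a.channels if isinstance(a, Subinterval) else np.asarray(a, dtype=float)
    bm = b.channels if isinstance(b, Subinterval) else np.asarray(b, dtype=float)
    if am.ndim == 1:
        am = am[:, None]
    if bm.ndim == 1:
        bm = bm[:, None]
    if am.shape[1] != bm.shape[1]:
        raise ValueError(
            f"channel count mismatch: {am.shape[1]} vs {bm.shape[1]}")
    cost, plen = _dtw_core(np.ascontiguousarray(am), np.ascontiguousarray(bm))
    return float(cost / plen) if normalized else float(cost)


@dataclass
class DissimilarityMatrix:
    """Symmetric non-negative pairwise dissimilarities with a zero diagonal."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids length must match matrix size")
        if np.any(v < 0):
            raise ValueError("dissimilarities must be non-negative")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def standardize_subintervals(
    subs: Sequence[Subinterval],
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[list[Subinterval], tuple[np.ndarray, np.ndarray]]:
    """Z-score each channel using pooled mean/SD over the given set.

    Without standardization the lane-offset channel (metres) would dominate
    the unit-interval pedal channels in the Euclidean local cost.  Channels
    with zero pooled SD are left unscaled.  Pass precomputed ``stats`` to
    reuse training-set scaling.
    """
    if stats is None:
        pooled = np.vstack([s.channels for s in subs])
        mean = pooled.mean(axis=0)
        sd = pooled.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
    else:
        mean, sd = stats
    out = [Subinterval(s.zone_id, s.drive_id, (s.channels - mean) / sd,
                       s.timestamps) for s in subs]
    return out, (mean, sd)


def dissimilarity_matrix(
    subs: Sequence[Subinterval], normalized: bool = True
) -> DissimilarityMatrix:
    """All-pairs DTW over one zone's subintervals (computed once, mirrored)."""
    if len(subs) < 2:
        raise ValueError("need at least 2 subintervals")
    zone_ids = {s.zone_id for s in subs}
    if len(zone_ids) != 1:
        raise ValueError(f"subintervals span multiple zones: {sorted(zone_ids)}")
    lengths = np.array([len(s) for s in subs], dtype=np.int64)
    lmax = int(lengths.max())
    nch = len(SUBINTERVAL_CHANNELS)
    stack = np.zeros((len(subs), lmax, nch))
    for i, s in enumerate(subs):
        stack[i, :len(s)] = s.channels
    values = _pairwise_dtw(stack, lengths, normalized)
    return DissimilarityMatrix(values=values, ids=[s.drive_id for s in subs])


# ---------------------------------------------------------------------------
# k-medoids

@dataclass
class ClusterModel:
    """A converged k-medoids model for one event zone.

    ``medoid_ids`` are indices into the dissimilarity matrix; ``assignment``
    maps each subinterval to a cluster in 0..k-1; ``inertia`` is the sum of
    squared dissimilarities to assigned medoids.  Per-cluster outcome
    summaries are attached by :func:`summarize_clusters`.
    """

    zone_id: int
    k: int
    medoid_ids: np.ndarray
    assignment: np.ndarray
    inertia: float
    ids: list[str]
    inertia_history: list[float] = field(default_factory=list)
    n_members: np.ndarray | None = None
    collision_rate: np.ndarray | None = None
    ore_score_mean: np.ndarray | None = None
    ore_score_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.medoid_ids = np.asarray(self.medoid_ids, dtype=int)
        self.assignment = np.asarray(self.assignment, dtype=int)
        if len(set(self.medoid_ids.tolist())) != self.k:
            raise ValueError("medoid indices must be k distinct values")
        for c, m in enumerate(self.medoid_ids):
            if self.assignment[m] != c:
                raise ValueError(f"medoid {m} not assigned to its own cluster {c}")
        if self.n_members is None:
            self.n_members = np.bincount(self.assignment, minlength=self.k)

    @property
    def medoid_drive_ids(self) -> list[str]:
        return [self.ids[m] for m in self.medoid_ids]


def _assign(D: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    # argmin takes the first minimum, i.e. the lowest medoid position on ties
    return np.argmin(D[:, medoids], axis=1)


def _inertia(D2: np.ndarray, medoids: np.ndarray, assign: np.ndarray) -> float:
    return float(D2[np.arange(len(assign)), medoids[assign]].sum())


def k_medoids(
    D: DissimilarityMatrix,
    k: int = 8,
    max_iter: int = 100,
    seed: int | np.random.Generator | None = 0,
    init: np.ndarray | None = None,
) -> ClusterModel:
    """Alternating k-medoids on a precomputed dissimilarity matrix.

    Each round assigns every subinterval to its nearest medoid, then elects
    within each cluster the member minimising the sum of squared
    dissimilarities to the other members — coordinate descent on the
    inertia — and stops when the inertia fails to decrease or after
    ``max_iter`` rounds.  Assignment ties break toward the lowest medoid
    position; election ties toward the lowest subinterval index.
    """
    n = D.n
    if n < k:
        raise ValueError(f"need at least k={k} subintervals, got {n}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    Dv = D.values
    D2 = Dv * Dv
    if init is None:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        medoids = np.sort(rng.choice(n, size=k, replace=False))
    else:
        medoids = np.asarray(init, dtype=int)
        if len(set(medoids.tolist())) != k:
            raise ValueError("init must contain k distinct indices")
    assign = _assign(Dv, medoids)
    inertia = _inertia(D2, medoids, assign)
    history = [inertia]
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue
            costs = D2[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(costs))]
        new_assign = _assign(Dv, new_medoids)
        new_inertia = _inertia(D2, new_medoids, new_assign)
        if new_inertia < inertia:
            medoids, assign, inertia = new_medoids, new_assign, new_inertia
            history.append(inertia)
        else:
            break
    # relabel clusters so each medoid is assigned to itself under ties:
    # a medoid is at distance 0 from itself, so argmin ties can only occur
    # with a duplicate subinterval; force self-assignment for medoids.
    for c, m in enumerate(medoids):
        assign[m] = c
    return ClusterModel(
        zone_id=getattr(D, "zone_id", 0) or 0,
        k=k, medoid_ids=medoids, assignment=assign, inertia=inertia,
        ids=list(D.ids), inertia_history=history,
    )


def best_clustering(
    D: DissimilarityMatrix,
    k: int = 8,
    restarts: int = 20,
    max_iter: int = 100,
    seed: int = 0,
) -> ClusterModel:
    """Minimum-inertia model over independent random initialisations.

    Each restart draws a uniform k-subset of indices from its own seed
    substream, so the result is deterministic given ``seed`` and
    non-increasing in ``restarts``.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    children = np.random.SeedSequence(seed).spawn(restarts)
    best: ClusterModel | None = None
    for child in children:
        model = k_medoids(D, k=k, max_iter=max_iter,
                          seed=np.random.default_rng(child))
        if best is None or model.inertia < best.inertia:
            best = model
    return best


def cluster_zones(
    D_by_zone: dict[int, DissimilarityMatrix],
    k: int = 8,
    restarts: int = 20,
    max_iter: int = 100,
    seed: int = 0,
) -> dict[int, ClusterModel]:
    """Cluster every zone; each zone gets an independent seed substream."""
    models: dict[int, ClusterModel] = {}
    for zone_id in sorted(D_by_zone):
        zone_seed = int(np.random.SeedSequence([seed, zone_id]).generate_state(1)[0]
                        % (2**31 - 1))
        model = best_clustering(D_by_zone[zone_id], k=k, restarts=restarts,
                                max_iter=max_iter, seed=zone_seed)
        model.zone_id = zone_id
        models[zone_id] = model
    return models


# ---------------------------------------------------------------------------
# Membership (soft-clustering) features

def membership_features(
    D_by_zone: dict[int, DissimilarityMatrix],
    models: dict[int, ClusterModel],
) -> pd.DataFrame:
    """Per-drive medoid-dissimilarity feature matrix.

    Columns are zone blocks in ascending zone id, ``zone{z}_m{j}`` for
    medoid j of zone z — width k x n_zones.  A drive that never visited a
    zone gets NaN for that zone's k entries; a drive whose subinterval *is*
    medoid j has a zero in that position.  Drives visiting no zone at all
    are dropped with a warning.
    """
    if set(D_by_zone) != set(models):
        raise ValueError("need one model per zone")
    all_ids: list[str] = []
    seen = set()
    for zone_id in sorted(D_by_zone):
        for did in D_by_zone[zone_id].ids:
            if did not in seen:
                seen.add(did)
                all_ids.append(did)
    blocks = []
    for zone_id in sorted(D_by_zone):
        D = D_by_zone[zone_id]
        model = models[zone_id]
        cols = [f"zone{zone_id}_m{j}" for j in range(model.k)]
        block = pd.DataFrame(np.nan, index=pd.Index(all_ids, name="drive_id"),
                             columns=cols)
        feat = D.values[:, model.medoid_ids]
        block.loc[D.ids, :] = feat
        blocks.append(block)
    out = pd.concat(blocks, axis=1)
    empty = out.isna().all(axis=1)
    if bool(empty.any()):
        warnings.warn(f"dropping {int(empty.sum())} drive(s) with no visited zone",
                      stacklevel=2)
        out = out.loc[~empty]
    return out


def summarize_clusters(
    model: ClusterModel,
    ore_scores: dict[str, int] | None = None,
    collision_flags: dict[str, bool] | None = None,
) -> ClusterModel:
    """Attach per-cluster membership counts, collision rates and score stats."""
    k = model.k
    n_members = np.bincount(model.assignment, minlength=k)
    coll = np.full(k, np.nan)
    mu = np.full(k, np.nan)
    sd = np.full(k, np.nan)
    for c in range(k):
        members = [model.ids[i] for i in np.flatnonzero(model.assignment == c)]
        if not members:
            continue
        if collision_flags is not None:
            flags = [bool(collision_flags.get(m, False)) for m in members]
            coll[c] = 100.0 * np.mean(flags)
        if ore_scores is not None:
            scores = np.array([ore_scores[m] for m in members if m in ore_scores])
            if scores.size:
                mu[c] = scores.mean()
                sd[c] = scores.std(ddof=1) if scores.size > 1 else 0.0
    model.n_members = n_members
    model.collision_rate = coll
    model.ore_score_mean = mu
    model.ore_score_sd = sd
    return model


# ---------------------------------------------------------------------------
# Model I/O

def save_models(models: dict[int, ClusterModel], path: str | Path) -> None:
    payload = {}
    for zone_id, m in sorted(models.items()):
        payload[str(zone_id)] = {
            "k": m.k,
            "medoid_indices": m.medoid_ids.tolist(),
            "medoid_drive_ids": m.medoid_drive_ids,
            "assignment": m.assignment.tolist(),
            "inertia": m.inertia,
            "ids": m.ids,
            "n_members": None if m.n_members is None else m.n_members.tolist(),
            "collision_rate": _optlist(m.collision_rate),
            "ore_score_mean": _optlist(m.ore_score_mean),
            "ore_score_sd": _optlist(m.ore_score_sd),
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def _optlist(arr: np.ndarray | None):
    if arr is None:
        return None
    return [None if (isinstance(v, float) and math.isnan(v)) else float(v)
            for v in arr.tolist()]


def load_models(path: str | Path) -> dict[int, ClusterModel]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for zone_id, m in payload.items():
        model = ClusterModel(
            zone_id=int(zone_id), k=m["k"],
            medoid_ids=np.array(m["medoid_indices"]),
            assignment=np.array(m["assignment"]),
            inertia=m["inertia"], ids=list(m["ids"]),
        )
        if m.get("n_members") is not None:
            model.n_members = np.array(m["n_members"])
        for key in ("collision_rate", "ore_score_mean", "ore_score_sd"):
            if m.get(key) is not None:
                setattr(model, key, np.array(
                    [np.nan if v is None else v for v in m[key]], dtype=float))
        out[int(zone_id)] = model
    return out
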