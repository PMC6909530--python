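"""Noise filtering, 3-way clustering and breakpoint refinement.

A candidate deletion region is curated in four steps:

1. the raw depth track is smoothed with a 61 bp sliding window into a
   trend-amplified score  f = gamma * mean / (sd + eps), assigned to the
   window centre (shrunken windows at the track edges);
2. each position becomes a point (f, -split_count, -discordant_count) —
   counts are negated so every component falls inside a deletion — and the
   points are clustered with k = 3 under a weighted even-power distance
   sqrt(sum_k eta_k |C_ik - C_jk|^p);
3. the cluster with the minimum mean feature value m = depth - split - disc
   is the putative deletion; a candidate is kept only when that cluster forms
   a largely contiguous block lying between the other clusters' positions;
4. the block's extreme positions are refined by pointers that walk one base
   at a time, comparing the per-position feature value m against the cluster
   mean, until they settle on the breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FILTER_WINDOW = 61  # sliding-window length for depth smoothing (bases)
RETRACT_RUN = 5     # consecutive sub-threshold positions confirming a breakpoint


@dataclass(frozen=True)
class DistanceParams:
    """Weights and exponent of the clustering distance."""

    eta: tuple[float, float, float] = (2.0, 1.0, 1.0)
    p: int = 2

    def __post_init__(self):
        if self.p <= 0 or self.p % 2 != 0:
            raise ValueError("p must be a positive even integer")
        # identity weights recover the plain Euclidean distance; the depth
        # weight is meant to be amplified (> 1) when clustering real tracks
        if self.eta[0] < 1.0:
            raise ValueError("depth weight eta[0] must be >= 1")
        if self.eta[1] != 1.0 or self.eta[2] != 1.0:
            raise ValueError("count weights eta[1], eta[2] must be 1")


@dataclass
class ClusterResult:
    """Three clusters ordered upstream/middle/downstream by median position."""

    positions: list[np.ndarray]        # genomic positions per cluster
    feature_means: np.ndarray          # mean m per cluster, shape (3,)
    labels: np.ndarray                 # cluster index per input point
    points: np.ndarray = field(repr=False, default=None)

    @property
    def min_index(self) -> int:
        return int(np.argmin(self.feature_means))

    @property
    def min_mean(self) -> float:
        return float(self.feature_means[self.min_index])


@dataclass(frozen=True)
class BreakpointEstimate:
    beta1: int
    beta2: int
    rho1: int
    rho2: int

    @property
    def interval(self) -> tuple[int, int]:
        """Refined deletion as a 0-based half-open interval."""
        return self.rho1, self.rho2 + 1


def filter_depth_track(depths: np.ndarray, gamma: float = 4.0,
                       eps: float = 1.0, window: int = FILTER_WINDOW) -> np.ndarray:
    """Smoothed, trend-amplified depth score per position.

    ``gamma`` scales the score onto the same order of magnitude as the split
    and discordant counts; ``eps`` keeps it finite where the window depth is
    constant (sd = 0).
    """
    depths = np.asarray(depths, dtype=np.float64)
    if depths.size < window:
        raise ValueError(f"track length {depths.size} shorter than the "
                         f"{window} bp filter window")
    s = pd.Series(depths)
    mean = s.rolling(window, center=True, min_periods=1).mean().to_numpy()
    sd = s.rolling(window, center=True, min_periods=1).std(ddof=0).to_numpy()
    return gamma * mean / (sd + eps)


def to_cluster_points(filtered_depth: np.ndarray, split: np.ndarray,
                      discordant: np.ndarray) -> np.ndarray:
    """Assemble (f, -split, -discordant) points, one row per position."""
    f = np.asarray(filtered_depth, dtype=np.float64)
    s = np.asarray(split, dtype=np.float64)
    d = np.asarray(discordant, dtype=np.float64)
    if not (f.shape == s.shape == d.shape):
        raise ValueError("feature tracks must have equal length")
    return np.column_stack([f, -s, -d])


def feature_values(depth: np.ndarray, split: np.ndarray,
                   discordant: np.ndarray) -> np.ndarray:
    """Per-position feature value m = depth - split - discordant (raw counts)."""
    return (np.asarray(depth, dtype=np.float64)
            - np.asarray(split, dtype=np.float64)
            - np.asarray(discordant, dtype=np.float64))


def feature_value(depth: float, split: float, discordant: float) -> float:
    return float(depth - split - discordant)


def weighted_distance(ci, cj, params: DistanceParams = DistanceParams()) -> float:
    """sqrt(sum_k eta_k |C_ik - C_jk|^p); Euclidean when eta=(1,..),p=2."""
    ci = np.asarray(ci, dtype=np.float64)
    cj = np.asarray(cj, dtype=np.float64)
    if ci.shape != cj.shape:
        raise ValueError("points must have equal dimension")
    eta = np.asarray(params.eta, dtype=np.float64)[:ci.size]
    return float(np.sqrt(np.sum(eta * np.abs(ci - cj) ** params.p)))


def _pairwise_cost(points: np.ndarray, centroids: np.ndarray,
                   params: DistanceParams) -> np.ndarray:
    """(n, k) matrix of sum_k eta |x - c|^p (monotone in the distance)."""
    eta = np.asarray(params.eta, dtype=np.float64)
    diff = np.abs(points[:, None, :] - centroids[None, :, :]) ** params.p
    return (diff * eta).sum(axis=2)


def kmeans3(points: np.ndarray, positions: np.ndarray,
            params: DistanceParams = DistanceParams(), seed: int = 0,
            restarts: int = 10, max_iter: int = 100,
            m_values: np.ndarray | None = None) -> ClusterResult:
    """Lloyd k-means with k=3 under the weighted distance.

    Farthest-point initialization, best of ``restarts`` seeded starts by
    within-cluster cost; assignment ties break toward the lowest cluster
    index.  Clusters come back ordered by median genomic position.
    ``m_values`` supplies the raw per-position feature values used for the
    cluster means (defaults to summing the point components).
    """
    points = np.asarray(points, dtype=np.float64)
    positions = np.asarray(positions, dtype=np.int64)
    n = points.shape[0]
    if np.unique(points, axis=0).shape[0] < 3:
        raise ValueError("need at least 3 distinct points for k=3 clustering")
    if m_values is None:
        m_values = points.sum(axis=1)

    best_labels, best_cost = None, np.inf
    for r in range(restarts):
        rng = np.random.default_rng(seed + r)
        centroids = _farthest_point_init(points, 3, rng, params)
        labels = np.zeros(n, dtype=np.int64)
        for _ in range(max_iter):
            cost = _pairwise_cost(points, centroids, params)
            new_labels = np.argmin(cost, axis=1)   # argmin takes lowest index on ties
            if np.array_equal(new_labels, labels) and _ > 0:
                break
            labels = new_labels
            for c in range(3):
                mask = labels == c
                if mask.any():
                    centroids[c] = points[mask].mean(axis=0)
                else:  # re-seed an emptied cluster at the worst-served point
                    worst = np.argmax(_pairwise_cost(points, centroids, params).min(axis=1))
                    centroids[c] = points[worst]
        total = float(_pairwise_cost(points, centroids, params).min(axis=1).sum())
        if total < best_cost - 1e-12:
            best_cost, best_labels = total, labels.copy()

    # order clusters upstream / middle / downstream by median position
    medians = []
    for c in range(3):
        pos_c = positions[best_labels == c]
        medians.append(np.median(pos_c) if pos_c.size else np.inf)
    order = np.argsort(medians, kind="stable")
    remap = np.empty(3, dtype=np.int64)
    remap[order] = np.arange(3)
    labels = remap[best_labels]

    pos_sets = [positions[labels == c] for c in range(3)]
    means = np.array([m_values[labels == c].mean() if (labels == c).any() else np.inf
                      for c in range(3)])
    return ClusterResult(positions=pos_sets, feature_means=means,
                         labels=labels, points=points)


def _farthest_point_init(points: np.ndarray, k: int, rng: np.random.Generator,
                         params: DistanceParams) -> np.ndarray:
    centroids = [points[int(rng.integers(points.shape[0]))]]
    while len(centroids) < k:
        cost = _pairwise_cost(points, np.array(centroids), params).min(axis=1)
        centroids.append(points[int(np.argmax(cost))])
    return np.array(centroids, dtype=np.float64)


def assess_candidate(result: ClusterResult, tau: float = 0.6) -> str:
    """Decide 'true_deletion' vs 'false_positive' from cluster geometry.

    The putative-deletion cluster (minimum mean feature value) must form a
    largely contiguous block sitting between the other clusters' positions:
    within the block's own span, at least a fraction ``tau`` of positions must
    belong to the cluster, and the flanking clusters must both have positions
    outside the block.  Interleaved or scattered minimum clusters — the
    fingerprint of clustering plain noise — are rejected.
    """
    smin = result.positions[result.min_index]
    others = [result.positions[c] for c in range(3) if c != result.min_index]
    if smin.size == 0 or any(o.size == 0 for o in others):
        return "false_positive"
    if tau <= 0:
        return "true_deletion"
    # occupancy of the cluster's central span; the 10/90% quantile trim keeps
    # ragged edges (cluster-boundary jitter at the breakpoints) from masking a
    # solid block, while scattered noise clusters stay near the region density
    q10, q90 = np.quantile(smin, [0.1, 0.9])
    core = smin[(smin >= q10) & (smin <= q90)]
    occupancy = core.size / max(q90 - q10 + 1, 1)
    # flanks must bracket the block (each side reachable by some other cluster)
    all_other = np.concatenate(others)
    brackets = (all_other.min() < smin.min()) and (all_other.max() > smin.max())
    return "true_deletion" if (occupancy >= tau and brackets) else "false_positive"


def refine_breakpoints(result: ClusterResult, m2_bar: float,
                       m_values: np.ndarray, region_start: int,
                       candidate: tuple[int, int] | None = None) -> BreakpointEstimate:
    """Walk pointers off the minimum-mean cluster's extremes to the breakpoints.

    beta1/beta2 are the extreme positions of the minimum-mean cluster.  Each
    pointer compares the raw feature value m at its position against the
    cluster mean m2_bar: where m < m2_bar the pointer is still inside
    deletion-like signal and extends outward one base at a time; where
    m >= m2_bar it has overshot into flank-like signal and retracts inward
    until it re-enters the deletion.  The two pointers move independently and
    halt at the region bounds.
    """
    smin = result.positions[result.min_index]
    if smin.size == 0:
        raise ValueError("minimum-mean cluster is empty; nothing to refine")
    beta1, beta2 = int(smin.min()), int(smin.max())
    lo = region_start
    hi = region_start + len(m_values) - 1
    below = np.asarray(m_values) < m2_bar

    def is_below(pos: int) -> bool:
        return bool(below[pos - region_start])

    def first_sustained(pos_range: np.ndarray) -> int | None:
        """First position in pos_range where `below` holds for `run` steps
        continuing in the range's direction (single-position dips are noise)."""
        run = min(RETRACT_RUN, len(pos_range))
        vals = below[pos_range - region_start]
        for i in range(len(pos_range)):
            j = min(i + run, len(vals))
            if vals[i:j].all() and (j - i) == run:
                return int(pos_range[i])
        return None

    rho1 = beta1
    if is_below(rho1):               # inside the deletion: extend outward (left)
        while rho1 > lo and is_below(rho1 - 1):
            rho1 -= 1
    else:                            # overshot into the flank: retract inward
        hit = first_sustained(np.arange(beta1, beta2 + 1))
        rho1 = hit if hit is not None else beta1

    rho2 = beta2
    if is_below(rho2):
        while rho2 < hi and is_below(rho2 + 1):
            rho2 += 1
    else:
        hit = first_sustained(np.arange(beta2, beta1 - 1, -1))
        rho2 = hit if hit is not None else beta2

    if rho1 > rho2:
        rho1, rho2 = beta1, beta2    # degenerate walk: fall back to the cluster span
    return BreakpointEstimate(beta1=beta1, beta2=beta2, rho1=rho1, rho2=rho2)


@dataclass
class CurationOutcome:
    verdict: str
    estimate: BreakpointEstimate | None
    result: ClusterResult


def curate_candidate(track, candidate: tuple[int, int],
                     gamma: float = 4.0, eps: float = 1.0,
                     params: DistanceParams = DistanceParams(),
                     tau: float = 0.6, seed: int = 0,
                     restarts: int = 10) -> CurationOutcome:
    """Run the full curation pipeline for one candidate over its feature track.

    ``track`` is a :class:`delcall.features.FeatureTrack` covering the
    candidate plus flanks.
    """
    f = filter_depth_track(track.depth, gamma=gamma, eps=eps)
    pts = to_cluster_points(f, track.split, track.discordant)
    m = feature_values(track.depth, track.split, track.discordant)
    positions = np.arange(track.start, track.end)
    try:
        result = kmeans3(pts, positions, params=params, seed=seed,
                         restarts=restarts, m_values=m)
    except ValueError:   # fewer than 3 distinct points: featureless region
        return CurationOutcome("false_positive", None, None)
    verdict = assess_candidate(result, tau=tau)
    estimate = None
    if verdict == "true_deletion":
        estimate = refine_breakpoints(result, result.min_mean, m,
                                      track.start, candidate=candidate)
    return CurationOutcome(verdict, estimate, result)
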