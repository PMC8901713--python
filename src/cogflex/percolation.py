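"""Targeted-attack robustness of weighted semantic networks.

The network is attacked by removing every link whose weight falls below
an increasing threshold.  The threshold starts at the smallest edge
weight and advances by the smallest positive difference between sorted
distinct weights; at each step the size of the largest connected
component (LCCS, recorded here as a fraction of n) is measured, and the
process stops before the first step whose largest component has fewer
than 3 nodes.  The percolation integral phi -- the sum of the recorded
LCCS values weighted by their thresholds -- summarizes how slowly the
network breaks apart.

Three null schemes attach inference to phi: leave-one-node-out,
leave-one-subject-out (both reusing the semantic-network machinery) and
link shuffling (weights permuted over a fixed topology, 10 random swaps
per link).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .semnet import WeightedNetwork, run_semnet_pipeline

__all__ = [
    "PercolationCurve",
    "PercolationResult",
    "percolation_curve",
    "percolation_integral",
    "percolate",
    "link_weight_shuffle",
    "ls_null",
    "percolation_lono",
    "percolation_loso",
]


@dataclass
class PercolationCurve:
    """LCCS fraction at each recorded weight threshold."""

    thresholds: np.ndarray
    lccs_fraction: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        l = np.asarray(self.lccs_fraction, dtype=float)
        if t.size != l.size:
            raise ValueError("thresholds and lccs_fraction must align")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if t.size > 1 and np.any(np.diff(l) > 1e-12):
            raise ValueError("lccs_fraction must be non-increasing")
        self.thresholds, self.lccs_fraction = t, l

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "lccs_fraction": self.lccs_fraction}
        )


@dataclass
class PercolationResult:
    integral_phi: float
    curve: PercolationCurve


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n
        self.max_size = 1 if n else 0

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        self.max_size = max(self.max_size, self.size[ra])


def _lcc_by_distinct_threshold(network: WeightedNetwork):
    """Largest-component size when only edges with weight >= w are kept,
    for each distinct edge weight w (computed once via reverse union-find)."""
    edges = network.edges()
    weights = np.array([w for _, _, w in edges])
    order = np.argsort(-weights)
    distinct = np.unique(weights)[::-1]  # descending
    uf = _UnionFind(network.n)
    lcc_at = {}
    k = 0
    for wv in distinct:
        while k < len(order) and weights[order[k]] >= wv:
            i, j, _ = edges[order[k]]
            uf.union(i, j)
            k += 1
        lcc_at[wv] = uf.max_size
    return distinct[::-1], lcc_at  # ascending distinct weights, lcc map


def percolation_curve(network: WeightedNetwork,
                      max_steps: int = 200_000) -> PercolationCurve:
    """Weight-threshold percolation curve of a connected weighted network.

    The threshold advances from the smallest weight by the smallest
    positive gap between distinct weights (gaps below 1e-9 are treated
    as duplicates, which also guards against floating-point noise in
    cosine weights).  If that resolution would need more than
    ``max_steps`` grid points, the resolution is coarsened to fit and a
    warning is emitted.  All-equal weights leave the resolution
    undefined; by convention a single-step curve at the common weight is
    returned.
    """
    if network.n < 3:
        raise ValueError("percolation needs at least 3 nodes")
    edges = network.edges()
    if not edges:
        raise ValueError("network has no positive-weight edges")
    n = network.n
    distinct_asc, lcc_at = _lcc_by_distinct_threshold(network)
    lcc_asc = np.array([lcc_at[w] for w in distinct_asc])

    # weights closer than 1e-9 are duplicates for resolution purposes
    gaps = np.diff(distinct_asc)
    gaps = gaps[gaps > 1e-9]
    w_min, w_max = distinct_asc[0], distinct_asc[-1]

    if gaps.size == 0:  # all weights equal: single-step curve by convention
        thresholds = np.array([w_min])
    else:
        resolution = float(gaps.min())
        span = w_max - w_min
        if span / resolution > max_steps:
            resolution = span / max_steps
            warnings.warn(
                f"threshold resolution coarsened to {resolution:.3g} to "
                f"stay within {max_steps} percolation steps")
        n_steps = int(np.floor(span / resolution + 1e-9)) + 1
        thresholds = w_min + resolution * np.arange(n_steps)

    # edges with weight < t are removed, i.e. keep weight >= t (float-safe)
    k = np.searchsorted(distinct_asc, thresholds - 1e-9, side="left")
    lccs = np.where(k < len(distinct_asc), lcc_asc[np.minimum(k, len(lcc_asc) - 1)], 1)
    below = np.flatnonzero(lccs < 3)
    stop = below[0] if below.size else len(thresholds)
    if stop == 0:
        raise ValueError("largest component below 3 nodes at the first threshold")
    return PercolationCurve(thresholds[:stop], lccs[:stop] / n)


def percolation_integral(
    curve: PercolationCurve, convention: str = "weighted_sum"
) -> float:
    """Percolation integral phi.

    Default is the threshold-weighted sum
    ``phi = sum_k lccs_k * threshold_k``; ``convention='trapezoid'``
    integrates the curve as an area under the curve instead.
    """
    if curve.thresholds.size == 0:
        warnings.warn("empty percolation curve; phi = 0")
        return 0.0
    if convention == "weighted_sum":
        return float(np.sum(curve.lccs_fraction * curve.thresholds))
    if convention == "trapezoid":
        if curve.thresholds.size == 1:
            return float(curve.lccs_fraction[0] * curve.thresholds[0])
        return float(np.trapezoid(curve.lccs_fraction, curve.thresholds))
    raise ValueError(f"unknown convention {convention!r}")


def percolate(
    network: WeightedNetwork, convention: str = "weighted_sum"
) -> PercolationResult:
    curve = percolation_curve(network)
    return PercolationResult(percolation_integral(curve, convention), curve)


def link_weight_shuffle(network: WeightedNetwork, seed: int = 0) -> WeightedNetwork:
    """Exchange weights between random edge pairs, topology fixed.

    10 swaps per link (10 x |E| total), each exchanging the weights of
    two distinct randomly chosen edges; the weight multiset and the
    binary adjacency structure are preserved exactly.
    """
    edges = network.edges()
    n_edges = len(edges)
    if n_edges < 2:
        raise ValueError("link shuffling needs at least 2 edges")
    rng = np.random.default_rng(seed)
    w_list = np.array([w for _, _, w in edges])
    n_swaps = 10 * n_edges
    idx_a = rng.integers(0, n_edges, size=n_swaps)
    idx_b = rng.integers(0, n_edges - 1, size=n_swaps)
    idx_b = np.where(idx_b >= idx_a, idx_b + 1, idx_b)  # distinct pair
    for a, b in zip(idx_a, idx_b):
        w_list[a], w_list[b] = w_list[b], w_list[a]
    new = np.zeros_like(network.weights)
    for (i, j, _), w in zip(edges, w_list):
        new[i, j] = new[j, i] = w
    adj = (network.adjacency.copy() if network.adjacency is not None else None)
    return WeightedNetwork(list(network.node_labels), new, adj)


def ls_null(
    network: WeightedNetwork,
    n_iter: int = 500,
    seed: int = 0,
    convention: str = "weighted_sum",
) -> np.ndarray:
    """Distribution of phi over ``n_iter`` link-shuffled networks."""
    rng = np.random.default_rng(seed)
    phis = np.empty(n_iter)
    for it in range(n_iter):
        shuffled = link_weight_shuffle(network, seed=int(rng.integers(2**31)))
        phis[it] = percolate(shuffled, convention).integral_phi
    return phis


def percolation_lono(
    network: WeightedNetwork, convention: str = "weighted_sum"
) -> tuple[list, np.ndarray]:
    """phi of each leave-one-node-out partial network.

    Returns (removed node labels, phi values); disconnected or degenerate
    partial networks are skipped with a warning.
    """
    ids, phis = [], []
    for label in network.node_labels:
        sub = network.subnetwork_without(label)
        try:
            phis.append(percolate(sub, convention).integral_phi)
            ids.append(label)
        except ValueError as exc:
            warnings.warn(f"percolation LONO iteration {label!r} skipped: {exc}")
    return ids, np.array(phis)


def percolation_loso(
    raw: pd.DataFrame,
    conditions: tuple[str, str],
    convention: str = "weighted_sum",
    participant_col: str = "participant_id",
    **pipeline_kwargs,
) -> dict[str, tuple[list, np.ndarray]]:
    """phi of each leave-one-subject-out re-run of the network pipeline."""
    participants = sorted(raw[participant_col].unique())
    out = {c: ([], []) for c in conditions}
    for p in participants:
        sub = raw[raw[participant_col] != p]
        try:
            nets = run_semnet_pipeline(sub, conditions,
                                       participant_col=participant_col,
                                       **pipeline_kwargs)
            phis = {c: percolate(nets[c], convention).integral_phi
                    for c in conditions}
        except ValueError as exc:
            warnings.warn(f"percolation LOSO iteration {p!r} skipped: {exc}")
            continue
        for c in conditions:
            out[c][0].append(p)
            out[c][1].append(phis[c])
    return {c: (ids, np.array(vals)) for c, (ids, vals) in out.items()}
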