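"""Group-level semantic networks from alternative-uses responses.

The pipeline mirrors standard practice in semantic-network research on
divergent-thinking data: free responses are normalized to canonical
tokens, encoded as a binary participants x unique-responses incidence
matrix per condition, restricted to responses given by at least two
participants in *both* conditions (matched node sets), turned into a
weighted network via pairwise cosine similarity of the participant
incidence vectors, denoised with the Triangulated Maximally Filtered
Graph (TMFG), and quantified after binarization with the clustering
coefficient (CC), average shortest path length (ASPL), modularity (Q,
Louvain) and small-worldness (S).

Inference attaches to the group-level statistics through two resampling
schemes: leave-one-node-out (LONO, metrics on the filtered network with
one node removed) and leave-one-subject-out (LOSO, the full pipeline
re-run without one participant).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .stats import ContingencyCounts

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseMatrix",
    "WeightedNetwork",
    "NetworkMetrics",
    "ResamplingDistribution",
    "preprocess_aut",
    "overlap_counts",
    "select_matched_responses",
    "cosine_network",
    "tmfg",
    "compute_metrics",
    "lono",
    "loso",
]


@dataclass
class ResponseMatrix:
    """Binary participants x unique-responses incidence matrix."""

    matrix: np.ndarray
    response_labels: list[str]
    participant_ids: list
    condition: str

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("incidence entries must be 0/1")
        if self.matrix.shape != (len(self.participant_ids), len(self.response_labels)):
            raise ValueError("matrix shape does not match labels/ids")
        if len(set(self.response_labels)) != len(self.response_labels):
            raise ValueError("response labels must be unique")

    @property
    def response_set(self) -> set[str]:
        return set(self.response_labels)


@dataclass
class WeightedNetwork:
    """Undirected weighted graph as a symmetric matrix with zero diagonal.

    ``adjacency`` is an optional boolean edge mask for graphs (such as
    TMFG output) that structurally retain edges whose weight happens to
    be zero; without it, any positive weight is an edge.
    """

    node_labels: list[str]
    weights: np.ndarray
    adjacency: Optional[np.ndarray] = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.node_labels), len(self.node_labels)):
            raise ValueError("weight matrix shape does not match labels")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.adjacency is not None:
            a = np.asarray(self.adjacency, dtype=bool)
            if a.shape != w.shape or not (a == a.T).all():
                raise ValueError("adjacency must be a symmetric boolean mask")
            a = a.copy()
            np.fill_diagonal(a, False)
            if ((w > 0) & ~a).any():
                raise ValueError("adjacency must cover all positive weights")
            self.adjacency = a

    @property
    def n(self) -> int:
        return len(self.node_labels)

    @property
    def edge_mask(self) -> np.ndarray:
        return self.adjacency if self.adjacency is not None else self.weights > 0

    def to_networkx(self, binarize: bool = False) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        mask = self.edge_mask
        idx = np.triu_indices(self.n, k=1)
        for i, j in zip(*idx):
            if mask[i, j]:
                if binarize:
                    g.add_edge(self.node_labels[i], self.node_labels[j])
                else:
                    g.add_edge(self.node_labels[i], self.node_labels[j],
                               weight=self.weights[i, j])
        return g

    def edges(self) -> list[tuple[int, int, float]]:
        i, j = np.triu_indices(self.n, k=1)
        mask = self.edge_mask[i, j]
        return list(zip(i[mask], j[mask], self.weights[i, j][mask]))

    def subnetwork_without(self, label: str) -> "WeightedNetwork":
        keep = [k for k, lab in enumerate(self.node_labels) if lab != label]
        if len(keep) == self.n:
            raise KeyError(f"node {label!r} not in network")
        sub = self.weights[np.ix_(keep, keep)]
        adj = (self.adjacency[np.ix_(keep, keep)]
               if self.adjacency is not None else None)
        return WeightedNetwork([self.node_labels[k] for k in keep], sub, adj)

    def to_edge_dataframe(self) -> pd.DataFrame:
        rows = [
            (self.node_labels[i], self.node_labels[j], w)
            for i, j, w in self.edges()
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])


@dataclass
class NetworkMetrics:
    """CC, ASPL, Q and S of a binarized network."""

    aspl: float
    cc: float
    q: float
    s: float

    def as_dict(self) -> dict:
        return {"aspl": self.aspl, "cc": self.cc, "q": self.q, "s": self.s}


@dataclass
class ResamplingDistribution:
    """Per-iteration metrics of a LONO or LOSO scheme.

    ``unit_ids`` names the removed node/participant of each retained
    iteration; iterations skipped (disconnected partial network, too few
    nodes) are listed in ``skipped``.
    """

    method: str
    unit_ids: list
    metrics: list[NetworkMetrics]
    skipped: list = field(default_factory=list)

    def values(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.metrics], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([m.as_dict() for m in self.metrics])
        df.insert(0, "unit_id", self.unit_ids)
        df.insert(0, "method", self.method)
        return df


# ---------------------------------------------------------------------------
# preprocessing

def preprocess_aut(
    raw: pd.DataFrame,
    normalization_map: Optional[dict[str, str]] = None,
    participant_col: str = "participant_id",
    condition_col: str = "condition",
    response_col: str = "response",
) -> dict[str, ResponseMatrix]:
    """Normalize response tokens and build one incidence matrix per condition.

    Tokens are lowercased and mapped through ``normalization_map``
    (identity by default; the hook for spell-checking/singularization).
    A participant giving the same token twice contributes a single 1.
    """
    if raw.empty:
        raise ValueError("empty response table")
    for col in (participant_col, condition_col, response_col):
        if col not in raw.columns:
            raise ValueError(f"missing column {col!r}")
    norm = normalization_map or {}
    df = raw[[participant_col, condition_col, response_col]].copy()
    tokens = df[response_col].astype(str).str.strip().str.lower()
    df[response_col] = tokens.map(lambda t: norm.get(t, t))
    df = df[df[response_col] != ""]

    participants = sorted(df[participant_col].unique())
    out: dict[str, ResponseMatrix] = {}
    for cond, sub in df.groupby(condition_col):
        labels = sorted(sub[response_col].unique())
        col_of = {lab: j for j, lab in enumerate(labels)}
        row_of = {p: i for i, p in enumerate(participants)}
        mat = np.zeros((len(participants), len(labels)), dtype=int)
        for p, tok in zip(sub[participant_col], sub[response_col]):
            mat[row_of[p], col_of[tok]] = 1
        out[str(cond)] = ResponseMatrix(mat, labels, list(participants), str(cond))
    return out


def overlap_counts(set_a: Iterable[str], set_b: Iterable[str]) -> ContingencyCounts:
    """Exclusive/shared token counts of two unique-response inventories."""
    a, b = set(set_a), set(set_b)
    return ContingencyCounts(
        discordant_a_only=len(a - b),
        discordant_b_only=len(b - a),
        concordant_both=len(a & b),
    )


def select_matched_responses(
    matrix_a: ResponseMatrix, matrix_b: ResponseMatrix, min_participants: int = 2
) -> tuple[ResponseMatrix, ResponseMatrix]:
    """Restrict both conditions to responses given by >= ``min_participants``
    participants in each condition, in identical column order."""
    counts_a = dict(zip(matrix_a.response_labels, matrix_a.matrix.sum(axis=0)))
    counts_b = dict(zip(matrix_b.response_labels, matrix_b.matrix.sum(axis=0)))
    keep = sorted(
        tok
        for tok in set(counts_a) & set(counts_b)
        if counts_a[tok] >= min_participants and counts_b[tok] >= min_participants
    )
    if len(keep) < 4:
        raise ValueError(
            f"only {len(keep)} matched responses survive the >= {min_participants}"
            "-participant threshold; at least 4 nodes are required for TMFG"
        )

    def restrict(m: ResponseMatrix) -> ResponseMatrix:
        cols = [m.response_labels.index(tok) for tok in keep]
        return ResponseMatrix(m.matrix[:, cols], keep, m.participant_ids, m.condition)

    return restrict(matrix_a), restrict(matrix_b)


def cosine_network(matrix: ResponseMatrix) -> WeightedNetwork:
    """Pairwise cosine similarity between response incidence vectors."""
    m = matrix.matrix.astype(float)
    norms = np.linalg.norm(m, axis=0)
    if (norms == 0).any():
        bad = [matrix.response_labels[j] for j in np.flatnonzero(norms == 0)]
        raise ValueError(f"all-zero response columns: {bad}")
    w = (m.T @ m) / np.outer(norms, norms)
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(list(matrix.response_labels), w)


# ---------------------------------------------------------------------------
# TMFG

def tmfg(network: WeightedNetwork) -> WeightedNetwork:
    """Triangulated Maximally Filtered Graph of a dense weighted network.

    Greedy construction: seed with a heavy 4-clique, then repeatedly
    insert the outside vertex whose connection to an existing triangular
    face adds the most weight, splitting that face in three.  The result
    is planar and connected with exactly 3(n - 2) edges; kept edges
    retain their original weights.
    """
    w = network.weights
    n = network.n
    if n < 4:
        raise ValueError("TMFG requires at least 4 nodes")
    if n == 4:
        adj4 = np.ones((4, 4), dtype=bool)
        np.fill_diagonal(adj4, False)
        return WeightedNetwork(list(network.node_labels), w.copy(), adj4)

    # greedy heavy 4-clique: heaviest edge, then twice the vertex with the
    # largest total weight into the current clique
    i, j = np.unravel_index(np.argmax(w), w.shape)
    clique = [int(i), int(j)]
    for _ in range(2):
        gain = w[clique].sum(axis=0)
        gain[clique] = -np.inf
        clique.append(int(np.argmax(gain)))

    in_graph = np.zeros(n, dtype=bool)
    in_graph[clique] = True
    adj = np.zeros((n, n), dtype=bool)
    for a in range(4):
        for b in range(a + 1, 4):
            adj[clique[a], clique[b]] = adj[clique[b], clique[a]] = True

    c0, c1, c2, c3 = clique
    faces = [(c0, c1, c2), (c0, c1, c3), (c0, c2, c3), (c1, c2, c3)]
    # gain[v, f] = weight added by attaching outside vertex v to face f
    gains = np.full((n, len(faces)), -np.inf)
    outside = ~in_graph
    for f, (a, b, c) in enumerate(faces):
        gains[outside, f] = w[outside, a] + w[outside, b] + w[outside, c]

    while not in_graph.all():
        v, f = np.unravel_index(np.argmax(gains), gains.shape)
        v = int(v)
        a, b, c = faces[f]
        in_graph[v] = True
        adj[v, [a, b, c]] = adj[[a, b, c], v] = True
        gains[v, :] = -np.inf
        outside = ~in_graph
        new_faces = [(v, a, b), (v, a, c), (v, b, c)]
        faces[f] = new_faces[0]
        col = w[:, v]
        if outside.any():
            gains[outside, f] = col[outside] + w[outside, a] + w[outside, b]
        for x, y, z in new_faces[1:]:
            faces.append((x, y, z))
            newcol = np.full(n, -np.inf)
            if outside.any():
                newcol[outside] = w[outside, x] + w[outside, y] + w[outside, z]
            gains = np.column_stack([gains, newcol])

    filtered = np.where(adj, w, 0.0)
    return WeightedNetwork(list(network.node_labels), filtered, adjacency=adj)


# ---------------------------------------------------------------------------
# topological quantifiers

@dataclass
class RandomBaseline:
    """Small-world normalization baseline.

    ``analytic`` uses the Erdos-Renyi closed forms
    CC_rand = 2m / (n(n-1)) and ASPL_rand = ln(n) / ln(2m/n); ``sampled``
    averages CC and ASPL over ``n_samples`` G(n, m) graphs.
    """

    kind: str = "analytic"
    n_samples: int = 20
    seed: int = 0


def _binary_graph(network: WeightedNetwork) -> nx.Graph:
    return network.to_networkx(binarize=True)


def compute_metrics(
    network: WeightedNetwork,
    rand_baseline: Optional[RandomBaseline] = None,
    cc_variant: str = "average_local",
    community_seed: int = 0,
) -> NetworkMetrics:
    """CC, ASPL, Q and S of the binarized network.

    CC is the mean local (Watts-Strogatz) clustering coefficient by
    default (``cc_variant='transitivity'`` for the global triangle
    ratio); ASPL is the unweighted mean shortest path length; Q is the
    modularity of the seeded Louvain partition; S is the
    Humphries-Gurney normalized small-worldness
    ``(CC / CC_rand) / (ASPL / ASPL_rand)``.
    """
    rand_baseline = rand_baseline or RandomBaseline()
    g = _binary_graph(network)
    if g.number_of_nodes() < 2:
        raise ValueError("metrics need at least 2 nodes")
    if not nx.is_connected(g):
        sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
        raise ValueError(f"graph is disconnected (component sizes {sizes})")

    if cc_variant == "average_local":
        cc = nx.average_clustering(g)
    elif cc_variant == "transitivity":
        cc = nx.transitivity(g)
    else:
        raise ValueError(f"unknown cc_variant {cc_variant!r}")
    aspl = nx.average_shortest_path_length(g)
    communities = nx.community.louvain_communities(g, seed=community_seed)
    q = nx.community.modularity(g, communities)

    n, m = g.number_of_nodes(), g.number_of_edges()
    if rand_baseline.kind == "analytic":
        cc_rand = 2.0 * m / (n * (n - 1))
        mean_deg = 2.0 * m / n
        aspl_rand = np.log(n) / np.log(mean_deg) if mean_deg > 1 else np.nan
    elif rand_baseline.kind == "sampled":
        rng = np.random.default_rng(rand_baseline.seed)
        ccs, aspls = [], []
        for _ in range(rand_baseline.n_samples):
            gr = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
            if not nx.is_connected(gr):
                gr = gr.subgraph(max(nx.connected_components(gr), key=len))
            ccs.append(nx.average_clustering(gr))
            aspls.append(nx.average_shortest_path_length(gr))
        cc_rand, aspl_rand = float(np.mean(ccs)), float(np.mean(aspls))
    else:
        raise ValueError(f"unknown baseline kind {rand_baseline.kind!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        s = (cc / cc_rand) / (aspl / aspl_rand)
    return NetworkMetrics(aspl=float(aspl), cc=float(cc), q=float(q), s=float(s))


# ---------------------------------------------------------------------------
# resampling

def lono(
    network: WeightedNetwork,
    rand_baseline: Optional[RandomBaseline] = None,
    community_seed: int = 0,
) -> ResamplingDistribution:
    """Leave-one-node-out on the already-filtered network.

    Each iteration computes the metrics on the induced subgraph with one
    node removed; iterations whose removal disconnects the graph are
    skipped with a warning.
    """
    if network.n < 5:
        raise ValueError("LONO needs at least 5 nodes")
    unit_ids, metrics, skipped = [], [], []
    for label in network.node_labels:
        sub = network.subnetwork_without(label)
        try:
            metrics.append(compute_metrics(sub, rand_baseline,
                                           community_seed=community_seed))
            unit_ids.append(label)
        except ValueError as exc:
            skipped.append(label)
            warnings.warn(f"LONO iteration {label!r} skipped: {exc}")
    return ResamplingDistribution("LONO", unit_ids, metrics, skipped)


def run_semnet_pipeline(
    raw: pd.DataFrame,
    conditions: tuple[str, str],
    normalization_map: Optional[dict[str, str]] = None,
    min_participants: int = 2,
    apply_tmfg: bool = True,
    **kwargs,
) -> dict[str, WeightedNetwork]:
    """Raw table -> matched, cosine-weighted, TMFG-filtered network per condition."""
    matrices = preprocess_aut(raw, normalization_map, **kwargs)
    for cond in conditions:
        if cond not in matrices:
            raise ValueError(f"condition {cond!r} absent from the table")
    ma, mb = select_matched_responses(
        matrices[conditions[0]], matrices[conditions[1]], min_participants
    )
    nets = {}
    for cond, m in zip(conditions, (ma, mb)):
        net = cosine_network(m)
        nets[cond] = tmfg(net) if apply_tmfg else net
    return nets


def loso(
    raw: pd.DataFrame,
    conditions: tuple[str, str],
    normalization_map: Optional[dict[str, str]] = None,
    min_participants: int = 2,
    rand_baseline: Optional[RandomBaseline] = None,
    community_seed: int = 0,
    participant_col: str = "participant_id",
    network_fn: Optional[Callable[[WeightedNetwork], float]] = None,
) -> dict[str, ResamplingDistribution]:
    """Leave-one-subject-out: the full pipeline re-run per left-out participant.

    The matched-response threshold is re-applied on every iteration, per
    the "repeat the pipeline" reading.  Returns one distribution per
    condition, paired across conditions by the removed participant id.
    """
    participants = sorted(raw[participant_col].unique())
    if len(participants) < 3:
        raise ValueError("LOSO needs at least 3 participants")
    dists = {c: ResamplingDistribution("LOSO", [], [], []) for c in conditions}
    for p in participants:
        sub = raw[raw[participant_col] != p]
        try:
            nets = run_semnet_pipeline(
                sub, conditions, normalization_map, min_participants,
                participant_col=participant_col,
            )
            mets = {
                c: compute_metrics(nets[c], rand_baseline,
                                   community_seed=community_seed)
                for c in conditions
            }
        except ValueError as exc:
            for c in conditions:
                dists[c].skipped.append(p)
            warnings.warn(f"LOSO iteration {p!r} skipped: {exc}")
            continue
        for c in conditions:
            dists[c].unit_ids.append(p)
            dists[c].metrics.append(mets[c])
    return dists
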