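"""Weighted gene-network clustering with gap-statistic model selection.

Hits are organized by building a confidence-weighted functional-association
network (e.g. a STRING edge-list export), embedding the connected genes
with the spectral coordinates of the symmetric normalized graph Laplacian,
and partitioning the embedding by k-means. The number of clusters k is
chosen with the gap statistic: within-cluster dispersion W_k is compared
with its expectation under B uniform reference datasets drawn over the
embedding's bounding box, and the smallest k whose gap is within one
standard error of the next is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .simulate import ValidationError


@dataclass
class ClusterAssignment:
    """Partition of network genes into k clusters (labels 1..k).

    Labels are canonicalized by descending cluster size, ties broken by
    the smallest member gene id, so identical inputs yield identical
    labels regardless of node order.
    """

    labels: dict[str, int]
    k: int
    embedding: pd.DataFrame  # index = gene, columns = spectral coords
    inertia: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.labels), "cluster": list(self.labels.values())}
        ).sort_values(["cluster", "gene"]).reset_index(drop=True)

    def members(self, cluster: int) -> list[str]:
        return sorted(g for g, c in self.labels.items() if c == cluster)


@dataclass
class GapResult:
    """Per-k gap-statistic table and the chosen k."""

    table: pd.DataFrame  # k, log_wk, gap, s_k
    chosen_k: int

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_edge_list(
    path,
    min_confidence: float = 0.4,
    node_whitelist: set[str] | None = None,
    score_scale: str | None = None,
) -> nx.Graph:
    """Load a weighted edge list (STRING-style TSV) as an undirected graph.

    Uses the first two columns as nodes and ``combined_score`` (or the
    third column) as confidence. Scores on a 0-1000 scale are auto-detected
    (max > 1) and divided by 1000; pass ``score_scale`` = ``"1000"`` or
    ``"unit"`` to override. Edges below ``min_confidence`` are dropped,
    duplicate/reciprocal edges are merged keeping the maximum confidence,
    self-loops are discarded, and nodes left without edges (disconnected
    genes) are not represented. Rows that fail to parse produce warnings;
    more than 10% malformed rows is an error.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment=None)
    if df.shape[1] < 3:
        raise ValidationError("edge list needs >= 3 columns (node, node, score)")
    score_col = "combined_score" if "combined_score" in df.columns else df.columns[2]
    raw = df[[df.columns[0], df.columns[1], score_col]].copy()
    raw.columns = ["a", "b", "score"]
    n_rows = len(raw)
    raw["score"] = pd.to_numeric(raw["score"], errors="coerce")
    malformed = raw["score"].isna() | raw["a"].isna() | raw["b"].isna()
    n_bad = int(malformed.sum())
    if n_bad:
        warnings.warn(f"{n_bad} malformed edge rows skipped")
        if n_rows and n_bad / n_rows > 0.10:
            raise ValidationError(f"{n_bad}/{n_rows} rows malformed (> 10%)")
    raw = raw[~malformed]
    return build_network(
        raw.itertuples(index=False, name=None),
        min_confidence=min_confidence,
        node_whitelist=node_whitelist,
        score_scale=score_scale,
    )


def build_network(
    edges,
    min_confidence: float = 0.4,
    node_whitelist: set[str] | None = None,
    score_scale: str | None = None,
) -> nx.Graph:
    """Build a GeneNetwork from (node_a, node_b, confidence) triples."""
    triples = [(str(a), str(b), float(s)) for a, b, s in edges]
    if score_scale not in (None, "1000", "unit"):
        raise ValidationError(f"unknown score_scale {score_scale!r}")
    scale = 1000.0 if (
        score_scale == "1000"
        or (score_scale is None and triples and max(s for _, _, s in triples) > 1.0)
    ) else 1.0
    g = nx.Graph()
    for a, b, s in triples:
        if a == b:
            continue
        conf = s / scale
        if not (0.0 <= conf <= 1.0):
            raise ValidationError(f"confidence {conf} outside [0, 1] for edge {a}-{b}")
        if node_whitelist is not None and (a not in node_whitelist or b not in node_whitelist):
            continue
        if conf < min_confidence:
            continue
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], conf)
        else:
            g.add_edge(a, b, weight=conf)
    g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
    return g


def spectral_embed(
    net: nx.Graph, d: int, weighting: str = "row_norm", diffusion_time: float = 3.0
) -> pd.DataFrame:
    """Spectral coordinates from the symmetric normalized Laplacian.

    Rows are the first ``d`` nontrivial eigenvectors (ascending eigenvalue,
    skipping the trivial constant-degree vector). With the default
    ``row_norm`` weighting rows are normalized to unit length (the
    Ng-Jordan-Weiss convention); with ``diffusion`` each eigenvector is
    scaled by ``max(1 - lambda, 0) ** diffusion_time`` instead, which damps
    high-frequency (large-eigenvalue) noise directions and leaves cluster
    structure — useful when the number of clusters is unknown and the
    embedding dimension exceeds it. Eigenvector sign is fixed by making
    each vector's largest-magnitude entry positive, so the embedding is
    deterministic.
    """
    nodes = sorted(net.nodes)
    n = len(nodes)
    if n == 0:
        raise ValidationError("empty network")
    if d < 1:
        raise ValidationError("d must be >= 1")
    if d >= n:
        raise ValidationError(f"d={d} must be < number of nodes ({n})")
    if weighting not in ("row_norm", "diffusion"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    w = nx.to_numpy_array(net, nodelist=nodes, weight="weight")
    deg = w.sum(axis=1)
    inv_sqrt = np.where(deg > 0, deg ** -0.5, 0.0)
    lap = np.eye(n) - inv_sqrt[:, None] * w * inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh(lap)
    order = np.argsort(vals)

    # The zero eigenspace is spanned by one degree-weighted indicator per
    # connected component; eigh returns an arbitrary basis for it, so it is
    # replaced with the indicators themselves (ordered by each component's
    # smallest node). For a connected graph that is the single trivial
    # vector, which is skipped; with several components the indicators
    # carry the component identity and lead the embedding.
    components = sorted(nx.connected_components(net), key=min)
    node_pos = {node: i for i, node in enumerate(nodes)}
    null_dim = len(components)
    null_vecs = np.zeros((n, null_dim))
    for j, comp in enumerate(components):
        idx = [node_pos[v] for v in comp]
        null_vecs[idx, j] = np.sqrt(deg[idx])
        norm = np.linalg.norm(null_vecs[:, j])
        if norm > 0:
            null_vecs[:, j] /= norm
    positive = [i for i in order if vals[i] > 1e-9]
    if null_dim == 1:
        columns: list[np.ndarray] = []  # single trivial vector: skipped
        eigvals: list[float] = []
    else:
        columns = [null_vecs[:, j] for j in range(null_dim)]
        eigvals = [0.0] * null_dim
    for i in positive:
        columns.append(vecs[:, i])
        eigvals.append(float(vals[i]))
    coords = np.column_stack(columns[:d])
    eigvals = np.array(eigvals[:d])
    if coords.shape[1] < d:
        raise ValidationError(f"graph spectrum provides only {coords.shape[1]} usable dimensions")
    # deterministic sign: largest-|entry| positive (first index on ties)
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    if weighting == "diffusion":
        weights = np.maximum(1.0 - eigvals, 0.0) ** diffusion_time
        coords = coords * weights[None, :]
    else:
        norms = np.linalg.norm(coords, axis=1)
        coords = np.where(
            norms[:, None] > 0, coords / np.maximum(norms, 1e-300)[:, None], coords
        )
    return pd.DataFrame(coords, index=nodes, columns=[f"dim{j+1}" for j in range(d)])


def _canonical_labels(nodes: list[str], raw_labels: np.ndarray, k: int) -> dict[str, int]:
    groups: dict[int, list[str]] = {}
    for node, lab in zip(nodes, raw_labels):
        groups.setdefault(int(lab), []).append(node)
    order = sorted(groups, key=lambda lab: (-len(groups[lab]), min(groups[lab])))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return {node: remap[int(lab)] for node, lab in zip(nodes, raw_labels)}


def kmeans_cluster(
    embedding: pd.DataFrame, k: int, seed: int = 0, n_init: int = 10
) -> ClusterAssignment:
    """Seeded k-means on an embedding; best of ``n_init`` restarts by inertia."""
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > len(embedding):
        raise ValidationError(f"k={k} exceeds number of points ({len(embedding)})")
    x = embedding.to_numpy(float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    labels = _canonical_labels(list(embedding.index), km.labels_, k)
    return ClusterAssignment(labels=labels, k=k, embedding=embedding,
                             inertia=float(km.inertia_))


def _log_wk(x: np.ndarray, k: int, seed: int, n_init: int) -> float:
    if k >= len(x):
        return -np.inf
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    return float(np.log(max(km.inertia_, 1e-300)))


def gap_statistic(
    embedding: pd.DataFrame,
    k_min: int = 1,
    k_max: int = 10,
    B: int = 50,
    seed: int = 0,
    n_init: int = 10,
    rule: str = "one_se",
) -> GapResult:
    """Gap-statistic scan over k in [k_min, k_max].

    gap(k) = mean_b log(W_k^b*) - log(W_k) with B uniform reference
    datasets over the embedding's bounding box; s_k is the reference
    standard error (sd * sqrt(1 + 1/B)). Selection rules: ``one_se``
    (default) picks the smallest k with gap(k) >= gap(k+1) - s_{k+1} among
    k whose gap exceeds its own standard error; ``max`` picks the global
    maximum of the gap curve; ``jump`` picks the k with the largest
    increase of the gap over its predecessor (the knee of the curve),
    which is robust when the gap plateaus and creeps upward after the true
    k, as it does on spectral embeddings of modular graphs.
    """
    x = embedding.to_numpy(float)
    n = len(x)
    if not (1 <= k_min <= k_max):
        raise ValidationError("need 1 <= k_min <= k_max")
    if k_max >= n:
        raise ValidationError(f"k_max={k_max} must be < number of points ({n})")
    if B < 10:
        raise ValidationError("need B >= 10 reference sets")
    if rule not in ("one_se", "max", "jump"):
        raise ValidationError(f"unknown selection rule {rule!r}")
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    ks = list(range(k_min, k_max + 1))
    log_wk = np.array([_log_wk(x, k, seed, n_init) for k in ks])
    ref_log = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=x.shape)
        ref_seed = int(rng.integers(0, 2**31 - 1))
        ref_log[b] = [_log_wk(ref, k, ref_seed, n_init) for k in ks]
    gap = ref_log.mean(axis=0) - log_wk
    s_k = ref_log.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    # a gap within one reference standard error of zero means the
    # partition is no tighter than uniform noise; such k carry no evidence
    # of structure and are not candidates (if no k qualifies, fall back to
    # k_min: no structure at all)
    positive = gap > s_k
    if rule == "max":
        chosen = ks[int(np.argmax(gap))]
    elif rule == "jump":
        # first jump is measured against a zero-gap baseline, so a single
        # tight cluster (large gap already at k_min) selects k_min
        jumps = np.diff(np.concatenate([[0.0], gap]))
        chosen = ks[int(np.argmax(jumps))]
    elif not positive.any():
        chosen = ks[0]
    else:
        chosen = ks[-1]
        for i, k in enumerate(ks[:-1]):
            if positive[i] and gap[i] >= gap[i + 1] - s_k[i + 1]:
                chosen = k
                break
    table = pd.DataFrame({"k": ks, "log_wk": log_wk, "gap": gap, "s_k": s_k})
    return GapResult(table=table, chosen_k=chosen)


def cluster_network(
    net: nx.Graph,
    k: int | None = None,
    k_range: tuple[int, int] = (1, 10),
    seed: int = 0,
    B: int = 50,
    n_init: int = 10,
    rule: str = "jump",
) -> tuple[ClusterAssignment, GapResult | None]:
    """Embed a gene network and partition it into k clusters.

    If ``k`` is None it is chosen by the gap statistic on a spectral
    embedding with d = k_max dimensions (capped below the node count).
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("cannot cluster an empty network")
    k_min, k_max = k_range
    n = net.number_of_nodes()
    d = min(k_max, n - 1)
    if d < 1:
        raise ValidationError("network too small to embed")
    # diffusion weighting: k is unknown, so the embedding keeps d = k_max
    # dimensions but damps the high-frequency ones instead of treating all
    # dimensions equally (which would hide the elbow in W_k)
    embedding = spectral_embed(net, d, weighting="diffusion")
    gap = None
    if k is None:
        k_max_eff = min(k_max, n - 1)
        gap = gap_statistic(embedding, k_min, k_max_eff, B=B, seed=seed,
                            n_init=n_init, rule=rule)
        k = gap.chosen_k
    assignment = kmeans_cluster(embedding, k, seed=seed, n_init=n_init)
    return assignment, gap


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)
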