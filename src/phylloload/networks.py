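"""Filtered Pearson co-occurrence networks and their comparison.

A network is built from all unordered taxon pairs of a table: the Pearson
product–moment coefficient r, its Student t statistic
t = r·sqrt((n−2)/(1−r²)) and the two-sided p-value from t(n−2) are
computed per pair, and edges are kept iff r² ≥ r2_min and p < alpha
(defaults 0.2 and 0.05).  Comparing the networks obtained from
absolute-scale and closed (relative) versions of the same data exposes
the compositional sign-flip artifact: closure can turn genuinely positive
associations negative.

Prevalence filtering ("min_count reads in at least min_samples samples")
always operates on raw counts, whatever transform the correlations are
computed on.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sstats

from .tables import FeatureTable, TableError

logger = logging.getLogger("phylloload")

#: smallest positive double; stored instead of p = 0 to keep files sortable
TINY_P = float(np.nextafter(0, 1))


class NetworkError(ValueError):
    """Raised for invalid network construction or comparison inputs."""


@dataclass(frozen=True)
class Edge:
    """A scored taxon pair; taxon_a < taxon_b lexicographically."""

    taxon_a: str
    taxon_b: str
    r: float
    t_stat: float
    p: float
    n: int

    @property
    def r2(self) -> float:
        return self.r * self.r

    @property
    def sign(self) -> str:
        return "positive" if self.r > 0 else "negative"


@dataclass
class CorrelationNetwork:
    """Taxon nodes (with mean-abundance ranks) and filter-surviving edges."""

    nodes: list[str]
    node_rank: pd.Series  # 1 = most abundant on average
    edges: list[Edge]
    provenance: dict = field(default_factory=dict)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.taxon_a, e.taxon_b) for e in self.edges}

    def find_edge(self, a: str, b: str) -> Edge | None:
        a, b = sorted((a, b))
        for e in self.edges:
            if (e.taxon_a, e.taxon_b) == (a, b):
                return e
        return None

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "taxon_a": e.taxon_a,
                "taxon_b": e.taxon_b,
                "r": e.r,
                "r2": e.r2,
                "t": e.t_stat,
                "p": e.p if e.p > 0 else TINY_P,
                "n": e.n,
            }
            for e in self.edges
        ]
        return pd.DataFrame(
            rows, columns=["taxon_a", "taxon_b", "r", "r2", "t", "p", "n"]
        )

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node, rank=int(self.node_rank[node]))
        for e in self.edges:
            g.add_edge(e.taxon_a, e.taxon_b, r=e.r, r2=e.r2, p=e.p, n=e.n)
        return g


def prevalence_filter(
    raw_table: FeatureTable, min_count: int = 1000, min_samples: int = 10
) -> list[str]:
    """Taxa with ≥ min_count reads in ≥ min_samples samples (inclusive)."""
    counts = raw_table.data
    ok = (counts >= min_count).sum(axis=1) >= min_samples
    return list(counts.index[ok])


def pearson_edge(x: np.ndarray, y: np.ndarray, taxon_a: str = "x", taxon_b: str = "y") -> Edge:
    """Score one taxon pair: r, Student t, and two-sided p from t(n−2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise NetworkError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise NetworkError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise NetworkError("constant vector: correlation undefined")
    xm = x - x.mean()
    ym = y - y.mean()
    r = float(xm @ ym / math.sqrt((xm @ xm) * (ym @ ym)))
    r = max(-1.0, min(1.0, r))
    a, b = sorted((taxon_a, taxon_b))
    if abs(r) == 1.0:
        return Edge(a, b, r, math.inf if r > 0 else -math.inf, 0.0, n)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sstats.t.sf(abs(t), df=n - 2))
    return Edge(a, b, r, t, p, n)


def build_network(
    table: FeatureTable,
    taxa: list[str] | None = None,
    r2_min: float = 0.2,
    alpha: float = 0.05,
    threshold_on: str = "r2",
) -> CorrelationNetwork:
    """Score all unordered pairs of *taxa* and keep the filter survivors.

    ``threshold_on="r2"`` keeps edges with r² ≥ r2_min (the default
    semantics); ``"r"`` interprets r2_min as a threshold on |r| instead.
    Constant taxa are excluded (with a warning) before pairing.  Nodes are
    annotated with their mean-abundance rank in *table*.
    """
    if threshold_on not in ("r2", "r"):
        raise NetworkError(f"threshold_on must be 'r2' or 'r', got {threshold_on!r}")
    if taxa is None:
        taxa = table.taxon_labels
    missing = [t for t in taxa if t not in set(table.taxon_labels)]
    if missing:
        raise NetworkError(f"taxa not in table: {missing}")
    if len(taxa) < 2:
        raise NetworkError("need at least 2 taxa to build a network")
    sub = table.data.loc[taxa]
    usable = []
    for t in taxa:
        if np.ptp(sub.loc[t].to_numpy(dtype=float)) == 0:
            logger.warning("build_network: taxon %r is constant; excluded", t)
        else:
            usable.append(t)
    mean_abund = table.data.loc[taxa].mean(axis=1)
    rank = mean_abund.rank(ascending=False, method="min").astype(int)
    edges = []
    for a, b in itertools.combinations(usable, 2):
        e = pearson_edge(
            sub.loc[a].to_numpy(dtype=float), sub.loc[b].to_numpy(dtype=float), a, b
        )
        strength_ok = (e.r2 >= r2_min) if threshold_on == "r2" else (abs(e.r) >= r2_min)
        if strength_ok and e.p < alpha:
            edges.append(e)
    provenance = {
        "mode": table.mode,
        "r2_min": r2_min,
        "alpha": alpha,
        "threshold_on": threshold_on,
        "n_samples": table.shape[1],
    }
    return CorrelationNetwork(list(taxa), rank, edges, provenance)


@dataclass
class NetworkComparison:
    """Pairwise status of two networks over a shared node universe."""

    statuses: pd.DataFrame  # per pair: status_a, status_b in {absent,positive,negative}
    retained: int
    lost: int
    gained: int
    sign_flipped: int
    jaccard: float


def compare_networks(
    net_a: CorrelationNetwork, net_b: CorrelationNetwork
) -> NetworkComparison:
    """Classify every pair as retained / lost / gained / sign-flipped.

    Both networks must share the same node universe.  ``sign_flipped``
    counts pairs present in both networks with opposite edge signs;
    ``jaccard`` is the Jaccard index of the edge sets (1.0 when both are
    empty).
    """
    if set(net_a.nodes) != set(net_b.nodes):
        only_a = sorted(set(net_a.nodes) - set(net_b.nodes))
        only_b = sorted(set(net_b.nodes) - set(net_a.nodes))
        raise NetworkError(
            f"node universes differ: only in A {only_a}, only in B {only_b}"
        )

    def status(net: CorrelationNetwork, a: str, b: str) -> str:
        e = net.find_edge(a, b)
        return "absent" if e is None else e.sign

    rows = []
    retained = lost = gained = flipped = 0
    for a, b in itertools.combinations(sorted(net_a.nodes), 2):
        sa, sb = status(net_a, a, b), status(net_b, a, b)
        if sa != "absent" and sb != "absent":
            retained += 1
            if sa != sb:
                flipped += 1
        elif sa != "absent":
            lost += 1
        elif sb != "absent":
            gained += 1
        rows.append({"taxon_a": a, "taxon_b": b, "status_a": sa, "status_b": sb})
    pairs_a, pairs_b = net_a.edge_pairs(), net_b.edge_pairs()
    union = pairs_a | pairs_b
    jaccard = len(pairs_a & pairs_b) / len(union) if union else 1.0
    return NetworkComparison(
        statuses=pd.DataFrame(rows),
        retained=retained,
        lost=lost,
        gained=gained,
        sign_flipped=flipped,
        jaccard=jaccard,
    )


def permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for |r|: fraction of shuffles at least as extreme.

    Uses add-one smoothing: p = (1 + #{|r_perm| ≥ |r_obs|}) / (n_perm + 1).
    Serves as the model-free oracle for the Student-t p-values.
    """
    if n_perm < 100:
        raise NetworkError("n_perm must be >= 100")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise NetworkError("constant vector: correlation undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(x)
    xm = (x - x.mean()) / np.sqrt(((x - x.mean()) ** 2).sum())
    ym = (y - y.mean()) / np.sqrt(((y - y.mean()) ** 2).sum())
    r_obs = abs(float(xm @ ym))
    # one permutation matrix pass; memory n_perm x n doubles
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    r_perm = np.abs(xm[idx] @ ym)
    exceed = int((r_perm >= r_obs - 1e-15).sum())
    return (1 + exceed) / (n_perm + 1)
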