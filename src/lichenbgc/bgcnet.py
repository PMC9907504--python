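"""Pairwise BGC distances, similarity networks, and family assignment.

The composite distance between two gene clusters combines three indices, each
in [0, 1]:

* J   — Jaccard similarity of the pooled protein-domain label sets,
* DSS — domain sequence similarity: shared domain copies are greedily paired
        by descending global-alignment identity of their parent genes and the
        summed identities are divided by the total (paired + unpaired) copy
        count, so copy-number mismatches are penalized,
* AI  — adjacency index: Jaccard similarity of the sets of unordered adjacent
        domain pairs along the linearized cluster (orientation-insensitive).

d = 1 - (wJ*J + wDSS*DSS + wAI*AI), default weights (0.2, 0.7, 0.1).
Clusters are compared only within the same BGC class; pairs at d <= cutoff
become network edges and each connected component is split into families by
affinity propagation on s = 1 - d. Every cluster belongs to exactly one
family ("hybrids off").
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "GeneRecord",
    "ClusterRecord",
    "SimilarityComponents",
    "NetworkConfig",
    "FamilyAssignment",
    "BGC_CLASSES",
    "EXCLUDED_CLASSES",
    "pairwise_identity",
    "domain_jaccard",
    "adjacency_index",
    "domain_sequence_similarity",
    "bgc_distance",
    "build_network",
    "assign_families",
    "select_cutoff",
    "presence_absence",
]

BGC_CLASSES = ("PKSI", "NRPS", "PKS-NRP Hybrid", "PKS other", "Terpene", "Others")
#: classes dropped before networking (ribosomal peptides and saccharides)
EXCLUDED_CLASSES = frozenset({"RiPPs", "Saccharides"})

DEFAULT_WEIGHTS = (0.2, 0.7, 0.1)


@dataclass
class GeneRecord:
    gene_id: str
    order_index: int
    strand: str = "+"
    role_annotation: str = ""
    domains: list[str] = field(default_factory=list)
    sequence: str = ""


@dataclass
class ClusterRecord:
    cluster_id: str
    genome_id: str
    bgc_class: str = "PKSI"
    genes: list[GeneRecord] = field(default_factory=list)
    is_reference: bool = False
    compound: str | None = None

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: g.order_index)

    def domain_sequence(self) -> list[str]:
        """Domains linearized in gene order."""
        out: list[str] = []
        for g in self.genes:
            out.extend(g.domains)
        return out

    def domain_set(self) -> frozenset[str]:
        return frozenset(self.domain_sequence())


@dataclass(frozen=True)
class SimilarityComponents:
    jaccard: float
    dss: float
    adjacency: float
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS

    @property
    def distance(self) -> float:
        wj, wd, wa = self.weights
        d = 1.0 - (wj * self.jaccard + wd * self.dss + wa * self.adjacency)
        if abs(d) < 1e-12:  # exact zero for identical clusters
            d = 0.0
        return float(min(max(d, 0.0), 1.0))


@dataclass
class NetworkConfig:
    cutoff: float = 0.46
    grid_start: float = 0.30
    grid_stop: float = 1.00
    grid_step: float = 0.01
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    preference: float = 0.3  # affinity-propagation exemplar preference on s = 1 - d
    damping: float = 0.9
    max_iter: int = 1000
    convergence_iter: int = 200
    seed: int = 0

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return np.round(self.grid_start + self.grid_step * np.arange(n), 10)


@dataclass
class FamilyAssignment:
    """Total partition of clusters into families (each cluster in exactly one)."""

    family_of: dict[str, str]
    clusters: dict[str, ClusterRecord]

    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cid, fam in self.family_of.items():
            out.setdefault(fam, []).append(cid)
        return {k: sorted(v) for k, v in out.items()}

    def summary(self) -> pd.DataFrame:
        rows = []
        for fam, members in sorted(self.families().items()):
            refs = [c for c in members if self.clusters[c].is_reference]
            compounds = sorted(
                {
                    self.clusters[c].compound
                    for c in refs
                    if self.clusters[c].compound
                }
            )
            rows.append(
                (fam, len(members), len(refs), ";".join(compounds), ";".join(members))
            )
        return pd.DataFrame(
            rows, columns=["family_id", "size", "n_reference", "compounds", "members"]
        )


# ---------------------------------------------------------------------------
# similarity components


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


_ALIGNER = _aligner()


@functools.lru_cache(maxsize=1_000_000)
def _identity_cached(seq_a: str, seq_b: str) -> float:
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Scoring: match +1, mismatch -1, linear gap -2. Symmetric by construction
    (arguments are canonically ordered before alignment).
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if seq_a == seq_b:
        return 1.0
    a, b = sorted((seq_a, seq_b))
    return float(_identity_cached(a, b))


def domain_jaccard(A: ClusterRecord, B: ClusterRecord) -> float:
    sa, sb = A.domain_set(), B.domain_set()
    if not sa and not sb:
        warnings.warn("both clusters have empty domain sets; Jaccard set to 1")
        return 1.0
    union = sa | sb
    return len(sa & sb) / len(union)


def _adjacent_pairs(domains: list[str]) -> set[frozenset[str] | tuple[str, str]]:
    pairs: set = set()
    for x, y in zip(domains, domains[1:]):
        pairs.add(frozenset((x, y)) if x != y else (x, y))
    return pairs


def adjacency_index(A: ClusterRecord, B: ClusterRecord) -> float:
    """Jaccard of unordered adjacent domain pairs; 0 if either side has < 2 domains."""
    da, db = A.domain_sequence(), B.domain_sequence()
    if len(da) < 2 or len(db) < 2:
        return 0.0
    pa = _adjacent_pairs(da)
    best = 0.0
    for dbv in (db, db[::-1]):
        pb = _adjacent_pairs(dbv)
        union = pa | pb
        best = max(best, len(pa & pb) / len(union)) if union else 1.0
    return best


def _domain_copies(cluster: ClusterRecord) -> dict[str, list[str]]:
    """Domain label -> one parent-gene sequence per copy of that domain."""
    copies: dict[str, list[str]] = {}
    for g in cluster.genes:
        for d in g.domains:
            copies.setdefault(d, []).append(g.sequence)
    return copies


def domain_sequence_similarity(A: ClusterRecord, B: ClusterRecord) -> float:
    """Identity-weighted matching of shared domain copies, copy-number aware.

    For every domain label present in both clusters, copies are greedily
    paired in order of decreasing parent-gene identity; the score is
    sum(paired identities) / (number of pairs + number of unpaired copies on
    both sides, over all labels).
    """
    ca, cb = _domain_copies(A), _domain_copies(B)
    total_a = sum(len(v) for v in ca.values())
    total_b = sum(len(v) for v in cb.values())
    if total_a == 0 or total_b == 0:
        return 0.0
    shared = set(ca) & set(cb)
    score = 0.0
    n_pairs = 0
    for label in shared:
        xs, ys = list(ca[label]), list(cb[label])
        pairs = sorted(
            (
                (pairwise_identity(x, y) if x and y else 0.0, i, j)
                for i, x in enumerate(xs)
                for j, y in enumerate(ys)
            ),
            key=lambda t: (-t[0], t[1], t[2]),
        )
        used_i: set[int] = set()
        used_j: set[int] = set()
        for ident, i, j in pairs:
            if i in used_i or j in used_j:
                continue
            used_i.add(i)
            used_j.add(j)
            score += ident
            n_pairs += 1
    denom = n_pairs + (total_a + total_b - 2 * n_pairs)
    return score / denom if denom else 0.0


def bgc_distance(
    A: ClusterRecord, B: ClusterRecord, weights=DEFAULT_WEIGHTS
) -> SimilarityComponents:
    wj, wd, wa = (float(w) for w in weights)
    if min(wj, wd, wa) < 0 or abs(wj + wd + wa - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    return SimilarityComponents(
        jaccard=domain_jaccard(A, B),
        dss=domain_sequence_similarity(A, B),
        adjacency=adjacency_index(A, B),
        weights=(wj, wd, wa),
    )


# ---------------------------------------------------------------------------
# network + families


def _pair_distances(
    clusters: list[ClusterRecord], weights
) -> dict[tuple[str, str], SimilarityComponents]:
    """All within-class pairwise components, keyed by sorted id pair."""
    by_class: dict[str, list[ClusterRecord]] = {}
    for c in clusters:
        if c.bgc_class in EXCLUDED_CLASSES:
            continue
        by_class.setdefault(c.bgc_class, []).append(c)
    out: dict[tuple[str, str], SimilarityComponents] = {}
    for members in by_class.values():
        members = sorted(members, key=lambda c: c.cluster_id)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                out[(a.cluster_id, b.cluster_id)] = bgc_distance(a, b, weights)
    return out


def build_network(
    clusters: list[ClusterRecord],
    config: NetworkConfig | None = None,
    *,
    _pairs: dict | None = None,
) -> pd.DataFrame:
    """Edge list (a_id, b_id, J, DSS, AI, d) of within-class pairs at d <= cutoff.

    The cutoff is inclusive, but pairs with no similarity at all (d = 1) are
    never linked, even at the maximal cutoff.
    """
    config = config or NetworkConfig()
    pairs = _pairs if _pairs is not None else _pair_distances(clusters, config.weights)
    rows = [
        (a, b, sc.jaccard, sc.dss, sc.adjacency, sc.distance)
        for (a, b), sc in sorted(pairs.items())
        if sc.distance <= config.cutoff + 1e-12 and sc.distance < 1.0
    ]
    return pd.DataFrame(rows, columns=["a_id", "b_id", "J", "DSS", "AI", "d"])


def _affinity_split(
    members: list[str],
    dist: dict[tuple[str, str], float],
    config: NetworkConfig,
) -> list[list[str]]:
    n = len(members)
    s = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = tuple(sorted((members[i], members[j])))
            s[i, j] = s[j, i] = 1.0 - dist[key]
    ap = AffinityPropagation(
        affinity="precomputed",
        damping=config.damping,
        max_iter=config.max_iter,
        convergence_iter=config.convergence_iter,
        preference=config.preference,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        labels = ap.fit_predict(s)
    if np.any(labels < 0):  # did not converge: keep the component whole
        return [list(members)]
    groups: dict[int, list[str]] = {}
    for m, lab in zip(members, labels):
        groups.setdefault(int(lab), []).append(m)
    return list(groups.values())


def assign_families(
    edges: pd.DataFrame,
    clusters: list[ClusterRecord],
    config: NetworkConfig | None = None,
) -> FamilyAssignment:
    """Partition clusters into families.

    Connected components of the edge graph are computed over all (non-excluded)
    clusters; components of size >= 3 are refined by affinity propagation on
    s = 1 - d. Family ids are canonical: the smallest member cluster_id.
    """
    config = config or NetworkConfig()
    usable = [c for c in clusters if c.bgc_class not in EXCLUDED_CLASSES]
    index = {c.cluster_id: c for c in usable}
    g = nx.Graph()
    g.add_nodes_from(sorted(index))
    dist: dict[tuple[str, str], float] = {}
    for row in edges.itertuples(index=False):
        key = tuple(sorted((row.a_id, row.b_id)))
        dist[key] = row.d
        g.add_edge(*key)

    family_of: dict[str, str] = {}
    for comp in nx.connected_components(g):
        members = sorted(comp)
        if len(members) < 3:
            for m in members:
                family_of[m] = members[0]
            continue
        # distances may be missing for non-edge pairs inside a component;
        # recompute them (same class by construction of the edge set)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                key = (members[i], members[j])
                if key not in dist:
                    dist[key] = bgc_distance(
                        index[key[0]], index[key[1]], config.weights
                    ).distance
        for group in _affinity_split(members, dist, config):
            fam = min(group)
            for m in group:
                family_of[m] = fam
    return FamilyAssignment(family_of=family_of, clusters=index)


def select_cutoff(
    clusters: list[ClusterRecord],
    reference_pair: tuple[str, str],
    config: NetworkConfig | None = None,
) -> float:
    """Smallest grid cutoff at which a designated reference pair co-clusters.

    Implements the rule of choosing the minimum cutoff that places two highly
    similar reference compounds' clusters in the same family; each candidate is
    verified one grid step up before being accepted.
    """
    config = config or NetworkConfig()
    ids = {c.cluster_id for c in clusters}
    for r in reference_pair:
        if r not in ids:
            raise ValueError(f"reference cluster {r!r} not present")
    pairs = _pair_distances(clusters, config.weights)

    def co_clustered(cut: float) -> bool:
        cfg = NetworkConfig(**{**config.__dict__, "cutoff": float(cut)})
        edges = build_network(clusters, cfg, _pairs=pairs)
        fam = assign_families(edges, clusters, cfg).family_of
        return fam[reference_pair[0]] == fam[reference_pair[1]]

    grid = config.grid()
    for i, cut in enumerate(grid):
        if co_clustered(cut):
            if i + 1 < len(grid) and not co_clustered(grid[i + 1]):
                warnings.warn(
                    f"co-clustering at {cut:.2f} not stable at the next grid step"
                )
                continue
            return float(cut)
    raise ValueError(
        f"reference pair never co-clustered up to cutoff {grid[-1]:.2f}"
    )


def presence_absence(
    assignment: FamilyAssignment, genomes: list[str] | None = None
) -> pd.DataFrame:
    """Genome x family 0/1 incidence matrix; reference-only families excluded."""
    fams = assignment.families()
    clus = assignment.clusters
    if genomes is None:
        genomes = sorted(
            {c.genome_id for c in clus.values() if not c.is_reference}
        )
    cols = [
        f
        for f, members in sorted(fams.items())
        if any(not clus[m].is_reference for m in members)
    ]
    mat = pd.DataFrame(0, index=list(genomes), columns=cols, dtype=int)
    for fam, members in fams.items():
        if fam not in cols:
            continue
        for m in members:
            c = clus[m]
            if not c.is_reference and c.genome_id in mat.index:
                mat.loc[c.genome_id, fam] = 1
    return mat
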