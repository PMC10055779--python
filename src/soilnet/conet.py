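"""Ensemble co-occurrence network inference.

For every unordered taxon pair, five association measures are computed across
samples (Spearman, Pearson, symmetrized Kullback-Leibler dissimilarity,
Bray-Curtis dissimilarity, mutual information).  Per-measure significance
comes from a sample-label permutation null; the five p-values are integrated
with the empirical Brown method (covariance-corrected Fisher combination
estimated from the same permutation replicates).  Edges are retained when
|Spearman| exceeds the score threshold and the combined p-value is below the
significance threshold; topology indices and hub detection operate on the
resulting undirected signed network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import chi2, rankdata

from .io_tables import CountTable

__all__ = [
    "MEASURES",
    "Edge",
    "AssociationResult",
    "CoNetwork",
    "TopologyIndices",
    "filter_taxa",
    "pairwise_measures",
    "permutation_pvalues",
    "brown_from_cov",
    "fisher_combine",
    "brown_combine",
    "build_network",
    "density",
    "topology",
    "detect_hubs",
    "edge_recovery",
]

MEASURES = ("spearman", "pearson", "kl", "bray_curtis", "mutual_info")
#: measures whose magnitude carries a sign (two-sided on |T|)
_SIGNED = ("spearman", "pearson")
#: dissimilarities: both tails are interesting (small = co-presence, large = exclusion)
_TWO_TAIL = ("kl", "bray_curtis")

_EPS = 1e-12


@dataclass
class AssociationResult:
    """Pairwise association scores, permutation p-values and combined p.

    All matrices are symmetric with a NaN diagonal.  ``w_cov`` holds, per
    pair, the empirical covariance of the ``-2 ln p`` transforms across the
    permutation replicates (filled by :func:`permutation_pvalues`).
    """

    taxa: list[str]
    scores: dict[str, np.ndarray]
    n_samples: int
    pvalues: dict[str, np.ndarray] | None = None
    brown_p: np.ndarray | None = None
    w_cov: np.ndarray | None = None  # (n_taxa, n_taxa, k, k)
    permutations: int | None = None
    seed: int | None = None

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def pairs(self):
        n = self.n_taxa
        for i in range(n):
            for j in range(i + 1, n):
                yield i, j


@dataclass(frozen=True)
class Edge:
    a: str
    b: str
    sign: int  # +1 or -1
    brown_p: float
    spearman: float


@dataclass
class CoNetwork:
    """Undirected signed co-occurrence network of retained taxa."""

    nodes: dict[str, float]  # taxon -> mean relative abundance
    edges: list[Edge]
    hubs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seen: set[frozenset[str]] = set()
        for edge in self.edges:
            if edge.a == edge.b:
                raise ValueError(f"self-loop on {edge.a!r}")
            if edge.a not in self.nodes or edge.b not in self.nodes:
                raise ValueError(f"edge endpoint missing from node set: {edge.a}-{edge.b}")
            key = frozenset((edge.a, edge.b))
            if key in seen:
                raise ValueError(f"parallel edge {edge.a}-{edge.b}")
            seen.add(key)
            if edge.sign not in (-1, 1):
                raise ValueError("edge sign must be +1 or -1")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        graph = nx.Graph()
        for taxon, abundance in self.nodes.items():
            graph.add_node(taxon, abundance=float(abundance), hub=taxon in self.hubs)
        for edge in self.edges:
            graph.add_edge(edge.a, edge.b, sign=int(edge.sign),
                           brown_p=float(edge.brown_p), spearman=float(edge.spearman))
        return graph

    def with_hubs(self, hubs) -> "CoNetwork":
        return CoNetwork(dict(self.nodes), list(self.edges), hubs=frozenset(hubs))


@dataclass(frozen=True)
class TopologyIndices:
    n_nodes: int
    n_edges: int
    network_density: float
    clustering_coefficient: float
    average_path_length: float
    positive_pct: float
    negative_pct: float
    n_components: int


# ---------------------------------------------------------------------------
# Filtering and observed measures
# ---------------------------------------------------------------------------

def filter_taxa(table: CountTable, min_mean_rel_abund: float) -> CountTable:
    """Keep taxa whose mean per-sample relative abundance strictly exceeds
    ``min_mean_rel_abund`` (a fraction, e.g. 0.001 for 0.1%)."""
    if not 0 <= min_mean_rel_abund < 1:
        raise ValueError("threshold must lie in [0, 1) as a fraction")
    mean = table.mean_relative_abundance()
    keep = [t for t, m in zip(table.taxa, mean) if m > min_mean_rel_abund]
    if not keep:
        raise ValueError("no taxa exceed the abundance threshold")
    return table.subset_taxa(keep)


def _profiles(table: CountTable, pseudocount: float = 0.5):
    """Derived per-taxon profiles used by the five measures."""
    rel = table.relative_abundance()  # taxa x samples
    ranks = np.vstack([rankdata(row) for row in rel])
    padded = table.counts + pseudocount
    prof = padded / padded.sum(axis=1, keepdims=True)  # per-taxon normalized
    logprof = np.log(prof)
    n = table.n_samples
    k = max(2, int(np.floor(np.sqrt(n))))
    # equal-frequency bins, ties broken by stable rank order
    order = np.argsort(rel, axis=1, kind="stable")
    bins = np.empty_like(order)
    pos = np.arange(n)
    for i in range(table.n_taxa):
        bins[i, order[i]] = pos * k // n
    return rel, ranks, prof, logprof, bins, k


def _mi_from_joint(joint: np.ndarray, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Plug-in MI for a stack of joint probability tables (..., k, k)."""
    outer = px[:, None] * py[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / outer)
    return np.where(joint > 0, terms, 0.0).sum(axis=(-2, -1))


def pairwise_measures(table: CountTable, pseudocount: float = 0.5) -> AssociationResult:
    """Compute the five association scores for every unordered taxon pair."""
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples")
    if table.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rel, ranks, prof, logprof, bins, k = _profiles(table, pseudocount)
    t, n = rel.shape

    constant = rel.std(axis=1) < _EPS
    if constant.any():
        bad = [table.taxa[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"constant profiles (correlations undefined): {bad}")

    with np.errstate(invalid="ignore"):
        spear = np.corrcoef(ranks)
        pear = np.corrcoef(rel)
    for mat in (spear, pear):
        mat[constant, :] = np.nan
        mat[:, constant] = np.nan

    cross = prof @ logprof.T
    h = np.diag(cross)
    kl = h[:, None] + h[None, :] - cross - cross.T
    np.fill_diagonal(kl, 0.0)
    kl = np.maximum(kl, 0.0)

    bc = np.zeros((t, t))
    for i in range(t):
        bc[i, i + 1:] = 0.5 * np.abs(prof[i] - prof[i + 1:]).sum(axis=1)
    bc = bc + bc.T

    marg = np.vstack([np.bincount(bins[i], minlength=k) for i in range(t)]) / n
    mi = np.zeros((t, t))
    for i in range(t):
        for j in range(i + 1, t):
            joint = np.zeros((k, k))
            np.add.at(joint, (bins[i], bins[j]), 1.0)
            mi[i, j] = mi[j, i] = _mi_from_joint(joint / n, marg[i], marg[j])

    scores = {"spearman": spear, "pearson": pear, "kl": kl,
              "bray_curtis": bc, "mutual_info": mi}
    for name, mat in scores.items():
        scores[name] = (mat + mat.T) / 2.0  # exact symmetry
        np.fill_diagonal(scores[name], np.nan)
    return AssociationResult(list(table.taxa), scores, n_samples=n)


# ---------------------------------------------------------------------------
# Permutation null and p-values
# ---------------------------------------------------------------------------

def _tail_counts(perm_stats: np.ndarray, obs: float):
    ge = int(np.count_nonzero(perm_stats >= obs - _EPS))
    le = int(np.count_nonzero(perm_stats <= obs + _EPS))
    return ge, le


def _perm_pseudo_p(perm_stats: np.ndarray, kind: str, b: int) -> np.ndarray:
    """Pseudo p-value of each permutation replicate within its own null."""
    if kind == "signed":
        a = np.abs(perm_stats)
        ge = b - (rankdata(a, method="min") - 1)
        return ge / (b + 1.0)
    if kind == "high":
        ge = b - (rankdata(perm_stats, method="min") - 1)
        return ge / (b + 1.0)
    # two-tailed dissimilarity
    ge = b - (rankdata(perm_stats, method="min") - 1)
    le = rankdata(perm_stats, method="max")
    return np.clip(2.0 * np.minimum(ge, le) / (b + 1.0), 1.0 / (b + 1.0), 1.0)


def permutation_pvalues(table: CountTable, b: int = 1000, seed: int | None = None,
                        assoc: AssociationResult | None = None,
                        pseudocount: float = 0.5) -> AssociationResult:
    """Fill permutation p-values (and Brown covariance inputs) for all pairs.

    The null shuffles one profile's sample assignment; the same ``b``
    permutations are shared by every pair and measure.
    """
    if b < 99:
        raise ValueError("b must be >= 99 (p-value resolution)")
    if assoc is None:
        assoc = pairwise_measures(table, pseudocount)
    # canonical sample order: p-values are then exactly invariant to the
    # column order of the input table
    canonical = table.subset_samples(sorted(table.samples))
    rel, ranks, prof, logprof, bins, k = _profiles(canonical, pseudocount)
    t, n = rel.shape
    rng = np.random.default_rng(seed)
    perms = np.vstack([rng.permutation(n) for _ in range(b)])  # (b, n)

    rank_c = ranks - ranks.mean(axis=1, keepdims=True)
    rank_norm = np.linalg.norm(rank_c, axis=1)
    rel_c = rel - rel.mean(axis=1, keepdims=True)
    rel_norm = np.linalg.norm(rel_c, axis=1)
    h = np.einsum("ij,ij->i", prof, logprof)
    marg = np.vstack([np.bincount(bins[i], minlength=k) for i in range(t)]) / n
    offsets = (np.arange(b) * k * k)[:, None]

    pvals = {m: np.full((t, t), np.nan) for m in MEASURES}
    w_cov = np.full((t, t, len(MEASURES), len(MEASURES)), np.nan)
    kinds = {"spearman": "signed", "pearson": "signed", "kl": "two",
             "bray_curtis": "two", "mutual_info": "high"}

    for i, j in assoc.pairs():
        # permute the lexicographically larger taxon's profile, so p-values
        # are exactly invariant to taxon order
        ii, jj = (i, j) if assoc.taxa[i] <= assoc.taxa[j] else (j, i)
        perm_stats: dict[str, np.ndarray] = {}

        if rank_norm[ii] > _EPS and rank_norm[jj] > _EPS:
            yr = rank_c[jj][perms]  # (b, n)
            perm_stats["spearman"] = (yr @ rank_c[ii]) / (rank_norm[ii] * rank_norm[jj])
        if rel_norm[ii] > _EPS and rel_norm[jj] > _EPS:
            yv = rel_c[jj][perms]
            perm_stats["pearson"] = (yv @ rel_c[ii]) / (rel_norm[ii] * rel_norm[jj])

        lq = logprof[jj][perms]
        qq = prof[jj][perms]
        perm_stats["kl"] = np.maximum(
            h[ii] + h[jj] - lq @ prof[ii] - qq @ logprof[ii], 0.0)
        perm_stats["bray_curtis"] = 0.5 * np.abs(prof[ii] - qq).sum(axis=1)

        codes = bins[ii][None, :] * k + bins[jj][perms]
        joint = np.bincount((codes + offsets).ravel(), minlength=b * k * k)
        joint = joint.reshape(b, k, k) / n
        perm_stats["mutual_info"] = _mi_from_joint(joint, marg[ii], marg[jj])

        ws = []
        for mi_, measure in enumerate(MEASURES):
            obs = assoc.scores[measure][i, j]
            stats = perm_stats.get(measure)
            if stats is None or not np.isfinite(obs):
                ws.append(None)
                continue
            kind = kinds[measure]
            ge, le = _tail_counts(stats, obs)
            if kind == "signed":
                ge_abs, _ = _tail_counts(np.abs(stats), abs(obs))
                p = (1 + ge_abs) / (b + 1.0)
            elif kind == "high":
                p = (1 + ge) / (b + 1.0)
            else:
                p = min(1.0, 2.0 * (1 + min(ge, le)) / (b + 1.0))
            pvals[measure][i, j] = pvals[measure][j, i] = p
            ws.append(-2.0 * np.log(_perm_pseudo_p(stats, kind, b)))

        valid = [w for w in ws if w is not None]
        if len(valid) >= 2:
            idx = [m for m, w in enumerate(ws) if w is not None]
            cov = np.cov(np.vstack(valid))
            block = np.full((len(MEASURES), len(MEASURES)), np.nan)
            block[np.ix_(idx, idx)] = cov
            w_cov[i, j] = w_cov[j, i] = block

    return replace(assoc, pvalues=pvals, w_cov=w_cov, permutations=b, seed=seed)


# ---------------------------------------------------------------------------
# Brown / Fisher combination
# ---------------------------------------------------------------------------

def fisher_combine(pvalues: np.ndarray) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi-square with 2k df."""
    p = np.asarray(pvalues, dtype=float)
    x = -2.0 * np.log(np.clip(p, _EPS, 1.0)).sum()
    return float(chi2.sf(x, 2 * p.size))


def brown_from_cov(pvalues: np.ndarray, cov: np.ndarray) -> float:
    """Brown's method with a supplied covariance of the -2 ln p transforms.

    X = -2 sum(ln p) is modeled as c * chi-square(f) with
    c = Var/(2 E), f = 2 E^2/Var, E = 2k, Var = sum of all covariance
    entries.  With a diagonal covariance of 4 this is exactly Fisher.
    """
    p = np.asarray(pvalues, dtype=float)
    cov = np.asarray(cov, dtype=float)
    var = float(cov.sum())
    if not np.isfinite(var) or var <= 0:
        return fisher_combine(p)
    expected = 2.0 * p.size
    c = var / (2.0 * expected)
    f = 2.0 * expected ** 2 / var
    x = -2.0 * np.log(np.clip(p, _EPS, 1.0)).sum()
    return float(chi2.sf(x / c, f))


def brown_combine(assoc: AssociationResult) -> AssociationResult:
    """Fill the combined (Brown) p-value for every pair with >= 2 valid
    per-measure p-values, using the stored empirical covariance."""
    if assoc.pvalues is None:
        raise ValueError("permutation p-values must be computed first")
    t = assoc.n_taxa
    brown = np.full((t, t), np.nan)
    skipped = []
    for i, j in assoc.pairs():
        ps, idx = [], []
        for m, measure in enumerate(MEASURES):
            p = assoc.pvalues[measure][i, j]
            if np.isfinite(p):
                ps.append(p)
                idx.append(m)
        if len(ps) < 2:
            skipped.append((assoc.taxa[i], assoc.taxa[j]))
            continue
        if assoc.w_cov is not None and np.all(np.isfinite(assoc.w_cov[i, j][np.ix_(idx, idx)])):
            cov = assoc.w_cov[i, j][np.ix_(idx, idx)]
            brown[i, j] = brown[j, i] = brown_from_cov(np.array(ps), cov)
        else:
            brown[i, j] = brown[j, i] = fisher_combine(np.array(ps))
    if skipped:
        warnings.warn(f"{len(skipped)} pairs skipped (<2 valid p-values)")
    return replace(assoc, brown_p=brown)


# ---------------------------------------------------------------------------
# Network construction and topology
# ---------------------------------------------------------------------------

def build_network(assoc: AssociationResult, table: CountTable,
                  score_threshold: float = 0.6,
                  p_threshold: float = 0.05,
                  use_max_correlation: bool = False) -> CoNetwork:
    """Retain edges with |Spearman| > score_threshold and Brown p < p_threshold.

    ``use_max_correlation`` gates on max(|Spearman|, |Pearson|) instead.
    The edge sign is the sign of the Spearman coefficient; nodes are the taxa
    incident to at least one retained edge.
    """
    if assoc.brown_p is None:
        raise ValueError("combined p-values must be computed first")
    mean_rel = dict(zip(table.taxa, table.mean_relative_abundance()))
    edges: list[Edge] = []
    for i, j in assoc.pairs():
        rho = assoc.scores["spearman"][i, j]
        p = assoc.brown_p[i, j]
        if not (np.isfinite(rho) and np.isfinite(p)):
            continue
        score = abs(rho)
        if use_max_correlation:
            r = assoc.scores["pearson"][i, j]
            if np.isfinite(r):
                score = max(score, abs(r))
        if score > score_threshold and p < p_threshold:
            edges.append(Edge(assoc.taxa[i], assoc.taxa[j],
                              1 if rho >= 0 else -1, float(p), float(rho)))
    nodes = {}
    for edge in edges:
        for taxon in (edge.a, edge.b):
            nodes.setdefault(taxon, float(mean_rel.get(taxon, 0.0)))
    return CoNetwork(nodes, edges)


def density(n_nodes: int, n_edges: int) -> float:
    """Undirected simple-graph density 2E/(N(N-1))."""
    if n_nodes < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def topology(net: CoNetwork) -> TopologyIndices:
    """Topology indices of a co-occurrence network.

    Average path length on disconnected graphs is the mean over connected
    pairs only; the component count is reported alongside.
    """
    import networkx as nx

    if net.n_nodes < 2:
        raise ValueError("topology requires at least 2 nodes")
    graph = net.to_networkx()
    dens = density(net.n_nodes, net.n_edges)
    clustering = float(np.mean(list(nx.clustering(graph).values())))
    total, pairs = 0.0, 0
    for source, lengths in nx.all_pairs_shortest_path_length(graph):
        for target, length in lengths.items():
            if target != source:
                total += length
                pairs += 1
    apl = total / pairs if pairs else float("nan")
    n_pos = sum(1 for e in net.edges if e.sign > 0)
    e = max(net.n_edges, 1)
    return TopologyIndices(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        network_density=dens,
        clustering_coefficient=clustering,
        average_path_length=apl,
        positive_pct=100.0 * n_pos / e,
        negative_pct=100.0 * (net.n_edges - n_pos) / e,
        n_components=nx.number_connected_components(graph),
    )


def detect_hubs(net: CoNetwork, cutoff: float = 0.2) -> list[str]:
    """Taxa with normalized degree centrality >= cutoff, ranked descending."""
    if net.n_nodes == 0:
        return []
    if net.n_nodes < 2:
        return []
    deg: dict[str, int] = {t: 0 for t in net.nodes}
    for edge in net.edges:
        deg[edge.a] += 1
        deg[edge.b] += 1
    denom = net.n_nodes - 1
    scored = [(t, d / denom) for t, d in deg.items() if d / denom >= cutoff]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return [t for t, _ in scored]


def edge_recovery(net: CoNetwork, planted_edges, check_sign: bool = True,
                  exclude_pairs=None):
    """Precision/recall of retained edges against a planted edge list.

    ``planted_edges`` is an iterable of (taxon_a, taxon_b, sign).
    ``exclude_pairs`` (a set of unordered pairs, e.g. design-driven
    associations from the generator's ground truth) is removed from the
    precision denominator: such pairs are genuinely associated, so calling
    them is not a false discovery, but they are not planted either.
    """
    truth = {frozenset((a, b)): sign for a, b, sign in planted_edges}
    exclude = set(exclude_pairs) if exclude_pairs else set()
    called = {frozenset((e.a, e.b)): e.sign for e in net.edges}
    tp = sum(
        1
        for pair, sign in called.items()
        if pair in truth and (not check_sign or truth[pair] == sign)
    )
    scored = [pair for pair in called if pair in truth or pair not in exclude]
    precision = tp / len(scored) if scored else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return precision, recall
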