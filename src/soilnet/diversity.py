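"""Alpha and beta diversity: rarefaction, Chao1, Shannon, Bray-Curtis,
principal coordinates, PERMANOVA and ANOSIM.

All estimators are implemented from first principles on top of numpy/scipy
primitives so that each one can be checked against closed-form hand values
and (in the tests) against independent library implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io_tables import CountTable

__all__ = [
    "AlphaResult",
    "DistanceMatrix",
    "OrdinationResult",
    "PermTestResult",
    "rarefy",
    "chao1",
    "shannon",
    "observed_richness",
    "alpha_diversity",
    "percent_increase",
    "fold_increase",
    "bray_curtis",
    "pcoa",
    "permanova",
    "anosim",
]


@dataclass(frozen=True)
class AlphaResult:
    """Per-sample alpha diversity indices."""

    samples: list[str]
    s_obs: np.ndarray
    chao1: np.ndarray
    shannon: np.ndarray
    depth: int | None  # rarefaction depth, None if computed on raw counts


@dataclass
class DistanceMatrix:
    samples: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.samples)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.samples), k=1)
        return self.matrix[iu]


@dataclass(frozen=True)
class OrdinationResult:
    """Classical-scaling ordination of a distance matrix."""

    samples: list[str]
    coordinates: np.ndarray  # (n_samples, n_axes), axes ordered by eigenvalue
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_fraction: float  # |sum of dropped negative eigenvalues| / total |eigenvalues|


@dataclass(frozen=True)
class PermTestResult:
    statistic: float
    p_value: float
    permutations: int
    seed: int | None
    r_squared: float | None = None  # PERMANOVA only
    method: str = ""


def rarefy(table: CountTable, depth: int, seed: int | None = None,
           drop_empty: bool = False) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    sizes = table.library_sizes()
    for sample, size in zip(table.samples, sizes):
        if depth > size:
            raise ValueError(
                f"depth {depth} exceeds library size {size} of sample {sample!r}"
            )
    rng = np.random.default_rng(seed)
    out = np.zeros_like(table.counts)
    for j in range(table.n_samples):
        column = table.counts[:, j]
        pool = np.repeat(np.arange(table.n_taxa), column)
        chosen = rng.choice(pool, size=depth, replace=False)
        out[:, j] = np.bincount(chosen, minlength=table.n_taxa)
    taxa = table.taxa
    if drop_empty:
        keep = out.sum(axis=1) > 0
        taxa = [t for t, k in zip(taxa, keep) if k]
        out = out[keep]
    return CountTable(taxa, list(table.samples), out)


def observed_richness(counts: np.ndarray) -> int:
    counts = np.asarray(counts)
    return int(np.count_nonzero(counts > 0))


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1)/(2(F2+1))."""
    counts = np.asarray(counts)
    if np.any(counts < 0) or not np.all(np.mod(counts, 1) == 0):
        raise ValueError("chao1 requires non-negative integer counts")
    s_obs = observed_richness(counts)
    if s_obs == 0:
        raise ValueError("chao1 undefined for an all-zero sample")
    f1 = int(np.count_nonzero(counts == 1))
    f2 = int(np.count_nonzero(counts == 2))
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts: np.ndarray) -> float:
    """Shannon entropy (natural log) of the relative-abundance distribution."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("shannon undefined for a zero-sum sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity(table: CountTable, depth: int | None = None,
                    seed: int | None = None) -> AlphaResult:
    """Compute S_obs, Chao1 and Shannon per sample, optionally after rarefying."""
    work = table if depth is None else rarefy(table, depth, seed=seed)
    s_obs = np.array([observed_richness(work.counts[:, j]) for j in range(work.n_samples)])
    ch = np.array([chao1(work.counts[:, j]) for j in range(work.n_samples)])
    sh = np.array([shannon(work.counts[:, j]) for j in range(work.n_samples)])
    return AlphaResult(list(work.samples), s_obs, ch, sh, depth)


def percent_increase(a: float, b: float) -> float:
    """100*(a-b)/b, reported to 2 decimals."""
    if b <= 0:
        raise ValueError("reference value must be positive")
    return round(100.0 * (a - b) / b, 2)


def fold_increase(a: float, b: float) -> float:
    """(a-b)/b, reported to 2 decimals."""
    if b <= 0:
        raise ValueError("reference value must be positive")
    return round((a - b) / b, 2)


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances between samples on relative abundances."""
    rel = table.relative_abundance()  # validates library sizes > 0
    n = table.n_samples
    out = np.zeros((n, n))
    for j in range(n):
        diff = np.abs(rel[:, j:j + 1] - rel[:, j + 1:]).sum(axis=0)
        sums = (rel[:, j:j + 1] + rel[:, j + 1:]).sum(axis=0)
        out[j, j + 1:] = diff / sums
    out = out + out.T
    return DistanceMatrix(list(table.samples), out)


def pcoa(dist: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Negative eigenvalues are dropped; their aggregate magnitude is reported as
    ``negative_fraction`` instead of applying a correction.
    """
    d2 = dist.matrix ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals).max(), 1.0) * 1e-10
    positive = eigvals > tol
    neg_mass = float(np.abs(eigvals[eigvals < -tol]).sum())
    total_mass = float(np.abs(eigvals).sum())
    lam = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(lam)
    if n_axes is not None:
        lam, coords = lam[:n_axes], coords[:, :n_axes]
    prop = lam / eigvals[positive].sum() if lam.size else lam
    return OrdinationResult(
        list(dist.samples),
        coords,
        lam,
        prop,
        neg_mass / total_mass if total_mass > 0 else 0.0,
    )


def _group_indices(groups) -> list[np.ndarray]:
    labels = np.asarray(groups)
    return [np.flatnonzero(labels == g) for g in np.unique(labels)]


def _validate_groups(dist: DistanceMatrix, groups) -> list[np.ndarray]:
    if len(groups) != len(dist.samples):
        raise ValueError("group labels must match the distance matrix samples")
    idx = _group_indices(groups)
    if len(idx) < 2:
        raise ValueError("need at least 2 groups")
    for members in idx:
        if len(members) < 2:
            raise ValueError("every group needs at least 2 samples")
    return idx


def _permanova_f(d2: np.ndarray, idx: list[np.ndarray], n: int):
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for members in idx:
        sub = d2[np.ix_(members, members)]
        ss_within += sub[np.triu_indices(len(members), k=1)].sum() / len(members)
    ss_between = ss_total - ss_within
    a = len(idx)
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def permanova(dist: DistanceMatrix, groups, n_perm: int = 999,
              seed: int | None = None) -> PermTestResult:
    """Distance-based pseudo-F test with a label-permutation p-value."""
    idx = _validate_groups(dist, groups)
    n = len(dist.samples)
    d2 = dist.matrix ** 2
    f_obs, r2 = _permanova_f(d2, idx, n)
    labels = np.asarray(groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm_labels = labels[rng.permutation(n)]
        perm_idx = _group_indices(perm_labels)
        f_perm, _ = _permanova_f(d2, perm_idx, n)
        if f_perm >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PermTestResult(float(f_obs), float(p), n_perm, seed, r_squared=float(r2),
                          method="permanova")


def _anosim_r(rank_matrix: np.ndarray, within_mask: np.ndarray, n: int) -> float:
    iu = np.triu_indices(n, k=1)
    ranks = rank_matrix[iu]
    within = within_mask[iu]
    m = n * (n - 1) / 2
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def anosim(dist: DistanceMatrix, groups, n_perm: int = 999,
           seed: int | None = None) -> PermTestResult:
    """Rank-based R statistic comparing between- vs within-group distances."""
    _validate_groups(dist, groups)
    n = len(dist.samples)
    labels = np.asarray(groups)
    iu = np.triu_indices(n, k=1)
    ranks = np.zeros((n, n))
    ranks[iu] = rankdata(dist.matrix[iu])
    ranks = ranks + ranks.T
    within = labels[:, None] == labels[None, :]
    r_obs = _anosim_r(ranks, within, n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm_labels = labels[rng.permutation(n)]
        mask = perm_labels[:, None] == perm_labels[None, :]
        if _anosim_r(ranks, mask, n) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PermTestResult(float(r_obs), float(p), n_perm, seed, method="anosim")
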