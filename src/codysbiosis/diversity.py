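"""Alpha/beta diversity, ordination and configuration-comparison tests.

Alpha diversity: Chao1 richness (classic and bias-corrected) and Shannon
entropy.  Beta diversity: Bray-Curtis dissimilarity, principal coordinate
analysis (PCoA) of the Gower-centred squared-distance matrix, one-way
PERMANOVA with label permutation (or exact enumeration on small designs),
and Procrustes superimposition with a PROTEST permutation test.

Bray-Curtis is not Euclidean-embeddable, so PCoA can produce negative
eigenvalues; these are discarded, never corrected, and their count is
reported so the distortion stays visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator

from .core_io import AbundanceTable, DistanceMatrix, SampleMetadata


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from a vector of per-taxon counts.

    Classic: ``S_obs + F1^2 / (2 F2)`` (falling back to
    ``S_obs + F1 (F1 - 1) / 2`` when there are no doubletons); bias-corrected
    (default): ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))``.  F1/F2 are the
    singleton/doubleton counts.  Defined on counts only; always >= S_obs.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.all(np.mod(c, 1) == 0):
        raise ValueError("Chao1 is defined on integer counts")
    s_obs = int((c > 0).sum())
    if s_obs == 0:
        return 0.0
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def shannon(abundances, base: float | None = None) -> float:
    """Shannon diversity ``H = -sum p_i log p_i`` over positive entries.

    ``base=None`` means natural log.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("Shannon diversity is undefined for an all-zero sample")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def alpha_diversity_frame(table: AbundanceTable, counts_scale: int = 10**6) -> pd.DataFrame:
    """Per-sample Chao1 and Shannon for each kingdom.

    Chao1 needs integer counts; fraction tables are rescaled to
    ``counts_scale`` reads and rounded (an approximation noted in the output
    column name).
    """
    rows = {}
    for sid in table.sample_ids:
        rec = {}
        for k in ("bacteria", "fungi"):
            cols = table.taxa_of(k)
            if not cols:
                continue
            v = table.data.loc[sid, cols].values
            counts = v if np.all(np.mod(v, 1) == 0) else np.round(v * counts_scale)
            rec[f"chao1_{k}"] = chao1(counts)
            rec[f"shannon_{k}"] = shannon(v) if v.sum() > 0 else np.nan
        rows[sid] = rec
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis_matrix(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity,
    ``d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)``, in [0, 1]."""
    x = table.data.values
    zero = np.where(x.sum(axis=1) == 0)[0]
    if len(zero) >= 2:
        names = [table.sample_ids[i] for i in zero]
        raise ValueError(
            f"Bray-Curtis is undefined between all-zero samples: {names}"
        )
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d)


@dataclass
class OrdinationResult:
    """PCoA output: sample coordinates plus the eigenvalue bookkeeping."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    n_negative_eigenvalues_discarded: int

    def __post_init__(self) -> None:
        e = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(e) > 1e-9):
            raise ValueError("eigenvalues must be in non-increasing order")
        if (e <= 0).any():
            raise ValueError("retained eigenvalues must be > 0")
        if self.proportion_explained.sum() > 1 + 1e-9:
            raise ValueError("proportion_explained must sum to <= 1")


class PCoA(BaseEstimator):
    """Principal coordinate analysis of a distance matrix.

    Eigendecomposition of the Gower-centred matrix ``-1/2 J D^2 J``;
    coordinates are eigenvectors scaled by sqrt(eigenvalue).  Negative
    eigenvalues (possible for non-Euclidean distances such as Bray-Curtis)
    are discarded and counted in ``n_negative_eigenvalues_discarded_``.

    Parameters
    ----------
    n_axes : int or None
        Number of axes to retain (None keeps all positive axes).
    """

    def __init__(self, n_axes: int | None = None):
        self.n_axes = n_axes

    def fit(self, d: DistanceMatrix) -> "PCoA":
        if self.n_axes is not None and self.n_axes < 1:
            raise ValueError("n_axes must be >= 1")
        D2 = d.values ** 2
        n = D2.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ D2 @ J
        evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        tol = max(abs(evals).max(), 1.0) * 1e-12 if n else 0.0
        positive = evals > tol
        self.n_negative_eigenvalues_discarded_ = int((evals < -tol).sum())
        lam = evals[positive]
        vec = evecs[:, positive]
        k = len(lam) if self.n_axes is None else min(self.n_axes, len(lam))
        coords = vec[:, :k] * np.sqrt(lam[:k])
        denom = lam.sum() if lam.size else 1.0
        self.eigenvalues_ = lam[:k]
        self.proportion_explained_ = lam[:k] / denom
        self.coordinates_ = pd.DataFrame(
            coords, index=d.sample_ids,
            columns=[f"PCo{i + 1}" for i in range(k)],
        )
        return self

    def fit_transform(self, d: DistanceMatrix) -> np.ndarray:
        return self.fit(d).coordinates_.values

    @property
    def result_(self) -> OrdinationResult:
        return OrdinationResult(
            self.coordinates_, self.eigenvalues_, self.proportion_explained_,
            self.n_negative_eigenvalues_discarded_,
        )


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Functional wrapper around :class:`PCoA`."""
    return PCoA(n_axes=n_axes).fit(d).result_


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_perm: int
    seed: int | None
    method: str = "permutation"

    def __post_init__(self) -> None:
        if not (0 <= self.r_squared <= 1):
            raise ValueError("r_squared must be in [0, 1]")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must be in (0, 1]")


def _labels_array(d: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, SampleMetadata):
        groups = groups.group
    if isinstance(groups, pd.Series):
        missing = [s for s in d.sample_ids if s not in groups.index]
        if missing:
            raise KeyError(f"samples missing from group labels: {missing}")
        return groups.loc[d.sample_ids].values
    arr = np.asarray(list(groups))
    if len(arr) != d.n_samples:
        raise ValueError("group labels do not match the distance matrix")
    return arr


def _permanova_F(d2: np.ndarray, codes: np.ndarray, n_groups: int,
                 ss_total: float):
    n = len(codes)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.where(codes == g)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_between = ss_total - ss_within
    df_b, df_w = n_groups - 1, n - n_groups
    f = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def _n_distinct_assignments(counts) -> int:
    total = math.factorial(sum(counts))
    for c in counts:
        total //= math.factorial(c)
    return total


def permanova(d: DistanceMatrix, groups, n_perm: int = 9999,
              seed: int | None = None,
              exact_if_feasible: bool = False,
              exact_limit: int = 10_000) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Partitions ``SS_total = (1/N) sum_{i<j} d_ij^2`` into between- and
    within-group parts; pseudo-F = ``(SS_B/(a-1)) / (SS_W/(N-a))`` and
    ``R^2 = SS_B / SS_total``.  The p-value permutes group labels with the
    add-one correction ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``, or — when
    ``exact_if_feasible`` and the number of distinct label assignments is at
    most ``exact_limit`` — enumerates every assignment exactly
    (``p = #{F >= F_obs} / n_assignments``, which includes the observed one).
    """
    labels = _labels_array(d, groups)
    uniq, codes = np.unique(labels, return_inverse=True)
    counts = np.bincount(codes)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"groups with < 2 samples: {small}")

    d2 = d.values ** 2
    n = d.n_samples
    ss_total = d2.sum() / (2.0 * n)
    f_obs, r2 = _permanova_F(d2, codes, len(uniq), ss_total)

    n_assign = _n_distinct_assignments(counts)
    if exact_if_feasible and n_assign <= exact_limit:
        from sympy.utilities.iterables import multiset_permutations

        hits = 0
        for perm in multiset_permutations(list(codes)):
            f_p, _ = _permanova_F(d2, np.asarray(perm), len(uniq), ss_total)
            if f_p >= f_obs - 1e-12:
                hits += 1
        return PermanovaResult(f_obs, r2, hits / n_assign, n_assign, seed,
                               method="exact")

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_p, _ = _permanova_F(d2, rng.permutation(codes), len(uniq), ss_total)
        if f_p >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(f_obs, r2, p, n_perm, seed)


# ---------------------------------------------------------------------------
# Procrustes / PROTEST
# ---------------------------------------------------------------------------

@dataclass
class ProcrustesResult:
    m_squared: float
    correlation_R: float
    p_value: float
    n_perm: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.m_squared <= 1 + 1e-12):
            raise ValueError("m_squared must be in [0, 1]")
        if abs(self.correlation_R - math.sqrt(max(0.0, 1 - self.m_squared))) > 1e-9:
            raise ValueError("correlation_R must equal sqrt(1 - m_squared)")


def procrustes_r_from_m2(m_squared: float) -> float:
    """Procrustes correlation ``R = sqrt(1 - M^2)``."""
    if not (0 <= m_squared <= 1):
        raise ValueError("m_squared must be in [0, 1]")
    return math.sqrt(1.0 - m_squared)


def _normalize_configuration(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=0)
    norm = np.linalg.norm(x)
    if norm == 0:
        raise ValueError("degenerate configuration (all points identical)")
    return x / norm


def _coords(x) -> np.ndarray:
    if isinstance(x, OrdinationResult):
        return x.coordinates.values
    if isinstance(x, pd.DataFrame):
        return x.values
    return np.asarray(x, dtype=float)


def _m_squared(x: np.ndarray, y: np.ndarray) -> float:
    s = np.linalg.svd(x.T @ y, compute_uv=False).sum()
    return float(max(0.0, 1.0 - s * s))


def procrustes_test(x, y, n_perm: int = 999, seed: int | None = None,
                    sample_ids_x=None, sample_ids_y=None) -> ProcrustesResult:
    """Procrustes superimposition with a PROTEST permutation test.

    Both configurations are centred and scaled to unit sum of squares; the
    optimal rotation comes from the SVD of the cross-product, giving
    ``M^2 = 1 - (sum singular values)^2`` and ``R = sqrt(1 - M^2)``.  The
    first configuration is the reference; PROTEST permutes the rows of the
    second, ``p = (b + 1) / (n_perm + 1)`` where b counts permutations at
    least as concordant (M^2 <= observed).
    """
    if isinstance(x, OrdinationResult) and isinstance(y, OrdinationResult):
        ix, iy = list(x.coordinates.index), list(y.coordinates.index)
        if ix != iy:
            raise ValueError("configurations must share samples in the same order")
    elif sample_ids_x is not None or sample_ids_y is not None:
        if list(sample_ids_x) != list(sample_ids_y):
            raise ValueError("configurations must share samples in the same order")
    xc, yc = _coords(x), _coords(y)
    if xc.shape[0] != yc.shape[0]:
        raise ValueError("configurations must have the same number of samples")
    if min(xc.shape[1], yc.shape[1]) < 2:
        raise ValueError("each configuration needs >= 2 axes")
    k = max(xc.shape[1], yc.shape[1])
    xc = np.pad(xc, ((0, 0), (0, k - xc.shape[1])))
    yc = np.pad(yc, ((0, 0), (0, k - yc.shape[1])))
    xn, yn = _normalize_configuration(xc), _normalize_configuration(yc)
    m2 = _m_squared(xn, yn)

    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        if _m_squared(xn, yn[rng.permutation(len(yn))]) <= m2 + 1e-12:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return ProcrustesResult(m2, procrustes_r_from_m2(min(m2, 1.0)), p, n_perm, seed)


# ---------------------------------------------------------------------------
# presence/absence partitioning
# ---------------------------------------------------------------------------

@dataclass
class SharedTaxaResult:
    group_a: str
    group_b: str
    unique_a: int
    unique_b: int
    shared: int
    taxa_unique_a: list = field(default_factory=list)
    taxa_unique_b: list = field(default_factory=list)
    taxa_shared: list = field(default_factory=list)


def unique_shared_taxa(table: AbundanceTable, metadata: SampleMetadata,
                       group_a: str | None = None,
                       group_b: str | None = None,
                       kingdom: str | None = None) -> SharedTaxaResult:
    """Count taxa unique to each group and shared between them.

    A taxon is "present" in a group when its abundance is > 0 in at least
    one of the group's samples.  ``unique_a + shared`` equals the number of
    taxa present in group A.
    """
    groups = metadata.groups
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise ValueError("specify group_a/group_b when not exactly 2 groups")
        group_a, group_b = groups
    taxa = table.taxa_of(kingdom) if kingdom else table.taxon_ids

    def present(group):
        samples = metadata.samples_in(group)
        samples = [s for s in samples if s in table.data.index]
        sub = table.data.loc[samples, taxa]
        return {t for t in taxa if (sub[t] > 0).any()}

    a, b = present(group_a), present(group_b)
    return SharedTaxaResult(
        group_a, group_b,
        unique_a=len(a - b), unique_b=len(b - a), shared=len(a & b),
        taxa_unique_a=sorted(a - b), taxa_unique_b=sorted(b - a),
        taxa_shared=sorted(a & b),
    )
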