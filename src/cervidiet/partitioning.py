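"""Ordination-based trophic resource partitioning.

Diet profiles are square-root (Hellinger) transformed, pairwise
Bray-Curtis dissimilarities are computed between samples, and the
dissimilarity matrix is embedded with principal coordinates analysis
(PCoA: Gower double-centering B = -1/2 J D^2 J followed by an
eigendecomposition; axes with positive eigenvalues are retained and
scaled by sqrt(eigenvalue), negative eigenvalues are reported but not
corrected).  Axis signs are fixed so the largest-magnitude score on each
axis is positive, making ordinations reproducible.

Species separation on the first two axes is tested per species pair with
a permutation test on a centroid R^2 statistic
(R^2 = 1 - SS_within / SS_total of the 2-D scores), an operational
surrogate for the pairwise factor-fitting procedure used with such
ordinations, with Bonferroni correction across pairs.  The taxa driving
the separation are identified by least-squares fitting of each taxon's
RRA onto the two axis-score columns (a vector-fitting, *envfit*-style
procedure): arrows point along the regression coefficients scaled by
sqrt(R^2), with permutation p-values by row shuffling; the ``top_k``
taxa by R^2 are reported.

Permutation p-values use the add-one estimator
p = (1 + #{permuted >= observed}) / (1 + n_perm) and are reproducible
given (seed, n_perm).
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_model import DietProfile

DEFAULT_N_PERM = 10_000


def hellinger(profile: DietProfile | np.ndarray) -> np.ndarray:
    """Square-root transform of relative abundances (rows sum to 1)."""
    mat = profile.matrix() if isinstance(profile, DietProfile) else \
        np.asarray(profile, dtype=float)
    return np.sqrt(mat)


def bray_curtis(matrix: np.ndarray) -> np.ndarray:
    """Square symmetric Bray-Curtis dissimilarity matrix.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i); rows must be non-negative
    and no two rows may both be all-zero (the pair is undefined).
    """
    matrix = np.asarray(matrix, dtype=float)
    if (matrix < 0).any():
        raise ValueError("Bray-Curtis requires non-negative entries")
    zero = matrix.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValueError("two all-zero rows: Bray-Curtis undefined")
    return squareform(pdist(matrix, metric="braycurtis"))


@dataclass
class OrdinationResult:
    scores: np.ndarray            # n_samples x n_axes
    eigenvalues: np.ndarray       # all eigenvalues, decreasing
    proportion_explained: np.ndarray  # per retained axis, of positive sum
    sample_ids: np.ndarray | None = None
    pair_tests: pd.DataFrame | None = None
    taxon_vectors: pd.DataFrame | None = None
    group_centroids: pd.DataFrame | None = None
    letters: dict[str, str] = field(default_factory=dict)


def pcoa(d: np.ndarray, n_axes: int = 2) -> OrdinationResult:
    """Principal coordinates analysis of a symmetric dissimilarity matrix.

    Returns scores on up to ``n_axes`` positive-eigenvalue axes (truncated
    with a warning-free fallback when fewer exist), all eigenvalues in
    decreasing order, and the proportion of the positive eigenvalue sum
    carried by each retained axis.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be square symmetric")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(np.abs(eigval).max(), 1.0) * 1e-12
    pos = eigval > tol
    k = min(n_axes, int(pos.sum()))
    scores = eigvec[:, :k] * np.sqrt(eigval[:k])
    # sign convention: largest-magnitude score positive on each axis
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    pos_sum = eigval[pos].sum()
    prop = eigval[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    return OrdinationResult(scores=scores, eigenvalues=eigval,
                            proportion_explained=prop)


def _centroid_r2(scores: np.ndarray, labels: np.ndarray) -> float:
    grand = scores.mean(axis=0)
    ss_total = ((scores - grand) ** 2).sum()
    if ss_total == 0:
        return 0.0
    ss_within = 0.0
    for g in np.unique(labels):
        sub = scores[labels == g]
        ss_within += ((sub - sub.mean(axis=0)) ** 2).sum()
    return 1.0 - ss_within / ss_total


def _perm_r2(scores: np.ndarray, n_a: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorized permuted centroid-R2 for a two-group split of sizes
    (n_a, n - n_a).  For two groups R2 depends only on which rows land in
    group a, so each permutation is a random choice of n_a rows."""
    n = len(scores)
    grand = scores.mean(axis=0)
    centered = scores - grand
    ss_total = (centered ** 2).sum()
    sq = (scores ** 2).sum(axis=1)
    sum_all = scores.sum(axis=0)
    sumsq_all = sq.sum()
    out = np.empty(n_perm)
    idx = np.arange(n)
    for b in range(n_perm):
        pick = rng.permutation(idx)[:n_a]
        sa = scores[pick].sum(axis=0)
        sqa = sq[pick].sum()
        sb = sum_all - sa
        sqb = sumsq_all - sqa
        n_b = n - n_a
        ss_within = (sqa - (sa ** 2).sum() / n_a) + \
                    (sqb - (sb ** 2).sum() / n_b)
        out[b] = 1.0 - ss_within / ss_total
    return out


def pairwise_species_test(scores: np.ndarray, labels,
                          n_perm: int = DEFAULT_N_PERM,
                          seed: int | None = 0) -> pd.DataFrame:
    """Permutation test of centroid separation for every species pair.

    Uses the first two columns of ``scores``.  Species with fewer than two
    samples are skipped.  p-values use the add-one estimator; Bonferroni
    correction multiplies by the number of tested pairs.
    """
    scores = np.asarray(scores, dtype=float)[:, :2]
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    groups = [g for g in pd.unique(labels) if (labels == g).sum() >= 2]
    rows = []
    for a, b in itertools.combinations(sorted(map(str, groups)), 2):
        mask = (labels == a) | (labels == b)
        sub, lab = scores[mask], labels[mask]
        obs = _centroid_r2(sub, lab)
        perms = _perm_r2(sub, int((lab == a).sum()), n_perm, rng)
        p = (1.0 + (perms >= obs - 1e-12).sum()) / (1.0 + n_perm)
        rows.append({"species_a": a, "species_b": b, "r2": obs, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
    return out


def significance_letters(pair_tests: pd.DataFrame, alpha: float = 0.05,
                         column: str = "p_bonferroni") -> dict[str, str]:
    """Compact letter display: groups sharing a letter do not differ.

    Greedy insert-and-absorb over the non-significance graph; adequate for
    the handful of species compared here.
    """
    species = sorted(set(pair_tests["species_a"]) |
                     set(pair_tests["species_b"]))
    ns = {s: {s} for s in species}
    for _, row in pair_tests.iterrows():
        if row[column] > alpha:
            ns[row["species_a"]].add(row["species_b"])
            ns[row["species_b"]].add(row["species_a"])
    cliques: list[set] = []
    for s in species:
        placed = False
        for c in cliques:
            if all(s in ns[m] for m in c):
                c.add(s)
                placed = True
        if not placed:
            cliques.append({s})
    cliques = [c for i, c in enumerate(cliques)
               if not any(c < other for j, other in enumerate(cliques)
                          if i != j)]
    letters: dict[str, str] = {s: "" for s in species}
    for letter, c in zip(string.ascii_lowercase, cliques):
        for s in sorted(c):
            letters[s] += letter
    return letters


def taxon_vector_fit(scores: np.ndarray, profile: DietProfile,
                     n_perm: int = DEFAULT_N_PERM,
                     seed: int | None = 0, top_k: int = 6) -> pd.DataFrame:
    """Fit taxon RRA vectors onto the first two ordination axes.

    For each taxon, ordinary least squares of its RRA on the two
    axis-score columns; R^2 is the squared multiple correlation and the
    arrow is the coefficient direction scaled by sqrt(R^2).  Permutation
    p-values shuffle taxon rows.  Constant taxa get R^2 = 0 and no
    direction.  Returns the ``top_k`` taxa by R^2.
    """
    X = np.asarray(scores, dtype=float)[:, :2]
    Y = profile.matrix()
    taxa = profile.taxa
    rng = np.random.default_rng(seed)
    Xc = X - X.mean(axis=0)
    Q, _ = np.linalg.qr(Xc)
    Yc = Y - Y.mean(axis=0)
    y_ss = (Yc ** 2).sum(axis=0)
    proj = Q.T @ Yc                                     # 2 x n_taxa
    fit_ss = (proj ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(y_ss > 0, fit_ss / y_ss, 0.0)
    # coefficients for arrow directions
    coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)      # 2 x n_taxa
    # permutation null: shuffle rows of Y
    n = len(X)
    exceed = np.zeros(len(taxa))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pp = Q.T @ Yc[perm]
        with np.errstate(invalid="ignore", divide="ignore"):
            r2p = np.where(y_ss > 0, (pp ** 2).sum(axis=0) / y_ss, 0.0)
        exceed += r2p >= r2 - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    rows = []
    for j, t in enumerate(taxa):
        b = coef[:, j]
        nrm = np.linalg.norm(b)
        if y_ss[j] == 0 or nrm == 0:
            dx = dy = 0.0
        else:
            dx, dy = b / nrm * np.sqrt(r2[j])
        rows.append({"taxon": t, "r2": float(r2[j]), "p": float(pvals[j]),
                     "dx": float(dx), "dy": float(dy)})
    out = pd.DataFrame(rows).sort_values("r2", ascending=False,
                                         kind="stable")
    return out.head(top_k).reset_index(drop=True)


def ordinate(profile: DietProfile, labels, n_axes: int = 2,
             n_perm: int = DEFAULT_N_PERM, seed: int | None = 0,
             top_k: int = 6) -> OrdinationResult:
    """Full partitioning analysis for one stratum of samples.

    Hellinger -> Bray-Curtis -> PCoA -> pairwise centroid permutation
    tests (Bonferroni) -> taxon vector fitting on the first two axes.
    """
    H = hellinger(profile)
    D = bray_curtis(H)
    res = pcoa(D, n_axes=n_axes)
    res.sample_ids = profile.sample_ids
    labels = np.asarray(labels)
    res.pair_tests = pairwise_species_test(res.scores, labels,
                                           n_perm=n_perm, seed=seed)
    if len(res.pair_tests):
        res.letters = significance_letters(res.pair_tests)
    cent = []
    for g in pd.unique(labels):
        sub = res.scores[labels == g]
        if len(sub):
            cent.append({"species": g,
                         **{f"axis{i+1}": float(m)
                            for i, m in enumerate(sub.mean(axis=0))}})
    res.group_centroids = pd.DataFrame(cent)
    res.taxon_vectors = taxon_vector_fit(res.scores, profile,
                                         n_perm=n_perm, seed=seed,
                                         top_k=top_k)
    return res
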