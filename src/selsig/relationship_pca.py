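"""Genomic relationship matrix (GRM) and PCA-based stratification check.

The GRM follows the GCTA/Yang convention: off-diagonals average
(x_ij - 2p_i)(x_ik - 2p_i) / (2p_i(1-p_i)) over SNPs, while the diagonal
uses the distinct estimator 1 + mean of [x^2 - (1+2p)x + 2p^2] / (2p(1-p)),
whose expectation is exactly 1 under Hardy-Weinberg proportions.  Allele
frequencies are estimated from non-missing genotypes; missing genotypes
contribute nothing, with the per-pair denominator adjusted to the number of
jointly non-missing SNPs (pairwise-complete mode, the default) or the global
SNP count (``global_m`` mode).

PCA is a plain eigendecomposition of the GRM as given (no re-centering),
eigenvalues descending, with scores eigvec * sqrt(eigval) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeDataset, _ext


@dataclass
class Grm:
    matrix: np.ndarray          # n x n, symmetric
    animal_ids: list[str]
    n_snps_used: int
    n_snps_excluded: int = 0    # monomorphic / uncalled SNPs skipped

    def __post_init__(self) -> None:
        a = self.matrix
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if not np.isfinite(a).all():
            raise ValueError("GRM has non-finite entries")


@dataclass
class PcaResult:
    eigenvalues: np.ndarray     # all n, descending
    scores: np.ndarray          # n x k
    variance_fractions: np.ndarray  # all n, sums to 1
    animal_ids: list[str]
    scaled_by_sqrt_eigenvalue: bool = True

    def scores_frame(self) -> pd.DataFrame:
        k = self.scores.shape[1]
        df = pd.DataFrame(self.scores,
                          columns=[f"PC{i + 1}" for i in range(k)])
        df.insert(0, "animal_id", self.animal_ids)
        return df


def compute_grm(ds: GenotypeDataset, pairwise_complete: bool = True) -> Grm:
    """Build the GCTA-style GRM from a genotype dataset.

    Monomorphic SNPs (frequency 0 or 1 among called genotypes) carry no
    information under this scaling and are skipped with a warning.
    """
    g = ds.genotypes.astype(np.float64)
    miss = ds.genotypes == MISSING
    g[miss] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(g, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    n_excl = int((~poly).sum())
    if n_excl:
        warnings.warn(f"{n_excl} monomorphic/uncalled SNPs excluded from GRM")
    g = g[:, poly]
    p = p[poly]
    miss = ~np.isfinite(g)
    m = g.shape[1]
    if m == 0:
        raise ValueError("no polymorphic SNPs for GRM")

    denom = 2.0 * p * (1.0 - p)
    z = (np.nan_to_num(g) - 2.0 * p) / np.sqrt(denom)
    z[miss] = 0.0
    num = z @ z.T

    if pairwise_complete:
        called = (~miss).astype(np.float64)
        m_pair = called @ called.T
        m_pair[m_pair == 0] = np.nan
        grm = num / m_pair
        grm = np.nan_to_num(grm)
    else:
        grm = num / m

    # GCTA diagonal: 1 + mean of (x^2 - (1+2p)x + 2p^2) / (2p(1-p))
    x = np.nan_to_num(g)
    d = (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom
    d[miss] = 0.0
    if pairwise_complete:
        m_self = (~miss).sum(axis=1).astype(np.float64)
        m_self[m_self == 0] = 1.0
    else:
        m_self = m
    np.fill_diagonal(grm, 1.0 + d.sum(axis=1) / m_self)
    grm = (grm + grm.T) / 2.0
    return Grm(matrix=grm, animal_ids=list(ds.animals["animal_id"]),
               n_snps_used=m, n_snps_excluded=n_excl)


def pca_grm(grm: Grm, k: int = 10, sqrt_scale: bool = True) -> PcaResult:
    """Eigendecompose the GRM and return the top-k component scores.

    Variance fractions are eigenvalue / sum of eigenvalues with negative
    eigenvalues floored at zero in the denominator (eigenvalues themselves
    are reported raw).
    """
    n = grm.matrix.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in 1..{n}")
    vals, vecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(n):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    denom = np.clip(vals, 0.0, None).sum()
    fracs = np.clip(vals, 0.0, None) / denom if denom > 0 else np.zeros(n)
    scores = vecs[:, :k]
    if sqrt_scale:
        scores = scores * np.sqrt(np.clip(vals[:k], 0.0, None))
    return PcaResult(eigenvalues=vals, scores=scores,
                     variance_fractions=fracs, animal_ids=grm.animal_ids,
                     scaled_by_sqrt_eigenvalue=sqrt_scale)


def compare_group_scores(
    pca: PcaResult, groups: np.ndarray | list[str], component: int = 0
) -> tuple[dict[str, float], float, float]:
    """Welch two-sample t-test on one principal component between two groups.

    Returns ``(group means, t statistic, two-sided p)``.
    """
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    x = pca.scores[:, component]
    s1 = x[groups == labels[0]]
    s2 = x[groups == labels[1]]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each group needs at least 2 animals")
    if np.ptp(s1) == 0 and np.ptp(s2) == 0 and s1.mean() == s2.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(s1, s2, equal_var=False)
    means = {labels[0]: float(s1.mean()), labels[1]: float(s2.mean())}
    return means, float(t), float(p)


# -- GCTA triplet IO --------------------------------------------------------

def write_grm_gcta(grm: Grm, path_prefix) -> None:
    """Write the GRM as the GCTA triplet (.grm.bin/.grm.N.bin/.grm.id).

    Lower-triangle float32 values, float32 per-pair SNP counts, and a
    two-column id file (family id repeated as the animal id).
    """
    from pathlib import Path
    prefix = Path(str(path_prefix))
    n = grm.matrix.shape[0]
    tri = grm.matrix[np.tril_indices(n)]
    tri.astype("<f4").tofile(_ext(prefix, ".grm.bin"))
    np.full(tri.shape, grm.n_snps_used, dtype="<f4").tofile(
        _ext(prefix, ".grm.N.bin"))
    with open(_ext(prefix, ".grm.id"), "w") as fh:
        for a in grm.animal_ids:
            fh.write(f"{a}\t{a}\n")


def read_grm_gcta(path_prefix) -> Grm:
    from pathlib import Path
    prefix = Path(str(path_prefix))
    ids = [line.split()[1] for line in
           open(_ext(prefix, ".grm.id")) if line.strip()]
    n = len(ids)
    tri = np.fromfile(_ext(prefix, ".grm.bin"), dtype="<f4")
    if len(tri) != n * (n + 1) // 2:
        raise ValueError("GRM triplet size mismatch with id file")
    mat = np.zeros((n, n))
    mat[np.tril_indices(n)] = tri.astype(np.float64)
    mat = mat + np.tril(mat, -1).T
    nsnps = np.fromfile(_ext(prefix, ".grm.N.bin"), dtype="<f4")
    return Grm(matrix=mat, animal_ids=ids,
               n_snps_used=int(nsnps[0]) if len(nsnps) else 0)
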