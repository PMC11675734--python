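"""Univariate selection-signature scan: Weir-Cockerham F_ST, LOWESS, outliers.

Per SNP, the two-population Weir-Cockerham variance components (a: among
populations, b: among individuals within populations, c: within individuals)
give the estimator theta = a / (a + b + c).  Theta is undefined when
a + b + c = 0 (e.g. both populations fixed for the same allele); such SNPs
are excluded from smoothing input and can never be outliers.

The raw theta series is smoothed per chromosome with LOWESS: a local linear
fit with tricube weights over the ``window_snps`` nearest neighbours
(nearest by bp position by default).  Outliers are called per chromosome as
SNPs whose smoothed value exceeds the chromosomal mean of the smoothed
series by ``k_sd`` standard deviations (one-sided, upper).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class SmoothParams:
    window_snps: int = 20
    robust_iterations: int = 0
    x_axis: str = "bp"  # or "index"

    def __post_init__(self) -> None:
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if self.x_axis not in ("bp", "index"):
            raise ValueError("x_axis must be 'bp' or 'index'")


@dataclass
class OutlierParams:
    k_sd: float = 3.0
    basis: str = "smoothed"  # mean/SD computed on smoothed or raw values

    def __post_init__(self) -> None:
        if not self.k_sd > 0:
            raise ValueError("k_sd must be > 0")
        if self.basis not in ("smoothed", "raw"):
            raise ValueError("basis must be 'smoothed' or 'raw'")


@dataclass
class FstScanResult:
    """Per-SNP scan table plus per-chromosome outlier thresholds."""

    table: pd.DataFrame  # snp_id chrom pos a b c theta smoothed is_outlier
    chrom_stats: pd.DataFrame  # chrom mean sd threshold

    def outlier_snp_ids(self) -> set[str]:
        return set(self.table.loc[self.table["is_outlier"], "snp_id"])

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Weir-Cockerham estimator (r = 2 populations)
# ---------------------------------------------------------------------------

def wc_fst(pop_counts) -> tuple[float, float, float, float]:
    """Weir-Cockerham variance components for one SNP, two populations.

    Parameters
    ----------
    pop_counts:
        Two (n_AA, n_Aa, n_aa) genotype-count triples, one per population.

    Returns ``(a, b, c, theta)``; theta is NaN when a + b + c = 0.
    """
    (c1, c2) = pop_counts
    counts = np.array([c1, c2], dtype=np.float64)  # 2 x 3
    if counts.shape != (2, 3) or (counts < 0).any():
        raise ValueError("expected two non-negative (n_AA, n_Aa, n_aa) triples")
    n = counts.sum(axis=1)
    if (n < 1).any():
        raise ValueError("each population needs at least one genotyped animal")
    a, b, c = _wc_components(
        n1=n[0], n2=n[1],
        p1=(2 * counts[0, 0] + counts[0, 1]) / (2 * n[0]),
        p2=(2 * counts[1, 0] + counts[1, 1]) / (2 * n[1]),
        h1=counts[0, 1] / n[0], h2=counts[1, 1] / n[1],
    )
    tot = a + b + c
    theta = a / tot if tot != 0 else np.nan
    return float(a), float(b), float(c), float(theta)


def _wc_components(n1, n2, p1, p2, h1, h2):
    """Vectorizable core of the two-population Weir-Cockerham estimator."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
    a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    return a, b, c


def wc_fst_scan(ds: GenotypeDataset, popA_idx, popB_idx) -> pd.DataFrame:
    """Vectorized per-SNP Weir-Cockerham components between two animal sets.

    Missing genotypes are dropped per SNP and population.  SNPs where a
    population has no called genotype, or where a + b + c = 0, get NaN
    theta.
    """
    out = ds.snps[["snp_id", "chrom", "pos"]].copy()
    comp = {}
    for name, idx in (("A", popA_idx), ("B", popB_idx)):
        g = ds.genotypes[np.asarray(idx)]
        called = g != MISSING
        n = called.sum(axis=0).astype(np.float64)
        het = ((g == 1) & called).sum(axis=0)
        dose = np.where(called, g, 0).sum(axis=0).astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            comp[name] = (n, dose / (2.0 * n), het / np.maximum(n, 1))
    nA, pA, hA = comp["A"]
    nB, pB, hB = comp["B"]
    ok = (nA >= 1) & (nB >= 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a, b, c = _wc_components(nA, nB, pA, pB, hA, hB)
        tot = a + b + c
        theta = np.where(ok & (tot != 0), a / np.where(tot != 0, tot, 1.0), np.nan)
    a = np.where(ok, a, np.nan)
    b = np.where(ok, b, np.nan)
    c = np.where(ok, c, np.nan)
    out["a"], out["b"], out["c"], out["theta"] = a, b, c, theta
    return out


# ---------------------------------------------------------------------------
# LOWESS
# ---------------------------------------------------------------------------

def _lowess_1d(x: np.ndarray, y: np.ndarray, k: int, iters: int) -> np.ndarray:
    """Local linear fit with tricube weights over k nearest neighbours.

    x must be strictly increasing.  Optional bisquare robustness
    iterations.  Evaluated at every x.
    """
    n = len(x)
    k = min(k, n)
    fitted = np.empty(n)
    delta = np.ones(n)
    for _ in range(iters + 1):
        left = 0
        for i in range(n):
            # slide the window of k points to the nearest neighbourhood of x[i]
            while left + k < n and x[left + k] - x[i] < x[i] - x[left]:
                left += 1
            sl = slice(left, left + k)
            xs, ys = x[sl], y[sl]
            d = np.abs(xs - x[i])
            dmax = d.max()
            if dmax <= 0:
                w = np.ones_like(d)
            else:
                w = np.clip(1.0 - (d / dmax) ** 3, 0.0, None) ** 3
            w = w * delta[sl]
            sw = w.sum()
            if sw <= 0:
                fitted[i] = y[i]
                continue
            xm = (w * xs).sum() / sw
            ym = (w * ys).sum() / sw
            sxx = (w * (xs - xm) ** 2).sum()
            if sxx <= 1e-12 * max(1.0, xm * xm):
                fitted[i] = ym
            else:
                beta = (w * (xs - xm) * (ys - ym)).sum() / sxx
                fitted[i] = ym + beta * (x[i] - xm)
        if iters:
            resid = y - fitted
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            delta = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, 1.0) ** 2
    return fitted


def lowess_smooth(values: np.ndarray, marker_map: pd.DataFrame,
                  params: SmoothParams | None = None) -> np.ndarray:
    """Smooth a per-SNP statistic per chromosome with windowed LOWESS.

    NaN entries are excluded from the fit and filled by linear
    interpolation of the smoothed curve at their positions.  Chromosomes
    with fewer defined values than the window are passed through with a
    warning.
    """
    params = params or SmoothParams()
    values = np.asarray(values, dtype=np.float64)
    chroms = marker_map["chrom"].to_numpy()
    pos = marker_map["pos"].to_numpy().astype(np.float64)
    out = np.empty_like(values)
    for ch in np.unique(chroms):
        sel = chroms == ch
        p = pos[sel]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"positions not sorted on chromosome {ch}")
        if np.any(np.diff(p) == 0):
            p = p + np.arange(len(p)) * 1e-6  # break exact ties stably
        x = p if params.x_axis == "bp" else np.arange(len(p), dtype=np.float64)
        v = values[sel]
        defined = np.isfinite(v)
        if defined.sum() < params.window_snps:
            warnings.warn(
                f"chromosome {ch}: fewer defined values than the window; "
                "passed through unsmoothed")
            out[sel] = v
            continue
        sm = _lowess_1d(x[defined], v[defined], params.window_snps,
                        params.robust_iterations)
        full = np.empty(len(v))
        full[defined] = sm
        if (~defined).any():
            full[~defined] = np.interp(x[~defined], x[defined], sm)
        out[sel] = full
    return out


# ---------------------------------------------------------------------------
# outlier calling
# ---------------------------------------------------------------------------

def call_outliers(table: pd.DataFrame,
                  params: OutlierParams | None = None) -> FstScanResult:
    """Flag SNPs whose smoothed value exceeds the per-chromosome mean + k*SD.

    ``table`` must carry snp_id/chrom/pos/theta/smoothed columns.  A
    chromosome with zero SD yields no outliers.  SNPs with undefined theta
    are never flagged.
    """
    params = params or OutlierParams()
    table = table.copy()
    flags = np.zeros(len(table), dtype=bool)
    stats_rows = []
    chroms = table["chrom"].to_numpy()
    basis_col = "smoothed" if params.basis == "smoothed" else "theta"
    for ch in np.unique(chroms):
        sel = chroms == ch
        basis = table.loc[sel, basis_col].to_numpy(dtype=np.float64)
        basis = basis[np.isfinite(basis)]
        if len(basis) == 0:
            stats_rows.append((ch, np.nan, np.nan, np.nan))
            continue
        mu = basis.mean()
        sd = basis.std(ddof=1) if len(basis) > 1 else 0.0
        thr = mu + params.k_sd * sd if np.isfinite(params.k_sd) else np.inf
        if sd > 0:
            sm = table.loc[sel, "smoothed"].to_numpy(dtype=np.float64)
            ok = np.isfinite(table.loc[sel, "theta"].to_numpy(dtype=np.float64))
            flags[sel] = ok & np.isfinite(sm) & (sm > thr)
        stats_rows.append((ch, mu, sd, thr))
    table["is_outlier"] = flags
    chrom_stats = pd.DataFrame(
        stats_rows, columns=["chrom", "mean", "sd", "threshold"])
    return FstScanResult(table=table, chrom_stats=chrom_stats)


def fst_scan(ds: GenotypeDataset, popA_idx, popB_idx,
             smooth: SmoothParams | None = None,
             outlier: OutlierParams | None = None) -> FstScanResult:
    """Full univariate branch: per-SNP theta, LOWESS smoothing, outliers."""
    table = wc_fst_scan(ds, popA_idx, popB_idx)
    table["smoothed"] = lowess_smooth(
        table["theta"].to_numpy(), ds.snps, smooth)
    return call_outliers(table, outlier)
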