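"""Multivariate branch: stepwise (SDA) and canonical (CDA) discriminant analysis.

SNP panels are p >> n, so canonical discriminant analysis cannot be fitted
directly: the data matrix must first be reduced to a full-rank subset.
Stepwise discriminant analysis does this greedily on Wilks' lambda
(det(W)/det(T), within- over total-SSCP determinant): at each step the
candidate with the largest partial F for entry is added if significant at
``slentry``, then the weakest selected variable is tested for removal at
``slstay`` — the STEPDISC procedure.  For genome panels the reduction is
hierarchical: stepwise within each chromosome first, the survivors pooled,
and the pooled set re-run genome-wide until fewer markers than animals
remain.

The canonical solution for two groups is the single discriminant direction
W^-1 (m2 - m1).  Scores are scaled to unit pooled within-group variance.
Separation is measured by Mahalanobis D^2 between centroids, tested with
Hotelling's T^2 via its exact F transform, and resubstitution assignment to
the nearest centroid (equal priors) gives the misclassification error.

Missing genotypes are mean-imputed per SNP before any discriminant
computation (the F_ST branch, by contrast, works on raw genotype counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class SdaParams:
    """Stepwise selection controls (STEPDISC-style defaults)."""

    slentry: float = 0.15
    slstay: float = 0.15
    entry_multiplicity: str = "bonferroni"  # or "none"
    tolerance: float = 1e-7       # minimum 1 - R^2 vs already-selected
    max_selected: int | None = None  # default n_animals - n_groups - 2
    forced_in: tuple[int, ...] = ()  # column indices always included

    def __post_init__(self) -> None:
        if not (0 < self.slentry <= 1 and 0 < self.slstay <= 1):
            raise ValueError("slentry/slstay must lie in (0, 1]")
        if self.entry_multiplicity not in ("bonferroni", "none"):
            raise ValueError("entry_multiplicity must be 'bonferroni' or 'none'")
        if self.max_selected is not None and self.max_selected < len(self.forced_in):
            raise ValueError("max_selected smaller than forced_in set")


@dataclass
class SdaResult:
    """Trace of one stepwise run (entry order, Wilks' lambda path)."""

    selected: list[int]                 # column indices, entry order
    lambda_trace: list[float]           # Wilks' lambda after each event
    steps: pd.DataFrame                 # event log: step, action, index, F, p, lambda
    per_chromosome_counts: dict[int, int] = field(default_factory=dict)
    rounds: int = 1


@dataclass
class CdaResult:
    """Canonical solution and two-group inference for a variable subset."""

    variable_idx: np.ndarray
    coefficients_raw: np.ndarray        # canonical weights on raw variables
    coefficients_std: np.ndarray        # weights x pooled within-group SD
    scores: np.ndarray                  # per-animal CAN values
    centroids: dict[str, float]
    mahalanobis_d2: float
    hotelling_t2: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    assignment_error: float
    confusion: pd.DataFrame
    group_labels: tuple[str, str]


# ---------------------------------------------------------------------------
# Wilks' lambda
# ---------------------------------------------------------------------------

def _group_indices(groups) -> tuple[np.ndarray, list]:
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    codes = np.searchsorted(np.array(labels, dtype=object), groups)
    return codes, labels


def _sscp(X: np.ndarray, groups) -> tuple[np.ndarray, np.ndarray]:
    """Within-group (W) and total (T) SSCP matrices."""
    codes, labels = _group_indices(groups)
    Xt = X - X.mean(axis=0)
    Xw = X.copy().astype(np.float64)
    for gi in range(len(labels)):
        sel = codes == gi
        Xw[sel] -= Xw[sel].mean(axis=0)
    return Xw.T @ Xw, Xt.T @ Xt


def wilks_lambda(X: np.ndarray, groups, subset=None) -> float:
    """Wilks' lambda det(W)/det(T) over a variable subset (1.0 if empty)."""
    X = np.asarray(X, dtype=np.float64)
    if subset is not None:
        subset = list(subset)
        if len(subset) == 0:
            return 1.0
        X = X[:, subset]
    if X.shape[1] == 0:
        return 1.0
    W, T = _sscp(X, groups)
    evals = np.linalg.eigvalsh(T)
    if evals[-1] <= 0 or evals[0] <= 1e-10 * evals[-1]:
        raise np.linalg.LinAlgError(
            "singular total SSCP — collinear or constant variables in subset")
    sign_t, logdet_t = np.linalg.slogdet(T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_w <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def _centered_views(X: np.ndarray, groups):
    codes, labels = _group_indices(groups)
    Xt = X - X.mean(axis=0)
    Xw = X.astype(np.float64).copy()
    for gi in range(len(labels)):
        sel = codes == gi
        Xw[sel] -= Xw[sel].mean(axis=0)
    return Xw, Xt, len(labels)


def _safe_inv(M: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(M)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(M)


def sda_select(X: np.ndarray, groups, params: SdaParams | None = None,
               order_key: np.ndarray | None = None) -> SdaResult:
    """Greedy Wilks'-lambda stepwise variable selection.

    At each step the partial F for entering candidate v given the current
    set S is ``F = ((n - g - q)/(g - 1)) (1 - lam)/lam`` with
    ``lam = Lambda(S + v)/Lambda(S)`` and ``q = |S|``; the best candidate
    enters if its p-value is at most ``slentry`` and its residual variance
    fraction against S (1 - R^2, total metric) is at least ``tolerance``.
    With ``entry_multiplicity='bonferroni'`` (the default) the entry
    threshold is ``slentry`` divided by the number of candidates scanned at
    that step — without this, scanning thousands of SNPs per step admits
    hundreds of expected false entries and the selection runs to its cap on
    pure noise.
    After each entry the weakest non-forced variable is removed if its
    partial F for removal has p > ``slstay``.  Ties on F break to the
    lowest ``order_key`` (map order), making runs deterministic.
    """
    params = params or SdaParams()
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    codes, labels = _group_indices(groups)
    g = len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if np.bincount(codes).min() < 2:
        raise ValueError("each group needs at least 2 animals")
    cap = params.max_selected
    if cap is None:
        cap = max(n - g - 2, 0)
    cap = min(cap, n - g - 1, p)

    Xw, Xt, _ = _centered_views(X, groups)
    wdiag = np.einsum("ij,ij->j", Xw, Xw)
    tdiag = np.einsum("ij,ij->j", Xt, Xt)
    tiny = 1e-12

    selected: list[int] = []
    Wcross = np.empty((0, p))
    Tcross = np.empty((0, p))
    lam_total = 1.0
    lam_trace: list[float] = []
    events = []
    forced = list(dict.fromkeys(params.forced_in))
    in_set = np.zeros(p, dtype=bool)
    seen_sets: set[frozenset] = set()

    def cond_ss(cross: np.ndarray, diag: np.ndarray):
        """Residual SS of every column given the selected set, one metric."""
        if not selected:
            return diag.copy()
        S = cross[:, selected]  # q x q gram of selected
        Minv = _safe_inv(S)
        A = Minv @ cross
        return diag - np.einsum("ij,ij->j", cross, A)

    def enter(j: int, F: float, pval: float, action: str):
        nonlocal lam_total, Wcross, Tcross
        ssw = cond_ss_w[j] if cond_ss_w is not None else wdiag[j]
        sst = cond_ss_t[j] if cond_ss_t is not None else tdiag[j]
        lam_p = min(max(ssw / sst, tiny), 1.0) if sst > tiny else 1.0
        lam_total *= lam_p
        selected.append(j)
        in_set[j] = True
        Wcross = np.vstack([Wcross, Xw[:, j] @ Xw])
        Tcross = np.vstack([Tcross, Xt[:, j] @ Xt])
        lam_trace.append(lam_total)
        events.append((len(events) + 1, action, j, F, pval, lam_total))

    # forced variables enter unconditionally, in the given order
    cond_ss_w = cond_ss_t = None
    for j in forced:
        cond_ss_w = cond_ss(Wcross, wdiag)
        cond_ss_t = cond_ss(Tcross, tdiag)
        if selected and cond_ss_t[j] < params.tolerance * max(tdiag[j], tiny):
            raise ValueError(
                f"forced-in variable {j} collinear with earlier forced set")
        enter(j, np.nan, np.nan, "forced")

    max_iter = 4 * cap + 20
    for _ in range(max_iter):
        if len(selected) >= cap:
            break
        q = len(selected)
        cond_ss_w = cond_ss(Wcross, wdiag)
        cond_ss_t = cond_ss(Tcross, tdiag)
        df2 = n - g - q
        if df2 < 1:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            lam_p = cond_ss_w / cond_ss_t
        eligible = (~in_set) & (cond_ss_t > params.tolerance * np.maximum(tdiag, tiny)) \
            & (tdiag > tiny) & np.isfinite(lam_p)
        lam_p = np.clip(lam_p, tiny, 1.0)
        F = (df2 / (g - 1.0)) * (1.0 - lam_p) / lam_p
        F[~eligible] = -np.inf
        j = int(np.argmax(F)) if order_key is None else _argmax_tiebreak(F, order_key)
        entered = False
        if np.isfinite(F[j]) and F[j] >= 0:
            pval = float(stats.f.sf(F[j], g - 1, df2))
            thr = params.slentry
            if params.entry_multiplicity == "bonferroni":
                thr = params.slentry / max(int(eligible.sum()), 1)
            if pval <= thr:
                enter(j, float(F[j]), pval, "enter")
                entered = True

        # removal test on the weakest non-forced selected variable
        removed = False
        q = len(selected)
        removable = [v for v in selected if v not in forced]
        if q >= 2 and removable and n - g - q + 1 >= 1:
            Winv = _safe_inv(Wcross[:, selected])
            Tinv = _safe_inv(Tcross[:, selected])
            dW = np.diag(Winv)
            dT = np.diag(Tinv)
            with np.errstate(divide="ignore", invalid="ignore"):
                lam_r = np.clip(dT / dW, tiny, 1.0)
            df2r = n - g - q + 1
            Fr = (df2r / (g - 1.0)) * (1.0 - lam_r) / lam_r
            pr = stats.f.sf(Fr, g - 1, df2r)
            cand = [(pr[i], -Fr[i], i) for i, v in enumerate(selected)
                    if v not in forced]
            worst_p, _, wi = max(cand)
            if worst_p > params.slstay:
                v = selected[wi]
                lam_total = lam_total / lam_r[wi]
                del selected[wi]
                in_set[v] = False
                Wcross = np.delete(Wcross, wi, axis=0)
                Tcross = np.delete(Tcross, wi, axis=0)
                lam_trace.append(lam_total)
                events.append((len(events) + 1, "remove", v,
                               float(Fr[wi]), float(worst_p), lam_total))
                removed = True

        if not entered and not removed:
            break
        key = frozenset(selected)
        if key in seen_sets:  # guard against enter/remove cycling
            break
        seen_sets.add(key)

    steps = pd.DataFrame(
        events, columns=["step", "action", "index", "F", "p", "wilks_lambda"])
    return SdaResult(selected=list(selected), lambda_trace=lam_trace, steps=steps)


def _argmax_tiebreak(F: np.ndarray, order_key: np.ndarray) -> int:
    best = F.max()
    ties = np.nonzero(F == best)[0]
    if len(ties) == 1:
        return int(ties[0])
    return int(ties[np.argmin(order_key[ties])])


# ---------------------------------------------------------------------------
# hierarchical reduction
# ---------------------------------------------------------------------------

def mean_impute(ds: GenotypeDataset) -> np.ndarray:
    """Float genotype matrix with missing entries replaced by the SNP mean."""
    import warnings as _warnings
    g = ds.genotypes.astype(np.float64)
    miss = ds.genotypes == MISSING
    g[miss] = np.nan
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(g, axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    g[miss] = np.broadcast_to(col_mean, g.shape)[miss]
    return g


def hierarchical_sda(ds: GenotypeDataset, groups,
                     params: SdaParams | None = None,
                     X: np.ndarray | None = None) -> SdaResult:
    """Chromosome-blocked stepwise reduction for p >> n panels.

    Pass 1 runs ``sda_select`` independently per chromosome; the retained
    SNPs are pooled and re-run genome-wide while the pool still holds at
    least as many markers as animals.  Returns global column indices into
    the dataset's map order.
    """
    params = params or SdaParams()
    if params.forced_in:
        raise ValueError("hierarchical_sda does not take forced_in; "
                         "use cda_refit_with_augmentation")
    if X is None:
        X = mean_impute(ds)
    n = X.shape[0]
    chroms = ds.snps["chrom"].to_numpy()
    joined: list[int] = []
    per_chrom: dict[int, int] = {}
    traces = []
    for ch in np.unique(chroms):
        cols = np.nonzero(chroms == ch)[0]
        res = sda_select(X[:, cols], groups, params)
        picked = [int(cols[j]) for j in res.selected]
        per_chrom[int(ch)] = len(picked)
        joined.extend(picked)
        traces.append(res.steps.assign(round=1, chrom=int(ch),
                                       index=[int(cols[j]) for j in res.steps["index"]]))
    joined.sort()
    rounds = 1
    while len(joined) >= n:
        rounds += 1
        cols = np.array(joined)
        res = sda_select(X[:, cols], groups, params)
        joined = sorted(int(cols[j]) for j in res.selected)
        traces.append(res.steps.assign(round=rounds, chrom=0,
                                       index=[int(cols[j]) for j in res.steps["index"]]))
        if res.steps.empty:
            break
    traces = [t for t in traces if not t.empty]
    steps = (pd.concat(traces, ignore_index=True)
             if traces else pd.DataFrame(
                 columns=["step", "action", "index", "F", "p",
                          "wilks_lambda", "round", "chrom"]))
    final_lambda = (wilks_lambda(X, groups, joined) if joined else 1.0)
    return SdaResult(selected=joined, lambda_trace=[final_lambda],
                     steps=steps, per_chromosome_counts=per_chrom,
                     rounds=rounds)


# ---------------------------------------------------------------------------
# canonical discriminant analysis (two groups)
# ---------------------------------------------------------------------------

def cda_fit(X: np.ndarray, groups, variable_idx=None,
            positive_group: str | None = None) -> CdaResult:
    """Fit the single canonical function separating two groups.

    ``positive_group`` fixes the sign orientation (that group's centroid is
    positive); defaults to the second group label in sorted order.
    """
    X = np.asarray(X, dtype=np.float64)
    if variable_idx is not None:
        variable_idx = np.asarray(list(variable_idx), dtype=int)
        Xs = X[:, variable_idx]
    else:
        Xs = X
        variable_idx = np.arange(X.shape[1])
    codes, labels = _group_indices(groups)
    if len(labels) != 2:
        raise ValueError("cda_fit handles exactly two groups")
    n, p = Xs.shape
    n1 = int((codes == 0).sum())
    n2 = int((codes == 1).sum())
    if p == 0:
        raise ValueError("empty variable set")
    if p > n - 3:
        raise ValueError(f"{p} variables for {n} animals: need p <= n - 3")
    m1 = Xs[codes == 0].mean(axis=0)
    m2 = Xs[codes == 1].mean(axis=0)
    Xw = Xs.copy()
    Xw[codes == 0] -= m1
    Xw[codes == 1] -= m2
    W = Xw.T @ Xw
    S_pooled = W / (n - 2)
    diff = m2 - m1
    try:
        sol = np.linalg.solve(S_pooled, diff)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular pooled covariance — reduce the variable set "
            "(stepwise tolerance should normally prevent this)") from exc
    d2 = float(diff @ sol)
    if d2 <= 0:
        d2 = 0.0
    # canonical vector prop. to S_pooled^-1 diff; scale scores to unit
    # pooled within-group variance
    var_within = float(sol @ S_pooled @ sol)
    if var_within > 0:
        coef = sol / np.sqrt(var_within)
    else:
        coef = sol
    grand = Xs.mean(axis=0)
    scores = (Xs - grand) @ coef
    cent = {labels[0]: float(scores[codes == 0].mean()),
            labels[1]: float(scores[codes == 1].mean())}
    ref = positive_group if positive_group is not None else labels[1]
    if ref not in cent:
        raise ValueError(f"unknown positive_group {ref!r}")
    if cent[ref] < 0:
        coef = -coef
        scores = -scores
        cent = {k: -v for k, v in cent.items()}

    t2 = (n1 * n2 / (n1 + n2)) * d2
    df1, df2 = p, n1 + n2 - p - 1
    f_stat = t2 * df2 / ((n1 + n2 - 2) * p)
    p_value = float(stats.f.sf(f_stat, df1, df2)) if d2 > 0 else 1.0

    # nearest-centroid resubstitution with equal priors
    c0, c1 = cent[labels[0]], cent[labels[1]]
    mid = (c0 + c1) / 2.0
    if c1 >= c0:
        pred = (scores > mid).astype(int)
    else:
        pred = (scores < mid).astype(int)
    conf = pd.crosstab(
        pd.Series(np.array(labels, dtype=object)[codes], name="true"),
        pd.Series(np.array(labels, dtype=object)[pred], name="assigned"),
        dropna=False,
    ).reindex(index=labels, columns=labels, fill_value=0)
    err = float((pred != codes).mean())

    sd_within = np.sqrt(np.diag(S_pooled))
    return CdaResult(
        variable_idx=variable_idx,
        coefficients_raw=coef,
        coefficients_std=coef * sd_within,
        scores=scores,
        centroids=cent,
        mahalanobis_d2=d2,
        hotelling_t2=float(t2),
        f_statistic=float(f_stat),
        df=(df1, df2),
        p_value=p_value,
        assignment_error=err,
        confusion=conf,
        group_labels=(labels[0], labels[1]),
    )


def cda_refit_with_augmentation(
    ds: GenotypeDataset, groups, fixed_set,
    params: SdaParams | None = None,
    X: np.ndarray | None = None,
    positive_group: str | None = None,
) -> tuple[SdaResult, CdaResult]:
    """Re-run stepwise over the whole panel with a fixed marker set forced in,
    then fit the canonical function on the union."""
    params = params or SdaParams()
    if X is None:
        X = mean_impute(ds)
    fixed = tuple(int(j) for j in fixed_set)
    p2 = SdaParams(slentry=params.slentry, slstay=params.slstay,
                   entry_multiplicity=params.entry_multiplicity,
                   tolerance=params.tolerance,
                   max_selected=params.max_selected, forced_in=fixed)
    if fixed:
        sda = sda_select(X, groups, p2)
    else:
        sda = hierarchical_sda(ds, groups, params, X=X)
    cda = cda_fit(X, groups, variable_idx=sda.selected,
                  positive_group=positive_group)
    return sda, cda
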