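"""Community statistics: dissimilarity, ANOSIM, PCA, rank tests,
and per-formula correlation screening against fluorescence components.

These are from-scratch implementations of the standard community-ecology
layer (Bray-Curtis, ANOSIM with permutation p-values, SVD-based PCA,
Wilcoxon rank-sum, Pearson/Spearman) so that every statistic reported by
the pipeline is reproducible from first principles; unit tests cross-check
them against independent library implementations.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist
from statsmodels.stats.multitest import multipletests

from .assignment import AssignedSample
from .formula import Formula


@dataclass
class DissimilarityMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have zero diagonal")

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.matrix[iu]


@dataclass
class AnosimResult:
    r: float
    p: float
    n_permutations: int
    seed: int


@dataclass
class PcaResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # variables x components
    explained_variance_ratio: np.ndarray
    ids: Optional[list[str]] = None
    columns: Optional[list[str]] = None


@dataclass
class FormulaCorrelation:
    """Per-formula Spearman screening against component scores.

    ``table`` columns: formula, component, rho, p, significant,
    bh_significant. ``summary`` has, per component, the count of
    significantly positively correlated formulas and their
    intensity-weighted mean H/C and O/C.
    """

    table: pd.DataFrame
    summary: pd.DataFrame
    n_skipped: int
    alpha: float


def bray_curtis(matrix: pd.DataFrame | np.ndarray, ids: Sequence[str] | None = None) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity between sample rows:
    d(x, y) = sum|xi - yi| / sum(xi + yi)."""
    if isinstance(matrix, pd.DataFrame):
        ids = list(matrix.index.astype(str))
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        ids = list(ids) if ids is not None else [str(i) for i in range(X.shape[0])]
    if np.any(X < 0):
        raise ValueError("abundances must be non-negative")
    row_sums = X.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("all-zero sample row")
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        num = np.abs(X[i] - X[i + 1 :]).sum(axis=1)
        den = (X[i] + X[i + 1 :]).sum(axis=1)
        D[i, i + 1 :] = num / den
    D = D + D.T
    return DissimilarityMatrix(ids=ids, matrix=D)


def anosim_r(d: DissimilarityMatrix | np.ndarray, groups: Sequence) -> float:
    """The ANOSIM R statistic for a fixed labelling.

    R = (mean rank of between-group dissimilarities - mean rank of
    within-group dissimilarities) / (M/2), M = n(n-1)/2, ranks computed
    over all pairwise dissimilarities with average ties.
    """
    if isinstance(d, DissimilarityMatrix):
        condensed = d.condensed()
        n = len(d.ids)
    else:
        mat = np.asarray(d, dtype=float)
        n = mat.shape[0]
        condensed = mat[np.triu_indices(n, k=1)]
    labels = np.asarray(groups)
    if len(labels) != n:
        raise ValueError("groups length must match the number of samples")
    ranks = rankdata(condensed)
    iu, ju = np.triu_indices(n, k=1)
    within = labels[iu] == labels[ju]
    m = len(condensed)
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    return float((r_b - r_w) / (m / 2.0))


def anosim(
    d: DissimilarityMatrix,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities with a label-permutation p-value.

    p = (1 + #{permuted R >= observed R}) / (1 + n_permutations).
    """
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if np.any(counts < 2):
        small = uniq[counts < 2]
        raise ValueError(f"every group needs >= 2 samples; too small: {list(small)}")
    condensed = d.condensed()
    n = len(d.ids)
    ranks = rankdata(condensed)
    iu, ju = np.triu_indices(n, k=1)
    m = len(condensed)

    def _r(lab: np.ndarray) -> float:
        within = lab[iu] == lab[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    observed = _r(labels)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        if _r(rng.permutation(labels)) >= observed:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return AnosimResult(r=float(observed), p=float(p), n_permutations=n_permutations, seed=seed)


def pca(matrix: pd.DataFrame | np.ndarray, standardize: bool = False) -> PcaResult:
    """PCA via SVD of the column-centered (optionally standardized) matrix.

    Scores are left singular vectors scaled by singular values; explained
    variance fractions are normalized squared singular values.
    """
    if isinstance(matrix, pd.DataFrame):
        ids = list(matrix.index.astype(str))
        columns = list(matrix.columns.astype(str))
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        ids = columns = None
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    total = float((Xc**2).sum())
    if total == 0:
        warnings.warn("constant input matrix: zero variance", stacklevel=2)
        k = min(X.shape)
        return PcaResult(
            scores=np.zeros((X.shape[0], k)),
            loadings=np.zeros((X.shape[1], k)),
            explained_variance_ratio=np.zeros(k),
            ids=ids,
            columns=columns,
        )
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    return PcaResult(
        scores=U * S,
        loadings=Vt.T,
        explained_variance_ratio=S**2 / (S**2).sum(),
        ids=ids,
        columns=columns,
    )


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test on two samples.

    Returns (W, p) where W is the rank sum of ``x`` in the pooled
    ranking (average ties). Exact enumeration of all C(n+m, n) rank
    allocations when both samples have <= 10 observations; otherwise a
    tie-corrected normal approximation. ``alternative`` is "two-sided",
    "greater" (x tends larger) or "less".
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, m = len(x), len(y)
    w_obs = float(ranks[:n].sum())
    if n <= 10 and m <= 10:
        sums = np.array(
            [ranks[list(idx)].sum() for idx in combinations(range(n + m), n)]
        )
        total = len(sums)
        eps = 1e-9
        p_ge = float((sums >= w_obs - eps).sum()) / total
        p_le = float((sums <= w_obs + eps).sum()) / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return w_obs, p
    N = n + m
    mean = n * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var == 0:
        return w_obs, 1.0
    z = (w_obs - mean) / math.sqrt(var)
    from scipy.stats import norm

    if alternative == "greater":
        p = float(norm.sf(z))
    elif alternative == "less":
        p = float(norm.cdf(z))
    else:
        p = float(2 * norm.sf(abs(z)))
    return w_obs, min(1.0, p)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with a t-transform p-value (n-2 df)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length series of length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt((xc**2).sum()))
    sy = float(np.sqrt((yc**2).sum()))
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    n = len(x)
    if abs(r) == 1.0:
        return r, 0.0
    t_stat = r * math.sqrt((n - 2) / (1 - r * r))
    p = float(2 * t_dist.sf(abs(t_stat), n - 2))
    return r, p


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation: Pearson on average-tie ranks."""
    return pearson(rankdata(np.asarray(list(x), dtype=float)),
                   rankdata(np.asarray(list(y), dtype=float)))


def abundance_matrix(samples: Sequence[AssignedSample]) -> pd.DataFrame:
    """Samples x formulas matrix of relative intensities (absent = 0)."""
    series = {s.meta.sample_id: s.rel_intensity_series() for s in samples}
    return pd.DataFrame(series).T.fillna(0.0).sort_index(axis=1)


def formula_component_correlation(
    samples: Sequence[AssignedSample],
    component_scores: pd.DataFrame,
    alpha: float = 0.05,
    min_obs: int = 4,
) -> FormulaCorrelation:
    """Spearman screening of every formula against every component score.

    For each formula present in >= ``min_obs`` samples, its relative
    intensities (over the samples where it is present) are correlated
    with the matching component scores. Significance is the raw
    p < alpha rule (a 95% confidence limit at the default); Benjamini-
    Hochberg adjusted flags are emitted alongside per component. The
    summary reports, per component, the intensity-weighted mean H/C and
    O/C of the significantly positively correlated formulas.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    mat = abundance_matrix(samples)
    mat = mat.loc[[s.meta.sample_id for s in samples]]
    missing = [sid for sid in mat.index if sid not in component_scores.index]
    if missing:
        raise ValueError(f"component scores missing for samples: {missing[:5]}")
    scores = component_scores.loc[mat.index]
    rows = []
    n_skipped = 0
    for f in mat.columns:
        v = mat[f]
        present = v > 0
        if int(present.sum()) < min_obs:
            n_skipped += 1
            continue
        vv = v[present].to_numpy()
        if np.all(vv == vv[0]):
            n_skipped += 1
            continue
        for comp in scores.columns:
            cs = scores.loc[present.to_numpy(), comp].to_numpy()
            if np.all(cs == cs[0]):
                rows.append({"formula": f, "component": comp, "rho": np.nan, "p": np.nan})
                continue
            rho, p = spearman(vv, cs)
            rows.append({"formula": f, "component": comp, "rho": rho, "p": p})
    table = pd.DataFrame(rows, columns=["formula", "component", "rho", "p"])
    table["significant"] = table["p"] < alpha
    table["bh_significant"] = False
    for comp in scores.columns:
        sel = (table["component"] == comp) & table["p"].notna()
        if sel.any():
            rej, *_ = multipletests(table.loc[sel, "p"], alpha=alpha, method="fdr_bh")
            table.loc[sel, "bh_significant"] = rej
    mean_rel = mat.replace(0.0, np.nan).mean(axis=0)
    summary_rows = []
    for comp in scores.columns:
        sig_pos = table[
            (table["component"] == comp) & table["significant"] & (table["rho"] > 0)
        ]["formula"]
        hc_vals, oc_vals, weights = [], [], []
        for fstr in sig_pos:
            fm = Formula.from_string(fstr)
            hc_vals.append(fm.h / fm.c)
            oc_vals.append(fm.o / fm.c)
            weights.append(float(mean_rel[fstr]))
        if weights and sum(weights) > 0:
            wsum = sum(weights)
            mean_hc = sum(v * w for v, w in zip(hc_vals, weights)) / wsum
            mean_oc = sum(v * w for v, w in zip(oc_vals, weights)) / wsum
        else:
            mean_hc = mean_oc = float("nan")
        summary_rows.append(
            {
                "component": comp,
                "n_significant_positive": int(len(sig_pos)),
                "mean_hc": mean_hc,
                "mean_oc": mean_oc,
            }
        )
    summary = pd.DataFrame(summary_rows)
    return FormulaCorrelation(table=table, summary=summary, n_skipped=n_skipped, alpha=alpha)
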