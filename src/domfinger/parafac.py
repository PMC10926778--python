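"""Nonnegative PARAFAC decomposition of EEM fluorescence stacks.

Fits the trilinear model X[i,j,k] = sum_r A[i,r] B[j,r] C[k,r] with all
factors nonnegative, by alternating least squares. Each factor-matrix row
update is an exact small nonnegative least-squares solve (active-set on
the Gram matrix), so the explained sum of squares is non-decreasing over
iterations; a faster clipped-least-squares update is available as an
option. Excitation and emission loadings are normalized to unit maximum,
with all scale carried by the sample scores.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .synthetic import EEMSet


@dataclass
class ComponentPeak:
    component: int
    excitation_nm: float
    emission_nm: float


@dataclass
class ParafacModel:
    """A fitted nonnegative trilinear model of an EEM stack."""

    n_components: int
    scores: np.ndarray  # samples x R
    ex_loadings: np.ndarray  # excitation x R, unit-max columns
    em_loadings: np.ndarray  # emission x R, unit-max columns
    excitation_nm: np.ndarray
    emission_nm: np.ndarray
    fit: float  # fraction of explained sum of squares
    n_iter: int
    converged: bool
    fit_history: list[float] = field(default_factory=list)
    sample_ids: Optional[list[str]] = None


def _nnls_gram(G: np.ndarray, f: np.ndarray, max_iter: int = 200) -> np.ndarray:
    """Solve min ||Z w - x||, w >= 0, given G = Z'Z and f = Z'x.

    Lawson-Hanson active-set on the normal equations; exact for the tiny
    systems (R <= ~10) that arise per factor row.
    """
    r = len(f)
    w = np.zeros(r)
    passive = np.zeros(r, dtype=bool)
    grad = f - G @ w
    tol = 1e-12 * max(1.0, float(np.abs(f).max()))
    for _ in range(max_iter):
        if passive.all():
            break
        j = int(np.argmax(np.where(passive, -np.inf, grad)))
        if grad[j] <= tol:
            break
        passive[j] = True
        while True:
            idx = np.nonzero(passive)[0]
            try:
                z = np.linalg.solve(G[np.ix_(idx, idx)], f[idx])
            except np.linalg.LinAlgError:
                z = np.linalg.lstsq(G[np.ix_(idx, idx)], f[idx], rcond=None)[0]
            if np.all(z > tol):
                w[:] = 0.0
                w[idx] = z
                break
            # step back to the feasibility boundary
            wp = w[idx]
            neg = z <= tol
            with np.errstate(divide="ignore", invalid="ignore"):
                alphas = wp[neg] / (wp[neg] - z[neg])
            alpha = float(np.min(alphas)) if len(alphas) else 0.0
            w[idx] = wp + alpha * (z - wp)
            drop = idx[w[idx] <= tol]
            w[drop] = 0.0
            passive[drop] = False
            if not passive.any():
                break
        grad = f - G @ w
    return w


def _update_factor(
    unfolded: np.ndarray, kr: np.ndarray, nonneg: str, rng: np.random.Generator
) -> np.ndarray:
    """Solve unfolded ~= F @ kr.T for F >= 0, row by row."""
    G = kr.T @ kr
    FtZ = unfolded @ kr
    try:
        F = np.linalg.solve(G, FtZ.T).T
    except np.linalg.LinAlgError:
        F = np.linalg.lstsq(G, FtZ.T, rcond=None)[0].T
    if nonneg == "clip":
        np.clip(F, 0.0, None, out=F)
    else:
        # the unconstrained solution is the NNLS solution wherever it is
        # already nonnegative; run the active set only on violating rows
        bad = np.nonzero((F < 0).any(axis=1))[0]
        for i in bad:
            F[i] = _nnls_gram(G, FtZ[i])
    # revive dead components so ALS cannot stall on a zero column
    dead = F.max(axis=0) <= 0
    if dead.any():
        F[:, dead] = rng.uniform(0.01, 0.1, size=(F.shape[0], int(dead.sum())))
    return F


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # column-wise Kronecker: rows indexed (i of a) x (j of b), row-major
    return (a[:, None, :] * b[None, :, :]).reshape(a.shape[0] * b.shape[0], a.shape[1])


def fit_parafac(
    eems: EEMSet,
    n_components: int,
    n_restarts: int = 3,
    max_iter: int = 300,
    tol: float = 1e-8,
    seed: int = 0,
    nonneg: str = "nnls",
) -> ParafacModel:
    """Fit a nonnegative PARAFAC model, best of ``n_restarts`` random starts.

    Convergence: change in explained sum of squares below ``tol``.
    ``nonneg`` selects the row update: "nnls" (exact active-set, monotone
    objective) or "clip" (least squares with negative entries zeroed).
    """
    X = eems.data
    S, J, K = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(S, J, K):
        raise ValueError(
            f"n_components={n_components} exceeds the smallest tensor dimension {min(S, J, K)}"
        )
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if nonneg not in ("nnls", "clip"):
        raise ValueError("nonneg must be 'nnls' or 'clip'")
    X0 = X.reshape(S, J * K)
    X1 = X.transpose(1, 0, 2).reshape(J, S * K)
    X2 = X.transpose(2, 0, 1).reshape(K, S * J)
    ss_total = float((X**2).sum())
    if ss_total == 0:
        raise ValueError("all-zero EEM tensor")

    best: Optional[ParafacModel] = None
    master = np.random.default_rng(seed)
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        B = rng.uniform(0.1, 1.0, (J, n_components))
        C = rng.uniform(0.1, 1.0, (K, n_components))
        A = np.zeros((S, n_components))
        fit_prev = -np.inf
        history: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            A = _update_factor(X0, _khatri_rao(B, C), nonneg, rng)
            B = _update_factor(X1, _khatri_rao(A, C), nonneg, rng)
            C = _update_factor(X2, _khatri_rao(A, B), nonneg, rng)
            resid = X0 - A @ _khatri_rao(B, C).T
            fit = 1.0 - float((resid**2).sum()) / ss_total
            history.append(fit)
            if fit - fit_prev < tol and it > 1:
                converged = True
                break
            fit_prev = fit
        # absorb scale into A, unit-max loadings
        for M in (B, C):
            mx = M.max(axis=0)
            mx[mx == 0] = 1.0
            A = A * mx
            M /= mx
        model = ParafacModel(
            n_components=n_components,
            scores=A,
            ex_loadings=B,
            em_loadings=C,
            excitation_nm=eems.excitation_nm,
            emission_nm=eems.emission_nm,
            fit=history[-1],
            n_iter=it,
            converged=converged,
            fit_history=history,
            sample_ids=eems.sample_ids,
        )
        if best is None or model.fit > best.fit:
            best = model
    assert best is not None
    return best


def congruence(
    model: ParafacModel,
    ref_ex_loadings: np.ndarray,
    ref_em_loadings: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Tucker congruence of fitted vs reference components.

    For each component the combined excitation (x) emission loading
    vector is compared by cosine similarity; components are matched to
    the reference by Hungarian assignment on the congruence matrix.
    Returns (congruences ordered by model component, permutation) where
    ``permutation[k]`` is the reference component matched to model
    component k.
    """
    B, C = model.ex_loadings, model.em_loadings
    refB = np.asarray(ref_ex_loadings, dtype=float)
    refC = np.asarray(ref_em_loadings, dtype=float)
    if refB.shape[0] != B.shape[0] or refC.shape[0] != C.shape[0]:
        raise ValueError("reference loadings are on a different grid")
    if refB.shape[1] != refC.shape[1]:
        raise ValueError("reference excitation/emission component counts differ")
    r_model, r_ref = B.shape[1], refB.shape[1]
    M = np.zeros((r_model, r_ref))
    for k in range(r_model):
        v = np.kron(B[:, k], C[:, k])
        nv = np.linalg.norm(v)
        for l in range(r_ref):
            w = np.kron(refB[:, l], refC[:, l])
            nw = np.linalg.norm(w)
            M[k, l] = float(v @ w / (nv * nw)) if nv > 0 and nw > 0 else 0.0
    row, col = linear_sum_assignment(-M)
    perm = np.empty(r_model, dtype=int)
    cong = np.empty(r_model)
    for k, l in zip(row, col):
        perm[k] = l
        cong[k] = M[k, l]
    return cong, perm


def component_peaks(model: ParafacModel) -> list[ComponentPeak]:
    """Excitation/emission maxima (nm) of each fitted component."""
    peaks = []
    for k in range(model.n_components):
        b = model.ex_loadings[:, k]
        c = model.em_loadings[:, k]
        for name, v in (("excitation", b), ("emission", c)):
            if np.ptp(v) == 0:
                warnings.warn(
                    f"component {k}: flat {name} loading, argmax defaults to the grid start",
                    stacklevel=2,
                )
        peaks.append(
            ComponentPeak(
                component=k,
                excitation_nm=float(model.excitation_nm[int(np.argmax(b))]),
                emission_nm=float(model.emission_nm[int(np.argmax(c))]),
            )
        )
    return peaks
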