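"""Molecular-formula assignment for negative-mode FT-ICR MS peak lists.

Each observed m/z is matched against all CHNOS formulas whose [M-H]- ion
mass lies within a ppm tolerance and which satisfy chemical-plausibility
windows (element bounds, H/C and O/C ratio limits, DBE range, nitrogen
rule). The search is exhaustively complete with respect to the configured
bounds: it enumerates every (C, N, O, S) combination and solves for the
hydrogen count, so nothing inside the windows can be missed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .formula import MONOISOTOPIC_MASS, PROTON_MASS, Formula

_MC = MONOISOTOPIC_MASS["C"]
_MH = MONOISOTOPIC_MASS["H"]
_MN = MONOISOTOPIC_MASS["N"]
_MO = MONOISOTOPIC_MASS["O"]
_MS = MONOISOTOPIC_MASS["S"]


@dataclass(frozen=True)
class AssignmentConstraints:
    """Chemical windows for candidate formula search.

    Defaults are community-standard windows for marine DOM: 1 ppm
    tolerance, CHNOS only, 0.3 <= H/C <= 2.5, O/C <= 1.2, 0 <= DBE <= 40,
    nitrogen rule enforced.
    """

    tolerance_ppm: float = 1.0
    c_range: tuple[int, int] = (1, 60)
    h_range: tuple[int, int] = (1, 120)
    n_range: tuple[int, int] = (0, 5)
    o_range: tuple[int, int] = (0, 30)
    s_range: tuple[int, int] = (0, 3)
    hc_range: tuple[float, float] = (0.3, 2.5)
    oc_max: float = 1.2
    dbe_range: tuple[float, float] = (0.0, 40.0)
    nitrogen_rule: bool = True

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be > 0")
        for name in ("c_range", "h_range", "n_range", "o_range", "s_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: {lo} > {hi}")
        if self.c_range[0] < 1 or self.h_range[0] < 1:
            raise ValueError("C and H minimum counts must be >= 1")


def constraints_matching(library_constraints, tolerance_ppm: float = 1.0) -> AssignmentConstraints:
    """Assignment windows equal to a synthetic library's generative bounds.

    The standard closed-loop setting: a practitioner constrains the
    candidate search to the elemental space the sample is expected to
    occupy. Accepts any object with ``c_range``/``h_range``/``n_range``/
    ``o_range``/``s_range``/``hc_range``/``oc_max``/``dbe_range`` fields
    (e.g. :class:`domfinger.synthetic.LibraryConstraints`).
    """
    lc = library_constraints
    return AssignmentConstraints(
        tolerance_ppm=tolerance_ppm,
        c_range=tuple(lc.c_range),
        h_range=tuple(lc.h_range),
        n_range=tuple(lc.n_range),
        o_range=tuple(lc.o_range),
        s_range=tuple(lc.s_range),
        hc_range=tuple(lc.hc_range),
        oc_max=lc.oc_max,
        dbe_range=tuple(lc.dbe_range),
    )


@dataclass
class SampleMeta:
    """Identity and design coordinates of one sample."""

    sample_id: str
    treatment: Optional[str] = None
    day: Optional[float] = None
    arm: Optional[str] = None
    replicate: Optional[int] = None


@dataclass
class PeakTable:
    """One sample's (m/z, intensity) peak list.

    ``source_formulas``, when present, carries per-peak ground-truth
    formula strings from the synthetic generator (for recovery tests).
    """

    meta: SampleMeta
    mz: np.ndarray
    intensity: np.ndarray
    source_formulas: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if np.any(self.mz <= 0):
            raise ValueError("m/z values must be strictly positive")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be strictly positive")
        rounded = np.round(self.mz, 6)
        if len(np.unique(rounded)) != len(rounded):
            raise ValueError("duplicate m/z values (at 6-decimal precision)")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class AssignedSample:
    """Per-sample table of assigned formulas with relative intensities.

    ``records`` columns: formula, c, h, n, o, s, mz_obs, mz_theor,
    error_ppm, intensity, rel_intensity. One row per distinct formula
    (duplicate peak assignments merged by intensity sum).
    """

    meta: SampleMeta
    records: pd.DataFrame
    n_unassigned: int = 0

    @property
    def formulas(self) -> set[str]:
        return set(self.records["formula"])

    def rel_intensity_series(self) -> pd.Series:
        return self.records.set_index("formula")["rel_intensity"]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Candidate search grid, cached per constraint set.

_GRID_CACHE: dict[AssignmentConstraints, tuple[np.ndarray, ...]] = {}


def _cnos_grid(constraints: AssignmentConstraints) -> tuple[np.ndarray, ...]:
    """All (c, n, o, s) combinations satisfying the static bounds,
    with their CNOS partial masses. H is solved per query mass."""
    cached = _GRID_CACHE.get(constraints)
    if cached is not None:
        return cached
    c = np.arange(constraints.c_range[0], constraints.c_range[1] + 1)
    n = np.arange(constraints.n_range[0], constraints.n_range[1] + 1)
    o = np.arange(constraints.o_range[0], constraints.o_range[1] + 1)
    s = np.arange(constraints.s_range[0], constraints.s_range[1] + 1)
    C, N, O, S = np.meshgrid(c, n, o, s, indexing="ij")
    C, N, O, S = (a.ravel() for a in (C, N, O, S))
    keep = O <= constraints.oc_max * C  # O/C bound is H-independent
    C, N, O, S = C[keep], N[keep], O[keep], S[keep]
    base = C * _MC + N * _MN + O * _MO + S * _MS
    order = np.argsort(base, kind="stable")
    out = (C[order], N[order], O[order], S[order], base[order])
    _GRID_CACHE[constraints] = out
    return out


def candidate_formulas(
    mz: float, constraints: AssignmentConstraints | None = None
) -> list[tuple[Formula, float]]:
    """All formulas whose [M-H]- ion mass is within tolerance of ``mz``.

    Returns (formula, error_ppm) pairs sorted by \\|error\\|; the list is
    complete with respect to the configured bounds. ``error_ppm`` is
    (observed - theoretical) / theoretical * 1e6.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if constraints is None:
        constraints = AssignmentConstraints()
    C, N, O, S, base = _cnos_grid(constraints)
    target = mz + PROTON_MASS  # neutral mass to match
    tol_da = constraints.tolerance_ppm * 1e-6 * mz
    h_lo, h_hi = constraints.h_range
    # Window the sorted CNOS base masses: H contributes h_lo..h_hi * mH.
    lo = np.searchsorted(base, target - h_hi * _MH - tol_da - 1e-9)
    hi = np.searchsorted(base, target - h_lo * _MH + tol_da + 1e-9)
    if lo >= hi:
        return []
    C, N, O, S, base = C[lo:hi], N[lo:hi], O[lo:hi], S[lo:hi], base[lo:hi]
    h_float = (target - base) / _MH
    results: list[tuple[Formula, float]] = []
    for h_cand in (np.floor(h_float).astype(int), np.ceil(h_float).astype(int)):
        mask = (h_cand >= h_lo) & (h_cand <= h_hi)
        if constraints.nitrogen_rule:
            mask &= (h_cand + N) % 2 == 0
        hc = h_cand / C
        mask &= (hc >= constraints.hc_range[0]) & (hc <= constraints.hc_range[1])
        dbe = 1.0 + C - h_cand / 2.0 + N / 2.0
        mask &= (dbe >= constraints.dbe_range[0]) & (dbe <= constraints.dbe_range[1])
        ion = base + h_cand * _MH - PROTON_MASS
        err_ppm = (mz - ion) / ion * 1e6
        mask &= np.abs(err_ppm) <= constraints.tolerance_ppm
        for i in np.nonzero(mask)[0]:
            f = Formula(int(C[i]), int(h_cand[i]), int(N[i]), int(O[i]), int(S[i]))
            results.append((f, float(err_ppm[i])))
    # floor == ceil when h_float is integral: drop duplicates
    seen: set[Formula] = set()
    unique = []
    for f, e in results:
        if f not in seen:
            seen.add(f)
            unique.append((f, e))
    unique.sort(key=lambda fe: abs(fe[1]))
    return unique


def _best_candidate(
    cands: Sequence[tuple[Formula, float]]
) -> tuple[Formula, float]:
    # Deterministic tie-break: |ppm error|, then fewest heteroatoms N+S,
    # then fewer O, then lower mass.
    return min(
        cands,
        key=lambda fe: (abs(fe[1]), fe[0].n + fe[0].s, fe[0].o, fe[0].neutral_mass),
    )


def assign_sample(
    peaks: PeakTable, constraints: AssignmentConstraints | None = None
) -> AssignedSample:
    """Assign the best candidate formula to every peak of a sample.

    Peaks with no candidate inside the windows are dropped and counted in
    ``n_unassigned``. Two peaks resolving to the same formula are merged
    (intensities summed, the lower-\\|error\\| peak kept as representative).
    Relative intensities are computed over assigned peaks only.
    """
    if constraints is None:
        constraints = AssignmentConstraints()
    rows = []
    n_unassigned = 0
    for mz, inten in zip(peaks.mz, peaks.intensity):
        cands = candidate_formulas(float(mz), constraints)
        if not cands:
            n_unassigned += 1
            continue
        f, err = _best_candidate(cands)
        rows.append(
            {
                "formula": str(f),
                "c": f.c,
                "h": f.h,
                "n": f.n,
                "o": f.o,
                "s": f.s,
                "mz_obs": float(mz),
                "mz_theor": f.ion_mz,
                "error_ppm": err,
                "intensity": float(inten),
            }
        )
    columns = [
        "formula", "c", "h", "n", "o", "s",
        "mz_obs", "mz_theor", "error_ppm", "intensity", "rel_intensity",
    ]
    if not rows:
        return AssignedSample(
            meta=peaks.meta,
            records=pd.DataFrame(columns=columns),
            n_unassigned=n_unassigned,
        )
    df = pd.DataFrame(rows)
    # merge duplicate formulas: sum intensity, keep min-|error| row
    df["abs_err"] = df["error_ppm"].abs()
    df = df.sort_values(["formula", "abs_err"], kind="stable")
    totals = df.groupby("formula", sort=False)["intensity"].sum()
    df = df.drop_duplicates("formula", keep="first").drop(columns="abs_err")
    df["intensity"] = df["formula"].map(totals)
    df = df.sort_values("mz_obs", kind="stable").reset_index(drop=True)
    df["rel_intensity"] = df["intensity"] / df["intensity"].sum()
    return AssignedSample(meta=peaks.meta, records=df[columns], n_unassigned=n_unassigned)
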