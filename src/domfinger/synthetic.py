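"""Synthetic ground-truth generators for the full analysis chain.

The generators emulate the statistical structure of a substrate/viral-lysis
incubation experiment on a marine heterotroph:

* a CHNOS formula library spanning DOM-like van Krevelen space, with
  latent lability classes (preformed / intermediated / remaining /
  viral-unique / background) assigned so that chemistry follows class:
  preformed formulas are reduced and H-saturated, remaining formulas are
  oxidized and unsaturated, viral-unique formulas are N- or N+S-rich and
  saturated;
* negative-mode peak tables per treatment x day x replicate in which the
  class-specific intensity profiles decay (preformed), peak mid-incubation
  (intermediated) or accumulate (remaining), with sub-ppm mass error and
  lognormal intensity noise;
* trilinear 4-component excitation-emission fluorescence landscapes whose
  protein-like component scores track early growth and whose humic-like
  scores accumulate over time;
* logistic bacterial growth with treatment-specific fractional DOC
  drawdown.

Every generator is deterministic for a fixed seed and returns its ground
truth alongside the observable data, so downstream stages can be scored
against a known answer.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .assignment import PeakTable, SampleMeta
from .formula import Formula

CLASS_LABELS = ("preformed", "intermediated", "remaining", "viral_unique", "background")

#: Default latent-class mixture of the formula library.
DEFAULT_CLASS_PROPORTIONS = {
    "preformed": 0.40,
    "intermediated": 0.20,
    "remaining": 0.25,
    "viral_unique": 0.05,
    "background": 0.10,
}

#: Excitation/emission maxima (nm) of the four fluorescent components:
#: two protein-like (tyrosine-like, tryptophan-like) and two humic-like.
DEFAULT_COMPONENT_PEAKS = [(270, 308), (275, 337), (310, 392), (365, 459)]


class InfeasibleConstraintsError(ValueError):
    """The formula-library constraint set admits no (or too few) formulas."""


@dataclass(frozen=True)
class LibraryConstraints:
    """Element and ratio bounds of the generated formula library."""

    c_range: tuple[int, int] = (4, 40)
    h_range: tuple[int, int] = (4, 80)
    n_range: tuple[int, int] = (0, 4)
    o_range: tuple[int, int] = (0, 25)
    s_range: tuple[int, int] = (0, 2)
    hc_range: tuple[float, float] = (0.3, 2.2)
    oc_max: float = 1.2
    dbe_range: tuple[float, float] = (0.0, 25.0)

    def validate(self) -> None:
        for name in ("c_range", "h_range", "n_range", "o_range", "s_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InfeasibleConstraintsError(f"{name} is empty: {lo} > {hi}")
        if self.c_range[0] < 1:
            raise InfeasibleConstraintsError("c_range must start at >= 1")
        if self.h_range[0] < 1:
            raise InfeasibleConstraintsError("h_range must start at >= 1")
        if self.o_range[0] > 0 and self.oc_max * self.c_range[1] < self.o_range[0]:
            raise InfeasibleConstraintsError(
                f"O/C bound oc_max={self.oc_max} is incompatible with "
                f"minimum O count {self.o_range[0]}"
            )
        if self.hc_range[0] > self.hc_range[1]:
            raise InfeasibleConstraintsError("hc_range is empty")
        if self.h_range[0] > self.hc_range[1] * self.c_range[1]:
            raise InfeasibleConstraintsError(
                "H/C upper bound excludes every H count in h_range"
            )
        if self.h_range[1] < self.hc_range[0] * self.c_range[0]:
            raise InfeasibleConstraintsError(
                "H/C lower bound excludes every H count in h_range"
            )


@dataclass(frozen=True)
class LibraryEntry:
    formula: Formula
    label: str  # one of CLASS_LABELS
    base_abundance: float


@dataclass
class FormulaLibrary:
    """Ground-truth formula set with latent lability classes."""

    entries: list[LibraryEntry]
    seed: int
    constraints: LibraryConstraints = field(default_factory=LibraryConstraints)

    def __len__(self) -> int:
        return len(self.entries)

    def by_label(self, label: str) -> list[LibraryEntry]:
        return [e for e in self.entries if e.label == label]

    def label_of(self) -> dict[str, str]:
        """Mapping formula string -> latent class label."""
        return {str(e.formula): e.label for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "formula": [str(e.formula) for e in self.entries],
                "label": [e.label for e in self.entries],
                "base_abundance": [e.base_abundance for e in self.entries],
            }
        )


@dataclass(frozen=True)
class ExperimentDesign:
    """Treatments, sampling days, replication, and optional lysis arms."""

    treatments: tuple[str, ...] = ("glucose", "laminarin", "syn_dom", "oligo_dom", "eu_dom")
    timepoints: tuple[float, ...] = (0.0, 4.0, 60.0)
    replicates: int = 3
    lysis_arms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.treatments) < 1:
            raise ValueError("at least one treatment is required")
        if len(self.timepoints) < 2:
            raise ValueError("at least two timepoints are required")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class EEMSet:
    """A stack of excitation-emission matrices on shared grids.

    ``data`` has shape (n_samples, n_excitation, n_emission). When
    produced by :func:`simulate_eems` the generating scores and loadings
    are attached for recovery scoring.
    """

    excitation_nm: np.ndarray
    emission_nm: np.ndarray
    data: np.ndarray
    sample_meta: list[SampleMeta]
    true_scores: Optional[np.ndarray] = None
    true_ex_loadings: Optional[np.ndarray] = None
    true_em_loadings: Optional[np.ndarray] = None
    component_peaks: Optional[list[tuple[float, float]]] = None

    def __post_init__(self) -> None:
        self.excitation_nm = np.asarray(self.excitation_nm, dtype=float)
        self.emission_nm = np.asarray(self.emission_nm, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if np.any(np.diff(self.excitation_nm) <= 0) or np.any(np.diff(self.emission_nm) <= 0):
            raise ValueError("wavelength grids must be strictly increasing")
        expected = (len(self.sample_meta), len(self.excitation_nm), len(self.emission_nm))
        if self.data.shape != expected:
            raise ValueError(f"data shape {self.data.shape} != {expected}")
        if np.any(self.data < 0):
            raise ValueError("EEM intensities must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.sample_meta]


# ---------------------------------------------------------------------------
# Formula library


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def generate_formula_library(
    n_formulas: int,
    seed: int,
    constraints: LibraryConstraints | None = None,
    class_proportions: Mapping[str, float] | None = None,
) -> FormulaLibrary:
    """Draw ``n_formulas`` distinct DOM-like CHNOS formulas with latent classes.

    Formulas are rejection-sampled uniformly over the element bounds and
    kept when they satisfy the ratio/DBE windows and the nitrogen rule.
    Latent classes are then assigned so that class correlates with
    chemistry (see module docstring); base abundances are lognormal.
    """
    if n_formulas < 1:
        raise ValueError("n_formulas must be >= 1")
    constraints = constraints or LibraryConstraints()
    constraints.validate()
    props = dict(class_proportions or DEFAULT_CLASS_PROPORTIONS)
    unknown = set(props) - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    total = sum(props.values())
    if total <= 0:
        raise ValueError("class proportions must sum to a positive value")
    props = {k: v / total for k, v in props.items()}

    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, int, int, int, int]] = set()
    batch = max(4 * n_formulas, 1024)
    # Composition sampler tuned to marine SPE-DOM: neutral masses centred
    # near ~350 Da, O/C mostly 0.05-0.95, H/C spanning the full window,
    # heteroatom counts geometrically weighted toward zero.
    c_lo, c_hi = constraints.c_range
    c_mu = min(max(16.0, c_lo), c_hi)
    c_sd = max(2.5, (c_hi - c_lo) / 9.0)

    def _geom_weights(lo: int, hi: int) -> np.ndarray:
        w = 0.45 ** np.arange(hi - lo + 1)
        return w / w.sum()

    n_vals = np.arange(constraints.n_range[0], constraints.n_range[1] + 1)
    s_vals = np.arange(constraints.s_range[0], constraints.s_range[1] + 1)
    n_w = _geom_weights(*constraints.n_range)
    s_w = _geom_weights(*constraints.s_range)
    oc_hi = min(constraints.oc_max, 0.8)
    for _ in range(400):
        if len(chosen) >= n_formulas:
            break
        c = np.clip(np.round(rng.normal(c_mu, c_sd, batch)), c_lo, c_hi).astype(int)
        n = rng.choice(n_vals, batch, p=n_w)
        s = rng.choice(s_vals, batch, p=s_w)
        oc = rng.uniform(0.02, max(oc_hi, 0.03), batch)
        o = np.clip(np.round(oc * c), *constraints.o_range).astype(int)
        hc_draw = rng.uniform(constraints.hc_range[0], constraints.hc_range[1], batch)
        h = np.round(hc_draw * c).astype(int)
        h += (h + n) % 2  # nitrogen-rule parity
        h = np.clip(h, *constraints.h_range)
        hc = h / c
        dbe = 1.0 + c - h / 2.0 + n / 2.0
        ok = (
            ((h + n) % 2 == 0)
            & (hc >= constraints.hc_range[0])
            & (hc <= constraints.hc_range[1])
            & (o <= constraints.oc_max * c)
            & (dbe >= constraints.dbe_range[0])
            & (dbe <= constraints.dbe_range[1])
        )
        for ci, hi_, ni, oi, si in zip(c[ok], h[ok], n[ok], o[ok], s[ok]):
            chosen.add((int(ci), int(hi_), int(ni), int(oi), int(si)))
            if len(chosen) >= n_formulas:
                break
    if len(chosen) < n_formulas:
        raise InfeasibleConstraintsError(
            f"only {len(chosen)} distinct formulas satisfy the constraints; "
            f"{n_formulas} requested (check ratio/DBE bounds)"
        )
    formulas = [Formula(*t) for t in sorted(chosen)]

    # ---- latent class assignment, chemistry-linked -----------------------
    n_total = n_formulas
    k = {
        lbl: int(round(props.get(lbl, 0.0) * n_total))
        for lbl in CLASS_LABELS
    }
    # fix rounding drift on the largest class
    drift = n_total - sum(k.values())
    k[max(k, key=k.get)] += drift

    hc_arr = np.array([f.h / f.c for f in formulas])
    oc_arr = np.array([f.o / f.c for f in formulas])
    ns_rich = np.array([(f.n >= 2) or (f.n >= 1 and f.s >= 1) for f in formulas])
    jitter = rng.normal(0.0, 0.05, n_total)  # mild chemistry/class overlap

    labels = np.array(["background"] * n_total, dtype=object)
    taken = np.zeros(n_total, dtype=bool)

    # viral-unique: the most H-saturated N>=2 or N+S-rich formulas
    k_viral = k.get("viral_unique", 0)
    if k_viral > 0:
        cand = np.nonzero(ns_rich)[0]
        if len(cand) < k_viral:
            raise InfeasibleConstraintsError(
                f"only {len(cand)} N/S-rich formulas available for "
                f"{k_viral} viral-unique slots; widen n_range/s_range"
            )
        order = cand[np.argsort(-(hc_arr[cand] + jitter[cand]), kind="stable")]
        idx = order[:k_viral]
        labels[idx] = "viral_unique"
        taken[idx] = True

    # lability score: high = reduced & H-saturated (labile), low = oxidized
    lability = hc_arr - oc_arr + jitter
    free = np.nonzero(~taken)[0]
    order = free[np.argsort(-lability[free], kind="stable")]
    k_pre, k_rem, k_int = k.get("preformed", 0), k.get("remaining", 0), k.get("intermediated", 0)
    labels[order[:k_pre]] = "preformed"
    if k_rem > 0:
        labels[order[len(order) - k_rem:]] = "remaining"
    middle = order[k_pre : len(order) - k_rem if k_rem > 0 else len(order)]
    # intermediates: the most O-rich of the middle band
    mid_order = middle[np.argsort(-(oc_arr[middle] + jitter[middle]), kind="stable")]
    labels[mid_order[:k_int]] = "intermediated"

    abundances = rng.lognormal(mean=0.0, sigma=1.0, size=n_total)
    entries = [
        LibraryEntry(f, str(lbl), float(a))
        for f, lbl, a in zip(formulas, labels, abundances)
    ]
    return FormulaLibrary(entries=entries, seed=seed, constraints=constraints)


# ---------------------------------------------------------------------------
# Peak tables


def _class_profile(label: str, n_timepoints: int, fold_change: float = 4.0) -> np.ndarray:
    """Relative intensity multiplier per timepoint index for one class.

    ``fold_change`` is the peak-to-trough intensity ratio of the designed
    profiles: large enough for rank shifts to dominate replicate noise,
    small enough that gross composition does not turn over completely
    between sampling days.
    """
    if fold_change <= 1:
        raise ValueError("fold_change must be > 1")
    t = np.arange(n_timepoints)
    trough = 1.0 / fold_change
    if label == "preformed":
        # strict decay, 1 -> trough
        return trough ** (t / (n_timepoints - 1))
    if label == "remaining":
        # strict accumulation, trough -> 1
        return trough ** (1.0 - t / (n_timepoints - 1))
    if label == "intermediated":
        mid = (n_timepoints - 1) / 2.0
        sigma = mid / math.sqrt(2.0 * math.log(fold_change))
        return np.exp(-0.5 * ((t - mid) / sigma) ** 2)
    # background and viral_unique are flat
    return np.ones(n_timepoints)


def simulate_peak_tables(
    library: FormulaLibrary,
    design: ExperimentDesign,
    mass_error_ppm_sd: float = 0.3,
    intensity_noise_cv: float = 0.3,
    seed: int = 0,
    treatment_effect_sd: float = 0.8,
    profile_fold_change: float = 4.0,
) -> list[PeakTable]:
    """Simulate per-sample negative-mode peak tables from a formula library.

    Substrate samples (treatment x day x replicate) contain every
    non-viral library formula with class-specific time profiles; lysis-arm
    samples (one per arm x replicate) contain all formulas at flat
    abundance except viral-unique ones, which appear only in the viral
    arm. Observed m/z = ion m/z x (1 + eps), eps ~ N(0, ppm_sd x 1e-6);
    intensity noise is mean-one lognormal with the given CV.

    ``treatment_effect_sd`` draws one lognormal substrate-affinity
    multiplier per (treatment, formula), constant over days and
    replicates: it separates treatments compositionally (as different
    substrates do) without disturbing any formula's own time profile.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    if mass_error_ppm_sd < 0:
        raise ValueError("mass_error_ppm_sd must be >= 0")
    if intensity_noise_cv < 0:
        raise ValueError("intensity_noise_cv must be >= 0")
    n_t = len(design.timepoints)
    if n_t < 3 and any(e.label == "intermediated" for e in library.entries):
        raise ValueError(
            "intermediated profiles need >= 3 timepoints (mid-incubation peak undefined)"
        )
    rng = np.random.default_rng(seed)
    sigma = _lognormal_sigma(intensity_noise_cv)
    profiles = {lbl: _class_profile(lbl, n_t, profile_fold_change) for lbl in CLASS_LABELS}

    substrate_entries = [e for e in library.entries if e.label != "viral_unique"]
    tables: list[PeakTable] = []

    def _make_table(meta: SampleMeta, entries: Sequence[LibraryEntry], mult: np.ndarray) -> PeakTable:
        ion = np.array([e.formula.ion_mz for e in entries])
        eps = rng.normal(0.0, mass_error_ppm_sd * 1e-6, len(entries))
        mz = ion * (1.0 + eps)
        base = np.array([e.base_abundance for e in entries])
        if sigma > 0:
            noise = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, len(entries)))
        else:
            noise = np.ones(len(entries))
        intensity = base * mult * noise * 1e6
        # guard the 6-decimal m/z uniqueness invariant by merging collisions
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        src = [str(entries[i].formula) for i in order]
        rounded = np.round(mz, 6)
        keep_mask = np.ones(len(mz), dtype=bool)
        for i in range(1, len(mz)):
            if rounded[i] == rounded[i - 1] and keep_mask[i - 1]:
                intensity[i - 1] += intensity[i]
                keep_mask[i] = False
        return PeakTable(
            meta=meta,
            mz=mz[keep_mask],
            intensity=intensity[keep_mask],
            source_formulas=[s for s, m in zip(src, keep_mask) if m],
        )

    for treatment in design.treatments:
        affinity = (
            np.exp(rng.normal(0.0, treatment_effect_sd, len(substrate_entries)))
            if treatment_effect_sd > 0
            else np.ones(len(substrate_entries))
        )
        for ti, day in enumerate(design.timepoints):
            for rep in range(1, design.replicates + 1):
                meta = SampleMeta(
                    sample_id=f"{treatment}_d{day:g}_r{rep}",
                    treatment=treatment,
                    day=float(day),
                    replicate=rep,
                )
                mult = np.array([profiles[e.label][ti] for e in substrate_entries])
                tables.append(_make_table(meta, substrate_entries, mult * affinity))

    for arm in design.lysis_arms:
        entries = (
            library.entries if arm == "viral" else substrate_entries
        )
        for rep in range(1, design.replicates + 1):
            meta = SampleMeta(
                sample_id=f"arm-{arm}_r{rep}",
                treatment=None,
                day=float(design.timepoints[0]),
                arm=arm,
                replicate=rep,
            )
            mult = np.ones(len(entries))
            tables.append(_make_table(meta, entries, mult))
    return tables


# ---------------------------------------------------------------------------
# EEMs


def simulate_eems(
    design: ExperimentDesign,
    component_peaks: Sequence[tuple[float, float]] | None = None,
    bandwidths: tuple[float, float] = (15.0, 20.0),
    snr: float = 20.0,
    seed: int = 0,
    excitation_nm: np.ndarray | None = None,
    emission_nm: np.ndarray | None = None,
    score_noise_cv: float = 0.1,
) -> EEMSet:
    """Simulate trilinear excitation-emission landscapes.

    Each sample's EEM is sum_k score[k] * gauss_ex(k) (x) gauss_em(k),
    plus Gaussian noise with sd = rms(signal) / snr, clipped at zero.
    Protein-like components (the first half) follow the decaying
    early-growth profile over incubation days; humic-like components
    (second half) accumulate; the last component is flat. True scores and
    loadings are attached to the returned set.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    peaks = [(float(a), float(b)) for a, b in (component_peaks or DEFAULT_COMPONENT_PEAKS)]
    ex = np.asarray(
        excitation_nm if excitation_nm is not None else np.arange(240.0, 421.0, 5.0)
    )
    em = np.asarray(
        emission_nm if emission_nm is not None else np.arange(280.0, 541.0, 1.0)
    )
    for px, pm in peaks:
        if not (ex[0] <= px <= ex[-1]) or not (em[0] <= pm <= em[-1]):
            raise ValueError(f"component peak ({px}, {pm}) nm outside the grids")
    rng = np.random.default_rng(seed)
    n_comp = len(peaks)
    bw_ex, bw_em = bandwidths
    B = np.stack([np.exp(-0.5 * ((ex - px) / bw_ex) ** 2) for px, _ in peaks], axis=1)
    C = np.stack([np.exp(-0.5 * ((em - pm) / bw_em) ** 2) for _, pm in peaks], axis=1)

    n_t = len(design.timepoints)
    decay = _class_profile("preformed", n_t)
    accum = _class_profile("remaining", n_t)
    flat = np.ones(n_t)
    comp_profiles = []
    for kidx in range(n_comp):
        if kidx < max(1, n_comp // 2):
            comp_profiles.append(decay)          # protein-like, growth-coupled
        elif kidx < n_comp - 1:
            comp_profiles.append(accum)          # humic-like, accumulating
        else:
            comp_profiles.append(flat)           # stable background component

    sigma = _lognormal_sigma(score_noise_cv) if score_noise_cv > 0 else 0.0
    metas: list[SampleMeta] = []
    scores = []
    for t_i, treatment in enumerate(design.treatments):
        t_factor = 1.0 - 0.1 * t_i  # substrate-dependent fluorescence yield
        for ti, day in enumerate(design.timepoints):
            for rep in range(1, design.replicates + 1):
                metas.append(
                    SampleMeta(
                        sample_id=f"{treatment}_d{day:g}_r{rep}",
                        treatment=treatment,
                        day=float(day),
                        replicate=rep,
                    )
                )
                row = np.array([10.0 * t_factor * comp_profiles[k][ti] for k in range(n_comp)])
                if sigma > 0:
                    row = row * np.exp(rng.normal(-0.5 * sigma * sigma, sigma, n_comp))
                scores.append(row)
    A = np.asarray(scores)
    clean = np.einsum("ir,jr,kr->ijk", A, B, C)
    noise_sd = float(np.sqrt(np.mean(clean**2))) / snr
    data = clean + rng.normal(0.0, noise_sd, clean.shape)
    np.clip(data, 0.0, None, out=data)
    return EEMSet(
        excitation_nm=ex,
        emission_nm=em,
        data=data,
        sample_meta=metas,
        true_scores=A,
        true_ex_loadings=B,
        true_em_loadings=C,
        component_peaks=peaks,
    )


# ---------------------------------------------------------------------------
# Growth / DOC


def simulate_growth_doc(
    design: ExperimentDesign,
    doc_consumed_fraction: Mapping[str, float],
    carrying_capacity: float = 1.7e7,
    initial_abundance: float = 2.6e5,
    growth_rate: float = 1.8,
    doc_initial: float = 300.0,
    doc_rate: float = 0.08,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Logistic bacterial growth with substrate-dependent DOC drawdown.

    Abundance follows N(t) = K / (1 + (K/N0 - 1) exp(-r t)) (cells/mL).
    DOC declines first-order, scaled so that at the final sampling day the
    consumed fraction is exactly ``doc_consumed_fraction[treatment]``:
    DOC(t) = D0 * (1 - f * (1 - e^(-k t)) / (1 - e^(-k T))).

    Returns a tidy DataFrame with one row per treatment x replicate x day
    (daily grid from 0 to the final design day), columns
    treatment, replicate, day, abundance, doc.
    """
    if not (0 < initial_abundance < carrying_capacity):
        raise ValueError("need 0 < initial_abundance < carrying_capacity")
    for tr in design.treatments:
        if tr not in doc_consumed_fraction:
            raise ValueError(f"doc_consumed_fraction missing treatment {tr!r}")
        f = doc_consumed_fraction[tr]
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"consumed fraction for {tr!r} must be in [0, 1], got {f}")
    rng = np.random.default_rng(seed)
    t_final = design.timepoints[-1]
    days = np.arange(0.0, t_final + 1.0)
    ratio = carrying_capacity / initial_abundance - 1.0
    abundance = carrying_capacity / (1.0 + ratio * np.exp(-growth_rate * days))
    depletion_norm = 1.0 - math.exp(-doc_rate * t_final)
    sigma = _lognormal_sigma(noise_cv) if noise_cv > 0 else 0.0
    rows = []
    for tr in design.treatments:
        f = doc_consumed_fraction[tr]
        doc = doc_initial * (1.0 - f * (1.0 - np.exp(-doc_rate * days)) / depletion_norm)
        for rep in range(1, design.replicates + 1):
            if sigma > 0:
                ab = abundance * np.exp(rng.normal(-0.5 * sigma**2, sigma, len(days)))
                dc = doc * np.exp(rng.normal(-0.5 * sigma**2, sigma, len(days)))
            else:
                ab, dc = abundance, doc
            for d, a_val, c_val in zip(days, ab, dc):
                rows.append(
                    {
                        "treatment": tr,
                        "replicate": rep,
                        "day": float(d),
                        "abundance": float(a_val),
                        "doc": float(c_val),
                    }
                )
    return pd.DataFrame(rows)
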