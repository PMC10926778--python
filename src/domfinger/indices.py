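"""Per-formula chemical indices and intensity-weighted sample summaries.

The van Krevelen-style quantities used throughout DOM fingerprinting:
H/C and O/C ratios, double bond equivalents (DBE), carbon-normalized
unsaturation (DBE/C), the modified aromaticity index (AImod), elemental
classes (CHO / CHON / CHOS / CHONS) and heteroatom species labels
(e.g. "O7", "N2O", "NOS").
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .assignment import AssignedSample
from .formula import Formula

ELEMENTAL_CLASSES = ("CHO", "CHON", "CHOS", "CHONS")


def dbe(formula: Formula) -> float:
    """Double bond equivalents: 1 + C - H/2 + N/2 (rings plus double bonds).

    Integer-valued for any nitrogen-rule-compliant formula.
    """
    return 1.0 + formula.c - formula.h / 2.0 + formula.n / 2.0


def aimod(formula: Formula) -> float:
    """Modified aromaticity index.

    AImod = (1 + C - 0.5 O - S - 0.5 (N + H)) / (C - 0.5 O - N - S),
    a conservative estimate of aromatic/condensed character that treats
    half the oxygen as carbonyl-like. Clamped to 0 when the numerator or
    denominator is non-positive (the index is undefined there).
    """
    num = 1.0 + formula.c - 0.5 * formula.o - formula.s - 0.5 * (formula.n + formula.h)
    den = formula.c - 0.5 * formula.o - formula.n - formula.s
    if num <= 0 or den <= 0:
        return 0.0
    return num / den


def elemental_class(formula: Formula) -> str:
    """CHO / CHON / CHOS / CHONS by heteroatom presence.

    Oxygen-free formulas are labeled by the same rule; their o == 0
    status is recoverable from the formula itself.
    """
    if formula.n > 0 and formula.s > 0:
        return "CHONS"
    if formula.n > 0:
        return "CHON"
    if formula.s > 0:
        return "CHOS"
    return "CHO"


def species_label(formula: Formula) -> str:
    """Heteroatom species label: N, O, S counts in that order.

    Counts of 1 are omitted ("NOS"), zero-count elements dropped
    ("N2O", "O7"). Pure-CH formulas get "CH".
    """
    parts = []
    for sym, cnt in (("N", formula.n), ("O", formula.o), ("S", formula.s)):
        if cnt > 0:
            parts.append(sym if cnt == 1 else f"{sym}{cnt}")
    return "".join(parts) if parts else "CH"


def weighted_mean(values, intensities) -> float:
    """Intensity-weighted mean: sum(v * w) / sum(w)."""
    values = list(values)
    intensities = list(intensities)
    if not values or len(values) != len(intensities):
        raise ValueError("values and intensities must be nonempty and equal-length")
    if any(w <= 0 for w in intensities):
        raise ValueError("intensities must be strictly positive")
    total = sum(intensities)
    return sum(v * w for v, w in zip(values, intensities)) / total


def index_table(sample: AssignedSample) -> pd.DataFrame:
    """Per-formula index records for one assigned sample.

    Columns: formula, hc, oc, dbe, dbe_c, aimod, elemental_class,
    species, rel_intensity.
    """
    rows = []
    for rec in sample.records.itertuples():
        f = Formula(int(rec.c), int(rec.h), int(rec.n), int(rec.o), int(rec.s))
        d = dbe(f)
        rows.append(
            {
                "formula": rec.formula,
                "hc": f.h / f.c,
                "oc": f.o / f.c,
                "dbe": d,
                "dbe_c": d / f.c,
                "aimod": aimod(f),
                "elemental_class": elemental_class(f),
                "species": species_label(f),
                "rel_intensity": rec.rel_intensity,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "formula", "hc", "oc", "dbe", "dbe_c", "aimod",
            "elemental_class", "species", "rel_intensity",
        ],
    )


@dataclass
class SampleSummary:
    """Intensity-weighted molecular characteristics of one sample."""

    sample_id: str
    richness: int
    mean_hc: float
    mean_oc: float
    mean_dbe: float
    mean_dbe_c: float
    mean_aimod: float
    class_share: dict[str, float]
    class_count: dict[str, int]

    def to_row(self) -> dict:
        row = {
            "sample_id": self.sample_id,
            "richness": self.richness,
            "mean_hc": self.mean_hc,
            "mean_oc": self.mean_oc,
            "mean_dbe": self.mean_dbe,
            "mean_dbe_c": self.mean_dbe_c,
            "mean_aimod": self.mean_aimod,
        }
        for cls in ELEMENTAL_CLASSES:
            row[f"share_{cls}"] = self.class_share.get(cls, 0.0)
            row[f"count_{cls}"] = self.class_count.get(cls, 0)
        return row


def summarize_sample(sample: AssignedSample) -> SampleSummary:
    """Richness, intensity-weighted index means, and elemental-class
    shares/counts for one assigned sample."""
    if len(sample) == 0:
        raise ValueError(f"sample {sample.meta.sample_id!r} has no assigned formulas")
    tbl = index_table(sample)
    w = tbl["rel_intensity"]
    wm = lambda col: float((tbl[col] * w).sum() / w.sum())  # noqa: E731
    share = tbl.groupby("elemental_class")["rel_intensity"].sum() / w.sum()
    count = tbl.groupby("elemental_class")["formula"].count()
    return SampleSummary(
        sample_id=sample.meta.sample_id,
        richness=len(tbl),
        mean_hc=wm("hc"),
        mean_oc=wm("oc"),
        mean_dbe=wm("dbe"),
        mean_dbe_c=wm("dbe_c"),
        mean_aimod=wm("aimod"),
        class_share={k: float(v) for k, v in share.items()},
        class_count={k: int(v) for k, v in count.items()},
    )


def summary_frame(samples: list[AssignedSample]) -> pd.DataFrame:
    """Stack per-sample summaries with design metadata attached."""
    rows = []
    for s in samples:
        row = summarize_sample(s).to_row()
        row["treatment"] = s.meta.treatment
        row["day"] = s.meta.day
        row["arm"] = s.meta.arm
        row["replicate"] = s.meta.replicate
        rows.append(row)
    return pd.DataFrame(rows)
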