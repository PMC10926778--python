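"""Inter-sample intensity-rank classification of molecular formulas.

Common formulas (present at every sampling time of a treatment) are
ranked by relative intensity within each sample; each formula is then
assigned to the sampling day at which its rank is best: Day-0 dominants
are "preformed" (stock molecules consumed later), mid-incubation
dominants are "intermediated" (transient transformation products), and
final-day dominants are "remaining" (produced or undegradable).
Formulas classified consistently across all treatments form the unique
class sets compared chemically downstream. A separate presence/absence
comparison isolates formulas found only in one DOM-release arm
(exudate / mechanical lysate / viral lysate).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .assignment import AssignedSample
from .formula import Formula
from .indices import elemental_class, species_label

DOMINANCE_CLASSES = ("preformed", "intermediated", "remaining")


@dataclass
class RankTable:
    """Descending relative-intensity ranks of one sample (1 = most intense).

    Exact intensity ties receive the average rank.
    """

    sample_id: str
    ranks: pd.Series  # index: formula string, values: rank

    def __len__(self) -> int:
        return len(self.ranks)


@dataclass
class DominanceClassification:
    """Per-treatment mapping of common formulas to dominance classes."""

    treatment: str
    classes: dict[str, str]  # formula -> preformed|intermediated|remaining|ambiguous
    coverage: float  # min over timepoints of common-set relative intensity

    def of_class(self, label: str) -> set[str]:
        return {f for f, c in self.classes.items() if c == label}


@dataclass
class UniqueSets:
    """Formulas whose dominance class is consistent across all treatments."""

    per_class: dict[str, set[str]]
    n_conflicting: int
    conflicting: set[str] = field(default_factory=set)


@dataclass
class ArmUniqueResult:
    """Presence/absence uniqueness across DOM-release arms."""

    unique: dict[str, set[str]]  # arm -> formulas found only in that arm
    common: set[str]  # formulas present in every arm
    coverage: float  # min over arm samples of common-set relative intensity


def rank_formulas(sample: AssignedSample) -> RankTable:
    """Rank a sample's formulas by relative intensity, descending,
    average ranks on exact ties."""
    if len(sample) == 0:
        raise ValueError(f"cannot rank empty sample {sample.meta.sample_id!r}")
    ranks = sample.rel_intensity_series().rank(ascending=False, method="average")
    return RankTable(sample_id=sample.meta.sample_id, ranks=ranks)


def _rank_series(series: pd.Series, sample_id: str) -> RankTable:
    present = series[series > 0]
    if present.empty:
        raise ValueError(f"no formulas present in {sample_id!r}")
    return RankTable(sample_id=sample_id, ranks=present.rank(ascending=False, method="average"))


def common_formulas(
    samples: Sequence[AssignedSample], coverage_threshold: float = 0.8
) -> tuple[set[str], float]:
    """Formulas present in every sample, with achieved intensity coverage.

    Coverage is the minimum over samples of the summed relative intensity
    of the common set; a warning is emitted when it falls below
    ``coverage_threshold`` (the threshold describes, it does not filter).
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    if not (0 < coverage_threshold <= 1):
        raise ValueError("coverage_threshold must be in (0, 1]")
    common: set[str] = set(samples[0].formulas)
    for s in samples[1:]:
        common &= s.formulas
    if not common:
        warnings.warn("no common formulas across the samples", stacklevel=2)
        return set(), 0.0
    coverage = min(
        float(s.rel_intensity_series().reindex(sorted(common)).fillna(0.0).sum())
        for s in samples
    )
    if coverage < coverage_threshold:
        warnings.warn(
            f"common-formula coverage {coverage:.3f} below threshold "
            f"{coverage_threshold:.2f}",
            stacklevel=2,
        )
    return common, coverage


def pool_replicates(samples: Sequence[AssignedSample]) -> dict[tuple[str, float], pd.Series]:
    """Mean relative intensity per formula over replicates of each
    treatment x day (absent-in-a-replicate counts as zero)."""
    groups: dict[tuple[str, float], list[pd.Series]] = {}
    for s in samples:
        key = (s.meta.treatment, s.meta.day)
        groups.setdefault(key, []).append(s.rel_intensity_series())
    pooled = {}
    for key, series_list in groups.items():
        df = pd.concat(series_list, axis=1).fillna(0.0)
        pooled[key] = df.mean(axis=1)
    return pooled


def classify_dominance(
    rank_tables: Mapping[float, RankTable],
    common: Iterable[str],
    treatment: str = "",
    coverage: float = float("nan"),
) -> DominanceClassification:
    """Assign each common formula to the day of its best (smallest) rank.

    ``rank_tables`` maps the three sampling days to rank tables (one per
    timepoint; replicates pre-averaged). Days map, in increasing order,
    to preformed / intermediated / remaining. Ties across days give the
    class "ambiguous".
    """
    days = sorted(rank_tables)
    if len(days) != 3:
        raise ValueError(f"exactly three timepoints required, got {len(days)}")
    day_class = dict(zip(days, DOMINANCE_CLASSES))
    classes: dict[str, str] = {}
    for f in common:
        ranks = []
        for d in days:
            r = rank_tables[d].ranks.get(f)
            if r is None:
                raise ValueError(f"common formula {f!r} missing from day {d:g} rank table")
            ranks.append(float(r))
        best = min(ranks)
        winners = [d for d, r in zip(days, ranks) if r == best]
        classes[f] = day_class[winners[0]] if len(winners) == 1 else "ambiguous"
    return DominanceClassification(treatment=treatment, classes=classes, coverage=coverage)


def classify_treatment(
    samples: Sequence[AssignedSample], coverage_threshold: float = 0.8
) -> DominanceClassification:
    """Pool replicates, find the treatment's common formulas across its
    sampling days, and classify their dominance."""
    treatments = {s.meta.treatment for s in samples}
    if len(treatments) != 1:
        raise ValueError(f"samples span multiple treatments: {sorted(map(str, treatments))}")
    treatment = treatments.pop()
    pooled = pool_replicates(samples)
    days = sorted(d for (_, d) in pooled)
    series_by_day = {d: pooled[(treatment, d)] for d in days}
    present_sets = [set(s[s > 0].index) for s in series_by_day.values()]
    common = set.intersection(*present_sets) if present_sets else set()
    if common:
        coverage = min(
            float(s.reindex(sorted(common)).fillna(0.0).sum() / s.sum())
            for s in series_by_day.values()
        )
    else:
        coverage = 0.0
    if coverage < coverage_threshold:
        warnings.warn(
            f"treatment {treatment!r}: common-formula coverage {coverage:.3f} "
            f"below threshold {coverage_threshold:.2f}",
            stacklevel=2,
        )
    tables = {d: _rank_series(s, f"{treatment}_d{d:g}") for d, s in series_by_day.items()}
    return classify_dominance(tables, common, treatment=treatment, coverage=coverage)


def unique_across_treatments(
    classifications: Sequence[DominanceClassification],
) -> UniqueSets:
    """Formulas receiving one consistent class across all treatments.

    A formula enters the unique set of class X iff every non-ambiguous
    class it received is X; formulas with conflicting classes are
    excluded and counted.
    """
    if not classifications:
        raise ValueError("need at least one classification")
    assigned: dict[str, set[str]] = {}
    for cl in classifications:
        for f, label in cl.classes.items():
            if label == "ambiguous":
                continue
            assigned.setdefault(f, set()).add(label)
    per_class: dict[str, set[str]] = {c: set() for c in DOMINANCE_CLASSES}
    conflicting: set[str] = set()
    for f, labels in assigned.items():
        if len(labels) == 1:
            per_class[next(iter(labels))].add(f)
        else:
            conflicting.add(f)
    return UniqueSets(
        per_class=per_class, n_conflicting=len(conflicting), conflicting=conflicting
    )


def species_count_table(
    unique_sets: UniqueSets, formulas: Mapping[str, Formula] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contingency counts of heteroatom species per dominance class.

    Returns (species_counts, elemental_class_counts): rows are species
    labels (or elemental classes), columns the dominance classes.
    """
    rows_species: dict[str, dict[str, int]] = {}
    rows_class: dict[str, dict[str, int]] = {}
    for cls in DOMINANCE_CLASSES:
        for fstr in unique_sets.per_class.get(cls, set()):
            f = formulas[fstr] if formulas is not None else Formula.from_string(fstr)
            sp = species_label(f)
            ec = elemental_class(f)
            rows_species.setdefault(sp, {c: 0 for c in DOMINANCE_CLASSES})[cls] += 1
            rows_class.setdefault(ec, {c: 0 for c in DOMINANCE_CLASSES})[cls] += 1
    species_df = pd.DataFrame.from_dict(rows_species, orient="index").fillna(0).astype(int)
    class_df = pd.DataFrame.from_dict(rows_class, orient="index").fillna(0).astype(int)
    for df in (species_df, class_df):
        for c in DOMINANCE_CLASSES:
            if c not in df.columns:
                df[c] = 0
    species_df = species_df[list(DOMINANCE_CLASSES)].sort_index()
    class_df = class_df[list(DOMINANCE_CLASSES)].sort_index()
    return species_df, class_df


def arm_unique_formulas(
    samples_by_arm: Mapping[str, Sequence[AssignedSample]]
) -> ArmUniqueResult:
    """Formulas detected in exactly one DOM-release arm.

    Presence is the union over an arm's samples. Also reports the
    formulas common to all arms and their minimum relative-intensity
    coverage over the individual samples.
    """
    if len(samples_by_arm) < 2:
        raise ValueError("need at least two arms")
    presence = {
        arm: set().union(*(s.formulas for s in samples))
        for arm, samples in samples_by_arm.items()
    }
    unique = {}
    for arm, present in presence.items():
        others = set().union(*(p for a, p in presence.items() if a != arm))
        unique[arm] = present - others
    common = set.intersection(*presence.values())
    if common:
        coverage = min(
            float(s.rel_intensity_series().reindex(sorted(common)).fillna(0.0).sum())
            for samples in samples_by_arm.values()
            for s in samples
        )
    else:
        coverage = 0.0
    return ArmUniqueResult(unique=unique, common=common, coverage=coverage)
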