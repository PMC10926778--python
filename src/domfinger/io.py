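"""CSV readers/writers, pipeline configuration, and the end-to-end runner.

File dialects (all UTF-8, dot-decimal, LF):

* peak tables: ``mz,intensity``
* sample metadata: ``sample_id,treatment,day,arm,replicate``
* assigned formulas: ``sample_id,formula,c,h,n,o,s,mz_obs,mz_theor,error_ppm,rel_intensity``
* EEMs, long format: ``sample_id,excitation_nm,emission_nm,intensity``
* library ground truth: ``formula,label,base_abundance``

The pipeline runner composes simulate -> assign -> indices -> rank ->
stats -> parafac from a single strict-schema YAML config and writes a
run manifest with seeds, the config hash and per-output checksums.
"""
from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .assignment import (
    AssignedSample,
    AssignmentConstraints,
    PeakTable,
    SampleMeta,
    assign_sample,
    constraints_matching,
)
from .indices import index_table, summary_frame
from .rank import (
    arm_unique_formulas,
    classify_treatment,
    species_count_table,
    unique_across_treatments,
)
from .stats import abundance_matrix, anosim, bray_curtis, formula_component_correlation, pca
from .synthetic import (
    EEMSet,
    ExperimentDesign,
    FormulaLibrary,
    LibraryConstraints,
    generate_formula_library,
    simulate_eems,
    simulate_growth_doc,
    simulate_peak_tables,
)
from .parafac import component_peaks, fit_parafac


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


# ---------------------------------------------------------------------------
# Readers / writers


def read_peak_table(path: str | Path, meta: SampleMeta | None = None) -> PeakTable:
    """Read a ``mz,intensity`` CSV into a validated PeakTable.

    Malformed rows are reported with their 1-based line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"mz", "intensity"}
    if set(df.columns) < required:
        raise ValueError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    problems = []
    mz_vals, int_vals = [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            mz = float(row.mz)
            inten = float(row.intensity)
        except (TypeError, ValueError):
            problems.append(f"line {i}: non-numeric value")
            continue
        if mz <= 0:
            problems.append(f"line {i}: non-positive m/z {mz}")
        elif inten <= 0:
            problems.append(f"line {i}: non-positive intensity {inten}")
        else:
            mz_vals.append(mz)
            int_vals.append(inten)
    rounded = np.round(np.array(mz_vals), 6)
    _, counts = np.unique(rounded, return_counts=True)
    if np.any(counts > 1):
        dups = np.unique(rounded)[counts > 1]
        problems.append(f"duplicate m/z values: {dups[:5].tolist()}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    if meta is None:
        meta = SampleMeta(sample_id=path.stem)
    return PeakTable(meta=meta, mz=np.array(mz_vals), intensity=np.array(int_vals))


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    df = pd.DataFrame({"mz": table.mz, "intensity": table.intensity})
    df.to_csv(path, index=False, lineterminator="\n")


def write_metadata(tables: list[PeakTable], path: str | Path) -> None:
    rows = [
        {
            "sample_id": t.meta.sample_id,
            "treatment": t.meta.treatment if t.meta.treatment is not None else "",
            "day": t.meta.day if t.meta.day is not None else "",
            "arm": t.meta.arm if t.meta.arm is not None else "",
            "replicate": t.meta.replicate if t.meta.replicate is not None else "",
        }
        for t in tables
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def read_metadata(path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"sample_id", "treatment", "day", "arm", "replicate"}
    if set(df.columns) < required:
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    metas = {}
    for row in df.itertuples(index=False):
        metas[row.sample_id] = SampleMeta(
            sample_id=row.sample_id,
            treatment=row.treatment or None,
            day=float(row.day) if row.day != "" else None,
            arm=row.arm or None,
            replicate=int(row.replicate) if row.replicate != "" else None,
        )
    return metas


def write_assigned(samples: list[AssignedSample], path: str | Path) -> None:
    frames = []
    for s in samples:
        df = s.records.copy()
        df.insert(0, "sample_id", s.meta.sample_id)
        frames.append(df.drop(columns=["intensity"]))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def write_eems(eems: EEMSet, path: str | Path) -> None:
    """Write an EEM stack as long-format CSV."""
    sids = eems.sample_ids
    rows = {
        "sample_id": np.repeat(sids, len(eems.excitation_nm) * len(eems.emission_nm)),
        "excitation_nm": np.tile(
            np.repeat(eems.excitation_nm, len(eems.emission_nm)), len(sids)
        ),
        "emission_nm": np.tile(eems.emission_nm, len(sids) * len(eems.excitation_nm)),
        "intensity": eems.data.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n", float_format="%.8g")


def read_eems(path: str | Path) -> EEMSet:
    """Read a long-format EEM CSV into an EEMSet (grids inferred)."""
    df = pd.read_csv(path)
    required = {"sample_id", "excitation_nm", "emission_nm", "intensity"}
    if set(df.columns) < required:
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    ex = np.sort(df["excitation_nm"].unique())
    em = np.sort(df["emission_nm"].unique())
    sids = list(dict.fromkeys(df["sample_id"]))
    data = np.zeros((len(sids), len(ex), len(em)))
    ex_idx = {v: i for i, v in enumerate(ex)}
    em_idx = {v: i for i, v in enumerate(em)}
    sid_idx = {v: i for i, v in enumerate(sids)}
    data[
        df["sample_id"].map(sid_idx).to_numpy(),
        df["excitation_nm"].map(ex_idx).to_numpy(),
        df["emission_nm"].map(em_idx).to_numpy(),
    ] = df["intensity"].to_numpy()
    metas = [SampleMeta(sample_id=s) for s in sids]
    return EEMSet(excitation_nm=ex, emission_nm=em, data=data, sample_meta=metas)


def write_library(library: FormulaLibrary, path: str | Path) -> None:
    library.to_frame().to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


# ---------------------------------------------------------------------------
# Configuration


_SCHEMA: dict[str, dict[str, type | tuple]] = {
    "simulate": {
        "n_formulas": int,
        "treatments": list,
        "timepoints": list,
        "replicates": int,
        "arms": list,
        "mass_error_ppm_sd": (int, float),
        "intensity_noise_cv": (int, float),
        "eem_snr": (int, float),
    },
    "assignment": {
        "tolerance_ppm": (int, float),
        "match_library_bounds": bool,
    },
    "rank": {
        "coverage_threshold": (int, float),
    },
    "stats": {
        "n_permutations": int,
        "alpha": (int, float),
    },
    "parafac": {
        "n_components": int,
        "n_restarts": int,
        "max_iter": int,
        "tol": (int, float),
    },
}

_DEFAULTS: dict[str, dict[str, Any]] = {
    "simulate": {
        "n_formulas": 600,
        "treatments": ["glucose", "laminarin", "syn_dom", "oligo_dom", "eu_dom"],
        "timepoints": [0, 4, 60],
        "replicates": 3,
        "arms": ["exudate", "mechanical", "viral"],
        "mass_error_ppm_sd": 0.3,
        "intensity_noise_cv": 0.3,
        "eem_snr": 20,
    },
    "assignment": {"tolerance_ppm": 1.0, "match_library_bounds": True},
    "rank": {"coverage_threshold": 0.8},
    "stats": {"n_permutations": 999, "alpha": 0.05},
    "parafac": {"n_components": 4, "n_restarts": 2, "max_iter": 600, "tol": 1e-11},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (strict schema, seed mandatory)."""

    seed: int
    output_dir: Path
    simulate: dict[str, Any] = field(default_factory=dict)
    assignment: dict[str, Any] = field(default_factory=dict)
    rank: dict[str, Any] = field(default_factory=dict)
    stats: dict[str, Any] = field(default_factory=dict)
    parafac: dict[str, Any] = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "simulate": self.simulate,
            "assignment": self.assignment,
            "rank": self.rank,
            "stats": self.stats,
            "parafac": self.parafac,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def make_config(raw: Mapping[str, Any], base_dir: str | Path = ".") -> PipelineConfig:
    """Validate a raw mapping against the strict schema."""
    allowed_top = {"seed", "output_dir"} | set(_SCHEMA)
    unknown = set(raw) - allowed_top
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError("config must specify a seed")
    if not isinstance(raw["seed"], int) or isinstance(raw["seed"], bool):
        raise ConfigError("seed must be an integer")
    if "output_dir" not in raw:
        raise ConfigError("config must specify output_dir")
    sections: dict[str, dict[str, Any]] = {}
    for section, fields_ in _SCHEMA.items():
        given = raw.get(section, {}) or {}
        if not isinstance(given, Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")
        unknown = set(given) - set(fields_)
        if unknown:
            raise ConfigError(f"unknown keys in {section!r}: {sorted(unknown)}")
        merged = dict(_DEFAULTS[section])
        for key, val in given.items():
            expected = fields_[key]
            if not isinstance(val, expected):
                raise ConfigError(
                    f"{section}.{key}: expected {expected}, got {type(val).__name__}"
                )
            merged[key] = val
        sections[section] = merged
    return PipelineConfig(
        seed=raw["seed"],
        output_dir=Path(base_dir) / str(raw["output_dir"]),
        **sections,
    )


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")
    return make_config(raw, base_dir=path.parent)


# ---------------------------------------------------------------------------
# Pipeline runner


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    timestamp: float
    config_hash: str
    seed: int
    stages: list[dict[str, Any]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, outputs: dict[str, str]) -> None:
        self.stages.append({"stage": name, "outputs": outputs})

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_outputs(paths: list[Path]) -> dict[str, str]:
    return {p.name: _sha256(p) for p in paths}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run simulate -> assign -> indices -> rank -> stats -> parafac.

    Deterministic for a fixed config + seed: rerunning produces
    byte-identical CSV/JSON outputs (the manifest timestamp aside).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        timestamp=time.time(), config_hash=config.config_hash(), seed=config.seed
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        _run_stages(config, out, manifest)
        manifest.warnings = [str(w.message) for w in caught]
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def _run_stages(config: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    sim = config.simulate
    rng_seed = config.seed

    # --- simulate ---------------------------------------------------------
    design = ExperimentDesign(
        treatments=tuple(sim["treatments"]),
        timepoints=tuple(float(t) for t in sim["timepoints"]),
        replicates=sim["replicates"],
        lysis_arms=tuple(sim["arms"]),
    )
    library = generate_formula_library(sim["n_formulas"], seed=rng_seed)
    tables = simulate_peak_tables(
        library,
        design,
        mass_error_ppm_sd=sim["mass_error_ppm_sd"],
        intensity_noise_cv=sim["intensity_noise_cv"],
        seed=rng_seed + 1,
    )
    eems = simulate_eems(design, snr=sim["eem_snr"], seed=rng_seed + 2)
    growth = simulate_growth_doc(
        design,
        doc_consumed_fraction={t: f for t, f in zip(
            design.treatments, (0.86, 0.81, 0.56, 0.17, 0.11))} if len(design.treatments) == 5
        else {t: 0.5 for t in design.treatments},
        seed=rng_seed + 3,
    )
    peaks_dir = out / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    peak_paths = []
    for t in tables:
        p = peaks_dir / f"{t.meta.sample_id}.csv"
        write_peak_table(t, p)
        peak_paths.append(p)
    write_metadata(tables, out / "metadata.csv")
    write_library(library, out / "library.csv")
    write_eems(eems, out / "eems.csv")
    growth.to_csv(out / "growth_doc.csv", index=False, lineterminator="\n", float_format="%.10g")
    manifest.add_stage(
        "simulate",
        _stage_outputs(
            [out / "metadata.csv", out / "library.csv", out / "eems.csv", out / "growth_doc.csv"]
            + peak_paths
        ),
    )

    # --- assign -----------------------------------------------------------
    if config.assignment["match_library_bounds"]:
        cons = constraints_matching(
            library.constraints, tolerance_ppm=config.assignment["tolerance_ppm"]
        )
    else:
        cons = AssignmentConstraints(tolerance_ppm=config.assignment["tolerance_ppm"])
    assigned = [assign_sample(t, cons) for t in tables]
    write_assigned(assigned, out / "assigned_formulas.csv")
    manifest.add_stage("assign", _stage_outputs([out / "assigned_formulas.csv"]))

    # --- indices ----------------------------------------------------------
    substrate = [s for s in assigned if s.meta.arm is None]
    summaries = summary_frame(assigned)
    summaries.to_csv(out / "sample_summaries.csv", index=False, lineterminator="\n",
                     float_format="%.10g")
    idx_frames = []
    for s in assigned:
        df = index_table(s)
        df.insert(0, "sample_id", s.meta.sample_id)
        idx_frames.append(df)
    pd.concat(idx_frames, ignore_index=True).to_csv(
        out / "formula_indices.csv", index=False, lineterminator="\n", float_format="%.10g"
    )
    manifest.add_stage(
        "indices", _stage_outputs([out / "sample_summaries.csv", out / "formula_indices.csv"])
    )

    # --- rank classification ---------------------------------------------
    classifications = []
    for treatment in design.treatments:
        group = [s for s in substrate if s.meta.treatment == treatment]
        classifications.append(
            classify_treatment(group, coverage_threshold=config.rank["coverage_threshold"])
        )
    cls_rows = [
        {"treatment": cl.treatment, "formula": f, "class": label, "coverage": cl.coverage}
        for cl in classifications
        for f, label in sorted(cl.classes.items())
    ]
    pd.DataFrame(cls_rows).to_csv(out / "classification.csv", index=False,
                                  lineterminator="\n", float_format="%.10g")
    unique = unique_across_treatments(classifications)
    uniq_rows = [
        {"class": cls, "formula": f}
        for cls, formulas in sorted(unique.per_class.items())
        for f in sorted(formulas)
    ]
    pd.DataFrame(uniq_rows).to_csv(out / "unique_sets.csv", index=False, lineterminator="\n")
    species_df, class_df = species_count_table(unique)
    species_df.to_csv(out / "species_counts.csv", lineterminator="\n")
    class_df.to_csv(out / "elemental_class_counts.csv", lineterminator="\n")
    rank_paths = [
        out / "classification.csv", out / "unique_sets.csv",
        out / "species_counts.csv", out / "elemental_class_counts.csv",
    ]
    arms = {a: [s for s in assigned if s.meta.arm == a] for a in design.lysis_arms}
    if len(arms) >= 2:
        arm_result = arm_unique_formulas(arms)
        arm_rows = [
            {"arm": arm, "formula": f}
            for arm, formulas in sorted(arm_result.unique.items())
            for f in sorted(formulas)
        ]
        pd.DataFrame(arm_rows).to_csv(out / "arm_unique.csv", index=False, lineterminator="\n")
        rank_paths.append(out / "arm_unique.csv")
    manifest.add_stage("rank", _stage_outputs(rank_paths))

    # --- stats ------------------------------------------------------------
    mat = abundance_matrix(substrate)
    dm = bray_curtis(mat)
    labels = [s.meta.treatment for s in substrate]
    res = anosim(dm, labels, n_permutations=config.stats["n_permutations"],
                 seed=config.seed + 10)
    (out / "anosim.json").write_text(
        json.dumps(
            {"r": res.r, "p": res.p, "n_permutations": res.n_permutations,
             "seed": res.seed, "grouping": "treatment"},
            sort_keys=True, indent=2,
        ) + "\n"
    )
    metric_cols = ["richness", "mean_hc", "mean_oc", "mean_dbe", "mean_dbe_c", "mean_aimod"]
    sub_summ = summaries[summaries["arm"].isna()]
    pca_res = pca(sub_summ.set_index("sample_id")[metric_cols], standardize=True)
    pd.DataFrame(
        pca_res.scores[:, :2], columns=["pc1", "pc2"],
        index=sub_summ["sample_id"],
    ).to_csv(out / "pca_scores.csv", lineterminator="\n", float_format="%.10g")
    manifest.add_stage("stats", _stage_outputs([out / "anosim.json", out / "pca_scores.csv"]))

    # --- parafac + formula-component correlation --------------------------
    model = fit_parafac(
        eems,
        n_components=config.parafac["n_components"],
        n_restarts=config.parafac["n_restarts"],
        max_iter=config.parafac["max_iter"],
        tol=config.parafac["tol"],
        seed=config.seed + 20,
    )
    peaks = component_peaks(model)
    comp_names = [f"C{k + 1}" for k in range(model.n_components)]
    pd.DataFrame(model.ex_loadings, index=eems.excitation_nm, columns=comp_names).to_csv(
        out / "parafac_ex_loadings.csv", lineterminator="\n", float_format="%.10g"
    )
    pd.DataFrame(model.em_loadings, index=eems.emission_nm, columns=comp_names).to_csv(
        out / "parafac_em_loadings.csv", lineterminator="\n", float_format="%.10g"
    )
    scores = pd.DataFrame(model.scores, index=eems.sample_ids, columns=comp_names)
    scores.to_csv(out / "parafac_scores.csv", lineterminator="\n", float_format="%.10g")
    (out / "parafac_fit.json").write_text(
        json.dumps(
            {
                "fit": model.fit,
                "n_iter": model.n_iter,
                "converged": model.converged,
                "component_peaks": [
                    {"component": comp_names[p.component],
                     "excitation_nm": p.excitation_nm, "emission_nm": p.emission_nm}
                    for p in peaks
                ],
            },
            sort_keys=True, indent=2,
        ) + "\n"
    )
    corr = formula_component_correlation(
        substrate, scores, alpha=config.stats["alpha"]
    )
    corr.table.to_csv(out / "formula_component_correlation.csv", index=False,
                      lineterminator="\n", float_format="%.10g")
    corr.summary.to_csv(out / "correlation_summary.csv", index=False,
                        lineterminator="\n", float_format="%.10g")
    manifest.add_stage(
        "parafac",
        _stage_outputs([
            out / "parafac_ex_loadings.csv", out / "parafac_em_loadings.csv",
            out / "parafac_scores.csv", out / "parafac_fit.json",
            out / "formula_component_correlation.csv", out / "correlation_summary.csv",
        ]),
    )
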