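"""End-to-end orchestration: simulate -> analyze -> integrate.

``run_pipeline`` executes the enabled stages in dependency order, writes
per-stage TSV outputs under the output directory, and records a
content-addressed manifest (inputs, parameters, seed, SHA-256 of every
output file).  Identical config + seed reruns produce byte-identical
outputs and manifest hashes.

Default planted effects mirror the two phenotype time courses the analysis
is built to expose: synaptogenesis-like parameters (spine density, mEPSC
and mIPSC frequency) are most strongly reduced in the VPA group at birth,
while plasticity-like parameters (E/I ratio, post-LFS field EPSP, spine
volume) dip at 3 months.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ephys, integration, io, spines, synthetic, transcriptomics, vocal
from ._util import AGES, GROUPS, AnalysisError, ConfigurationError, stream_rng

__all__ = ["RunConfig", "run_pipeline", "validate_inputs",
           "MissingDependencyError"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ephys", "spines", "vocal", "degs", "integrate")

#: stage -> stages whose outputs it reads
DEPENDENCIES = {
    "ephys": ("simulate",),
    "spines": ("simulate",),
    "vocal": ("simulate",),
    "degs": ("simulate",),
    "integrate": ("simulate", "ephys", "spines", "degs"),
}

# planted group-effect trajectories over (0M, 3M, 6M), log2 scale
PLANTED_LOGFC = {
    "mepsc_rate": (-0.8, -0.2, -0.1),
    "mipsc_rate": (-0.6, 0.3, 0.1),
    "spine_density": (-0.8, -0.2, -0.1),
    "spine_volume": (0.0, -0.7, -0.1),
}
LTD_POST_LEVELS = {"UE": (0.85, 0.95, 1.0), "VPA": (0.80, 0.60, 0.98)}

DEFAULTS: dict = {
    "out_dir": "pipeline_out",
    "seed": 0,
    "stages": {s: True for s in STAGES},
    "ephys": {
        "duration_s": 20.0,
        "cells_per_group": 3,
        "base_rate_hz": {"mEPSC": 1.0, "mIPSC": 1.5},
        "amp_mean_pa": 10.0,
        "noise_sd_pa": 1.25,
        "ltd_pathways": 4,
        "amp_thresh_sd": None,     # None -> age/condition defaults
        "area_thresh_sd_ms": None,
    },
    "spines": {
        "n_spines": 40,
        "n_dendrites": 8,
        "base_density_per_um": 0.5,
        "diam_range_um": [0.25, 0.8],
        "profile_noise_frac": 0.05,
        "od_coeff": 2.5,
        "od_noise_frac": 0.05,
    },
    "vocal": {
        "n_animals": {"UE": 8, "VPA": 5},
        "weeks": [11, 13],
        "mean_calls_per_session": 60,
        "phee_prob": {"UE": 0.44, "VPA": 0.79},
    },
    "degs": {
        "n_genes": 5000,
        "n_samples_per_cell": 8,
        "k_range": [1, 8],
        "n_init": 50,
    },
    "integrate": {
        "module_sizes": {f"M{i}": 200 for i in range(1, 7)},
        "concordance_probs": {"M1": 0.9, "M2": 0.9, "M3": 0.8,
                              "M4": 0.7, "M5": 0.5, "M6": 0.5},
        "p_cut": 0.1,
    },
}


class MissingDependencyError(AnalysisError):
    pass


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults merged in)."""

    settings: dict = field(default_factory=lambda: _merge(DEFAULTS, {}))

    @classmethod
    def from_dict(cls, overrides: dict | None = None) -> "RunConfig":
        cfg = cls(settings=_merge(DEFAULTS, overrides or {}))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def validate(self) -> None:
        unknown = set(self.settings.get("stages", {})) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"stages: unknown stage(s) {sorted(unknown)}")
        if not isinstance(self.settings.get("seed"), int):
            raise ConfigurationError("seed: must be an integer")
        enabled = self.enabled_stages
        for stage in enabled:
            for dep in DEPENDENCIES.get(stage, ()):
                if dep not in enabled:
                    # tolerated iff the dependency's outputs already exist
                    dep_dir = Path(self.settings["out_dir"]) / dep
                    if not dep_dir.is_dir():
                        raise MissingDependencyError(
                            f"stage '{stage}' requires outputs of disabled "
                            f"stage '{dep}'")

    @property
    def enabled_stages(self) -> list[str]:
        st = self.settings["stages"]
        return [s for s in STAGES if st.get(s, False)]

    @property
    def seed(self) -> int:
        return int(self.settings["seed"])

    @property
    def out_dir(self) -> Path:
        return Path(self.settings["out_dir"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _trace_name(condition, age, group, cell) -> str:
    return f"trace_{condition}_{age}_{group}_{cell:02d}.tsv"


def _cell_seed(seed, *parts) -> int:
    h = hashlib.sha256(("|".join(map(str, parts))).encode()).digest()
    return (int.from_bytes(h[:4], "big") ^ seed) % (2 ** 31)


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    written: list[Path] = []
    seed = cfg.seed
    s = cfg.settings

    # miniature-current traces + planted events
    ep = s["ephys"]
    for condition in ("mEPSC", "mIPSC"):
        base = ep["base_rate_hz"][condition]
        lfc = PLANTED_LOGFC[f"{condition.lower()}_rate"]
        for ai, age in enumerate(AGES):
            for group in GROUPS:
                rate = base * (2.0 ** lfc[ai] if group == "VPA" else 1.0)
                for cell in range(1, ep["cells_per_group"] + 1):
                    sim = synthetic.SimConfig(
                        seed=_cell_seed(seed, "mini", condition, age, group, cell),
                        duration_s=ep["duration_s"],
                        event_rate_hz=rate,
                        amp_mean_pa=ep["amp_mean_pa"],
                        noise_sd_pa=ep["noise_sd_pa"],
                        polarity="negative" if condition == "mEPSC" else "positive",
                    )
                    trace, truth = synthetic.gen_mini_trace(sim)
                    trace.condition, trace.age = condition, age
                    name = _trace_name(condition, age, group, cell)
                    written.append(io.write_trace(trace, out / name))
                    written.append(io.write_events(truth, out / f"truth_{name}"))

    # LTD series
    for ai, age in enumerate(AGES):
        for group in GROUPS:
            for path_i in range(1, ep["ltd_pathways"] + 1):
                series = synthetic.gen_ltd_series(
                    seed=_cell_seed(seed, "ltd", age, group, path_i),
                    post_level=LTD_POST_LEVELS[group][ai])
                written.append(io.write_ltd_series(
                    series, out / f"ltd_{age}_{group}_{path_i:02d}.tsv"))

    # spine profiles, optical densities and per-dendrite counts
    sp = s["spines"]
    count_rows = []
    for ai, age in enumerate(AGES):
        segment = (25.0, 50.0) if age == "0M" else (50.0, 75.0)
        for group in GROUPS:
            scale = (2.0 ** (PLANTED_LOGFC["spine_volume"][ai] / 3.0)
                     if group == "VPA" else 1.0)
            lo, hi = sp["diam_range_um"]
            profiles, truths = synthetic.gen_spine_profiles(
                seed=_cell_seed(seed, "spines", age, group),
                n_spines=sp["n_spines"],
                diam_range_um=(lo * scale, hi * scale),
                profile_noise_frac=sp["profile_noise_frac"],
                od_coeff=sp["od_coeff"], od_noise_frac=sp["od_noise_frac"])
            written.append(io.write_tsv(
                profiles, out / f"profiles_{age}_{group}.tsv", index=False))
            written.append(io.write_tsv(
                truths, out / f"spine_truth_{age}_{group}.tsv", index=False))
            dens = (sp["base_density_per_um"]
                    * (2.0 ** PLANTED_LOGFC["spine_density"][ai]
                       if group == "VPA" else 1.0))
            rng = stream_rng(_cell_seed(seed, "density", age, group), "counts")
            seg_len = segment[1] - segment[0]
            for dend in range(1, sp["n_dendrites"] + 1):
                count = int(rng.poisson(dens * seg_len))
                count_rows.append((age, group, dend, segment[0], segment[1],
                                   count))
    written.append(io.write_tsv(pd.DataFrame(
        count_rows, columns=["age", "group", "dendrite", "segment_start_um",
                             "segment_end_um", "spine_count"]),
        out / "spine_counts.tsv", index=False))

    # call sessions
    vc = s["vocal"]
    call_rows = []
    for group in GROUPS:
        phee = vc["phee_prob"][group]
        rest = (1.0 - phee) / 6.0
        probs = {t: (phee if t == "phee" else rest) for t in vocal.CALL_TYPES}
        for animal_i in range(1, vc["n_animals"][group] + 1):
            animal = f"{group}{animal_i:02d}"
            for week in range(vc["weeks"][0], vc["weeks"][1] + 1):
                srng = stream_rng(_cell_seed(seed, "calls", animal, week), "n")
                n_calls = int(srng.poisson(vc["mean_calls_per_session"]))
                table, _counts = synthetic.gen_call_session(
                    seed=_cell_seed(seed, "callsession", animal, week),
                    n_calls=n_calls, type_probs=probs)
                table.insert(0, "animal", animal)
                table.insert(1, "week", week)
                table.insert(2, "group", group)
                call_rows.append(table)
    written.append(io.write_tsv(pd.concat(call_rows, ignore_index=True),
                                out / "calls.tsv", index=False))

    # expression study
    dg = s["degs"]
    expr_cfg = synthetic.ExprSimConfig(
        seed=_cell_seed(seed, "expression"),
        n_genes=dg["n_genes"], n_samples_per_cell=dg["n_samples_per_cell"])
    study, truth = synthetic.gen_expression(expr_cfg)
    written.append(io.write_tsv(study.matrix, out / "expression_matrix.tsv"))
    written.append(io.write_tsv(study.metadata, out / "expression_metadata.tsv"))
    written.append(io.write_tsv(truth, out / "expression_truth.tsv"))

    # cross-species tables
    ig = s["integrate"]
    ta, tb, module_map, xtruth = synthetic.gen_cross_species(
        seed=_cell_seed(seed, "xspecies"),
        module_sizes=ig["module_sizes"],
        concordance_probs=ig["concordance_probs"])
    written.append(io.write_tsv(ta, out / "xspecies_model.tsv"))
    written.append(io.write_tsv(tb, out / "xspecies_external.tsv"))
    written.append(io.write_tsv(module_map.to_frame(), out / "module_map.tsv"))
    written.append(io.write_tsv(xtruth, out / "xspecies_truth.tsv"))
    return written


def _stage_ephys(cfg: RunConfig, out: Path, sim: Path) -> list[Path]:
    written: list[Path] = []
    ep = cfg.settings["ephys"]
    rows = []
    for condition in ("mEPSC", "mIPSC"):
        for age in AGES:
            params = ephys.default_params(age, condition)
            if ep.get("amp_thresh_sd"):
                params.amp_thresh_sd = float(ep["amp_thresh_sd"])
            if ep.get("area_thresh_sd_ms"):
                params.area_thresh_sd_ms = float(ep["area_thresh_sd_ms"])
            for group in GROUPS:
                for cell in range(1, ep["cells_per_group"] + 1):
                    name = _trace_name(condition, age, group, cell)
                    trace = io.read_trace(sim / name)
                    events = ephys.detect_minis(trace, params)
                    summ = ephys.summarize_cells(events, condition=condition,
                                                 age=age, group=group)
                    written.append(io.write_events(
                        events, out / f"events_{name}"))
                    rows.append((condition, age, group, cell,
                                 summ.frequency_hz, summ.mean_amplitude_pa,
                                 summ.n_events))
    summary = pd.DataFrame(rows, columns=[
        "condition", "age", "group", "cell", "frequency_hz",
        "mean_amplitude_pa", "n_events"])
    written.append(io.write_tsv(summary, out / "cell_summaries.tsv",
                                index=False))

    # LTD magnitudes
    ltd_rows = []
    for age in AGES:
        for group in GROUPS:
            for path in sorted(sim.glob(f"ltd_{age}_{group}_*.tsv")):
                series = io.read_ltd_series(path)
                ltd_rows.append((age, group, path.name,
                                 ephys.ltd_magnitude(series)))
    ltd = pd.DataFrame(ltd_rows,
                       columns=["age", "group", "series", "ltd_magnitude"])
    written.append(io.write_tsv(ltd, out / "ltd_magnitudes.tsv", index=False))

    # phenotype logFC trajectories from group means
    pheno = {}
    for condition, label in (("mEPSC", "mepsc_frequency"),
                             ("mIPSC", "mipsc_frequency")):
        vals = []
        for age in AGES:
            sel = summary[(summary.condition == condition)
                          & (summary.age == age)]
            vals.append(ephys.phenotype_logfc(
                sel[sel.group == "UE"]["frequency_hz"],
                sel[sel.group == "VPA"]["frequency_hz"]))
        pheno[label] = vals
    # E/I ratio of group-mean frequencies: logFC(E/I) = logFC(E) - logFC(I)
    pheno["ei_ratio_miniature"] = [
        e - i for e, i in zip(pheno["mepsc_frequency"],
                              pheno["mipsc_frequency"])]
    vals = []
    for age in AGES:
        sel = ltd[ltd.age == age]
        vals.append(ephys.phenotype_logfc(
            sel[sel.group == "UE"]["ltd_magnitude"],
            sel[sel.group == "VPA"]["ltd_magnitude"]))
    pheno["post_lfs_fepsp"] = vals
    pheno_df = pd.DataFrame(pheno, index=[f"logFC_{a}" for a in AGES]).T
    pheno_df.index.name = "phenotype"
    written.append(io.write_tsv(pheno_df, out / "phenotypes.tsv"))

    # group statistics (Welch + Holm-Sidak across ages)
    stat_frames = []
    for condition in ("mEPSC", "mIPSC"):
        sub = summary[summary.condition == condition]
        by_age = {age: (sub[(sub.age == age) & (sub.group == "UE")]
                        ["frequency_hz"].to_numpy(),
                        sub[(sub.age == age) & (sub.group == "VPA")]
                        ["frequency_hz"].to_numpy())
                  for age in AGES}
        res = ephys.group_compare(by_age)
        res.insert(0, "condition", condition)
        stat_frames.append(res)
    written.append(io.write_tsv(pd.concat(stat_frames),
                                out / "group_stats.tsv"))
    return written


def _stage_spines(cfg: RunConfig, out: Path, sim: Path) -> list[Path]:
    written: list[Path] = []
    record_frames = []
    for age in AGES:
        for group in GROUPS:
            profiles = pd.read_csv(sim / f"profiles_{age}_{group}.tsv",
                                   sep="\t")
            truths = pd.read_csv(sim / f"spine_truth_{age}_{group}.tsv",
                                 sep="\t")
            ods = truths.set_index("spine_id")["optical_density"]
            recs = []
            for spine_id, grp in profiles.groupby("spine_id"):
                t = grp[grp.axis == "t"].sort_values("position_um")
                a = grp[grp.axis == "a"].sort_values("position_um")
                prof = spines.SpineProfile(
                    t["position_um"].to_numpy(), t["intensity"].to_numpy(),
                    a["position_um"].to_numpy(), a["intensity"].to_numpy())
                d_t, d_a = spines.fit_profile_diameter(prof)
                recs.append({"spine_id": spine_id, "age": age, "group": group,
                             "d_t_um": d_t, "d_a_um": d_a,
                             "volume_um3": spines.spine_volume(d_t, d_a),
                             "optical_density": float(ods[spine_id])})
            df = pd.DataFrame(recs)
            cal = spines.calibrate_od(df)
            df["volume_from_od_um3"] = [
                spines.estimate_volume_from_od(od, cal)
                for od in df["optical_density"]]
            df["calibration_coeff"] = cal.coefficient
            record_frames.append(df)
    records = pd.concat(record_frames, ignore_index=True)
    written.append(io.write_tsv(records, out / "spine_records.tsv",
                                index=False))

    counts = pd.read_csv(sim / "spine_counts.tsv", sep="\t")
    counts["density_per_um"] = [
        spines.spine_density(int(r.spine_count),
                             (r.segment_start_um, r.segment_end_um))
        for r in counts.itertuples()]
    written.append(io.write_tsv(counts, out / "spine_density.tsv",
                                index=False))

    # phenotype trajectories and distribution tests
    pheno = {"spine_density": [], "spine_volume": []}
    ks_rows = []
    for age in AGES:
        cnt = counts[counts.age == age]
        pheno["spine_density"].append(ephys.phenotype_logfc(
            cnt[cnt.group == "UE"]["density_per_um"],
            cnt[cnt.group == "VPA"]["density_per_um"]))
        rec = records[records.age == age]
        ue = rec[rec.group == "UE"]["volume_from_od_um3"]
        vpa = rec[rec.group == "VPA"]["volume_from_od_um3"]
        pheno["spine_volume"].append(ephys.phenotype_logfc(ue, vpa))
        d_stat, p = spines.compare_distributions_ks(ue, vpa)
        ks_rows.append((age, d_stat, p))
    pheno_df = pd.DataFrame(pheno, index=[f"logFC_{a}" for a in AGES]).T
    pheno_df.index.name = "phenotype"
    written.append(io.write_tsv(pheno_df, out / "phenotypes.tsv"))
    written.append(io.write_tsv(
        pd.DataFrame(ks_rows, columns=["age", "ks_d", "ks_p"]),
        out / "volume_ks.tsv", index=False))
    return written


def _stage_vocal(cfg: RunConfig, out: Path, sim: Path) -> list[Path]:
    written: list[Path] = []
    weeks = cfg.settings["vocal"]["weeks"]
    calls = pd.read_csv(sim / "calls.tsv", sep="\t")
    ratio_rows = []
    for (animal, group, week), grp in calls.groupby(["animal", "group",
                                                     "week"]):
        summ = vocal.summarize_session(grp.sort_values("onset_s"))
        if summ.ratios is None:
            continue
        row = {"animal": animal, "group": group, "week": week,
               "total_bouts": summ.total_calls,
               "entropy_bits": summ.entropy_bits}
        row.update({f"ratio_{t}": r for t, r in summ.ratios.items()})
        ratio_rows.append(row)
    summary = pd.DataFrame(ratio_rows)
    written.append(io.write_tsv(summary, out / "session_summaries.tsv",
                                index=False))
    per_animal = vocal.entropy_by_animal(calls, weeks=tuple(weeks))
    groups = calls.drop_duplicates("animal").set_index("animal")["group"]
    ent = per_animal.to_frame()
    ent["group"] = groups.reindex(ent.index)
    written.append(io.write_tsv(ent, out / "entropy_by_animal.tsv"))
    from scipy import stats as _st
    ue = ent[ent.group == "UE"]["entropy_bits"]
    vpa = ent[ent.group == "VPA"]["entropy_bits"]
    t, p = _st.ttest_ind(vpa, ue, equal_var=False)
    written.append(io.write_tsv(pd.DataFrame(
        [{"mean_entropy_UE": float(ue.mean()),
          "mean_entropy_VPA": float(vpa.mean()),
          "t_stat": float(t), "p_value": float(p)}]),
        out / "entropy_stats.tsv", index=False))
    return written


def _stage_degs(cfg: RunConfig, out: Path, sim: Path) -> list[Path]:
    written: list[Path] = []
    dg = cfg.settings["degs"]
    study = transcriptomics.ExpressionStudy(
        matrix=io.read_tsv(sim / "expression_matrix.tsv"),
        metadata=io.read_tsv(sim / "expression_metadata.tsv"))
    k_lo, k_hi = dg["k_range"]
    table, model = transcriptomics.deg_pipeline(
        study, k_range=range(k_lo, k_hi + 1), n_init=dg["n_init"],
        seed=cfg.seed)
    written.append(io.write_tsv(table, out / "deg_table.tsv"))
    if model is not None:
        written.append(io.write_tsv(model.centroids, out / "centroids.tsv"))
        written.append(io.write_tsv(
            model.assignments.to_frame(), out / "cluster_assignments.tsv"))
        report = pd.DataFrame({"k": model.aic_by_k.index,
                               "rss": model.rss_by_k.to_numpy(),
                               "aic": model.aic_by_k.to_numpy()})
        report["selected"] = report["k"] == model.k
        written.append(io.write_tsv(report, out / "aic_curve.tsv",
                                    index=False))
    return written


def _stage_integrate(cfg: RunConfig, out: Path, base: Path) -> list[Path]:
    written: list[Path] = []
    centroids = io.read_tsv(base / "degs" / "centroids.tsv")
    pheno = pd.concat([io.read_tsv(base / "ephys" / "phenotypes.tsv"),
                       io.read_tsv(base / "spines" / "phenotypes.tsv")])
    dist = integration.distance_matrix(centroids, pheno)
    written.append(io.write_tsv(dist, out / "distance_matrix.tsv"))

    sim = base / "simulate"
    ta = io.read_tsv(sim / "xspecies_model.tsv")
    tb = io.read_tsv(sim / "xspecies_external.tsv")
    module_map = io.read_tsv(sim / "module_map.tsv")["module"]
    cross = pd.DataFrame({
        "logFC_model": ta["logFC"], "padj_model": ta["p_adj"],
        "logFC_ext": tb["logFC"], "padj_ext": tb["p_adj"]})
    res = integration.cross_species_spearman(
        cross, p_cut=cfg.settings["integrate"]["p_cut"])
    written.append(io.write_tsv(pd.DataFrame(
        [{"rho": res.rho, "p_value": res.p_value, "n_genes": res.n_genes,
          "insufficient": res.insufficient}]),
        out / "spearman.tsv", index=False))
    conc = integration.module_concordance(cross, module_map)
    written.append(io.write_tsv(conc, out / "module_concordance.tsv"))
    return written


_STAGE_FUNCS = {
    "simulate": lambda cfg, out, base: _stage_simulate(cfg, out),
    "ephys": lambda cfg, out, base: _stage_ephys(cfg, out, base / "simulate"),
    "spines": lambda cfg, out, base: _stage_spines(cfg, out, base / "simulate"),
    "vocal": lambda cfg, out, base: _stage_vocal(cfg, out, base / "simulate"),
    "degs": lambda cfg, out, base: _stage_degs(cfg, out, base / "simulate"),
    "integrate": _stage_integrate,
}


def run_pipeline(config: RunConfig | dict | None = None) -> dict:
    """Execute the enabled stages in dependency order; return the manifest.

    The manifest records the configuration, seed, and the SHA-256 of every
    output file per stage, and is written as ``manifest.json`` alongside a
    short human-readable ``report.txt``.
    """
    if config is None or isinstance(config, dict):
        config = RunConfig.from_dict(config)
    else:
        config.validate()
    base = config.out_dir
    base.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": config.settings,
                      "stages": {}}
    for stage in config.enabled_stages:
        logger.info("running stage %s", stage)
        out = base / stage
        out.mkdir(parents=True, exist_ok=True)
        try:
            files = _STAGE_FUNCS[stage](config, out, base)
        except FileNotFoundError as exc:
            raise MissingDependencyError(
                f"stage '{stage}' is missing an input file: {exc}") from exc
        manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(base)): _sha256(p)
                        for p in sorted(files)}}
    with open(base / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    lines = [f"pipeline run (seed={config.seed})"]
    for stage, info in manifest["stages"].items():
        lines.append(f"  {stage}: {len(info['outputs'])} output file(s)")
    (base / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return manifest


# ---------------------------------------------------------------------------
# input validation

def _check_columns(df: pd.DataFrame, required: set, path) -> list[str]:
    missing = required - set(df.columns)
    return [f"{path}: missing column(s) {sorted(missing)}"] if missing else []


def validate_inputs(paths: dict[str, str]) -> pd.DataFrame:
    """Schema-check input files; returns a per-file pass/fail report.

    ``paths`` maps a kind in {trace, events, calls, profiles, matrix+meta}
    to a file path (matrix+meta takes "matrix_path:meta_path").
    """
    rows = []
    for kind, path in paths.items():
        problems: list[str] = []
        try:
            if kind == "trace":
                trace = io.read_trace(path)
                if not np.isfinite(trace.samples).all():
                    problems.append(f"{path}: non-numeric or non-finite samples")
            elif kind == "events":
                io.read_events(path)
            elif kind == "calls":
                df = pd.read_csv(path, sep="\t")
                problems += _check_columns(df, {"onset_s", "call_type"}, path)
                if not problems:
                    bad = set(df["call_type"]) - set(vocal.CALL_TYPES)
                    if bad:
                        problems.append(f"{path}: unknown call types {sorted(bad)}")
            elif kind == "profiles":
                df = pd.read_csv(path, sep="\t")
                problems += _check_columns(
                    df, {"spine_id", "axis", "position_um", "intensity"}, path)
            elif kind == "matrix+meta":
                mpath, _, metapath = path.partition(":")
                mat = io.read_tsv(mpath)
                meta = io.read_tsv(metapath)
                missing = set(mat.columns) - set(meta.index)
                if missing:
                    problems.append(
                        f"{mpath}: samples without metadata {sorted(missing)[:5]}")
                nonnum = mat.columns[
                    ~mat.dtypes.map(pd.api.types.is_numeric_dtype)]
                for col in nonnum:
                    bad_rows = mat.index[
                        pd.to_numeric(mat[col], errors="coerce").isna()]
                    problems.append(
                        f"{mpath}: non-numeric value(s) in column {col!r}, "
                        f"row(s) {list(bad_rows[:3])}")
            else:
                problems.append(f"unknown input kind {kind!r}")
        except FileNotFoundError:
            problems.append(f"{path}: file not found")
        except Exception as exc:  # surfaced, not raised: this is a report
            problems.append(f"{path}: {exc}")
        rows.append((kind, str(path), not problems, "; ".join(problems)))
    return pd.DataFrame(rows, columns=["kind", "path", "passed",
                                       "diagnostics"])
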