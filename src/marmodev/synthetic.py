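"""Seeded generators for every input kind, with planted ground truth.

Each generator is a pure function of its configuration (including the
seed): identical configs produce bit-identical outputs.  Randomness is
split per sub-stream from the one seed, so adding a generator never
perturbs the draws of existing ones.  Every generator returns its data
together with a serializable ground-truth table, so downstream detection,
fitting, testing and clustering can be scored against the planted truth
without any external download.

Generated kinds:

* miniature-current traces: homogeneous Poisson event trains convolved
  with a difference-of-exponentials kernel (peak-normalized, so detection
  thresholds act on the drawn amplitude), plus Gaussian noise;
* spine intensity profiles: per-axis Gaussians with σ = diameter/2, plus
  multiplicative noise, and optical densities proportional to true volume;
* call sessions: i.i.d. categorical draws over the seven call types;
* expression studies: per-gene baselines with three planted logFC-trajectory
  clusters among the DEGs (defaults mimic a strongly neonatal-downregulated
  cluster, an infancy-downregulated cluster and an infancy-upregulated
  cluster);
* paired cross-species logFC tables with planted per-module sign
  concordance;
* piecewise-constant LTD series (baseline level 1, a planted post-LFS
  level) for phenotype plumbing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import AGES, GROUPS, ConfigurationError, require, stream_rng
from .ephys import EventList, Trace, LTDSeries
from .transcriptomics import ExpressionStudy
from .vocal import CALL_TYPES

__all__ = [
    "SimConfig",
    "ExprSimConfig",
    "gen_mini_trace",
    "gen_spine_profiles",
    "gen_call_session",
    "gen_expression",
    "gen_cross_species",
    "gen_ltd_series",
]

AREAS = ("8", "12", "TE")


# ---------------------------------------------------------------------------
# miniature-current traces

@dataclass
class SimConfig:
    """Simulated miniature-current recording.

    Amplitude and kinetic defaults are placeholders in the plausible range
    for cortical miniature currents (no distributional parameters are
    established for marmoset cortex): 10 pA mean peak, CV 0.3, 0.5 ms rise,
    5 ms decay, 1.25 pA baseline noise at 10 kHz.
    """

    seed: int = 0
    duration_s: float = 60.0
    sampling_hz: float = 10_000.0
    event_rate_hz: float = 1.0
    amp_mean_pa: float = 10.0
    amp_cv: float = 0.3
    rise_ms: float = 0.5
    decay_ms: float = 5.0
    noise_sd_pa: float = 1.25
    polarity: str = "negative"

    def validate(self) -> None:
        require(self.duration_s > 0, "duration_s", "must be positive")
        require(self.sampling_hz > 0, "sampling_hz", "must be positive")
        require(self.event_rate_hz >= 0, "event_rate_hz", "must be >= 0")
        require(self.amp_mean_pa > 0, "amp_mean_pa", "must be positive")
        require(self.amp_cv >= 0, "amp_cv", "must be >= 0")
        require(0 < self.rise_ms < self.decay_ms, "rise_ms",
                "need 0 < rise_ms < decay_ms")
        require(self.noise_sd_pa >= 0, "noise_sd_pa", "must be >= 0")
        require(self.polarity in ("negative", "positive"), "polarity",
                "must be 'negative' or 'positive'")


def _doe_kernel(cfg: SimConfig) -> tuple[np.ndarray, int]:
    """Difference-of-exponentials kernel normalized to unit peak.

    Returns the kernel and the index of its peak (samples after onset).
    """
    tr = cfg.rise_ms * 1e-3
    td = cfg.decay_ms * 1e-3
    dt = 1.0 / cfg.sampling_hz
    length = max(2, int(round(8 * td / dt)))
    t = np.arange(length) * dt
    k = np.exp(-t / td) - np.exp(-t / tr)
    peak = int(np.argmax(k))
    k /= k[peak]
    return k, peak


def gen_mini_trace(cfg: SimConfig) -> tuple[Trace, EventList]:
    """Simulate a miniature-current trace; returns (trace, planted events).

    Event times follow a homogeneous Poisson process; each event is the
    unit-peak kernel scaled by a gamma-distributed amplitude with the
    configured mean and CV (constant when CV = 0).  Overlapping events sum
    linearly; polarity flips the deflection sign; Gaussian noise is added
    throughout.  The ground-truth table records onset and peak times and
    peak amplitudes.
    """
    cfg.validate()
    n = int(round(cfg.duration_s * cfg.sampling_hz))
    rng_ev = stream_rng(cfg.seed, "mini.events")
    rng_amp = stream_rng(cfg.seed, "mini.amplitudes")
    rng_noise = stream_rng(cfg.seed, "mini.noise")

    n_events = rng_ev.poisson(cfg.event_rate_hz * cfg.duration_s)
    onsets = np.sort(rng_ev.uniform(0.0, cfg.duration_s, size=n_events))
    if cfg.amp_cv > 0:
        shape = 1.0 / cfg.amp_cv ** 2
        amps = rng_amp.gamma(shape, cfg.amp_mean_pa / shape, size=n_events)
    else:
        amps = np.full(n_events, cfg.amp_mean_pa)

    clean = np.zeros(n)
    kernel, kpeak = _doe_kernel(cfg)
    onset_idx = np.minimum((onsets * cfg.sampling_hz).astype(int), n - 1)
    for i0, a in zip(onset_idx, amps):
        seg = kernel[: n - i0]
        clean[i0:i0 + seg.size] += a * seg
    sign = -1.0 if cfg.polarity == "negative" else 1.0
    samples = sign * clean
    if cfg.noise_sd_pa > 0:
        samples = samples + rng_noise.normal(0.0, cfg.noise_sd_pa, size=n)

    truth = pd.DataFrame({
        "onset_s": onsets,
        "peak_s": np.minimum(onset_idx + kpeak, n - 1) / cfg.sampling_hz,
        "peak_amplitude_pa": amps,
    })
    trace = Trace(samples=samples, sampling_hz=cfg.sampling_hz,
                  polarity=cfg.polarity)
    events = EventList(events=truth.assign(area_pa_ms=np.nan),
                       trace_duration_s=cfg.duration_s)
    return trace, events


# ---------------------------------------------------------------------------
# spine profiles

def gen_spine_profiles(seed: int, n_spines: int = 30,
                       diam_range_um: tuple[float, float] = (0.2, 0.8),
                       profile_noise_frac: float = 0.05,
                       od_coeff: float = 2.5,
                       od_noise_frac: float = 0.05
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate spine intensity profiles and optical densities.

    For each spine, transverse and axial diameters are drawn uniformly from
    ``diam_range_um``; each axis gets a Gaussian profile with σ = d/2 on a
    fixed position grid, scaled by a random amplitude over a constant
    background, with multiplicative noise.  Optical density is
    od_coeff × true volume × (1 + noise).  Returns (profiles, truths);
    ``truths`` carries the planted diameters, volume, OD and the reference
    flag (both diameters > 0.4 µm and volume < 0.4 µm³).
    """
    lo, hi = diam_range_um
    require(0 < lo <= hi <= 2.0, "diam_range_um", "must lie within (0, 2] µm")
    require(n_spines >= 1, "n_spines", "must be >= 1")
    require(od_coeff > 0, "od_coeff", "must be positive")
    rng = stream_rng(seed, "spines")
    positions = np.linspace(-1.5 * hi, 1.5 * hi, 61)

    prof_rows, truth_rows = [], []
    for sid in range(n_spines):
        spine_id = f"spine{sid:03d}"
        d_t, d_a = rng.uniform(lo, hi, size=2)
        volume = math.pi * d_t ** 2 * d_a / 6.0
        od = od_coeff * volume * (1.0 + od_noise_frac * rng.standard_normal())
        for axis, diam in (("t", d_t), ("a", d_a)):
            sigma = diam / 2.0
            amp = rng.uniform(500.0, 1500.0)
            background = rng.uniform(20.0, 80.0)
            intensity = amp * np.exp(-positions ** 2 / (2 * sigma ** 2)) + background
            if profile_noise_frac > 0:
                intensity = intensity * (
                    1.0 + profile_noise_frac * rng.standard_normal(positions.size))
            for x, y in zip(positions, intensity):
                prof_rows.append((spine_id, axis, x, y))
        truth_rows.append((spine_id, d_t, d_a, volume, od,
                           d_t > 0.4 and d_a > 0.4 and volume < 0.4))
    profiles = pd.DataFrame(
        prof_rows, columns=["spine_id", "axis", "position_um", "intensity"])
    truths = pd.DataFrame(
        truth_rows, columns=["spine_id", "d_t_um", "d_a_um", "volume_um3",
                             "optical_density", "is_reference"])
    return profiles, truths


# ---------------------------------------------------------------------------
# call sessions

def gen_call_session(seed: int, n_calls: int,
                     type_probs: dict[str, float],
                     mean_gap_s: float = 2.0) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate an annotated call session; returns (table, true counts).

    Call types are i.i.d. categorical draws over the seven-label
    vocabulary; onsets accumulate exponential inter-call gaps.
    """
    require(n_calls >= 0, "n_calls", "must be >= 0")
    unknown = set(type_probs) - set(CALL_TYPES)
    if unknown:
        raise ConfigurationError(f"type_probs: unknown labels {sorted(unknown)}")
    labels = [t for t in CALL_TYPES if t in type_probs]
    probs = np.array([type_probs[t] for t in labels], dtype=float)
    require(bool(np.all(probs >= 0)), "type_probs", "must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigurationError(
            f"type_probs: probabilities sum to {probs.sum()!r}, not 1")
    rng = stream_rng(seed, "calls")
    idx = rng.choice(len(labels), size=n_calls, p=probs / probs.sum())
    onsets = np.cumsum(rng.exponential(mean_gap_s, size=n_calls))
    table = pd.DataFrame({"onset_s": onsets,
                          "call_type": [labels[i] for i in idx]})
    counts = pd.Series(np.bincount(idx, minlength=len(labels)),
                       index=list(labels), dtype=int, name="count")
    return table, counts


# ---------------------------------------------------------------------------
# expression studies

@dataclass
class ExprSimConfig:
    """Planted-trajectory expression study.

    Defaults: 5000 genes, 10% DEGs split 40/30/30 over three clusters with
    logFC trajectories (−0.8, −0.2, −0.1), (−0.1, −0.7, −0.3) and
    (0.1, 0.7, 0.3) over (0M, 3M, 6M) — a strongly neonatal-downregulated
    cluster and two oppositely-signed infancy-peaked clusters — with
    baseline log2 level 7 ± 1.5 across genes, residual noise SD 0.3 and
    8 samples per (age × group) cell.
    """

    seed: int = 0
    n_genes: int = 5000
    n_samples_per_cell: int = 8
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.3
    deg_fraction: float = 0.1
    cluster_fractions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    cluster_effects: tuple[tuple[float, float, float], ...] = (
        (-0.8, -0.2, -0.1),
        (-0.1, -0.7, -0.3),
        (0.1, 0.7, 0.3),
    )

    def validate(self) -> None:
        require(self.n_genes >= 1, "n_genes", "must be >= 1")
        require(self.n_samples_per_cell >= 2, "n_samples_per_cell",
                "must be >= 2 (Welch test undefined otherwise)")
        require(self.baseline_sd >= 0, "baseline_sd", "must be >= 0")
        require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        require(0 <= self.deg_fraction <= 1, "deg_fraction", "must be in [0, 1]")
        fr = np.array(self.cluster_fractions, dtype=float)
        require(len(fr) == len(self.cluster_effects), "cluster_fractions",
                "must match the number of cluster_effects rows")
        require(bool(np.all(fr >= 0)) and fr.sum() <= 1 + 1e-9,
                "cluster_fractions", "must be >= 0 and sum <= 1")
        for row in self.cluster_effects:
            require(len(row) == 3, "cluster_effects",
                    "each row needs 3 ages in order (0M, 3M, 6M)")


def gen_expression(cfg: ExprSimConfig) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Simulate a log2 expression study; returns (study, gene truth table).

    Per-gene baselines are Normal(baseline_mean, baseline_sd²).  VPA samples
    of a planted DEG at age t get the cluster's logFC effect added.  The
    truth table records is_deg and the planted cluster (1-based, 0 for
    non-DEGs).
    """
    cfg.validate()
    rng = stream_rng(cfg.seed, "expression")
    genes = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)

    # plant DEG effects only on genes safely above the expression floor
    # (log2 > 5), so every planted truth is recoverable in principle: at
    # zero noise, no planted DEG may be lost to the expressed-gene filter.
    n_deg = int(round(cfg.deg_fraction * cfg.n_genes))
    eligible = np.where(baseline > 5.5)[0]
    if eligible.size < n_deg:
        eligible = np.arange(cfg.n_genes)
    deg_idx = rng.choice(eligible, size=n_deg, replace=False)
    cluster = np.zeros(cfg.n_genes, dtype=int)
    fr = np.array(cfg.cluster_fractions, dtype=float)
    counts = np.zeros(len(fr), dtype=int)
    if n_deg:
        counts = np.floor(fr / fr.sum() * n_deg).astype(int)
        counts[0] += n_deg - counts.sum()  # remainder to the first cluster
    start = 0
    for c, cnt in enumerate(counts, start=1):
        cluster[deg_idx[start:start + cnt]] = c
        start += cnt

    effects = np.array(cfg.cluster_effects, dtype=float)

    sample_ids, meta_rows, cols = [], [], []
    for ai, age in enumerate(AGES):
        for group in GROUPS:
            for i in range(cfg.n_samples_per_cell):
                sid = f"{age}_{group}_{i + 1:02d}"
                sample_ids.append(sid)
                meta_rows.append((sid, age, group, AREAS[i % len(AREAS)]))
                col = baseline.copy()
                if group == "VPA":
                    planted = cluster > 0
                    col[planted] += effects[cluster[planted] - 1, ai]
                if cfg.noise_sd > 0:
                    col = col + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
                cols.append(col)
    matrix = pd.DataFrame(np.column_stack(cols), index=genes,
                          columns=sample_ids)
    metadata = pd.DataFrame(meta_rows,
                            columns=["sample_id", "age", "group", "area"]
                            ).set_index("sample_id")
    truth = pd.DataFrame({"gene": genes, "is_deg": cluster > 0,
                          "cluster": cluster}).set_index("gene")
    return ExpressionStudy(matrix=matrix, metadata=metadata), truth


# ---------------------------------------------------------------------------
# cross-species logFC tables

def gen_cross_species(seed: int, module_sizes: dict[str, int],
                      concordance_probs: dict[str, float],
                      effect_sd: float = 0.5
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series,
                                 pd.DataFrame]:
    """Simulate paired logFC tables with planted module-level concordance.

    Per gene, logFC_A ~ Normal(0, effect_sd²); logFC_B has the same-sign
    magnitude drawn independently, with its sign agreeing with logFC_A with
    the module's concordance probability.  Adjusted p-values are drawn
    uniform on (0, 0.09) so every gene passes the standard 0.1 modulation
    cut.  Returns (table_A, table_B, module map, truth per module).
    """
    require(effect_sd > 0, "effect_sd", "must be positive")
    for m, size in module_sizes.items():
        require(size >= 1, "module_sizes", f"module {m!r} is empty")
        p = concordance_probs.get(m)
        require(p is not None, "concordance_probs", f"missing module {m!r}")
        require(0 <= p <= 1, "concordance_probs",
                f"module {m!r}: {p} outside [0, 1]")
    rng = stream_rng(seed, "cross_species")
    rows_a, rows_b, mod_rows, truth_rows = [], [], [], []
    for module in sorted(module_sizes):
        size = module_sizes[module]
        p_conc = concordance_probs[module]
        lfc_a = rng.normal(0.0, effect_sd, size=size)
        mag_b = np.abs(rng.normal(0.0, effect_sd, size=size))
        agree = rng.random(size) < p_conc
        sign_a = np.where(lfc_a >= 0, 1.0, -1.0)
        lfc_b = mag_b * np.where(agree, sign_a, -sign_a)
        padj_a = rng.uniform(0.0, 0.09, size=size)
        padj_b = rng.uniform(0.0, 0.09, size=size)
        for i in range(size):
            gene = f"{module}_g{i:04d}"
            rows_a.append((gene, lfc_a[i], padj_a[i]))
            rows_b.append((gene, lfc_b[i], padj_b[i]))
            mod_rows.append((gene, module))
        realized = float(np.mean(np.sign(lfc_b) == np.sign(lfc_a)))
        truth_rows.append((module, p_conc, realized))
    table_a = pd.DataFrame(rows_a, columns=["gene", "logFC", "p_adj"]
                           ).set_index("gene")
    table_b = pd.DataFrame(rows_b, columns=["gene", "logFC", "p_adj"]
                           ).set_index("gene")
    module_map = pd.Series({g: m for g, m in mod_rows}, name="module")
    truth = pd.DataFrame(truth_rows, columns=["module", "concordance_prob",
                                              "realized_agreement"]
                         ).set_index("module")
    return table_a, table_b, module_map, truth


# ---------------------------------------------------------------------------
# LTD series (piecewise-constant convenience generator)

def gen_ltd_series(seed: int, post_level: float, noise_sd: float = 0.02,
                   baseline_level: float = 1.0, dt_min: float = 0.5
                   ) -> LTDSeries:
    """Piecewise-constant normalized field-EPSP series around LFS onset.

    Baseline level over (−10, 0] min, a planted post-LFS level over
    (0, 40] min, plus Gaussian jitter.  Induction dynamics are not
    modeled; this exists to exercise the LTD-magnitude computation and the
    phenotype logFC plumbing.
    """
    require(post_level > 0, "post_level", "must be positive")
    rng = stream_rng(seed, "ltd")
    times = np.arange(-10.0 + dt_min, 40.0 + dt_min / 2, dt_min)
    amps = np.where(times <= 0, baseline_level, post_level).astype(float)
    if noise_sd > 0:
        amps = amps + rng.normal(0.0, noise_sd, size=times.size)
    return LTDSeries(times_min=times, amplitudes=amps)
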