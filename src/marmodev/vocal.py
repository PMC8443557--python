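"""Call-repertoire analysis: bout merging, call-type ratios and entropy.

Marmoset isolation calls are annotated with one of seven labels; continuous
multisyllabic sequences are treated as a single bout.  The repertoire
summary is the vector of per-type ratios r_i and the Shannon entropy
−Σ_i r_i log2 r_i (bits), which drops when one call type (typically phee)
dominates the repertoire.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import AnalysisError, ConfigurationError

__all__ = [
    "CALL_TYPES",
    "COMPOUND_TYPE",
    "CallSummary",
    "merge_bouts",
    "call_ratios",
    "call_entropy",
    "summarize_session",
    "entropy_by_animal",
]

COMPOUND_TYPE = "phee-trill/trill-phee"
CALL_TYPES = ("ekk/cough", "phee", "trill", "tsik", "twitter",
              COMPOUND_TYPE, "other")


@dataclass
class CallSummary:
    total_calls: int
    ratios: dict[str, float] | None  # None when the session is empty
    entropy_bits: float = math.nan


def _gaps(df: pd.DataFrame) -> np.ndarray:
    onset = df["onset_s"].to_numpy(dtype=float)
    if "offset_s" in df.columns and df["offset_s"].notna().all():
        prev_end = df["offset_s"].to_numpy(dtype=float)[:-1]
    else:
        prev_end = onset[:-1]
    return onset[1:] - prev_end


def _bout_type(types: list[str]) -> str:
    uniq = set(types)
    if COMPOUND_TYPE in uniq or {"phee", "trill"} <= uniq:
        return COMPOUND_TYPE
    # modal type; ties broken by order of first occurrence
    counts: dict[str, int] = {}
    for t in types:
        counts[t] = counts.get(t, 0) + 1
    best = max(counts.values())
    for t in types:
        if counts[t] == best:
            return t
    raise AssertionError("unreachable")


def merge_bouts(raw_calls: pd.DataFrame, max_gap_s: float = 0.05) -> pd.DataFrame:
    """Merge consecutive calls separated by <= ``max_gap_s`` into bouts.

    A bout mixing phee and trill takes the compound phee-trill/trill-phee
    label; otherwise the bout is labeled with its modal call type (ties go
    to the type occurring first).  Input rows must be time-ordered.
    """
    df = raw_calls.reset_index(drop=True)
    if len(df) == 0:
        return df.copy()
    onset = df["onset_s"].to_numpy(dtype=float)
    if np.any(np.diff(onset) < 0):
        raise AnalysisError("call table is not time-ordered by onset_s")
    unknown = set(df["call_type"]) - set(CALL_TYPES)
    if unknown:
        raise ConfigurationError(f"call_type: unknown labels {sorted(unknown)}")
    gaps = _gaps(df)
    new_bout = np.concatenate(([True], gaps > max_gap_s))
    bout_id = np.cumsum(new_bout) - 1
    rows = []
    for bid, grp in df.groupby(bout_id):
        row = {"onset_s": float(grp["onset_s"].iloc[0]),
               "call_type": _bout_type(list(grp["call_type"])),
               "n_syllables": len(grp)}
        if "offset_s" in df.columns:
            row["offset_s"] = float(grp["offset_s"].iloc[-1])
        rows.append(row)
    return pd.DataFrame(rows)


def call_ratios(table: pd.DataFrame) -> CallSummary:
    """Per-type ratios r_i = count_i / total; empty sessions are flagged."""
    total = len(table)
    if total == 0:
        return CallSummary(total_calls=0, ratios=None)
    counts = table["call_type"].value_counts()
    ratios = {t: float(counts.get(t, 0)) / total for t in CALL_TYPES}
    return CallSummary(total_calls=total, ratios=ratios)


def call_entropy(ratios) -> float:
    """Shannon entropy −Σ r_i log2 r_i in bits, with 0·log 0 := 0."""
    if isinstance(ratios, dict):
        r = np.array(list(ratios.values()), dtype=float)
    else:
        r = np.asarray(ratios, dtype=float)
    if np.any(r < 0):
        raise AnalysisError("ratios must be non-negative")
    if abs(r.sum() - 1.0) > 1e-9:
        raise AnalysisError(f"ratios must sum to 1, got {r.sum()!r}")
    nz = r[r > 0]
    return float(-(nz * np.log2(nz)).sum())


def summarize_session(raw_calls: pd.DataFrame, max_gap_s: float = 0.05,
                      on_bouts: bool = True) -> CallSummary:
    """Bout-merge (optional), then ratios and entropy for one session."""
    table = merge_bouts(raw_calls, max_gap_s) if on_bouts else raw_calls
    summary = call_ratios(table)
    if summary.ratios is not None:
        summary.entropy_bits = call_entropy(summary.ratios)
    return summary


def entropy_by_animal(sessions: pd.DataFrame, weeks=(11, 13),
                      max_gap_s: float = 0.05, on_bouts: bool = True
                      ) -> pd.Series:
    """Mean session entropy per animal over an age window (weeks, inclusive).

    ``sessions`` needs columns (animal, week, onset_s, call_type).  Empty
    sessions are skipped.
    """
    lo, hi = weeks
    sel = sessions[(sessions["week"] >= lo) & (sessions["week"] <= hi)]
    out = {}
    for (animal, _week), grp in sel.groupby(["animal", "week"]):
        s = summarize_session(grp, max_gap_s=max_gap_s, on_bouts=on_bouts)
        if s.ratios is not None:
            out.setdefault(animal, []).append(s.entropy_bits)
    return pd.Series({a: float(np.mean(v)) for a, v in out.items()},
                     name="entropy_bits", dtype=float)
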