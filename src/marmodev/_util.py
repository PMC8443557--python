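"""Shared plumbing: error types, seeded stream splitting, TSV conventions."""

from __future__ import annotations

import zlib

import numpy as np

AGES = ("0M", "3M", "6M")
GROUPS = ("UE", "VPA")


class ConfigurationError(ValueError):
    """A config field failed validation; the message names the field."""


class AnalysisError(RuntimeError):
    """A computation could not be carried out on the given data."""


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Independent child generator for a named sub-stream of ``seed``.

    Streams are split by a CRC32 of the stream name, so adding a new
    generator to the package never perturbs the draws of existing ones.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


def require(cond: bool, field: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{field}: {msg}")
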