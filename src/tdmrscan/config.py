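"""Pipeline configuration and seeded random-number substreams.

All randomness in a pipeline run flows from one integer seed through named
substreams: ``rng_for(seed, "digest:B:rep1")`` is independent of every other
stage's stream, so changing one stage's parameters never perturbs another
stage's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Deterministic generator for a named stage under a master seed."""
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


@dataclass
class PipelineConfig:
    """Validated knobs for the end-to-end demo analysis."""

    seed: int = 0
    # synthetic design
    n_genes: int = 200
    cgi_fraction: float = 0.5
    n_implants_per_direction: int = 30
    implant_delta: float = 0.6
    # assay readout
    size_range: tuple[int, int] = (40, 1000)
    probe_step: int = 35
    probe_length: int = 25
    n_replicates: int = 2
    background: float = 10.0
    gain: float = 50.0
    noise_sd: float = 0.3
    digestion_mode: str = "deterministic_expected"
    # scoring
    bandwidth: int = 500
    trim: float = 0.1
    min_probes: int = 4
    # calling
    threshold: float = 2.0
    min_probes_run: int = 4
    max_gap_bp: int = 300
    # clustering
    k: int = 2
    n_init: int = 20
    # misc
    outdir: str | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        checks = [
            (self.n_genes >= 1, "n_genes must be >= 1"),
            (0.0 <= self.cgi_fraction <= 1.0, "cgi_fraction must lie in [0, 1]"),
            (self.size_range[0] < self.size_range[1], "size_range min must be < max"),
            (self.n_replicates >= 1, "n_replicates must be >= 1"),
            (self.background > 0, "background must be positive"),
            (self.gain > 0, "gain must be positive"),
            (self.noise_sd >= 0, "noise_sd must be non-negative"),
            (0.0 <= self.trim < 0.5, "trim must lie in [0, 0.5)"),
            (self.min_probes >= 1, "min_probes must be >= 1"),
            (self.threshold > 0, "threshold must be positive"),
            (self.min_probes_run >= 1, "min_probes_run must be >= 1"),
            (self.max_gap_bp >= 0, "max_gap_bp must be non-negative"),
            (self.k >= 1, "k must be >= 1"),
            (self.n_init >= 1, "n_init must be >= 1"),
            (self.digestion_mode in ("deterministic_expected", "sampled"),
             "digestion_mode must be deterministic_expected or sampled"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
        self.size_range = (int(self.size_range[0]), int(self.size_range[1]))

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        if "size_range" in kwargs:
            kwargs["size_range"] = tuple(kwargs["size_range"])
        return cls(extra=extra, **kwargs)

    def to_yaml(self, path: str) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "extra"}
        data["size_range"] = list(self.size_range)
        data.update(self.extra)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
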