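"""Run-wide configuration.

:class:`RunConfig` gathers every numeric threshold the pipeline uses so
that a whole analysis is reproducible from one small YAML file. Defaults
follow the published protocol for depth-based homeologous-exchange
detection (10-kb windows, 1.5x duplication threshold, 50-kb linking,
>80-kb minimum segment) and the 50-bp structural-variant size floor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

from .errors import ParameterError


@dataclass
class RunConfig:
    #: width of non-overlapping depth windows (bp)
    window_size_bp: int = 10_000
    #: window mean depth >= dup_factor * genome mean flags a duplication
    dup_factor: float = 1.5
    #: window mean depth <= del_factor * genome mean flags a deletion
    del_factor: float = 0.25
    #: same-kind flagged windows closer than this are linked (bp)
    link_gap_bp: int = 50_000
    #: merged segments must exceed this length to be kept (bp, exclusive)
    min_he_len_bp: int = 80_000
    #: cis-regulatory flank around genes for PAV annotation (bp)
    cis_flank_bp: int = 2_000
    #: minimum |SVLEN| for a PAV record (bp, inclusive)
    min_pav_len_bp: int = 50
    #: TE family size difference that counts as lineage-divergent (bp)
    te_diff_threshold_bp: int = 10_000
    #: BH false-discovery-rate threshold for bias / DEG calls
    fdr_alpha: float = 0.05
    #: substitutions per site per year; no default is meaningful, so None
    mutation_rate: Optional[float] = None
    #: seed for every stochastic step
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "window_size_bp",
            "link_gap_bp",
            "min_he_len_bp",
            "cis_flank_bp",
            "min_pav_len_bp",
            "te_diff_threshold_bp",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.window_size_bp <= 0:
            raise ParameterError("window_size_bp must be > 0")
        if not (0 < self.del_factor < 1 < self.dup_factor):
            raise ParameterError("require 0 < del_factor < 1 < dup_factor")
        if not (0 < self.fdr_alpha < 1):
            raise ParameterError("fdr_alpha must be in (0, 1)")
        if self.mutation_rate is not None and self.mutation_rate <= 0:
            raise ParameterError("mutation_rate must be > 0")

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
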