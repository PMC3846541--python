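"""Pipeline configuration and end-to-end wiring.

A :class:`PipelineConfig` gathers every tunable threshold with its
default; configs layer as defaults < config file < explicit overrides,
and unknown keys are rejected so a typo cannot silently fall back to a
default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .annotate import JunctionAnnotation, annotate_calls
from .detect import JunctionCall, detect_junctions
from .locus import LocusModel
from .simulate import CaptureConfig, ReadPair


class ConfigSchemaError(ValueError):
    """Unknown or ill-typed configuration key."""


@dataclass
class PipelineConfig:
    """All pipeline parameters with their defaults.

    Simulation: ``coverage`` fold over bait-covered bases, ``read_len``
    / ``insert_median`` read geometry, ``on_target_fraction`` realized
    capture specificity, ``error_rate`` per-base substitutions.
    Detection: ``min_support`` discordant pairs per cluster (a single
    split read rescues a cluster), ``min_interval_support`` pairs
    required when no split read is found, ``min_anchor`` matching bases
    per split-read half, ``aligner_k`` seed length, ``max_edits``
    alignment budget.  Annotation: ``min_coding_fraction`` truncation
    threshold, ``cryptic_window`` cryptic-heptamer search radius.
    Bait design: ``window_len`` per-RSS target window, ``bait_len``,
    ``tiling`` fold, ``symmetric_baits`` window placement.
    """

    seed: int = 0
    coverage: float = 50.0
    read_len: int = 100
    insert_median: int = 254
    on_target_fraction: float = 0.5
    error_rate: float = 0.001
    min_support: int = 2
    min_interval_support: int = 4
    min_anchor: int = 20
    aligner_k: int = 21
    max_edits: int = 5
    min_coding_fraction: float = 0.5
    cryptic_window: int = 50
    window_len: int = 200
    bait_len: int = 120
    tiling: int = 5
    symmetric_baits: bool = False
    sample_lineage: str | None = None

    @classmethod
    def from_sources(cls, config_file: str | Path | None = None, **overrides) -> "PipelineConfig":
        """Layer defaults < JSON config file < keyword overrides."""
        values: dict = {}
        if config_file is not None:
            with open(config_file) as fh:
                values.update(json.load(fh))
        values.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ConfigSchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**values)

    def capture_config(self, seed: int | None = None) -> CaptureConfig:
        return CaptureConfig(
            read_len=self.read_len,
            insert_median=self.insert_median,
            coverage=self.coverage,
            on_target_fraction=self.on_target_fraction,
            error_rate=self.error_rate,
            seed=self.seed if seed is None else seed,
        )

    def non_defaults(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if val != f.default:
                out[f.name] = val
        return out


def run_detection(
    model: LocusModel, pairs: list[ReadPair], cfg: PipelineConfig
) -> list[JunctionCall]:
    return detect_junctions(
        model,
        pairs=pairs,
        min_support=cfg.min_support,
        min_interval_support=cfg.min_interval_support,
        min_anchor=cfg.min_anchor,
        aligner_k=cfg.aligner_k,
        max_edits=cfg.max_edits,
    )


def run_annotation(
    calls: list[JunctionCall], model: LocusModel, cfg: PipelineConfig
) -> list[JunctionAnnotation]:
    return annotate_calls(
        calls, model, sample_lineage=cfg.sample_lineage,
        min_coding_fraction=cfg.min_coding_fraction,
    )
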