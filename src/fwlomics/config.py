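"""Single structured config file (YAML sections per pipeline stage)."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .cohort import CohortConfig
from .modeling import ExperimentConfig
from .radiomics.settings import ExtractionSettings
from .selection import SelectionConfig


@dataclasses.dataclass
class PipelineConfig:
    threshold: float = 0.3
    threshold_sweep: tuple[float, ...] = ()
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    extraction: ExtractionSettings = dataclasses.field(default_factory=ExtractionSettings)
    selection: SelectionConfig = dataclasses.field(default_factory=SelectionConfig)
    experiment: ExperimentConfig = dataclasses.field(default_factory=ExperimentConfig)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def _build(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in (data or {}).items():
        if k not in fields:
            raise KeyError(f"unknown {cls.__name__} key {k!r}")
        ftype = fields[k].type
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    exp_data = data.pop("experiment", {}) or {}
    exp_data.pop("selection", None)  # taken from the selection section
    sub = {
        "cohort": _build(CohortConfig, data.pop("cohort", {})),
        "extraction": _build(ExtractionSettings, data.pop("extraction", {})),
        "experiment": _build(ExperimentConfig, exp_data),
    }
    sel = _build(SelectionConfig, data.pop("selection", {}))
    exp = sub["experiment"]
    exp = dataclasses.replace(exp, selection=sel)
    if "threshold_sweep" in data and data["threshold_sweep"] is not None:
        data["threshold_sweep"] = tuple(data["threshold_sweep"])
    return PipelineConfig(
        cohort=sub["cohort"], extraction=sub["extraction"],
        selection=sel, experiment=exp, **data,
    )
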