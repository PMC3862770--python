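"""Analysis configuration (filter window, correction constant, thresholds)."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Knobs of the full pipeline, loadable from YAML/JSON.

    ``followup_window``: months; angiographic restenosis is time-related, so
    studies outside the window are excluded. ``continuity_constant`` is the
    Haldane-Anscombe constant added to all four cells of a zero-cell table.
    ``size_threshold``: total N at or above which a study counts as "large"
    in the study-size subgroup (the split is literature-dependent, hence
    user-settable). ``heterogeneity_alpha``: P(Q) significance level.
    """

    followup_window: tuple[float, float] = (3.0, 12.0)
    continuity_constant: float = 0.5
    size_threshold: int = 500
    heterogeneity_alpha: float = 0.10
    hwe_alpha: float = 0.05
    exclude_hwe_violations: bool = False
    subgroup_axes: tuple[str, ...] = ("ethnicity", "study_size")
    moderators: tuple[str, ...] = ("ethnicity", "size", "followup", "age", "pct_male")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, value in raw.items():
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["followup_window"] = list(self.followup_window)
        d["subgroup_axes"] = list(self.subgroup_axes)
        d["moderators"] = list(self.moderators)
        return d
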