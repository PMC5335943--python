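"""Run configuration: one object holding every pipeline knob.

A :class:`RunConfig` can be loaded from a TOML file and overridden by CLI
flags.  Loading validates internal consistency — in particular that the
decision window is exactly tiled by epochs (decisions_per_window x epoch
duration = window duration), which is what makes "ten decisions per 15 s"
hold under the defaults.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from ._errors import InvalidArgumentError
from .features import FRONTAL_CENTRAL_6
from .preprocessing import DEFAULT_BANDS, DEFAULT_EPOCH_LENGTH, Band

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    band_edges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {b.name: (b.low_hz, b.high_hz) for b in DEFAULT_BANDS}
    )
    epoch_length: int = DEFAULT_EPOCH_LENGTH
    sampling_rate: float = 128.0
    window_duration: float = 15.0
    decisions_per_window: int = 10
    feature_family: str = "hjorth14"
    channel_subset: tuple[str, ...] = FRONTAL_CENTRAL_6.channels
    method: str = "svm"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        epoch_duration = self.epoch_length / self.sampling_rate
        expected = self.decisions_per_window * epoch_duration
        if abs(expected - self.window_duration) > 1e-9:
            raise InvalidArgumentError(
                f"decisions_per_window ({self.decisions_per_window}) x epoch "
                f"duration ({epoch_duration} s) = {expected} s, which does not "
                f"equal window_duration ({self.window_duration} s)"
            )
        if self.feature_family not in ("filtered", "hjorth14", "hjorth6"):
            raise InvalidArgumentError(
                f"unknown feature family {self.feature_family!r}"
            )

    @property
    def bands(self) -> tuple[Band, ...]:
        return tuple(Band(name, lo, hi) for name, (lo, hi) in self.band_edges.items())


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional TOML file plus keyword overrides.

    CLI flags take precedence over file values, which take precedence over
    defaults.  Unknown keys in the file are rejected to catch typos.
    """
    values: dict = {}
    if path is not None:
        raw = tomllib.loads(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        if "band_edges" in raw:
            raw["band_edges"] = {
                k: tuple(v) for k, v in raw["band_edges"].items()
            }
        if "channel_subset" in raw:
            raw["channel_subset"] = tuple(raw["channel_subset"])
        values.update(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
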