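"""Run configuration: window/level, compartment threshold bands, outputs.

No universally valid numeric window/level/threshold values exist —
they depend on the scanner, sequence and display pipeline — so the
defaults here are calibrated to the synthetic phantom's 8-bit intensity
model (identity window, muscle band 50-149, fat band 150-255) and must
be set per acquisition protocol for real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from .errors import ConfigError, FormatError
from .imaging_io import DEFAULT_COLORS
from .preprocess import ThresholdRange, WindowLevel


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a quantification run."""

    window: float = 255.0
    level: float = 127.5
    threshold_muscle: tuple[int, int] = (50, 149)
    threshold_fat: tuple[int, int] = (150, 255)
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    min_component_size: int = 0  # 0/1 = no component filtering
    image_formats: tuple[str, ...] = ("png",)

    def window_level(self) -> WindowLevel:
        return WindowLevel(window=self.window, level=self.level)

    def threshold(self, compartment: str) -> ThresholdRange:
        """Band for a compartment tag: muscle for M, fat for S and V."""
        if compartment == "M":
            return ThresholdRange(*self.threshold_muscle)
        if compartment in ("S", "V"):
            return ThresholdRange(*self.threshold_fat)
        raise ConfigError(f"unknown compartment {compartment!r}")

    def provenance(self) -> dict:
        """Flat provenance fields recorded in every quantification CSV row."""
        return {
            "window": f"{self.window:g}",
            "level": f"{self.level:g}",
            "thr_muscle_low": str(self.threshold_muscle[0]),
            "thr_muscle_high": str(self.threshold_muscle[1]),
            "thr_fat_low": str(self.threshold_fat[0]),
            "thr_fat_high": str(self.threshold_fat[1]),
        }


def load_config(path) -> RunConfig:
    """Load a RunConfig from a JSON file; missing keys keep defaults.

    Recognized keys: window, level, threshold.muscle / threshold.fat
    (two-element [low, high] lists), colors (tag -> [r, g, b]),
    min_component_size, image_formats.
    """
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise FormatError(f"{path}: config must be a JSON object")

    kwargs = {}
    for key in ("window", "level"):
        if key in obj:
            kwargs[key] = float(obj[key])
    thresholds = obj.get("threshold", {})
    if "muscle" in thresholds:
        kwargs["threshold_muscle"] = tuple(int(v) for v in thresholds["muscle"])
    if "fat" in thresholds:
        kwargs["threshold_fat"] = tuple(int(v) for v in thresholds["fat"])
    if "colors" in obj:
        kwargs["colors"] = {tag: tuple(int(c) for c in rgb)
                            for tag, rgb in obj["colors"].items()}
    if "min_component_size" in obj:
        kwargs["min_component_size"] = int(obj["min_component_size"])
    if "image_formats" in obj:
        kwargs["image_formats"] = tuple(str(f) for f in obj["image_formats"])
    try:
        cfg = RunConfig(**kwargs)
        cfg.window_level()  # validate
        cfg.threshold("M")
        cfg.threshold("S")
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: invalid config: {exc}") from exc
    return cfg
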