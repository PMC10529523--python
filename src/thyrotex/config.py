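"""Run configuration shared across the pipeline stages.

All the constants that govern a run live here: the patch footprint
(20 x 20 px, i.e. 5.296 x 5.296 mm at the default probe calibration of
0.2648 mm/px), the autoregressive model order, the frequency-band edges
used by the signal decomposition, the random-forest size, and the
composition-category breakpoints used by the observer statistics.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

#: Default pixel spacing, mm per pixel (20 px patch <-> 5.296 mm footprint).
DEFAULT_PIXEL_SPACING_MM = 5.296 / 20.0

#: Band edges in cycles/sample: low [0, .05], mid (.05, .20], high (.20, .50].
DEFAULT_BAND_EDGES = (0.05, 0.20)


@dataclasses.dataclass
class RunConfig:
    """Validated bag of pipeline parameters with documented defaults."""

    patch_size_px: int = 20
    stride_px: int = 10
    min_inside_fraction: float = 0.8
    ar_order: int = 2
    band_edges: tuple[float, float] = DEFAULT_BAND_EDGES
    rf_trees: int = 200
    composition_breakpoints: tuple[float, ...] = (10.0, 50.0, 90.0)
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size_px < 2:
            raise ValueError("patch_size_px must be >= 2")
        if self.stride_px < 1:
            raise ValueError("stride_px must be >= 1")
        if not 0.0 <= self.min_inside_fraction <= 1.0:
            raise ValueError("min_inside_fraction must lie in [0, 1]")
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")
        lo, hi = self.band_edges
        if not 0.0 < lo < hi < 0.5:
            raise ValueError("band_edges must satisfy 0 < low < high < 0.5")
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be >= 1")
        bp = tuple(float(b) for b in self.composition_breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])) or not bp:
            raise ValueError("composition_breakpoints must be strictly increasing")
        if not all(0.0 < b < 100.0 for b in bp):
            raise ValueError("composition_breakpoints must lie in (0, 100)")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")

    @property
    def n_features(self) -> int:
        """Features per patch: 4 signals x 3 bands x (order + 1)."""
        return 4 * 3 * (self.ar_order + 1)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_edges"] = list(self.band_edges)
        d["composition_breakpoints"] = list(self.composition_breakpoints)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "band_edges" in kwargs:
            kwargs["band_edges"] = tuple(kwargs["band_edges"])
        if "composition_breakpoints" in kwargs:
            kwargs["composition_breakpoints"] = tuple(kwargs["composition_breakpoints"])
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
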