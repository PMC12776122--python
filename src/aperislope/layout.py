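"""Scalp channel layout: labels, schematic 2-D positions, and region maps.

The layout mirrors a 64-channel BioSemi-style extended 10-20 montage with the
eight frontal-pole sites (Fp1, Fp2, AF3, AF4, AF7, AF8, AFz, Fpz) removed,
leaving the 56 scalp channels the analysis operates on.  Positions are
schematic head coordinates (x: left negative / right positive, y: posterior
negative / anterior positive, unit head radius), sufficient for region
assignment and Gaussian scalp weight maps; they are not digitized electrode
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BIOSEMI64 = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]

FRONTAL_POLE = ["Fp1", "Fp2", "AF3", "AF4", "AF7", "AF8", "AFz", "Fpz"]

# anterior-posterior coordinate per electrode row
_ROW_Y = {
    "Fp": 0.95, "AF": 0.78, "F": 0.58, "FT": 0.38, "FC": 0.36, "C": 0.12,
    "T": 0.12, "TP": -0.12, "CP": -0.14, "P": -0.40, "PO": -0.64, "O": -0.82,
    "I": -0.95,
}

# lateral coordinate magnitude per electrode number (odd = left, even = right)
_NUM_X = {0: 0.0, 1: 0.16, 2: 0.16, 3: 0.34, 4: 0.34, 5: 0.52, 6: 0.52,
          7: 0.72, 8: 0.72, 9: 0.88, 10: 0.88}

_TEMPORAL_LEFT = {"FT7", "T7", "TP7", "P9"}
_TEMPORAL_RIGHT = {"FT8", "T8", "TP8", "P10"}

REGIONS = ("frontal", "central", "occipital", "left-temporal", "right-temporal")

REGION_CENTERS = {
    "frontal": (0.0, 0.58),
    "central": (0.0, 0.0),
    "occipital": (0.0, -0.60),
    "left-temporal": (-0.80, 0.05),
    "right-temporal": (0.80, 0.05),
}


def _split(label: str) -> tuple[str, int]:
    row = label.rstrip("z0123456789")
    rest = label[len(row):]
    num = 0 if rest in ("z", "") else int(rest)
    return row, num


def _position(label: str) -> tuple[float, float]:
    row, num = _split(label)
    y = _ROW_Y[row]
    x = _NUM_X[num]
    if num % 2 == 1 or num == 9:
        x = -abs(x)
    if num == 10:
        x = abs(_NUM_X[10])
    # T7/T8 sit further out than C5/C6
    if row == "T":
        x = -0.92 if num == 7 else 0.92
    return x, y


def _region(label: str) -> str:
    if label in _TEMPORAL_LEFT:
        return "left-temporal"
    if label in _TEMPORAL_RIGHT:
        return "right-temporal"
    row, _ = _split(label)
    if row in ("Fp", "AF", "F"):
        return "frontal"
    if row in ("FC", "C", "CP"):
        return "central"
    return "occipital"  # P, PO, O, I rows


@dataclass
class ChannelLayout:
    """Channel labels with schematic positions and scalp-region membership."""

    labels: list[str]
    positions: np.ndarray  # (n_channels, 2)
    regions: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 2):
            raise ValueError("positions must be (n_channels, 2)")
        missing = {r for r in ("frontal", "central", "occipital")} - set(
            self.regions.values()
        )
        if missing:
            raise ValueError(
                f"channel layout missing required scalp groups: {sorted(missing)}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def region_of(self, label: str) -> str:
        return self.regions[label]

    def region_members(self, region: str) -> list[str]:
        return [ch for ch in self.labels if self.regions[ch] == region]

    def gaussian_weights(self, region: str, sigma: float = 0.45) -> np.ndarray:
        """Gaussian scalp weight map centred on a region's schematic centre."""
        cx, cy = REGION_CENTERS[region]
        d2 = (self.positions[:, 0] - cx) ** 2 + (self.positions[:, 1] - cy) ** 2
        return np.exp(-d2 / (2.0 * sigma**2))


def default_layout() -> ChannelLayout:
    """The 56-channel layout used throughout: BioSemi-64 minus frontal poles."""
    labels = [ch for ch in BIOSEMI64 if ch not in FRONTAL_POLE]
    positions = np.array([_position(ch) for ch in labels])
    regions = {ch: _region(ch) for ch in labels}
    return ChannelLayout(labels=labels, positions=positions, regions=regions)
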