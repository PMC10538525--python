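"""Shared domain records: trait vectors and pouch images."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

#: Canonical column order for trait tables (7 morphological + 5 architectural).
TRAIT_NAMES = (
    "TRL", "TSA", "DIM", "TRV", "TRT", "TSA1", "TSA3",
    "TRW", "TCA", "RDI", "SOL", "COPM",
)


@dataclass
class TraitRecord:
    """One plant's root traits.

    Units: lengths cm, areas cm^2, volume cm^3, diameter mm, counts
    dimensionless, RDI and SOL ratios in [0, 1].
    """

    TRL: float = 0.0   # total root length (cm)
    TSA: float = 0.0   # total root surface area (cm^2)
    DIM: float = 0.0   # length-weighted mean root diameter (mm)
    TRV: float = 0.0   # total root volume (cm^3)
    TRT: int = 0       # total number of root tips
    TSA1: float = 0.0  # surface area of roots with diameter in [0, 0.5) mm
    TSA3: float = 0.0  # surface area of roots with diameter in [1.0, 1.5) mm
    TRW: float = 0.0   # total root-system width (cm)
    TCA: float = 0.0   # convex area of the projected root system (cm^2)
    RDI: float = 0.0   # fraction of surface area in the lower two-thirds of depth
    SOL: float = 0.0   # solidity: projected root area / convex area
    COPM: float = 0.0  # vertical centroid offset from the root-shoot junction (cm)

    def to_dict(self) -> dict:
        return {k: asdict(self)[k] for k in TRAIT_NAMES}

    def validate(self) -> None:
        """Raise ValueError if any trait invariant is violated."""
        d = self.to_dict()
        for name, v in d.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if not (0.0 <= self.RDI <= 1.0):
            raise ValueError(f"RDI must be in [0,1], got {self.RDI}")
        if not (0.0 < self.SOL <= 1.0 + 1e-9):
            raise ValueError(f"SOL must be in (0,1], got {self.SOL}")
        if self.TSA1 + self.TSA3 > self.TSA * (1 + 1e-9):
            raise ValueError("TSA1 + TSA3 exceeds TSA")


@dataclass
class PouchImage:
    """An RGB pouch photograph plus its physical pixel scale."""

    pixels: np.ndarray           # H x W x 3, uint8
    pixels_per_cm: float
    id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if self.pixels_per_cm <= 0:
            raise ValueError("pixels_per_cm must be positive")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[:2]
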