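"""Unit-cell geometry of mineralized collagen.

The model subdivides a unit volume of cortical bone into four compartments
seen in projection through a thin (~100 nm) longitudinal section:

* ``G`` -- the gap zone of a collagen fibril (can host mineral),
* ``O`` -- the overlap zone (modelled as mineral-free),
* ``V`` -- the stack of plate-like mineral structures standing vertically
  between adjacent fibrils,
* ``H`` -- the mineral structures lying horizontally over and under the
  fibril, spanning the whole unit cell.

Projected areas of these compartments weight the background-corrected EDXS
count rates in :mod:`extrafib.partition` to estimate the fraction of mineral
external to the fibrils.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import pandas as pd
import yaml

from .errors import InvalidGeometryError, UndefinedFractionError

__all__ = [
    "UnitCellGeometry",
    "ProjectedAreas",
    "compute_projected_areas",
    "mass_balance_bound",
    "plates_per_interfibril_span",
]


@dataclass(frozen=True)
class UnitCellGeometry:
    """Dimensions (nm) of the unit cell of mineralized collagen.

    Defaults describe human cortical bone: 50 nm-wide fibrils with a
    40 nm gap / 27 nm overlap banding (D-period 67 nm), 27 nm-wide stacks
    of 5 x 65 x 200 nm mineral plates between fibrils, in a 100 nm-thick
    section.
    """

    fibril_width: float = 50.0
    gap_length: float = 40.0
    overlap_length: float = 27.0
    stack_width: float = 27.0
    plate_thickness: float = 5.0
    plate_width: float = 65.0
    plate_length: float = 200.0
    section_thickness: float = 100.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name == "stack_width":
                if value < 0:
                    raise InvalidGeometryError(f"{name} must be >= 0, got {value}")
            elif value <= 0:
                raise InvalidGeometryError(f"{name} must be > 0, got {value}")

    @property
    def d_period(self) -> float:
        """Axial repeat of the gap + overlap banding (nm)."""
        return self.gap_length + self.overlap_length

    def replace(self, **changes) -> "UnitCellGeometry":
        return replace(self, **changes)

    # -- flat key: value config --------------------------------------------

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "UnitCellGeometry":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class ProjectedAreas:
    """Projected areas (nm^2) of the unit-cell compartments."""

    A_G: float
    A_O: float
    A_V: float
    A_H: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compartment": ["G", "O", "V", "H"],
                "area_nm2": [self.A_G, self.A_O, self.A_V, self.A_H],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_projected_areas(
    geom: UnitCellGeometry, round_to: float | None = None
) -> ProjectedAreas:
    """Projected compartment areas of the unit cell.

    ``A_G``/``A_O`` are the fibril-width slices of the gap and overlap
    zones, ``A_V`` the inter-fibril stack footprint over one D-period, and
    ``A_H`` the whole unit-cell area covered by the over/underlying plates.

    Parameters
    ----------
    geom
        Validated unit-cell geometry.
    round_to
        If given, round each area to this granularity in nm^2 (display
        convention used when matching figures quoted to the nearest 10).
        Internally areas are always computed unrounded.
    """
    d = geom.d_period
    areas = ProjectedAreas(
        A_G=geom.fibril_width * geom.gap_length,
        A_O=geom.fibril_width * geom.overlap_length,
        A_V=geom.stack_width * d,
        A_H=(geom.fibril_width + geom.stack_width) * d,
    )
    if round_to is not None:
        if round_to <= 0:
            raise ValueError("round_to must be positive")
        areas = ProjectedAreas(
            *(round(a / round_to) * round_to for a in (areas.A_G, areas.A_O, areas.A_V, areas.A_H))
        )
    return areas


def mass_balance_bound(
    mineral_vol_frac_of_bone: float,
    gap_vol_frac_of_fibrils: float,
    fibril_vol_frac_of_bone: float = 1.0,
) -> dict[str, float]:
    """Lower bound on the mineral fraction that cannot fit in gap zones.

    Mineral occupies ``mineral_vol_frac_of_bone`` of bone while the gap
    zones can hold at most ``gap_vol_frac_of_fibrils x
    fibril_vol_frac_of_bone`` of bone volume; whatever exceeds that
    capacity must reside outside the gap zones.

    Returns a dict with ``min_external_fraction`` (fraction of the mineral
    forced outside gap zones) and ``extragap_vol_frac_of_bone`` (that same
    mineral as a volume fraction of bone).
    """
    for name, v in (
        ("mineral_vol_frac_of_bone", mineral_vol_frac_of_bone),
        ("gap_vol_frac_of_fibrils", gap_vol_frac_of_fibrils),
        ("fibril_vol_frac_of_bone", fibril_vol_frac_of_bone),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if mineral_vol_frac_of_bone == 0:
        raise UndefinedFractionError("mineral volume fraction is zero")
    gap_capacity = gap_vol_frac_of_fibrils * fibril_vol_frac_of_bone
    extragap = max(0.0, mineral_vol_frac_of_bone - gap_capacity)
    return {
        "min_external_fraction": extragap / mineral_vol_frac_of_bone,
        "extragap_vol_frac_of_bone": extragap,
    }


def plates_per_interfibril_span(
    interfibril_distance: float,
    plate_thickness: float,
    plate_spacing: float = 1.5,
) -> int:
    """Number of plate (+ spacing) periods fitting between adjacent fibrils.

    Returns ``floor(distance / (thickness + spacing))``, but at least 1
    whenever the distance can accommodate a single plate.  A distance
    smaller than one plate thickness returns 0 with a warning.
    """
    if interfibril_distance <= 0 or plate_thickness <= 0:
        raise ValueError("distance and plate thickness must be positive")
    if plate_spacing < 0:
        raise ValueError("plate spacing must be >= 0")
    if interfibril_distance < plate_thickness:
        warnings.warn(
            "inter-fibril distance is smaller than one plate thickness; "
            "no plate fits",
            stacklevel=2,
        )
        return 0
    n = math.floor(interfibril_distance / (plate_thickness + plate_spacing))
    return max(n, 1)
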