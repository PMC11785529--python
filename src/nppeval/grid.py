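"""Grid and biome containers shared by every pipeline stage.

A :class:`GridSpec` describes a regular latitude/longitude grid with an
annual time axis and a land mask.  A :class:`BiomeMask` labels every ocean
cell with a small-integer biome id and records each biome's areal
proportion of the global ocean, which downstream distance averaging uses
as weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["GridSpec", "BiomeMask"]


@dataclass(frozen=True)
class GridSpec:
    """A regular lat/lon grid with an annual time axis.

    Parameters
    ----------
    lat : array of float
        Cell-centre latitudes, degrees north, strictly inside (-90, 90),
        strictly monotone increasing.
    lon : array of float
        Cell-centre longitudes, degrees east.
    years : array of int
        Consecutive calendar years (at least two).
    land_mask : bool array, shape (lat, lon)
        True where the cell is land.  At least one cell must be ocean.
    """

    lat: np.ndarray
    lon: np.ndarray
    years: np.ndarray
    land_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        years = np.asarray(self.years, dtype=int)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        object.__setattr__(self, "years", years)
        if lat.ndim != 1 or lon.ndim != 1:
            raise ValidationError("lat and lon must be 1-D")
        if np.any(np.abs(lat) >= 90.0):
            raise ValidationError("latitudes must lie strictly inside (-90, 90)")
        if np.any(np.diff(lat) <= 0):
            raise ValidationError("latitudes must be strictly increasing")
        if years.size < 2:
            raise ValidationError("need at least two years")
        if np.any(np.diff(years) != 1):
            raise ValidationError("years must be consecutive integers")
        if self.land_mask is None:
            object.__setattr__(
                self, "land_mask", np.zeros((lat.size, lon.size), dtype=bool)
            )
        else:
            mask = np.asarray(self.land_mask, dtype=bool)
            if mask.shape != (lat.size, lon.size):
                raise ValidationError(
                    f"land_mask shape {mask.shape} != {(lat.size, lon.size)}"
                )
            object.__setattr__(self, "land_mask", mask)
        if not np.any(self.ocean_mask):
            raise ValidationError("grid has no ocean cells")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    @property
    def ocean_mask(self) -> np.ndarray:
        return ~self.land_mask

    @classmethod
    def regular(
        cls,
        n_lat: int = 18,
        n_lon: int = 36,
        year_start: int = 1998,
        n_years: int = 26,
        lat_extent: float = 80.0,
        land_mask: np.ndarray | None = None,
    ) -> "GridSpec":
        """Equally spaced cell centres spanning ±``lat_extent`` and the globe in
        longitude; the default 36x18 x 26-year grid is the package's desk-scale
        stand-in for a 1-degree satellite-era grid."""
        lat = np.linspace(-lat_extent, lat_extent, n_lat)
        lon = np.linspace(-180.0, 180.0, n_lon, endpoint=False)
        years = np.arange(year_start, year_start + n_years)
        return cls(lat=lat, lon=lon, years=years, land_mask=land_mask)


@dataclass(frozen=True)
class BiomeMask:
    """Integer biome labels over ocean cells plus areal proportions.

    ``labels`` is -1 on land; ``proportions[label]`` is that biome's
    fraction of global ocean area and the proportions sum to one.
    """

    labels: np.ndarray
    proportions: dict[int, float]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"biome proportions sum to {total}, not 1")
        ocean_labels = labels[labels >= 0]
        if not set(np.unique(ocean_labels)) <= set(self.proportions):
            raise ValidationError("every ocean cell must carry a known biome label")

    @property
    def biome_ids(self) -> list[int]:
        return sorted(self.proportions)
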