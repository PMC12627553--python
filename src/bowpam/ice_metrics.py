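"""Sea-ice covariates around a passive-acoustic recorder.

Two quantities are derived per daily concentration grid: the mean sea-ice
concentration within a fixed radius of the recorder, and the signed shortest
distance from the recorder to the ice edge.  "Ice" is any cell with
concentration >= 15 %; the edge distance is measured to the nearest cell of
the class opposite the recorder's own, after removing small isolated patches
(<= 50 cells) of either class.  The sign is negative when the recorder sits
inside the ice and positive when it sits in open water.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from skimage.measure import label as _cc_label

#: Grid cell edge length of the source concentration product, km.
DEFAULT_CELL_KM = 3.125
#: Concentration (%) at and above which a cell counts as sea ice.
ICE_THRESHOLD_PCT = 15.0
#: Connected patches of this many cells or fewer are ignored as edge targets.
MAX_PATCH_CELLS = 50
#: Averaging radius for mean concentration, km.
CONCENTRATION_RADIUS_KM = 35.0
#: Spherical Earth radius used for geolocated grids, km.
EARTH_RADIUS_KM = 6371.0


@dataclass
class IceField:
    """Gridded sea-ice concentration plus the recorder location.

    ``concentration`` is a 2-D array in percent [0, 100]; NaN marks missing
    cells.  Synthetic fields are planar: cell centers sit on a regular grid
    with spacing ``cell_size_km`` and distances are Euclidean.  Geolocated
    fields carry per-cell ``lat``/``lon`` arrays and use great-circle
    distances instead.
    """

    concentration: np.ndarray
    cell_size_km: float = DEFAULT_CELL_KM
    recorder_row: int = 0
    recorder_col: int = 0
    lat: Optional[np.ndarray] = None
    lon: Optional[np.ndarray] = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.concentration.ndim != 2:
            raise ValueError("concentration must be a 2-D grid")
        r, c = self.recorder_row, self.recorder_col
        n_rows, n_cols = self.concentration.shape
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValueError("recorder cell outside grid")
        finite = self.concentration[np.isfinite(self.concentration)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("concentrations must lie in [0, 100] %")
        if (self.lat is None) != (self.lon is None):
            raise ValueError("lat and lon must be given together")

    @property
    def geolocated(self) -> bool:
        return self.lat is not None

    def cell_distances_km(self) -> np.ndarray:
        """Distance from the recorder's cell center to every cell center."""
        if self.geolocated:
            return _haversine_km(
                self.lat[self.recorder_row, self.recorder_col],
                self.lon[self.recorder_row, self.recorder_col],
                self.lat, self.lon,
            )
        rows, cols = np.indices(self.concentration.shape)
        dy = (rows - self.recorder_row) * self.cell_size_km
        dx = (cols - self.recorder_col) * self.cell_size_km
        return np.hypot(dy, dx)

    # -- plain-text persistence (grid + JSON sidecar) --------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.concentration, fmt="%.4f", delimiter=",")
        sidecar = {
            "cell_size_km": self.cell_size_km,
            "recorder_row": int(self.recorder_row),
            "recorder_col": int(self.recorder_col),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "IceField":
        path = Path(path)
        conc = np.loadtxt(path, delimiter=",", ndmin=2)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(concentration=conc, cell_size_km=meta["cell_size_km"],
                   recorder_row=meta["recorder_row"],
                   recorder_col=meta["recorder_col"])


@dataclass(frozen=True)
class EdgeDistance:
    """Signed shortest distance to the ice edge, km.

    ``defined`` is False when no opposite-class cell survives patch
    filtering (e.g. a fully ice-free or fully ice-covered grid).
    """

    value_km: float
    defined: bool
    recorder_in_ice: Optional[bool] = None


@dataclass(frozen=True)
class FilteredMask:
    """Ice/water classification with small patches marked ineligible."""

    ice_mask: np.ndarray          # bool: concentration >= threshold
    valid: np.ndarray             # bool: non-missing cells
    small_patch: np.ndarray       # bool: member of a component <= max_patch
    ice_candidates: np.ndarray    # ice cells eligible as distance targets
    water_candidates: np.ndarray  # water cells eligible as distance targets


def _haversine_km(lat0, lon0, lat, lon) -> np.ndarray:
    lat0, lon0 = np.radians(lat0), np.radians(lon0)
    lat, lon = np.radians(np.asarray(lat, float)), np.radians(np.asarray(lon, float))
    a = (np.sin((lat - lat0) / 2) ** 2
         + np.cos(lat0) * np.cos(lat) * np.sin((lon - lon0) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def patch_area_km2(n_cells: int, cell_size_km: float = DEFAULT_CELL_KM) -> float:
    """Area of an ``n_cells``-cell patch (50 cells -> 488.28 km^2)."""
    return n_cells * cell_size_km ** 2


def mean_concentration(ice_field: IceField,
                       radius_km: float = CONCENTRATION_RADIUS_KM) -> float:
    """Unweighted mean concentration over cells whose centers lie within
    ``radius_km`` of the recorder.  Missing cells are excluded; NaN is
    returned when no valid cell center falls inside the radius."""
    dist = ice_field.cell_distances_km()
    sel = (dist <= radius_km) & np.isfinite(ice_field.concentration)
    if not sel.any():
        return float("nan")
    return float(ice_field.concentration[sel].mean())


def classify_and_filter(ice_field: IceField,
                        ice_threshold: float = ICE_THRESHOLD_PCT,
                        max_patch: int = MAX_PATCH_CELLS) -> FilteredMask:
    """Classify cells as ice (>= threshold) or water and mark small patches.

    Connected components (4-connectivity) of both classes are measured on
    the original classification in a single pass; components of at most
    ``max_patch`` cells are flagged and excluded from distance candidacy.
    """
    conc = ice_field.concentration
    valid = np.isfinite(conc)
    ice = np.zeros_like(valid)
    ice[valid] = conc[valid] >= ice_threshold
    water = valid & ~ice

    small = np.zeros_like(valid)
    for mask in (ice, water):
        labels = _cc_label(mask, connectivity=1)
        if labels.max() == 0:
            continue
        sizes = np.bincount(labels.ravel())
        small_ids = np.flatnonzero(sizes[1:] <= max_patch) + 1
        small |= np.isin(labels, small_ids)

    return FilteredMask(
        ice_mask=ice,
        valid=valid,
        small_patch=small,
        ice_candidates=ice & ~small,
        water_candidates=water & ~small,
    )


def edge_distance(ice_field: IceField,
                  filtered: Optional[FilteredMask] = None,
                  ice_threshold: float = ICE_THRESHOLD_PCT,
                  max_patch: int = MAX_PATCH_CELLS) -> EdgeDistance:
    """Signed shortest recorder-to-edge distance.

    The magnitude is the minimum distance from the recorder's cell center to
    the center of any non-excluded cell of the opposite class; the sign is
    negative when the recorder's own cell is ice.  Undefined (not an error)
    when the recorder cell is missing or no opposite-class cell survives
    filtering.
    """
    if filtered is None:
        filtered = classify_and_filter(ice_field, ice_threshold, max_patch)
    r, c = ice_field.recorder_row, ice_field.recorder_col
    if not filtered.valid[r, c]:
        return EdgeDistance(float("nan"), defined=False)
    in_ice = bool(filtered.ice_mask[r, c])
    targets = filtered.water_candidates if in_ice else filtered.ice_candidates
    if not targets.any():
        return EdgeDistance(float("nan"), defined=False, recorder_in_ice=in_ice)
    dist = ice_field.cell_distances_km()
    magnitude = float(dist[targets].min())
    sign = -1.0 if in_ice else 1.0
    return EdgeDistance(sign * magnitude, defined=True, recorder_in_ice=in_ice)


def ice_covariates(fields_by_date: dict,
                   radius_km: float = CONCENTRATION_RADIUS_KM,
                   ice_threshold: float = ICE_THRESHOLD_PCT,
                   max_patch: int = MAX_PATCH_CELLS):
    """Per-day covariate table: mean concentration and signed edge distance.

    ``fields_by_date`` maps a date (or date-like key) to an :class:`IceField`.
    Returns a pandas DataFrame with columns
    ``date, mean_concentration_pct, edge_distance_km, defined``.
    """
    import pandas as pd

    rows = []
    for date in sorted(fields_by_date):
        fld = fields_by_date[date]
        ed = edge_distance(fld, ice_threshold=ice_threshold, max_patch=max_patch)
        rows.append({
            "date": date,
            "mean_concentration_pct": mean_concentration(fld, radius_km),
            "edge_distance_km": ed.value_km,
            "defined": ed.defined,
        })
    return pd.DataFrame(rows, columns=["date", "mean_concentration_pct",
                                       "edge_distance_km", "defined"])
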