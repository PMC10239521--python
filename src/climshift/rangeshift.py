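"""Species range-shift velocities and colonisation-route direction inference.

Northward range-shift velocity for a species and period is the northward
distance between the centroids of its northernmost occupied provinces at the
period's start and end, divided by the period length in years, floored at
zero (cumulative occupancy cannot retreat).  Colonisation direction is
inferred per colonisation event as the vector from the centroid of the
closest already-occupied province (the shortest colonisation route) to the
newly occupied province; provinces then average the bearings of the events
they received, one mean direction per province and period.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .circular import circular_mean
from .geo import GeoPoint, HexGrid, ProvinceMap, northward_eastward_components, vector_from_points
from .occupancy import OccupancyCube

logger = logging.getLogger(__name__)

__all__ = [
    "northward_velocity",
    "infer_colonisation_vectors",
    "province_mean_shift_direction",
    "velocity_correlation_by_period",
]


def _northernmost(occ_row: np.ndarray, lats: np.ndarray, province_ids: list[str]) -> int:
    """Index of the occupied province with maximal centroid latitude
    (ties broken by smallest province id)."""
    occ = np.nonzero(occ_row)[0]
    best = occ[np.argmax(lats[occ])]
    ties = occ[lats[occ] == lats[best]]
    if len(ties) > 1:
        best = min(ties, key=lambda i: province_ids[i])
    return int(best)


def northward_velocity(cube: OccupancyCube, pmap: ProvinceMap) -> pd.DataFrame:
    """Northward range-shift velocity (km/yr) per species and period.

    A species enters the analysis for a period only once it is present in the
    study area at the period start, so sample sizes grow over time as new
    species arrive.
    """
    cents = [pmap.centroid(p) for p in cube.province_ids]
    lats = np.array([c.lat for c in cents])
    eff = cube.effective_presence()
    tp = cube.time_points
    rows = []
    for s, sp in enumerate(cube.species_ids):
        for j in range(len(tp) - 1):
            if not eff[s, :, j].any() or not eff[s, :, j + 1].any():
                continue
            i0 = _northernmost(eff[s, :, j], lats, cube.province_ids)
            i1 = _northernmost(eff[s, :, j + 1], lats, cube.province_ids)
            north_km, _ = northward_eastward_components(cents[i0], cents[i1])
            years = int(tp[j + 1] - tp[j])
            rows.append(
                {
                    "species_id": sp,
                    "start": int(tp[j]),
                    "end": int(tp[j + 1]),
                    "velocity_km_per_yr": max(0.0, north_km) / years,
                    "origin_lat": cents[i0].lat,
                    "origin_lon": cents[i0].lon,
                }
            )
    return pd.DataFrame(rows)


def infer_colonisation_vectors(cube: OccupancyCube, pmap: ProvinceMap) -> pd.DataFrame:
    """Shortest-colonisation-route vector for every colonisation event.

    Source candidates are the provinces the species occupied at the period
    start; a species debuting within the period instead draws candidates from
    its period-end range excluding the focal province.  The source is the
    candidate whose centroid is closest to the colonised province's centroid
    (ties by smallest province id).  Events with no possible source (a
    single-province debut) are skipped and logged.
    """
    cents = {p: pmap.centroid(p) for p in cube.province_ids}
    eff = cube.effective_presence()
    first = cube.first_record_index()
    tp = cube.time_points
    rows = []
    for s, sp in enumerate(cube.species_ids):
        for j in range(1, len(tp)):
            new_idx = np.nonzero(first[s] == j)[0]
            if len(new_idx) == 0:
                continue
            start_occ = np.nonzero(eff[s, :, j - 1])[0]
            for pi in new_idx:
                focal = cube.province_ids[pi]
                if len(start_occ):
                    candidates = [cube.province_ids[i] for i in start_occ]
                else:
                    candidates = [
                        cube.province_ids[i]
                        for i in np.nonzero(eff[s, :, j])[0]
                        if i != pi
                    ]
                if not candidates:
                    logger.info(
                        "species %s: single-province debut in %s at %d; no route inferable",
                        sp, focal, tp[j],
                    )
                    continue
                target = cents[focal]

                def _dist(pid: str) -> float:
                    n, e = northward_eastward_components(cents[pid], target)
                    return float(np.hypot(n, e))

                source = min(candidates, key=lambda pid: (_dist(pid), pid))
                vec = vector_from_points(cents[source], target, (int(tp[j - 1]), int(tp[j])))
                rows.append(
                    {
                        "species_id": sp,
                        "province_id": focal,
                        "source_province_id": source,
                        "start": int(tp[j - 1]),
                        "end": int(tp[j]),
                        "east_km": vec.east_km,
                        "north_km": vec.north_km,
                        "magnitude_km": vec.magnitude_km,
                        "direction_deg": vec.direction_deg,
                    }
                )
    return pd.DataFrame(rows)


def province_mean_shift_direction(vectors: pd.DataFrame) -> pd.DataFrame:
    """Circular mean colonisation bearing per (colonised province, period).

    Provinces that received no colonisations in a period are absent, so the
    number of direction estimates varies between periods.  Undefined means
    (cancelled resultants or zero-length vectors only) come back NaN.
    """
    rows = []
    for (pid, t0, t1), sub in vectors.groupby(["province_id", "start", "end"], sort=True):
        dirs = sub.loc[sub["magnitude_km"] > 0, "direction_deg"].to_numpy()
        if len(dirs) == 0:
            mean_dir, rbar = float("nan"), 0.0
        else:
            mean_dir, rbar = circular_mean(dirs)
        rows.append(
            {
                "province_id": pid,
                "start": int(t0),
                "end": int(t1),
                "mean_direction_deg": mean_dir,
                "resultant_length": rbar,
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows)


def velocity_correlation_by_period(
    range_vel: pd.DataFrame, cell_vectors: pd.DataFrame, grid: HexGrid
) -> pd.DataFrame:
    """Pearson correlation between species and temperature northward velocities.

    Each species-period range-shift record is paired with the temperature
    velocity of the hexagon containing its origin (the species' northernmost
    province centroid at the period start).  Correlations are reported per
    period and pooled; records with no matching temperature vector are
    dropped and counted.
    """
    cv = cell_vectors.copy()
    cv["temp_velocity"] = cv["north_km"] / (cv["end"] - cv["start"])
    lookup = {(int(r.cell_id), int(r.start), int(r.end)): r.temp_velocity
              for r in cv.itertuples(index=False)}

    paired = []
    n_dropped = 0
    for r in range_vel.itertuples(index=False):
        cell = grid.cell_containing(GeoPoint(r.origin_lat, r.origin_lon))
        key = (int(cell), int(r.start), int(r.end))
        if cell is None or key not in lookup:
            n_dropped += 1
            continue
        paired.append(
            {"start": int(r.start), "end": int(r.end),
             "species_v": r.velocity_km_per_yr, "temp_v": lookup[key]}
        )
    dfp = pd.DataFrame(paired)

    def _corr(sub: pd.DataFrame, label: str) -> dict:
        x = sub["temp_v"].to_numpy()
        y = sub["species_v"].to_numpy()
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            r_val, p_val = float("nan"), float("nan")
        else:
            r_val, p_val = stats.pearsonr(x, y)
        return {"period": label, "r": float(r_val), "p": float(p_val),
                "n": len(sub), "n_dropped": n_dropped}

    rows = [
        _corr(sub, f"{t0}-{t1}")
        for (t0, t1), sub in dfp.groupby(["start", "end"], sort=True)
    ]
    rows.append(_corr(dfp, "pooled"))
    return pd.DataFrame(rows)
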