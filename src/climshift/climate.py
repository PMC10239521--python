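"""Temperature aggregation and nearest-thermal-analogue climate velocity.

Annual gridded temperatures are averaged into decadal time-point means on the
equal-area hexagon grid, then the analogue algorithm turns consecutive
time-point fields into one shift vector per hexagon: for each start cell the
``k_temp`` cells closest in temperature at the later time point are selected,
of those the ``k_dist`` geographically closest, and the displacement vectors
to them are averaged componentwise.  The start cell is itself an eligible
analogue, so an unchanged field yields near-zero velocity.  Province-level
velocity is the mean northward component of member-cell vectors per year;
province direction is the circular mean of member-vector bearings.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .circular import circular_mean
from .geo import EARTH_RADIUS_KM, GeoPoint, HexGrid, ProvinceMap, compass_from_components

__all__ = [
    "timepoint_means",
    "province_mean_temperature",
    "province_temperature_change",
    "analogue_shift_vectors",
    "analogue_shift_vectors_all_periods",
    "province_temperature_velocity",
]


def timepoint_means(temps: pd.DataFrame, time_points) -> pd.DataFrame:
    """Average annual cell temperatures into per-time-point means.

    The first time point uses the decade starting the year before it (1901 ->
    1900-1909); every later time point t uses the last ten years of its
    period, [t-9, t].  Missing years raise an error naming them.
    """
    tps = sorted(int(t) for t in time_points)
    have = set(temps["year"].unique().tolist())
    rows = []
    for i, t in enumerate(tps):
        years = range(t - 1, t + 9) if i == 0 else range(t - 9, t + 1)
        missing = sorted(set(years) - have)
        if missing:
            raise ValueError(f"temperature series lacks years {missing} for time point {t}")
        sub = temps[temps["year"].isin(list(years))]
        m = sub.groupby("cell_id", sort=True)["temp_c"].mean()
        rows.append(pd.DataFrame({"cell_id": m.index, "time_point": t, "mean_temp_c": m.values}))
    return pd.concat(rows, ignore_index=True)


def province_mean_temperature(
    htt: pd.DataFrame, grid: HexGrid, pmap: ProvinceMap
) -> pd.DataFrame:
    """Unweighted mean of hexagon time-point temperatures within each province.

    Hexagons belong to the province containing their centroid; a province
    containing no centroid falls back to its nearest cell, with a warning.
    """
    cell_prov = pmap.province_of_cells(grid)
    assign = pd.DataFrame(
        {"cell_id": list(cell_prov.keys()), "province_id": list(cell_prov.values())}
    )
    merged = htt.merge(assign, on="cell_id")
    out = (
        merged.dropna(subset=["province_id"])
        .groupby(["province_id", "time_point"], sort=True)["mean_temp_c"]
        .mean()
        .reset_index()
        .rename(columns={"mean_temp_c": "temp_c"})
    )
    empty = set(pmap.province_ids) - set(out["province_id"].unique())
    if empty:
        warnings.warn(f"provinces without hexagon centroids, using nearest cell: {sorted(empty)}")
        extra = []
        for pid in sorted(empty):
            c = pmap.centroid(pid)
            d2 = (grid.centroid_lat - c.lat) ** 2 + (grid.centroid_lon - c.lon) ** 2
            cid = int(grid.cell_ids[int(np.argmin(d2))])
            sub = htt[htt["cell_id"] == cid]
            for r in sub.itertuples(index=False):
                extra.append(
                    {"province_id": pid, "time_point": r.time_point, "temp_c": r.mean_temp_c}
                )
        out = pd.concat([out, pd.DataFrame(extra)], ignore_index=True)
    return out.sort_values(["province_id", "time_point"]).reset_index(drop=True)


def province_temperature_change(ptemps: pd.DataFrame) -> pd.DataFrame:
    """Per-province temperature change between consecutive time points (deg C),
    plus the rate per decade."""
    rows = []
    for pid, sub in ptemps.groupby("province_id", sort=True):
        sub = sub.sort_values("time_point")
        tps = sub["time_point"].to_numpy()
        tc = sub["temp_c"].to_numpy()
        for j in range(1, len(tps)):
            years = int(tps[j] - tps[j - 1])
            rows.append(
                {
                    "province_id": pid,
                    "start": int(tps[j - 1]),
                    "end": int(tps[j]),
                    "delta_c": tc[j] - tc[j - 1],
                    "delta_c_per_decade": (tc[j] - tc[j - 1]) / (years / 10.0),
                }
            )
    return pd.DataFrame(rows)


def _cell_displacements(grid: HexGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise (north_km, east_km, dist_km) between all cell centroids."""
    lat = np.radians(np.asarray(grid.centroid_lat))
    lon = np.radians(np.asarray(grid.centroid_lon))
    north = EARTH_RADIUS_KM * (lat[None, :] - lat[:, None])
    mean_lat = 0.5 * (lat[None, :] + lat[:, None])
    east = EARTH_RADIUS_KM * np.cos(mean_lat) * (lon[None, :] - lon[:, None])
    return north, east, np.hypot(north, east)


def _smallest_k(values: np.ndarray, ids: np.ndarray, k: int) -> np.ndarray:
    """Positions of the k smallest values, ties broken by ascending id — exact
    even for wide tie blocks, without sorting the full array."""
    n = len(values)
    if k >= n:
        return np.lexsort((ids, values))
    thr = np.partition(values, k - 1)[k - 1]
    sel = np.nonzero(values <= thr)[0]
    order = np.lexsort((ids[sel], values[sel]))
    return sel[order[:k]]


def analogue_shift_vectors(
    htt: pd.DataFrame,
    grid: HexGrid,
    period: tuple[int, int],
    k_temp: int = 100,
    k_dist: int = 10,
) -> pd.DataFrame:
    """Nearest-thermal-analogue shift vector for every hexagon over one period.

    For each start cell the candidates are all cells (the start cell
    included), ranked by |temp at period end - start temp at period start|;
    the best ``k_temp`` survive (temperature ties broken by ascending
    cell_id), are re-ranked by centroid distance to the start cell, and the
    closest ``k_dist`` (distance ties again by cell_id) contribute their
    displacement vectors, which are averaged componentwise.

    Returns one row per cell: origin coordinates, east/north components (km),
    magnitude, and compass direction (NaN for a zero vector).
    """
    if k_dist > k_temp:
        raise ValueError("k_dist must not exceed k_temp")
    t0, t1 = int(period[0]), int(period[1])
    n = len(grid)
    if k_temp > n:
        warnings.warn(f"k_temp={k_temp} exceeds {n} cells; clipping")
        k_temp = n
        k_dist = min(k_dist, n)

    piv = htt.pivot(index="cell_id", columns="time_point", values="mean_temp_c")
    piv = piv.loc[np.sort(grid.cell_ids)]
    temp0 = piv[t0].to_numpy()
    temp1 = piv[t1].to_numpy()
    ids = piv.index.to_numpy()

    # grid axes re-ordered to match ascending cell_id
    order_ids = np.argsort(grid.cell_ids)
    lat = np.radians(np.asarray(grid.centroid_lat)[order_ids])
    lon = np.radians(np.asarray(grid.centroid_lon)[order_ids])

    rows = []
    for i in range(n):
        # stage 1: k_temp nearest in temperature (ties by ascending id)
        dtemp = np.abs(temp1 - temp0[i])
        cand = _smallest_k(dtemp, ids, k_temp)
        # stage 2: k_dist geographically nearest among them
        north = EARTH_RADIUS_KM * (lat[cand] - lat[i])
        east = EARTH_RADIUS_KM * np.cos(0.5 * (lat[cand] + lat[i])) * (lon[cand] - lon[i])
        dist = np.hypot(north, east)
        pick = _smallest_k(dist, ids[cand], k_dist)
        e = float(east[pick].mean())
        nn = float(north[pick].mean())
        mag = float(np.hypot(e, nn))
        rows.append(
            {
                "cell_id": int(ids[i]),
                "origin_lat": float(np.degrees(lat[i])),
                "origin_lon": float(np.degrees(lon[i])),
                "start": t0,
                "end": t1,
                "east_km": e,
                "north_km": nn,
                "magnitude_km": mag,
                "direction_deg": compass_from_components(e, nn) if mag > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def analogue_shift_vectors_all_periods(
    htt: pd.DataFrame, grid: HexGrid, k_temp: int = 100, k_dist: int = 10
) -> pd.DataFrame:
    """Analogue vectors for every consecutive time-point pair, concatenated."""
    tps = sorted(htt["time_point"].unique().tolist())
    parts = [
        analogue_shift_vectors(htt, grid, (tps[i], tps[i + 1]), k_temp, k_dist)
        for i in range(len(tps) - 1)
    ]
    return pd.concat(parts, ignore_index=True)


def province_temperature_velocity(
    vectors: pd.DataFrame, grid: HexGrid, pmap: ProvinceMap
) -> pd.DataFrame:
    """Province-level temperature shift: northward km/yr and mean bearing.

    Northward velocity is the mean north component of the province's member
    cell vectors divided by the period length (it may be negative, i.e.
    southward).  Direction is the circular mean of member bearings,
    zero-magnitude vectors excluded; it is NaN when undefined.
    """
    cell_prov = pmap.province_of_cells(grid)
    v = vectors.copy()
    v["province_id"] = v["cell_id"].map(cell_prov)
    v = v.dropna(subset=["province_id"])
    rows = []
    for (pid, t0, t1), sub in v.groupby(["province_id", "start", "end"], sort=True):
        years = int(t1 - t0)
        north_v = float(sub["north_km"].mean()) / years
        east_v = float(sub["east_km"].mean()) / years
        dirs = sub.loc[sub["magnitude_km"] > 0, "direction_deg"].to_numpy()
        if len(dirs):
            mean_dir, rbar = circular_mean(dirs)
        else:
            mean_dir, rbar = float("nan"), 0.0
        rows.append(
            {
                "province_id": pid,
                "start": int(t0),
                "end": int(t1),
                "northward_km_per_yr": north_v,
                "eastward_km_per_yr": east_v,
                "mean_direction_deg": mean_dir,
                "resultant_length": rbar,
                "n_cells": len(sub),
            }
        )
    return pd.DataFrame(rows)
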