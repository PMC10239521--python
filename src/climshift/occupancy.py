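"""Cumulative occupancy cube and the richness/colonisation metrics derived from it.

The central container is :class:`OccupancyCube`: a species x province x
time-point boolean tensor of cumulative presence (once a species is recorded
in a province it stays recorded — the catalogue data carry no reliable
extirpation signal, so richness is cumulative by construction).  An optional
(province, time-point) mask excludes combinations judged unreliable; masked
entries drop out of every aggregation, and a species' colonisation of a
masked province is counted at its first unmasked appearance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OccupancyCube",
    "merge_taxa",
    "apply_exclusions",
    "cumulative_richness",
    "richness_increase",
    "colonisation_rate",
    "establishment_success",
    "initial_occupancy",
]


@dataclass
class OccupancyCube:
    species_ids: list[str]
    province_ids: list[str]
    time_points: np.ndarray  # strictly increasing years
    presence: np.ndarray  # bool [species, province, time]
    mask: np.ndarray | None = None  # bool [province, time]; True = excluded

    def __post_init__(self):
        self.time_points = np.asarray(self.time_points, dtype=int)
        if not np.all(np.diff(self.time_points) > 0):
            raise ValueError("time points must be strictly increasing")
        self.presence = np.asarray(self.presence, dtype=bool)
        S, P, T = self.presence.shape
        if S != len(self.species_ids) or P != len(self.province_ids) or T != len(self.time_points):
            raise ValueError("presence tensor shape does not match axis labels")
        if np.any(self.presence[:, :, :-1] & ~self.presence[:, :, 1:]):
            raise ValueError("presence must be monotone non-decreasing along time")
        if self.mask is None:
            self.mask = np.zeros((P, T), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (P, T):
                raise ValueError("mask shape must be (provinces, time points)")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_provinces(self) -> int:
        return len(self.province_ids)

    @property
    def periods(self) -> list[tuple[int, int]]:
        tp = self.time_points
        return [(int(tp[i]), int(tp[i + 1])) for i in range(len(tp) - 1)]

    def effective_presence(self) -> np.ndarray:
        """Presence with masked (province, time) entries treated as absent."""
        return self.presence & ~self.mask[None, :, :]

    def first_record_index(self) -> np.ndarray:
        """Index of the first unmasked time point each species is present in each
        province; -1 where never (unmasked-)present.  Shape [species, province]."""
        eff = self.effective_presence()
        any_rec = eff.any(axis=2)
        first = np.argmax(eff, axis=2)
        first[~any_rec] = -1
        return first

    def to_long_frame(self) -> pd.DataFrame:
        """Long (species_id, province_id, first_time_point) records."""
        first = self.first_record_index()
        s, p = np.nonzero(first >= 0)
        return pd.DataFrame(
            {
                "species_id": [self.species_ids[i] for i in s],
                "province_id": [self.province_ids[j] for j in p],
                "first_time_point": self.time_points[first[s, p]],
            }
        )

    @classmethod
    def from_long_frame(
        cls,
        records: pd.DataFrame,
        time_points: Iterable[int],
        species_ids: list[str] | None = None,
        province_ids: list[str] | None = None,
    ) -> "OccupancyCube":
        """Build a cumulative cube from long (species, province, first_time_point) rows."""
        tp = np.asarray(sorted(set(int(t) for t in time_points)))
        if species_ids is None:
            species_ids = sorted(records["species_id"].astype(str).unique())
        if province_ids is None:
            province_ids = sorted(records["province_id"].astype(str).unique())
        s_idx = {s: i for i, s in enumerate(species_ids)}
        p_idx = {p: i for i, p in enumerate(province_ids)}
        pres = np.zeros((len(species_ids), len(province_ids), len(tp)), dtype=bool)
        for row in records.itertuples(index=False):
            t0 = int(np.searchsorted(tp, int(row.first_time_point)))
            if t0 >= len(tp) or tp[t0] != int(row.first_time_point):
                raise ValueError(f"first_time_point {row.first_time_point} not a study time point")
            pres[s_idx[str(row.species_id)], p_idx[str(row.province_id)], t0:] = True
        return cls(species_ids, province_ids, tp, pres)


def merge_taxa(cube: OccupancyCube, merge_map: Mapping[str, Iterable[str]]) -> OccupancyCube:
    """Merge taxa split during the study period into single taxa (logical OR of
    their presence), e.g. merging later-recognised sibling species back into
    one recording unit so early and late catalogues stay comparable."""
    members: set[str] = set()
    for new_id, olds in merge_map.items():
        olds = list(olds)
        unknown = [o for o in olds if o not in cube.species_ids]
        if unknown:
            raise ValueError(f"unknown species ids in merge group {new_id}: {unknown}")
        overlap = members.intersection(olds)
        if overlap:
            raise ValueError(f"species {sorted(overlap)} appear in more than one merge group")
        members.update(olds)

    idx = {s: i for i, s in enumerate(cube.species_ids)}
    new_species: list[str] = []
    rows = []
    for s in cube.species_ids:
        if s not in members:
            new_species.append(s)
            rows.append(cube.presence[idx[s]])
    for new_id, olds in merge_map.items():
        new_species.append(new_id)
        rows.append(np.logical_or.reduce([cube.presence[idx[o]] for o in olds]))
    return OccupancyCube(
        new_species, list(cube.province_ids), cube.time_points.copy(),
        np.stack(rows), cube.mask.copy(),
    )


def apply_exclusions(
    cube: OccupancyCube, exclusions: Iterable[tuple[str, int]]
) -> OccupancyCube:
    """Mask (province, time point) combinations with inadequate sampling."""
    mask = cube.mask.copy()
    p_idx = {p: i for i, p in enumerate(cube.province_ids)}
    t_idx = {int(t): i for i, t in enumerate(cube.time_points)}
    for prov, tp in exclusions:
        if prov not in p_idx:
            raise ValueError(f"unknown province {prov!r}")
        if int(tp) not in t_idx:
            raise ValueError(f"unknown time point {tp}")
        mask[p_idx[prov], t_idx[int(tp)]] = True
    return replace(cube, presence=cube.presence.copy(), mask=mask)


def cumulative_richness(cube: OccupancyCube) -> pd.DataFrame:
    """Cumulative species count per (province, time point); NaN where masked."""
    counts = cube.presence.sum(axis=0).astype(float)  # [province, time]
    counts[cube.mask] = np.nan
    recs = [
        {"province_id": p, "time_point": int(t), "richness": counts[i, j]}
        for i, p in enumerate(cube.province_ids)
        for j, t in enumerate(cube.time_points)
    ]
    return pd.DataFrame(recs)


def richness_increase(
    cube: OccupancyCube, per: str = "period", rate_unit: str = "absolute"
) -> pd.DataFrame:
    """Richness change per province, per period or over the whole study range.

    rate_unit: 'absolute' (species), 'per_year' or 'per_decade'.
    Periods with a masked endpoint are missing.
    """
    if per not in ("period", "overall"):
        raise ValueError("per must be 'period' or 'overall'")
    if rate_unit not in ("absolute", "per_year", "per_decade"):
        raise ValueError("rate_unit must be absolute, per_year or per_decade")
    counts = cube.presence.sum(axis=0).astype(float)
    counts[cube.mask] = np.nan
    tp = cube.time_points
    rows = []
    if per == "period":
        spans = [(j, j + 1) for j in range(len(tp) - 1)]
    else:
        spans = [(0, len(tp) - 1)]
    for i, prov in enumerate(cube.province_ids):
        for j0, j1 in spans:
            years = int(tp[j1] - tp[j0])
            inc = counts[i, j1] - counts[i, j0]
            if rate_unit == "per_year":
                inc = inc / years
            elif rate_unit == "per_decade":
                inc = inc / (years / 10.0)
            rows.append(
                {
                    "province_id": prov,
                    "start": int(tp[j0]),
                    "end": int(tp[j1]),
                    "years": years,
                    "increase": inc,
                }
            )
    return pd.DataFrame(rows)


def colonisation_rate(cube: OccupancyCube) -> pd.DataFrame:
    """Species newly recorded per province and period, expressed per decade.

    A colonisation is attributed to the period ending at the species' first
    unmasked record.  Periods whose end point is masked are missing.
    """
    first = cube.first_record_index()
    tp = cube.time_points
    rows = []
    for i, prov in enumerate(cube.province_ids):
        for j in range(1, len(tp)):
            years = int(tp[j] - tp[j - 1])
            if cube.mask[i, j]:
                n_new, rate = np.nan, np.nan
            else:
                n_new = int(np.sum(first[:, i] == j))
                rate = n_new / (years / 10.0)
            rows.append(
                {
                    "province_id": prov,
                    "start": int(tp[j - 1]),
                    "end": int(tp[j]),
                    "decades": years / 10.0,
                    "n_colonisations": n_new,
                    "rate_per_decade": rate,
                }
            )
    return pd.DataFrame(rows)


def establishment_success(cube: OccupancyCube) -> pd.DataFrame:
    """Number of provinces newly colonised per species and period."""
    first = cube.first_record_index()
    tp = cube.time_points
    rows = []
    for s, sp in enumerate(cube.species_ids):
        for j in range(1, len(tp)):
            newly = int(np.sum((first[s] == j) & ~cube.mask[:, j]))
            rows.append(
                {
                    "species_id": sp,
                    "start": int(tp[j - 1]),
                    "end": int(tp[j]),
                    "n_new_provinces": newly,
                }
            )
    return pd.DataFrame(rows)


def initial_occupancy(cube: OccupancyCube, time_point: int) -> pd.DataFrame:
    """Provinces occupied per species at ``time_point`` (unmasked records only)."""
    tp = list(cube.time_points)
    if int(time_point) not in tp:
        raise ValueError(f"{time_point} is not a study time point")
    j = tp.index(int(time_point))
    eff = cube.effective_presence()[:, :, j]
    return pd.DataFrame(
        {"species_id": cube.species_ids, "n_provinces": eff.sum(axis=1).astype(int)}
    )
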