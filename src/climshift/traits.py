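"""Trait-space construction and ecological-filtering analyses.

Communities are compared in a z-scored Euclidean trait space built from the
four continuous species traits (wingspan, European range size, STI mean, STI
range).  PERMANOVA asks whether the *location* of the original community and
the colonising species differs in that space; PERMDISP asks whether their
*spread* (mean distance to the group centroid) differs.  Both use label
permutations for inference; the overall PERMANOVA can restrict permutations
within provinces (strata), mirroring a design with province as a grouping
factor.  Per-province scans are corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .geo import ProvinceMap
from .occupancy import OccupancyCube

CONTINUOUS_TRAITS = ["wingspan_mm", "range_size_cells", "sti_mean_c", "sti_range_c"]

__all__ = [
    "CONTINUOUS_TRAITS",
    "PermTestResult",
    "normalise_and_distance",
    "permanova",
    "permdisp",
    "per_province_filtering_scan",
    "dispersion_latitude_trend",
    "variable_cluster_select",
]


@dataclass(frozen=True)
class PermTestResult:
    statistic: float
    p: float
    n_perm: int
    seed: int
    group_sizes: dict
    group_dispersions: dict | None = None


def normalise_and_distance(
    traits: pd.DataFrame, species: list[str] | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Z-score the four continuous traits over a species subset and return the
    normalised trait matrix plus the pairwise Euclidean distance matrix."""
    t = traits.set_index("species_id")
    if species is not None:
        t = t.loc[list(species)]
    if len(t) < 2:
        raise ValueError("need at least two species")
    X = t[CONTINUOUS_TRAITS].astype(float)
    if X.isna().any().any():
        raise ValueError("missing trait values in selected species")
    sd = X.std(ddof=1)
    zero = [c for c in CONTINUOUS_TRAITS if sd[c] == 0]
    if zero:
        raise ValueError(f"zero-variance trait column(s): {zero}")
    Z = (X - X.mean()) / sd
    coords = Z.to_numpy()
    diff = coords[:, None, :] - coords[None, :, :]
    dmat = np.sqrt((diff**2).sum(axis=2))
    return Z, dmat


def _permuted_labels(
    labels: np.ndarray, n_perm: int, rng: np.random.Generator,
    strata: np.ndarray | None,
) -> np.ndarray:
    """(n_perm, n) matrix of permuted group labels, optionally within strata."""
    n = len(labels)
    out = np.tile(labels, (n_perm, 1))
    if strata is None:
        for b in range(n_perm):
            out[b] = labels[rng.permutation(n)]
    else:
        for stratum in np.unique(strata):
            idx = np.nonzero(strata == stratum)[0]
            for b in range(n_perm):
                out[b, idx] = labels[idx[rng.permutation(len(idx))]]
    return out


def _permanova_f(d2: np.ndarray, label_matrix: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Pseudo-F for each row of permuted labels (vectorised over permutations)."""
    n = d2.shape[0]
    g = len(groups)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ssw = np.zeros(label_matrix.shape[0])
    for grp in groups:
        Z = (label_matrix == grp).astype(float).T  # (n, n_perm)
        n_g = Z[:, 0].sum()
        quad = np.einsum("ip,ip->p", d2 @ Z, Z) / 2.0
        ssw += quad / n_g
    ssb = ss_total - ssw
    return (ssb / (g - 1)) / (ssw / (n - g))


def permanova(
    dmat: np.ndarray,
    groups,
    n_perm: int = 9999,
    seed: int = 0,
    strata=None,
) -> PermTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F compares among-group to within-group sums of squared distances;
    the null distribution comes from shuffling group labels (within strata
    when given).  p uses the (b+1)/(m+1) estimator, so it is never zero.
    """
    labels = np.asarray(groups)
    d2 = np.asarray(dmat, dtype=float) ** 2
    n = len(labels)
    if d2.shape != (n, n):
        raise ValueError("distance matrix and group labels disagree in size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    if ss_total <= 1e-12:
        warnings.warn("all points identical; PERMANOVA p set to 1")
        return PermTestResult(0.0, 1.0, n_perm, seed, dict(zip(uniq, counts)))
    strata_arr = np.asarray(strata) if strata is not None else None

    f_obs = float(_permanova_f(d2, labels[None, :], uniq)[0])
    rng = np.random.default_rng(seed)
    perm = _permuted_labels(labels, n_perm, rng, strata_arr)
    f_perm = _permanova_f(d2, perm, uniq)
    p = (np.sum(f_perm >= f_obs - 1e-12) + 1.0) / (n_perm + 1.0)
    return PermTestResult(f_obs, float(p), n_perm, seed, dict(zip(uniq, counts.tolist())))


def _pcoa_coords(dmat: np.ndarray) -> np.ndarray:
    """Principal-coordinate embedding of a distance matrix (positive axes)."""
    n = dmat.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dmat**2) @ J
    w, v = np.linalg.eigh((B + B.T) / 2.0)
    keep = w > 1e-10
    return v[:, keep] * np.sqrt(w[keep])


def _dispersion_f(X: np.ndarray, label_matrix: np.ndarray, groups: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """ANOVA F on distances-to-own-group-centroid for each permutation row.

    Returns (F per permutation, per-group mean dispersions for the first row).
    """
    n, _ = X.shape
    P = label_matrix.shape[0]
    x2 = (X**2).sum(axis=1)
    disp = np.zeros((n, P))
    means = np.zeros((len(groups), P))
    counts = np.zeros(len(groups))
    for gi, grp in enumerate(groups):
        Z = (label_matrix == grp).astype(float).T  # (n, P)
        n_g = Z[:, 0].sum()
        counts[gi] = n_g
        C = (X.T @ Z) / n_g  # (d, P) centroids per permutation
        d2 = x2[:, None] - 2.0 * (X @ C) + (C**2).sum(axis=0)[None, :]
        d = np.sqrt(np.clip(d2, 0.0, None))
        disp += d * Z
        means[gi] = (d * Z).sum(axis=0) / n_g
    grand = disp.mean(axis=0)
    ssb = (counts[:, None] * (means - grand[None, :]) ** 2).sum(axis=0)
    own_mean = np.zeros((n, P))
    for gi, grp in enumerate(groups):
        Z = (label_matrix == grp).astype(float).T
        own_mean += means[gi][None, :] * Z
    ssw = ((disp - own_mean) ** 2).sum(axis=0)
    g = len(groups)
    F = (ssb / (g - 1)) / (ssw / (n - g))
    return F, means[:, 0]


def permdisp(
    data: np.ndarray,
    groups,
    n_perm: int = 9999,
    seed: int = 0,
    input_type: str = "coords",
) -> PermTestResult:
    """Homogeneity of multivariate dispersions (distance to group centroid).

    ``data`` is either a coordinate matrix in the (Euclidean, z-scored) trait
    space, or a distance matrix (``input_type='distance'``), which is first
    embedded by principal coordinates — identical dispersions for Euclidean
    distances.  The statistic is the one-way ANOVA F on the member-to-centroid
    distances; the permutation null shuffles group membership of the points
    and recomputes centroids and F.
    """
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    small = uniq[counts < 2]
    if len(small):
        warnings.warn(f"dropping singleton group(s) {small.tolist()} from PERMDISP")
        keepers = ~np.isin(labels, small)
        labels = labels[keepers]
        data = np.asarray(data)[keepers][:, keepers] if input_type == "distance" else np.asarray(data)[keepers]
        uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups of size >= 2")
    X = _pcoa_coords(np.asarray(data, float)) if input_type == "distance" else np.asarray(data, float)

    f_obs_arr, obs_means = _dispersion_f(X, labels[None, :], uniq)
    f_obs = float(f_obs_arr[0])
    rng = np.random.default_rng(seed)
    perm = _permuted_labels(labels, n_perm, rng, None)
    f_perm, _ = _dispersion_f(X, perm, uniq)
    p = (np.sum(f_perm >= f_obs - 1e-12) + 1.0) / (n_perm + 1.0)
    return PermTestResult(
        f_obs, float(p), n_perm, seed,
        dict(zip(uniq.tolist(), counts.tolist())),
        group_dispersions=dict(zip(uniq.tolist(), obs_means.tolist())),
    )


def per_province_filtering_scan(
    traits: pd.DataFrame,
    cube: OccupancyCube,
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """PERMANOVA + PERMDISP per province: original community vs colonisers.

    "Original" species were present at the first time point; "colonisers"
    first appeared later.  Each province with both groups of size >= 2 gets a
    location test (PERMANOVA) and a dispersion test (PERMDISP); p-values are
    Benjamini-Hochberg adjusted across provinces separately per test family.
    The sign column records whether colonisers are more (+1) or less (-1)
    dispersed than the original community.
    """
    eff = cube.effective_presence()
    first = cube.first_record_index()
    rows = []
    for pi, pid in enumerate(cube.province_ids):
        orig = [cube.species_ids[s] for s in np.nonzero(first[:, pi] == 0)[0]]
        colon = [cube.species_ids[s] for s in np.nonzero(first[:, pi] > 0)[0]]
        avail = set(traits["species_id"])
        orig = [s for s in orig if s in avail]
        colon = [s for s in colon if s in avail]
        if len(orig) < 2 or len(colon) < 2:
            rows.append({"province_id": pid, "testable": False,
                         "n_original": len(orig), "n_coloniser": len(colon)})
            continue
        species = orig + colon
        labels = np.array(["original"] * len(orig) + ["coloniser"] * len(colon))
        Z, dmat = normalise_and_distance(traits, species)
        pa = permanova(dmat, labels, n_perm=n_perm, seed=seed)
        pdsp = permdisp(Z.to_numpy(), labels, n_perm=n_perm, seed=seed)
        d_col = pdsp.group_dispersions["coloniser"]
        d_org = pdsp.group_dispersions["original"]
        rows.append(
            {
                "province_id": pid,
                "testable": True,
                "n_original": len(orig),
                "n_coloniser": len(colon),
                "permanova_F": pa.statistic,
                "permanova_p": pa.p,
                "permdisp_F": pdsp.statistic,
                "permdisp_p": pdsp.p,
                "dispersion_original": d_org,
                "dispersion_coloniser": d_col,
                "dispersion_sign": int(np.sign(d_col - d_org)),
            }
        )
    out = pd.DataFrame(rows)
    ok = out["testable"] == True  # noqa: E712
    for col in ("permanova_p", "permdisp_p"):
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, col], method="fdr_bh")[1]
        out[col.replace("_p", "_p_adj")] = adj
    return out


def dispersion_latitude_trend(
    dispersions: pd.DataFrame, pmap: ProvinceMap
) -> dict:
    """Latitudinal trend in within-group trait dispersion.

    ``dispersions`` has columns province_id, group, mean_dispersion.  Fits
    per-group OLS of mean dispersion on province centroid latitude and
    province area, plus a combined model with a group x latitude interaction.
    Returns per-group slope tables and the interaction estimate with its
    Wald z.
    """
    import statsmodels.api as sm

    df = dispersions.copy()
    df["latitude"] = [pmap.centroid(p).lat for p in df["province_id"]]
    df["area_km2"] = [pmap.area_km2(p) for p in df["province_id"]]
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")

    def _fit(sub: pd.DataFrame):
        X = sm.add_constant(sub[["latitude", "area_km2"]].astype(float))
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError("collinear predictors in dispersion trend model")
        return sm.OLS(sub["mean_dispersion"].astype(float), X).fit()

    per_group = {}
    for g in groups:
        sub = df[df["group"] == g]
        if len(sub) < 3:
            raise ValueError(f"need >= 3 provinces per group, got {len(sub)} for {g}")
        fit = _fit(sub)
        per_group[g] = {
            "slope_latitude": float(fit.params["latitude"]),
            "se_latitude": float(fit.bse["latitude"]),
            "z_latitude": float(fit.params["latitude"] / fit.bse["latitude"]),
            "n": len(sub),
        }

    df["is_second"] = (df["group"] == groups[1]).astype(float)
    df["lat_x_group"] = df["latitude"] * df["is_second"]
    X = sm.add_constant(df[["latitude", "area_km2", "is_second", "lat_x_group"]].astype(float))
    fit = sm.OLS(df["mean_dispersion"].astype(float), X).fit()
    inter = {
        "estimate": float(fit.params["lat_x_group"]),
        "se": float(fit.bse["lat_x_group"]),
        "z": float(fit.params["lat_x_group"] / fit.bse["lat_x_group"]),
        "groups": groups,
    }
    return {"per_group": per_group, "interaction": inter}


def variable_cluster_select(
    data: pd.DataFrame, rho_threshold: float = 0.3, preference_order=None
) -> list[str]:
    """Collinearity screen by single-linkage clustering on |Spearman rho|.

    Columns whose |Spearman correlation| chains at or above ``rho_threshold``
    form a cluster; one representative per cluster is retained, chosen by
    ``preference_order`` (default: input column order).  Constant columns have
    undefined correlations and are isolated with a warning.
    """
    cols = list(data.columns)
    if len(cols) < 2 or len(data) < 3:
        raise ValueError("need >= 2 columns and >= 3 rows")
    X = data.to_numpy(dtype=float)
    const = [c for i, c in enumerate(cols) if np.std(X[:, i]) == 0]
    if const:
        warnings.warn(f"constant column(s) isolated: {const}")
    rho = stats.spearmanr(X).statistic
    if np.isscalar(rho):  # two columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
    sim = np.abs(np.nan_to_num(rho, nan=0.0))
    np.fill_diagonal(sim, 1.0)
    dist = 1.0 - sim
    link = linkage(squareform(dist, checks=False), method="single")
    flat = fcluster(link, t=1.0 - rho_threshold, criterion="distance")

    pref = list(preference_order) if preference_order is not None else cols
    rank = {c: pref.index(c) if c in pref else len(pref) + cols.index(c) for c in cols}
    retained = []
    for cl in np.unique(flat):
        members = [cols[i] for i in np.nonzero(flat == cl)[0]]
        retained.append(min(members, key=lambda c: rank[c]))
    return sorted(retained, key=lambda c: cols.index(c))
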