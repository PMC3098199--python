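"""Neural-response statistics for simulated units.

Covers the quantities used to characterize the model's codes: occupancy-
normalized rate maps and receptive-field sizes, Skaggs information per
spike and plug-in spatial mutual information, decoder-based population
information against the occupancy-entropy upper bound, lifetime/population
kurtosis sparseness measures, tuning-curve skewness, cross-correlogram
anticipation lags, goal-distance rate correlations, task-phase information,
and PCA + k-means clustering of per-unit statistic vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .maze import DT
from .columns import ColumnNetwork
from .planner import PlanState

RATE_QUANTILE_BINS = 8   # discretization of rates for plug-in MI
FIELD_THRESHOLD = 0.2    # field = bins with rate >= 20% of the map peak
SPATIAL_BIN_CM = 5.0


class AnalysisError(ValueError):
    pass


# -- binning helpers -------------------------------------------------------

def _position_bins(positions: np.ndarray,
                   bin_cm: float = SPATIAL_BIN_CM) -> np.ndarray:
    """Integer spatial bin index per sample (row-major over occupied bins)."""
    pos = np.asarray(positions, dtype=float)
    cells = np.floor(pos / bin_cm).astype(int)
    _, inv = np.unique(cells, axis=0, return_inverse=True)
    return inv


def _quantile_bins(rates: np.ndarray,
                   n_bins: int = RATE_QUANTILE_BINS) -> np.ndarray:
    r = np.asarray(rates, dtype=float)
    edges = np.unique(np.quantile(r, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.digitize(r, edges)


def _plugin_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two discrete label arrays."""
    x = np.asarray(x)
    y = np.asarray(y)
    joint = pd.crosstab(x, y).to_numpy().astype(float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px @ py))
    return float(np.nansum(terms))


# -- single-unit measures --------------------------------------------------

def rate_map(rates: np.ndarray, positions: np.ndarray,
             bin_cm: float = SPATIAL_BIN_CM,
             threshold: float = FIELD_THRESHOLD):
    """Occupancy-normalized rate map over visited bins.

    Returns (DataFrame with columns cx, cy, occupancy_s, rate_hz, and the
    receptive-field size = number of visited bins at >= ``threshold`` of
    the map peak).
    """
    rates = np.asarray(rates, dtype=float)
    if len(rates) == 0:
        raise AnalysisError("empty trajectory")
    pos = np.asarray(positions, dtype=float)
    cells = np.floor(pos / bin_cm).astype(int)
    df = pd.DataFrame({"cx": cells[:, 0], "cy": cells[:, 1], "rate": rates})
    g = df.groupby(["cx", "cy"])["rate"].agg(["mean", "count"]).reset_index()
    g = g.rename(columns={"mean": "rate_hz", "count": "n"})
    g["occupancy_s"] = g.pop("n") * DT
    peak = g["rate_hz"].max()
    size = int((g["rate_hz"] >= threshold * peak).sum()) if peak > 0 else 0
    return g, size


def spatial_info(rates: np.ndarray, positions: np.ndarray,
                 bin_cm: float = SPATIAL_BIN_CM) -> tuple[float, float]:
    """(plug-in spatial MI in bits, Skaggs information per spike in bits)."""
    rates = np.asarray(rates, dtype=float)
    xbin = _position_bins(positions, bin_cm)
    if len(np.unique(xbin)) < 2:
        raise AnalysisError("need at least two visited bins")
    if np.ptp(rates) == 0:
        return 0.0, 0.0
    mi = _plugin_mi(_quantile_bins(rates), xbin)
    # Skaggs: sum_x p(x) (lam_x / lam) log2(lam_x / lam)
    lam_x = np.array([rates[xbin == b].mean() for b in np.unique(xbin)])
    p_x = np.array([(xbin == b).mean() for b in np.unique(xbin)])
    lam = float(p_x @ lam_x)
    if lam <= 0:
        return mi, 0.0
    ratio = lam_x / lam
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p_x * ratio * np.log2(ratio)
    return mi, float(np.nansum(terms))


def synthesize_spikes(rates: np.ndarray, seed: int,
                      dt: float = DT) -> np.ndarray:
    """Inhomogeneous Poisson spike times from a rate trace (seeded)."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise AnalysisError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rates * dt)
    times = []
    for i, c in enumerate(counts):
        if c:
            times.extend(i * dt + np.sort(rng.uniform(0, dt, size=c)))
    return np.asarray(times)


def tuning_skewness(linear_pos: np.ndarray, rates: np.ndarray) -> float:
    """Third standardized moment of the rate-weighted coordinate
    distribution along a linearized path (NaN for zero variance)."""
    x = np.asarray(linear_pos, dtype=float)
    r = np.asarray(rates, dtype=float)
    if len(x) < 3:
        raise AnalysisError("need at least three samples")
    total = r.sum()
    if total <= 0:
        return float("nan")
    w = r / total
    mu = float(w @ x)
    var = float(w @ (x - mu) ** 2)
    if var <= 0:
        return float("nan")
    return float(w @ (x - mu) ** 3) / var ** 1.5


def anticipation_lag(trace_a: np.ndarray, trace_b: np.ndarray,
                     dt: float = DT) -> float:
    """Cross-correlation peak lag in seconds; positive when a leads b."""
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape:
        raise AnalysisError("traces must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    a = a - a.mean()
    b = b - b.mean()
    c = np.correlate(a, b, mode="full")
    return float((len(a) - 1 - int(np.argmax(c))) * dt)


# -- population measures ---------------------------------------------------

def population_spatial_info(rate_matrix: np.ndarray, positions: np.ndarray,
                            trial_ids: np.ndarray,
                            bin_cm: float = SPATIAL_BIN_CM) -> dict:
    """Decoder-based population spatial information.

    A leave-one-trial-out nearest-centroid population-vector decoder over
    ``bin_cm`` bins estimates I(decoded; true) in bits; the theoretical
    upper bound is the entropy of the empirical occupancy distribution.
    Returns {"mi_bits", "upper_bound_bits", "ratio"}.
    """
    R = np.asarray(rate_matrix, dtype=float)
    if R.ndim != 2 or R.shape[1] < 2:
        raise AnalysisError("need a (samples x units) matrix with >= 2 units")
    xbin = _position_bins(positions, bin_cm)
    n_bins = int(xbin.max()) + 1
    if n_bins < 2:
        raise AnalysisError("degenerate occupancy (single bin)")
    trial_ids = np.asarray(trial_ids)
    p_occ = np.bincount(xbin, minlength=n_bins) / len(xbin)
    upper = float(-(p_occ[p_occ > 0] * np.log2(p_occ[p_occ > 0])).sum())
    decoded = np.empty_like(xbin)
    for t in np.unique(trial_ids):
        test = trial_ids == t
        train = ~test
        if not train.any():
            raise AnalysisError("leave-one-trial-out needs >= 2 trials")
        sums = np.zeros((n_bins, R.shape[1]))
        counts = np.bincount(xbin[train], minlength=n_bins).astype(float)
        np.add.at(sums, xbin[train], R[train])
        present = counts > 0
        centroids = sums[present] / counts[present, None]
        bins_present = np.nonzero(present)[0]
        d2 = (np.sum(R[test] ** 2, axis=1)[:, None]
              - 2 * R[test] @ centroids.T
              + np.sum(centroids ** 2, axis=1)[None, :])
        decoded[test] = bins_present[np.argmin(d2, axis=1)]
    mi = _plugin_mi(xbin, decoded)
    return {"mi_bits": mi, "upper_bound_bits": upper,
            "ratio": mi / upper if upper > 0 else float("nan")}


def sparseness_stats(rate_matrix: np.ndarray,
                     positions: np.ndarray | None = None,
                     trial_ids: np.ndarray | None = None,
                     bin_cm: float = SPATIAL_BIN_CM) -> dict:
    """Lifetime kurtosis per unit, mean population kurtosis per location,
    and (when positions are given) the information sparseness ratio
    population MI / sum of single-unit MI."""
    R = np.asarray(rate_matrix, dtype=float)
    lifetime = np.array([sps.kurtosis(R[:, u], fisher=True, bias=True)
                         if np.ptp(R[:, u]) > 0 else np.nan
                         for u in range(R.shape[1])])
    out = {"lifetime_kurtosis": lifetime}
    if positions is not None:
        xbin = _position_bins(positions, bin_cm)
        pk = []
        for b in np.unique(xbin):
            vec = R[xbin == b].mean(axis=0)
            if np.ptp(vec) > 0:
                pk.append(sps.kurtosis(vec, fisher=True, bias=True))
        out["population_kurtosis"] = float(np.mean(pk)) if pk else float("nan")
        single = []
        for u in range(R.shape[1]):
            try:
                mi, _ = spatial_info(R[:, u], positions, bin_cm)
            except AnalysisError:
                mi = 0.0
            single.append(mi)
        if trial_ids is not None and R.shape[1] >= 2:
            pop = population_spatial_info(R, positions, trial_ids, bin_cm)
            denom = float(np.sum(single))
            out["info_sparseness"] = (pop["mi_bits"] / denom
                                      if denom > 0 else float("nan"))
    return out


# -- task-related measures -------------------------------------------------

def goal_distance_correlation(net: ColumnNetwork, plan: PlanState,
                              within_horizon: bool = True,
                              noise_sd: float = 0.0,
                              rng: np.random.Generator | None = None):
    """Spearman correlation of each column's goal-signal rate with its
    shortest-path relay distance to the goal (graph BFS distances)."""
    from collections import deque
    nu = net.params.noise_floor
    # BFS on reversed forward edges from the goal
    incoming: dict[int, list] = {c.id: [] for c in net.columns}
    for (i, _a, j) in net.W_fwd:
        incoming[j].append(i)
    dist = {plan.goal: 0}
    q = deque([plan.goal])
    while q:
        j = q.popleft()
        for i in incoming[j]:
            if i not in dist:
                dist[i] = dist[j] + 1
                q.append(i)
    rates, ds = [], []
    for c in net.columns:
        if c.id not in dist:
            continue
        above = plan.g.get(c.id, nu) > nu
        if above != within_horizon:
            continue
        r = plan.g.get(c.id, nu)
        if noise_sd > 0:
            r += (rng or np.random.default_rng()).normal(0, noise_sd)
        rates.append(r)
        ds.append(dist[c.id])
    if len(rates) < 3:
        raise AnalysisError("need at least three columns in the regime")
    rho, p = sps.spearmanr(rates, ds)
    return float(rho), float(p), dict(zip(ds, rates))


def phase_information(rates_by_phase: dict) -> float:
    """Plug-in MI (bits) between task phase and discretized unit rate."""
    if len(rates_by_phase) < 2:
        raise AnalysisError("need at least two phases")
    labels, values = [], []
    for k, (phase, r) in enumerate(sorted(rates_by_phase.items())):
        r = np.asarray(r, dtype=float)
        if len(r) < 2:
            raise AnalysisError("need >= 2 samples per phase")
        labels.extend([k] * len(r))
        values.extend(r)
    return _plugin_mi(np.asarray(labels),
                      _quantile_bins(np.asarray(values)))


# -- unit statistic table + clustering ------------------------------------

FEATURES = ["mean_rate", "rate_sd", "skewness", "lifetime_kurtosis",
            "info_per_spike", "spatial_mi"]


def unit_stats_table(traces: dict, positions: np.ndarray,
                     bin_cm: float = SPATIAL_BIN_CM) -> pd.DataFrame:
    """Six summary statistics per unit from {kind: (samples x units)} traces."""
    rows = []
    for kind, R in traces.items():
        R = np.asarray(R, dtype=float)
        for u in range(R.shape[1]):
            r = R[:, u]
            if np.ptp(r) == 0:
                continue
            try:
                mi, ips = spatial_info(r, positions, bin_cm)
            except AnalysisError:
                mi, ips = 0.0, 0.0
            rows.append({
                "unit": f"{kind}_{u}", "kind": kind,
                "mean_rate": float(r.mean()), "rate_sd": float(r.std()),
                "skewness": float(sps.skew(r, bias=True)),
                "lifetime_kurtosis": float(sps.kurtosis(r, bias=True)),
                "info_per_spike": ips, "spatial_mi": mi,
            })
    return pd.DataFrame(rows).set_index("unit")


def cluster_units(stats: pd.DataFrame, k: int = 3, seed: int = 0,
                  n_components: int = 3) -> dict:
    """PCA on the z-scored feature table, k-means on the leading components.

    Returns principal-axis loadings, explained variance ratios, component
    scores and cluster labels (10 seeded k-means restarts).
    """
    X = stats[FEATURES].to_numpy(dtype=float)
    if len(X) < k:
        raise AnalysisError("fewer units than clusters")
    Z = StandardScaler().fit_transform(X)
    pca = PCA(n_components=min(n_components, Z.shape[1], len(Z)))
    scores = pca.fit_transform(Z)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(scores)
    return {"loadings": pca.components_,
            "explained_variance_ratio": pca.explained_variance_ratio_,
            "scores": scores,
            "labels": km.labels_}


def cluster_purity(labels: np.ndarray, groups: np.ndarray) -> float:
    """Fraction of units whose cluster's majority group matches their own."""
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    correct = 0
    for c in np.unique(labels):
        members = groups[labels == c]
        _, counts = np.unique(members, return_counts=True)
        correct += counts.max()
    return correct / len(labels)
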