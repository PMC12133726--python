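"""Statistical machinery: paired tests, correlations, summary tables and
cluster-based permutation testing in time-frequency and electrode space.

The cluster test controls the family-wise error of mass-univariate paired
comparisons: bins (or electrodes) whose paired t exceeds the two-sided
forming threshold are grouped by adjacency separately per t-sign, each
cluster is scored by its mass (sum of t-values), and the observed masses
are ranked against a null distribution of maximum |mass| built by randomly
sign-flipping each subject's condition difference -- the exchangeability
that holds under "no condition effect" in a within-subject design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sst

from .montage import Adjacency
from .paradigm import ATTENTION, INATTENTION

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


def paired_t(a, b) -> tuple[float, int, float]:
    """Classical paired-samples t-test; returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.allclose(d, d[0]):
        raise ValueError("degenerate differences: t undefined "
                         "(all pairs differ by the same amount)")
    res = sst.ttest_rel(a, b)
    return float(res.statistic), n - 1, float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation; p from the exact t transform (df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input vector")
    res = sst.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p)."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError("Shapiro-Wilk needs 3..5000 values")
    if np.allclose(values, values[0]):
        raise ValueError("constant vector")
    res = sst.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def summary_stats(values) -> tuple[float, float]:
    """Mean and population standard deviation (divisor N).

    The population convention is what reproduces the printed per-column
    dispersion ("SDT") rows of the reference tables.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    return float(values.mean()), float(values.std(ddof=0))


# ---------------------------------------------------------------------------
# cluster-based permutation tests
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    bins: np.ndarray  # flat indices into the map / electrode axis
    mass: float
    sign: int
    p: float = np.nan


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    null: np.ndarray  # permutation null of max |mass|, length n_perm
    sig_mask: np.ndarray  # t-values inside significant clusters, else 0
    t_map: np.ndarray
    alpha_form: float
    alpha_cluster: float
    n_perm: int
    seed: int
    labels: tuple[str, ...] | None = None  # electrode-space runs only

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.alpha_cluster]

    def to_json(self, path=None) -> str:
        payload = {
            "n_perm": self.n_perm,
            "seed": self.seed,
            "alpha_form": self.alpha_form,
            "alpha_cluster": self.alpha_cluster,
            "clusters": [
                {
                    "bins": (np.asarray(c.bins).tolist() if self.labels is None
                             else [self.labels[i] for i in np.asarray(c.bins)]),
                    "mass": c.mass,
                    "sign": c.sign,
                    "p": c.p,
                }
                for c in self.clusters
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text


def _t_one_sample(d: np.ndarray) -> np.ndarray:
    """Vectorised one-sample t over axis 0 with zero-variance guard."""
    n = d.shape[0]
    m = d.mean(axis=0)
    s = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / np.sqrt(n))
    zero_var = s <= 0
    if np.any(zero_var):
        with np.errstate(invalid="ignore"):
            t = np.where(zero_var, np.where(np.abs(m) <= 1e-300, 0.0,
                                            np.sign(m) * np.inf), t)
    return t


def _grid_clusters(t: np.ndarray, tcrit: float, structure) -> list[Cluster]:
    clusters = []
    for sign in (1, -1):
        mask = (sign * t) > tcrit
        lab, n_lab = ndimage.label(mask, structure=structure)
        for k in range(1, n_lab + 1):
            bins = np.flatnonzero(lab.ravel() == k)
            clusters.append(Cluster(bins, float(t.ravel()[bins].sum()), sign))
    return clusters


def _graph_clusters(t: np.ndarray, tcrit: float, adj: np.ndarray
                    ) -> list[Cluster]:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    clusters = []
    for sign in (1, -1):
        idx = np.flatnonzero((sign * t) > tcrit)
        if idx.size == 0:
            continue
        sub = csr_matrix(adj[np.ix_(idx, idx)])
        n_comp, comp = connected_components(sub, directed=False)
        for k in range(n_comp):
            bins = idx[comp == k]
            clusters.append(Cluster(bins, float(t[bins].sum()), sign))
    return clusters


def _max_mass(clusters: list[Cluster]) -> float:
    return max((abs(c.mass) for c in clusters), default=0.0)


def _perm_cluster(diffs: np.ndarray, cluster_fn, n_perm: int,
                  alpha_form: float, alpha_cluster: float, seed: int
                  ) -> tuple[list[Cluster], np.ndarray, np.ndarray]:
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    tcrit = float(sst.t.ppf(1.0 - alpha_form / 2.0, n - 1))
    t_obs = _t_one_sample(diffs)
    observed = cluster_fn(t_obs, tcrit)

    rng = np.random.default_rng(seed)
    flat = diffs.reshape(n, -1)
    ss = np.sum(flat * flat, axis=0)
    null = np.empty(n_perm)
    shape = diffs.shape[1:]
    for i in range(n_perm):
        signs = rng.choice(np.array([-1.0, 1.0]), size=n)
        m = signs @ flat / n
        var = (ss - n * m * m) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_p = m / np.sqrt(var / n)
            t_p = np.where(var <= 0, np.where(np.abs(m) <= 1e-300, 0.0,
                                              np.sign(m) * np.inf), t_p)
        null[i] = _max_mass(cluster_fn(t_p.reshape(shape), tcrit))
    for c in observed:
        c.p = float((1 + np.sum(null >= abs(c.mass))) / (n_perm + 1))
    return observed, null, t_obs


def cluster_perm_tf(maps_a, maps_b, n_perm: int = 1000,
                    alpha_form: float = 0.05, alpha_cluster: float = 0.05,
                    seed: int = 0, connectivity: int = 4) -> ClusterResult:
    """Cluster-based permutation test on per-subject time-frequency maps.

    ``maps_a``/``maps_b`` are lists of ERSPMap (shared axes) or arrays of
    shape (n_subjects, n_freqs, n_times).  Clusters grow over the grid with
    4-connectivity by default (no diagonals), separately per t-sign.
    """
    arr_a = _stack_maps(maps_a)
    arr_b = _stack_maps(maps_b)
    if arr_a.shape != arr_b.shape:
        raise ValueError("conditions must have equal subjects and axes")
    structure = _STRUCT4 if connectivity == 4 else _STRUCT8
    diffs = arr_a - arr_b
    observed, null, t_obs = _perm_cluster(
        diffs, lambda t, c: _grid_clusters(t, c, structure),
        n_perm, alpha_form, alpha_cluster, seed)
    sig = np.zeros_like(t_obs)
    for c in observed:
        if c.p < alpha_cluster:
            sig.ravel()[c.bins] = t_obs.ravel()[c.bins]
    return ClusterResult(observed, null, sig, t_obs, alpha_form,
                         alpha_cluster, n_perm, seed)


def _stack_maps(maps) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        return np.asarray(maps, dtype=float)
    first = maps[0]
    if hasattr(first, "values") and hasattr(first, "freqs"):
        for m in maps[1:]:
            if (not np.allclose(m.freqs, first.freqs)
                    or not np.allclose(m.times, first.times)):
                raise ValueError("maps must share axes")
        return np.stack([m.values for m in maps])
    return np.asarray(maps, dtype=float)


def cluster_perm_channels(values_a: np.ndarray, values_b: np.ndarray,
                          adjacency: Adjacency, n_perm: int = 1000,
                          alpha_form: float = 0.05,
                          alpha_cluster: float = 0.05,
                          seed: int = 0,
                          labels: tuple[str, ...] | None = None
                          ) -> ClusterResult:
    """Cluster permutation test over electrodes on an adjacency graph.

    ``values_*`` are (n_subjects, n_electrodes) per-subject scalars in the
    order of ``labels`` (default: the adjacency's own label order).
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    labels = tuple(labels) if labels is not None else adjacency.labels
    missing = [l for l in labels if l not in adjacency.labels]
    if missing:
        raise KeyError(f"electrodes absent from adjacency: {missing}")
    order = [adjacency.labels.index(l) for l in labels]
    adj = adjacency.matrix[np.ix_(order, order)]
    if values_a.shape != values_b.shape or values_a.shape[1] != len(labels):
        raise ValueError("value arrays must be (n_subjects, n_electrodes)")
    diffs = values_a - values_b
    observed, null, t_obs = _perm_cluster(
        diffs, lambda t, c: _graph_clusters(t, c, adj),
        n_perm, alpha_form, alpha_cluster, seed)
    sig = np.zeros_like(t_obs)
    for c in observed:
        if c.p < alpha_cluster:
            sig[c.bins] = t_obs[c.bins]
    return ClusterResult(observed, null, sig, t_obs, alpha_form,
                         alpha_cluster, n_perm, seed, labels=labels)


def bonferroni_per_second(series_a: np.ndarray, series_b: np.ndarray,
                          times=None, alpha_family: float = 0.01
                          ) -> pd.DataFrame:
    """Paired t per second with Bonferroni correction across seconds.

    ``series_*`` are (n_subjects, n_seconds) aligned per-subject TBR
    values; corrected p = raw p x n_seconds, capped at 1.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("series must be aligned (n_subjects, n_seconds)")
    n_sec = a.shape[1]
    if times is None:
        times = np.arange(1, n_sec + 1, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.size != n_sec:
        raise ValueError("misaligned time stamps")
    rows = []
    for j in range(n_sec):
        try:
            t, df, p = paired_t(a[:, j], b[:, j])
        except ValueError:
            # zero-variance differences: no evidence either way
            t, df, p = np.nan, a.shape[0] - 1, 1.0
        p_corr = min(1.0, p * n_sec)
        rows.append(dict(time=times[j], t=t, df=df, p_raw=p,
                         p_corrected=p_corr,
                         significant=bool(p_corr < alpha_family)))
    return pd.DataFrame(rows)


def build_summary_table(indices, metrics: tuple[str, str] = ("erd", "ami")
                        ) -> pd.DataFrame:
    """Per-subject table with Mean, SDT (population SD), r and p rows.

    ``indices`` is a list of SubjectIndices (one per subject-condition).
    The r/p rows correlate the two metrics across subjects within each
    condition and are stored under the second metric's column; with a
    single subject they are reported absent (NaN).
    """
    met_a, met_b = metrics
    per_cond: dict[str, dict[str, list]] = {}
    subjects: list[str] = []
    for si in indices:
        d = per_cond.setdefault(si.condition, {met_a: [], met_b: [], "subject": []})
        va, vb = getattr(si, met_a), getattr(si, met_b)
        if va is None or vb is None:
            raise ValueError(f"missing {metrics} for subject {si.subject}")
        d[met_a].append(va)
        d[met_b].append(vb)
        d["subject"].append(si.subject)
        if si.subject not in subjects:
            subjects.append(si.subject)
    cols = []
    data = {}
    for cond in (ATTENTION, INATTENTION):
        if cond not in per_cond:
            continue
        d = per_cond[cond]
        if d["subject"] != subjects:
            raise ValueError("incomplete subject rows for " + cond)
        for met in metrics:
            vals = np.asarray(d[met], dtype=float)
            mean, sdt = summary_stats(vals)
            col = list(vals) + [mean, sdt, np.nan, np.nan]
            data[(cond, met.upper())] = col
            cols.append((cond, met.upper()))
        if len(subjects) >= 3:
            r, p = pearson_r(d[met_a], d[met_b])
            data[(cond, met_b.upper())][-2] = r
            data[(cond, met_b.upper())][-1] = p
    index = subjects + ["Mean", "SDT", "r", "p"]
    return pd.DataFrame(data, index=index,
                        columns=pd.MultiIndex.from_tuples(cols))
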