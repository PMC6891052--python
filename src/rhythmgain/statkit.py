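"""Shared nonparametric and parametric inference.

Cluster-based permutation tests control the family-wise error over time
(and, for the time-frequency variant, over channels and time-frequency
cells) without distributional assumptions: pointwise t statistics are
thresholded at the two-tailed critical value, contiguous supra-threshold
samples form clusters whose mass (sum of t) is compared with the null
distribution of maximal cluster masses under sign-flip permutation of the
per-subject series.  For paired designs the caller supplies condition
differences, making the sign-flip test the standard paired permutation
test.  Small samples (n <= 12) use the full enumeration of sign flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage, sparse, stats
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Cluster",
    "ClusterResult",
    "AnovaResult",
    "InfluenceCorrelation",
    "cluster_test_1d",
    "cluster_test_chan_tf",
    "rm_anova_2x4",
    "correlate_with_influence",
    "paired_t",
    "bonferroni_alpha",
    "channel_adjacency",
]

ENUMERATION_LIMIT = 12  # full sign-flip enumeration up to 2**12 permutations


@dataclass
class Cluster:
    indices: np.ndarray  # member indices (time, or (chan, freq, time) triples)
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold: float
    n_permutations: int
    null_max_mass: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)


def _sign_matrix(n: int, n_perm: int, seed: int) -> tuple[np.ndarray, bool]:
    """Sign-flip matrix: full enumeration when feasible, else Monte Carlo."""
    if n <= ENUMERATION_LIMIT:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        return signs, True
    rng = np.random.default_rng(seed)
    return rng.choice([1.0, -1.0], size=(n_perm, n)), False


def _t_stat(data: np.ndarray) -> np.ndarray:
    n = data.shape[0]
    m = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)


def _perm_t(data: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t maps for all sign-flip permutations, vectorised.

    ``data`` is (n, ...); returns (n_perm, ...).  Uses the identity that
    flipping whole subject series leaves per-point sums of squares intact.
    """
    n = data.shape[0]
    flat = data.reshape(n, -1)
    m = signs @ flat / n
    ssq = np.sum(flat**2, axis=0)
    var = (ssq[None, :] - n * m**2) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(var > 0, m / np.sqrt(var / n), 0.0)
    return t.reshape((signs.shape[0],) + data.shape[1:])


def _row_max_cluster_mass(t_rows: np.ndarray, thr: float) -> np.ndarray:
    """Max |cluster mass| per row of a (rows, time) t array (1-d clustering)."""
    n_rows = t_rows.shape[0]
    out = np.zeros(n_rows)
    structure = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]])
    for sign in (1.0, -1.0):
        mask = sign * t_rows > thr
        lab, n_lab = ndimage.label(mask, structure=structure)
        if n_lab == 0:
            continue
        sums = np.abs(ndimage.sum_labels(t_rows, lab, index=np.arange(1, n_lab + 1)))
        uniq, first = np.unique(lab.ravel(), return_index=True)
        keep = uniq > 0
        rows = first[keep] // t_rows.shape[1]
        np.maximum.at(out, rows, sums[uniq[keep] - 1])
    return out


def _clusters_1d(t: np.ndarray, thr: float) -> list[tuple[np.ndarray, float]]:
    found = []
    for sign in (1.0, -1.0):
        mask = sign * t > thr
        lab, n_lab = ndimage.label(mask)
        for k in range(1, n_lab + 1):
            idx = np.flatnonzero(lab == k)
            found.append((idx, float(t[idx].sum())))
    found.sort(key=lambda c: -abs(c[1]))
    return found


def cluster_test_1d(
    data: np.ndarray,
    kind: str = "one-sample",
    alpha_cluster: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test on subject x time data.

    ``kind='paired'`` documents that the rows are condition differences;
    the computation is identical to the one-sample test against zero.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be subjects x time")
    n = data.shape[0]
    if n < 5:
        raise ValueError("cluster test needs at least 5 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if kind not in ("one-sample", "paired"):
        raise ValueError(f"unknown test kind {kind!r}")
    thr = float(stats.t.ppf(1.0 - alpha_cluster / 2.0, n - 1))
    t_obs = _t_stat(data)
    observed = _clusters_1d(t_obs, thr)
    signs, enumerated = _sign_matrix(n, n_perm, seed)
    t_perm = _perm_t(data, signs)
    null_max = _row_max_cluster_mass(t_perm, thr)
    n_eff = signs.shape[0]
    clusters = []
    for idx, mass in observed:
        # relative tolerance so the identity permutation (and its sign
        # mirror) always count despite floating-point rounding
        count = int(np.sum(null_max >= abs(mass) * (1.0 - 1e-10)))
        p = count / n_eff if enumerated else (1 + count) / (1 + n_eff)
        p = max(p, 1.0 / n_eff)
        clusters.append(Cluster(indices=idx, mass=mass, p_value=float(min(p, 1.0))))
    return ClusterResult(
        clusters=clusters, threshold=thr, n_permutations=n_eff, null_max_mass=null_max
    )


# ---------------------------------------------------------------------------
# channel x time-frequency clustering
# ---------------------------------------------------------------------------


def channel_adjacency(positions: np.ndarray, factor: float = 1.3) -> np.ndarray:
    """Neighbourhood graph: channels within ``factor`` x median
    nearest-neighbour distance of each other."""
    pos = np.asarray(positions, dtype=float)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    radius = factor * np.median(d.min(axis=1))
    adj = d <= radius
    return adj


def _clusters_chan_tf(t: np.ndarray, thr: float, adjacency: np.ndarray):
    """Connected supra-threshold components over (chan, freq, time).

    Within a channel, cells are 4-connected on the freq x time grid; across
    channels, co-localised cells of adjacent channels connect.
    """
    n_c, n_f, n_t = t.shape
    found = []
    lin = np.arange(n_c * n_f * n_t).reshape(n_c, n_f, n_t)
    adj_pairs = np.argwhere(np.triu(adjacency, k=1))
    for sign in (1.0, -1.0):
        mask = sign * t > thr
        if not mask.any():
            continue
        edges_a, edges_b = [], []
        both = mask[:, :-1, :] & mask[:, 1:, :]
        edges_a.append(lin[:, :-1, :][both])
        edges_b.append(lin[:, 1:, :][both])
        both = mask[:, :, :-1] & mask[:, :, 1:]
        edges_a.append(lin[:, :, :-1][both])
        edges_b.append(lin[:, :, 1:][both])
        for ci, cj in adj_pairs:
            both = mask[ci] & mask[cj]
            edges_a.append(lin[ci][both])
            edges_b.append(lin[cj][both])
        nodes = lin[mask]
        a = np.concatenate(edges_a) if edges_a else np.array([], dtype=int)
        b = np.concatenate(edges_b) if edges_b else np.array([], dtype=int)
        n_nodes = n_c * n_f * n_t
        graph = sparse.coo_matrix(
            (np.ones(len(a) + len(nodes)), (np.concatenate([a, nodes]), np.concatenate([b, nodes]))),
            shape=(n_nodes, n_nodes),
        )
        n_comp, label = connected_components(graph, directed=False)
        flat_mask = mask.ravel()
        comp_of_node = label[flat_mask]
        tvals = t.ravel()[flat_mask]
        node_idx = np.flatnonzero(flat_mask)
        for comp in np.unique(comp_of_node):
            members = node_idx[comp_of_node == comp]
            mass = float(tvals[comp_of_node == comp].sum())
            found.append((members, mass))
    found.sort(key=lambda c: -abs(c[1]))
    return found


def cluster_test_chan_tf(
    data: np.ndarray,
    adjacency: np.ndarray,
    alpha_cluster: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster permutation test over subjects x channels x freq x time.

    Clusters span 4-connected time-frequency cells and, at co-localised
    cells, channels that are neighbours under ``adjacency``.  Channels with
    no neighbours form singleton-channel clusters.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("data must be subjects x channels x freqs x times")
    n = data.shape[0]
    if n < 5:
        raise ValueError("cluster test needs at least 5 subjects")
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != (data.shape[1], data.shape[1]):
        raise ValueError("adjacency must be n_channels x n_channels")
    thr = float(stats.t.ppf(1.0 - alpha_cluster / 2.0, n - 1))
    t_obs = _t_stat(data)
    observed = _clusters_chan_tf(t_obs, thr, adjacency)
    signs, enumerated = _sign_matrix(n, n_perm, seed)
    t_perm = _perm_t(data, signs)
    null_max = np.zeros(signs.shape[0])
    for k in range(signs.shape[0]):
        perm_clusters = _clusters_chan_tf(t_perm[k], thr, adjacency)
        if perm_clusters:
            null_max[k] = abs(perm_clusters[0][1])
    n_eff = signs.shape[0]
    clusters = []
    for idx, mass in observed:
        # relative tolerance so the identity permutation (and its sign
        # mirror) always count despite floating-point rounding
        count = int(np.sum(null_max >= abs(mass) * (1.0 - 1e-10)))
        p = count / n_eff if enumerated else (1 + count) / (1 + n_eff)
        p = max(p, 1.0 / n_eff)
        clusters.append(Cluster(indices=idx, mass=mass, p_value=float(min(p, 1.0))))
    return ClusterResult(
        clusters=clusters, threshold=thr, n_permutations=n_eff, null_max_mass=null_max
    )


# ---------------------------------------------------------------------------
# parametric helpers
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    """F tests of a 2 x 4 fully within-subject design."""

    effects: dict  # name -> (F, df1, df2, p)

    def __getitem__(self, name):
        return self.effects[name]


def rm_anova_2x4(values: np.ndarray) -> AnovaResult:
    """Repeated-measures ANOVA for a subjects x 2 x 4 within design.

    Tests the two main effects and their interaction, each against its own
    subject-interaction error term.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3 or y.shape[1] != 2 or y.shape[2] != 4:
        raise ValueError("values must be subjects x 2 x 4")
    if not np.all(np.isfinite(y)):
        raise ValueError("design contains missing cells")
    s, a, b = y.shape
    if s < 3:
        raise ValueError("need at least 3 subjects")
    gm = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)
    ss_a = s * b * np.sum((m_a - gm) ** 2)
    ss_b = s * a * np.sum((m_b - gm) ** 2)
    ss_ab = s * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + gm) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + gm) ** 2)
    resid = (
        y
        - m_ab[None, :, :]
        - m_as[:, :, None]
        - m_bs[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - gm
    )
    ss_abs = np.sum(resid**2)
    # rounding floor: sums of squares this small relative to the data are
    # numerically zero (e.g. per-subject-constant input)
    ss_floor = 1e-10 * max(np.sum((y - gm) ** 2), np.finfo(float).tiny)
    effects = {}
    for name, ss_eff, df1, ss_err, df_err in [
        ("condition", ss_a, a - 1, ss_as, (a - 1) * (s - 1)),
        ("frequency_class", ss_b, b - 1, ss_bs, (b - 1) * (s - 1)),
        ("interaction", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (s - 1)),
    ]:
        ms_eff = ss_eff / df1
        ms_err = ss_err / df_err
        if ss_err <= ss_floor:
            f, p = (0.0, 1.0) if ss_eff <= ss_floor else (np.inf, 0.0)
        else:
            f = ms_eff / ms_err
            p = float(stats.f.sf(f, df1, df_err))
        effects[name] = (float(f), int(df1), int(df_err), p)
    return AnovaResult(effects=effects)


@dataclass
class InfluenceCorrelation:
    r: float
    p: float
    r_excluded: float
    p_excluded: float
    excluded: np.ndarray  # indices of high-influence points


def correlate_with_influence(x: np.ndarray, y: np.ndarray) -> InfluenceCorrelation:
    """z-scored Pearson correlation with Cook's-distance screening.

    Points whose Cook's distance (from the y-on-x simple regression)
    exceeds the mean Cook's distance are excluded and the correlation is
    recomputed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples, n >= 4")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero variance input; correlation undefined")
    xz = (x - x.mean()) / x.std(ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    r, p = stats.pearsonr(xz, yz)
    n = len(xz)
    xc = xz - xz.mean()
    beta = np.sum(xc * yz) / np.sum(xc**2)
    resid = yz - (yz.mean() + beta * xc)
    h = 1.0 / n + xc**2 / np.sum(xc**2)
    n_params = 2
    mse = np.sum(resid**2) / (n - n_params)
    with np.errstate(invalid="ignore", divide="ignore"):
        cook = resid**2 * h / (n_params * mse * (1.0 - h) ** 2)
    excluded = np.flatnonzero(cook > cook.mean())
    keep = np.setdiff1d(np.arange(n), excluded)
    if len(keep) >= 3 and xz[keep].std() > 0 and yz[keep].std() > 0:
        r_ex, p_ex = stats.pearsonr(xz[keep], yz[keep])
    else:
        r_ex, p_ex = np.nan, np.nan
    return InfluenceCorrelation(
        r=float(r), p=float(p), r_excluded=float(r_ex), p_excluded=float(p_ex), excluded=excluded
    )


def paired_t(a, b) -> tuple[float, int, float]:
    """Paired t test; returns (t, df, two-tailed p).

    Zero-variance differences return an infinite-t sentinel (sign of the
    mean difference) with p = 0, or (0, df, 1) for identical inputs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t needs two equal-length samples, n >= 2")
    d = a - b
    df = len(d) - 1
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), df, float(p)


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted per-test alpha."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
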