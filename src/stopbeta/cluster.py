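"""Nonparametric cluster-based permutation tests for paired condition contrasts.

Generic over the sample space: 1-D frequency or time axes, 2-D
time-frequency grids (4-connectivity), or an arbitrary adjacency callback.
The test statistic per cluster is the summed paired t value; family-wise
control uses the max-statistic convention (each observed cluster mass is
compared against the permutation distribution of the maximum absolute
cluster mass).  The within-subject "random assignment" of conditions is
implemented as sign flips of the paired difference maps, which is exactly a
condition swap for a paired design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats


@dataclass
class Cluster:
    members: np.ndarray      # flat sample indices
    mass: float              # summed t values
    p_value: float


@dataclass
class ClusterResult:
    clusters: list = field(default_factory=list)
    significance_mask: np.ndarray | None = None
    n_permutations: int = 0
    alpha_cluster: float = 0.05
    alpha: float = 0.05
    tail: str = "two-sided"

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c.p_value <= self.alpha]


def dependent_t_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Paired t statistic per sample; a, b are (subjects, *grid).

    Samples undefined (NaN) for any subject are NaN in the output; zero
    difference variance gives +/-inf (degenerate, flagged by the caller) or
    NaN when the mean difference is also zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired maps must share the sample grid")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for a paired t map")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return t


def _label_clusters(mask: np.ndarray, adjacency):
    """Split a boolean supra-threshold mask into connected clusters.

    ``adjacency`` is '1d' (contiguous runs along the flattened axis),
    'grid' (4-connectivity on the mask's own shape), or a callable
    ``neighbors(i) -> iterable of flat indices``.
    """
    if callable(adjacency):
        flat = mask.ravel()
        seen = np.zeros(flat.size, dtype=bool)
        clusters = []
        for start in np.flatnonzero(flat):
            if seen[start]:
                continue
            stack = [start]
            seen[start] = True
            members = []
            while stack:
                i = stack.pop()
                members.append(i)
                for j in adjacency(i):
                    if flat[j] and not seen[j]:
                        seen[j] = True
                        stack.append(j)
            clusters.append(np.array(sorted(members)))
        return clusters
    if adjacency == "grid" and mask.ndim >= 2:
        structure = ndimage.generate_binary_structure(mask.ndim, 1)
        labels, n = ndimage.label(mask, structure=structure)
        flat = labels.ravel()
        return [np.flatnonzero(flat == k) for k in range(1, n + 1)]
    # 1-D contiguous runs
    flat = mask.ravel()
    clusters = []
    run = []
    for i, v in enumerate(flat):
        if v:
            run.append(i)
        elif run:
            clusters.append(np.array(run))
            run = []
    if run:
        clusters.append(np.array(run))
    return clusters


def _cluster_masses(t_flat: np.ndarray, thresh: float, adjacency, shape):
    """(members, mass) for every supra-threshold cluster, both signs."""
    out = []
    for sign in (1.0, -1.0):
        mask = (sign * t_flat > thresh) & np.isfinite(t_flat)
        for members in _label_clusters(mask.reshape(shape), adjacency):
            out.append((members, float(t_flat[members].sum())))
    return out


def cluster_permutation_test(a, b, adjacency="1d", alpha_cluster=0.05,
                             n_perm=5000, seed=0, alpha=0.05) -> ClusterResult:
    """Paired cluster permutation test of ``a`` vs ``b``.

    Parameters
    ----------
    a, b : arrays (subjects, *grid)
        Paired per-subject sample maps; ``b`` may be a scalar for a
        one-sample test against that constant.
    adjacency : '1d' | 'grid' | callable
        Neighborhood of the sample grid.
    alpha_cluster : float
        Two-sided cluster-forming threshold on the paired t map.
    alpha : float
        Significance level applied to cluster p values for the mask (set by
        the caller to include any Bonferroni correction).

    The null distribution is formed by within-subject condition swaps
    (sign flips of difference maps); cluster p values compare each observed
    mass against the permutation maximum |mass| (strictly-greater at ties
    resolved by >=, counting the observed partition once).
    """
    a = np.asarray(a, dtype=float)
    if np.isscalar(b) or np.ndim(b) == 0:
        b = np.full_like(a, float(b))
    b = np.asarray(b, dtype=float)
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    d = (a - b).reshape(n, -1)
    shape = a.shape[1:] if a.ndim > 1 else (a.shape[-1],)

    t_obs = dependent_t_map(a.reshape(n, -1), b.reshape(n, -1))
    thresh = stats.t.ppf(1.0 - alpha_cluster / 2.0, df=n - 1)
    observed = _cluster_masses(t_obs, thresh, adjacency, shape)

    result = ClusterResult(n_permutations=n_perm, alpha_cluster=alpha_cluster,
                           alpha=alpha, tail="two-sided")
    if not observed:
        result.significance_mask = np.zeros(shape, dtype=bool)
        return result

    rng = np.random.default_rng(seed)
    ss = np.nansum(d * d, axis=0)  # invariant under sign flips
    max_null = np.empty(n_perm)
    for p in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n)
        mean = (flips @ d) / n
        var = (ss - n * mean ** 2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = mean / np.sqrt(var / n)
        masses = _cluster_masses(t_perm, thresh, adjacency, shape)
        max_null[p] = max((abs(m) for _, m in masses), default=0.0)

    mask = np.zeros(int(np.prod(shape)), dtype=bool)
    for members, mass in observed:
        p_val = (1.0 + np.sum(max_null >= abs(mass))) / (n_perm + 1.0)
        result.clusters.append(Cluster(members=members, mass=mass,
                                       p_value=float(p_val)))
        if p_val <= alpha:
            mask[members] = True
    result.clusters.sort(key=lambda c: c.p_value)
    result.significance_mask = mask.reshape(shape)
    return result
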