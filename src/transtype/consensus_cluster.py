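"""Resampling-based consensus clustering with hierarchical base clustering.

For each of ``iterations`` rounds a random fraction of the samples is drawn
without replacement and clustered at every k in the requested range by
agglomerative clustering on Pearson distance (d = 1 - r between sample
profiles).  The consensus matrix entry (i, j) is the fraction of co-sampled
rounds in which i and j landed in the same cluster; the final partition at
each k cuts a hierarchical tree built on 1 - consensus with the same linkage.

Ward linkage is applied with the Pearson distances playing the role of the
squared Euclidean distances in the Lance-Williams recurrence (the classical
"ward.D" convention), since Ward on a non-Euclidean dissimilarity is
convention-dependent.  Average linkage is plain UPGMA.  Pearson correlations
use pairwise-complete observations; a sample pair sharing fewer than three
observed features is an error.

The per-k stability diagnostic is the area under the empirical CDF of the
off-diagonal consensus values, with the relative area increase from k-1 to k
flagging where additional clusters stop improving consensus.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .dataio import OmicsMatrix, ValidationError

logger = logging.getLogger(__name__)

MIN_SHARED_FEATURES = 3


@dataclass
class ClusterParams:
    k_min: int = 2
    k_max: int = 15
    iterations: int = 1000
    subsample_frac: float = 0.8
    linkage: str = "ward"
    distance: str = "pearson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValidationError("need 2 <= k_min <= k_max")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if not 0.0 < self.subsample_frac <= 1.0:
            raise ValidationError("subsample_frac must lie in (0, 1]")
        if self.linkage not in ("ward", "average"):
            raise ValidationError(f"unknown linkage {self.linkage!r}")
        if self.distance not in ("pearson", "euclidean"):
            raise ValidationError(f"unknown distance {self.distance!r}")


@dataclass
class ConsensusResult:
    """One k's consensus matrix, final labels, and stability diagnostics."""

    k: int
    consensus: pd.DataFrame
    labels: pd.Series  # sample_id -> 1..k
    cosample_counts: np.ndarray
    cdf_area: float
    delta_area: float = math.nan
    excluded: list[str] = field(default_factory=list)


def pearson_distance(data: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Sample x sample distance d = 1 - Pearson r between columns.

    Correlations are computed over features observed in both samples
    (pairwise-complete).  Constant sample profiles have undefined correlation
    and raise; so do pairs sharing fewer than three observed features.
    """
    df = pd.DataFrame(data) if not isinstance(data, pd.DataFrame) else data
    if df.shape[0] < 2:
        raise ValidationError("need >=2 features for correlation distance")
    obs = df.notna()
    sds = df.std(axis=0, ddof=0)
    constant = sds[(sds < 1e-15) | sds.isna()]
    if len(constant):
        raise ValidationError(
            f"constant sample profile(s), correlation undefined: "
            f"{list(constant.index)[:5]}"
        )
    if obs.all().all():
        x = df.to_numpy()
        r = np.corrcoef(x, rowvar=False)
    else:
        shared = obs.to_numpy().astype(int).T @ obs.to_numpy().astype(int)
        if (shared < MIN_SHARED_FEATURES).any():
            i, j = map(int, next(zip(*np.nonzero(shared < MIN_SHARED_FEATURES))))
            raise ValidationError(
                f"samples {df.columns[i]!r} and {df.columns[j]!r} share fewer "
                f"than {MIN_SHARED_FEATURES} observed features"
            )
        r = df.corr(method="pearson", min_periods=MIN_SHARED_FEATURES).to_numpy()
        if np.isnan(r).any():
            raise ValidationError("undefined pairwise correlation (constant overlap)")
    d = 1.0 - r
    np.clip(d, 0.0, 2.0, out=d)
    np.fill_diagonal(d, 0.0)
    return d


def _euclidean_distance(data: pd.DataFrame | np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import cdist

    x = pd.DataFrame(data).to_numpy().T
    return cdist(x, x)


def compute_distance(data: pd.DataFrame | np.ndarray, metric: str = "pearson") -> np.ndarray:
    if metric == "pearson":
        return pearson_distance(data)
    if metric == "euclidean":
        return _euclidean_distance(data)
    raise ValidationError(f"unknown distance {metric!r}")


def hier_cluster(distance: np.ndarray, linkage: str = "ward", k: int = 2) -> np.ndarray:
    """Cut an agglomerative tree on a precomputed distance matrix into k groups.

    Ward uses the Lance-Williams update with the supplied distances treated as
    squared (achieved by handing their square roots to the Euclidean-form Ward
    recurrence); average linkage is UPGMA.  Labels are 1..k, deterministic for
    a given input.
    """
    distance = np.asarray(distance, dtype=float)
    n = distance.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds number of samples {n}")
    if n == 1:
        return np.array([1])
    condensed = squareform(distance, checks=False)
    if linkage == "ward":
        z = scipy_linkage(np.sqrt(condensed), method="ward")
    elif linkage == "average":
        z = scipy_linkage(condensed, method="average")
    else:
        raise ValidationError(f"unknown linkage {linkage!r}")
    labels = cut_tree(z, n_clusters=k).ravel() + 1
    return labels


def consensus_cluster(
    matrix: OmicsMatrix | pd.DataFrame,
    params: ClusterParams,
) -> dict[int, ConsensusResult]:
    """Run resampled consensus clustering over k = k_min..k_max.

    Returns one :class:`ConsensusResult` per k.  The Pearson distance between
    two samples does not depend on which other samples were co-drawn, so the
    full distance matrix is computed once and sliced per iteration.
    """
    df = matrix.data if isinstance(matrix, OmicsMatrix) else pd.DataFrame(matrix)
    n = df.shape[1]
    if n < params.k_max + 1:
        raise ValidationError(
            f"need at least k_max+1={params.k_max + 1} samples, got {n}"
        )
    dist = compute_distance(df, params.distance)
    rng = np.random.default_rng(params.seed)
    m = int(math.ceil(params.subsample_frac * n))
    ks = range(params.k_min, params.k_max + 1)
    cocluster = {k: np.zeros((n, n)) for k in ks}
    cosample = np.zeros((n, n))
    for _ in range(params.iterations):
        if m == n:
            idx = np.arange(n)
        else:
            idx = np.sort(rng.choice(n, size=m, replace=False))
        cosample[np.ix_(idx, idx)] += 1
        sub = dist[np.ix_(idx, idx)]
        for k in ks:
            labels = hier_cluster(sub, params.linkage, k)
            same = labels[:, None] == labels[None, :]
            cocluster[k][np.ix_(idx, idx)] += same
    never = cosample == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn(
            f"{int(never.sum() // 2)} sample pair(s) never co-sampled; their "
            "consensus is reported as 0",
            stacklevel=2,
        )
    denom = np.where(cosample == 0, 1.0, cosample)
    samples = list(df.columns)
    results: dict[int, ConsensusResult] = {}
    prev_area = None
    for k in ks:
        cons = cocluster[k] / denom
        cons = (cons + cons.T) / 2.0
        np.fill_diagonal(cons, 1.0)
        final = hier_cluster(1.0 - cons, params.linkage, k)
        area = _cdf_area(cons)
        if prev_area is None:
            delta = area
        else:
            delta = (area - prev_area) / prev_area if prev_area > 0 else math.nan
        prev_area = area
        results[k] = ConsensusResult(
            k=k,
            consensus=pd.DataFrame(cons, index=samples, columns=samples),
            labels=pd.Series(final, index=samples, name="cluster"),
            cosample_counts=cosample.copy(),
            cdf_area=area,
            delta_area=delta,
        )
    return results


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus values.

    For values v_1..v_m in [0, 1] the area under the ECDF over [0, 1] equals
    mean(1 - v), which this uses directly.
    """
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = consensus[iu]
    if len(vals) == 0:
        return math.nan
    return float(np.mean(1.0 - vals))


def consensus_cdf_stats(results: dict[int, ConsensusResult]) -> pd.DataFrame:
    """Tabulate (k, cdf_area, delta_area) for a consensus run."""
    if len(results) < 2:
        raise ValidationError("need results for at least two values of k")
    rows = [
        {"k": k, "cdf_area": res.cdf_area, "delta_area": res.delta_area}
        for k, res in sorted(results.items())
    ]
    return pd.DataFrame(rows)
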