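"""Cluster-of-clusters analysis (COCA): integrating per-platform subtype calls.

Each platform's subtype calls are re-coded as binary indicator variables (one
row per platform:label pair, 1 iff the sample received that label) and the
resulting 0/1 matrix is consensus-clustered over samples, yielding integrated
subtypes that reconcile the platform-level partitions.  Samples missing a
platform get zeros across that platform's rows; a sample with no call on any
platform cannot be placed and is excluded with a warning.

Indicator rows that are constant across samples (a platform that gave
everyone the same label) carry no clustering information and would only
distort the correlation distance, so they are dropped before clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus_cluster import ClusterParams, ConsensusResult, consensus_cluster
from .dataio import ValidationError

DEFAULT_COCA_K = 9


@dataclass
class IndicatorMatrix:
    """Binary platform:subtype indicator variables (rows) x samples (columns)."""

    data: pd.DataFrame
    provenance: dict[str, tuple[str, str]]  # row id -> (platform, label)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("indicator entries must be 0 or 1")


def encode_indicators(calls: dict[str, dict[str, str]]) -> IndicatorMatrix:
    """Encode per-platform calls as a binary indicator matrix.

    Rows are named ``platform|label``; columns are the sorted union of all
    samples seen on any platform.  A sample missing from a platform gets 0
    across that platform's rows.
    """
    if not calls:
        raise ValidationError("no platform calls supplied")
    samples = sorted({s for platform_calls in calls.values() for s in platform_calls})
    if not samples:
        raise ValidationError("no samples in any platform's calls")
    rows: dict[str, list[int]] = {}
    provenance: dict[str, tuple[str, str]] = {}
    for platform in sorted(calls):
        platform_calls = calls[platform]
        labels = sorted(set(platform_calls.values()))
        for label in labels:
            row_id = f"{platform}|{label}"
            rows[row_id] = [
                1 if platform_calls.get(s) == label else 0 for s in samples
            ]
            provenance[row_id] = (platform, label)
    df = pd.DataFrame(rows, index=samples).T
    return IndicatorMatrix(data=df.astype(float), provenance=provenance)


def coca_cluster(
    ind: IndicatorMatrix,
    k: int = DEFAULT_COCA_K,
    params: ClusterParams | None = None,
) -> ConsensusResult:
    """Consensus-cluster the indicator matrix and return the k-group cut.

    Samples with no call on any platform (all-zero columns) are excluded with
    a warning and listed in ``result.excluded``.
    """
    params = params or ClusterParams(k_min=k, k_max=k)
    if not params.k_min <= k <= params.k_max:
        params = ClusterParams(
            k_min=min(k, params.k_min),
            k_max=max(k, params.k_max),
            iterations=params.iterations,
            subsample_frac=params.subsample_frac,
            linkage=params.linkage,
            distance=params.distance,
            seed=params.seed,
        )
    df = ind.data
    zero_cols = df.columns[(df.sum(axis=0) == 0)].tolist()
    if zero_cols:
        warnings.warn(
            f"excluding {len(zero_cols)} sample(s) with no platform call: "
            f"{zero_cols[:5]}",
            stacklevel=2,
        )
        df = df.drop(columns=zero_cols)
    const_rows = df.index[df.nunique(axis=1) <= 1].tolist()
    if const_rows:
        warnings.warn(
            f"dropping {len(const_rows)} uninformative constant indicator row(s)",
            stacklevel=2,
        )
        df = df.drop(index=const_rows)
    if df.shape[1] <= k:
        raise ValidationError(f"k={k} requires more than k samples with calls")
    results = consensus_cluster(df, params)
    result = results[k]
    result.excluded = zero_cols
    return result


def assign_subtype_names(labels: pd.Series) -> pd.Series:
    """Rename integer cluster ids to c1..ck in decreasing cluster-size order."""
    sizes = labels.value_counts()
    order = sorted(sizes.index, key=lambda lb: (-sizes[lb], lb))
    mapping = {lb: f"c{i + 1}" for i, lb in enumerate(order)}
    return labels.map(mapping).rename("subtype")
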