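"""Normalizations that strip lineage-dominant location/scale differences.

The central device of the pipeline: per feature, values are centered to the
median computed *within each lineage* and (optionally) scaled to that
lineage's standard deviation, so that the dominant tissue-of-origin signal is
removed and weaker cross-lineage structure can surface.  ``global_median_sd``
is the conventional whole-cohort comparator.

"Standard deviations from the median" is read as (x - median) / SD with SD the
usual sample standard deviation about the mean (n-1 denominator); medians of
even-sized groups use midpoint interpolation.  Constant features fall below
``sd_floor`` and map to zero rather than blowing up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import OmicsMatrix, ValidationError

logger = logging.getLogger(__name__)

MODES = ("median_sd", "median_only", "global_median_sd")


@dataclass
class NormalizationSpec:
    mode: str = "median_sd"
    log_transform: bool = False
    pseudocount: float = 1.0
    sd_floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown normalization mode {self.mode!r}")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        if self.sd_floor <= 0:
            raise ValidationError("sd_floor must be > 0")


def _center_block(block: np.ndarray, scale: bool, sd_floor: float) -> np.ndarray:
    """Center (and optionally scale) one feature x samples block, NaN-aware."""
    med = np.nanmedian(block, axis=1, keepdims=True)
    out = block - med
    if scale:
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(block, axis=1, ddof=1, keepdims=True)
        small = ~np.isfinite(sd) | (sd < sd_floor)
        if small.any():
            logger.debug("sd_floor hit for %d features", int(small.sum()))
        sd_safe = np.where(small, 1.0, sd)
        out = out / sd_safe
        out = np.where(np.broadcast_to(small, out.shape), np.where(np.isnan(out), np.nan, 0.0), out)
    return out


def center_within_lineage(matrix: OmicsMatrix, spec: NormalizationSpec | None = None) -> OmicsMatrix:
    """Center each feature to the per-lineage median (and SD, per ``spec.mode``).

    Missing values are ignored when computing the median/SD and stay missing.
    Feature and sample order are preserved.
    """
    spec = spec or NormalizationSpec()
    vals = matrix.data.to_numpy(copy=True)
    out = np.empty_like(vals)
    if spec.mode == "global_median_sd":
        out = _center_block(vals, scale=True, sd_floor=spec.sd_floor)
    else:
        scale = spec.mode == "median_sd"
        lineage = matrix.lineage.to_numpy()
        for lab in pd.unique(lineage):
            cols = np.flatnonzero(lineage == lab)
            if scale and len(cols) < 2:
                raise ValidationError(
                    f"lineage {lab!r} has {len(cols)} sample(s); median_sd needs >=2"
                )
            out[:, cols] = _center_block(vals[:, cols], scale=scale, sd_floor=spec.sd_floor)
    df = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return matrix.replace_values(df, normalized=True)


def log_transform(matrix: OmicsMatrix, pseudocount: float = 1.0) -> OmicsMatrix:
    """Elementwise log2(value + pseudocount); errors name the offending cell."""
    vals = matrix.data.to_numpy(copy=True)
    shifted = vals + pseudocount
    bad = np.nan_to_num(shifted, nan=1.0) <= 0
    if bad.any():
        r, c = map(int, next(zip(*np.nonzero(bad))))
        raise ValidationError(
            f"log2 of nonpositive value at feature {matrix.data.index[r]!r}, "
            f"sample {matrix.data.columns[c]!r}: {vals[r, c]} + {pseudocount}"
        )
    df = pd.DataFrame(
        np.log2(shifted), index=matrix.data.index, columns=matrix.data.columns
    )
    return matrix.replace_values(df, normalized=True)


def batch_adjust(matrix: OmicsMatrix, batch: dict[str, str] | pd.Series) -> OmicsMatrix:
    """Moment-matching batch adjustment (location/scale, not empirical-Bayes).

    Per feature, each batch's values are standardized to mean 0 / SD 1 and
    rescaled to the pooled feature mean and SD, which removes additive and
    multiplicative batch effects.  This is a plain moment-matching adjustment;
    it performs no shrinkage across features.
    """
    batch = pd.Series(dict(batch)) if not isinstance(batch, pd.Series) else batch
    missing = [s for s in matrix.sample_ids if s not in batch.index]
    if missing:
        raise ValidationError(f"samples without batch label: {missing[:5]}")
    batch = batch.loc[matrix.data.columns].to_numpy()
    vals = matrix.data.to_numpy(copy=True)
    pooled_mean = np.nanmean(vals, axis=1, keepdims=True)
    pooled_sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    out = np.empty_like(vals)
    for lab in pd.unique(batch):
        cols = np.flatnonzero(batch == lab)
        if len(cols) < 2:
            raise ValidationError(f"batch {lab!r} has fewer than 2 samples")
        block = vals[:, cols]
        bmean = np.nanmean(block, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            bsd = np.nanstd(block, axis=1, ddof=1, keepdims=True)
        const = ~np.isfinite(bsd) | (bsd < 1e-12)
        z = np.where(
            np.broadcast_to(const, block.shape), 0.0, (block - bmean) / np.where(const, 1.0, bsd)
        )
        out[:, cols] = pooled_mean + z * pooled_sd
    out = np.where(np.isnan(vals), np.nan, out)
    df = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return matrix.replace_values(df, normalized=True)
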