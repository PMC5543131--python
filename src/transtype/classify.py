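"""Nearest-centroid classification of external expression profiles.

A centroid per integrated subtype is the mean of the centered training values
over the classifier genes.  External profiles are first normalized per gene to
standard deviations from the median — across samples within each lineage by
default (whole-cohort mode for single-lineage sets) — and each profile is
assigned the candidate subtype whose centroid it correlates with most strongly
(Pearson).  A per-lineage candidate list restricts assignments to the subtypes
plausibly populated by that lineage.  Pearson correlation makes assignments
invariant to per-sample positive affine transformations of the profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import OmicsMatrix, ValidationError

#: Assignments whose best correlation falls below this may be flagged.
LOW_CONFIDENCE_R = 0.1


@dataclass
class CentroidSet:
    """Classifier gene list and per-subtype mean (centroid) expression."""

    genes: list[str]
    centroids: pd.DataFrame  # genes x subtypes
    sizes: dict[str, int]

    def __post_init__(self) -> None:
        if list(self.centroids.index) != list(self.genes):
            raise ValidationError("centroid rows must match the gene list")
        small = {st: n for st, n in self.sizes.items() if n < 2}
        if small:
            raise ValidationError(f"subtypes with <2 training samples: {small}")


def build_centroids(
    matrix: OmicsMatrix,
    labels: dict[str, str] | pd.Series,
    genes: list[str],
) -> CentroidSet:
    """Mean centered expression per gene, per subtype, over member samples."""
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    missing = [g for g in genes if g not in matrix.data.index]
    if missing:
        raise ValidationError(f"classifier genes not in matrix: {missing[:10]}")
    common = [s for s in matrix.sample_ids if s in labels.index]
    lab = labels.loc[common]
    subtypes = sorted(lab.unique())
    if len(subtypes) < 2:
        warnings.warn(
            "centroid set built from a single subtype; classification against "
            "it is degenerate",
            stacklevel=2,
        )
    data = matrix.data.loc[genes, common]
    cents = {}
    sizes = {}
    for st in subtypes:
        members = lab.index[lab == st]
        sizes[st] = len(members)
        cents[st] = data[members].mean(axis=1, skipna=True)
    return CentroidSet(genes=list(genes), centroids=pd.DataFrame(cents), sizes=sizes)


def _center_to_sd_from_median(df: pd.DataFrame) -> pd.DataFrame:
    med = df.median(axis=1)
    sd = df.std(axis=1, ddof=1)
    sd = sd.where(sd > 1e-12, 1.0)
    out = df.sub(med, axis=0).div(sd, axis=0)
    return out


def classify_profiles(
    external: OmicsMatrix,
    centroids: CentroidSet,
    candidates: dict[str, list[str]] | None = None,
    center_mode: str = "within_lineage",
) -> pd.DataFrame:
    """Assign each external profile to its best-correlated candidate centroid.

    External values are centered per gene to (x - median)/SD across samples —
    within each lineage by default, or across the whole cohort
    (``center_mode='cohort'``, appropriate for single-lineage sets).  Per
    sample, the Pearson correlation with each candidate centroid is computed
    over the shared classifier genes and the argmax among that sample's
    lineage candidates wins; ties go to the first candidate in declared order
    and are flagged.

    Returns a table with columns ``lineage``, ``assigned``, ``best_r``,
    ``tie``, ``low_confidence`` plus one ``r_<subtype>`` column per centroid.
    """
    if center_mode not in ("within_lineage", "cohort"):
        raise ValidationError(f"unknown center_mode {center_mode!r}")
    shared = [g for g in centroids.genes if g in external.data.index]
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} classifier genes shared with the external "
            "matrix; need >=3"
        )
    subtypes = list(centroids.centroids.columns)
    if candidates is None:
        candidates = {lab: subtypes for lab in external.lineage.unique()}
    for lab in external.lineage.unique():
        if lab not in candidates:
            raise ValidationError(f"no candidate subtype list for lineage {lab!r}")
        unknown = [c for c in candidates[lab] if c not in subtypes]
        if unknown:
            raise ValidationError(
                f"candidates for lineage {lab!r} not in centroid set: {unknown}"
            )

    # Standardize each external profile across genes first.  The final
    # correlation is already location/scale-free per profile, but the per-gene
    # median/SD statistics below are not; standardizing first makes the whole
    # procedure exactly invariant to positive affine transforms of any single
    # profile (scanner gain/offset differences between external arrays).
    ext = external.data.loc[shared]
    mu = ext.mean(axis=0)
    sd = ext.std(axis=0, ddof=0).replace(0.0, 1.0)
    ext = ext.sub(mu, axis=1).div(sd, axis=1)
    if center_mode == "cohort" or external.lineage.nunique() == 1:
        centered = _center_to_sd_from_median(ext)
    else:
        centered = ext.copy()
        for lab in external.lineage.unique():
            cols = external.lineage.index[external.lineage == lab]
            centered[cols] = _center_to_sd_from_median(ext[cols])

    cent = centroids.centroids.loc[shared]

    def _zcols(df: pd.DataFrame) -> np.ndarray:
        x = df.to_numpy()
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        sd = np.where(sd < 1e-15, 1.0, sd)
        return (x - mu) / sd

    r = _zcols(centered).T @ _zcols(cent) / len(shared)
    r = pd.DataFrame(r, index=centered.columns, columns=subtypes)

    rows = []
    for sample in centered.columns:
        lab = external.lineage[sample]
        cand = candidates[lab]
        cand_r = r.loc[sample, cand]
        best = float(cand_r.max())
        winners = [c for c in cand if np.isclose(cand_r[c], best, rtol=0, atol=1e-15)]
        assigned = winners[0]
        row = {
            "sample_id": sample,
            "lineage": lab,
            "assigned": assigned,
            "best_r": best,
            "tie": len(winners) > 1,
            "low_confidence": best < LOW_CONFIDENCE_R,
        }
        for st in subtypes:
            row[f"r_{st}"] = float(r.loc[sample, st]) if st in cand else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
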