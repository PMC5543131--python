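"""Feature ranking by cross-lineage average variability.

A feature's score is the mean over lineages of its per-lineage standard
deviation, so a gene must vary *within* several tissues to rank highly —
a gene that merely differs in level between tissues scores no better than a
flat one.  The top-N cut mirrors the per-platform conventions used for
TCGA-style data: 2000 genes for mRNA and methylation, 500 for miRNA, all
features for protein arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import OmicsMatrix, ValidationError

DEFAULT_TOP_N = {
    "mrna": 2000,
    "methylation": 2000,
    "mirna": 500,
    "protein": None,  # all features
    "copynumber": None,
    "mutation": None,
}


@dataclass
class FeatureRanking:
    """Features ordered by descending average within-lineage SD."""

    feature_ids: list[str]
    scores: pd.Series  # indexed by feature_id, non-increasing in the order above

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.feature_ids, "score": self.scores.to_numpy()})


def top_variable_features(
    matrix: OmicsMatrix,
    n: int | None,
    use_log: bool = False,
    pseudocount: float = 1.0,
) -> FeatureRanking:
    """Rank features by mean per-lineage SD and keep the top ``n``.

    With ``use_log`` the SDs are computed on log2(value + pseudocount), the
    usual choice for count-like expression data.  Lineages where a feature has
    fewer than 2 observed values are omitted from that feature's mean.  Ties
    are broken by feature id (lexicographic) for determinism.  ``n=None``
    returns all features ranked.
    """
    if n is not None and n < 1:
        raise ValidationError("n must be >= 1")
    vals = matrix.data.to_numpy(copy=True)
    if use_log:
        shifted = vals + pseudocount
        if np.nanmin(shifted) <= 0:
            raise ValidationError("log ranking requires value + pseudocount > 0")
        vals = np.log2(shifted)
    lineage = matrix.lineage.to_numpy()
    per_lineage_sd = []
    for lab in pd.unique(lineage):
        cols = np.flatnonzero(lineage == lab)
        block = vals[:, cols]
        n_obs = (~np.isnan(block)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(block, axis=1, ddof=1)
        sd[n_obs < 2] = np.nan
        per_lineage_sd.append(sd)
    with np.errstate(invalid="ignore"):
        score = np.nanmean(np.column_stack(per_lineage_sd), axis=1)
    score = np.nan_to_num(score, nan=0.0)
    order = sorted(
        range(len(score)),
        key=lambda i: (-score[i], str(matrix.data.index[i])),
    )
    if n is not None:
        order = order[: min(n, len(order))]
    ids = [matrix.data.index[i] for i in order]
    return FeatureRanking(
        feature_ids=ids,
        scores=pd.Series([score[i] for i in order], index=ids, name="score"),
    )


def restrict(matrix: OmicsMatrix, feature_ids: list[str]) -> OmicsMatrix:
    """Row-subset the matrix to ``feature_ids`` in the given order."""
    missing = [f for f in feature_ids if f not in matrix.data.index]
    if missing:
        raise ValidationError(f"features not in matrix: {missing[:10]}")
    return matrix.replace_values(matrix.data.loc[feature_ids])
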