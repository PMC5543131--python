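"""Subtype characterization: differential features and signature scoring.

All scores assume expression values already normalized within lineage
(standard deviations from the per-lineage median), so that a signature score
compares a sample against its own tissue background rather than against other
tissues.

Scoring modes
-------------
mean
    Average of the normalized values over the signature's (up) genes.
tscore
    Per sample, the Welch two-sample t-statistic contrasting the sample's
    up-gene values against its down-gene values; positive when the up genes
    dominate.
sumdiff
    Sum of up-gene values minus sum of down-gene values (the EMT convention).

The epithelial-mesenchymal transition (EMT) score uses a fixed 14-gene
mesenchymal / 3-gene epithelial marker panel; the proteomic MAPK signature is
the mean of nine phospho-protein features.  Both member lists ship with the
package; every other signature arrives via GMT.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import GeneSignature, OmicsMatrix, ValidationError

logger = logging.getLogger(__name__)

#: Mesenchymal marker genes (score contributes positively).
EMT_MESENCHYMAL = (
    "ZEB1", "CDH2", "FN1", "FOXC2", "GSC", "ITGB6", "MMP2", "MMP3", "MMP9",
    "SNAI1", "SNAI2", "SOX10", "TWIST1", "VIM",
)
#: Epithelial marker genes (score contributes negatively).
EMT_EPITHELIAL = ("CDH1", "DSP", "OCLN")

#: Phospho-protein features averaged into the proteomic MAPK signature.
RPPA_MAPK_PROTEINS = (
    "pSHC", "pRAF", "pMEK", "pERK", "pSRK", "pYB1", "pP38", "pJNK", "pJUN",
)


def emt_signature() -> GeneSignature:
    return GeneSignature(
        name="EMT",
        up_genes=list(EMT_MESENCHYMAL),
        down_genes=list(EMT_EPITHELIAL),
        mode="sumdiff",
    )


def mapk_protein_signature() -> GeneSignature:
    return GeneSignature(
        name="MAPK_protein", up_genes=list(RPPA_MAPK_PROTEINS), mode="mean"
    )


@dataclass
class ScoreVector:
    """Per-sample scores for one signature, with gene-coverage metadata."""

    name: str
    mode: str
    values: pd.Series
    coverage: float  # fraction of the signature's genes present in the matrix


@dataclass
class DifferentialResult:
    """Per-subtype differential features and the pooled classifier gene list."""

    per_subtype: dict[str, pd.DataFrame]
    classifier_genes: list[str]


# -- differential testing -----------------------------------------------------


def differential_features(
    matrix: OmicsMatrix,
    labels: dict[str, str] | pd.Series,
    top_n: int = 100,
) -> DifferentialResult:
    """One-vs-rest Welch t-test per feature, per subtype.

    Per subtype the ``top_n`` features with the lowest p-value are retained
    (ties broken by descending |t|, then feature id); the classifier gene list
    concatenates the per-subtype lists in subtype order and removes duplicates
    keeping first occurrence, so it can be shorter than
    ``top_n * n_subtypes``.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    common = [s for s in matrix.sample_ids if s in labels.index]
    if len(common) < 4:
        raise ValidationError("need at least 4 labeled samples")
    data = matrix.data[common]
    lab = labels.loc[common]
    subtypes = sorted(lab.unique())
    per_subtype: dict[str, pd.DataFrame] = {}
    for st in subtypes:
        in_mask = (lab == st).to_numpy()
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        if n_in < 2 or n_out < 2:
            raise ValidationError(
                f"subtype {st!r} needs >=2 members and >=2 non-members "
                f"(got {n_in}/{n_out})"
            )
        x = data.to_numpy()[:, in_mask]
        y = data.to_numpy()[:, ~in_mask]
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(x, y, axis=1, equal_var=False, nan_policy="omit")
        t = np.asarray(t, dtype=float)
        p = np.asarray(p, dtype=float)
        # A feature identical inside and outside the subtype is uninformative:
        # t = 0, p = 1, ranked last.
        degenerate = ~np.isfinite(t)
        t[degenerate] = 0.0
        p[degenerate] = 1.0
        table = pd.DataFrame(
            {
                "feature": data.index,
                "t_statistic": t,
                "p_value": p,
                "mean_in": np.nanmean(x, axis=1),
                "mean_out": np.nanmean(y, axis=1),
            }
        )
        table = table.sort_values(
            by=["p_value", "t_statistic", "feature"],
            ascending=[True, True, True],
            key=lambda col: -col.abs() if col.name == "t_statistic" else col,
        ).reset_index(drop=True)
        per_subtype[st] = table.head(min(top_n, len(table)))
    classifier: list[str] = []
    seen: set[str] = set()
    for st in subtypes:
        for feat in per_subtype[st]["feature"]:
            if feat not in seen:
                seen.add(feat)
                classifier.append(feat)
    logger.info(
        "classifier gene list: %d unique of %d slots",
        len(classifier),
        top_n * len(subtypes),
    )
    return DifferentialResult(per_subtype=per_subtype, classifier_genes=classifier)


# -- signature scoring --------------------------------------------------------


def _present(matrix: OmicsMatrix, genes: list[str]) -> list[str]:
    idx = set(matrix.data.index)
    return [g for g in genes if g in idx]


def mean_signature_score(matrix: OmicsMatrix, sig: GeneSignature) -> ScoreVector:
    """Per sample, the mean normalized value over the signature's up genes."""
    present = _present(matrix, sig.up_genes)
    if not present:
        raise ValidationError(f"no genes of signature {sig.name!r} in matrix")
    missing = sorted(set(sig.up_genes) - set(present))
    if missing:
        logger.info("signature %s: %d gene(s) absent: %s", sig.name, len(missing), missing[:5])
    values = matrix.data.loc[present].mean(axis=0, skipna=True)
    return ScoreVector(
        name=sig.name,
        mode="mean",
        values=values.rename(sig.name),
        coverage=len(present) / len(sig.up_genes),
    )


def t_score(matrix: OmicsMatrix, sig: GeneSignature) -> ScoreVector:
    """Per sample, Welch t-statistic of up-gene values vs down-gene values.

    Positive when the sample's up genes exceed its down genes.  A sample in
    which both gene groups are constant has an undefined statistic and scores
    0 (with a warning) rather than +/-inf.
    """
    up = _present(matrix, sig.up_genes)
    dn = _present(matrix, sig.down_genes)
    if len(up) < 2 or len(dn) < 2:
        raise ValidationError(
            f"signature {sig.name!r}: need >=2 up and >=2 down genes present "
            f"(got {len(up)}/{len(dn)})"
        )
    xu = matrix.data.loc[up].to_numpy()
    xd = matrix.data.loc[dn].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, _ = stats.ttest_ind(xu, xd, axis=0, equal_var=False, nan_policy="omit")
    t = np.asarray(t, dtype=float)
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn(
            f"signature {sig.name}: {int(bad.sum())} sample(s) with degenerate "
            "t-score set to 0",
            stacklevel=2,
        )
        t[bad] = 0.0
    n_total = len(sig.up_genes) + len(sig.down_genes)
    return ScoreVector(
        name=sig.name,
        mode="tscore",
        values=pd.Series(t, index=matrix.data.columns, name=sig.name),
        coverage=(len(up) + len(dn)) / n_total,
    )


def emt_score(matrix: OmicsMatrix) -> ScoreVector:
    """Sum of mesenchymal marker values minus sum of epithelial marker values."""
    sig = emt_signature()
    mes = _present(matrix, sig.up_genes)
    epi = _present(matrix, sig.down_genes)
    if not mes or not epi:
        raise ValidationError(
            "EMT score requires at least one mesenchymal and one epithelial "
            "marker in the matrix"
        )
    score = matrix.data.loc[mes].sum(axis=0, skipna=True) - matrix.data.loc[epi].sum(
        axis=0, skipna=True
    )
    return ScoreVector(
        name="EMT",
        mode="sumdiff",
        values=score.rename("EMT"),
        coverage=(len(mes) + len(epi)) / (len(sig.up_genes) + len(sig.down_genes)),
    )


def score_signature(matrix: OmicsMatrix, sig: GeneSignature) -> ScoreVector:
    """Dispatch on the signature's scoring mode."""
    if sig.mode == "mean":
        return mean_signature_score(matrix, sig)
    if sig.mode == "tscore":
        return t_score(matrix, sig)
    if sig.mode == "sumdiff":
        present_up = _present(matrix, sig.up_genes)
        present_dn = _present(matrix, sig.down_genes)
        if not present_up or not present_dn:
            raise ValidationError(f"signature {sig.name!r}: both gene groups required")
        vals = matrix.data.loc[present_up].sum(axis=0, skipna=True) - matrix.data.loc[
            present_dn
        ].sum(axis=0, skipna=True)
        return ScoreVector(
            name=sig.name,
            mode="sumdiff",
            values=vals.rename(sig.name),
            coverage=(len(present_up) + len(present_dn))
            / (len(sig.up_genes) + len(sig.down_genes)),
        )
    raise ValidationError(f"unknown mode {sig.mode!r}")


def score_table(matrix: OmicsMatrix, sigs: list[GeneSignature]) -> pd.DataFrame:
    """Samples x signatures score table (long-format metadata in attrs)."""
    vectors = [score_signature(matrix, s) for s in sigs]
    table = pd.concat([v.values for v in vectors], axis=1)
    table.attrs["coverage"] = {v.name: v.coverage for v in vectors}
    table.attrs["mode"] = {v.name: v.mode for v in vectors}
    return table


def summary_score(scores: list[pd.Series]) -> pd.Series:
    """Average of median/SD-normalized score vectors (pathway summary score).

    Each input vector is normalized across samples to standard deviations
    from the median, then the normalized vectors are averaged per sample.  A
    constant vector contributes 0 after normalization (warned).
    """
    if len(scores) < 2:
        raise ValidationError("summary score needs >=2 component score vectors")
    index = scores[0].index
    for s in scores[1:]:
        if not s.index.equals(index):
            raise ValidationError("score vectors cover different samples")
    normed = []
    for s in scores:
        sd = s.std(ddof=1)
        if not np.isfinite(sd) or sd < 1e-12:
            warnings.warn(
                f"constant score vector {s.name!r} contributes 0 to summary",
                stacklevel=2,
            )
            normed.append(pd.Series(0.0, index=index))
        else:
            normed.append((s - s.median()) / sd)
    return pd.concat(normed, axis=1).mean(axis=1).rename("summary")


# -- methylation summaries ----------------------------------------------------


def methylation_index(matrix: OmicsMatrix, threshold: float = 0.3) -> pd.Series:
    """Per sample, fraction of probes with beta strictly above ``threshold``.

    Computed over non-missing probes only; a sample with no observed probe is
    an error.  The strict inequality means a beta exactly at the threshold
    does not count as methylated.
    """
    vals = matrix.data.to_numpy()
    observed = (~np.isnan(vals)).sum(axis=0)
    if (observed == 0).any():
        bad = [c for c, o in zip(matrix.data.columns, observed) if o == 0]
        raise ValidationError(f"all probes missing for sample(s): {bad[:5]}")
    count = np.nansum(vals > threshold, axis=0)
    return pd.Series(
        count / observed, index=matrix.data.columns, name="methylation_index"
    )


def silencing_call(
    matrix: OmicsMatrix, probe_id: str, threshold: float = 0.2
) -> pd.Series:
    """Epigenetic-silencing call: beta at or above ``threshold`` (inclusive).

    Missing betas yield missing calls (pandas nullable boolean).
    """
    if probe_id not in matrix.data.index:
        raise ValidationError(f"probe {probe_id!r} not in matrix")
    betas = matrix.data.loc[probe_id]
    calls = pd.Series(pd.NA, index=betas.index, dtype="boolean", name=probe_id)
    obs = betas.notna()
    calls[obs] = betas[obs] >= threshold
    return calls


# -- reference-profile similarity ---------------------------------------------


def reference_similarity(
    tumor_matrix: OmicsMatrix,
    tumor_labels: dict[str, str] | pd.Series,
    reference_matrix: pd.DataFrame,
    reference_groups: dict[str, str] | pd.Series,
) -> pd.DataFrame:
    """Summarize tumor-subtype similarity to reference cell/tissue profiles.

    Reference profiles are median-centered per gene across reference samples;
    each reference profile in a group is Pearson-correlated with each tumor
    profile in a subtype over the shared genes, and the cell value is the
    one-sample t-statistic of those correlations against zero.  Cells with
    fewer than two correlation values are reported missing.
    """
    tumor_labels = (
        pd.Series(dict(tumor_labels))
        if not isinstance(tumor_labels, pd.Series)
        else tumor_labels
    )
    reference_groups = (
        pd.Series(dict(reference_groups))
        if not isinstance(reference_groups, pd.Series)
        else reference_groups
    )
    shared = [g for g in tumor_matrix.data.index if g in reference_matrix.index]
    if len(shared) < 3:
        raise ValidationError("need >=3 genes shared with the reference matrix")
    ref = reference_matrix.loc[shared]
    ref = ref.sub(ref.median(axis=1), axis=0)
    tum = tumor_matrix.data.loc[shared]
    groups = sorted(reference_groups.unique())
    subtypes = sorted(tumor_labels.unique())
    # r[i, j] between reference column i and tumor column j over shared genes
    refz = (ref - ref.mean(axis=0)) / ref.std(axis=0, ddof=0)
    tumz = (tum - tum.mean(axis=0)) / tum.std(axis=0, ddof=0)
    r = refz.to_numpy().T @ tumz.to_numpy() / len(shared)
    r = pd.DataFrame(r, index=ref.columns, columns=tum.columns)
    out = pd.DataFrame(index=groups, columns=subtypes, dtype=float)
    for g in groups:
        ref_cols = reference_groups.index[reference_groups == g]
        ref_cols = [c for c in ref_cols if c in r.index]
        for st in subtypes:
            tum_cols = tumor_labels.index[tumor_labels == st]
            tum_cols = [c for c in tum_cols if c in r.columns]
            vals = r.loc[ref_cols, tum_cols].to_numpy().ravel()
            vals = vals[np.isfinite(vals)]
            if len(vals) < 2:
                out.loc[g, st] = np.nan
                continue
            t, _ = stats.ttest_1samp(vals, 0.0)
            out.loc[g, st] = float(t)
    return out


# -- pathway alteration aggregation -------------------------------------------

GENE_ROLES = ("oncogene", "tumor_suppressor", "always_nonsilent")


def pathway_alteration_matrix(
    variants: pd.DataFrame,
    copynumber: OmicsMatrix | None,
    pathway_map: dict[str, list[str]],
    gene_roles: dict[str, str],
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Aggregate gene-level alterations into per-sample pathway calls.

    A gene counts as altered in a sample when:

    * oncogene — a hotspot-flagged nonsilent variant, or a +2 (high-level)
      amplification;
    * tumor_suppressor — any nonsilent variant, or a -2 (deep) deletion;
    * always_nonsilent — any nonsilent variant (the convention for receptor
      kinases whose activating mutations are not confined to hotspots).

    ``variants`` needs columns ``sample``, ``gene``, ``hotspot`` (bool) and
    optionally ``silent`` (bool; silent rows are ignored).  A pathway is
    altered when any member gene is; fractions are over the supplied sample
    universe (default: samples seen in the variant table or copy matrix).
    """
    if not pathway_map:
        raise ValidationError("empty pathway map")
    for pw, genes in pathway_map.items():
        for g in genes:
            if g not in gene_roles:
                raise ValidationError(f"gene {g!r} in pathway {pw!r} lacks a role")
            if gene_roles[g] not in GENE_ROLES:
                raise ValidationError(f"unknown role {gene_roles[g]!r} for gene {g!r}")
    var = variants.copy()
    required = {"sample", "gene", "hotspot"}
    if not required.issubset(var.columns):
        raise ValidationError(f"variant table needs columns {sorted(required)}")
    if "silent" in var.columns:
        var = var[~var["silent"].astype(bool)]
    if samples is None:
        universe = set(var["sample"])
        if copynumber is not None:
            universe |= set(copynumber.sample_ids)
        samples = sorted(universe)
    if not samples:
        raise ValidationError("no samples with mutation data")

    mutated = set(zip(var["sample"], var["gene"]))
    hotspot = set(
        zip(var.loc[var["hotspot"].astype(bool), "sample"],
            var.loc[var["hotspot"].astype(bool), "gene"])
    )

    def gene_altered(gene: str, sample: str) -> bool:
        role = gene_roles[gene]
        cn = 0.0
        if (
            copynumber is not None
            and gene in copynumber.data.index
            and sample in copynumber.data.columns
        ):
            cn = copynumber.data.at[gene, sample]
        if role == "oncogene":
            return (sample, gene) in hotspot or cn == 2
        if role == "tumor_suppressor":
            return (sample, gene) in mutated or cn == -2
        return (sample, gene) in mutated

    altered = pd.DataFrame(False, index=sorted(pathway_map), columns=samples)
    for pw, genes in pathway_map.items():
        for s in samples:
            altered.at[pw, s] = any(gene_altered(g, s) for g in genes)
    fractions = altered.mean(axis=1).rename("altered_fraction")
    return altered, fractions
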