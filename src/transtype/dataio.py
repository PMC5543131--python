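"""Shared data model and plain-text I/O.

Every platform matrix in the pipeline is features-in-rows, samples-in-columns,
tab-separated text.  The header row holds sample identifiers, the first column
holds feature identifiers, and missing values are written as the literal token
``NA`` (matched case-insensitively on read).  Empty cells and any other
non-numeric token are format errors rather than silently coerced missings.

The :class:`OmicsMatrix` container enforces the per-platform value ranges
(beta values in [0, 1] for methylation, thresholded integer calls in
{-2..2} for copy number, {0, 1} for mutation indicators) on raw data.  After
normalization those ranges no longer apply, which the ``normalized`` flag
records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

PLATFORMS = ("mrna", "mirna", "protein", "methylation", "copynumber", "mutation")

#: Platforms carrying continuous expression-like values.
CONTINUOUS_PLATFORMS = ("mrna", "mirna", "protein")


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Parsed data violate a platform invariant."""


@dataclass
class OmicsMatrix:
    """One platform's feature x sample matrix with per-sample lineage labels.

    Parameters
    ----------
    platform_id:
        One of :data:`PLATFORMS`.
    data:
        Features-in-rows DataFrame; index = feature ids, columns = sample ids.
    lineage:
        Series mapping every sample id to its lineage (tissue-of-origin) label.
    normalized:
        True once the values have been centered/scaled; relaxes the raw-scale
        range invariants.
    """

    platform_id: str
    data: pd.DataFrame
    lineage: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.platform_id not in PLATFORMS:
            raise ValidationError(
                f"unknown platform {self.platform_id!r}; expected one of {PLATFORMS}"
            )
        if not isinstance(self.lineage, pd.Series):
            self.lineage = pd.Series(dict(self.lineage))
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        missing_lineage = [s for s in self.data.columns if s not in self.lineage.index]
        if missing_lineage:
            raise ValidationError(
                f"samples without lineage label: {missing_lineage[:5]}"
            )
        self.lineage = self.lineage.reindex(self.data.columns)
        self.data = self.data.astype(float)
        if not self.normalized:
            self._check_ranges()

    def _check_ranges(self) -> None:
        vals = self.data.to_numpy()
        finite = ~np.isnan(vals)
        if self.platform_id == "methylation":
            bad = finite & ((vals < 0.0) | (vals > 1.0))
            if bad.any():
                r, c = map(int, next(zip(*np.nonzero(bad))))
                raise ValidationError(
                    "methylation beta outside [0, 1] at feature "
                    f"{self.data.index[r]!r}, sample {self.data.columns[c]!r}"
                )
        elif self.platform_id == "copynumber":
            ok = np.isin(vals[finite], (-2.0, -1.0, 0.0, 1.0, 2.0))
            if not ok.all():
                raise ValidationError(
                    "copy-number calls must be integers in {-2..2}"
                )
        elif self.platform_id == "mutation":
            ok = np.isin(vals[finite], (0.0, 1.0))
            if not ok.all():
                raise ValidationError("mutation indicators must be 0 or 1")

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def replace_values(self, data: pd.DataFrame, *, normalized: bool | None = None) -> "OmicsMatrix":
        """Return a copy of this matrix with new values (same samples)."""
        return OmicsMatrix(
            platform_id=self.platform_id,
            data=data,
            lineage=self.lineage.loc[data.columns],
            normalized=self.normalized if normalized is None else normalized,
        )


@dataclass
class GeneSignature:
    """A named gene set with up-regulated members and optional down members."""

    name: str
    up_genes: list[str]
    down_genes: list[str] = field(default_factory=list)
    mode: str = "mean"  # mean | tscore | sumdiff

    def __post_init__(self) -> None:
        if not self.up_genes:
            raise ValidationError(f"signature {self.name!r} has no up genes")
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValidationError(
                f"signature {self.name!r}: genes in both up and down lists: "
                f"{sorted(overlap)[:5]}"
            )
        if self.mode not in ("mean", "tscore", "sumdiff"):
            raise ValidationError(f"unknown scoring mode {self.mode!r}")


# -- matrix I/O ---------------------------------------------------------------


def _parse_cell(token: str, row: str, col: str) -> float:
    if token.strip().lower() == "na":
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"non-numeric cell {token!r} at feature {row!r}, sample {col!r}"
        ) from None


def read_matrix(
    path: str | Path,
    platform_id: str,
    lineage: Mapping[str, str] | pd.Series | None = None,
) -> OmicsMatrix:
    """Read a tab-separated feature x sample matrix.

    Lines starting with ``#`` (provenance headers) are skipped.  When no
    lineage mapping is supplied every sample is assigned the single lineage
    ``"all"`` — callers working with multi-lineage cohorts attach the real
    labels from the annotation table.
    """
    path = Path(path)
    lines = [
        ln.rstrip("\n")
        for ln in path.read_text().splitlines()
        if not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    samples = header[1:]
    features: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1:]:
        if not ln:
            continue
        parts = ln.split("\t")
        if len(parts) != len(samples) + 1:
            raise FormatError(
                f"{path}: row {parts[0]!r} has {len(parts) - 1} cells, "
                f"expected {len(samples)}"
            )
        feat = parts[0]
        features.append(feat)
        rows.append([_parse_cell(tok, feat, samples[j]) for j, tok in enumerate(parts[1:])])
    data = pd.DataFrame(rows, index=features, columns=samples, dtype=float)
    if lineage is None:
        lineage = pd.Series("all", index=samples)
    return OmicsMatrix(platform_id=platform_id, data=data, lineage=pd.Series(lineage))


def write_matrix(matrix: OmicsMatrix, path: str | Path, header_comments: Iterable[str] = ()) -> None:
    """Write a matrix as tab-separated text, ``NA`` for missing, full precision."""
    path = Path(path)
    try:
        with path.open("w") as fh:
            for comment in header_comments:
                fh.write(f"# {comment}\n")
            fh.write("\t".join(["feature"] + list(matrix.data.columns)) + "\n")
            for feat, row in zip(matrix.data.index, matrix.data.to_numpy()):
                cells = ["NA" if math.isnan(v) else repr(float(v)) for v in row]
                fh.write("\t".join([str(feat)] + cells) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing matrix to {path}: {exc}") from exc


# -- annotation I/O -----------------------------------------------------------

REQUIRED_ANNOTATION_COLUMNS = ("sample_id", "lineage")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table (TSV; required columns sample_id, lineage).

    Optional columns: ``histology``, ``surv_time`` (days), ``surv_event``
    (0/1); any further column is treated as an external label set.  The
    survival invariant — an event flag present wherever a time is present —
    is enforced here.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    for col in REQUIRED_ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"annotation missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise FormatError("annotation contains duplicate sample ids")
    if "surv_time" in df.columns:
        if "surv_event" not in df.columns:
            raise ValidationError("surv_time present without surv_event column")
        has_time = df["surv_time"].notna()
        if (has_time & df["surv_event"].isna()).any():
            raise ValidationError("surv_event missing for samples with surv_time")
        if (df.loc[has_time, "surv_time"] < 0).any():
            raise ValidationError("negative survival time")
    return df.set_index("sample_id", drop=False)


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# -- GMT ----------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Parse a Broad-dialect GMT file into signatures.

    Paired sets named ``X_UP`` / ``X_DN`` merge into one signature ``X`` with
    ``mode='tscore'``; unpaired sets become mean-scored signatures with no
    down genes.  The GMT description field is ignored.
    """
    up_sets: dict[str, list[str]] = {}
    dn_sets: dict[str, list[str]] = {}
    plain: dict[str, list[str]] = {}
    order: list[str] = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line with fewer than 3 fields: {ln[:60]!r}")
        name, genes = parts[0], [g for g in parts[2:] if g]
        upper = name.upper()
        if upper.endswith("_UP"):
            base = name[:-3]
            target, store = base, up_sets
        elif upper.endswith("_DN") or upper.endswith("_DOWN"):
            base = name[: -3 if upper.endswith("_DN") else -5]
            target, store = base, dn_sets
        else:
            target, store = name, plain
        if target in store:
            raise FormatError(f"duplicate signature name {name!r}")
        store[target] = genes
        if target not in order:
            order.append(target)
    signatures = []
    for name in order:
        if name in plain and (name in up_sets or name in dn_sets):
            raise FormatError(f"signature name {name!r} used both plain and paired")
        if name in plain:
            signatures.append(GeneSignature(name=name, up_genes=plain[name], mode="mean"))
        else:
            up = up_sets.get(name, [])
            dn = dn_sets.get(name, [])
            if not up:
                raise FormatError(f"signature {name!r} has a _DN list but no _UP list")
            mode = "tscore" if dn else "mean"
            signatures.append(GeneSignature(name=name, up_genes=up, down_genes=dn, mode=mode))
    return signatures
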