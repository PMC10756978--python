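"""Loading, filtering and normalization of per-omic feature matrices.

The pipeline consumes three tab-separated matrices (genes x samples, first
column ``Hugo_Symbol``, header row = sample IDs — the dialect of
cBioPortal-style exports), one per omic: gene expression, DNA methylation
and copy-number alteration (CNA).  Preprocessing removes low-variance
genes, restricts to an approved (HUGO) symbol list, min-max normalizes
values into [0, 1], and aligns the three matrices over the samples present
in all of them.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class OmicKind(str, enum.Enum):
    EXPRESSION = "expression"
    METHYLATION = "methylation"
    CNA = "cna"


class MissingPolicy(str, enum.Enum):
    DROP_GENE = "drop_gene"
    IMPUTE_ZERO = "impute_zero"


class NormalizeMethod(str, enum.Enum):
    MINMAX_PER_GENE = "minmax_per_gene"
    MINMAX_GLOBAL = "minmax_global"


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class ParseError(ValueError):
    """Raised when a table cell cannot be interpreted as a number."""


@dataclass
class FeatureMatrix:
    """A named numeric matrix for one omic: rows = genes, columns = samples.

    When genes are embedded, each gene's row vector across samples is one
    high-dimensional point.  Values are platform-native before
    normalization and dimensionless in [0, 1] afterwards.
    """

    omic_kind: OmicKind
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_ids in FeatureMatrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_ids in FeatureMatrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "Hugo_Symbol"
        df.to_csv(path, sep="\t")


@dataclass
class MultiOmicsDataset:
    """Three aligned omic matrices plus per-sample class labels.

    Invariant: expression, methylation and cna share identical gene and
    sample orderings, and every sample carries a class index < K.
    """

    expression: FeatureMatrix
    methylation: FeatureMatrix
    cna: FeatureMatrix
    labels: dict[str, int]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ref = self.expression
        for m in (self.methylation, self.cna):
            if m.gene_ids != ref.gene_ids or m.sample_ids != ref.sample_ids:
                raise ValidationError("omic matrices are not identically indexed")
        k = len(self.class_names)
        if k < 2:
            raise ValidationError("need at least 2 classes")
        for s in ref.sample_ids:
            if s not in self.labels:
                raise ValidationError(f"sample {s!r} has no label")
            if not 0 <= self.labels[s] < k:
                raise ValidationError(f"label of sample {s!r} out of range")

    @property
    def gene_ids(self) -> list[str]:
        return self.expression.gene_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def label_vector(self) -> np.ndarray:
        return np.array([self.labels[s] for s in self.sample_ids], dtype=int)

    def write_manifest(self, path: str | Path) -> None:
        manifest = {
            "gene_order": self.gene_ids,
            "sample_order": self.sample_ids,
            "class_names": self.class_names,
            "labels": {s: int(self.labels[s]) for s in self.sample_ids},
        }
        Path(path).write_text(json.dumps(manifest, indent=1))


def read_omics_table(
    path: str | Path,
    omic_kind: OmicKind | str,
    missing_policy: MissingPolicy | str = MissingPolicy.DROP_GENE,
) -> FeatureMatrix:
    """Read a genes-x-samples TSV into a :class:`FeatureMatrix`.

    First column holds gene symbols, the header row sample IDs.  Duplicate
    gene symbols keep the first occurrence (logged).  Empty cells are
    handled per ``missing_policy``: ``drop_gene`` removes the gene's row,
    ``impute_zero`` fills zeros.
    """
    omic_kind = OmicKind(omic_kind)
    missing_policy = MissingPolicy(missing_policy)
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except OSError as exc:
        raise OSError(f"cannot read omics table {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"empty omics table: {path}")

    dup = df.index.duplicated(keep="first")
    if dup.any():
        dropped = sorted(set(df.index[dup]))
        logger.warning(
            "%s: %d duplicate gene symbol(s) dropped (first kept): %s",
            path.name, int(dup.sum()), ", ".join(dropped[:10]),
        )
        df = df[~dup]

    numeric = df.apply(pd.to_numeric, errors="coerce")
    # A cell that has text but fails numeric conversion is a parse error;
    # a cell that was empty in the file is a missing value.
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    missing = numeric.isna()
    if missing.to_numpy().any():
        if missing_policy is MissingPolicy.DROP_GENE:
            keep = ~missing.any(axis=1)
            logger.info(
                "%s: dropped %d gene(s) with missing values",
                path.name, int((~keep).sum()),
            )
            numeric = numeric[keep]
            if numeric.shape[0] == 0:
                raise ValidationError(f"{path}: all genes dropped by missing policy")
        else:
            numeric = numeric.fillna(0.0)

    return FeatureMatrix(
        omic_kind=omic_kind,
        gene_ids=[str(g) for g in numeric.index],
        sample_ids=[str(s) for s in numeric.columns],
        values=numeric.to_numpy(dtype=float),
    )


def filter_low_variance(m: FeatureMatrix, threshold: float) -> FeatureMatrix:
    """Keep genes whose sample variance (ddof=1) is >= ``threshold``."""
    if threshold < 0:
        raise ValidationError("variance threshold must be >= 0")
    if m.n_samples < 2:
        raise ValidationError("variance filter needs at least 2 samples")
    var = m.values.var(axis=1, ddof=1)
    keep = var >= threshold
    if not keep.any():
        raise ValidationError(
            f"variance filter at {threshold} removed every gene; lower the threshold"
        )
    return FeatureMatrix(
        omic_kind=m.omic_kind,
        gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
        sample_ids=list(m.sample_ids),
        values=m.values[keep],
    )


def normalize_matrix(
    m: FeatureMatrix, method: NormalizeMethod | str = NormalizeMethod.MINMAX_PER_GENE
) -> FeatureMatrix:
    """Min-max scale values into [0, 1].

    ``minmax_per_gene`` maps each gene row's min to 0 and max to 1; a
    constant row maps to 0.5.  ``minmax_global`` uses the matrix-wide min
    and max (an all-constant matrix maps to 0.5).
    """
    method = NormalizeMethod(method)
    if m.values.size == 0:
        raise ValidationError("cannot normalize an empty matrix")
    if not np.isfinite(m.values).all():
        raise ValidationError("matrix contains non-finite entries")
    v = m.values
    if method is NormalizeMethod.MINMAX_PER_GENE:
        lo = v.min(axis=1, keepdims=True)
        hi = v.max(axis=1, keepdims=True)
    else:
        lo = np.full((1, 1), v.min())
        hi = np.full((1, 1), v.max())
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, (v - lo) / np.where(span > 0, span, 1.0), 0.5)
    return FeatureMatrix(
        omic_kind=m.omic_kind,
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        values=out,
    )


def filter_symbols(m: FeatureMatrix, approved: set[str]) -> FeatureMatrix:
    """Keep exactly the genes whose symbol is in the approved (HUGO) set."""
    if not approved:
        raise ValidationError("approved symbol set is empty")
    keep = [g in approved for g in m.gene_ids]
    if not any(keep):
        raise ValidationError("no gene symbols remain after the approved-list filter")
    return FeatureMatrix(
        omic_kind=m.omic_kind,
        gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
        sample_ids=list(m.sample_ids),
        values=m.values[np.array(keep)],
    )


def read_symbol_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def read_labels(path: str | Path) -> tuple[dict[str, int], list[str]]:
    """Read a 2-column TSV ``sample_id<TAB>class`` into (labels, class_names).

    Class names are mapped to indices in sorted order for determinism.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "class"], dtype=str)
    if df.empty:
        raise ValidationError(f"empty label table: {path}")
    class_names = sorted(df["class"].unique())
    idx = {c: i for i, c in enumerate(class_names)}
    labels = {str(s): idx[c] for s, c in zip(df["sample_id"], df["class"])}
    return labels, class_names


def assemble_dataset(
    expr: FeatureMatrix,
    meth: FeatureMatrix,
    cna: FeatureMatrix,
    labels: dict[str, int],
    gene_list: list[str],
    class_names: list[str] | None = None,
) -> MultiOmicsDataset:
    """Align the three omics over common labelled samples and ``gene_list``.

    Samples are the intersection of the three matrices' sample sets with
    the labelled samples (order taken from the expression matrix); genes
    are restricted and reordered to ``gene_list`` in all three matrices.
    """
    if not gene_list:
        raise ValidationError("gene_list is empty")
    if not labels:
        raise ValidationError("labels are empty")
    if len(set(gene_list)) != len(gene_list):
        raise ValidationError("gene_list contains duplicates")
    matrices = {"expression": expr, "methylation": meth, "cna": cna}
    for name, m in matrices.items():
        missing = [g for g in gene_list if g not in set(m.gene_ids)]
        if missing:
            raise ValidationError(
                f"gene(s) absent from the {name} matrix: {', '.join(missing)}"
            )
    common = set(expr.sample_ids) & set(meth.sample_ids) & set(cna.sample_ids)
    common &= set(labels)
    samples = [s for s in expr.sample_ids if s in common]
    if not samples:
        raise ValidationError("no sample is present in all three omics and labelled")

    def _reindex(m: FeatureMatrix) -> FeatureMatrix:
        gpos = {g: i for i, g in enumerate(m.gene_ids)}
        spos = {s: i for i, s in enumerate(m.sample_ids)}
        rows = [gpos[g] for g in gene_list]
        cols = [spos[s] for s in samples]
        return FeatureMatrix(
            omic_kind=m.omic_kind,
            gene_ids=list(gene_list),
            sample_ids=list(samples),
            values=m.values[np.ix_(rows, cols)],
        )

    if class_names is None:
        k = max(labels.values()) + 1
        class_names = [f"class_{i}" for i in range(k)]
    return MultiOmicsDataset(
        expression=_reindex(expr),
        methylation=_reindex(meth),
        cna=_reindex(cna),
        labels={s: labels[s] for s in samples},
        class_names=list(class_names),
    )


def top_variance_genes(m: FeatureMatrix, k: int) -> list[str]:
    """Fallback significant-gene list: the k genes with highest variance.

    Stands in when no externally computed mutation-significance list (e.g.
    a MutSigCV output) is supplied.
    """
    if not 0 < k <= m.n_genes:
        raise ValidationError(f"k must be in 1..{m.n_genes}")
    var = m.values.var(axis=1, ddof=1)
    order = np.argsort(-var, kind="stable")[:k]
    return [m.gene_ids[i] for i in sorted(order)]
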