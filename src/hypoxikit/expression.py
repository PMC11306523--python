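"""Count-matrix handling: I/O, low-count filtering, and RLE normalisation.

Bulk RNA-seq counts are held as a genes x samples integer matrix with a
per-sample annotation table (sample type, tumour model, replicate, optional
treatment group). Library-size correction uses the relative log expression
(RLE / median-of-ratios) method: a per-gene geometric-mean reference is built
over genes detected in every sample, and each sample's size factor is the
median ratio of its counts to that reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_TYPES = ("cell", "cdx", "pdx", "clinical_tumour", "normal")
XENOGRAFT_TYPES = ("cdx", "pdx")

ANNOTATION_COLUMNS = ("sample_id", "sample_type", "model_id", "replicate", "group")


@dataclass(frozen=True)
class CountMatrix:
    """Integer gene x sample count matrix with per-sample annotations.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample, non-negative
        integers.
    annotations
        DataFrame indexed by sample id with columns ``sample_type``,
        ``model_id``, ``replicate`` and optional ``group``; every sample in
        ``counts`` must be annotated.
    """

    counts: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        counts, ann = self.counts, self.annotations
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere((~np.isfinite(arr)) | (arr != np.floor(arr)))[0]
                raise ValueError(
                    "non-integer count at gene "
                    f"{counts.index[bad[0]]!r}, sample {counts.columns[bad[1]]!r}"
                )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {counts.index[bad[0]]!r}, "
                f"sample {counts.columns[bad[1]]!r}"
            )
        missing = counts.columns.difference(ann.index)
        if len(missing):
            raise ValueError(f"samples missing annotation: {sorted(missing)}")
        bad_types = set(ann["sample_type"]) - set(SAMPLE_TYPES)
        if bad_types:
            raise ValueError(f"unknown sample_type values: {sorted(bad_types)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def xenograft_sample_ids(self) -> list[str]:
        """Sample ids annotated as xenograft tumours (CDX or PDX)."""
        ann = self.annotations.loc[self.counts.columns]
        mask = ann["sample_type"].isin(XENOGRAFT_TYPES)
        return list(ann.index[mask])


@dataclass(frozen=True)
class NormalizedMatrix:
    """RLE-normalised expression values plus the per-sample size factors.

    Invariant: ``values * size_factors`` reproduces the raw counts.
    """

    values: pd.DataFrame
    size_factors: pd.Series
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("all size factors must be positive")
        if list(self.values.columns) != list(self.size_factors.index):
            raise ValueError("size factor index must match sample columns")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def read_count_matrix(path, annotation_path) -> CountMatrix:
    """Read a TSV count matrix (first column gene ids) plus annotation sidecar.

    The annotation file is TSV with columns sample_id, sample_type, model_id,
    replicate and optional group, keyed by sample id. Sample order is taken
    from the matrix header.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    for col in counts.columns:
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any():
            gene = counts.index[vals.isna().to_numpy().argmax()]
            raise ValueError(f"non-numeric count at gene {gene!r}, sample {col!r}")
        counts[col] = vals
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "sample_type", "model_id", "replicate"}
    missing_cols = required - set(ann.columns)
    if missing_cols:
        raise ValueError(f"annotation file missing columns: {sorted(missing_cols)}")
    if "group" not in ann.columns:
        ann["group"] = pd.NA
    if ann["sample_id"].duplicated().any():
        dup = ann.loc[ann["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id in annotations: {dup!r}")
    ann = ann.set_index("sample_id")
    cm = CountMatrix(counts=counts, annotations=ann)
    # cast to int only after validation so error messages can cite the cell
    object.__setattr__(cm, "counts", counts.astype(np.int64))
    return cm


def write_count_matrix(cm: CountMatrix, path, annotation_path) -> None:
    """Write a count matrix and its annotations in the TSV dialect read back
    by :func:`read_count_matrix`."""
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    ann = cm.annotations.copy()
    ann.index.name = "sample_id"
    ann.to_csv(annotation_path, sep="\t")


def filter_low_counts(
    cm: CountMatrix, min_in_one_sample: int = 10, min_total: int = 15
) -> CountMatrix:
    """Drop genes failing the low-count rule.

    A gene is retained iff its maximum count over samples is at least
    ``min_in_one_sample`` AND its total count over samples is at least
    ``min_total``. Gene order and the sample set are preserved.
    """
    if min_in_one_sample < 0 or min_total < 0:
        raise ValueError("filter thresholds must be non-negative")
    arr = cm.counts.to_numpy()
    keep = (arr.max(axis=1) >= min_in_one_sample) & (arr.sum(axis=1) >= min_total)
    return CountMatrix(counts=cm.counts.loc[keep], annotations=cm.annotations)


def rle_normalize(cm: CountMatrix) -> NormalizedMatrix:
    """RLE (median-of-ratios) normalisation of a count matrix.

    The per-gene reference is the geometric mean across samples, computed
    over genes with strictly positive counts in every sample; each sample's
    size factor is the median of counts/reference over those genes. Genes
    with a zero anywhere are excluded from size-factor estimation but are
    retained and normalised. Size factors are reported as the raw medians
    (no rescaling to geometric mean one); downstream signature scores are
    invariant to a common rescaling.
    """
    counts = cm.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("RLE normalisation requires at least 2 samples")
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "apply filter_low_counts first"
        )
    ref_genes = counts[all_positive]
    log_ref = np.log(ref_genes).mean(axis=1)  # log geometric mean
    ratios = np.log(ref_genes) - log_ref[:, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    values = counts / size_factors[None, :]
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=cm.counts.index, columns=cm.counts.columns),
        size_factors=pd.Series(size_factors, index=cm.counts.columns, name="size_factor"),
        annotations=cm.annotations,
    )
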