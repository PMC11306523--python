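"""Hypoxia gene-signature scoring of normalised expression matrices.

Three per-sample scores are computed from a normalised count matrix and a
reference population (by default the xenograft tumour samples, where some
hypoxia is expected):

* **z-sum score** — per-gene z-scores against the reference mean/sd, each
  clamped to [-3, 3], summed over the signature genes.
* **simple score** — +1 for each signature gene above the reference median
  in that sample, -1 for each below (exact ties contribute 0).
* **Hypoxia Score** — the fraction of signature genes above the reference
  median, in [0, 1]; the affine rescaling of the simple score that maps the
  all-below sample to 0 and the all-above sample to 1.

Scores are computed per individual sample; replicate averaging (per-model
mean +/- SEM, and the cross-signature mean score) happens only in
:func:`aggregate_scores`.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSignature:
    """Named ordered set of gene identifiers."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


def read_signature(path, name: str | None = None) -> GeneSignature:
    """Read a signature from a plain-text gene list (one id per line,
    ``#`` comments and blank lines ignored)."""
    path = Path(path)
    genes: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return GeneSignature(name=name or path.stem, genes=tuple(genes))


def read_signature_manifest(manifest_path) -> list[GeneSignature]:
    """Read a TOML manifest mapping signature name -> gene-list file.

    Expected layout::

        [signatures]
        buffa = "signatures/buffa.txt"

    Relative paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path, "rb") as fh:
        manifest = tomllib.load(fh)
    entries = manifest.get("signatures", manifest)
    sigs = []
    for name, rel in entries.items():
        sigs.append(read_signature(manifest_path.parent / rel, name=name))
    return sigs


@dataclass(frozen=True)
class ReferenceSet:
    """Per-gene mean, sd (n-1 denominator) and median over a reference
    sample population."""

    sample_ids: tuple[str, ...]
    mean: pd.Series
    sd: pd.Series
    median: pd.Series


def build_reference(nm: NormalizedMatrix, reference_sample_ids=None) -> ReferenceSet:
    """Compute reference statistics over the given samples.

    ``reference_sample_ids`` defaults to all xenograft (CDX + PDX) samples
    in the annotations. At least two reference samples are required (the
    sample standard deviation is undefined for one).
    """
    if reference_sample_ids is None:
        ann = nm.annotations.loc[nm.values.columns]
        mask = ann["sample_type"].isin(("cdx", "pdx"))
        reference_sample_ids = list(ann.index[mask])
    reference_sample_ids = list(reference_sample_ids)
    unknown = set(reference_sample_ids) - set(nm.sample_ids)
    if unknown:
        raise ValueError(f"reference samples not in matrix: {sorted(unknown)}")
    if len(reference_sample_ids) < 2:
        raise ValueError("need at least 2 reference samples (sd undefined)")
    ref = nm.values[reference_sample_ids]
    return ReferenceSet(
        sample_ids=tuple(reference_sample_ids),
        mean=ref.mean(axis=1),
        sd=ref.std(axis=1, ddof=1),
        median=ref.median(axis=1),
    )


def zscore_matrix(
    nm: NormalizedMatrix, ref: ReferenceSet, clamp: float = 3.0
) -> pd.DataFrame:
    """Per-gene z-scores against the reference, clipped to [-clamp, clamp].

    Genes with zero reference sd yield z = 0 (logged as a warning).
    """
    sd = ref.sd.to_numpy(dtype=float)
    zero_sd = sd == 0
    if zero_sd.any():
        logger.warning(
            "%d genes have zero reference sd; their z-scores are set to 0",
            int(zero_sd.sum()),
        )
    safe_sd = np.where(zero_sd, 1.0, sd)
    z = (nm.values.to_numpy(dtype=float) - ref.mean.to_numpy()[:, None]) / safe_sd[:, None]
    z[zero_sd, :] = 0.0
    z = np.clip(z, -clamp, clamp)
    return pd.DataFrame(z, index=nm.values.index, columns=nm.values.columns)


def _present_genes(gene_index: pd.Index, sig: GeneSignature) -> list[str]:
    present = [g for g in sig.genes if g in gene_index]
    if not present:
        raise ValueError(f"no genes of signature {sig.name!r} present in the matrix")
    n_missing = len(sig.genes) - len(present)
    if n_missing:
        logger.warning(
            "signature %s: %d of %d genes absent from the matrix",
            sig.name, n_missing, len(sig.genes),
        )
    return present


def zsum_score(z_matrix: pd.DataFrame, sig: GeneSignature) -> pd.Series:
    """Sum of clamped z-scores over the signature genes present, per sample."""
    present = _present_genes(z_matrix.index, sig)
    scores = z_matrix.loc[present].sum(axis=0)
    scores.name = f"{sig.name}_zsum"
    return scores


def simple_signature_score(
    nm: NormalizedMatrix, ref: ReferenceSet, sig: GeneSignature
) -> pd.Series:
    """Sum over signature genes of sign(value - reference median):
    +1 above, -1 below, 0 at an exact tie."""
    present = _present_genes(nm.values.index, sig)
    diff = nm.values.loc[present].to_numpy() - ref.median.loc[present].to_numpy()[:, None]
    scores = np.sign(diff).sum(axis=0).astype(int)
    return pd.Series(scores, index=nm.values.columns, name=f"{sig.name}_simple")


def hypoxia_score(
    nm: NormalizedMatrix, ref: ReferenceSet, sig: GeneSignature
) -> pd.Series:
    """Fraction of signature genes (present in the matrix) strictly above the
    reference median; ranges over [0, 1]."""
    present = _present_genes(nm.values.index, sig)
    diff = nm.values.loc[present].to_numpy() - ref.median.loc[present].to_numpy()[:, None]
    frac = (diff > 0).mean(axis=0)
    return pd.Series(frac, index=nm.values.columns, name=f"{sig.name}_hypoxia_score")


def score_signatures(
    nm: NormalizedMatrix,
    signatures,
    ref: ReferenceSet | None = None,
    clamp: float = 3.0,
) -> pd.DataFrame:
    """Score every signature on every sample.

    Returns a tidy table with one row per sample x signature and columns
    sample_id, model_id, signature, zsum_score, simple_score, hypoxia_score,
    n_genes_used.
    """
    if ref is None:
        ref = build_reference(nm)
    z = zscore_matrix(nm, ref, clamp=clamp)
    ann = nm.annotations
    rows = []
    for sig in signatures:
        present = _present_genes(nm.values.index, sig)
        zsum = zsum_score(z, sig)
        simple = simple_signature_score(nm, ref, sig)
        hyp = hypoxia_score(nm, ref, sig)
        for s in nm.sample_ids:
            rows.append(
                {
                    "sample_id": s,
                    "model_id": ann.loc[s, "model_id"] if s in ann.index else "",
                    "signature": sig.name,
                    "zsum_score": zsum[s],
                    "simple_score": int(simple[s]),
                    "hypoxia_score": hyp[s],
                    "n_genes_used": len(present),
                }
            )
    return pd.DataFrame(rows)


def aggregate_scores(
    score_table: pd.DataFrame, value: str = "hypoxia_score"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-model mean +/- SEM per signature, plus the cross-signature mean.

    Returns ``(per_model, cross_signature)``. ``per_model`` has one row per
    model x signature with columns mean, sem, n; SEM for a single replicate
    is reported as 0 with ``single_replicate`` flagged. ``cross_signature``
    averages the per-model means over signatures (mean of means).
    """
    rows = []
    for (model, signame), grp in score_table.groupby(["model_id", "signature"]):
        vals = grp[value].to_numpy(dtype=float)
        n = len(vals)
        if n == 0:
            logger.warning("model %s has no samples for %s; omitted", model, signame)
            continue
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "model_id": model,
                "signature": signame,
                "mean": float(vals.mean()),
                "sem": sem,
                "n": n,
                "single_replicate": n == 1,
            }
        )
    per_model = pd.DataFrame(rows)
    cross = (
        per_model.groupby("model_id")["mean"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "mean_score", "count": "n_signatures"})
        .reset_index()
    )
    return per_model, cross
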