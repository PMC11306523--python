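"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's data shapes so the whole pipeline is
testable without animals or sequencers:

* **Expression** — negative-binomial RNA-seq counts for a panel of xenograft
  models with a planted per-model hypoxia level h in [0, 1] that shifts the
  signature genes' means by ``2**(beta*h)``, plus log-normal library-size
  variation. Default shape mirrors a 20-model panel with 3 replicate tumours
  each.
* **Growth** — Gompertz tumour trajectories measured every 2-3 days from a
  week before treatment to day 21, with multiplicative log-normal calliper
  noise and a treatment effect expressed as a multiplier on the growth rate
  Ku. Ground truth is the analytic mean derivative over days 1..21.
* **Viral reads** — read intervals placed uniformly in a genome region, with
  the expected presence call computed by an independent per-base pileup loop.

All outputs are fully determined by the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .growth import gompertz_rate, gompertz_volume
from .signatures import GeneSignature
from .viral import (
    DEFAULT_MIN_DEPTH,
    DEFAULT_MIN_READS,
    DEFAULT_MIN_SPAN,
    HPVCall,
)


@dataclass(frozen=True)
class ExpressionDesign:
    """Design of a synthetic RNA-seq count panel with planted hypoxia."""

    n_models: int = 20
    replicates: int = 3
    n_genes: int = 1000
    signature_size: int = 15
    beta: float = 1.0  # log2 shift of signature-gene means at h = 1
    dispersion: float = 0.2  # NB variance = mu + phi * mu^2
    library_sigma: float = 0.3  # sd of log library-size factors
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sigma: float = 1.0
    hypoxia_levels: tuple[float, ...] | None = None  # default: evenly spaced 0..1


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial parameterised by mean and dispersion phi
    (variance mu + phi*mu^2); Poisson limit at phi = 0."""
    if phi == 0:
        return rng.poisson(mu)
    n = 1.0 / phi
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_expression(
    design: ExpressionDesign = ExpressionDesign(), seed: int = 0
) -> tuple[CountMatrix, GeneSignature, pd.DataFrame]:
    """Generate a count matrix with planted per-model hypoxia.

    Returns ``(count_matrix, signature, truth)`` where ``truth`` has one row
    per model with its planted hypoxia level ``h``. The first
    ``signature_size`` genes form the hypoxia signature; their means are
    multiplied by ``2**(beta*h)`` in samples of a model at level h.
    """
    rng = np.random.default_rng(seed)
    d = design
    if d.hypoxia_levels is not None:
        h = np.asarray(d.hypoxia_levels, dtype=float)
        if len(h) != d.n_models:
            raise ValueError("hypoxia_levels length must equal n_models")
    elif d.n_models > 1:
        h = np.linspace(0.0, 1.0, d.n_models)
    else:
        h = np.array([0.5])
    gene_ids = [f"G{i:05d}" for i in range(d.n_genes)]
    sig_genes = tuple(gene_ids[: d.signature_size])
    base_mu = rng.lognormal(d.baseline_log_mean, d.baseline_log_sigma, size=d.n_genes)

    counts = {}
    ann_rows = []
    for m in range(d.n_models):
        model_id = f"M{m:02d}"
        mu_model = base_mu.copy()
        mu_model[: d.signature_size] *= 2.0 ** (d.beta * h[m])
        for r in range(d.replicates):
            sample_id = f"{model_id}_r{r + 1}"
            lib = rng.lognormal(0.0, d.library_sigma)
            counts[sample_id] = _nb_draw(rng, mu_model * lib, d.dispersion)
            ann_rows.append(
                {
                    "sample_id": sample_id,
                    "sample_type": "pdx" if m % 2 else "cdx",
                    "model_id": model_id,
                    "replicate": r + 1,
                    "group": "",
                }
            )
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"))
    ann = pd.DataFrame(ann_rows).set_index("sample_id")
    truth = pd.DataFrame(
        {"model_id": [f"M{m:02d}" for m in range(d.n_models)], "h": h}
    )
    cm = CountMatrix(counts=counts_df, annotations=ann)
    return cm, GeneSignature(name="planted_hypoxia", genes=sig_genes), truth


@dataclass(frozen=True)
class GrowthDesign:
    """Design of synthetic Gompertz tumour-growth trajectories."""

    n_models: int = 1
    n_per_arm: int = 8
    w0: float = 250.0  # mm^3 at treatment start
    ku: float = 40.0  # mm^3/day maximum growth rate
    a: float = 2000.0  # mm^3 asymptote
    treatment_multiplier: float = 0.4  # Ku multiplier in the treated arm
    noise_cv: float = 0.10  # multiplicative log-normal measurement noise
    day_start: float = -7.0
    day_end: float = 21.0
    arms: tuple[str, ...] = ("control", "treated")


def _measurement_days(rng: np.random.Generator, start: float, end: float) -> np.ndarray:
    """Calliper schedule: every 2-3 days from start through end."""
    days = [start]
    while days[-1] < end:
        days.append(days[-1] + rng.integers(2, 4))
    days[-1] = min(days[-1], end)
    return np.unique(np.asarray(days, dtype=float))


def simulate_growth(
    design: GrowthDesign = GrowthDesign(), seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate calliper measurement tables plus per-animal ground truth.

    Volumes follow the W0-form Gompertz curve (Ku scaled by the treatment
    multiplier in treated animals) times log-normal noise at the design CV.
    Returns ``(measurements, truth)``; ``truth`` records each animal's true
    parameters and the analytic mean derivative over days 1..21 — the
    quantity the growth-rate pipeline estimates.
    """
    rng = np.random.default_rng(seed)
    d = design
    sigma = np.sqrt(np.log1p(d.noise_cv**2))
    meas_rows, truth_rows = [], []
    day_grid = np.arange(1.0, 22.0)
    for m in range(d.n_models):
        model_id = f"M{m:02d}"
        for arm in d.arms:
            ku = d.ku * (d.treatment_multiplier if arm == "treated" else 1.0)
            for i in range(d.n_per_arm):
                animal_id = f"{model_id}_{arm}_{i + 1}"
                days = _measurement_days(rng, d.day_start, d.day_end)
                true_vol = gompertz_volume(days, d.w0, ku, d.a)
                noise = rng.lognormal(0.0, sigma, size=len(days)) if sigma > 0 else 1.0
                obs = true_vol * noise
                for day, vol in zip(days, obs):
                    meas_rows.append(
                        {
                            "animal_id": animal_id,
                            "model_id": model_id,
                            "group": arm,
                            "day": day,
                            "volume_mm3": vol,
                        }
                    )
                truth_rows.append(
                    {
                        "animal_id": animal_id,
                        "model_id": model_id,
                        "group": arm,
                        "w0": d.w0,
                        "ku": ku,
                        "a": d.a,
                        "true_mean_daily_rate": float(
                            gompertz_rate(day_grid, d.w0, ku, d.a).mean()
                        ),
                    }
                )
    return pd.DataFrame(meas_rows), pd.DataFrame(truth_rows)


def simulate_viral_reads(
    n_reads: int,
    genome_length: int,
    region: tuple[int, int],
    read_length: int = 100,
    seed: int = 0,
    virus_id: str = "HPV16",
    min_reads: int = DEFAULT_MIN_READS,
    min_span: int = DEFAULT_MIN_SPAN,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> tuple[pd.DataFrame, HPVCall]:
    """Place reads uniformly in a genome region and compute the expected call.

    Returns ``(alignments, expected_call)``. The alignment table has columns
    virus_id, start, end (0-based half-open). The expected call is computed
    here by a naive per-base counting loop, independent of the pileup code
    it is used to check.
    """
    rng = np.random.default_rng(seed)
    start, end = region
    if not (0 <= start < end <= genome_length):
        raise ValueError(f"region {region} outside genome of length {genome_length}")
    region_len = end - start
    rows = []
    for _ in range(n_reads):
        if region_len <= read_length:
            s, e = start, end
        else:
            s = int(rng.integers(start, end - read_length + 1))
            e = s + read_length
        rows.append({"virus_id": virus_id, "start": s, "end": e})
    alignments = pd.DataFrame(rows, columns=["virus_id", "start", "end"])

    # independent oracle: per-base counting loop over every read
    depth = [0] * genome_length
    for row in rows:
        for pos in range(row["start"], row["end"]):
            depth[pos] += 1
    best_len = best_start = cur_len = cur_start = 0
    for pos in range(genome_length):
        if depth[pos] >= min_depth:
            if cur_len == 0:
                cur_start = pos
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    expected = HPVCall(
        virus_id=virus_id,
        positive=(n_reads >= min_reads and best_len >= min_span),
        mapped_reads=n_reads,
        longest_run_at_min_depth=best_len,
        evidence_region=(best_start, best_start + best_len),
    )
    return alignments, expected


@dataclass(frozen=True)
class RateStudyDesign:
    """Design for operating-characteristic studies of the group comparison:
    per-animal mean daily growth rates drawn directly around model baselines."""

    n_models: int = 20
    n_affected: int = 5
    n_per_arm: int = 8
    base_rate: float = 40.0  # mm^3/day
    effect_multiplier: float = 0.4  # treated-arm rate multiplier in affected models
    noise_sd_fraction: float = 0.15  # relative Gaussian noise on each animal's rate


def simulate_rate_study(
    design: RateStudyDesign = RateStudyDesign(), seed: int = 0
) -> tuple[pd.DataFrame, set[str]]:
    """Animal-level mean daily growth rates for a multi-model efficacy study.

    The first ``n_affected`` models carry a true treated-arm rate reduction;
    the rest are null. Returns ``(rates, affected_model_ids)`` with columns
    model_id, group, animal_id, mean_daily_rate.
    """
    rng = np.random.default_rng(seed)
    d = design
    rows = []
    affected = {f"M{m:02d}" for m in range(d.n_affected)}
    for m in range(d.n_models):
        model_id = f"M{m:02d}"
        for arm in ("control", "treated"):
            mult = (
                d.effect_multiplier
                if (arm == "treated" and model_id in affected)
                else 1.0
            )
            mean = d.base_rate * mult
            rates = mean * (1.0 + d.noise_sd_fraction * rng.standard_normal(d.n_per_arm))
            for i, rate in enumerate(rates):
                rows.append(
                    {
                        "model_id": model_id,
                        "group": arm,
                        "animal_id": f"{model_id}_{arm}_{i + 1}",
                        "mean_daily_rate": float(rate),
                    }
                )
    return pd.DataFrame(rows), affected
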