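"""Biomarker variability (CV) and cross-biomarker agreement (Pearson r).

Model-level biomarker summaries — hypoxia scores, pimonidazole-positive
hypoxic fraction, EdU proliferation counts, treated growth rates — are
compared on per-model means; models missing either measurement are dropped
pairwise.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats


def coefficient_of_variation(values) -> float:
    """CV as a percentage: 100 * sd / mean (sample sd, n-1 denominator).

    Undefined (raises) for fewer than two values or zero mean.
    """
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise ValueError("CV requires at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined: mean is zero")
    return float(100.0 * arr.std(ddof=1) / mean)


def pearson_correlation(x, y) -> tuple[float, int]:
    """Sample Pearson r on paired values; incomplete pairs dropped.

    Accepts aligned sequences or pandas Series (aligned on index). Returns
    (r, n) where n is the number of complete pairs; fewer than three raises.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        df = pd.concat({"x": x, "y": y}, axis=1)
    else:
        df = pd.DataFrame({"x": np.asarray(x, dtype=float), "y": np.asarray(y, dtype=float)})
    df = df.dropna()
    if len(df) < 3:
        raise ValueError("Pearson correlation requires >= 3 complete pairs")
    r, _ = stats.pearsonr(df["x"], df["y"])
    return float(r), len(df)


def model_cv_table(measurements: pd.DataFrame, value: str, by: str = "model_id") -> pd.DataFrame:
    """Per-model CV of a replicate-level biomarker column.

    Models with fewer than two replicates or zero mean carry NaN CV.
    """
    rows = []
    for model, grp in measurements.groupby(by):
        vals = grp[value].dropna().to_numpy(dtype=float)
        try:
            cv = coefficient_of_variation(vals)
        except ValueError:
            cv = math.nan
        rows.append({by: model, "n": len(vals), "cv_percent": cv})
    return pd.DataFrame(rows)


def correlate_biomarkers(
    table: pd.DataFrame, pairs: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations between biomarker columns of a
    per-model table (one row per model; columns are per-model means).

    ``pairs`` defaults to all ordered pairs of numeric columns.
    """
    numeric = table.select_dtypes("number").columns
    if pairs is None:
        pairs = [
            (a, b) for i, a in enumerate(numeric) for b in numeric[i + 1:]
        ]
    rows = []
    for a, b in pairs:
        try:
            r, n = pearson_correlation(table[a], table[b])
        except ValueError:
            r, n = math.nan, int(table[[a, b]].dropna().shape[0])
        rows.append({"x": a, "y": b, "pearson_r": r, "n": n})
    return pd.DataFrame(rows)
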