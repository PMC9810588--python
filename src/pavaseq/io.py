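"""CSV input/output for the fitting routines and the distributional fit."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import PavaResult, WeightedVector
from .idr import DistributionalFit, quantile_curve

__all__ = [
    "read_weighted_vector",
    "write_fit",
    "read_regression_sample",
    "write_cdf",
    "write_quantiles",
]


def read_weighted_vector(path) -> WeightedVector:
    """Read a direct-mode CSV: column ``z`` and optional ``w`` (default 1),
    one row per index in covariate order."""
    df = pd.read_csv(path)
    if "z" not in df.columns:
        raise ValueError("input CSV must contain a 'z' column")
    w = df["w"].to_numpy(float) if "w" in df.columns else None
    return WeightedVector(df["z"].to_numpy(float), w)


def write_fit(path, data: WeightedVector, result: PavaResult) -> None:
    """Write ``index`` (1-based), ``z``, ``w``, ``fitted``, ``block``
    (1-based block label)."""
    out = pd.DataFrame(
        {
            "index": np.arange(1, data.m + 1),
            "z": np.asarray(data.values, float),
            "w": np.asarray(data.weights, float),
            "fitted": np.asarray(result.fitted, float),
            "block": result.state.block_labels(),
        }
    )
    out.to_csv(path, index=False)


def read_regression_sample(path):
    """Read a regression-mode CSV with columns ``x`` and ``y``."""
    df = pd.read_csv(path)
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValueError(f"input CSV must contain a {col!r} column")
    return df["x"].to_numpy(float), df["y"].to_numpy(float)


def write_cdf(path, fit: DistributionalFit) -> None:
    """Wide CSV: first column ``x``, one column per response threshold
    (header = threshold value), 17 significant digits throughout."""
    cols = ["x"] + [format(t, ".17g") for t in fit.thresholds]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for j in range(fit.x.size):
            row = [format(fit.x[j], ".17g")] + [
                format(v, ".17g") for v in fit.cdf[j]
            ]
            fh.write(",".join(row) + "\n")


def write_quantiles(path, fit: DistributionalFit, betas) -> None:
    """Long CSV with columns ``x``, ``beta``, ``quantile``."""
    rows = []
    for beta in betas:
        q = quantile_curve(fit, beta)
        for xj, qj in zip(fit.x, q):
            rows.append({"x": xj, "beta": beta, "quantile": qj})
    pd.DataFrame(rows).to_csv(path, index=False)
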