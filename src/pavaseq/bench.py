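"""Operation-count benchmark of the three PAV variants on simulated data.

Wall-clock times are hardware- and implementation-dependent, so the primary
comparison metric is the exact number of averaging operations each variant
performs to produce the full conditional-CDF matrix.  Each replication
draws one sample and fits it with all three variants, so every comparison
is on identical data.  Wall time can be recorded as well, but is labelled
informational and is not reproducible across machines.
"""

from __future__ import annotations

import time
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .idr import VARIANTS, fit_idr
from .simulate import (
    GammaDesign,
    GaussianDesign,
    gen_gamma_sample,
    gen_gauss_sample,
)

__all__ = ["run_benchmark", "summarize_ratios"]


def _draw(design: str, n: int, rho: float | None, seed: int):
    if design == "gamma":
        return gen_gamma_sample(GammaDesign(n=n, seed=seed))
    if design == "gauss":
        return gen_gauss_sample(GaussianDesign(n=n, rho=rho, seed=seed))
    raise ValueError(f"unknown design {design!r}")


def run_benchmark(
    designs: Iterable[str] = ("gamma",),
    sample_sizes: Sequence[int] = (200,),
    rhos: Sequence[float] = (0.0,),
    reps: int = 5,
    seed: int = 0,
    record_time: bool = False,
) -> pd.DataFrame:
    """Fit every configuration with all three variants; long results table.

    Columns: design, n, rho (NaN for the gamma design), rep, variant,
    op_total, block_inits, pool_merges and, when ``record_time`` is set,
    wall_seconds (informational only).
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    rows = []
    ss = np.random.SeedSequence(seed)
    for design in designs:
        rho_grid = rhos if design == "gauss" else [None]
        for n in sample_sizes:
            for rho in rho_grid:
                for rep in range(reps):
                    child = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
                    x, y = _draw(design, n, rho, child)
                    for variant in VARIANTS:
                        t0 = time.perf_counter()
                        _, ops = fit_idr(x, y, variant=variant)
                        dt = time.perf_counter() - t0
                        row = {
                            "design": design,
                            "n": n,
                            "rho": np.nan if rho is None else rho,
                            "rep": rep,
                            "variant": variant,
                            "op_total": ops.total,
                            "block_inits": ops.block_inits,
                            "pool_merges": ops.pool_merges,
                        }
                        if record_time:
                            row["wall_seconds"] = dt
                        rows.append(row)
    return pd.DataFrame(rows)


def summarize_ratios(
    results: pd.DataFrame,
    numerator: str = "standard",
    denominator: str = "abridged",
) -> pd.DataFrame:
    """Mean and standard deviation, across replications, of the per-sample
    operation-count ratio ``numerator / denominator``."""
    keys = ["design", "n", "rho"]
    # set_index/unstack (not pivot_table) so NaN rho keys survive
    wide = results.set_index(keys + ["rep", "variant"])["op_total"].unstack(
        "variant"
    )
    ratio = (wide[numerator] / wide[denominator]).rename("ratio").reset_index()
    out = (
        ratio.groupby(keys, dropna=False)["ratio"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"count": "reps"})
    )
    return out
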