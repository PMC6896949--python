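"""Shannon-index saturation (rarefaction) simulation with a nonlinear
saturation fit, and exponential growth rates on skyline series.

The rarefaction asks how fast the Shannon information index of a reference
group saturates with sample size: individuals are drawn without
replacement along a gradient of sizes (default 2, 5, 25, 50, 100, 200,
400, ten replicates each), the locus-averaged Shannon index of each draw
is divided by the full-group index, and a saturating curve is fitted to
the proportion.  The growth-rate estimator applies r = ln(Nt/N0)/t to
effective-population-size trajectories, locating the contiguous interval
of fastest exponential growth with N0 taken as the minimum size
immediately preceding the growth phase.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .genio import GenotypeMatrix, SkylineSeries
from .popstats import allele_frequencies, _locus_indices

logger = logging.getLogger("invmix")

DEFAULT_SIZES = (2, 5, 25, 50, 100, 200, 400)
DEFAULT_REPS = 10


# ---------------------------------------------------------------------------
# Shannon rarefaction
# ---------------------------------------------------------------------------

def _shannon_of(matrix: GenotypeMatrix, individuals: Sequence[str]) -> float:
    """Locus-averaged Shannon index of a pooled set of individuals."""
    sub = matrix.subset(individuals)
    table = allele_frequencies(sub, {i: "pool" for i in sub.individuals})
    vals = []
    for locus in table.loci:
        if ("pool", locus) in table.undefined:
            continue
        p = np.array(list(table.frequencies("pool", locus).values()))
        vals.append(_locus_indices(p)[1])
    return float(np.mean(vals)) if vals else math.nan


@dataclass
class SaturationTable:
    rows: pd.DataFrame           # sample_size, replicate, I_sample, proportion_I
    i_total: float
    reference_group: str
    fitted_params: dict | None = None


def shannon_rarefaction(
    matrix: GenotypeMatrix,
    reference_group: str,
    sizes: Sequence[int] = DEFAULT_SIZES,
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
) -> SaturationTable:
    """Rarefy the reference group along a gradient of sample sizes.

    Each row is one without-replacement draw of individuals; sizes larger
    than the group are skipped with a warning.  At the full group size the
    proportion is exactly 1.
    """
    members = [
        i for i in matrix.individuals
        if matrix.group[matrix.population[i]] == reference_group
    ]
    if not members:
        raise ValueError(f"no individuals in group {reference_group!r}")
    rng = np.random.default_rng(seed)
    i_total = _shannon_of(matrix, members)
    if i_total == 0:
        raise ValueError("reference group is monomorphic; proportion undefined")
    rows = []
    for size in sizes:
        if size > len(members):
            logger.warning(
                "sample size %d exceeds group size %d; skipped", size, len(members)
            )
            continue
        for rep in range(reps):
            if size == len(members):
                chosen = list(members)
            else:
                chosen = [
                    members[k]
                    for k in rng.choice(len(members), size=size, replace=False)
                ]
            i_sample = _shannon_of(matrix, chosen)
            rows.append(
                {
                    "sample_size": size,
                    "replicate": rep + 1,
                    "I_sample": i_sample,
                    "proportion_I": i_sample / i_total,
                }
            )
    return SaturationTable(
        rows=pd.DataFrame(rows), i_total=i_total, reference_group=reference_group
    )


def _michaelis(x, k):
    return x / (k + x)


def _exponential_sat(x, lam):
    return 1.0 - np.exp(-lam * x)


_MODELS = {"michaelis": (_michaelis, ["k"]), "exponential": (_exponential_sat, ["lam"])}


def fit_saturation_curve(
    table: SaturationTable,
    model: str = "michaelis",
    aggregate: str = "replicates",
) -> dict:
    """Least-squares fit of a saturating curve to proportion_I vs size.

    ``model``: ``"michaelis"`` (x/(k+x), default) or ``"exponential"``
    (1 − exp(−λx)).  ``aggregate="replicates"`` fits all replicate rows;
    ``"mean"`` averages per size first.  Returns params, residual SS, the
    model id and the size at which the predicted proportion reaches 0.95.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    func, names = _MODELS[model]
    df = table.rows
    if df["sample_size"].nunique() < 3:
        raise ValueError("need at least 3 distinct sample sizes to fit")
    if aggregate == "mean":
        df = df.groupby("sample_size", as_index=False)["proportion_I"].mean()
    elif aggregate != "replicates":
        raise ValueError(f"unknown aggregate {aggregate!r}")
    x = df["sample_size"].to_numpy(dtype=float)
    y = df["proportion_I"].to_numpy(dtype=float)
    if float(np.std(y)) < 1e-12:
        raise ValueError("degenerate saturation data: proportion is constant")
    params, _ = curve_fit(func, x, y, p0=[1.0], maxfev=10_000)
    pred = func(x, *params)
    rss = float(np.sum((y - pred) ** 2))
    if model == "michaelis":
        size_95 = 19.0 * params[0]            # x/(k+x) = 0.95  =>  x = 19k
    else:
        size_95 = math.log(20.0) / params[0]  # 1 - exp(-λx) = 0.95
    fitted = {
        "model": model,
        "params": dict(zip(names, map(float, params))),
        "rss": rss,
        "size_at_95pct": float(size_95),
    }
    table.fitted_params = fitted
    return fitted


# ---------------------------------------------------------------------------
# Growth rates
# ---------------------------------------------------------------------------

def growth_rate(n0: float, nt: float, t: float) -> float:
    """Exponential growth rate per year, r = ln(Nt/N0)/t."""
    if n0 <= 0 or nt <= 0:
        raise ValueError("population sizes must be positive")
    if t <= 0:
        raise ValueError("elapsed time must be positive")
    return math.log(nt / n0) / t


@dataclass
class GrowthEstimate:
    r: float
    n0: float
    nt: float
    t: float
    interval: tuple[float, float]   # (start, end) times before present
    flat: bool = field(default=False)

    def __post_init__(self) -> None:
        assert abs(self.r - math.log(self.nt / self.n0) / self.t) < 1e-9


def fastest_growth_interval(
    series: SkylineSeries, window: int | None = None
) -> GrowthEstimate:
    """Locate the contiguous window of fastest exponential growth.

    All contiguous windows of >= 2 points are scanned (or only windows of
    exactly ``window`` points when given).  For each window the initial
    size N0 is the minimum Ne over the window's first point and its
    immediate predecessor — the minimum size immediately preceding the
    growth phase — and the elapsed time runs from that minimum to the
    window's last point.  Ties go to the earliest window.
    """
    chrono = series.chronological()   # oldest first, time-before-present decreasing
    times = chrono.times
    ne = chrono.ne
    n = len(times)
    if n < 2:
        raise ValueError("need at least 2 skyline points")
    best: GrowthEstimate | None = None
    lengths = range(2, n + 1) if window is None else [window]
    for i in range(n):
        for length in lengths:
            j = i + length - 1
            if j >= n:
                continue
            # candidate starts: the window's leading point, or a strictly
            # lower immediate predecessor (a dip just before growth began)
            starts = [i]
            if i > 0 and ne[i - 1] < ne[i]:
                starts.append(i - 1)
            for i_star in starts:
                t_elapsed = times[i_star] - times[j]   # years b.p. shrink forward
                if t_elapsed <= 0:
                    continue
                r = growth_rate(ne[i_star], ne[j], t_elapsed)
                if best is None or r > best.r + 1e-15:
                    best = GrowthEstimate(
                        r=r, n0=ne[i_star], nt=ne[j], t=t_elapsed,
                        interval=(times[i_star], times[j]),
                    )
    assert best is not None
    if abs(best.r) < 1e-15:
        logger.warning("skyline series is flat; growth rate 0")
        best.flat = True
    return best
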