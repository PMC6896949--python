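"""Three-source admixture-contribution likelihood and its grid-search
maximizer.

The invasive group's allele counts are modelled as draws from a mixture of
the three source populations' allele-frequency spectra with weights
(a, b, c = 1 − a − b):

    lnP(a, b) = Σ_i Σ_j n_ij · ln[a·f_ij,1 + b·f_ij,2 + (1 − a − b)·f_ij,3]

summed over loci i and alleles j, where n_ij are pooled invasive allele
counts and f_ij,s the source frequencies.  The objective is concave in
(a, b) (a sum of logs of affine functions), so a lattice scan over the
simplex finds the global maximum up to grid resolution; an optional
refinement pass re-scans at one tenth of the step around the coarse
optimum.

Alleles observed in the invasive group but carried by no source would make
the likelihood identically zero; they are excluded from the sum and
reported (candidate post-introduction mutations), or optionally absorbed
with a small pseudo-frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .popstats import AlleleTable

logger = logging.getLogger("invmix")


@dataclass
class ContributionEstimate:
    """Maximum-likelihood source contributions (a, b, c = 1 − a − b)."""

    a: float
    b: float
    lnP: float
    grid_step: float
    excluded_alleles: list[tuple[str, int]] = field(default_factory=list)
    surface: pd.DataFrame | None = None
    refined: bool = False

    @property
    def c(self) -> float:
        return 1.0 - self.a - self.b

    def as_dict(self) -> dict[str, float]:
        return {"a": self.a, "b": self.b, "c": self.c, "lnP": self.lnP}


@dataclass
class _Arrays:
    """Counts and the three source-frequency vectors aligned over the
    (locus, allele) support actually entering the sum."""

    counts: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    f3: np.ndarray
    excluded: list[tuple[str, int]]
    support: list[tuple[str, int]]


def _align(
    source_freqs: AlleleTable,
    sources: Sequence[str],
    invasive_counts: AlleleTable,
    invasive_unit: str,
    pseudo_freq: float = 0.0,
) -> _Arrays:
    if len(sources) != 3:
        raise ValueError("exactly three source units are required")
    for s in sources:
        if s not in source_freqs.counts:
            raise ValueError(f"source unit {s!r} absent from frequency table")
    if invasive_unit not in invasive_counts.counts:
        raise ValueError(f"invasive unit {invasive_unit!r} absent from count table")
    if set(source_freqs.loci) != set(invasive_counts.loci):
        raise ValueError(
            "locus mismatch between source and invasive tables: "
            f"{sorted(set(source_freqs.loci) ^ set(invasive_counts.loci))}"
        )
    counts, f1, f2, f3 = [], [], [], []
    excluded: list[tuple[str, int]] = []
    support: list[tuple[str, int]] = []
    for locus in invasive_counts.loci:
        n_loc = invasive_counts.counts[invasive_unit][locus]
        freqs = [source_freqs.frequencies(s, locus) for s in sources]
        for allele, n in sorted(n_loc.items()):
            if n == 0:
                continue
            fs = [f.get(allele, 0.0) for f in freqs]
            if all(v == 0.0 for v in fs):
                if pseudo_freq > 0.0:
                    fs = [pseudo_freq] * 3
                else:
                    excluded.append((locus, allele))
                    continue
            counts.append(n)
            f1.append(fs[0])
            f2.append(fs[1])
            f3.append(fs[2])
            support.append((locus, allele))
    if excluded:
        logger.warning(
            "%d invasive allele(s) absent from all sources excluded from the "
            "likelihood: %s", len(excluded), excluded,
        )
    return _Arrays(
        counts=np.array(counts, dtype=float),
        f1=np.array(f1), f2=np.array(f2), f3=np.array(f3),
        excluded=excluded, support=support,
    )


def _lnp(arrays: _Arrays, a: float, b: float) -> float:
    mix = a * arrays.f1 + b * arrays.f2 + (1.0 - a - b) * arrays.f3
    if np.any(mix <= 0.0):
        bad = [arrays.support[k] for k in np.nonzero(mix <= 0.0)[0]]
        logger.debug("zero mixture frequency at %s for (a,b)=(%g,%g)", bad, a, b)
        return -math.inf
    return float(arrays.counts @ np.log(mix))


def log_likelihood(
    a: float,
    b: float,
    source_freqs: AlleleTable,
    invasive_counts: AlleleTable,
    sources: Sequence[str],
    invasive_unit: str,
    pseudo_freq: float = 0.0,
) -> float:
    """lnP(a, b) for one point of the simplex; −inf where an observed allele
    gets zero mixture frequency (its sole carrier has weight 0)."""
    if a < 0 or b < 0 or a + b > 1 + 1e-12:
        raise ValueError(f"(a, b) = ({a}, {b}) outside the simplex")
    arrays = _align(source_freqs, sources, invasive_counts, invasive_unit, pseudo_freq)
    return _lnp(arrays, a, b)


def _lattice(step: float) -> list[tuple[float, float]]:
    n = round(1.0 / step)
    pts = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            pts.append((i * step, j * step))
    return pts


def grid_search(
    source_freqs: AlleleTable,
    invasive_counts: AlleleTable,
    sources: Sequence[str],
    invasive_unit: str,
    step: float = 0.01,
    refine: bool = False,
    keep_surface: bool = False,
    pseudo_freq: float = 0.0,
) -> ContributionEstimate:
    """Maximize lnP over the simplex lattice {(a, b): a, b ∈ {0, step, …, 1},
    a + b ≤ 1}; ties broken by smallest a, then smallest b."""
    if not 0.0 < step <= 0.5:
        raise ValueError("step must lie in (0, 0.5]")
    arrays = _align(source_freqs, sources, invasive_counts, invasive_unit, pseudo_freq)

    def scan(points: list[tuple[float, float]]):
        a_vec = np.array([p[0] for p in points])
        b_vec = np.array([p[1] for p in points])
        # lattice x allele-entry mixture matrix, evaluated in one shot
        mix = (
            a_vec[:, None] * arrays.f1[None, :]
            + b_vec[:, None] * arrays.f2[None, :]
            + (1.0 - a_vec - b_vec)[:, None] * arrays.f3[None, :]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            lnp = np.where(mix > 0.0, np.log(mix), -np.inf) @ arrays.counts
        values = [float(v) for v in lnp]
        best = max(values)
        if best == -math.inf:
            raise RuntimeError(
                "likelihood is -inf on the whole lattice; offending alleles: "
                f"{arrays.excluded or arrays.support}"
            )
        # ties -> smallest a, then smallest b
        cands = [p for p, v in zip(points, values) if v == best]
        a, b = min(cands)
        return a, b, best, values

    points = _lattice(step)
    a, b, best, values = scan(points)
    refined = False
    if refine:
        fine = step / 10.0
        fine_pts = [
            (round(a + i * fine, 12), round(b + j * fine, 12))
            for i in range(-10, 11)
            for j in range(-10, 11)
            if a + i * fine >= -1e-12 and b + j * fine >= -1e-12
            and (a + i * fine) + (b + j * fine) <= 1 + 1e-12
        ]
        fine_pts = [(max(x, 0.0), max(y, 0.0)) for x, y in fine_pts]
        fa, fb, fbest, _ = scan(fine_pts)
        if fbest >= best:
            a, b, best = fa, fb, fbest
            refined = True
    surface = None
    if keep_surface:
        surface = pd.DataFrame(
            {"a": [p[0] for p in points], "b": [p[1] for p in points], "lnP": values}
        )
    return ContributionEstimate(
        a=a, b=b, lnP=best, grid_step=step,
        excluded_alleles=arrays.excluded, surface=surface, refined=refined,
    )


def likelihood_surface(estimate: ContributionEstimate) -> pd.DataFrame:
    """The full (a, b, lnP) lattice evaluated by the grid search."""
    if estimate.surface is None:
        raise ValueError("grid_search was run without keep_surface=True")
    return estimate.surface
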