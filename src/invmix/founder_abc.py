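"""Approximate Bayesian computation scan over the founder sample size N.

For a candidate N, a founding event draws 2N allele copies per locus —
a·2N from source 1, b·2N from source 2 and (1 − a − b)·2N from source 3
under the conventional diploid counting — and the simulated allele
*presence* spectrum is compared with the observed invasive spectrum.  The
matching frequency over replicates is a Monte-Carlo estimate of the
probability that a founding sample of that size reproduces exactly the
invasive allele pool: too few founders miss observed alleles, too many
import source alleles absent from the invaders, so the curve over N is
bell-shaped and its mode estimates the founding sample size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .popstats import AlleleTable

logger = logging.getLogger("invmix")

# Observed/simulated spectra: mapping locus -> frozenset of present alleles.
Spectrum = Mapping[str, frozenset]


def spectrum_from_table(table: AlleleTable, unit: str) -> dict[str, frozenset]:
    """Per-locus allele presence sets of one unit of an allele table."""
    return {
        locus: frozenset(
            a for a, c in table.counts[unit][locus].items() if c > 0
        )
        for locus in table.loci
    }


def founder_composition(a: float, b: float, n_founders: int) -> tuple[int, int, int]:
    """Allele-draw counts (k1, k2, k3) = (a·2N, b·2N, rest), rounded half
    away from zero with the remainder forced onto the third component;
    a negative remainder is repaired by decrementing the largest component."""
    if a < 0 or b < 0 or a + b > 1 + 1e-12:
        raise ValueError(f"(a, b) = ({a}, {b}) outside the simplex")
    if n_founders < 1:
        raise ValueError("N must be >= 1")
    total = 2 * n_founders

    def round_half_away(x: float) -> int:
        return int(np.floor(x + 0.5))

    k1 = round_half_away(a * total)
    k2 = round_half_away(b * total)
    k3 = total - k1 - k2
    while k3 < 0:
        if k1 >= k2:
            k1 -= 1
        else:
            k2 -= 1
        k3 = total - k1 - k2
    return k1, k2, k3


def _locus_freq_arrays(
    source_freqs: AlleleTable, sources: Sequence[str]
) -> dict[str, tuple[list, np.ndarray]]:
    """Per locus: (allele labels, 3 x n_alleles frequency matrix over the
    union of source supports)."""
    out: dict[str, tuple[list, np.ndarray]] = {}
    for locus in source_freqs.loci:
        freqs = [source_freqs.frequencies(s, locus) for s in sources]
        alleles = sorted(set().union(*[f.keys() for f in freqs]))
        mat = np.array([[f.get(a, 0.0) for a in alleles] for f in freqs])
        out[locus] = (alleles, mat)
    return out


def simulate_founder_spectrum(
    source_freqs: AlleleTable,
    sources: Sequence[str],
    composition: tuple[int, int, int],
    seed: int | np.random.Generator | None = None,
) -> dict[str, frozenset]:
    """One founding draw: at each locus, k_s multinomial allele draws from
    source s; returns the per-locus set of alleles drawn."""
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    arrays = _locus_freq_arrays(source_freqs, sources)
    spectrum: dict[str, frozenset] = {}
    for locus, (alleles, mat) in arrays.items():
        counts = np.zeros(len(alleles), dtype=np.int64)
        for s, k in enumerate(composition):
            if k > 0:
                counts += rng.multinomial(k, mat[s])
        spectrum[locus] = frozenset(
            a for a, c in zip(alleles, counts) if c > 0
        )
    return spectrum


def _parse_criterion(criterion: str) -> int:
    """Return the allowed number of allele mismatches (0 for exact-set)."""
    if criterion == "exact-set":
        return 0
    if criterion.startswith("tolerant(") and criterion.endswith(")"):
        try:
            k = int(criterion[len("tolerant("):-1])
        except ValueError:
            raise ValueError(f"unknown criterion {criterion!r}") from None
        if k < 0:
            raise ValueError("tolerance must be >= 0")
        return k
    raise ValueError(f"unknown criterion {criterion!r}")


def is_match(
    simulated: Spectrum, observed: Spectrum, criterion: str = "exact-set"
) -> bool:
    """Exact-set: per-locus allele presence sets identical everywhere;
    tolerant(k): at most k allele mismatches (symmetric differences) total."""
    if set(simulated) != set(observed):
        raise ValueError("spectra cover different locus sets")
    tol = _parse_criterion(criterion)
    mismatches = sum(
        len(frozenset(simulated[l]) ^ frozenset(observed[l])) for l in observed
    )
    return mismatches <= tol


@dataclass
class ABCScanResult:
    grid: pd.DataFrame            # columns: N, matching_frequency, n_reps
    optimal_n: int | None
    match_criterion: str
    seed: int | None
    a: float
    b: float
    no_signal: bool = False

    def as_dict(self) -> dict:
        return {
            "optimal_N": self.optimal_n,
            "criterion": self.match_criterion,
            "no_signal": self.no_signal,
            "grid": self.grid.to_dict(orient="records"),
        }


def abc_scan(
    source_freqs: AlleleTable,
    sources: Sequence[str],
    observed_spectrum: Spectrum,
    a: float,
    b: float,
    n_grid: Sequence[int],
    n_reps: int = 100_000,
    criterion: str = "exact-set",
    seed: int | None = None,
) -> ABCScanResult:
    """Scan founder sizes N, estimating the matching frequency at each by
    Monte Carlo; optimal N is the argmax (ties -> smallest N).

    Replicates are vectorized: per source and locus one multinomial block
    of shape (n_reps, n_alleles), presence compared against the observed
    spectrum per locus, then AND-ed across loci.
    """
    n_grid = list(n_grid)
    if not n_grid or any(
        n2 <= n1 for n1, n2 in zip(n_grid, n_grid[1:])
    ):
        raise ValueError("N grid must be nonempty and strictly ascending")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tol = _parse_criterion(criterion)
    if set(observed_spectrum) != set(source_freqs.loci):
        raise ValueError("observed spectrum and source table cover different loci")
    rng = np.random.default_rng(seed)
    arrays = _locus_freq_arrays(source_freqs, sources)
    obs_masks = {}
    for locus, (alleles, _) in arrays.items():
        extra = set(observed_spectrum[locus]) - set(alleles)
        if extra:
            logger.warning(
                "observed alleles %s at locus %s absent from all sources can "
                "never be drawn", sorted(extra), locus,
            )
        obs_masks[locus] = (
            np.array([al in observed_spectrum[locus] for al in alleles]),
            len(extra),
        )

    rows = []
    for n_founders in n_grid:
        comp = founder_composition(a, b, n_founders)
        mismatch_total = np.zeros(n_reps, dtype=np.int64)
        for locus, (alleles, mat) in arrays.items():
            counts = np.zeros((n_reps, len(alleles)), dtype=np.int64)
            for s, k in enumerate(comp):
                if k > 0:
                    counts += rng.multinomial(k, mat[s], size=n_reps)
            presence = counts > 0
            obs_mask, n_unreachable = obs_masks[locus]
            mismatch_total += (presence != obs_mask).sum(axis=1) + n_unreachable
        matches = int(np.count_nonzero(mismatch_total <= tol))
        rows.append(
            {"N": n_founders, "matching_frequency": matches / n_reps, "n_reps": n_reps}
        )
    grid = pd.DataFrame(rows)
    if grid["matching_frequency"].max() == 0.0:
        logger.warning(
            "no matches at any N; consider a tolerant(k) criterion or more reps"
        )
        return ABCScanResult(
            grid=grid, optimal_n=None, match_criterion=criterion, seed=seed,
            a=a, b=b, no_signal=True,
        )
    best = grid["matching_frequency"].max()
    optimal = int(grid.loc[grid["matching_frequency"] == best, "N"].min())
    return ABCScanResult(
        grid=grid, optimal_n=optimal, match_criterion=criterion, seed=seed, a=a, b=b,
    )
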