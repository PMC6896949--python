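"""Readers/writers and validated containers for genotype matrices,
haplotype alignments and skyline series.

Genotype matrices hold codominant microsatellite calls for polyploid
individuals: each cell is a *multiset* of allele labels (integer fragment
sizes), at most ``ploidy`` of them, with dosage not necessarily resolved.
Two on-disk dialects are supported:

* a GenAlex-style codominant CSV with ``ploidy`` allele columns per locus
  and ``0`` marking an unscored allele slot (three header rows:
  counts, titles, column names);
* a long-format TSV, one row per (individual, locus) with columns
  ``individual  population  group  locus  a1..a<ploidy>`` — this is the
  package's canonical, bit-exact round-trip format.

Chloroplast alignments are read from FASTA with headers ``>individual|population``.
Haplotypes are called on the variable characters of the alignment, where a
contiguous run of gap columns sharing one gap pattern is collapsed to a
single fifth-state (indel) character, so a multi-base indel counts as one
polymorphism.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("invmix")

MISSING: tuple[int, ...] = ()


class FormatError(ValueError):
    """Malformed input file (bad header, ragged rows, wrong column count)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a container invariant."""


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x loci table of allele-call multisets with population labels.

    ``calls[(individual, locus)]`` is a sorted tuple of positive integer
    allele labels of length <= ``ploidy``; the empty tuple flags a missing
    (fully unscored) cell.  ``group`` maps population codes to group labels
    (e.g. ``source`` / ``non-source`` / ``introduced``).
    """

    individuals: list[str]
    population: dict[str, str]
    group: dict[str, str]
    loci: list[str]
    calls: dict[tuple[str, str], tuple[int, ...]]
    ploidy: int = 6

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.ploidy < 1:
            raise ValidationError("ploidy must be a positive integer")
        for ind in self.individuals:
            pop = self.population.get(ind)
            if pop is None:
                raise ValidationError(f"individual {ind!r} has no population")
            if pop not in self.group:
                raise ValidationError(
                    f"population {pop!r} of {ind!r} missing from group mapping"
                )
            for locus in self.loci:
                cell = self.calls.get((ind, locus))
                if cell is None:
                    raise ValidationError(f"no entry for ({ind!r}, {locus!r})")
                if len(cell) > self.ploidy:
                    raise ValidationError(
                        f"cell ({ind!r}, {locus!r}) holds {len(cell)} calls "
                        f"> ploidy {self.ploidy}"
                    )
                if any((not isinstance(a, int)) or a <= 0 for a in cell):
                    raise ValidationError(
                        f"cell ({ind!r}, {locus!r}) holds a non-positive allele label"
                    )

    @property
    def populations(self) -> list[str]:
        """Population codes in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.population[ind], None)
        return list(seen)

    def individuals_of(self, pop: str) -> list[str]:
        return [i for i in self.individuals if self.population[i] == pop]

    def subset(self, individuals: Sequence[str]) -> "GenotypeMatrix":
        keep = set(individuals)
        return GenotypeMatrix(
            individuals=[i for i in self.individuals if i in keep],
            population={i: p for i, p in self.population.items() if i in keep},
            group=dict(self.group),
            loci=list(self.loci),
            calls={
                (i, l): c for (i, l), c in self.calls.items() if i in keep
            },
            ploidy=self.ploidy,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.population == other.population
            and self.group == other.group
            and self.loci == other.loci
            and self.calls == other.calls
            and self.ploidy == other.ploidy
        )


def _normalize_cell(alleles: Iterable[int]) -> tuple[int, ...]:
    """Sorted multiset of the nonzero allele calls (0 = unscored slot)."""
    return tuple(sorted(a for a in alleles if a != 0))


def read_genotypes(
    path: str | Path,
    dialect: str = "long",
    ploidy: int = 6,
    groups: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix in the ``"long"`` TSV or ``"genalex"`` CSV dialect.

    For the GenAlex dialect (which carries no group labels) ``groups`` maps
    population codes to group labels; populations absent from it default to
    ``"ungrouped"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long":
        matrix = _read_long(path, ploidy)
    elif dialect == "genalex":
        matrix = _read_genalex(path, ploidy, groups or {})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    logger.info(
        "read %d individuals, %d loci, %d populations from %s",
        len(matrix.individuals), len(matrix.loci), len(matrix.populations), path,
    )
    return matrix


def _read_long(path: Path, ploidy: int) -> GenotypeMatrix:
    expected = 4 + ploidy
    individuals: list[str] = []
    population: dict[str, str] = {}
    group: dict[str, str] = {}
    loci: list[str] = []
    calls: dict[tuple[str, str], tuple[int, ...]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["individual", "population", "group", "locus"]:
            raise FormatError(f"{path}:1: malformed long-format header {header[:4]}")
        if len(header) != expected:
            raise FormatError(
                f"{path}:1: expected {ploidy} allele columns, got {len(header) - 4}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != expected:
                raise FormatError(f"{path}:{lineno}: expected {expected} fields")
            ind, pop, grp, locus = fields[:4]
            try:
                alleles = [int(a) for a in fields[4:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer allele call") from exc
            if ind not in population:
                individuals.append(ind)
                population[ind] = pop
            elif population[ind] != pop:
                raise ValidationError(
                    f"{path}:{lineno}: individual {ind!r} listed under two populations"
                )
            if pop in group and group[pop] != grp:
                raise ValidationError(
                    f"{path}:{lineno}: population {pop!r} listed under two groups"
                )
            group[pop] = grp
            if locus not in loci:
                loci.append(locus)
            calls[(ind, locus)] = _normalize_cell(alleles)
    # absent (individual, locus) rows are missing cells
    for ind in individuals:
        for locus in loci:
            calls.setdefault((ind, locus), MISSING)
    return GenotypeMatrix(individuals, population, group, loci, calls, ploidy)


def _read_genalex(
    path: Path, ploidy: int, groups: Mapping[str, str]
) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3:
        raise FormatError(f"{path}: GenAlex file needs 3 header rows")
    try:
        n_loci = int(rows[0][0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}:1: first header cell must be the locus count") from exc
    colnames = rows[2]
    if len(colnames) < 2 + n_loci * ploidy:
        raise FormatError(
            f"{path}:3: allele column count {len(colnames) - 2} is not "
            f"{n_loci} loci x ploidy {ploidy}"
        )
    loci = [colnames[2 + k * ploidy] for k in range(n_loci)]
    if any(not name for name in loci):
        raise FormatError(f"{path}:3: empty locus name in header")
    individuals: list[str] = []
    population: dict[str, str] = {}
    calls: dict[tuple[str, str], tuple[int, ...]] = {}
    for lineno, row in enumerate(rows[3:], start=4):
        if not any(cell.strip() for cell in row):
            continue
        if len(row) < 2 + n_loci * ploidy:
            raise FormatError(f"{path}:{lineno}: short data row")
        ind, pop = row[0], row[1]
        individuals.append(ind)
        population[ind] = pop
        for k, locus in enumerate(loci):
            cells = row[2 + k * ploidy: 2 + (k + 1) * ploidy]
            try:
                alleles = [int(c) if c.strip() else 0 for c in cells]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer allele call") from exc
            calls[(ind, locus)] = _normalize_cell(alleles)
    group = {pop: groups.get(pop, "ungrouped") for pop in set(population.values())}
    unknown = set(groups) - set(population.values())
    if unknown:
        raise ValidationError(
            f"group mapping names unknown population code(s): {sorted(unknown)}"
        )
    return GenotypeMatrix(individuals, population, group, loci, calls, ploidy)


def write_genotypes(
    matrix: GenotypeMatrix, path: str | Path, dialect: str = "long"
) -> None:
    """Serialize a matrix; the long-format TSV round-trips bit-exactly."""
    matrix.validate()  # refuses over-ploidy cells before touching disk
    path = Path(path)
    if dialect == "long":
        _write_long(matrix, path)
    elif dialect == "genalex":
        _write_genalex(matrix, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_long(matrix: GenotypeMatrix, path: Path) -> None:
    p = matrix.ploidy
    with open(path, "w") as fh:
        cols = ["individual", "population", "group", "locus"] + [
            f"a{k + 1}" for k in range(p)
        ]
        fh.write("\t".join(cols) + "\n")
        for ind in matrix.individuals:
            pop = matrix.population[ind]
            grp = matrix.group[pop]
            for locus in matrix.loci:
                cell = matrix.calls[(ind, locus)]
                padded = list(cell) + [0] * (p - len(cell))
                fh.write(
                    "\t".join([ind, pop, grp, locus] + [str(a) for a in padded])
                    + "\n"
                )


def _write_genalex(matrix: GenotypeMatrix, path: Path) -> None:
    p = matrix.ploidy
    pops = matrix.populations
    sizes = [len(matrix.individuals_of(pop)) for pop in pops]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([len(matrix.loci), len(matrix.individuals), len(pops)] + sizes)
        w.writerow(["invmix export", "", ""] + pops)
        header = ["Sample", "Pop"]
        for locus in matrix.loci:
            header += [locus] + [""] * (p - 1)
        w.writerow(header)
        for ind in matrix.individuals:
            row: list[object] = [ind, matrix.population[ind]]
            for locus in matrix.loci:
                cell = matrix.calls[(ind, locus)]
                row += list(cell) + [0] * (p - len(cell))
            w.writerow(row)


# ---------------------------------------------------------------------------
# HaplotypeAlignment
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAlignment:
    """Aligned haploid (chloroplast) sequences with haplotype assignments.

    ``variable_sites`` indexes the reduced character matrix (0-based), in
    which each indel event occupies a single column; ``site_columns`` maps
    each reduced character back to the alignment columns it spans.
    Haplotype labels are ``H1, H2, ...`` by decreasing global frequency,
    ties broken by first occurrence in the input.
    """

    sequences: dict[str, str]
    population: dict[str, str]
    variable_sites: list[int]
    haplotype_of: dict[str, str]
    alignment_length: int
    site_columns: list[tuple[int, ...]] = field(default_factory=list)
    haplotype_profile: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def individuals(self) -> list[str]:
        return list(self.sequences)

    @property
    def haplotypes(self) -> list[str]:
        """Labels sorted by their numeric rank (H1 first)."""
        return sorted(set(self.haplotype_of.values()), key=lambda h: int(h[1:]))

    def haplotype_counts(self) -> Counter:
        return Counter(self.haplotype_of.values())

    def distance_matrix(self) -> pd.DataFrame:
        """Pairwise haplotype distances: number of differing variable characters."""
        labels = self.haplotypes
        dm = pd.DataFrame(0.0, index=labels, columns=labels)
        for i, hi in enumerate(labels):
            for hj in labels[i + 1:]:
                d = sum(
                    a != b
                    for a, b in zip(self.haplotype_profile[hi], self.haplotype_profile[hj])
                )
                dm.loc[hi, hj] = dm.loc[hj, hi] = float(d)
        return dm


def _reduce_characters(seqs: list[str]) -> tuple[list[tuple[int, ...]], list[tuple[str, ...]]]:
    """Collapse each indel event (run of gap columns with one gap pattern)
    into a single character; return (column spans, per-character state vectors)."""
    length = len(seqs[0])
    spans: list[tuple[int, ...]] = []
    states: list[tuple[str, ...]] = []
    col = 0
    while col < length:
        column = tuple(s[col] for s in seqs)
        if "-" in column:
            gap_pattern = tuple(c == "-" for c in column)
            run = [col]
            nxt = col + 1
            while nxt < length:
                nxt_col = tuple(s[nxt] for s in seqs)
                if "-" in nxt_col and tuple(c == "-" for c in nxt_col) == gap_pattern:
                    run.append(nxt)
                    nxt += 1
                else:
                    break
            # fifth state: present/absent of the indel, plus the inserted bases
            states.append(
                tuple("-" if g else "".join(s[c] for c in run) for s, g in zip(seqs, gap_pattern))
            )
            spans.append(tuple(run))
            col = nxt
        else:
            states.append(column)
            spans.append((col,))
            col += 1
    return spans, states


def read_alignment(path: str | Path) -> HaplotypeAlignment:
    """Read an aligned FASTA (headers ``>individual|population``), detect
    variable characters and call haplotypes by identity over them."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or non-FASTA file")
    sequences: dict[str, str] = {}
    population: dict[str, str] = {}
    for rec in records:
        tokens = rec.id.split("|")
        ind = tokens[0]
        pop = tokens[1] if len(tokens) > 1 else "unknown"
        sequences[ind] = str(rec.seq).upper()
        population[ind] = pop
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged alignment, lengths {sorted(lengths)}")
    return build_alignment(sequences, population)


def build_alignment(
    sequences: Mapping[str, str], population: Mapping[str, str]
) -> HaplotypeAlignment:
    """Assemble a HaplotypeAlignment from in-memory sequences (the reader's core)."""
    inds = list(sequences)
    seqs = [sequences[i] for i in inds]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise FormatError("ragged alignment")
    spans, states = _reduce_characters(seqs)
    variable = [k for k, st in enumerate(states) if len(set(st)) > 1]
    profiles = {
        ind: tuple(states[k][i] for k in variable) for i, ind in enumerate(inds)
    }
    # label by decreasing frequency, ties by first occurrence
    counts: Counter = Counter(profiles.values())
    first_seen = {}
    for pos, ind in enumerate(inds):
        first_seen.setdefault(profiles[ind], pos)
    ordered = sorted(counts, key=lambda pr: (-counts[pr], first_seen[pr]))
    label_of = {pr: f"H{k + 1}" for k, pr in enumerate(ordered)}
    haplotype_of = {ind: label_of[profiles[ind]] for ind in inds}
    return HaplotypeAlignment(
        sequences=dict(sequences),
        population=dict(population),
        variable_sites=variable,
        haplotype_of=haplotype_of,
        alignment_length=length,
        site_columns=[spans[k] for k in variable],
        haplotype_profile={label_of[pr]: pr for pr in ordered},
    )


def write_alignment(alignment: HaplotypeAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind, seq in alignment.sequences.items():
            fh.write(f">{ind}|{alignment.population[ind]}\n{seq}\n")


# ---------------------------------------------------------------------------
# SkylineSeries
# ---------------------------------------------------------------------------

@dataclass
class SkylineSeries:
    """Ordered (time-before-present, Ne) points from a Bayesian skyline plot.

    ``orientation`` declares whether times run from past to present
    ("decreasing", time-before-present shrinking along the series) or the
    reverse; growth-rate scans normalise to chronological order internally.
    """

    times: list[float]
    ne: list[float]
    lower: list[float] | None = None
    upper: list[float] | None = None
    orientation: str = "decreasing"

    def __post_init__(self) -> None:
        if len(self.times) != len(self.ne):
            raise ValidationError("times and Ne differ in length")
        if any(n <= 0 for n in self.ne):
            raise ValidationError("Ne must be positive at every skyline point")
        diffs = [b - a for a, b in zip(self.times, self.times[1:])]
        if all(d < 0 for d in diffs):
            self.orientation = "decreasing"
        elif all(d > 0 for d in diffs):
            self.orientation = "increasing"
        elif diffs:
            raise ValidationError("skyline times must be strictly monotone")

    @property
    def n_points(self) -> int:
        return len(self.times)

    def chronological(self) -> "SkylineSeries":
        """Points ordered oldest-first (time before present decreasing)."""
        if self.orientation == "increasing":
            return SkylineSeries(
                times=self.times[::-1],
                ne=self.ne[::-1],
                lower=None if self.lower is None else self.lower[::-1],
                upper=None if self.upper is None else self.upper[::-1],
            )
        return self


def read_skyline(path: str | Path) -> SkylineSeries:
    """Read a skyline TSV with columns ``time  ne [lower upper]``."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "time" not in cols or "ne" not in cols:
        raise FormatError(f"{path}: need 'time' and 'ne' columns, got {cols}")
    return SkylineSeries(
        times=df["time"].astype(float).tolist(),
        ne=df["ne"].astype(float).tolist(),
        lower=df["lower"].astype(float).tolist() if "lower" in cols else None,
        upper=df["upper"].astype(float).tolist() if "upper" in cols else None,
    )


def write_skyline(series: SkylineSeries, path: str | Path) -> None:
    data = {"time": series.times, "ne": series.ne}
    if series.lower is not None:
        data["lower"] = series.lower
    if series.upper is not None:
        data["upper"] = series.upper
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
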