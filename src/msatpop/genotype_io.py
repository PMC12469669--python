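"""Data model and I/O for codominant diploid microsatellite genotypes.

Genotypes are unordered pairs of integer allele sizes (bp). Two table formats
are supported: a simple CSV dialect (``individual,population,<locus>,...`` with
``A/B`` cells, empty cell = missing) and GenePop 4.x (three- or six-digit
allele coding on read, six-digit on write, ``0`` codes for missing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger("msatpop")

MISSING = None  # sentinel meaning "both alleles untyped"


class ParseError(ValueError):
    """Malformed genotype table (names the offending line)."""


class NoDataError(ValueError):
    """A population x locus cell has zero typed individuals."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite marker.

    Parameters
    ----------
    name : str
        Marker label, unique within a dataset (e.g. ``"Sat3"``).
    expected_size_range : tuple of (int, int), optional
        Expected PCR product size range in bp; bands outside it are suspect.
    annealing_temp : float, optional
        PCR annealing temperature in deg C (metadata only).
    """

    name: str
    expected_size_range: tuple[int, int] | None = None
    annealing_temp: float | None = None

    def __post_init__(self) -> None:
        if self.expected_size_range is not None:
            lo, hi = self.expected_size_range
            if not lo < hi:
                raise ValueError(f"locus {self.name}: size range min must be < max")


@dataclass(frozen=True)
class Individual:
    id: str
    population: str


@dataclass(frozen=True)
class Genotype:
    """Unordered diploid genotype; stored canonically with allele_a <= allele_b.

    Either both alleles are present (positive integer bp) or both are missing.
    """

    allele_a: int | None
    allele_b: int | None

    def __post_init__(self) -> None:
        a, b = self.allele_a, self.allele_b
        if (a is None) != (b is None):
            raise ValueError("genotype must have both alleles present or both missing")
        if a is not None:
            if a <= 0 or b <= 0:
                raise ValueError("allele sizes must be positive")
            if a > b:  # canonicalise: unordered pair
                object.__setattr__(self, "allele_a", b)
                object.__setattr__(self, "allele_b", a)

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None

    @property
    def is_heterozygous(self) -> bool:
        if self.is_missing:
            raise ValueError("missing genotype has no zygosity")
        return self.allele_a != self.allele_b

    def alleles(self) -> tuple[int, int]:
        if self.is_missing:
            raise ValueError("missing genotype has no alleles")
        return (self.allele_a, self.allele_b)


MISSING_GENOTYPE = Genotype(None, None)


@dataclass
class GenotypeDataset:
    """Individuals x loci table of diploid allele-size genotypes.

    ``calls`` maps ``(individual_id, locus_name)`` to a :class:`Genotype`;
    every pair must be resolvable (missing cells are explicit).
    """

    loci: list[Locus]
    individuals: list[Individual]
    calls: dict[tuple[str, str], Genotype]

    def __post_init__(self) -> None:
        locus_names = [l.name for l in self.loci]
        if len(set(locus_names)) != len(locus_names):
            raise ValueError("duplicate locus names")
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual id(s): {dup}")
        if not self.populations():
            raise ValueError("dataset must contain at least one population")
        for ind in self.individuals:
            for name in locus_names:
                if (ind.id, name) not in self.calls:
                    raise ValueError(f"missing call entry for ({ind.id}, {name})")

    # -- grouping helpers -------------------------------------------------

    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population, None)
        return list(seen)

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for ind in self.individuals:
            sizes[ind.population] = sizes.get(ind.population, 0) + 1
        return sizes

    def members(self, population: str) -> list[Individual]:
        return [ind for ind in self.individuals if ind.population == population]

    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def genotypes(self, population: str, locus: str) -> list[Genotype]:
        """Non-missing genotypes for one population x locus cell."""
        return [
            g
            for ind in self.members(population)
            if not (g := self.calls[(ind.id, locus)]).is_missing
        ]


@dataclass(frozen=True)
class AlleleFrequencySpectrum:
    """Per (population, locus) allele -> frequency map with gene sample count.

    ``n_genes`` is 2 x the number of typed (non-missing) individuals.
    """

    population: str
    locus: str
    freqs: Mapping[int, float]
    n_genes: int

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_genes % 2:
            raise ValueError("n_genes must be even and >= 2")
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")
        if any(not (0.0 < f <= 1.0) for f in self.freqs.values()):
            raise ValueError("every frequency must lie in (0, 1]")

    def frequencies(self) -> list[float]:
        """Frequencies in ascending-allele order."""
        return [self.freqs[a] for a in sorted(self.freqs)]


def allele_frequencies(
    ds: GenotypeDataset, population: str, locus: str
) -> AlleleFrequencySpectrum:
    """Sample allele frequencies for one population x locus cell.

    Each non-missing individual contributes 2 genes. Raises
    :class:`NoDataError` when no individual is typed.
    """
    counts: dict[int, int] = {}
    n_genes = 0
    for g in ds.genotypes(population, locus):
        for a in g.alleles():
            counts[a] = counts.get(a, 0) + 1
            n_genes += 1
    if n_genes == 0:
        raise NoDataError(f"no typed individuals for {population} x {locus}")
    return AlleleFrequencySpectrum(
        population=population,
        locus=locus,
        freqs={a: c / n_genes for a, c in counts.items()},
        n_genes=n_genes,
    )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------


def _parse_csv_cell(cell: str, lineno: int) -> Genotype:
    cell = cell.strip()
    if not cell:
        return MISSING_GENOTYPE
    parts = cell.split("/")
    if len(parts) != 2:
        raise ParseError(f"line {lineno}: genotype cell {cell!r} is not 'A/B'")
    try:
        a, b = (int(p) for p in parts)
    except ValueError:
        raise ParseError(
            f"line {lineno}: non-integer allele size in cell {cell!r}"
        ) from None
    if a == 0 and b == 0:
        return MISSING_GENOTYPE
    try:
        return Genotype(a, b)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None


def _read_csv(path: Path) -> GenotypeDataset:
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(",")]
    if len(header) < 3 or header[0] != "individual" or header[1] != "population":
        raise ParseError(
            f"{path}: header must be 'individual,population,<locus1>,...'"
        )
    loci = [Locus(name) for name in header[2:]]
    individuals: list[Individual] = []
    calls: dict[tuple[str, str], Genotype] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != len(header):
            raise ParseError(
                f"line {lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        ind = Individual(id=cells[0].strip(), population=cells[1].strip())
        individuals.append(ind)
        for locus, cell in zip(loci, cells[2:]):
            calls[(ind.id, locus.name)] = _parse_csv_cell(cell, lineno)
    return GenotypeDataset(loci=loci, individuals=individuals, calls=calls)


def _write_csv(ds: GenotypeDataset, path: Path) -> None:
    rows = ["individual,population," + ",".join(ds.locus_names())]
    for ind in ds.individuals:
        cells = []
        for name in ds.locus_names():
            g = ds.calls[(ind.id, name)]
            cells.append("" if g.is_missing else f"{g.allele_a}/{g.allele_b}")
        rows.append(f"{ind.id},{ind.population}," + ",".join(cells))
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# GenePop 4.x
# ---------------------------------------------------------------------------


def _parse_genepop_allele_pair(code: str, lineno: int) -> Genotype:
    if len(code) == 4:
        width = 2
    elif len(code) == 6:
        width = 3
    else:
        raise ParseError(
            f"line {lineno}: genotype code {code!r} is neither 4 nor 6 digits"
        )
    try:
        a, b = int(code[:width]), int(code[width:])
    except ValueError:
        raise ParseError(f"line {lineno}: non-numeric genotype code {code!r}") from None
    if a == 0 or b == 0:
        if a != b:
            raise ParseError(
                f"line {lineno}: half-missing genotype {code!r} not supported"
            )
        return MISSING_GENOTYPE
    return Genotype(a, b)


def _read_genepop(path: Path) -> GenotypeDataset:
    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated GenePop file")
    # line 0 is the title; locus names follow, one per line or comma-separated,
    # until the first "Pop" line.
    cursor = 1
    locus_names: list[str] = []
    while cursor < len(lines) and lines[cursor].strip().lower() != "pop":
        locus_names.extend(
            name.strip() for name in lines[cursor].split(",") if name.strip()
        )
        cursor += 1
    if cursor == len(lines):
        raise ParseError(f"{path}: no 'Pop' line found")
    loci = [Locus(name) for name in locus_names]
    individuals: list[Individual] = []
    calls: dict[tuple[str, str], Genotype] = {}
    pop_index = 0
    for lineno, line in enumerate(lines[cursor:], start=cursor + 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            pop_index += 1
            continue
        if "," not in stripped:
            raise ParseError(f"line {lineno}: expected '<id> , <genotypes>'")
        ind_id, _, geno_part = stripped.partition(",")
        ind_id = ind_id.strip()
        codes = geno_part.split()
        if len(codes) != len(loci):
            raise ParseError(
                f"line {lineno}: expected {len(loci)} genotypes, got {len(codes)}"
            )
        ind = Individual(id=ind_id, population=f"Pop{pop_index}")
        individuals.append(ind)
        for locus, code in zip(loci, codes):
            calls[(ind.id, locus.name)] = _parse_genepop_allele_pair(code, lineno)
    return GenotypeDataset(loci=loci, individuals=individuals, calls=calls)


def _write_genepop(ds: GenotypeDataset, path: Path, title: str = "msatpop export") -> None:
    out = [title]
    out.extend(ds.locus_names())
    for pop in ds.populations():
        out.append("Pop")
        for ind in ds.members(pop):
            codes = []
            for name in ds.locus_names():
                g = ds.calls[(ind.id, name)]
                if g.is_missing:
                    codes.append("000000")
                else:
                    if g.allele_b > 999:
                        raise ValueError(
                            f"allele {g.allele_b} bp exceeds GenePop 3-digit coding"
                        )
                    codes.append(f"{g.allele_a:03d}{g.allele_b:03d}")
            out.append(f"{ind.id} , " + " ".join(codes))
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def read_genotype_table(path: str | Path, format: str = "csv") -> GenotypeDataset:
    """Read a genotype table in the ``csv`` or ``genepop`` dialect.

    Missing cells are recorded as missing, never dropped. Per-population
    counts are logged at INFO level.
    """
    path = Path(path)
    if format == "csv":
        ds = _read_csv(path)
    elif format == "genepop":
        ds = _read_genepop(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'genepop')")
    for pop, n in ds.population_sizes().items():
        log.info("population %s: %d individuals", pop, n)
    return ds


def write_genotype_table(
    ds: GenotypeDataset, path: str | Path, format: str = "csv"
) -> None:
    """Write a genotype table (inverse of :func:`read_genotype_table`)."""
    path = Path(path)
    if format == "csv":
        _write_csv(ds, path)
    elif format == "genepop":
        _write_genepop(ds, path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'genepop')")


def dataset_from_rows(
    loci: Iterable[str],
    rows: Iterable[tuple[str, str, Iterable[tuple[int, int] | None]]],
) -> GenotypeDataset:
    """Convenience constructor from (id, population, genotype list) rows.

    Genotypes are ``(a, b)`` bp pairs or ``None`` for missing.
    """
    locus_objs = [Locus(n) for n in loci]
    individuals: list[Individual] = []
    calls: dict[tuple[str, str], Genotype] = {}
    for ind_id, pop, genos in rows:
        individuals.append(Individual(id=ind_id, population=pop))
        for locus, g in zip(locus_objs, genos):
            calls[(ind_id, locus.name)] = (
                MISSING_GENOTYPE if g is None else Genotype(*g)
            )
    return GenotypeDataset(loci=locus_objs, individuals=individuals, calls=calls)
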