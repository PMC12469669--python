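"""Ladder-calibrated fragment sizing and allele binning.

The conventional gel calibration is used: log10(fragment size in bp) is
linear in migration distance, fitted by least squares on the ladder rungs.
Raw band sizes are then binned into integer allele classes by single-linkage
clustering with a greedy span cap, so that no class spans more than the
binning tolerance (default 2 bp, typical PAGE resolution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .genotype_io import Genotype, GenotypeDataset, Individual, Locus

log = logging.getLogger("msatpop")

#: r2 below which the ladder fit is flagged as poor calibration QC.
R2_WARNING_THRESHOLD = 0.99
DEFAULT_BIN_TOLERANCE = 2.0


@dataclass(frozen=True)
class LadderSpec:
    """A molecular size standard: rung sizes (bp) with their migrations.

    Sizes must be strictly increasing and migrations strictly decreasing —
    larger fragments migrate less.
    """

    rung_sizes: tuple[float, ...]
    rung_migrations: tuple[float, ...]

    def __post_init__(self) -> None:
        s, m = self.rung_sizes, self.rung_migrations
        if len(s) != len(m):
            raise ValueError("rung_sizes and rung_migrations differ in length")
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("ladder sizes must be strictly increasing")
        if any(b >= a for a, b in zip(m, m[1:])):
            raise ValueError("ladder migrations must be strictly decreasing")


@dataclass(frozen=True)
class SizingCurve:
    """Fitted log-linear calibration: log10(size) = slope * migration + intercept."""

    slope: float
    intercept: float
    r2: float
    migration_span: tuple[float, float]  # [min, max] of the ladder migrations

    def size_at(self, migration: float) -> float:
        return 10.0 ** (self.slope * migration + self.intercept)


@dataclass(frozen=True)
class BandObservation:
    """1 or 2 band migrations for one individual at one locus (diploid)."""

    individual: str
    population: str
    locus: str
    migrations: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.migrations) <= 2:
            raise ValueError(
                f"{self.individual} x {self.locus}: {len(self.migrations)} bands "
                "(diploid codominant model allows 1 or 2)"
            )


def fit_sizing_curve(ladder: LadderSpec) -> SizingCurve:
    """Least-squares fit of log10(size) on migration over the ladder rungs.

    Emits a warning (never an error) when r2 falls below the QC threshold
    of 0.99.
    """
    if len(ladder.rung_sizes) < 3:
        raise ValueError("ladder must have at least 3 rungs")
    x = np.asarray(ladder.rung_migrations, dtype=float)
    y = np.log10(ladder.rung_sizes)
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if r2 < R2_WARNING_THRESHOLD:
        log.warning("sizing curve r2 = %.4f below QC threshold %.2f", r2, R2_WARNING_THRESHOLD)
    return SizingCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        migration_span=(float(x.min()), float(x.max())),
    )


def estimate_band_size(curve: SizingCurve, migration: float) -> float:
    """Fragment size in bp at a migration distance; extrapolation is flagged."""
    lo, hi = curve.migration_span
    if not lo <= migration <= hi:
        log.warning(
            "migration %.3f outside ladder span [%.3f, %.3f]: extrapolating",
            migration, lo, hi,
        )
    return curve.size_at(migration)


def bin_alleles(
    raw_sizes: list[float], tolerance: float = DEFAULT_BIN_TOLERANCE
) -> dict[float, int]:
    """Cluster raw band sizes into integer allele classes.

    Sizes are sorted, then chained single-linkage (a gap strictly below the
    tolerance joins; a gap of at least the tolerance separates two distinct
    allele classes); any chain whose span would exceed the tolerance is split
    greedily at the point where the running span first exceeds it. Each
    cluster is labelled by its rounded mean. Deterministic: depends only on
    the multiset of sizes.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not raw_sizes:
        return {}
    ordered = sorted(raw_sizes)
    clusters: list[list[float]] = [[ordered[0]]]
    for size in ordered[1:]:
        cur = clusters[-1]
        if size - cur[-1] < tolerance and size - cur[0] <= tolerance:
            cur.append(size)
        else:
            clusters.append([size])
    mapping: dict[float, int] = {}
    prev_label: int | None = None
    for cluster in clusters:
        label = int(round(float(np.mean(cluster))))
        # distinct ascending labels: adjacent clusters may round to the same
        # integer when narrower than 1 bp apart
        if prev_label is not None and label <= prev_label:
            label = prev_label + 1
        prev_label = label
        for size in cluster:
            mapping[size] = label
    return mapping


def call_genotypes(
    observations: list[BandObservation],
    curve: SizingCurve,
    tolerance: float = DEFAULT_BIN_TOLERANCE,
) -> GenotypeDataset:
    """Convert band observations into a genotype dataset.

    One band -> homozygote; two bands -> heterozygote, unless both bands bin
    to the same allele class, in which case the call collapses to a
    homozygote with a logged warning. Binning is global across all
    observations of a locus so that allele classes are comparable between
    individuals.
    """
    by_locus: dict[str, list[BandObservation]] = {}
    order: list[tuple[str, str]] = []  # (individual, population) first-appearance
    for obs in observations:
        by_locus.setdefault(obs.locus, []).append(obs)
        key = (obs.individual, obs.population)
        if key not in order:
            order.append(key)

    calls: dict[tuple[str, str], Genotype] = {}
    for locus, obs_list in by_locus.items():
        sizes = [estimate_band_size(curve, m) for o in obs_list for m in o.migrations]
        binned = bin_alleles(sizes, tolerance)
        i = 0
        for obs in obs_list:
            if (obs.individual, locus) in calls:
                raise ValueError(
                    f"duplicate observation for {obs.individual} x {locus}"
                )
            classes = [binned[sizes[i + j]] for j in range(len(obs.migrations))]
            i += len(obs.migrations)
            if len(classes) == 1:
                g = Genotype(classes[0], classes[0])
            elif classes[0] == classes[1]:
                log.warning(
                    "%s x %s: two bands co-binned to %d bp, calling homozygote",
                    obs.individual, locus, classes[0],
                )
                g = Genotype(classes[0], classes[0])
            else:
                g = Genotype(classes[0], classes[1])
            calls[(obs.individual, locus)] = g

    loci = [Locus(name) for name in by_locus]
    individuals = [Individual(id=i, population=p) for i, p in order]
    # explicit missing for individuals unobserved at some locus
    for ind in individuals:
        for locus in loci:
            calls.setdefault((ind.id, locus.name), Genotype(None, None))
    return GenotypeDataset(loci=loci, individuals=individuals, calls=calls)


# ---------------------------------------------------------------------------
# CSV interfaces: band table and ladder
# ---------------------------------------------------------------------------


def read_ladder_csv(path: str | Path) -> LadderSpec:
    """Read a ladder CSV with header ``size_bp,migration``."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rungs = []
    for line in lines[1:]:
        if not line.strip():
            continue
        size, mig = line.split(",")
        rungs.append((float(size), float(mig)))
    rungs.sort()
    return LadderSpec(
        rung_sizes=tuple(s for s, _ in rungs),
        rung_migrations=tuple(m for _, m in rungs),
    )


def read_band_table_csv(path: str | Path) -> list[BandObservation]:
    """Read a band table CSV: ``individual,population,locus,migration_1[,migration_2]``."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = [c.strip() for c in line.split(",")]
        if len(cells) not in (4, 5):
            raise ValueError(f"line {lineno}: expected 4 or 5 columns")
        migrations = tuple(float(c) for c in cells[3:] if c)
        if not migrations:
            raise ValueError(f"line {lineno}: no migration values")
        out.append(
            BandObservation(
                individual=cells[0], population=cells[1], locus=cells[2],
                migrations=migrations,
            )
        )
    return out


def write_band_table_csv(observations: list[BandObservation], path: str | Path) -> None:
    rows = ["individual,population,locus,migration_1,migration_2"]
    for o in observations:
        m = [f"{x:.6g}" for x in o.migrations]
        rows.append(",".join([o.individual, o.population, o.locus, m[0], m[1] if len(m) > 1 else ""]))
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def write_ladder_csv(ladder: LadderSpec, path: str | Path) -> None:
    rows = ["size_bp,migration"]
    for s, m in zip(ladder.rung_sizes, ladder.rung_migrations):
        rows.append(f"{s:.6g},{m:.6g}")
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")
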