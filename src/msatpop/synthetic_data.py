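"""Genotype and band-table simulation matching the seven-breed study design.

The generator emulates a survey of seven rabbit breeds (Black Baladi n=127,
White Baladi 40, Red Baladi 40, Jabali 112, New Zealand White 87, American
Rex 60, Chinchilla 60) typed at 14 microsatellite loci with 2-10 alleles per
locus, differentiated at FST ~ 0.22 and with near-zero within-breed
inbreeding.

Population allele frequencies follow the Balding-Nichols model: per locus an
ancestral frequency vector is drawn from a flat Dirichlet, and each breed's
frequencies from Dirichlet(p_anc * (1 - FST)/FST), which induces the target
differentiation in expectation. Genotypes are drawn with an inbreeding
adjustment: P(homozygote i) = p_i^2 + FIS * p_i (1 - p_i),
P(heterozygote i,j) = 2 p_i p_j (1 - FIS). Allele identities map to plausible
bp sizes on a 2-bp grid (dinucleotide-style spacing; cosmetic only).
Everything is driven by a single mandatory seed; a fixed config yields a
byte-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gel_sizing import BandObservation, LadderSpec
from .genotype_io import Genotype, GenotypeDataset, Individual, Locus

#: Breed labels and sample sizes of the emulated study design.
DEFAULT_POPULATIONS: tuple[tuple[str, int], ...] = (
    ("BB", 127),
    ("WB", 40),
    ("RB", 40),
    ("JAB", 112),
    ("NZW", 87),
    ("AR", 60),
    ("CH", 60),
)

#: The 14 marker names of the emulated panel.
DEFAULT_LOCUS_NAMES: tuple[str, ...] = (
    "Sat3", "Sol33", "Sol44", "Sat5",
    "D5Utr4a", "D5Utr4b", "D5Utr4c", "D5Utr4d", "D5Utr4e", "D5Utr4f",
    "D7Utr4a", "D7Utr4b", "D19Utr4a", "D19Utr4b",
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the genotype simulator.

    Defaults are the emulated survey's conditions: 7 breeds with sizes
    127/40/40/112/87/60/60, 14 loci, 2-10 alleles per locus, between-breed
    FST 0.22, within-breed FIS 0, 2% missing calls.
    """

    populations: tuple[tuple[str, int], ...] = DEFAULT_POPULATIONS
    n_loci: int = 14
    alleles_per_locus: tuple[int, int] = (2, 10)
    fst_target: float = 0.22
    fis_target: float = 0.0
    missing_rate: float = 0.02
    allele_size_start: int = 100
    # tetranucleotide-style 4-bp spacing: allele classes must be separated by
    # more than the binning tolerance plus the band-size noise spread for the
    # gel stage to resolve them
    allele_size_step: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for _, n in self.populations):
            raise ValueError("every population needs at least 2 individuals")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must lie in [0, 1)")
        if not -1.0 < self.fis_target < 1.0:
            raise ValueError("fis_target must lie in (-1, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.alleles_per_locus
        if not 2 <= lo <= hi:
            raise ValueError("alleles_per_locus range must satisfy 2 <= lo <= hi")


def _genotype_distribution(
    p: np.ndarray, fis: float
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Exact genotype distribution under inbreeding coefficient ``fis``.

    P(ii) = p_i^2 + fis * p_i (1 - p_i); P(ij) = 2 p_i p_j (1 - fis).
    Raises when a negative fis drives some homozygote probability below 0
    (the inbreeding model's validity bound fis >= -p_i/(1-p_i)).
    """
    pairs: list[tuple[int, int]] = []
    probs: list[float] = []
    k = len(p)
    for i in range(k):
        pairs.append((i, i))
        probs.append(p[i] ** 2 + fis * p[i] * (1.0 - p[i]))
        for j in range(i + 1, k):
            pairs.append((i, j))
            probs.append(2.0 * p[i] * p[j] * (1.0 - fis))
    arr = np.asarray(probs)
    if np.any(arr < -1e-12):
        raise ValueError(f"fis={fis} invalid for these allele frequencies")
    arr = np.clip(arr, 0.0, None)
    return pairs, arr / arr.sum()


def simulate_dataset(cfg: SimConfig) -> GenotypeDataset:
    """Simulate a genotype dataset under the Balding-Nichols model.

    With ``fst_target == 0`` every population shares the ancestral
    frequencies exactly. Negative ``fis_target`` (heterozygote excess) is
    implemented by rejection of homozygotes at the matching rate.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.alleles_per_locus
    loci: list[Locus] = []
    pop_freqs: dict[tuple[str, str], np.ndarray] = {}
    allele_sizes: dict[str, np.ndarray] = {}

    for li in range(cfg.n_loci):
        name = (
            DEFAULT_LOCUS_NAMES[li]
            if cfg.n_loci == len(DEFAULT_LOCUS_NAMES)
            else f"L{li + 1:02d}"
        )
        n_alleles = int(rng.integers(lo, hi + 1))
        p_anc = rng.dirichlet(np.ones(n_alleles))
        sizes = cfg.allele_size_start + cfg.allele_size_step * np.arange(n_alleles)
        allele_sizes[name] = sizes
        loci.append(Locus(name, expected_size_range=(int(sizes[0]) - 10, int(sizes[-1]) + 10)))
        for pop, _ in cfg.populations:
            if cfg.fst_target == 0.0:
                pop_freqs[(pop, name)] = p_anc
            else:
                conc = p_anc * (1.0 - cfg.fst_target) / cfg.fst_target
                # Dirichlet with tiny concentrations can underflow to all-zero;
                # floor the parameters far below any frequency of interest.
                pop_freqs[(pop, name)] = rng.dirichlet(np.maximum(conc, 1e-6))

    geno_dists = {
        key: _genotype_distribution(p, cfg.fis_target) for key, p in pop_freqs.items()
    }
    individuals: list[Individual] = []
    calls: dict[tuple[str, str], Genotype] = {}
    for pop, n in cfg.populations:
        for ix in range(n):
            ind_id = f"{pop}_{ix + 1:03d}"
            individuals.append(Individual(id=ind_id, population=pop))
            for locus in loci:
                if rng.random() < cfg.missing_rate:
                    calls[(ind_id, locus.name)] = Genotype(None, None)
                    continue
                pairs, probs = geno_dists[(pop, locus.name)]
                sizes = allele_sizes[locus.name]
                i, j = pairs[rng.choice(len(pairs), p=probs)]
                calls[(ind_id, locus.name)] = Genotype(int(sizes[i]), int(sizes[j]))
    return GenotypeDataset(loci=loci, individuals=individuals, calls=calls)


@dataclass(frozen=True)
class CurveParams:
    """True log-linear gel calibration used to invert sizes into migrations."""

    slope: float = -0.012
    intercept: float = 2.85


def simulate_band_table(
    ds: GenotypeDataset,
    curve: CurveParams = CurveParams(),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[BandObservation], LadderSpec]:
    """Invert the sizing model to band migrations, with Gaussian size noise.

    Homozygotes produce a single band; heterozygotes two. Returns the band
    observations together with a 50-bp ladder spanning the allele range,
    placed exactly on the calibration line.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)

    def migration_of(size_bp: float) -> float:
        return (np.log10(size_bp) - curve.intercept) / curve.slope

    observations: list[BandObservation] = []
    max_size = 0
    for ind in ds.individuals:
        for locus in ds.locus_names():
            g = ds.calls[(ind.id, locus)]
            if g.is_missing:
                continue
            bands = sorted(set(g.alleles()))
            max_size = max(max_size, bands[-1])
            noisy = [b + rng.normal(0.0, noise_sd) if noise_sd else float(b) for b in bands]
            observations.append(
                BandObservation(
                    individual=ind.id,
                    population=ind.population,
                    locus=locus,
                    migrations=tuple(migration_of(s) for s in noisy),
                )
            )
    top = max(300, 50 * ((max_size // 50) + 2))
    rung_sizes = tuple(float(s) for s in range(50, top + 1, 50))
    ladder = LadderSpec(
        rung_sizes=rung_sizes,
        rung_migrations=tuple(migration_of(s) for s in rung_sizes),
    )
    return observations, ladder
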