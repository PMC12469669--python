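"""Ewens-Watterson homozygosity test of neutrality.

The observed sample homozygosity F = sum(p_hat_i^2) at a locus is compared
with its null distribution under the Ewens sampling formula conditioned on
the number of genes n and the number of alleles k observed. Conditioned on
(n, k) the null is parameter-free: an allele-count configuration (a partition
lambda of n with k parts) has probability

    P(lambda | n, k) = [ n! / prod_j (j^{a_j} a_j!) ] / |s(n, k)|

where a_j counts parts of size j and |s(n, k)| is the unsigned Stirling
number of the first kind — the cycle-type distribution of a uniform random
permutation of n elements conditioned on having exactly k cycles.

The normalized deviate D = (E_null[F] - F_obs) / sd_null[F] is positive for
allele-rich, evenly distributed samples (balancing-selection-like) and
negative for skewed ones, under the default sign convention.

Null moments are available three ways, and agree:

* ``exact`` — closed-form first and second moments of sum(lambda_i^2) from
  expected cycle counts E[a_j] and cycle-pair counts, computed with exact
  big-integer Stirling arithmetic; works for any (n, k).
* full partition enumeration (:func:`esf_partition_distribution`) when the
  number of partitions fits a budget; yields the whole null distribution.
* ``monte_carlo`` — Chinese-restaurant-process sampling with the dispersion
  theta solved from E[K | theta, n] = k, rejecting samples with K != k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import optimize

from .genotype_io import (
    AlleleFrequencySpectrum,
    GenotypeDataset,
    NoDataError,
    allele_frequencies,
)

log = logging.getLogger("msatpop")

DEFAULT_ENUMERATION_BUDGET = 1_000_000
DEFAULT_MC_REPS = 10_000


def observed_homozygosity(spec: AlleleFrequencySpectrum) -> float:
    """Sample homozygosity F = sum(p_hat_i^2)."""
    return sum(f * f for f in spec.freqs.values())


# ---------------------------------------------------------------------------
# Stirling numbers and partition machinery
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def stirling_first_unsigned(n: int, k: int) -> int:
    """Unsigned Stirling number of the first kind |s(n, k)|.

    Recurrence |s(n, k)| = |s(n-1, k-1)| + (n-1) |s(n-1, k)| with
    |s(0, 0)| = 1. Exact integer arithmetic.
    """
    if n < 0 or k < 0:
        raise ValueError("n and k must be non-negative")
    if n == 0 and k == 0:
        return 1
    if n == 0 or k == 0 or k > n:
        return 0
    return stirling_first_unsigned(n - 1, k - 1) + (n - 1) * stirling_first_unsigned(
        n - 1, k
    )


@lru_cache(maxsize=None)
def partition_count(n: int, k: int) -> int:
    """Number of partitions of n into exactly k parts."""
    if n == 0 and k == 0:
        return 1
    if n <= 0 or k <= 0 or k > n:
        return 0
    return partition_count(n - 1, k - 1) + partition_count(n - k, k)


def partitions_into_k_parts(n: int, k: int, max_part: int | None = None) -> Iterator[tuple[int, ...]]:
    """Yield partitions of n into exactly k parts, non-increasing order."""
    if max_part is None:
        max_part = n
    if k == 0:
        if n == 0:
            yield ()
        return
    if k == 1:
        if 1 <= n <= max_part:
            yield (n,)
        return
    # largest part first; remaining k-1 parts each >= 1 and <= first
    for first in range(min(n - k + 1, max_part), max(1, (n + k - 1) // k) - 1, -1):
        for rest in partitions_into_k_parts(n - first, k - 1, first):
            yield (first,) + rest


def _partition_weight(partition: tuple[int, ...]) -> Fraction:
    """n! / prod_j (j^{a_j} a_j!) — permutations with this cycle type."""
    n = sum(partition)
    counts: dict[int, int] = {}
    for part in partition:
        counts[part] = counts.get(part, 0) + 1
    denom = 1
    for j, a in counts.items():
        denom *= j**a * math.factorial(a)
    return Fraction(math.factorial(n), denom)


@dataclass(frozen=True)
class NullDistribution:
    """Exact conditional-ESF null over allele-count partitions of (n, k)."""

    n: int
    k: int
    partitions: tuple[tuple[int, ...], ...]
    probabilities: tuple[float, ...]

    def homozygosities(self) -> np.ndarray:
        n = float(self.n)
        return np.array(
            [sum((part / n) ** 2 for part in p) for p in self.partitions]
        )

    def moments(self) -> tuple[float, float]:
        """(mean, sd) of F under the null."""
        f = self.homozygosities()
        p = np.asarray(self.probabilities)
        mean = float(np.dot(p, f))
        var = float(np.dot(p, (f - mean) ** 2))
        return mean, math.sqrt(max(var, 0.0))


def esf_partition_distribution(
    n: int, k: int, budget: int = DEFAULT_ENUMERATION_BUDGET
) -> NullDistribution:
    """Enumerate the full conditional null: every partition with its probability."""
    _validate_nk(n, k)
    count = partition_count(n, k)
    if count > budget:
        raise ValueError(
            f"partition count {count} for (n={n}, k={k}) exceeds budget {budget}"
        )
    total = stirling_first_unsigned(n, k)
    parts, probs = [], []
    for p in partitions_into_k_parts(n, k):
        parts.append(p)
        probs.append(float(_partition_weight(p) / total))
    return NullDistribution(
        n=n, k=k, partitions=tuple(parts), probabilities=tuple(probs)
    )


def _validate_nk(n: int, k: int) -> None:
    if k > n:
        raise ValueError(f"k={k} alleles cannot exceed n={n} genes")
    if k < 1 or n < 1:
        raise ValueError("n and k must be positive")


@lru_cache(maxsize=4096)
def _exact_moments(n: int, k: int) -> tuple[float, float]:
    """Closed-form (mean, sd) of F = sum((lambda_i/n)^2) under the (n,k) null.

    Uses the cycle-count moments of a uniform permutation of n elements
    conditioned on k cycles: the expected number of cycles of size j is
    C(n,j) (j-1)! |s(n-j, k-1)| / |s(n,k)|, and the expected number of
    ordered pairs of distinct cycles of sizes (j, l) is
    C(n,j)(j-1)! C(n-j,l)(l-1)! |s(n-j-l, k-2)| / |s(n,k)|. All arithmetic
    is exact until the final float conversion.
    """
    total = stirling_first_unsigned(n, k)
    # first moment of S2 = sum lambda_i^2, and the j^4 diagonal of the second
    m1_num = 0
    diag_num = 0
    single = []
    for j in range(1, n + 1):
        w = math.comb(n, j) * math.factorial(j - 1) * stirling_first_unsigned(n - j, k - 1)
        single.append(w)
        m1_num += j * j * w
        diag_num += j**4 * w
    # cross terms: ordered pairs of distinct cycles of sizes j and l
    cross_num = 0
    if k >= 2:
        for j in range(1, n):
            cj = math.comb(n, j) * math.factorial(j - 1)
            for l in range(1, n - j + 1):
                s = stirling_first_unsigned(n - j - l, k - 2)
                if s == 0:
                    continue
                cross_num += (
                    j * j * l * l
                    * cj
                    * math.comb(n - j, l)
                    * math.factorial(l - 1)
                    * s
                )
    e_s2 = Fraction(m1_num, total)
    e_s2_sq = Fraction(diag_num + cross_num, total)
    n2 = Fraction(n * n)
    mean = e_s2 / n2
    var = e_s2_sq / (n2 * n2) - mean * mean
    return float(mean), math.sqrt(max(float(var), 0.0))


def _solve_theta(n: int, k: int) -> float:
    """Solve E[K | theta, n] = sum_{i=0}^{n-1} theta/(theta+i) = k for theta."""

    def expected_k(theta: float) -> float:
        i = np.arange(n, dtype=float)
        return float(np.sum(theta / (theta + i)))

    lo, hi = 1e-8, 1e8
    return float(optimize.brentq(lambda t: expected_k(t) - k, lo, hi, xtol=1e-10))


def _sample_crp_configurations(
    n: int, k: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``reps`` homozygosity values from the (n, k)-conditional null.

    Chinese-restaurant-process proposals at the theta matching E[K] = k;
    configurations with K != k are rejected and redrawn.
    """
    theta = _solve_theta(n, k)
    out = np.empty(reps)
    filled = 0
    max_tries = 2000 * reps
    tries = 0
    while filled < reps:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"CRP rejection sampling for (n={n}, k={k}) did not converge"
            )
        sizes = [1]
        for i in range(1, n):
            if rng.random() < theta / (theta + i):
                sizes.append(1)
            else:
                # join an existing table proportional to its size
                u = rng.random() * i
                acc = 0.0
                for t, sz in enumerate(sizes):
                    acc += sz
                    if u < acc:
                        sizes[t] += 1
                        break
        if len(sizes) != k:
            continue
        out[filled] = sum((s / n) ** 2 for s in sizes)
        filled += 1
    return out


def esf_null(
    n: int,
    k: int,
    method: str = "exact",
    reps: int = DEFAULT_MC_REPS,
    seed: int | None = None,
) -> tuple[float, float]:
    """Null mean and sd of the sample homozygosity F under conditional ESF.

    ``method="exact"`` uses closed-form moments (exact for any n, k);
    ``method="monte_carlo"`` draws ``reps`` seeded CRP samples conditioned
    on k alleles. Degenerate cases: k == 1 gives (1, 0); k == n gives
    (1/n, 0).
    """
    _validate_nk(n, k)
    if k == 1:
        return 1.0, 0.0
    if k == n:
        return 1.0 / n, 0.0
    if method == "exact":
        return _exact_moments(n, k)
    if method == "monte_carlo":
        if reps < 1000:
            raise ValueError("monte_carlo requires reps >= 1000")
        if seed is None:
            raise ValueError("monte_carlo requires a seed for reproducibility")
        samples = _sample_crp_configurations(n, k, reps, np.random.default_rng(seed))
        return float(samples.mean()), float(samples.std(ddof=1))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# The neutrality deviate and the per-breed table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeutralityConfig:
    method: str = "exact"
    reps: int = DEFAULT_MC_REPS
    seed: int = 0
    sign: int = +1  # +1: allele-rich/even spectra -> positive D


@dataclass(frozen=True)
class NeutralityRecord:
    population: str
    locus: str
    F_obs: float
    k: int
    n: int
    F_null_mean: float | None
    F_null_sd: float | None
    D: float | None
    method: str
    reps: int
    seed: int


def neutrality_D(
    ds: GenotypeDataset,
    population: str,
    locus: str,
    cfg: NeutralityConfig = NeutralityConfig(),
) -> NeutralityRecord:
    """Normalized homozygosity deviate D = (E_null[F] - F_obs)/sd_null[F].

    A monomorphic cell (k = 1) has no null variance; D is undefined and
    rendered "-" in tabular output.
    """
    spec = allele_frequencies(ds, population, locus)
    f_obs = observed_homozygosity(spec)
    k = len(spec.freqs)
    n = spec.n_genes
    if k == 1:
        return NeutralityRecord(
            population, locus, f_obs, k, n, None, None, None,
            cfg.method, cfg.reps, cfg.seed,
        )
    mean, sd = esf_null(n, k, method=cfg.method, reps=cfg.reps, seed=cfg.seed)
    d = None if sd == 0 else cfg.sign * (mean - f_obs) / sd
    return NeutralityRecord(
        population, locus, f_obs, k, n, mean, sd, d,
        cfg.method, cfg.reps, cfg.seed,
    )


def neutrality_table(
    ds: GenotypeDataset, cfg: NeutralityConfig = NeutralityConfig()
) -> pd.DataFrame:
    """Loci x breeds matrix of D values with Mean and SE rows.

    Undefined cells (monomorphic or untyped) are NaN; the breed mean is the
    arithmetic mean over loci with defined D, and the SE uses the
    sd(n-1)/sqrt(L) convention over the same loci.
    """
    pops = ds.populations()
    data: dict[str, list[float]] = {p: [] for p in pops}
    for locus in ds.locus_names():
        for pop in pops:
            try:
                rec = neutrality_D(ds, pop, locus, cfg)
                data[pop].append(float("nan") if rec.D is None else rec.D)
            except NoDataError:
                data[pop].append(float("nan"))
    table = pd.DataFrame(data, index=ds.locus_names())
    means, ses = {}, {}
    for pop in pops:
        col = table[pop].dropna()
        if len(col) == 0:
            means[pop] = ses[pop] = float("nan")
        else:
            means[pop] = float(col.mean())
            ses[pop] = (
                float(col.std(ddof=1) / math.sqrt(len(col)))
                if len(col) > 1 else float("nan")
            )
    table.loc["Mean"] = pd.Series(means)
    table.loc["SE"] = pd.Series(ses)
    return table
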