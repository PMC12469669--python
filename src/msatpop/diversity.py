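"""Per-locus, per-population diversity statistics and the breed summary table.

Statistics: observed allele count No, effective allele count Ne = 1/sum(p^2),
observed heterozygosity Ho, expected heterozygosity He (Nei's unbiased
small-sample form by default), Botstein's polymorphic information content
PIC, and the inbreeding coefficient F = 1 - Ho/He.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import (
    AlleleFrequencySpectrum,
    GenotypeDataset,
    NoDataError,
    allele_frequencies,
)

PIC_HIGH = 0.50      # PIC > 0.50: highly informative marker
PIC_MODERATE = 0.25  # 0.25 < PIC <= 0.50: moderately informative


@dataclass(frozen=True)
class DiversityRecord:
    """Diversity statistics for one population x locus cell."""

    population: str
    locus: str
    No: int
    Ne: float
    Ho: float
    He: float
    PIC: float
    F: float | None  # None when He == 0 (monomorphic)


def observed_allele_count(spec: AlleleFrequencySpectrum) -> int:
    """Number of distinct alleles observed (frequency > 0)."""
    return len(spec.freqs)


def effective_allele_count(spec: AlleleFrequencySpectrum) -> float:
    """Ne = 1 / sum(p_i^2): equifrequent-allele equivalent of the homozygosity."""
    return 1.0 / sum(f * f for f in spec.freqs.values())


def observed_heterozygosity(ds: GenotypeDataset, population: str, locus: str) -> float:
    """Fraction of typed individuals carrying two distinct alleles."""
    genos = ds.genotypes(population, locus)
    if not genos:
        raise NoDataError(f"no typed individuals for {population} x {locus}")
    return sum(g.is_heterozygous for g in genos) / len(genos)


def expected_heterozygosity(
    spec: AlleleFrequencySpectrum, unbiased: bool = True
) -> float:
    """Gene diversity 1 - sum(p_i^2).

    With ``unbiased=True`` (default) applies Nei's small-sample correction
    n/(n-1) with n the number of genes sampled, capped at 1.
    """
    h = 1.0 - sum(f * f for f in spec.freqs.values())
    if unbiased:
        n = spec.n_genes
        if n < 2:
            raise ValueError("unbiased He needs at least 2 genes")
        h = min(1.0, n / (n - 1) * h)
    return h


def pic(spec: AlleleFrequencySpectrum) -> float:
    """Botstein's polymorphic information content.

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2, evaluated via the
    closed form sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4.
    """
    p = np.asarray(spec.frequencies())
    sum_sq = float(np.sum(p**2))
    cross = sum_sq**2 - float(np.sum(p**4))
    return 1.0 - sum_sq - cross


def pic_class(value: float) -> str:
    """Marker informativeness band: 'high' (>0.50), 'moderate' (0.25-0.50), 'low'."""
    if value > PIC_HIGH:
        return "high"
    if value > PIC_MODERATE:
        return "moderate"
    return "low"


def breed_inbreeding(Ho: float, He: float) -> float:
    """Per-locus inbreeding coefficient F = 1 - Ho/He.

    Negative values indicate heterozygote excess. Undefined (raises) when
    He == 0; such loci are excluded from breed means upstream.
    """
    if He <= 0:
        raise ValueError("F undefined for He = 0 (monomorphic locus)")
    return 1.0 - Ho / He


def diversity_record(
    ds: GenotypeDataset, population: str, locus: str, unbiased_he: bool = True
) -> DiversityRecord:
    """All diversity statistics for one population x locus cell."""
    spec = allele_frequencies(ds, population, locus)
    ho = observed_heterozygosity(ds, population, locus)
    he = expected_heterozygosity(spec, unbiased=unbiased_he)
    return DiversityRecord(
        population=population,
        locus=locus,
        No=observed_allele_count(spec),
        Ne=effective_allele_count(spec),
        Ho=ho,
        He=he,
        PIC=pic(spec),
        F=None if he <= 0 else breed_inbreeding(ho, he),
    )


def mean_and_se(values: list[float]) -> tuple[float, float]:
    """Mean and standard error (n-1 sample sd / sqrt(n)); SE is NaN for n < 2."""
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else float("nan")
    return mean, se


def diversity_table(
    ds: GenotypeDataset,
    unbiased_he: bool = True,
    f_averaging: str = "mean_of_ratios",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell records plus the breed summary (mean +/- SE over loci).

    Returns ``(records, summary)`` DataFrames. The summary has one row per
    breed with mean and SE columns for No/Ne/Ho/He/PIC, the breed F, and
    ``loci_used``. Breed F is by default the across-loci mean of the
    per-locus 1 - Ho/He, excluding monomorphic loci
    (``f_averaging="mean_of_ratios"``); ``"ratio_of_means"`` instead uses
    1 - mean(Ho)/mean(He) over polymorphic loci.
    """
    if f_averaging not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError(f"unknown f_averaging {f_averaging!r}")
    rows = []
    for pop in ds.populations():
        for locus in ds.locus_names():
            try:
                rec = diversity_record(ds, pop, locus, unbiased_he=unbiased_he)
            except NoDataError:
                continue
            rows.append(rec.__dict__)
    records = pd.DataFrame(rows)

    summary_rows = []
    for pop, grp in records.groupby("population", sort=False):
        row: dict[str, object] = {"population": pop, "loci_used": len(grp)}
        for col in ("No", "Ne", "Ho", "He", "PIC"):
            mean, se = mean_and_se(grp[col].tolist())
            row[f"{col}_mean"], row[f"{col}_se"] = mean, se
        poly = grp[grp["F"].notna()]
        if len(poly) == 0:
            row["F_mean"] = float("nan")
        elif f_averaging == "mean_of_ratios":
            row["F_mean"] = float(poly["F"].mean())
        else:
            row["F_mean"] = 1.0 - float(poly["Ho"].mean()) / float(poly["He"].mean())
        summary_rows.append(row)
    return records, pd.DataFrame(summary_rows)
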