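"""Hierarchical F-statistics across populations, gene flow, and the summary table.

Wright's fixation indices are computed per locus from Nei's gene-diversity
decomposition: HI (mean observed heterozygosity), HS (mean within-population
expected heterozygosity, biased form), and HT (expected heterozygosity of the
pooled allele frequencies) give

    FIS = 1 - HI/HS,   FST = 1 - HS/HT,   FIT = 1 - HI/HT,

which satisfy Wright's identity (1-FIS)(1-FST) = (1-FIT) exactly by
construction. Gene flow under the island model is Nm = (1-FST)/(4*FST),
suppressed below a configurable FST floor where the estimate is unstable.

A Weir-Cockerham variance-components estimator (theta) is offered behind a
flag for sensitivity comparison; it does not satisfy the identity exactly
and may go negative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import mean_and_se
from .genotype_io import GenotypeDataset, NoDataError, allele_frequencies

log = logging.getLogger("msatpop")

DEFAULT_FST_FLOOR = 0.005
FST_HIGH_DIFFERENTIATION = 0.15  # conventional band: FST > 0.15 = high


@dataclass(frozen=True)
class FStatRecord:
    """Per-locus F-statistics with their component heterozygosities.

    ``FIS``/``FST``/``FIT``/``Nm`` are ``None`` where undefined (see
    :func:`locus_fstats` for the degenerate cases).
    """

    locus: str
    HI: float
    HS: float
    HT: float
    FIS: float | None
    FIT: float | None
    FST: float | None
    Nm: float | None
    n_populations: int


def _per_population_components(
    ds: GenotypeDataset, locus: str, weighting: str
) -> tuple[float, float, float, int]:
    """Return (HI, HS, HT, n_pops) for one locus."""
    ho_list, hs_list, weights = [], [], []
    pooled: dict[int, float] = {}
    for pop in ds.populations():
        try:
            spec = allele_frequencies(ds, pop, locus)
        except NoDataError:
            continue
        genos = ds.genotypes(pop, locus)
        n_ind = len(genos)
        ho = sum(g.is_heterozygous for g in genos) / n_ind
        hs = 1.0 - sum(f * f for f in spec.freqs.values())  # biased form
        ho_list.append(ho)
        hs_list.append(hs)
        weights.append(n_ind if weighting == "by_sample_size" else 1.0)
        for allele, f in spec.freqs.items():
            w = n_ind if weighting == "by_sample_size" else 1.0
            pooled[allele] = pooled.get(allele, 0.0) + w * f
    if len(ho_list) < 2:
        raise NoDataError(f"locus {locus}: fewer than 2 populations typed")
    w = np.asarray(weights, dtype=float)
    w /= w.sum()
    hi = float(np.dot(w, ho_list))
    hs = float(np.dot(w, hs_list))
    total_w = sum(pooled.values())
    ht = 1.0 - sum((c / total_w) ** 2 for c in pooled.values())
    return hi, hs, ht, len(ho_list)


def gene_flow(fst: float, fst_floor: float = DEFAULT_FST_FLOOR) -> float | None:
    """Island-model effective migrants per generation, Nm = (1-FST)/(4*FST).

    Returns ``None`` (reported as "-") when FST <= fst_floor, where the
    transform blows up and the estimate is not meaningful.
    """
    if fst is None or fst <= fst_floor:
        if fst is not None and 0 < fst <= fst_floor:
            log.info("Nm suppressed at FST=%.4f (floor %.4f): raw Nm=%.2f",
                     fst, fst_floor, (1 - fst) / (4 * fst))
        return None
    if fst > 1:
        raise ValueError("FST cannot exceed 1")
    return (1.0 - fst) / (4.0 * fst)


def locus_fstats(
    ds: GenotypeDataset,
    locus: str,
    weighting: str = "by_sample_size",
    fst_floor: float = DEFAULT_FST_FLOOR,
) -> FStatRecord:
    """Nei gene-diversity decomposition of one locus into FIS/FIT/FST + Nm.

    Degenerate cases: a locus monomorphic overall (HT = 0) yields a record
    with FST/FIS/FIT undefined; HS = 0 with HT > 0 (each population fixed,
    for different alleles) yields FIS undefined and FST = 1.
    """
    if weighting not in ("by_sample_size", "equal"):
        raise ValueError(f"unknown weighting {weighting!r}")
    hi, hs, ht, n_pops = _per_population_components(ds, locus, weighting)
    if ht <= 0:
        log.warning("locus %s monomorphic overall: F-statistics undefined", locus)
        return FStatRecord(locus, hi, hs, ht, None, None, None, None, n_pops)
    fst = 1.0 - hs / ht
    fit = 1.0 - hi / ht
    fis = None if hs <= 0 else 1.0 - hi / hs
    return FStatRecord(
        locus=locus, HI=hi, HS=hs, HT=ht,
        FIS=fis, FIT=fit, FST=fst,
        Nm=gene_flow(fst, fst_floor),
        n_populations=n_pops,
    )


def weir_cockerham_theta(ds: GenotypeDataset, locus: str) -> float:
    """Weir-Cockerham theta for one locus (variance-components FST).

    Provided for sensitivity comparison with the Nei decomposition; can be
    negative for weakly differentiated loci and is reported raw.
    """
    pops = []
    for pop in ds.populations():
        genos = ds.genotypes(pop, locus)
        if genos:
            pops.append((pop, genos))
    r = len(pops)
    if r < 2:
        raise NoDataError(f"locus {locus}: fewer than 2 populations typed")
    n_i = np.array([len(g) for _, g in pops], dtype=float)
    n_bar = n_i.mean()
    n_c = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (r - 1)
    alleles = sorted({a for _, genos in pops for g in genos for a in g.alleles()})
    num = den = 0.0
    for allele in alleles:
        p_i = np.array(
            [sum(g.alleles().count(allele) for g in genos) / (2 * len(genos))
             for _, genos in pops]
        )
        h_i = np.array(
            [sum(g.is_heterozygous and allele in g.alleles() for g in genos) / len(genos)
             for _, genos in pops]
        )
        p_bar = float(np.dot(n_i, p_i) / n_i.sum())
        s2 = float(np.dot(n_i, (p_i - p_bar) ** 2) / ((r - 1) * n_bar))
        h_bar = float(np.dot(n_i, h_i) / n_i.sum())
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        num += a
        den += a + b + c
    if den == 0:
        raise NoDataError(f"locus {locus}: no variation for Weir-Cockerham theta")
    return num / den


def fstats_table(
    ds: GenotypeDataset,
    weighting: str = "by_sample_size",
    fst_floor: float = DEFAULT_FST_FLOOR,
) -> tuple[pd.DataFrame, dict[str, object]]:
    """One F-statistics record per locus plus column means and SEs.

    Returns ``(table, summary)``: the table has one row per locus with
    columns locus/HI/HS/HT/FIS/FIT/FST/Nm; the summary dict holds
    ``<col>_mean`` and ``<col>_se`` for FIS/FIT/FST/Nm (Nm averaged over
    loci where defined) and a differentiation label from the conventional
    FST > 0.15 band.
    """
    rows = []
    for locus in ds.locus_names():
        try:
            rec = locus_fstats(ds, locus, weighting=weighting, fst_floor=fst_floor)
        except NoDataError as exc:
            log.warning("%s", exc)
            continue
        rows.append(rec.__dict__)
    table = pd.DataFrame(rows)
    summary: dict[str, object] = {}
    for col in ("FIS", "FIT", "FST", "Nm"):
        vals = [v for v in table[col] if v is not None and not math.isnan(v)]
        if vals:
            summary[f"{col}_mean"], summary[f"{col}_se"] = mean_and_se(vals)
        else:
            summary[f"{col}_mean"] = summary[f"{col}_se"] = float("nan")
    fst_mean = summary["FST_mean"]
    summary["differentiation"] = (
        "high" if fst_mean > FST_HIGH_DIFFERENTIATION else
        "moderate" if fst_mean > 0.05 else "low"
    )
    return table, summary


def summarize_printed_columns(
    fis: list[float], fit: list[float], fst: list[float], nm: list[float | None]
) -> dict[str, float]:
    """Column means/SEs for externally supplied per-locus F-statistics.

    Used to check internal consistency of a published table: means over all
    loci, Nm averaged over defined entries only, SEs under the
    sd(n-1)/sqrt(L) convention.
    """
    out = {}
    for name, vals in (("FIS", fis), ("FIT", fit), ("FST", fst)):
        out[f"{name}_mean"], out[f"{name}_se"] = mean_and_se(list(vals))
    nm_def = [v for v in nm if v is not None]
    out["Nm_mean"], out["Nm_se"] = mean_and_se(nm_def)
    return out
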