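"""Pipeline orchestration: genotypes -> diversity -> F-statistics ->
neutrality -> per-locus trees, written as a reproducible report bundle.

Every output table carries a commented ``# key=value`` provenance header
(package version, seed, thresholds), so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .diversity import diversity_table
from .fstatistics import DEFAULT_FST_FLOOR, fstats_table
from .genotype_io import GenotypeDataset, read_genotype_table
from .neutrality import NeutralityConfig, neutrality_table
from .phylogenetics import (
    breed_distance_matrix,
    individual_distance_matrix,
    upgma,
    write_newick,
)

log = logging.getLogger("msatpop")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    input_path: str
    output_dir: str
    input_format: str = "csv"
    unbiased_he: bool = True
    f_averaging: str = "mean_of_ratios"
    weighting: str = "by_sample_size"
    fst_floor: float = DEFAULT_FST_FLOOR
    neutrality_method: str = "exact"
    neutrality_reps: int = 10_000
    neutrality_sign: int = +1
    seed: int = 0
    tree_loci: tuple[str, ...] = ()  # empty = every locus
    tree_level: str = "breed"  # or "individual"
    tree_metric: str = "nei"  # or "dice" (forced for individual level)


def _header(cfg: RunConfig, extra: dict[str, object] | None = None) -> str:
    items: dict[str, object] = {
        "msatpop_version": __version__,
        "seed": cfg.seed,
        "unbiased_he": cfg.unbiased_he,
        "weighting": cfg.weighting,
        "fst_floor": cfg.fst_floor,
        "neutrality_method": cfg.neutrality_method,
    }
    if extra:
        items.update(extra)
    return "".join(f"# {k}={v}\n" for k, v in items.items())


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig,
               extra: dict[str, object] | None = None, index: bool = False) -> None:
    body = df.to_csv(sep="\t", index=index, na_rep="-", float_format="%.6g")
    path.write_text(_header(cfg, extra) + body, encoding="utf-8")


def run_all(cfg: RunConfig, ds: GenotypeDataset | None = None) -> dict[str, Path]:
    """Run the full analysis and write the report bundle.

    Returns a name -> path map of everything written. Any stage failure is
    re-raised annotated with the stage name.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    stage = "read"
    try:
        if ds is None:
            ds = read_genotype_table(cfg.input_path, format=cfg.input_format)

        stage = "diversity"
        records, summary = diversity_table(
            ds, unbiased_he=cfg.unbiased_he, f_averaging=cfg.f_averaging
        )
        path = out_dir / "diversity.tsv"
        block = records.to_csv(sep="\t", index=False, na_rep="-", float_format="%.6g")
        block += "\n" + summary.to_csv(sep="\t", index=False, na_rep="-", float_format="%.6g")
        path.write_text(_header(cfg) + block, encoding="utf-8")
        written["diversity"] = path

        stage = "fstatistics"
        table, fsummary = fstats_table(
            ds, weighting=cfg.weighting, fst_floor=cfg.fst_floor
        )
        path = out_dir / "fstats.tsv"
        footer = pd.DataFrame([fsummary])
        block = table.to_csv(sep="\t", index=False, na_rep="-", float_format="%.6g")
        block += "\n" + footer.to_csv(sep="\t", index=False, na_rep="-", float_format="%.6g")
        path.write_text(_header(cfg) + block, encoding="utf-8")
        written["fstats"] = path

        stage = "neutrality"
        ncfg = NeutralityConfig(
            method=cfg.neutrality_method, reps=cfg.neutrality_reps,
            seed=cfg.seed, sign=cfg.neutrality_sign,
        )
        ntable = neutrality_table(ds, ncfg)
        path = out_dir / "neutrality.tsv"
        _write_tsv(ntable, path, cfg, {"sign": cfg.neutrality_sign}, index=True)
        written["neutrality"] = path

        stage = "trees"
        tree_loci = cfg.tree_loci or tuple(ds.locus_names())
        for locus in tree_loci:
            if cfg.tree_level == "breed":
                matrix = breed_distance_matrix(ds, locus)
            else:
                matrix = individual_distance_matrix(ds, locus)
            newick = write_newick(upgma(matrix))
            path = out_dir / f"tree_{locus}.nwk"
            path.write_text(newick + "\n", encoding="utf-8")
            written[f"tree_{locus}"] = path

        stage = "log"
        path = out_dir / "run.log"
        path.write_text(
            _header(cfg, {"n_individuals": len(ds.individuals),
                          "n_loci": len(ds.loci),
                          "populations": ",".join(ds.populations())}),
            encoding="utf-8",
        )
        written["log"] = path
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return written
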