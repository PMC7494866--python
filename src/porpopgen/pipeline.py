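"""Full-study orchestration: config -> publication-shaped output tables.

``run_pipeline`` ingests an alignment, annotation, optional mask and a
lineage table, then per group and partition runs the diversity, selection
and demography stages, writing five TSV/JSON outputs (diversity table,
rarefaction summaries, MK table, neutrality table, mismatch fits) plus a
plain-text log.  Outputs are a pure function of (inputs, config): every
table embeds the config hash and the seeds used, and groups below the
minimum sample size for an analysis are skipped with a logged reason rather
than failing the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .seqio import (
    GenomeAlignment,
    MaskSet,
    apply_mask,
    extract_partition,
    gene_blocks,
    read_alignment,
    read_annotation,
    read_lineage_table,
    read_mask,
)
from .diversity import diversity_table, rarefied_pi
from .selection import CodonAlignment, mk_test, pi_n_pi_s
from .demography import (
    fit_sudden_expansion,
    neutrality_stats,
    observed_mismatch,
    tau_to_time,
)

logger = logging.getLogger("porpopgen")

__all__ = ["RunConfig", "run_pipeline"]

DEFAULT_PARTITIONS = ("whole", "noncoding", "cds_concat")


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    alignment: Path
    annotation: Path
    lineage_table: Path
    output_dir: Path
    mask: Path | None = None
    mask_coordinates: str = "bed"
    partitions: tuple[str, ...] = DEFAULT_PARTITIONS
    rarefaction_k: int = 3
    rarefaction_B: int = 2500
    mk_outgroup: str | None = None  # lineage id used as MK outgroup
    genetic_code: int = 2
    neutrality_sims: int = 10000
    mismatch_B: int = 10000
    min_n_demography: int = 10  # reliable demographic inference threshold
    rate_per_site_per_year: float = 5e-8
    generation_years: float = 10.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        paths = {k: base / raw[k] for k in ("alignment", "annotation", "lineage_table")}
        cfg = cls(
            **paths,
            output_dir=base / raw.get("output_dir", "results"),
            mask=(base / raw["mask"]) if raw.get("mask") else None,
            **{k: v for k, v in raw.items()
               if k not in ("alignment", "annotation", "lineage_table",
                            "output_dir", "mask")},
        )
        if seed is not None:
            cfg.seed = seed
        for p in (cfg.alignment, cfg.annotation, cfg.lineage_table, cfg.mask):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg

    def digest(self) -> str:
        payload = {k: str(v) for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# porpopgen {__version__} config={cfg.digest()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run every stage and return the mapping output-name -> written path."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    outputs: dict[str, Path] = {"log": log_path}
    try:
        logger.info("porpopgen %s config=%s seed=%d", __version__, cfg.digest(), cfg.seed)
        aln = read_alignment(cfg.alignment)
        ann = read_annotation(cfg.annotation)
        lineages = read_lineage_table(cfg.lineage_table)
        unknown = lineages.validate_against(aln)
        if unknown:
            logger.warning("lineage-table samples absent from alignment: %s", unknown)
        if cfg.mask is not None:
            mask = read_mask(cfg.mask, coordinates=cfg.mask_coordinates)
            before = aln.length
            aln = apply_mask(aln, mask)
            logger.info("mask removed %d columns (%d -> %d)",
                        before - aln.length, before, aln.length)

        partitions = {
            name: extract_partition(aln, ann, name) for name in cfg.partitions
        }
        in_aln = set(aln.sample_ids)

        # --- diversity table (one row per group x partition) ---------------
        div = diversity_table(aln, lineages, partitions)
        _write_tsv(div, out / "diversity.tsv", cfg)
        outputs["diversity"] = out / "diversity.tsv"

        # --- rarefaction ----------------------------------------------------
        rows = []
        for lg, samples in lineages.groups("lineage").items():
            samples = [s for s in samples if s in in_aln]
            if len(samples) < cfg.rarefaction_k:
                logger.info("rarefaction skipped for %s: n=%d < k=%d",
                            lg, len(samples), cfg.rarefaction_k)
                continue
            res = rarefied_pi(partitions["whole"].subset(samples),
                              k=cfg.rarefaction_k, B=cfg.rarefaction_B,
                              seed=cfg.seed)
            rows.append({"lineage": lg, "n": len(samples), "k": res.k,
                         "B": res.B, "median": res.median, "mean": res.mean,
                         "ci_low": res.ci_low, "ci_high": res.ci_high})
        _write_tsv(pd.DataFrame(rows), out / "rarefaction.tsv", cfg)
        outputs["rarefaction"] = out / "rarefaction.tsv"

        # --- selection: piN/piS and MK tests -------------------------------
        genes = gene_blocks(aln, ann)
        codon_all = CodonAlignment.from_gene_alignments(genes, cfg.genetic_code)
        rows = []
        out_samples = (
            [s for s in lineages.samples(lineage=cfg.mk_outgroup) if s in in_aln]
            if cfg.mk_outgroup else []
        )
        for lg, samples in lineages.groups("lineage").items():
            samples = [s for s in samples if s in in_aln]
            if lg == cfg.mk_outgroup or len(samples) < 2:
                if lg != cfg.mk_outgroup:
                    logger.info("selection skipped for %s: n=%d < 2", lg, len(samples))
                continue
            sub = codon_all.subset(samples)
            pin, pis, ratio = pi_n_pi_s(sub)
            row = {"lineage": lg, "n": len(samples),
                   "piN": pin, "piS": pis,
                   "piN_piS": ratio if ratio is not None else np.nan}
            if out_samples:
                tab, res = mk_test(sub, codon_all.subset(out_samples))
                row.update({
                    "outgroup": cfg.mk_outgroup,
                    "Dn": tab.Dn, "Ds": tab.Ds, "Pn": tab.Pn, "Ps": tab.Ps,
                    "NI": res.NI if res.NI is not None else np.nan,
                    "G": res.g_stat, "p_G": res.g_pvalue,
                    "p_Fisher": res.fisher_pvalue,
                    "interpretation": res.interpretation,
                })
            rows.append(row)
        _write_tsv(pd.DataFrame(rows), out / "mk.tsv", cfg)
        outputs["mk"] = out / "mk.tsv"

        # --- demography: neutrality tests + mismatch fits -------------------
        neut_rows = []
        fits = {}
        for lg, samples in lineages.groups("lineage").items():
            samples = [s for s in samples if s in in_aln]
            if len(samples) < cfg.min_n_demography:
                logger.info("demography skipped for %s: n=%d < %d",
                            lg, len(samples), cfg.min_n_demography)
                continue
            sub = partitions["whole"].subset(samples)
            ns = neutrality_stats(sub, n_sims=cfg.neutrality_sims, seed=cfg.seed)
            neut_rows.append({
                "lineage": lg, "n": ns.n, "S": ns.S,
                "eta": ns.eta, "eta_s": ns.eta_s,
                "tajima_D": ns.tajima_d, "fu_li_Dstar": ns.fu_li_dstar,
                "fu_li_Fstar": ns.fu_li_fstar,
                "p_D": ns.p_values.get("tajima_d"),
                "p_Dstar": ns.p_values.get("fu_li_dstar"),
                "p_Fstar": ns.p_values.get("fu_li_fstar"),
                "significant_05": any(p < 0.05 for p in ns.p_values.values())
                if ns.p_values else False,
            })
            hist = observed_mismatch(sub)
            fit = fit_sudden_expansion(hist, n=len(samples),
                                       B=cfg.mismatch_B, seed=cfg.seed)
            t_gen, t_years = tau_to_time(
                fit.tau, cfg.rate_per_site_per_year, sub.length,
                cfg.generation_years,
            )
            fits[lg] = {
                "model": fit.model, "theta0": fit.theta0, "theta1": fit.theta1,
                "tau": fit.tau, "ssd": fit.ssd, "p_ssd": fit.p_ssd,
                "ci": fit.ci, "B": fit.B,
                "expansion_time_generations": t_gen,
                "expansion_time_years": t_years,
                "histogram": fit.observed.tolist(),
                "seed": cfg.seed,
            }
        _write_tsv(pd.DataFrame(neut_rows), out / "neutrality.tsv", cfg)
        outputs["neutrality"] = out / "neutrality.tsv"
        (out / "mismatch.json").write_text(json.dumps(
            {"version": __version__, "config": cfg.digest(), "seed": cfg.seed,
             "fits": fits},
            indent=2,
        ))
        outputs["mismatch"] = out / "mismatch.json"
        logger.info("pipeline complete: %d outputs", len(outputs))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outputs
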