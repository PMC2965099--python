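"""End-to-end orchestration: simulate/load -> QC -> associate -> report.

A run is driven by one YAML config with optional sections ``data`` (paths
to genotype/pedigree/phenotype files), ``simulate`` (generator settings;
used when no data section is present), ``qc`` (threshold overrides),
``assoc`` (methods, traits, weight mode) and ``report`` (alpha).  Every
stage's input/output counts, the seed and the input-file digests go into
``manifest.json`` so that a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, replace
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .inference import SignificanceConfig, cross_method_summary, qq_points
from .io_model import (METHOD_L1TDT, METHOD_MMRA, GenotypeMatrix, Pedigree,
                       PhenotypeTable, read_genotypes, read_genotypes_tsv,
                       read_pedigree, read_phenotypes, results_to_frame,
                       write_genotypes_tsv, write_pedigree, write_phenotypes,
                       write_results)
from .l1tdt import scan_l1tdt
from .mmra import scan_mmra
from .qc import QcThresholds, run_individual_qc, run_snp_qc
from .synthetic_data import (QtlEffect, SimulationConfig,
                             simulate_daughter_design)

__all__ = ["PipelineError", "load_config", "run_pipeline"]

log = logging.getLogger("daughter_gwas")

METHODS = {"l1tdt": METHOD_L1TDT, "mmra": METHOD_MMRA}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineError("config: top level must be a mapping")
    return cfg


def simulation_config_from_mapping(section: Mapping[str, Any]
                                   ) -> SimulationConfig:
    """Build a SimulationConfig from a flat key:value mapping."""
    section = dict(section)
    qtl = tuple(QtlEffect(int(q["snp_index"]), str(q["trait"]),
                          float(q["effect_sd"]))
                for q in section.pop("qtl", []))
    known = {f for f in SimulationConfig.__dataclass_fields__}
    unknown = set(section) - known
    if unknown:
        raise PipelineError(f"simulate: unknown keys {sorted(unknown)}")
    for key in ("maf_range", "reliability_range"):
        if key in section:
            section[key] = tuple(section[key])
    if "traits" in section:
        section["traits"] = tuple(section["traits"])
    if "daughters_per_sire" in section and isinstance(
            section["daughters_per_sire"], list):
        section["daughters_per_sire"] = list(section["daughters_per_sire"])
    return SimulationConfig(qtl=qtl, **section)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_data(section: Mapping[str, Any], manifest: dict
               ) -> tuple[GenotypeMatrix, Pedigree, PhenotypeTable]:
    digests = {}
    try:
        if "genotypes_tsv" in section:
            gpath = Path(section["genotypes_tsv"])
            genotypes = read_genotypes_tsv(gpath)
            digests["genotypes_tsv"] = _digest(gpath)
        else:
            ped, mp = Path(section["ped"]), Path(section["map"])
            genotypes = read_genotypes(ped, mp)
            digests["ped"] = _digest(ped)
            digests["map"] = _digest(mp)
        pedpath = Path(section["pedigree"])
        pedigree = read_pedigree(pedpath)
        digests["pedigree"] = _digest(pedpath)
        phpath = Path(section["phenotypes"])
        phenotypes = read_phenotypes(phpath)
        digests["phenotypes"] = _digest(phpath)
    except FileNotFoundError as exc:
        raise PipelineError(f"data: missing input file {exc.filename}") from exc
    except KeyError as exc:
        raise PipelineError(f"data: config key {exc} required") from exc
    manifest["input_digests"] = digests
    return genotypes, pedigree, phenotypes


def run_pipeline(config: str | Path | Mapping[str, Any],
                 out_dir: str | Path) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(
        config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool_version": __version__,
        "config": json.loads(json.dumps(cfg, default=str)),
        "stages": {},
    }

    # ---- stage: data -------------------------------------------------------
    if "data" in cfg:
        genotypes, pedigree, phenotypes = _load_data(cfg["data"], manifest)
        seed = int(cfg.get("seed", 0))
    else:
        sim_section = cfg.get("simulate", {})
        sim_cfg = simulation_config_from_mapping(sim_section)
        if "seed" in cfg:
            sim_cfg = replace(sim_cfg, seed=int(cfg["seed"]))
        seed = sim_cfg.seed
        study = simulate_daughter_design(sim_cfg)
        genotypes, pedigree, phenotypes = (study.genotypes, study.pedigree,
                                           study.phenotypes)
        write_genotypes_tsv(genotypes, out / "genotypes.tsv")
        write_pedigree(pedigree, out / "pedigree.csv")
        write_phenotypes(phenotypes, out / "phenotypes.tsv")
        study.truth["qtl"].to_csv(out / "truth_qtl.tsv", sep="\t", index=False)
        manifest["stages"]["simulate"] = {
            "n_individuals": genotypes.n_individuals,
            "n_snps": genotypes.n_snps,
            "config": asdict(sim_cfg) | {"qtl": [asdict(q)
                                                 for q in sim_cfg.qtl]},
        }
    manifest["seed"] = seed
    log.info("data: %d individuals x %d SNPs",
             genotypes.n_individuals, genotypes.n_snps)

    # ---- stage: qc ---------------------------------------------------------
    qc_section = dict(cfg.get("qc", {}))
    skip_qc = bool(qc_section.pop("skip", False))
    if skip_qc:
        kept_geno = genotypes
        manifest["stages"]["qc"] = {"skipped": True}
    else:
        try:
            thresholds = QcThresholds(**qc_section)
        except TypeError as exc:
            raise PipelineError(f"qc: bad threshold override ({exc})") from exc
        kept_ids, ind_report = run_individual_qc(
            genotypes, pedigree, thresholds, seed=seed)
        kept_geno = genotypes.subset_individuals(kept_ids)
        kept_snps, snp_report = run_snp_qc(kept_geno, thresholds)
        kept_geno = kept_geno.subset_snps(kept_snps)
        for report in (ind_report, snp_report):
            log.info("%s", report.summary())
        pd.concat([ind_report.to_frame(), snp_report.to_frame()]
                  ).to_csv(out / "qc_report.tsv", sep="\t", index=False)
        (out / "qc_summary.txt").write_text(
            ind_report.summary() + "\n" + snp_report.summary() + "\n")
        manifest["stages"]["qc"] = {
            "individuals_in": ind_report.counts_in,
            "individuals_out": ind_report.counts_out,
            "individual_removals": ind_report.removals,
            "snps_in": snp_report.counts_in,
            "snps_out": snp_report.counts_out,
            "snp_removals": snp_report.removals,
        }

    # ---- stage: assoc ------------------------------------------------------
    assoc = cfg.get("assoc", {})
    methods = [m.lower() for m in assoc.get("methods", ["l1tdt", "mmra"])]
    for m in methods:
        if m not in METHODS:
            raise PipelineError(f"assoc: unknown method {m!r}")
    traits = assoc.get("traits") or phenotypes.traits()
    for t in traits:
        if t not in phenotypes.traits():
            raise PipelineError(f"assoc: trait {t!r} absent from phenotypes")
    weight_mode = assoc.get("weight_mode", "reliability")
    per_snp_reml = bool(assoc.get("per_snp_reml", False))
    alpha = float(cfg.get("report", {}).get("alpha", 0.05))

    snp_info = {s.snp_id: s for s in kept_geno.snps}
    all_results = []
    sig_configs: dict[str, SignificanceConfig] = {}
    vc_rows = []
    for trait in traits:
        if "l1tdt" in methods:
            res, info = scan_l1tdt(kept_geno, pedigree, phenotypes, trait,
                                   weight_mode=weight_mode, alpha=alpha)
            all_results += res
            sig_configs[METHOD_L1TDT] = SignificanceConfig(
                alpha=alpha, n_tests=info["n_tested"])
            manifest["stages"].setdefault("assoc", {})[
                f"l1tdt_{trait}"] = info
        if "mmra" in methods:
            res, vc, info = scan_mmra(kept_geno, pedigree, phenotypes, trait,
                                      per_snp_reml=per_snp_reml, alpha=alpha)
            all_results += res
            sig_configs[METHOD_MMRA] = SignificanceConfig(
                alpha=alpha, n_tests=info["n_tested"])
            vc_rows.append((trait, vc.sigma_a2, vc.sigma_e2,
                            vc.log_likelihood, vc.n_iterations))
            manifest["stages"].setdefault("assoc", {})[
                f"mmra_{trait}"] = info
    write_results(all_results, snp_info, out / "results.tsv")
    if vc_rows:
        pd.DataFrame(vc_rows, columns=["trait", "sigma_a2", "sigma_e2",
                                       "log_likelihood", "n_iterations"]
                     ).to_csv(out / "variance_components.tsv", sep="\t",
                              index=False, float_format="%.12g")

    # ---- stage: report -----------------------------------------------------
    summary = cross_method_summary(all_results, sig_configs)
    summary.per_trait.to_csv(out / "summary_counts.tsv", sep="\t",
                             index=False)
    frame = results_to_frame(all_results, snp_info)
    sig_rows = []
    for _, row in frame.iterrows():
        cfg_m = sig_configs[row["method"]]
        if row["raw_p"] < cfg_m.threshold:
            sig_rows.append(row)
    (pd.DataFrame(sig_rows, columns=frame.columns) if sig_rows
     else frame.iloc[0:0]).to_csv(out / "significant_snps.tsv", sep="\t",
                                  index=False, float_format="%.12g")
    qq_rows = []
    for trait in traits:
        for method in sig_configs:
            ps = frame[(frame["trait"] == trait)
                       & (frame["method"] == method)]["raw_p"].to_numpy()
            if ps.size == 0:
                continue
            qq = qq_points(ps, reference="uniform")
            qq_rows.append((trait, method, qq.inflation_factor))
    pd.DataFrame(qq_rows, columns=["trait", "method", "inflation_factor"]
                 ).to_csv(out / "qq_inflation.tsv", sep="\t", index=False,
                          float_format="%.6g")
    manifest["stages"]["report"] = {
        "n_results": len(all_results),
        "n_significant": len(sig_rows),
        "distinct_significant_snps": summary.n_distinct,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str) + "\n")
    return manifest
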