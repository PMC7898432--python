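"""End-to-end orchestration: simulate/load -> classify -> phase -> associate ->
diplotype -> candidate genes, with a deterministic run manifest.

Configuration is a flat YAML mapping; unknown keys are rejected so typos fail
loudly.  All randomness derives from the single ``seed`` entry.  Stage
failures raise :class:`StageError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotation as annotation_mod
from . import association, diplotypes, markers, phasing, popsim

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All stage parameters of one run.  See field names for the YAML keys."""

    out_dir: str = "crosshap_run"
    seed: int = 0
    # inputs: either simulate=True or paths to genotype/phenotype files
    simulate: bool = True
    genotypes: str | None = None
    genotype_format: str | None = None
    phenotypes: str | None = None
    annotation: str | None = None
    annotation_format: str = "gff3"     # or "tsv"
    mother_id: str = "mother"
    father_id: str = "father"
    # simulation parameters (used when simulate=True)
    n_lg: int = 5
    markers_per_lg: int = 200
    lg_length_bp: int = 16_000_000
    lg_length_cm: float = 60.0
    n_progeny: int = 104
    frac_maternal_informative: float = 0.4
    frac_paternal_informative: float = 0.4
    frac_both_het: float = 0.1
    missing_rate: float = 0.1
    genotype_error_rate: float = 0.01
    qtl_lg: str = "LG1"
    qtl_position_bp: int = 8_000_000
    qtl_effects: dict = field(default_factory=lambda: {
        "M1P1": -56.0, "M1P2": 84.0, "M2P1": -71.0, "M2P2": 99.0})
    trait_baseline: float = 400.0
    trait_noise_sd: float = 80.0
    # analysis parameters
    min_run: int = 3
    n_perm: int = 9999
    p_threshold: float = 0.001
    max_gap_bp: int = 1_000_000
    min_info_frac: float = 0.5
    gene_rule: str = "start-in-region"
    prefixes: tuple[str, str] = ("M", "P")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "prefixes" in raw:
            raw["prefixes"] = tuple(raw["prefixes"])
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            if not self.genotypes or not self.phenotypes:
                raise ConfigError(
                    "simulation disabled but genotypes/phenotypes paths missing")

    def sim_config(self) -> popsim.SimulationConfig:
        return popsim.SimulationConfig(
            n_lg=self.n_lg, markers_per_lg=self.markers_per_lg,
            lg_length_bp=self.lg_length_bp, lg_length_cm=self.lg_length_cm,
            n_progeny=self.n_progeny,
            frac_maternal_informative=self.frac_maternal_informative,
            frac_paternal_informative=self.frac_paternal_informative,
            frac_both_het=self.frac_both_het, missing_rate=self.missing_rate,
            genotype_error_rate=self.genotype_error_rate, seed=self.seed,
            mother_id=self.mother_id, father_id=self.father_id,
        )


def _perm_rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 7])))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write per-stage TSV/JSON outputs and manifest.json.

    Returns the manifest (parameters, seeds, per-stage record counts).  A
    fixed config and seed give byte-identical outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "crosshap_version": __version__,
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(config).items()},
        "stages": {},
    }

    # ---- inputs -----------------------------------------------------------
    truth = None
    try:
        if config.simulate:
            gm, pheno, truth = popsim.simulate_population(
                config.sim_config(),
                qtls=[popsim.QTLSpec(config.qtl_lg, config.qtl_position_bp,
                                     dict(config.qtl_effects),
                                     baseline=config.trait_baseline,
                                     noise_sd=config.trait_noise_sd)],
            )
            markers.write_vcf(gm, out / "genotypes.vcf")
            markers.write_phenotypes_tsv(pheno, out / "phenotypes.tsv")
            popsim.write_truth_tsv(truth, out / "truth")
        else:
            gm = markers.read_genotypes(config.genotypes, config.genotype_format,
                                        config.mother_id, config.father_id)
            pheno = markers.read_phenotypes(config.phenotypes, gm.progeny)
    except (OSError, ValueError) as e:
        raise StageError("inputs", str(e)) from e
    manifest["stages"]["inputs"] = {
        "n_markers": int(len(gm.markers)), "n_individuals": len(gm.individuals),
        "n_phenotyped": int(len(pheno)),
    }

    # ---- classify ---------------------------------------------------------
    try:
        classes = markers.classify_markers(gm)
    except ValueError as e:
        raise StageError("classify", str(e)) from e
    cls_df = pd.DataFrame({"lg": gm.markers["lg"], "bp": gm.markers["bp"],
                           "marker_class": [c.value for c in classes]})
    cls_df.to_csv(out / "marker_classes.tsv", sep="\t")
    manifest["stages"]["classify"] = {
        cls.value: int((classes == cls).sum()) for cls in markers.MarkerClass
    }

    # ---- phase + breakpoints ---------------------------------------------
    tms = {}
    bp_frames = []
    try:
        for parent in ("maternal", "paternal"):
            at = phasing.raw_transmission(gm, classes, parent)
            tm = phasing.phase_parent(at)
            tms[parent] = tm
            phasing.write_transmissions_tsv(tm, out / f"transmissions_{parent}.tsv")
            bp_frames.append(phasing.detect_breakpoints(tm, config.min_run))
    except ValueError as e:
        raise StageError("phase", str(e)) from e
    breakpoints = pd.concat(bp_frames, ignore_index=True)
    breakpoints.to_csv(out / "breakpoints.tsv", sep="\t", index=False)
    manifest["stages"]["phase"] = {
        "n_informative_maternal": int(len(tms["maternal"].markers)),
        "n_informative_paternal": int(len(tms["paternal"].markers)),
        "n_breakpoints": int(len(breakpoints)),
    }

    # ---- association ------------------------------------------------------
    try:
        rng = _perm_rng(config.seed)
        scans = [association.scan_association(tms[p], pheno, config.n_perm, rng)
                 for p in ("maternal", "paternal")]
        assoc = pd.concat(scans, ignore_index=True).sort_values(
            ["lg", "bp"], kind="stable").reset_index(drop=True)
        regions = association.define_regions(assoc, config.p_threshold,
                                             config.max_gap_bp)
    except ValueError as e:
        raise StageError("associate", str(e)) from e
    assoc.to_csv(out / "assoc.tsv", sep="\t", index=False, float_format="%.6g")
    association.regions_to_frame(regions).to_csv(out / "regions.tsv", sep="\t",
                                                 index=False, float_format="%.6g")
    manifest["stages"]["associate"] = {
        "n_tests": int(len(assoc)), "n_perm": config.n_perm,
        "n_regions": len(regions),
        "regions": [r.region_id for r in regions],
    }

    # ---- diplotypes -------------------------------------------------------
    manifest["stages"]["diplotype"] = {}
    try:
        for r in regions:
            calls = diplotypes.call_region_diplotypes(
                tms, r, config.min_info_frac, config.min_run)
            calls = calls.assign(
                rendered=[diplotypes.render_call(c, config.prefixes)
                          for c in calls["call"]])
            safe = r.region_id.replace(":", "_")
            calls.to_csv(out / f"diplotypes_{safe}.tsv", sep="\t", index=False,
                         float_format="%.4g")
            report = diplotypes.diplotype_effect_test(calls, pheno, config.prefixes)
            (out / f"effects_{safe}.json").write_text(report.to_json() + "\n")
            manifest["stages"]["diplotype"][r.region_id] = {
                "n_called": report.n_called,
                "n_recombinant": report.n_recombinant,
                "n_unknown": report.n_unknown,
                "anova_p": report.p_value,
            }
    except ValueError as e:
        raise StageError("diplotype", str(e)) from e

    # ---- candidate genes --------------------------------------------------
    if config.annotation:
        try:
            if config.annotation_format == "tsv":
                genes = annotation_mod.load_gene_table(config.annotation)
            else:
                genes = annotation_mod.load_genes_gff3(config.annotation)
            n_by_region = {}
            for r in regions:
                hits = annotation_mod.genes_in_region(genes, r, config.gene_rule)
                safe = r.region_id.replace(":", "_")
                hits.to_csv(out / f"genes_{safe}.tsv", sep="\t", index=False)
                n_by_region[r.region_id] = int(len(hits))
            manifest["stages"]["genes"] = n_by_region
        except (OSError, ValueError) as e:
            raise StageError("genes", str(e)) from e

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
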