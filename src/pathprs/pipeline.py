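"""Configuration, logging and the orchestrated end-to-end run.

``run_all`` reproduces the full analysis sequence on a synthetic cohort:
simulate -> cohort summary + age-corrected epidemiological regression ->
GWAS for both traits -> LD score regression genetic correlation ->
genome-wide PRS association per sex and threshold -> pathway PRS scan with
per-iteration FDR. Every stage writes its outputs under the run directory and
the run is summarised in a JSON manifest with config hash and file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields, is_dataclass, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import epi as epi_mod
from . import io as io_mod
from .gwas import run_gwas
from .ldsc import compute_ld_scores, estimate_rg
from .pathways import PprsConfig, map_snps_to_genes, run_pprs_scan
from .prs import PrsConfig, associate_prs, compute_prs, ld_clump, select_variants
from .simulate import (
    SimulationConfig,
    implied_rg,
    simulate_annotation,
    simulate_genotypes,
    simulate_model_sumstats,
    simulate_phenotypes,
    subset_individuals,
)

__all__ = ["PipelineConfig", "EpiSettings", "LdscSettings", "RunManifest", "run_all"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A configuration mapping contains an unknown or invalid key."""


@dataclass(frozen=True)
class EpiSettings:
    definition: str = "patterns_3_and_4"
    age_window: tuple[float, float] | None = (52.0, 59.0)
    bins: tuple[tuple[int, int], ...] = epi_mod.DEFAULT_AGE_BINS
    make_plot: bool = True


@dataclass(frozen=True)
class LdscSettings:
    """Genetic-correlation stage settings.

    The rg estimate operates on "published-scale" summary statistics drawn
    from the bivariate LD score regression model (sample size ``sumstats_n``,
    balding heritability from the simulation config, COVID heritability
    ``covid_h2``, cross-trait correlation implied by the planted ground
    truth), emulating the external GWAS pairs such an analysis consumes; a
    desk-scale cohort GWAS carries far too little information for LD score
    regression. LD scores come from the simulated genotypes.
    """

    window_bp: int = 1_000_000
    n_blocks: int = 50
    adjusted: bool = False
    weighted: bool = True
    sumstats_n: int = 20_000
    covid_h2: float = 0.05


@dataclass(frozen=True)
class PprsSettings:
    mapping_window_bp: int = 10_000
    min_variants: int = 1
    fdr_scope: str = "cell"
    clump_within_pathway: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    """Nested pipeline configuration; every default is documented on the
    corresponding settings dataclass. The global ``seed`` drives all
    stochastic stages (the simulation derives per-operation substreams from
    it)."""

    seed: int = 0
    out_dir: str = "pathprs_run"
    verbosity: str = "info"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    epi: EpiSettings = field(default_factory=EpiSettings)
    ldsc: LdscSettings = field(default_factory=LdscSettings)
    prs: PrsConfig = field(default_factory=PrsConfig)
    pprs: PprsSettings = field(default_factory=PprsSettings)


def _coerce(value: Any) -> Any:
    if isinstance(value, list):
        return tuple(_coerce(v) for v in value)
    return value


def _build_dataclass(cls: type, data: dict[str, Any], path: str) -> Any:
    if not isinstance(data, dict):
        raise ConfigError(f"section {path or '<root>'} must be a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown configuration key: {path + '.' if path else ''}{key}")
    kwargs: dict[str, Any] = {}
    for name, value in data.items():
        f = known[name]
        sub = f.default_factory() if f.default_factory is not dataclasses.MISSING else None  # type: ignore[misc]
        if sub is not None and is_dataclass(sub) and isinstance(value, dict):
            kwargs[name] = _build_dataclass(type(sub), value, f"{path + '.' if path else ''}{name}")
        else:
            kwargs[name] = _coerce(value)
    return cls(**kwargs)


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    """Build a PipelineConfig from a nested mapping, rejecting unknown keys
    with the offending dotted path named."""
    return _build_dataclass(PipelineConfig, data, "")


def config_from_yaml(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def config_to_dict(config: Any) -> Any:
    if is_dataclass(config):
        return {f.name: config_to_dict(getattr(config, f.name)) for f in fields(config)}
    if isinstance(config, tuple):
        return [config_to_dict(v) for v in config]
    return config


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    files: dict[str, str]
    started: str
    finished: str
    completed_stages: list[str]
    incomplete: bool = False

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


_STAGES = ("simulate", "epi", "gwas", "ldsc", "prs", "pprs", "report")


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline, writing all stage outputs plus a manifest.

    Any stage failure halts the run with the stage named; outputs written so
    far stay in place and the manifest is flagged incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    level = {"debug": logging.DEBUG, "info": logging.INFO, "quiet": logging.WARNING}.get(
        config.verbosity, logging.INFO
    )
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")

    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    cfg_dict = config_to_dict(config)
    cfg_dict.pop("out_dir")  # run location is not part of the scientific config
    cfg_yaml = yaml.safe_dump(cfg_dict, sort_keys=True)
    config_hash = hashlib.sha256(cfg_yaml.encode()).hexdigest()
    (out / "config.yaml").write_text(cfg_yaml)
    completed: list[str] = []
    state: dict[str, Any] = {}

    def finish(incomplete: bool) -> RunManifest:
        files = {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        }
        manifest = RunManifest(
            config_hash=config_hash,
            seed=config.seed,
            version=__version__,
            files=files,
            started=started,
            finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
            completed_stages=list(completed),
            incomplete=incomplete,
        )
        manifest.to_json(out / "manifest.json")
        return manifest

    try:
        for stage in _STAGES:
            logger.info("stage %s", stage)
            _run_stage(stage, config, out, state)
            completed.append(stage)
    except Exception as exc:
        finish(incomplete=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return finish(incomplete=False)


def _run_stage(stage: str, config: PipelineConfig, out: Path, state: dict[str, Any]) -> None:
    if stage == "simulate":
        sim = replace(config.simulation, seed=config.seed)
        genotypes = simulate_genotypes(sim)
        annotation, libraries = simulate_annotation(sim)
        phenotypes, effects = simulate_phenotypes(genotypes, annotation, libraries, sim)
        io_mod.write_vcf(genotypes, out / "genotypes.vcf")
        io_mod.write_dosage_tsv(genotypes, out / "genotypes.dosage.tsv")
        io_mod.write_phenotypes(phenotypes, out / "phenotypes.tsv")
        io_mod.write_annotation_bed(annotation, out / "genes.bed.tsv")
        for lib in libraries:
            io_mod.write_gmt(lib, out / f"{lib.library_name}.gmt")
        logger.info(
            "simulated %d individuals x %d variants; %d genes, %d libraries",
            genotypes.n_individuals, genotypes.n_variants, len(annotation), len(libraries),
        )
        state.update(
            genotypes=genotypes, annotation=annotation, libraries=libraries,
            phenotypes=phenotypes, effects=effects, sim=sim,
        )
    elif stage == "epi":
        phen = state["phenotypes"]
        summary = epi_mod.summarize_cohort(phen)
        pd.DataFrame(
            [{
                "n_total": summary.n_total, "n_male": summary.n_male,
                "n_female": summary.n_female,
                "n_hospitalized_male": summary.n_hospitalized_male,
                "n_hospitalized_female": summary.n_hospitalized_female,
                "control_case_ratio_male": summary.control_case_ratio_male,
                "control_case_ratio_female": summary.control_case_ratio_female,
                **{f"freq_pattern_{k}": v for k, v in summary.aga_pattern_freqs.items()},
            }]
        ).to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
        summary.age_summary.to_csv(out / "cohort_ages.tsv", sep="\t", index=False)
        residuals = epi_mod.residualize_aga_on_age(phen)
        results = []
        windows: list[tuple[float, float] | None] = [None]
        if config.epi.age_window is not None:
            windows.append(config.epi.age_window)
        for window in windows:
            r = epi_mod.regress_severity_on_aga(phen, residuals, age_window=window)
            results.append(
                {"age_window": "full" if window is None else f"{window[0]}-{window[1]}",
                 "beta": r.beta, "se": r.se, "p": r.p, "n": r.n}
            )
        pd.DataFrame(results).to_csv(out / "epi_regression.tsv", sep="\t", index=False)
        tables = {}
        for definition in epi_mod.SEVERITY_DEFINITIONS:
            t = epi_mod.prevalence_by_age_group(
                phen, phen, definition=definition, bins=config.epi.bins
            )
            t.to_csv(out / f"prevalence_{definition}.tsv", sep="\t", index=False)
            tables[definition] = t
        if config.epi.make_plot:
            io_mod.plot_prevalence(
                tables["patterns_3_and_4"], tables["pattern_4_only"],
                out / "prevalence.png",
            )
        state["epi_results"] = results
    elif stage == "gwas":
        genotypes, phen = state["genotypes"], state["phenotypes"]
        males = (phen["sex"] == "male") & phen["aga_pattern"].notna()
        male_idx = np.flatnonzero(males.to_numpy())
        male_geno = subset_individuals(genotypes, male_idx)
        aga_ss = run_gwas(
            male_geno,
            phen.loc[males, "aga_pattern"].to_numpy(float),
            covariates=phen.loc[males, "age_at_assessment"].to_numpy(float),
            model="linear",
        )
        covid_ss = run_gwas(
            genotypes,
            phen["hospitalized"].to_numpy(float),
            covariates=phen["age_at_event"].to_numpy(float),
            model="logistic",
        )
        io_mod.write_sumstats(aga_ss, out / "sumstats_aga.tsv")
        io_mod.write_sumstats(covid_ss, out / "sumstats_covid.tsv")
        state.update(aga_ss=aga_ss, covid_ss=covid_ss)
    elif stage == "ldsc":
        ld = compute_ld_scores(
            state["genotypes"], config.ldsc.window_bp, adjusted=config.ldsc.adjusted
        )
        io_mod.write_ld_scores(ld, out / "ld_scores.tsv")
        # Published-scale sumstats pair consistent with the bivariate model,
        # at the cross-trait correlation implied by the planted ground truth.
        rg_true = implied_rg(state["effects"])
        ss1, ss2 = simulate_model_sumstats(
            m_variants=len(ld),
            ld_scores=ld["l2"].to_numpy(),
            n1=config.ldsc.sumstats_n,
            n2=config.ldsc.sumstats_n,
            h2_1=config.simulation.aga_h2,
            h2_2=config.ldsc.covid_h2,
            rg=rg_true,
            seed=(config.seed * 9973 + 17) % 2**31,
        )
        for ss, name in ((ss1, "aga"), (ss2, "covid")):
            ss[["id", "chrom", "pos"]] = ld[["id", "chrom", "pos"]].to_numpy()
            io_mod.write_sumstats(ss, out / f"sumstats_{name}_published_scale.tsv")
        res = estimate_rg(
            ss1, ss2, ld,
            n_blocks=config.ldsc.n_blocks, weighted=config.ldsc.weighted,
        )
        row = dataclasses.asdict(res)
        jk = row.pop("jackknife_rg")
        pd.DataFrame([row]).assign(rg_generating=rg_true).to_csv(
            out / "ldsc_rg.tsv", sep="\t", index=False
        )
        if jk is not None:
            pd.DataFrame({"block": range(len(jk)), "rg_delete_block": jk}).to_csv(
                out / "ldsc_rg_jackknife.tsv", sep="\t", index=False
            )
        state.update(ld=ld, ldsc_result=res, rg_generating=rg_true)
    elif stage == "prs":
        genotypes, phen, aga_ss = state["genotypes"], state["phenotypes"], state["aga_ss"]
        score_frames, assoc_rows = [], []
        for threshold in config.prs.p_thresholds:
            sel = select_variants(aga_ss, threshold)
            if config.prs.clump_enabled and not sel.empty:
                sel = ld_clump(sel, genotypes, config.prs.clump_r2, config.prs.clump_window_bp)
            prs = compute_prs(genotypes, sel, config.prs, threshold=threshold)
            score_frames.append(
                pd.DataFrame(
                    {"IID": prs.scores.index, "threshold": threshold,
                     "score": prs.scores.to_numpy(), "n_variants": prs.n_variants_used}
                )
            )
            for sex in ("male", "female"):
                try:
                    a = associate_prs(prs, phen, sex)
                    assoc_rows.append(dataclasses.asdict(a))
                except (ValueError, RuntimeError) as exc:
                    assoc_rows.append(
                        {"sex": sex, "threshold": threshold, "beta": np.nan,
                         "se": np.nan, "p": np.nan, "n_cases": np.nan,
                         "n_controls": np.nan, "flag": str(exc)}
                    )
        pd.concat(score_frames).to_csv(out / "prs_scores.tsv", sep="\t", index=False)
        prs_assoc = pd.DataFrame(assoc_rows)
        prs_assoc.to_csv(out / "prs_association.tsv", sep="\t", index=False)
        state["prs_assoc"] = prs_assoc
    elif stage == "pprs":
        pprs_config = PprsConfig(
            prs=config.prs,
            mapping_window_bp=config.pprs.mapping_window_bp,
            min_variants=config.pprs.min_variants,
            fdr_scope=config.pprs.fdr_scope,
            clump_within_pathway=config.pprs.clump_within_pathway,
        )
        table = run_pprs_scan(
            state["genotypes"], state["aga_ss"], state["phenotypes"],
            state["annotation"], state["libraries"], pprs_config,
        )
        table.to_csv(out / "pprs_table.tsv", sep="\t", index=False)
        snp_map = map_snps_to_genes(
            state["genotypes"].variants, state["annotation"],
            window_bp=pprs_config.mapping_window_bp,
        )
        audit = pd.DataFrame(
            {
                "variant": list(snp_map.variant_to_genes),
                "genes": [
                    ",".join(sorted(g)) for g in snp_map.variant_to_genes.values()
                ],
            }
        )
        audit.to_csv(out / "snp_gene_map.tsv", sep="\t", index=False)
        state["pprs_table"] = table
    elif stage == "report":
        res = state["ldsc_result"]
        lines = [
            "# pathprs end-to-end report",
            f"epi: {state['epi_results']}",
            f"ldsc: rg={res.rg} se={res.se_rg} p={res.p} "
            f"(h2_1={res.h2_trait1:.4f}, h2_2={res.h2_trait2:.4f})",
        ]
        table = state["pprs_table"]
        if not table.empty and table["p_fdr"].notna().any():
            top = table.loc[table["p_fdr"].idxmin()]
            lines.append(
                f"top pathway: {top['pathway']} ({top['library']}, sex={top['sex']}, "
                f"threshold={top['threshold']:g}) p_fdr={top['p_fdr']:.3g}"
            )
        (out / "report.txt").write_text("\n".join(lines) + "\n")
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage!r}")
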