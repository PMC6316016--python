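"""End-to-end orchestration: simulate -> scan -> kaks/date -> expr -> report.

A run is described by a flat, human-editable YAML config (RunConfig); every
stochastic stage derives its seed deterministically from the single global
seed, so identical config + seed reproduce byte-identical statistical
outputs.  Each run writes a manifest (manifest.json) listing the stages,
parameters, derived seeds, software version and every output file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as dio
from .expression import contribution_partition, correlate_expression, fit_trait_model
from .kaks import date_duplication, estimate_kaks
from .simulate import (CodonSimParams, ExprSimParams, PopSimParams,
                       simulate_codon_pair, simulate_expression_trait,
                       simulate_populations)
from .sweep import classify_genes, scan_windows, write_sweep_calls, write_window_stats

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "scan", "kaks", "date", "expr", "report")


@dataclass
class ScanConfig:
    window_size: int = 20_000
    step: int = 2_000
    min_snps: int = 3
    top: tuple[float, float] = (0.01, 0.05)
    orientation: str = "ancestral-over-derived"
    pseudocount: float = 1e-6


@dataclass
class RunConfig:
    """Full configuration of a pipeline run."""

    outdir: str = "run"
    seed: int = 1
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    pop_sim: PopSimParams = field(default_factory=PopSimParams)
    codon_sim: CodonSimParams = field(default_factory=CodonSimParams)
    expr_sim: ExprSimParams = field(default_factory=ExprSimParams)
    genes: list[tuple[str, int, int]] = field(default_factory=list)
    scan: ScanConfig = field(default_factory=ScanConfig)
    lambda_rate: float | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "pop_sim" in kwargs and isinstance(kwargs["pop_sim"], dict):
            kwargs["pop_sim"] = PopSimParams(**kwargs["pop_sim"])
        if "codon_sim" in kwargs and isinstance(kwargs["codon_sim"], dict):
            kwargs["codon_sim"] = CodonSimParams(**kwargs["codon_sim"])
        if "expr_sim" in kwargs and isinstance(kwargs["expr_sim"], dict):
            d = dict(kwargs["expr_sim"])
            for key in ("betas", "expr_means", "expr_sds", "genes"):
                if key in d and isinstance(d[key], list):
                    d[key] = tuple(d[key])
            kwargs["expr_sim"] = ExprSimParams(**d)
        if "scan" in kwargs and isinstance(kwargs["scan"], dict):
            d = dict(kwargs["scan"])
            if "top" in d and isinstance(d["top"], list):
                d["top"] = tuple(d["top"])
            kwargs["scan"] = ScanConfig(**d)
        if "genes" in kwargs:
            kwargs["genes"] = [tuple(g) for g in kwargs["genes"]]
        return cls(**kwargs)


def _plain(obj):
    """Make asdict output YAML-safe (tuples -> lists, numpy scalars -> python)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def derive_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2^31) from the global seed."""
    state = np.random.SeedSequence(global_seed).generate_state(3, dtype=np.uint64)
    return {
        "pop_sim": int(state[0] % (2**31)),
        "codon_sim": int(state[1] % (2**31)),
        "expr_sim": int(state[2] % (2**31)),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(outdir / "run.log")
    logging.getLogger().addHandler(fh)

    seeds = derive_seeds(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "derived_seeds": seeds,
        "stages": [],
        "outputs": {},
        "parameters": _plain(asdict(config)),
    }
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "pops": outdir / "populations.tsv",
        "genes": outdir / "genes.bed",
        "fasta": outdir / "codon_pair.fasta",
        "traits": outdir / "traits.tsv",
        "windows": outdir / "window_stats.tsv",
        "calls": outdir / "sweep_calls.tsv",
        "kaks": outdir / "kaks.tsv",
        "dating": outdir / "dating.tsv",
        "correlations": outdir / "correlations.tsv",
        "model_fit": outdir / "model_fit.tsv",
        "contributions": outdir / "contributions.tsv",
    }

    def record(stage: str, *keys: str) -> None:
        manifest["stages"].append(stage)
        for k in keys:
            manifest["outputs"][k] = str(paths[k].relative_to(outdir))

    try:
        if "simulate" in config.stages:
            pop_params = dataclasses.replace(config.pop_sim, seed=seeds["pop_sim"])
            matrix = simulate_populations(pop_params)
            dio.write_vcf(matrix, paths["vcf"])
            dio.write_pop_map(matrix.pop_map, paths["pops"])
            regions = [dio.GeneRegion(pop_params.chrom, s, e, n) for n, s, e in config.genes]
            dio.write_gene_regions(regions, paths["genes"])
            codon_params = dataclasses.replace(config.codon_sim, seed=seeds["codon_sim"])
            pair = simulate_codon_pair(codon_params)
            dio.write_fasta_pair(pair, paths["fasta"])
            expr_params = dataclasses.replace(config.expr_sim, seed=seeds["expr_sim"])
            table = simulate_expression_trait(expr_params)
            dio.write_trait_table(table, paths["traits"])
            record("simulate", "vcf", "pops", "genes", "fasta", "traits")

        if "scan" in config.stages:
            if not paths["vcf"].exists():
                raise FileNotFoundError(
                    "scan stage: missing genotypes.vcf — run the simulate stage first "
                    "or place inputs in the output directory"
                )
            matrix = dio.read_vcf(paths["vcf"], paths["pops"])
            sc = config.scan
            windows = scan_windows(
                matrix, window_size=sc.window_size, step=sc.step,
                min_snps=sc.min_snps, pseudocount=sc.pseudocount,
                orientation=sc.orientation,
            )
            write_window_stats(windows, paths["windows"])
            regions = dio.read_gene_regions(paths["genes"]) if paths["genes"].exists() else []
            calls = []
            if regions:
                try:
                    calls = classify_genes(windows, regions, top=sc.top)
                except ValueError as exc:
                    logger.warning("sweep classification skipped: %s", exc)
            write_sweep_calls(calls, paths["calls"])
            record("scan", "windows", "calls")

        if "kaks" in config.stages:
            if not paths["fasta"].exists():
                raise FileNotFoundError("kaks stage: missing codon_pair.fasta — run simulate first")
            pair = dio.read_fasta_pair(paths["fasta"])
            res = estimate_kaks(pair)
            pd.DataFrame([{
                "n_codons": pair.n_codons, "S": res.s_sites, "N": res.n_sites,
                "Sd": res.sd, "Nd": res.nd, "ps": res.ps, "pn": res.pn,
                "Ks": res.ks, "Ka": res.ka,
                "omega": res.omega if res.omega is not None else float("nan"),
            }]).to_csv(paths["kaks"], sep="\t", index=False, float_format="%.8g")
            record("kaks", "kaks")

        if "date" in config.stages:
            if config.lambda_rate is None:
                raise ValueError(
                    "date stage requires lambda_rate (neutral substitutions per "
                    "silent site per year); it has no default"
                )
            if not paths["kaks"].exists():
                raise FileNotFoundError("date stage: missing kaks.tsv — run the kaks stage first")
            ks = float(pd.read_csv(paths["kaks"], sep="\t")["Ks"].iloc[0])
            d = date_duplication(ks, config.lambda_rate)
            pd.DataFrame([{
                "Ks": d.ks_value, "lambda": d.lambda_rate,
                "T_years": d.t_years, "T_mya": d.t_mya,
            }]).to_csv(paths["dating"], sep="\t", index=False, float_format="%.8g")
            record("date", "dating")

        if "expr" in config.stages:
            if not paths["traits"].exists():
                raise FileNotFoundError("expr stage: missing traits.tsv — run simulate first")
            genes = list(config.expr_sim.genes)
            table = dio.read_trait_table(paths["traits"], genes=genes)
            corrs = correlate_expression(table)
            pd.DataFrame([asdict(c) for c in corrs]).to_csv(
                paths["correlations"], sep="\t", index=False, float_format="%.8g")
            fit = fit_trait_model(table)
            pd.DataFrame({
                "term": list(fit.coefficients),
                "coefficient": list(fit.coefficients.values()),
                "std_error": list(fit.std_errors.values()),
            }).to_csv(paths["model_fit"], sep="\t", index=False, float_format="%.8g")
            contrib = contribution_partition(table)
            pd.DataFrame({
                "gene": list(contrib.contributions),
                "contribution_pct": list(contrib.contributions.values()),
                "main_effects_r2": contrib.main_effects_r2,
                "full_model_r2": contrib.full_model_r2,
                "method": contrib.method,
            }).to_csv(paths["contributions"], sep="\t", index=False, float_format="%.8g")
            record("expr", "correlations", "model_fit", "contributions")

        manifest_path = outdir / "manifest.json"
        with open(manifest_path, "w") as out:
            json.dump(manifest, out, indent=2)

        if "report" in config.stages:
            from .report import render_report
            report_files = render_report(outdir)
            manifest["stages"].append("report")
            for k, p in report_files.items():
                manifest["outputs"][k] = str(Path(p).relative_to(outdir))
            with open(manifest_path, "w") as out:
                json.dump(manifest, out, indent=2)
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()

    missing = [k for k, p in manifest["outputs"].items() if not (outdir / p).exists()]
    if missing:
        raise RuntimeError(f"manifest lists outputs that were not written: {missing}")
    return manifest
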