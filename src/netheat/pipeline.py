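"""End-to-end orchestration of the three differential conditions.

For each contrast: rank-product differential expression -> heat from FDR ->
insulated-diffusion module discovery per interactome with permutation
significance -> majority consensus across interactomes -> GO-style
functional filter -> eigengene/Kendall evaluation against phenotypes.
Every stochastic stage receives a seed derived deterministically from the
master seed and a stage tag, so stages can be re-run in isolation and full
runs are byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexp, enrich, evaluate, modules
from .diffusion import (DEFAULT_BETA, DEFAULT_HEAT_CAP, build_diffusion,
                        heat_from_fdr)
from .io import (Contrast, ExpressionMatrix, GeneSetCollection,
                 InteractionNetwork, PhenotypeTable, harmonize,
                 read_expression, read_gmt, read_network, read_phenotypes,
                 standard_contrasts)

logger = logging.getLogger("netheat")


def derive_seed(master: int, tag: str) -> int:
    """Stable per-stage seed below 2**31."""
    return zlib.crc32(f"{master}:{tag}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Flat run configuration mirroring the YAML/JSON config document."""

    expression: str = ""
    metadata: str = ""
    networks: dict[str, str] = field(default_factory=dict)
    genesets: str = ""
    phenotypes: str | None = None
    probe_map: str | None = None
    contrasts: list[str] = field(default_factory=lambda: ["COPD-DE", "COPD-TE",
                                                          "Healthy-TE"])
    beta: float = DEFAULT_BETA
    delta: float | str = "auto"
    l_max: int = modules.DEFAULT_L_MAX
    min_size: int = modules.DEFAULT_MIN_SIZE
    n_perm_rp: int = diffexp.DEFAULT_N_PERM
    n_perm_delta: int = modules.DEFAULT_DELTA_PERM
    n_perm_sig: int = modules.DEFAULT_SIG_PERM
    max_pairs: int = diffexp.DEFAULT_MAX_PAIRS
    heat_cap: float = DEFAULT_HEAT_CAP
    universe: str = "network"  # or "array"
    rho_threshold: float = evaluate.RHO_THRESHOLD
    p_threshold: float = evaluate.P_THRESHOLD
    seed: int = 0
    outdir: str = "netheat_run"

    def __post_init__(self) -> None:
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")
        if self.universe not in ("network", "array"):
            raise ValueError("universe must be 'network' or 'array'")
        if not 0 < self.rho_threshold <= 1 or not 0 < self.p_threshold <= 1:
            raise ValueError("association thresholds out of range")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        missing = [p for p in [cfg.expression, cfg.metadata, cfg.genesets,
                               *cfg.networks.values(),
                               *( [cfg.phenotypes] if cfg.phenotypes else [] )]
                   if p and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing files: {missing}")
        return cfg


@dataclass
class ConditionResult:
    contrast: str
    differential: diffexp.DifferentialResult
    per_network: list[modules.ModuleSet]
    consensus: modules.ModuleSet
    functional: modules.ModuleSet
    enrichment: enrich.EnrichmentResult
    associations: evaluate.AssociationResult | None
    report: dict


def _stage(report: dict, name: str, **info) -> None:
    report.setdefault("stages", []).append({"stage": name, **info})
    logger.info("stage %-18s %s", name,
                " ".join(f"{k}={v}" for k, v in info.items()))


def _association_inputs(expr: ExpressionMatrix, contrast: Contrast,
                        pheno: PhenotypeTable):
    """Align expression profiles and phenotype rows for a contrast.

    Disease-effect contrasts correlate per-sample values over the contrast's
    samples; training-effect contrasts correlate per-subject post-minus-pre
    differentials on both sides.
    """
    md = expr.metadata
    if contrast.design == "paired":
        post = {md.loc[s, "subject"]: s for s in contrast.class_a}
        pre = {md.loc[s, "subject"]: s for s in contrast.class_b}
        diff_map = {s: (post[s], pre[s]) for s in sorted(set(post) & set(pre))}
        ph = pheno.frame
        rows = {}
        for subj, (sp, spre) in diff_map.items():
            if sp in ph.index and spre in ph.index:
                rows[subj] = ph.loc[sp] - ph.loc[spre]
        pheno_aligned = PhenotypeTable(pd.DataFrame(rows).T)
        return diff_map, None, pheno_aligned
    samples = list(contrast.class_a) + list(contrast.class_b)
    keep = [s for s in samples if s in pheno.frame.index]
    return None, samples, PhenotypeTable(pheno.frame.loc[keep])


def run_condition(
    expr: ExpressionMatrix,
    networks: list[InteractionNetwork],
    genesets: GeneSetCollection,
    contrast: Contrast,
    config: RunConfig,
    phenotypes: PhenotypeTable | None = None,
) -> ConditionResult:
    """Execute the full chain for one differential condition in memory."""
    report: dict = {"contrast": contrast.label, "config": {
        "beta": config.beta, "delta": config.delta, "l_max": config.l_max,
        "min_size": config.min_size, "n_perm_rp": config.n_perm_rp,
        "n_perm_delta": config.n_perm_delta, "n_perm_sig": config.n_perm_sig,
        "heat_cap": config.heat_cap, "universe": config.universe,
        "max_pairs": config.max_pairs, "seed": config.seed,
        "probe_collapse": "highest-mean-intensity",
    }}
    t0 = time.perf_counter()
    expr, nets, harm_report = harmonize(expr, networks)
    report["harmonization"] = harm_report
    _stage(report, "harmonize", networks=len(nets))

    diff = diffexp.differential_expression(
        expr, contrast, n_perm=config.n_perm_rp, max_pairs=config.max_pairs,
        seed=derive_seed(config.seed, f"diffexp:{contrast.label}"))
    _stage(report, "diffexp", genes=len(diff.genes),
           comparisons=diff.n_comparisons)

    fdr = diff.fdr()
    per_network: list[modules.ModuleSet] = []
    deltas: dict[str, float] = {}
    for net in nets:
        if net.graph.number_of_edges() == 0:
            continue
        op = build_diffusion(net, beta=config.beta)
        heat = heat_from_fdr(fdr.loc[op.nodes].to_numpy(), cap=config.heat_cap)
        E = op.exchanged_heat(heat)
        if config.delta == "auto":
            delta = modules.select_delta(
                op, heat, n_perm=config.n_perm_delta, l_max=config.l_max,
                seed=derive_seed(config.seed, f"delta:{contrast.label}:{net.name}"))
        else:
            delta = float(config.delta)
        deltas[net.name] = delta
        ms = modules.extract_modules(E, op.nodes, delta,
                                     min_size=config.min_size, heat=heat,
                                     network=net.name, contrast=contrast.label)
        modules.module_significance(
            ms, op, heat, delta, n_perm=config.n_perm_sig,
            seed=derive_seed(config.seed, f"sig:{contrast.label}:{net.name}"))
        per_network.append(ms)
        _stage(report, f"modules[{net.name}]", delta=f"{delta:.3g}",
               n_modules=len(ms),
               n_significant=len(ms.significant_modules()))
    report["delta_per_network"] = deltas

    cons = modules.consensus(
        per_network, min_size=config.min_size,
        heat_by_gene=dict(zip(fdr.index, heat_from_fdr(
            fdr.to_numpy(), cap=config.heat_cap))))
    _stage(report, "consensus", n_modules=len(cons))

    if config.universe == "network":
        universe = set().union(*(set(n.graph.nodes) for n in nets)) if nets else set()
    else:
        universe = set(expr.genes)
    enr = enrich.enrich_modules(cons, genesets, universe)
    functional = enrich.functional_filter(enr, cons)
    _stage(report, "enrichment", n_functional=len(functional))

    associations = None
    if phenotypes is not None and len(functional):
        diff_map, samples, pheno_aligned = _association_inputs(
            expr, contrast, phenotypes)
        eigs = evaluate.eigengenes_for_modules(
            expr, functional, samples=samples,
            differential_by_subject=diff_map)
        associations = evaluate.associate(eigs, pheno_aligned,
                                          contrast=contrast.label)
        report["eigengene_cumulative_variance"] = [
            round(e.cumulative_variance, 4) for e in eigs]
        _stage(report, "evaluation",
               n_selected=int(associations.table["selected"].sum())
               if len(associations.table) else 0)
    report["elapsed_s"] = round(time.perf_counter() - t0, 2)
    return ConditionResult(
        contrast=contrast.label, differential=diff, per_network=per_network,
        consensus=cons, functional=functional, enrichment=enr,
        associations=associations, report=report)


def shared_modules(a: modules.ModuleSet, b: modules.ModuleSet,
                   min_jaccard: float = 0.5) -> list[tuple[int, int, float]]:
    """Pairs of modules from two contrasts with Jaccard overlap >= threshold."""
    out = []
    for i, ma in enumerate(a.modules):
        for j, mb in enumerate(b.modules):
            ga, gb = set(ma.genes), set(mb.genes)
            jac = len(ga & gb) / len(ga | gb)
            if jac >= min_jaccard:
                out.append((i, j, jac))
    return out


def run_study(config: RunConfig, subset: list[str] | None = None) -> dict:
    """Load inputs from config paths, run every contrast and write outputs.

    ``subset`` restricts the analysis to the listed sample ids (metadata is
    subset accordingly) for sensitivity re-runs.  Returns the study report.
    """
    expr = read_expression(config.expression, config.metadata,
                           probe_map_path=config.probe_map)
    if subset is not None:
        expr = expr.subset_samples([s for s in expr.samples if s in set(subset)])
    nets = [read_network(path, name) for name, path in config.networks.items()]
    genesets = read_gmt(config.genesets)
    pheno = read_phenotypes(config.phenotypes) if config.phenotypes else None

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contrasts = standard_contrasts(expr)
    study_report: dict = {"contrasts": {}, "config_seed": config.seed}
    results: dict[str, ConditionResult] = {}
    for label in config.contrasts:
        if label not in contrasts:
            raise ValueError(f"unknown contrast {label!r}")
        res = run_condition(expr, nets, genesets, contrasts[label], config,
                            phenotypes=pheno)
        results[label] = res
        tag = label.replace("-", "_").lower()
        diffexp.write_differential(res.differential, outdir / f"{tag}.diffexp.tsv")
        modules.write_modules(res.consensus, outdir / f"{tag}.modules.tsv")
        enrich.write_enrichment(res.enrichment, outdir / f"{tag}.enrichment.tsv")
        if res.associations is not None:
            evaluate.write_associations(res.associations,
                                        outdir / f"{tag}.associations.tsv")
        study_report["contrasts"][label] = res.report

    if "COPD-TE" in results and "Healthy-TE" in results:
        pairs = shared_modules(results["COPD-TE"].functional,
                               results["Healthy-TE"].functional)
        study_report["shared_TE_modules"] = [
            {"copd_module": i + 1, "healthy_module": j + 1,
             "jaccard": round(jac, 3)} for i, j, jac in pairs]
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(study_report, fh, indent=2, default=str)
    manifest = sorted(p.name for p in outdir.iterdir())
    with open(outdir / "manifest.txt", "w") as fh:
        fh.write("\n".join(m for m in manifest if m != "manifest.txt") + "\n")
    study_report["results"] = results
    return study_report
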