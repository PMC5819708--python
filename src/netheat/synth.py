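"""Synthetic studies with known ground truth.

Emulates the study design the pipeline targets: two groups (COPD, healthy)
of roughly a dozen subjects each, measured pre and post an endurance-training
program on a scale-free interactome, with a minority of genes differentially
expressed in connected network neighborhoods and phenotype variables coupled
to module activity.  Every stage of the pipeline can be validated against
the planted structure.

Scale defaults: 1000 genes on a preferential-attachment graph (3 edges per
new node), 15 COPD and 12 healthy subjects, planted modules of 6-10 genes
with 2.0 log2-unit effects, gene-level noise SD 0.5 and subject-effect SD
0.3 — small enough for desk-scale runs while keeping the heavy-tailed
degree structure and group sizes of a realistic training study.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .evaluate import kendall_tau_b
from .io import (ExpressionMatrix, GeneSetCollection, InteractionNetwork,
                 PhenotypeTable, write_expression, write_gmt, write_network,
                 write_phenotypes)

CONTRASTS = ("COPD-DE", "COPD-TE", "Healthy-TE")


@dataclass
class PlantedModule:
    size: int
    effect: float           # log2 units added to affected samples
    contrast: str           # which differential condition it drives
    topology: str = "connected-subgraph"  # or "clique-ish"


@dataclass
class Coupling:
    """A phenotype variable driven by a planted module's activity."""

    module_index: int       # index into the scenario's planted list
    variable: str
    target_tau: float       # population Kendall tau of signal vs variable
    direction: int = 1


@dataclass
class SyntheticScenario:
    seed: int = 0
    n_genes: int = 1000
    m_edges_per_node: int = 3
    n_copd: int = 15
    n_healthy: int = 12
    planted: list[PlantedModule] = field(default_factory=list)
    couplings: list[Coupling] = field(default_factory=list)
    n_uncoupled_vars: int = 3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    subject_sd: float = 0.3
    noise_sd: float = 0.5
    n_networks: int = 3
    rewire_fraction: float = 0.15


@dataclass
class GroundTruth:
    modules: list[list[str]]            # gene sets, scenario order
    contrast_of: list[str]
    de_genes: dict[str, list[str]]      # contrast -> truly perturbed genes
    couplings: list[Coupling]

    def modules_for(self, contrast: str) -> list[set[str]]:
        return [set(m) for m, c in zip(self.modules, self.contrast_of)
                if c == contrast]


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(n_genes: int, m_edges_per_node: int,
                     seed: int, name: str = "synthetic") -> InteractionNetwork:
    """Connected scale-free-like interactome by preferential attachment."""
    g = nx.barabasi_albert_graph(n_genes, m_edges_per_node, seed=seed)
    mapping = dict(zip(range(n_genes), _gene_names(n_genes)))
    return InteractionNetwork(name=name, graph=nx.relabel_nodes(g, mapping))


def plant_modules(net: InteractionNetwork,
                  scenario: SyntheticScenario) -> GroundTruth:
    """Choose pairwise-disjoint connected subgraphs as ground-truth modules.

    Each module grows by seeded breadth-first expansion (lowest-degree
    neighbors first) from a random start node.  Two realism constraints keep
    the ground truth identifiable: growth avoids the top-decile hubs, which
    belong to no single functional module, and planted modules keep a
    one-edge buffer from each other — distinct biological processes occupy
    distinct network neighborhoods, and adjacent hot modules would be
    inseparable for any diffusion method.  Clique-ish modules additionally
    receive all their internal edges.
    """
    rng = np.random.default_rng(scenario.seed)
    total = sum(p.size for p in scenario.planted)
    if total > len(net):
        raise ValueError(f"planted sizes sum to {total} > {len(net)} genes")
    deg = dict(net.graph.degree)
    hub_cap = float(np.percentile(list(deg.values()), 90)) if deg else 0.0
    eligible = {n for n, d in deg.items() if d <= hub_cap}
    claimed: set[str] = set()  # module members plus their one-edge buffer
    modules: list[list[str]] = []
    nodes = sorted(net.graph.nodes)
    for planted in scenario.planted:
        chosen = None
        for _ in range(500):
            start = nodes[rng.integers(len(nodes))]
            if start in claimed or start not in eligible:
                continue
            grown = [start]
            frontier = [start]
            seen = {start}
            while len(grown) < planted.size and frontier:
                nxt = frontier.pop(0)
                for nb in sorted(net.graph.neighbors(nxt),
                                 key=lambda x: (deg[x], x)):
                    if nb in claimed or nb in seen or nb not in eligible:
                        continue
                    seen.add(nb)
                    grown.append(nb)
                    frontier.append(nb)
                    if len(grown) == planted.size:
                        break
            if len(grown) == planted.size:
                chosen = sorted(grown)
                break
        if chosen is None:
            raise ValueError(f"could not grow a connected module of size "
                             f"{planted.size}")
        if planted.topology == "clique-ish":
            for i, a in enumerate(chosen):
                for b in chosen[i + 1:]:
                    net.graph.add_edge(a, b)
        claimed.update(chosen)
        for x in chosen:
            claimed.update(net.graph.neighbors(x))
        modules.append(chosen)
    de: dict[str, list[str]] = {c: [] for c in CONTRASTS}
    for genes, planted in zip(modules, scenario.planted):
        de.setdefault(planted.contrast, []).extend(genes)
    return GroundTruth(
        modules=modules,
        contrast_of=[p.contrast for p in scenario.planted],
        de_genes={c: sorted(v) for c, v in de.items()},
        couplings=list(scenario.couplings),
    )


def network_variants(net: InteractionNetwork, truth: GroundTruth,
                     scenario: SyntheticScenario) -> list[InteractionNetwork]:
    """The base interactome plus rewired copies that keep planted edges.

    Each variant drops a fraction of edges outside planted modules and adds
    the same number of random new edges, mimicking the partial overlap of
    independently curated PPI databases.
    """
    planted_genes: set[str] = set().union(*map(set, truth.modules)) if truth.modules else set()
    out = [InteractionNetwork(name="net1", graph=net.graph.copy())]
    rng = np.random.default_rng(scenario.seed + 1)
    nodes = sorted(net.graph.nodes)
    for v in range(2, scenario.n_networks + 1):
        g = net.graph.copy()
        free_edges = [e for e in g.edges
                      if not (e[0] in planted_genes and e[1] in planted_genes)]
        k = int(round(scenario.rewire_fraction * len(free_edges)))
        drop_idx = rng.choice(len(free_edges), size=k, replace=False)
        g.remove_edges_from([free_edges[i] for i in drop_idx])
        added = 0
        while added < k:
            a, b = (nodes[i] for i in rng.integers(len(nodes), size=2))
            if a != b and not g.has_edge(a, b):
                g.add_edge(a, b)
                added += 1
        out.append(InteractionNetwork(name=f"net{v}", graph=g))
    return out


def _sample_ids(scenario: SyntheticScenario) -> tuple[list[str], pd.DataFrame]:
    rows = []
    for grp, prefix, n in (("COPD", "C", scenario.n_copd),
                           ("healthy", "H", scenario.n_healthy)):
        for i in range(1, n + 1):
            subj = f"{prefix}{i:02d}"
            for tp in ("pre", "post"):
                rows.append({"sample": f"{subj}_{tp}", "group": grp,
                             "timepoint": tp, "subject": subj})
    md = pd.DataFrame(rows).set_index("sample")
    return list(md.index), md


def _affected_mask(md: pd.DataFrame, contrast: str) -> np.ndarray:
    if contrast == "COPD-DE":
        return (md["group"] == "COPD").to_numpy()
    if contrast == "COPD-TE":
        return ((md["group"] == "COPD") & (md["timepoint"] == "post")).to_numpy()
    if contrast == "Healthy-TE":
        return ((md["group"] == "healthy") & (md["timepoint"] == "post")).to_numpy()
    raise ValueError(f"unknown contrast {contrast!r}")


def simulate_expression(scenario: SyntheticScenario, truth: GroundTruth,
                        genes: list[str]) -> ExpressionMatrix:
    """Log2-scale expression: baseline + subject effect + planted effect + noise."""
    rng = np.random.default_rng(scenario.seed + 2)
    samples, md = _sample_ids(scenario)
    g, s = len(genes), len(samples)
    baseline = rng.normal(scenario.baseline_mean, scenario.baseline_sd, size=g)
    subjects = sorted(md["subject"].unique())
    subj_eff = rng.normal(0.0, scenario.subject_sd, size=(g, len(subjects)))
    subj_col = np.array([subjects.index(md.loc[smp, "subject"]) for smp in samples])
    values = baseline[:, None] + subj_eff[:, subj_col]
    gene_pos = {gn: i for i, gn in enumerate(genes)}
    for mod_genes, planted in zip(truth.modules, [
            p for p in scenario.planted]):
        mask = _affected_mask(md, planted.contrast)
        rows = [gene_pos[x] for x in mod_genes]
        values[np.ix_(rows, np.flatnonzero(mask))] += planted.effect
    values += rng.normal(0.0, scenario.noise_sd, size=(g, s))
    return ExpressionMatrix(genes=list(genes), samples=samples,
                            values=values, metadata=md)


def _calibrate_noise_sd(target_tau: float, rng: np.random.Generator,
                        n_cal: int = 3000, tol: float = 0.02) -> float:
    """Bisect the additive-noise SD so tau(signal, signal+noise) hits target.

    Calibration runs on a large standard-normal sample, so the returned SD
    realizes the target population tau regardless of study size.
    """
    if not 0 < abs(target_tau) < 1:
        raise ValueError("target tau must lie in (-1, 1) and be nonzero")
    z = rng.standard_normal(n_cal)
    eps = rng.standard_normal(n_cal)

    def realized(sd: float) -> float:
        tau, _ = kendall_tau_b(z, z + sd * eps)
        return tau

    lo, hi = 1e-6, 1.0
    while realized(hi) > abs(target_tau) and hi < 1e3:
        lo, hi = hi, hi * 2
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if realized(mid) > abs(target_tau):
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * 1e-2:
            break
    return 0.5 * (lo + hi)


def module_activity(expr: ExpressionMatrix, genes: list[str]) -> pd.Series:
    """Mean standardized expression of a gene set per sample."""
    sub = expr.frame.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).all():
        raise ValueError("module genes do not vary across samples")
    z = sub.loc[sd > 0].sub(sub.loc[sd > 0].mean(axis=1), axis=0).div(
        sd[sd > 0], axis=0)
    return z.mean(axis=0)


def simulate_phenotypes(scenario: SyntheticScenario, truth: GroundTruth,
                        expr: ExpressionMatrix) -> PhenotypeTable:
    """Per-sample phenotypes coupled to planted-module activity.

    Each coupled variable is a monotone (linear) function of the module's
    mean standardized expression plus Gaussian noise whose SD is bisected to
    realize the target population Kendall tau; uncoupled variables are pure
    noise.
    """
    rng = np.random.default_rng(scenario.seed + 3)
    cols: dict[str, np.ndarray] = {}
    for coup in scenario.couplings:
        genes = truth.modules[coup.module_index]
        signal = module_activity(expr, genes).to_numpy()
        zsig = (signal - signal.mean()) / signal.std(ddof=1)
        sd = _calibrate_noise_sd(coup.target_tau, rng)
        noise = rng.standard_normal(zsig.size)
        cols[coup.variable] = coup.direction * math.copysign(1.0, coup.target_tau) \
            * zsig + sd * noise
    for i in range(1, scenario.n_uncoupled_vars + 1):
        cols[f"noise_var{i}"] = rng.standard_normal(len(expr.samples))
    frame = pd.DataFrame(cols, index=pd.Index(expr.samples, name="sample"))
    return PhenotypeTable(frame=frame)


# ---------------------------------------------------------------------------
# presets


def preset(name: str, seed: int = 0) -> SyntheticScenario:
    """Named study scenarios.

    disease-effect: four COPD-specific modules; training-effect-healthy /
    training-effect-copd: one training-responsive module per group
    (bioenergetics-like and remodeling-like responses); global-null: no
    planted structure at all.
    """
    if name == "disease-effect":
        planted = [PlantedModule(size, 2.0, "COPD-DE")
                   for size in (6, 8, 9, 10)]
        couplings = [Coupling(0, "VO2_peak", 0.5, direction=1),
                     Coupling(1, "BODE_index", 0.5, direction=-1)]
    elif name == "training-effect-healthy":
        planted = [PlantedModule(8, 2.0, "Healthy-TE"),
                   PlantedModule(6, 1.5, "Healthy-TE")]
        couplings = [Coupling(0, "glutamine_delta", 0.5)]
    elif name == "training-effect-copd":
        planted = [PlantedModule(8, 2.0, "COPD-TE")]
        couplings = [Coupling(0, "watts_peak_delta", 0.5)]
    elif name == "global-null":
        planted, couplings = [], []
    else:
        raise ValueError(f"unknown preset {name!r}")
    return SyntheticScenario(seed=seed, planted=planted, couplings=couplings)


@dataclass
class SyntheticStudy:
    scenario: SyntheticScenario
    truth: GroundTruth
    networks: list[InteractionNetwork]
    expression: ExpressionMatrix
    phenotypes: PhenotypeTable
    genesets: GeneSetCollection


def generate_study(scenario: SyntheticScenario) -> SyntheticStudy:
    """Run the whole generator chain deterministically from the scenario seed."""
    base = generate_network(scenario.n_genes, scenario.m_edges_per_node,
                            scenario.seed)
    truth = plant_modules(base, scenario)
    nets = network_variants(base, truth, scenario)
    expr = simulate_expression(scenario, truth, sorted(base.graph.nodes))
    pheno = simulate_phenotypes(scenario, truth, expr)
    genesets = _annotation_sets(scenario, truth, sorted(base.graph.nodes))
    return SyntheticStudy(scenario=scenario, truth=truth, networks=nets,
                          expression=expr, phenotypes=pheno, genesets=genesets)


def _annotation_sets(scenario: SyntheticScenario, truth: GroundTruth,
                     genes: list[str], n_random: int = 30) -> GeneSetCollection:
    """GMT terms: one per planted module plus random decoy sets."""
    rng = np.random.default_rng(scenario.seed + 4)
    sets: dict[str, tuple[str, list[str]]] = {}
    for i, mod in enumerate(truth.modules, 1):
        sets[f"TRUE:{i:04d}"] = (f"planted module {i} process", list(mod))
    for i in range(1, n_random + 1):
        size = int(rng.integers(5, 40))
        members = [genes[j] for j in rng.choice(len(genes), size, replace=False)]
        sets[f"RAND:{i:04d}"] = (f"decoy set {i}", sorted(members))
    return GeneSetCollection(sets=sets)


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Write a study as pipeline-ready plain-text inputs plus the truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(out / "expression.tsv"),
        "metadata": str(out / "metadata.csv"),
        "genesets": str(out / "annotations.gmt"),
        "phenotypes": str(out / "phenotypes.csv"),
        "truth": str(out / "ground_truth.json"),
    }
    write_expression(study.expression, paths["expression"], paths["metadata"])
    write_gmt(study.genesets, paths["genesets"])
    write_phenotypes(study.phenotypes, paths["phenotypes"])
    net_paths = {}
    for net in study.networks:
        p = str(out / f"{net.name}.edges.tsv")
        write_network(net, p)
        net_paths[net.name] = p
    paths["networks"] = net_paths
    with open(paths["truth"], "w") as fh:
        json.dump({
            "scenario": asdict(study.scenario),
            "modules": study.truth.modules,
            "contrast_of": study.truth.contrast_of,
            "de_genes": study.truth.de_genes,
            "couplings": [asdict(c) for c in study.truth.couplings],
        }, fh, indent=2)
    return paths
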