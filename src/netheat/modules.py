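"""Network-module discovery from exchanged heat.

A directed edge j -> i is kept when node j passes at least delta heat to
node i; modules are the strongly connected components of the resulting
digraph.  The edge-retention threshold delta is chosen from heat
permutations (smallest delta keeping the largest null component at or below
l_max), module count/size significance comes from a permutation test, and a
consensus step merges significant modules discovered on several
interactomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .diffusion import DiffusionOperator

DEFAULT_MIN_SIZE = 3
# Null strong components must stay below the smallest reportable module,
# otherwise delta cannot separate planted structure from background.
DEFAULT_L_MAX = DEFAULT_MIN_SIZE
DEFAULT_DELTA_PERM = 20
DEFAULT_SIG_PERM = 100
ALPHA = 0.05


@dataclass
class Module:
    genes: list[str]
    mean_heat: float
    support: list[str] = field(default_factory=list)  # networks backing it

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class SignificanceTable:
    """Observed vs permuted module counts by minimum size k.

    For each k in [2, k_max]: X_k = observed number of components of size
    >= k; expected = mean permuted count; p_k = (1 + #{perm count >= X_k})
    / (1 + n_perm).
    """

    sizes: np.ndarray          # k values
    observed: np.ndarray       # X_k
    expected: np.ndarray
    p: np.ndarray
    n_perm: int

    def significant_sizes(self, alpha: float = ALPHA) -> list[int]:
        return [int(k) for k, pk in zip(self.sizes, self.p) if pk < alpha]


@dataclass
class ModuleSet:
    """Modules from one network (or the consensus) for one contrast."""

    modules: list[Module]
    network: str
    contrast: str
    delta: float | None = None
    significance: SignificanceTable | None = None

    def __len__(self) -> int:
        return len(self.modules)

    def gene_sets(self) -> list[set[str]]:
        return [set(m.genes) for m in self.modules]

    def significant_modules(self, alpha: float = ALPHA) -> list[Module]:
        """Modules whose size is reachable by a significant k.

        A module of size s is reported significant when the count of
        components of size >= k was significant for some k <= s.
        """
        if self.significance is None:
            return list(self.modules)
        ks = self.significance.significant_sizes(alpha)
        if not ks:
            return []
        kmin = min(ks)
        return [m for m in self.modules if m.size >= kmin]


def _scc_labels(E: np.ndarray, delta: float) -> np.ndarray:
    """Strong-component labels of the digraph with edge j->i iff E_ij >= delta."""
    mask = E >= delta
    np.fill_diagonal(mask, False)
    graph = csr_matrix(mask)
    # csgraph treats entry (i, j) as edge i->j; orientation is irrelevant for
    # strong components (reversing every edge preserves them).
    _, labels = connected_components(graph, directed=True, connection="strong")
    return labels


def _component_sizes(E: np.ndarray, delta: float) -> np.ndarray:
    labels = _scc_labels(E, delta)
    return np.bincount(labels)


def extract_modules(
    E: np.ndarray,
    nodes: list[str],
    delta: float,
    min_size: int = DEFAULT_MIN_SIZE,
    heat: np.ndarray | None = None,
    network: str = "",
    contrast: str = "",
) -> ModuleSet:
    """Strongly connected components of the delta-thresholded digraph.

    Components with at least ``min_size`` genes become modules, annotated
    with their mean input heat when ``heat`` is given.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    labels = _scc_labels(np.asarray(E, dtype=float), delta)
    modules: list[Module] = []
    for lab in range(labels.max() + 1):
        idx = np.flatnonzero(labels == lab)
        if idx.size >= min_size:
            genes = sorted(nodes[i] for i in idx)
            mh = float(np.mean(heat[idx])) if heat is not None else math.nan
            modules.append(Module(genes=genes, mean_heat=mh,
                                  support=[network] if network else []))
    modules.sort(key=lambda m: (-m.size, m.genes))
    return ModuleSet(modules=modules, network=network, contrast=contrast,
                     delta=delta)


def _min_delta_for_lmax(E: np.ndarray, l_max: int) -> float:
    """Smallest threshold keeping the largest strong component <= l_max.

    Bisection over the sorted distinct off-diagonal entries of E; when even
    the largest entry leaves an oversized component, a value just above it
    is returned.
    """
    off = E[~np.eye(E.shape[0], dtype=bool)]
    cand = np.unique(off[off > 0])
    if cand.size == 0:
        return np.finfo(float).tiny
    lo, hi = 0, cand.size - 1
    if _component_sizes(E, cand[hi]).max() > l_max:
        return float(np.nextafter(cand[hi], np.inf))
    # invariant: condition holds at hi; find the first candidate where it does
    if _component_sizes(E, cand[lo]).max() <= l_max:
        return float(cand[lo])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _component_sizes(E, cand[mid]).max() <= l_max:
            hi = mid
        else:
            lo = mid
    return float(cand[hi])


def select_delta(
    op: DiffusionOperator,
    heat: np.ndarray,
    n_perm: int = DEFAULT_DELTA_PERM,
    l_max: int = DEFAULT_L_MAX,
    seed: int = 0,
) -> float:
    """Permutation heuristic for the edge-retention threshold delta.

    For each of ``n_perm`` shuffles of the heat values over nodes, find the
    minimal delta at which the largest strong component of the permuted
    exchanged-heat digraph has size <= l_max; return the median of those
    minima.  Under null heat this delta keeps spurious components small, so
    surviving observed components reflect concentrated real heat.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    heat = np.asarray(heat, dtype=float)
    rng = np.random.default_rng(seed)
    minima = []
    for _ in range(n_perm):
        h_perm = heat[rng.permutation(heat.size)]
        E_perm = op.F * h_perm[np.newaxis, :]
        minima.append(_min_delta_for_lmax(E_perm, l_max))
    return float(np.median(minima))


def module_significance(
    observed: ModuleSet,
    op: DiffusionOperator,
    heat: np.ndarray,
    delta: float,
    n_perm: int = DEFAULT_SIG_PERM,
    seed: int = 0,
    k_max: int | None = None,
) -> SignificanceTable:
    """Permutation test on the number of components of size >= k.

    Heat values are shuffled over nodes (topology preserved), modules are
    re-extracted at the same delta, and for each k in [2, k_max] the count
    of components of size >= k is compared with the observed count X_k.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 for a p below 0.05")
    heat = np.asarray(heat, dtype=float)
    E_obs = op.exchanged_heat(heat)
    obs_sizes = _component_sizes(E_obs, delta)
    if k_max is None:
        k_max = max(2, int(obs_sizes.max()))
    ks = np.arange(2, k_max + 1)
    X = np.array([(obs_sizes >= k).sum() for k in ks])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(ks.size)
    total = np.zeros(ks.size)
    for _ in range(n_perm):
        h_perm = heat[rng.permutation(heat.size)]
        sizes = _component_sizes(op.F * h_perm[np.newaxis, :], delta)
        counts = np.array([(sizes >= k).sum() for k in ks])
        exceed += counts >= X
        total += counts
    p = (1.0 + exceed) / (1.0 + n_perm)
    table = SignificanceTable(sizes=ks, observed=X, expected=total / n_perm,
                              p=p, n_perm=n_perm)
    observed.significance = table
    return table


def consensus(
    module_sets: list[ModuleSet],
    min_size: int = DEFAULT_MIN_SIZE,
    min_support: int | None = None,
    alpha: float = ALPHA,
    heat_by_gene: dict[str, float] | None = None,
) -> ModuleSet:
    """Majority-vote consensus of significant modules across interactomes.

    Two genes are linked once per network whose significant modules place
    them together; links present in at least ``min_support`` networks
    (default: majority, ceil(n/2)) survive, and the connected components of
    the surviving graph (size >= min_size) are the consensus modules, each
    annotated with the union of supporting networks.
    """
    if not module_sets:
        raise ValueError("need at least one ModuleSet")
    if min_support is None:
        min_support = math.ceil(len(module_sets) / 2)
    counts: dict[frozenset, set[str]] = {}
    gene_nets: dict[str, set[str]] = {}
    for ms in module_sets:
        for mod in ms.significant_modules(alpha):
            for g in mod.genes:
                gene_nets.setdefault(g, set()).add(ms.network)
            for i, a in enumerate(mod.genes):
                for b in mod.genes[i + 1:]:
                    counts.setdefault(frozenset((a, b)), set()).add(ms.network)
    g = nx.Graph()
    for pair, nets in counts.items():
        if len(nets) >= min_support:
            a, b = sorted(pair)
            g.add_edge(a, b)
    modules = []
    for comp in nx.connected_components(g):
        if len(comp) >= min_size:
            genes = sorted(comp)
            support = sorted(set().union(*(gene_nets[x] for x in genes)))
            if heat_by_gene is not None:
                mh = float(np.mean([heat_by_gene.get(x, 0.0) for x in genes]))
            else:
                mh = math.nan
            modules.append(Module(genes=genes, mean_heat=mh, support=support))
    modules.sort(key=lambda m: (-m.size, m.genes))
    contrast = module_sets[0].contrast
    return ModuleSet(modules=modules, network="consensus", contrast=contrast)


def write_modules(ms: ModuleSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("module_id\tgene\tnetwork_support\tmean_heat\tcontrast\n")
        for i, mod in enumerate(ms.modules, 1):
            for gene in mod.genes:
                fh.write(f"M{i}\t{gene}\t{','.join(mod.support)}\t"
                         f"{mod.mean_heat:.4g}\t{ms.contrast}\n")
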