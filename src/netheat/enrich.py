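"""Gene-set over-representation of modules and the functional filter.

Each module is tested against every annotation term it overlaps, with a
one-sided hypergeometric tail and Benjamini-Hochberg adjustment across the
terms tested for that module.  A module counts as functionally significant
when at least one term reaches adjusted p < 0.05 with an overlap of at
least two module genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .diffexp import bh_adjust
from .io import GeneSetCollection
from .modules import ModuleSet

ADJ_P_THRESHOLD = 0.05
MIN_OVERLAP = 2


@dataclass
class EnrichmentResult:
    """Tidy per-(module, term) enrichment table with the filter verdict.

    Columns: module_id, term, term_name, overlap, module_size, term_size,
    universe_size, p, adj_p, genes (comma-joined overlap).
    """

    contrast: str
    table: pd.DataFrame

    def verdicts(self) -> dict[str, bool]:
        """Functional-significance verdict per module id."""
        out: dict[str, bool] = {}
        for mid, sub in self.table.groupby("module_id", sort=False):
            hit = (sub["adj_p"] < ADJ_P_THRESHOLD) & (sub["overlap"] >= MIN_OVERLAP)
            out[mid] = bool(hit.any())
        return out


def hypergeom_overrep(module_size: int, term_size: int, universe_size: int,
                      overlap: int) -> float:
    """Upper-tail hypergeometric p: P(X >= overlap) for the drawn module.

    X counts term genes in a size-``module_size`` draw without replacement
    from a universe containing ``term_size`` term genes.
    """
    n, K, N, x = module_size, term_size, universe_size, overlap
    if not (0 <= x <= min(n, K) <= N and n <= N):
        raise ValueError("invalid hypergeometric configuration")
    return float(hypergeom.sf(x - 1, N, K, n))


def enrich_module(
    module_genes: set[str], sets: GeneSetCollection, universe: set[str]
) -> list[dict]:
    """One hypergeometric test per term that overlaps the module.

    Terms and the module are clipped to the universe first; BH adjustment is
    applied across the tested terms.
    """
    module_u = module_genes & universe
    rows = []
    for term, (name, genes) in sets.sets.items():
        term_u = set(genes) & universe
        ov = sorted(module_u & term_u)
        if not ov or not term_u:
            continue
        p = hypergeom_overrep(len(module_u), len(term_u), len(universe), len(ov))
        rows.append({
            "term": term, "term_name": name, "overlap": len(ov),
            "module_size": len(module_u), "term_size": len(term_u),
            "universe_size": len(universe), "p": p, "genes": ",".join(ov),
        })
    if rows:
        adj = bh_adjust([r["p"] for r in rows])
        for r, a in zip(rows, adj):
            r["adj_p"] = float(a)
    rows.sort(key=lambda r: (r["p"], r["term"]))
    return rows


def enrich_modules(
    ms: ModuleSet, sets: GeneSetCollection, universe: set[str]
) -> EnrichmentResult:
    all_rows = []
    for i, mod in enumerate(ms.modules, 1):
        for row in enrich_module(set(mod.genes), sets, universe):
            all_rows.append({"module_id": f"M{i}", **row})
    cols = ["module_id", "term", "term_name", "overlap", "module_size",
            "term_size", "universe_size", "p", "adj_p", "genes"]
    table = pd.DataFrame(all_rows, columns=cols)
    return EnrichmentResult(contrast=ms.contrast, table=table)


def functional_filter(result: EnrichmentResult, ms: ModuleSet) -> ModuleSet:
    """Keep only functionally significant modules of a ModuleSet."""
    verdicts = result.verdicts()
    keep = [m for i, m in enumerate(ms.modules, 1) if verdicts.get(f"M{i}", False)]
    return ModuleSet(modules=keep, network=ms.network, contrast=ms.contrast,
                     delta=ms.delta, significance=ms.significance)


def write_enrichment(result: EnrichmentResult, path) -> None:
    table = result.table.copy()
    verdicts = result.verdicts()
    table["functional"] = table["module_id"].map(verdicts)
    with open(path, "w") as fh:
        fh.write(f"# contrast={result.contrast} adj_p<{ADJ_P_THRESHOLD} "
                 f"overlap>={MIN_OVERLAP}\n")
        table.to_csv(fh, sep="\t", index=False)
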