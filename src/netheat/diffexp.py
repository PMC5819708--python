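"""Rank-product differential expression with permutation p-values.

The rank product is the geometric mean of a gene's ranks across replicate
comparisons; consistently extreme genes get values near 1 regardless of the
scale of individual log-ratios, which makes the statistic robust on noisy
small-sample microarray data.  Significance comes from a permutation null in
which the rank column of each comparison is shuffled independently, pooled
over genes (the expected-false-positives construction normalized to a
p-value), followed by Benjamini-Hochberg FDR control.  The resulting per-gene
FDRs are the heat source for network-module discovery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import Contrast, ExpressionMatrix

DEFAULT_N_PERM = 1000
DEFAULT_MAX_PAIRS = 30


@dataclass
class DifferentialResult:
    """Per-gene rank-product statistics for one contrast.

    ``table`` columns: RP_up, RP_down, p_up, p_down, p (two-sided), FDR,
    direction ('up'/'down' by sign of effect) and effect (mean log2
    difference, class A minus class B or post minus pre).
    """

    contrast: str
    table: pd.DataFrame
    n_comparisons: int
    n_perm: int

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def fdr(self) -> pd.Series:
        return self.table["FDR"]


def pairwise_comparisons(
    expr: ExpressionMatrix,
    contrast: Contrast,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> np.ndarray:
    """Build the genes x comparisons matrix of log-ratios for a contrast.

    Unpaired contrasts enumerate all n_A x n_B sample pairs (class A minus
    class B), subsampled without replacement to ``max_pairs`` with the given
    seed when larger.  Paired contrasts yield one post-minus-pre difference
    column per subject.
    """
    frame = expr.frame
    if contrast.design == "two-class-unpaired":
        a, b = contrast.class_a, contrast.class_b
        pairs = list(itertools.product(range(len(a)), range(len(b))))
        if len(pairs) < 3:
            raise ValueError(
                f"{contrast.label}: only {len(pairs)} comparisons available (<3)"
            )
        if len(pairs) > max_pairs:
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[i] for i in sorted(idx)]
        va = frame[a].to_numpy()
        vb = frame[b].to_numpy()
        cols = [va[:, i] - vb[:, j] for i, j in pairs]
    else:  # paired: match post (class_a) to pre (class_b) by subject
        md = expr.metadata
        post_by_subj = {md.loc[s, "subject"]: s for s in contrast.class_a}
        pre_by_subj = {md.loc[s, "subject"]: s for s in contrast.class_b}
        subjects = sorted(set(post_by_subj) & set(pre_by_subj))
        if set(post_by_subj) != set(pre_by_subj):
            raise ValueError(
                f"{contrast.label}: post/pre subjects do not match bijectively"
            )
        if len(subjects) < 3:
            raise ValueError(f"{contrast.label}: fewer than 3 subject pairs")
        cols = [
            frame[post_by_subj[s]].to_numpy() - frame[pre_by_subj[s]].to_numpy()
            for s in subjects
        ]
    out = np.column_stack(cols)
    if not np.all(np.isfinite(out)):
        raise ValueError(f"{contrast.label}: non-finite log-ratios")
    return out


def _rank_columns(comparisons: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ascending (down-regulation) and descending (up-regulation) ranks.

    Rank 1 marks the most extreme gene in each direction; ties get average
    ranks.
    """
    ranks_down = np.apply_along_axis(rankdata, 0, comparisons)
    ranks_up = np.apply_along_axis(rankdata, 0, -comparisons)
    return ranks_up, ranks_down


def rank_product(comparisons: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Geometric-mean rank statistics (RP_up, RP_down) per gene."""
    comparisons = np.asarray(comparisons, dtype=float)
    if comparisons.ndim != 2 or comparisons.shape[0] < 2:
        raise ValueError("need a genes x comparisons matrix with G >= 2")
    if not np.all(np.isfinite(comparisons)):
        raise ValueError("non-finite log-ratios")
    ranks_up, ranks_down = _rank_columns(comparisons)
    rp_up = np.exp(np.mean(np.log(ranks_up), axis=1))
    rp_down = np.exp(np.mean(np.log(ranks_down), axis=1))
    return rp_up, rp_down


def _pool_pvalues(observed_rp: np.ndarray, pool: np.ndarray, pseudo: bool) -> np.ndarray:
    """p per gene from a pooled null sample of rank products."""
    pool = np.sort(pool)
    hits = np.searchsorted(pool, observed_rp, side="right")
    if pseudo:
        return (1.0 + hits) / (1.0 + pool.size)
    return hits / pool.size


def rp_pvalues(
    comparisons: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values (p_up, p_down) for the rank-product statistics.

    Each permutation shuffles the observed rank column of every comparison
    independently; the permuted rank products of all genes are pooled, and
    p_gene = (1 + #{pooled RP <= observed RP_gene}) / (1 + n_perm * G).

    With ``exhaustive=True`` all rank-column arrangements are enumerated
    (feasible only for tiny G and few comparisons) and p is the exact pooled
    fraction without the pseudo-count.
    """
    ranks_up, ranks_down = _rank_columns(np.asarray(comparisons, dtype=float))
    g, c = ranks_up.shape
    rp_up = np.exp(np.mean(np.log(ranks_up), axis=1))
    rp_down = np.exp(np.mean(np.log(ranks_down), axis=1))

    if exhaustive:
        pools = []
        for ranks in (ranks_up, ranks_down):
            cols = [list(itertools.permutations(ranks[:, j])) for j in range(c)]
            logs = [np.log(np.array(cj)) for cj in cols]  # (g!)^c arrangements
            pool = np.zeros(1)
            acc = logs[0]
            for lj in logs[1:]:
                acc = (acc[:, None, :] + lj[None, :, :]).reshape(-1, g)
            pool = np.exp(acc / c).ravel()
            pools.append(pool)
        p_up = _pool_pvalues(rp_up, pools[0], pseudo=False)
        p_down = _pool_pvalues(rp_down, pools[1], pseudo=False)
        return p_up, p_down

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    log_up = np.log(ranks_up)
    log_down = np.log(ranks_down)
    pool_up = np.empty(n_perm * g)
    pool_down = np.empty(n_perm * g)
    for t in range(n_perm):
        acc_up = np.zeros(g)
        acc_down = np.zeros(g)
        for j in range(c):
            perm = rng.permutation(g)
            acc_up += log_up[perm, j]
            acc_down += log_down[perm, j]
        pool_up[t * g:(t + 1) * g] = np.exp(acc_up / c)
        pool_down[t * g:(t + 1) * g] = np.exp(acc_down / c)
    p_up = _pool_pvalues(rp_up, pool_up, pseudo=True)
    p_down = _pool_pvalues(rp_down, pool_down, pseudo=True)
    return p_up, p_down


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def differential_expression(
    expr: ExpressionMatrix,
    contrast: Contrast,
    n_perm: int = DEFAULT_N_PERM,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> DifferentialResult:
    """Full rank-product analysis of one contrast.

    The two-sided summary p is 2*min(p_up, p_down) capped at 1; FDR is BH
    over the two-sided p-values.
    """
    comps = pairwise_comparisons(expr, contrast, max_pairs=max_pairs, seed=seed)
    rp_up, rp_down = rank_product(comps)
    p_up, p_down = rp_pvalues(comps, n_perm=n_perm, seed=seed)
    p = np.minimum(2.0 * np.minimum(p_up, p_down), 1.0)
    fdr = bh_adjust(p)
    effect = comps.mean(axis=1)
    table = pd.DataFrame(
        {
            "RP_up": rp_up,
            "RP_down": rp_down,
            "p_up": p_up,
            "p_down": p_down,
            "p": p,
            "FDR": fdr,
            "direction": np.where(effect >= 0, "up", "down"),
            "effect": effect,
        },
        index=pd.Index(expr.genes, name="gene"),
    )
    return DifferentialResult(
        contrast=contrast.label,
        table=table,
        n_comparisons=comps.shape[1],
        n_perm=n_perm,
    )


def write_differential(result: DifferentialResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# contrast={result.contrast} n_comparisons={result.n_comparisons} "
                 f"n_perm={result.n_perm} fdr=BH\n")
        result.table.to_csv(fh, sep="\t")
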