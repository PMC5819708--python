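"""Module eigengenes and Kendall association screening against phenotypes.

A module's transcriptional activity across samples is summarized by the
first three principal components ("eigengenes") of its standardized
expression submatrix.  Associations between eigengene (or single-gene)
profiles and clinical / metabolomic / redox variables are screened with
Kendall tau-b, keeping pairs with |rho| >= 0.4 and p < 0.05.  For
training-effect contrasts both sides are per-subject post-minus-pre
differentials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .diffexp import bh_adjust
from .io import ExpressionMatrix, PhenotypeTable
from .modules import ModuleSet

RHO_THRESHOLD = 0.4
P_THRESHOLD = 0.05
N_COMPONENTS = 3


@dataclass
class EigengeneSummary:
    """Sample scores on a module's first principal components.

    ``scores`` is samples x components; ``variance_fraction`` gives the
    fraction of total variance each component explains.  Component signs are
    fixed so each correlates non-negatively with the mean standardized
    module profile, making eigengene orientation reproducible.
    """

    module_id: str
    samples: list[str]
    scores: np.ndarray
    variance_fraction: np.ndarray

    @property
    def cumulative_variance(self) -> float:
        return float(self.variance_fraction.sum())


def module_eigengenes(
    submatrix: np.ndarray,
    samples: list[str],
    module_id: str = "",
    n_components: int = N_COMPONENTS,
) -> EigengeneSummary:
    """Principal decomposition of a samples x genes module submatrix.

    Genes are standardized to zero mean and unit variance across samples
    (correlation-based PCA); zero-variance genes are dropped with a warning.
    At most ``n_components`` components are returned (fewer when the matrix
    rank is lower).
    """
    X = np.asarray(submatrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need >= 3 samples and a 2-d samples x genes matrix")
    if X.shape[0] != len(samples):
        raise ValueError("sample list does not match matrix rows")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all module genes have zero variance")
    if not keep.all():
        warnings.warn(
            f"module {module_id or '?'}: dropped {int((~keep).sum())} "
            "zero-variance gene(s)", stacklevel=2,
        )
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    total = float((s ** 2).sum())
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    k = min(n_components, rank)
    scores = U[:, :k] * s[:k]
    var_frac = (s[:k] ** 2) / total
    mean_profile = Z.mean(axis=1)
    for j in range(k):
        if np.dot(scores[:, j], mean_profile) < 0:
            scores[:, j] = -scores[:, j]
    return EigengeneSummary(
        module_id=module_id, samples=list(samples),
        scores=scores, variance_fraction=var_frac,
    )


def kendall_tau_b(x, y) -> tuple[float, float]:
    """Kendall tau-b with tie correction; two-sided p.

    Pairs with a missing value on either side are dropped.  For n < 10
    without ties the p-value is exact (full pair-permutation null);
    otherwise the tie-corrected normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    method = "exact" if (n < 10 and not has_ties) else "asymptotic"
    res = scipy.stats.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


def _select(rho: float, p: float) -> bool:
    return abs(rho) >= RHO_THRESHOLD and p < P_THRESHOLD


@dataclass
class AssociationResult:
    """Tidy screen: one row per (profile, variable) with the verdict.

    Columns: level ('module-PC1'..'module-PC3' or 'gene'), profile (module
    id or gene symbol), variable, rho, p, FDR (BH across the whole screen,
    reported for transparency only), n, selected.
    """

    contrast: str
    table: pd.DataFrame

    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]]


def _screen_rows(profiles: dict[tuple[str, str], pd.Series],
                 pheno: pd.DataFrame) -> list[dict]:
    rows = []
    for (level, name), prof in profiles.items():
        for var in pheno.columns:
            joined = pd.concat([prof, pheno[var]], axis=1, join="inner").dropna()
            if len(joined) < 4:
                continue
            rho, p = kendall_tau_b(joined.iloc[:, 0], joined.iloc[:, 1])
            rows.append({
                "level": level, "profile": name, "variable": var,
                "rho": rho, "p": p, "n": len(joined),
                "selected": _select(rho, p),
            })
    return rows


def associate(
    eigengenes: list[EigengeneSummary],
    pheno: PhenotypeTable,
    contrast: str = "",
    gene_profiles: dict[str, pd.Series] | None = None,
) -> AssociationResult:
    """Screen eigengene (and optional gene) profiles against phenotypes.

    Profiles and phenotype rows are aligned on their index keys; missing
    values are handled pairwise-complete with the n used reported per row.
    The selection rule is the raw dual threshold |rho| >= 0.4 and p < 0.05;
    the FDR column is informational.
    """
    profiles: dict[tuple[str, str], pd.Series] = {}
    for eg in eigengenes:
        for j in range(eg.scores.shape[1]):
            profiles[(f"module-PC{j + 1}", eg.module_id)] = pd.Series(
                eg.scores[:, j], index=eg.samples)
    for name, series in (gene_profiles or {}).items():
        profiles[("gene", name)] = series
    rows = _screen_rows(profiles, pheno.frame)
    cols = ["level", "profile", "variable", "rho", "p", "n", "selected"]
    table = pd.DataFrame(rows, columns=cols)
    if len(table):
        table["FDR"] = bh_adjust(table["p"].to_numpy())
        table = table[["level", "profile", "variable", "rho", "p", "FDR",
                       "n", "selected"]]
    return AssociationResult(contrast=contrast, table=table)


def eigengenes_for_modules(
    expr: ExpressionMatrix,
    ms: ModuleSet,
    samples: list[str] | None = None,
    differential_by_subject: dict[str, tuple[str, str]] | None = None,
) -> list[EigengeneSummary]:
    """Eigengene summaries for every module of a ModuleSet.

    With ``differential_by_subject`` (subject -> (post sample, pre sample))
    the decomposition runs on per-subject post-minus-pre expression
    differences, which is the training-effect alignment; score rows are then
    keyed by subject id.
    """
    out = []
    for i, mod in enumerate(ms.modules, 1):
        genes = [g for g in mod.genes if g in expr.genes]
        sub = expr.subset_genes(genes)
        if differential_by_subject is not None:
            subjects = sorted(differential_by_subject)
            mat = np.column_stack([
                sub.frame[differential_by_subject[s][0]].to_numpy()
                - sub.frame[differential_by_subject[s][1]].to_numpy()
                for s in subjects
            ]).T  # subjects x genes
            keys = subjects
        else:
            keys = samples if samples is not None else expr.samples
            mat = sub.frame[keys].to_numpy().T
        out.append(module_eigengenes(mat, keys, module_id=f"M{i}"))
    return out


def plot_association(x: pd.Series, y: pd.Series, path,
                     groups: pd.Series | None = None,
                     xlabel: str = "", ylabel: str = "") -> None:
    """Scatter of one association, points colored by group (optional).

    Requires matplotlib (optional dependency); annotates Kendall tau-b and
    its p-value in the title.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    joined = pd.concat([x.rename("x"), y.rename("y")], axis=1,
                       join="inner").dropna()
    rho, p = kendall_tau_b(joined["x"], joined["y"])
    fig, ax = plt.subplots(figsize=(4, 4))
    if groups is not None:
        for name, sub in joined.groupby(groups.reindex(joined.index)):
            ax.scatter(sub["x"], sub["y"], label=str(name), alpha=0.8)
        ax.legend(frameon=False, fontsize=8)
    else:
        ax.scatter(joined["x"], joined["y"], alpha=0.8)
    ax.set_xlabel(xlabel or x.name or "profile")
    ax.set_ylabel(ylabel or y.name or "variable")
    ax.set_title(f"tau-b = {rho:.2f}, p = {p:.3g}, n = {len(joined)}",
                 fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_associations(result: AssociationResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# contrast={result.contrast} |rho|>={RHO_THRESHOLD} "
                 f"p<{P_THRESHOLD}\n")
        result.table.to_csv(fh, sep="\t", index=False)
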