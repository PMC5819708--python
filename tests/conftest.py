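import numpy as np
import pandas as pd
import pytest

from netheat.io import ExpressionMatrix
from netheat.synth import (Coupling, PlantedModule, SyntheticScenario,
                           generate_study)


def jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b) if (a or b) else 1.0


def best_jaccard(planted: set, modules) -> float:
    """Best overlap between a planted gene set and any discovered module."""
    return max((jaccard(planted, set(m.genes)) for m in modules), default=0.0)


def toy_expression(n_genes=6, n_subjects=4, seed=0) -> ExpressionMatrix:
    """Small two-group, two-timepoint expression matrix for unit tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        grp = "COPD" if i % 2 == 0 else "healthy"
        subj = f"S{i}"
        for tp in ("pre", "post"):
            rows.append({"sample": f"{subj}_{tp}", "group": grp,
                         "timepoint": tp, "subject": subj})
    md = pd.DataFrame(rows).set_index("sample")
    genes = [f"G{i}" for i in range(n_genes)]
    values = rng.normal(7, 1, size=(n_genes, len(md)))
    return ExpressionMatrix(genes=genes, samples=list(md.index),
                            values=values, metadata=md)


def small_scenario(seed=0, **kw) -> SyntheticScenario:
    """Desk-scale scenario (150 genes) for fast pipeline tests."""
    defaults = dict(
        seed=seed, n_genes=150, m_edges_per_node=2, n_copd=6, n_healthy=5,
        planted=[PlantedModule(6, 2.5, "COPD-DE")],
        couplings=[Coupling(0, "VO2_peak", 0.6)],
        n_networks=2,
    )
    defaults.update(kw)
    return SyntheticScenario(**defaults)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_scenario(seed=11))
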