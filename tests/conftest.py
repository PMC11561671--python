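import numpy as np
import pandas as pd
import pytest

from crossage import synthetic


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 organs x 1 strain x 1 sex x 2 ages x 3 replicates, 50 genes."""
    design = synthetic.CohortDesign(
        organs=["o1", "o2"], strains=["s"], sexes=["f"], ages=[3, 6],
        replicates_per_cell=3, seed=42,
    )
    structure = synthetic.PlantedStructure(
        n_genes=50, variance_fractions={"organ": 0.5, "age": 0.1, "residual": 0.4}
    )
    return synthetic.generate_cohort(design, structure)


@pytest.fixture(scope="session")
def aging_cohort():
    """Single-organ cohort with all four archetypes and antiparallel twins."""
    design = synthetic.CohortDesign(
        organs=["o"], strains=["s"], sexes=["f"], ages=[3, 6, 12, 18, 24],
        replicates_per_cell=5, seed=7,
    )
    structure = synthetic.default_planted_structure(
        n_genes=100, n_per_archetype=6, n_regulators=0,
        variance_fractions={"age": 0.5, "residual": 0.5}, noise_sd=0.3,
    )
    return synthetic.generate_cohort(design, structure)


@pytest.fixture()
def toy_edges():
    from crossage.network import EDGE_COLUMNS, EdgeTable

    rows = [
        ("A", "B", 2.0, 0.9, "confirmed"),
        ("A", "C", 2.0, 0.8, "tentative"),
        ("B", "A", 2.0, 0.7, "confirmed"),
        ("C", "D", 1.0, 0.5, "tentative"),
    ]
    return EdgeTable(pd.DataFrame(rows, columns=EDGE_COLUMNS))


def anova_fractions(expression: pd.DataFrame, samples: pd.DataFrame, factors):
    """Independent oracle: pooled one-way ANOVA sums of squares per factor."""
    col_of = {"age": "age_months"}
    X = expression.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    total = float((Xc**2).sum())
    out = {}
    explained = 0.0
    for f in factors:
        col = samples[col_of.get(f, f)].to_numpy()
        ss = 0.0
        for level in np.unique(col):
            mask = col == level
            ss += mask.sum() * float((Xc[:, mask].mean(axis=1) ** 2).sum())
        out[f] = ss / total
        explained += ss
    out["residual"] = (total - explained) / total
    return out
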