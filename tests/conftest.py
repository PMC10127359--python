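import numpy as np
import pandas as pd
import pytest

from aridtrait import models
from aridtrait.phylo import Node, PhyloTree
from aridtrait.synthetic import AssayConfig, SpeciesParams


def design_from_glmm_df(df: pd.DataFrame) -> models.DesignSpec:
    """DesignSpec for a simulate_glmm_dataset table: intercept + x columns."""
    xcols = sorted(c for c in df.columns if c.startswith("x"))
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy() for c in xcols])
    names = ["intercept"] + xcols
    terms = [models.Term("intercept", [0], "intercept")] + [
        models.Term(c, [i + 1]) for i, c in enumerate(xcols)
    ]
    species = sorted(df["species"].unique(), key=lambda s: int(s[2:]))
    codes = df["species"].map({s: i for i, s in enumerate(species)}).to_numpy()
    return models.DesignSpec(
        X=X,
        column_names=names,
        successes=df["successes"].to_numpy(),
        trials=df["trials"].to_numpy(),
        terms=terms,
        groups=codes,
        group_names=species,
    )


def brownian_covariance(tree: PhyloTree) -> tuple[np.ndarray, list[str]]:
    """Brute-force Brownian tip covariance: C_ij = shared path length.

    Built from root-to-tip paths only; independent of the pruning recursion
    it serves as an oracle for.
    """
    paths: dict[str, list[Node]] = {}

    def walk(node: Node, acc: list[Node]) -> None:
        acc = acc + [node]
        if node.is_tip:
            paths[node.label] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, [])
    labels = tree.tip_labels
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = 0.0
            for na, nb in zip(paths[a], paths[b]):
                if na is nb and na.length is not None:
                    shared += na.length
            C[i, j] = shared
    return C, labels


def gls_contrast_sum_of_squares(tree: PhyloTree, traits: dict[str, float]) -> float:
    """REML residual sum of squares from the full Brownian covariance matrix:
    x'C^-1 x - (1'C^-1 x)^2 / (1'C^-1 1). Equals the sum of squared
    standardized contrasts."""
    C, labels = brownian_covariance(tree)
    x = np.array([traits[t] for t in labels])
    Ci = np.linalg.inv(C)
    one = np.ones(len(x))
    return float(x @ Ci @ x - (one @ Ci @ x) ** 2 / (one @ Ci @ one))


@pytest.fixture
def small_assay_config() -> AssayConfig:
    """Noise-free 3-species assay with deterministic death times."""
    return AssayConfig(
        species_params={
            "fast": SpeciesParams("dweller", 20.0, 0.0, 2.0, 0.02, 0.0, 60.0),
            "slow": SpeciesParams("tunneler", 100.0, 0.0, 2.5, 0.004, 0.0, 55.0),
            "mid": SpeciesParams("roller", 30.0, 0.0, 2.2, 0.008, 0.0, 51.2),
        },
        n_individuals={"fast": 4, "slow": 4, "mid": 4},
        measurement_noise_sd_mg=0.0,
        seed=5,
    )
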