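"""Shared fixtures and independent oracle utilities.

The oracles here deliberately avoid the shortcuts used by the package:
leave-one-out predictions are obtained by explicitly refitting the
ridge-stabilized estimator n times, and the box-constrained weight problem
is solved by exhaustive grid search.
"""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def loo_refit_oracle(G: np.ndarray, y: np.ndarray, delta: float) -> np.ndarray:
    """Leave-one-out predictions by explicitly refitting the delta-ridge
    estimator n times, each time without sample i."""
    n, m = G.shape
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        Gi, yi = G[keep], y[keep]
        beta = np.linalg.solve(Gi.T @ Gi + delta * np.eye(m), Gi.T @ yi)
        out[i] = G[i] @ beta
    return out


def grid_search_weights(Ytilde: np.ndarray, y: np.ndarray, step: float = 0.01,
                        lower: float = 0.0, upper: float = 1.0):
    """Exhaustive grid search over the weight box; returns (w, criterion)."""
    K = Ytilde.shape[1]
    axis = np.arange(lower, upper + step / 2, step)
    grids = np.meshgrid(*([axis] * K), indexing="ij")
    W = np.column_stack([g.ravel() for g in grids])
    resid = y[:, None] - Ytilde @ W.T
    crits = np.einsum("ij,ij->j", resid, resid)
    best = int(np.argmin(crits))
    return W[best], float(crits[best])


@pytest.fixture
def gmt_two_pathways(tmp_path):
    """GMT with pathways {A,B,C} and {C,D}; expression genes are [A..E]."""
    path = tmp_path / "two.gmt"
    path.write_text("pw1\tdesc\tA\tB\tC\npw2\tdesc\tC\tD\n")
    return path


@pytest.fixture
def gmt_21_of_100_overlapping(tmp_path):
    """100 genes in 10 pathways of 10; the first 21 genes each also appear
    in a second pathway, so the multi-membership fraction is exactly 0.21."""
    genes = [f"g{i}" for i in range(100)]
    pathways = {f"pw{j}": genes[10 * j:10 * (j + 1)] for j in range(10)}
    for i in range(21):
        home = i // 10
        pathways[f"pw{(home + 1) % 10}"].append(genes[i])
    path = tmp_path / "overlap.gmt"
    lines = [
        "\t".join([name, "synthetic fixture", *members])
        for name, members in pathways.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path, genes
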