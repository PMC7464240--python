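import numpy as np
import pandas as pd
import pytest

from commgenes.containers import ExpressionMatrix
from commgenes.graph import Graph


@pytest.fixture
def star4() -> Graph:
    return Graph([("c", "a"), ("c", "b"), ("c", "d")])


@pytest.fixture
def path4() -> Graph:
    return Graph([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def two_triangles_bridge() -> Graph:
    """Two K3 cliques joined by a single bridge edge."""
    return Graph(
        [("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
         ("b1", "b2"), ("b2", "b3"), ("b1", "b3"),
         ("a3", "b1")]
    )


def make_paired_expression(diffs: np.ndarray, seed: int = 0) -> ExpressionMatrix:
    """Build an ExpressionMatrix whose paired LL-NL differences are ``diffs``
    (probes x pairs) exactly."""
    rng = np.random.default_rng(seed)
    n_probes, n_pairs = diffs.shape
    probes = [f"pr{i:04d}" for i in range(n_probes)]
    nl = rng.normal(8.0, 1.0, size=diffs.shape)
    samples, cols = [], []
    design_rows = []
    for j in range(n_pairs):
        pat = f"P{j + 1:03d}"
        samples += [f"{pat}_NL", f"{pat}_LL"]
        cols += [nl[:, j], nl[:, j] + diffs[:, j]]
        design_rows += [
            {"patient": pat, "condition": "NL"},
            {"patient": pat, "condition": "LL"},
        ]
    values = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(probes, name="probe"), columns=samples
    )
    design = pd.DataFrame(design_rows, index=pd.Index(samples, name="sample"))
    probe_map = pd.Series(probes, index=probes, name="gene")
    return ExpressionMatrix(values=values, design=design, probe_map=probe_map)
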