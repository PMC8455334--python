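import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netsig import simulate
from netsig.datatypes import CohortPhenotype


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic experiment shared by read-only tests."""
    graph, membership = simulate.generate_interactome(
        500, [30], p_in=0.3, p_out=0.01, seed=7
    )
    planted = sorted(g for g, m in membership.items() if m == 0)
    truth = simulate.default_truth(planted, seed=8, bio_r2=0.3)
    expr, pheno = simulate.generate_cohort(
        truth, graph, {"GHD": 24, "TS": 16}, 300, seed=9
    )
    return {
        "graph": graph,
        "membership": membership,
        "planted": planted,
        "truth": truth,
        "expr": expr,
        "pheno": pheno,
    }


@pytest.fixture()
def tiny_phenotype():
    """Hand-built 8-sample GHD phenotype table."""
    n = 8
    idx = [f"S{i}" for i in range(n)]
    table = pd.DataFrame(
        {
            "condition": "GHD",
            "sex": ["M", "F"] * 4,
            "age": np.linspace(6, 11, n),
            "bmi_sds": np.linspace(-1, 1, n),
            "weight_sds": np.zeros(n),
            "birthweight_sds": np.zeros(n),
            "dth_sds": np.zeros(n),
            "peak_gh": np.full(n, 4.0),
            "batch": ["B1", "B2"] * 4,
            **{f"tanner{y}": np.ones(n, dtype=int) for y in range(1, 6)},
            **{f"hv{y}": np.linspace(9, 5, n) for y in range(1, 6)},
        },
        index=pd.Index(idx, name="sample_id"),
    )
    return CohortPhenotype(table)


@pytest.fixture()
def two_clique_graph():
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    g = nx.relabel_nodes(g, lambda x: f"n{x}")
    g.add_edge("n0", "n5")
    return g
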