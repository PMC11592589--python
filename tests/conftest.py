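import itertools

import numpy as np
import pandas as pd
import pytest

from bnsens.network import CPT, Network, Variable, joint_probability


@pytest.fixture
def bayes_net():
    """A -> B with P(A=t)=0.3, P(B=t|A=t)=0.9, P(B=t|A=f)=0.2."""
    return Network(
        [Variable("A", ("t", "f")), Variable("B", ("t", "f"))],
        [
            CPT("A", (), [[0.3, 0.7]]),
            CPT("B", ("A",), [[0.9, 0.1], [0.2, 0.8]]),
        ],
    )


def random_binary_network(n_vars: int, rng: np.random.Generator, edge_prob: float = 0.4) -> Network:
    """Random DAG over binary variables with Dirichlet(1, 1) CPT columns."""
    names = [f"v{i}" for i in range(n_vars)]
    variables = [Variable(n, ("a", "b")) for n in names]
    cpts = []
    for i, name in enumerate(names):
        mask = rng.random(i) < edge_prob
        pars = tuple(np.array(names[:i])[mask])
        table = rng.dirichlet([1.0, 1.0], size=2 ** len(pars))
        cpts.append(CPT(name, pars, table))
    return Network(variables, cpts)


def brute_force_posterior(net: Network, evidence: dict, query: str) -> np.ndarray:
    """Renormalized sum of chain-rule joint probabilities over all completions
    of the free variables — the enumeration oracle for variable elimination."""
    states = {v.name: v.states for v in net.variables}
    free = [n for n in net.names if n not in evidence and n != query]
    out = np.zeros(len(states[query]))
    for qi, qs in enumerate(states[query]):
        for combo in itertools.product(*(states[f] for f in free)):
            full = dict(evidence)
            full[query] = qs
            full.update(dict(zip(free, combo)))
            out[qi] += joint_probability(net, full)
    z = out.sum()
    if z == 0:
        raise ValueError("evidence has probability 0")
    return out / z


@pytest.fixture
def deterministic_chain():
    """Three-variable chain with 0/1 CPTs: a single consistent trajectory."""
    return Network(
        [Variable(n, ("x", "y")) for n in ("A", "B", "C")],
        [
            CPT("A", (), [[1.0, 0.0]]),
            CPT("B", ("A",), [[0.0, 1.0], [1.0, 0.0]]),
            CPT("C", ("B",), [[1.0, 0.0], [0.0, 1.0]]),
        ],
    )


def dataset_from_arrays(columns: dict, class_variable: str):
    from bnsens.learning import RecordDataset

    return RecordDataset(
        frame=pd.DataFrame({k: list(v) for k, v in columns.items()}),
        class_variable=class_variable,
    )
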