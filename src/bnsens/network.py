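"""Discrete Bayesian networks: representation, validation, exact inference,
Markov blankets and ancestral sampling.

A network is an acyclic directed graph over categorical variables with one
conditional probability table (CPT) per variable.  Each CPT stores one
probability distribution over the variable's states ("column") per
configuration of its parents; a root variable has a single column, its prior.
The joint distribution is the chain-rule product of CPT entries.

Columns are stored as rows of a 2-D array of shape
``(n_parent_configs, n_states)``.  Parent configurations are indexed
row-major over the declared parent order and declared state orders, i.e. the
last declared parent varies fastest.  This fixed indexing is the
serialization and noise-draw order used throughout the package.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

TAGS = ("history", "physical", "lab", "disease", "untagged")

#: Mapping from variable name to observed state label.
Evidence = dict

__all__ = [
    "Variable",
    "CPT",
    "Network",
    "Evidence",
    "validate_network",
    "markov_blanket",
    "joint_probability",
    "posterior",
    "forward_sample",
    "TAGS",
]


@dataclass(frozen=True)
class Variable:
    """A categorical variable: a name, an ordered tuple of state labels and an
    optional semantic tag (history / physical / lab / disease)."""

    name: str
    states: tuple
    tag: str = "untagged"

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        if not self.name:
            raise ValueError("variable name must be non-empty")
        if self.tag not in TAGS:
            raise ValueError(f"unknown tag {self.tag!r}; expected one of {TAGS}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, label) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise KeyError(
                f"{label!r} is not a state of variable {self.name!r}"
            ) from None


@dataclass
class CPT:
    """Conditional probability table of one variable.

    ``table[r, s]`` is P(owner = state s | parents = configuration r), with
    configurations enumerated row-major over declared parent state orders.
    """

    owner: str
    parents: tuple
    table: np.ndarray

    def __post_init__(self):
        self.parents = tuple(self.parents)
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim != 2:
            raise ValueError(f"CPT of {self.owner!r}: table must be 2-D")

    @property
    def n_configs(self) -> int:
        return self.table.shape[0]


class Network:
    """A discrete Bayesian network.

    Parameters
    ----------
    variables : sequence of Variable
    cpts : sequence of CPT, one per variable (any order)

    Construction is cheap and performs only structural bookkeeping; call
    :func:`validate_network` for full invariant checking.
    """

    def __init__(self, variables, cpts):
        self.variables = tuple(variables)
        self._var = {v.name: v for v in self.variables}
        if len(self._var) != len(self.variables):
            raise ValueError("duplicate variable names")
        self.cpts = {c.owner: c for c in cpts}
        self._children = {v.name: [] for v in self.variables}
        for c in self.cpts.values():
            for p in c.parents:
                if p in self._children:
                    self._children[p].append(c.owner)
        self._topo = None

    # -- basic accessors -------------------------------------------------
    @property
    def names(self):
        return tuple(v.name for v in self.variables)

    def variable(self, name: str) -> Variable:
        try:
            return self._var[name]
        except KeyError:
            raise KeyError(f"unknown variable {name!r}") from None

    def parents(self, name: str) -> tuple:
        return self.cpts[name].parents

    def children(self, name: str) -> tuple:
        self.variable(name)
        return tuple(sorted(self._children[name]))

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        for c in self.cpts.values():
            for p in c.parents:
                g.add_edge(p, c.owner)
        return g

    def topological_order(self) -> tuple:
        if self._topo is None:
            # lexicographic tie-break keeps sampling order deterministic
            self._topo = tuple(
                nx.lexicographical_topological_sort(self.graph())
            )
        return self._topo

    # -- CPT indexing ----------------------------------------------------
    def parent_strides(self, name: str) -> np.ndarray:
        """Row-major strides: config row = sum_j state_idx[parent_j]*stride[j]."""
        pars = self.parents(name)
        sizes = [self._var[p].n_states for p in pars]
        strides = np.ones(len(pars), dtype=np.int64)
        for j in range(len(pars) - 2, -1, -1):
            strides[j] = strides[j + 1] * sizes[j + 1]
        return strides

    def config_index(self, name: str, parent_states: dict) -> int:
        """Row index of the CPT column selected by a full assignment of the
        variable's parents (``parent_states`` maps name -> state label)."""
        pars = self.parents(name)
        strides = self.parent_strides(name)
        idx = 0
        for j, p in enumerate(pars):
            idx += self._var[p].state_index(parent_states[p]) * strides[j]
        return int(idx)

    def cpt_column(self, name: str, parent_states: dict) -> np.ndarray:
        return self.cpts[name].table[self.config_index(name, parent_states)]

    def parent_configs(self, name: str):
        """Iterate parent-state-label tuples in row-major column order."""
        pars = self.parents(name)
        if not pars:
            yield ()
            return
        yield from itertools.product(*(self._var[p].states for p in pars))

    def copy(self) -> "Network":
        return Network(
            self.variables,
            [CPT(c.owner, c.parents, c.table.copy()) for c in self.cpts.values()],
        )


# ---------------------------------------------------------------------------
# validation


def validate_network(net: Network, atol: float = 1e-9) -> list:
    """Check all structural and numerical invariants; return a list of
    human-readable violation strings (empty iff the network is valid).

    Never raises: validation reports.
    """
    issues = []
    names = set()
    for v in net.variables:
        if v.name in names:
            issues.append(f"duplicate variable {v.name!r}")
        names.add(v.name)
        if v.n_states < 2:
            issues.append(f"variable {v.name!r} has fewer than 2 states")
        if len(set(v.states)) != v.n_states:
            issues.append(f"variable {v.name!r} has duplicate state labels")

    for v in net.variables:
        if v.name not in net.cpts:
            issues.append(f"variable {v.name!r} has no CPT")
    for c in net.cpts.values():
        if c.owner not in names:
            issues.append(f"CPT owner {c.owner!r} is not a declared variable")
            continue
        bad_parent = False
        for p in c.parents:
            if p not in names:
                issues.append(
                    f"CPT of {c.owner!r}: parent {p!r} is not a declared variable"
                )
                bad_parent = True
        if bad_parent:
            continue
        n_cfg = int(np.prod([net.variable(p).n_states for p in c.parents], dtype=np.int64)) if c.parents else 1
        k = net.variable(c.owner).n_states
        if c.table.shape != (n_cfg, k):
            issues.append(
                f"CPT of {c.owner!r}: table shape {c.table.shape} does not match "
                f"{n_cfg} parent configurations x {k} states"
            )
            continue
        if np.any(c.table < -atol) or np.any(c.table > 1 + atol):
            issues.append(f"CPT of {c.owner!r}: entries outside [0, 1]")
        sums = c.table.sum(axis=1)
        bad = np.nonzero(np.abs(sums - 1.0) > atol)[0]
        for r in bad[:5]:
            issues.append(
                f"CPT of {c.owner!r}: column {int(r)} sums to {sums[r]:.6g}, not 1"
            )

    g = net.graph()
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        issues.append("cycle: " + " -> ".join(e[0] for e in cyc) + f" -> {cyc[-1][1]}")
    return issues


# ---------------------------------------------------------------------------
# Markov blanket


def markov_blanket(net: Network, target: str) -> set:
    """Parents, children and children's co-parents of ``target`` (itself
    excluded).  Given its Markov blanket a variable is independent of every
    other variable in the network."""
    net.variable(target)
    mb = set(net.parents(target))
    for ch in net.children(target):
        mb.add(ch)
        mb.update(net.parents(ch))
    mb.discard(target)
    return mb


# ---------------------------------------------------------------------------
# joint probability (chain rule)


def joint_probability(net: Network, full_assignment: Evidence) -> float:
    """Chain-rule probability of one complete assignment of every variable."""
    missing = [n for n in net.names if n not in full_assignment]
    if missing:
        raise ValueError(f"assignment missing variables: {missing}")
    p = 1.0
    for v in net.variables:
        col = net.cpt_column(v.name, full_assignment)
        p *= float(col[v.state_index(full_assignment[v.name])])
    return p


# ---------------------------------------------------------------------------
# exact inference: variable elimination


class _Factor:
    __slots__ = ("vars", "values")

    def __init__(self, vars_, values):
        self.vars = tuple(vars_)
        self.values = np.asarray(values, dtype=float)

    def reduce(self, name, idx):
        ax = self.vars.index(name)
        vals = np.take(self.values, idx, axis=ax)
        return _Factor(self.vars[:ax] + self.vars[ax + 1:], vals)

    def multiply(self, other):
        all_vars = list(self.vars)
        for v in other.vars:
            if v not in all_vars:
                all_vars.append(v)
        a = _expand(self, all_vars)
        b = _expand(other, all_vars)
        return _Factor(all_vars, a * b)

    def marginalize(self, name):
        ax = self.vars.index(name)
        return _Factor(
            self.vars[:ax] + self.vars[ax + 1:], self.values.sum(axis=ax)
        )


def _expand(f: _Factor, all_vars):
    """Broadcast a factor's array onto the axis order ``all_vars``."""
    shape = [1] * len(all_vars)
    src_axes = [all_vars.index(v) for v in f.vars]
    vals = np.transpose(f.values, np.argsort(src_axes)) if f.vars else f.values
    for ax, full_ax in zip(range(vals.ndim), sorted(src_axes)):
        shape[full_ax] = vals.shape[ax]
    return vals.reshape(shape)


def _cpt_factor(net: Network, name: str) -> _Factor:
    v = net.variable(name)
    pars = net.parents(name)
    shape = [net.variable(p).n_states for p in pars] + [v.n_states]
    vals = net.cpts[name].table.reshape(shape)
    return _Factor(tuple(pars) + (name,), vals)


def posterior(net: Network, evidence: Evidence, query: str) -> np.ndarray:
    """Exact posterior distribution over the states of ``query`` given
    ``evidence``, by variable elimination.

    Elimination order: min-degree on the moralized evidence-reduced graph,
    ties broken by variable name.  Raises ``ValueError`` if the evidence has
    probability zero under the model (a silent uniform fallback would corrupt
    downstream accuracy statistics).
    """
    qv = net.variable(query)
    if query in evidence:
        raise ValueError(f"query {query!r} is observed")
    for name, state in evidence.items():
        net.variable(name).state_index(state)  # validates both

    factors = []
    for v in net.variables:
        f = _cpt_factor(net, v.name)
        for name in f.vars:
            if name in evidence:
                f = f.reduce(name, net.variable(name).state_index(evidence[name]))
        factors.append(f)

    hidden = [
        n for n in net.names if n != query and n not in evidence
    ]
    # min-degree elimination on the induced factor graph
    neighbors = {h: set() for h in hidden}
    for f in factors:
        hv = [v for v in f.vars if v in neighbors]
        for a in hv:
            neighbors[a].update(x for x in hv if x != a)
    order = []
    remaining = set(hidden)
    while remaining:
        pick = min(remaining, key=lambda h: (len(neighbors[h] & remaining), h))
        order.append(pick)
        remaining.discard(pick)
        nb = neighbors[pick] & remaining
        for a in nb:
            neighbors[a].update(x for x in nb if x != a)

    for h in order:
        involved = [f for f in factors if h in f.vars]
        rest = [f for f in factors if h not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.marginalize(h)]

    result = _Factor((), np.array(1.0))
    for f in factors:
        result = result.multiply(f)
    vals = result.values
    if result.vars == (query,):
        out = vals
    elif result.vars == ():
        raise RuntimeError("query variable eliminated")  # pragma: no cover
    else:  # pragma: no cover - all other vars are reduced or summed out
        ax = result.vars.index(query)
        out = vals.sum(axis=tuple(i for i in range(vals.ndim) if i != ax))
    z = out.sum()
    if z <= 0.0:
        raise ValueError("evidence has probability 0 under the model")
    return out / z


# ---------------------------------------------------------------------------
# ancestral sampling


def forward_sample(net: Network, n: int, rng: np.random.Generator):
    """Draw ``n`` complete records by ancestral sampling in topological
    order.  Returns a pandas DataFrame of state labels with one column per
    variable (declared variable order)."""
    import pandas as pd

    if n < 1:
        raise ValueError("n must be >= 1")
    order = net.topological_order()
    codes = {}
    for name in order:
        v = net.variable(name)
        cpt = net.cpts[name]
        pars = cpt.parents
        if pars:
            strides = net.parent_strides(name)
            rows = np.zeros(n, dtype=np.int64)
            for j, p in enumerate(pars):
                rows += codes[p] * strides[j]
        else:
            rows = np.zeros(n, dtype=np.int64)
        u = rng.random(n)
        cum = np.cumsum(cpt.table, axis=1)
        cum[:, -1] = 1.0  # guard against round-off
        codes[name] = (u[:, None] > cum[rows]).sum(axis=1)
    data = {
        v.name: np.asarray(v.states, dtype=object)[codes[v.name]]
        for v in net.variables
    }
    return pd.DataFrame(data, columns=list(net.names))
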