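"""Synthetic gold-standard diagnostic networks and sampled patient records.

Real diagnostic BN models with matched patient datasets are essentially
unavailable (clinical data are proprietary; public repositories hold models
or datasets, not both), so sensitivity experiments here run on generated
gold standards: a single multi-state disease (class) node plus finding nodes
tagged as history, physical-examination or laboratory variables.  The class
node is a root and an ancestor of every finding; most findings are its
direct children (a naive-Bayes-like core, optionally augmented with
finding-finding edges, mirroring the TAN/ANB shapes common in learned
diagnostic models), and a configurable fraction attach only transitively,
which shrinks the class node's Markov blanket and creates the structural
regimes that blanket-restricted noise experiments contrast.

CPT columns are drawn from a symmetric Dirichlet: low concentration gives
extreme, highly diagnostic columns (an easy dataset), high concentration
approaches uniform columns (chance-level accuracy).  Laboratory nodes can be
sharpened further — lab tests are typically the most diagnostic findings —
by raising their columns to a power and renormalizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .learning import MISSING, RecordDataset
from .network import CPT, Network, Variable, forward_sample, posterior

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "BayesAccuracy",
    "generate_network",
    "bayes_optimal_accuracy",
    "make_benchmark",
]

_ENUM_CELL_LIMIT = 4_000_000  # largest joint table enumerated exactly


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the gold-standard generator.

    Parameters
    ----------
    n_disease_states : number of diagnoses competing in the class node.
    n_history, n_physical, n_lab : finding nodes per semantic class.
    direct_child_fraction : fraction of findings attached directly to the
        class node; the rest hang off earlier findings, keeping the class an
        ancestor of everything while shrinking its Markov blanket.
    extra_edge_density : probability of an additional finding->finding edge
        per ordered pair (capped at 3 parents per node to bound CPT width).
    concentration : symmetric Dirichlet parameter for CPT columns; lower
        means more extreme columns and a more diagnostic model.
    lab_boost : exponent applied to laboratory CPT columns (then
        renormalized); > 1 sharpens them.
    finding_state_range : inclusive (lo, hi) range of per-finding state
        counts, drawn uniformly.
    missing_rate : default MCAR blanking rate used by :func:`make_benchmark`.
    seed : generator seed; identical config implies identical network.
    """

    n_disease_states: int = 4
    n_history: int = 4
    n_physical: int = 4
    n_lab: int = 4
    direct_child_fraction: float = 1.0
    extra_edge_density: float = 0.1
    concentration: float = 0.5
    lab_boost: float = 2.0
    finding_state_range: tuple = (2, 3)
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_disease_states < 2:
            raise ValueError("class node needs at least 2 states")
        if self.n_history + self.n_physical + self.n_lab < 1:
            raise ValueError("at least one finding node is required")
        if self.n_history + self.n_physical + self.n_lab + 1 > 70:
            raise ValueError("total nodes must not exceed 70")
        if not 0 <= self.extra_edge_density < 1:
            raise ValueError("extra_edge_density must be in [0, 1)")
        if not 0 < self.direct_child_fraction <= 1:
            raise ValueError("direct_child_fraction must be in (0, 1]")
        if self.concentration <= 0 or self.lab_boost <= 0:
            raise ValueError("concentration and lab_boost must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """A generating network, its semantic tag map and the class variable."""

    network: Network
    tags: dict
    class_variable: str
    config: GeneratorConfig = None


@dataclass(frozen=True)
class BayesAccuracy:
    """Ceiling accuracy of the argmax classifier under the generating
    distribution, with its estimation method and standard error (0 when
    exact)."""

    value: float
    se: float
    method: str


def _dirichlet_table(rng, n_cfg: int, k: int, concentration: float) -> np.ndarray:
    return rng.dirichlet(np.full(k, concentration), size=n_cfg)


def generate_network(config: GeneratorConfig) -> GroundTruth:
    """Build a gold-standard diagnostic network from ``config``.

    Deterministic: the same config (including seed) always yields the same
    network, tag map and CPTs.
    """
    rng = np.random.default_rng(config.seed)
    class_name = "disease"
    lo, hi = config.finding_state_range

    specs = (
        [("h", "history")] * config.n_history
        + [("p", "physical")] * config.n_physical
        + [("l", "lab")] * config.n_lab
    )
    names, tags = [], {class_name: "disease"}
    for i, (prefix, tag) in enumerate(specs):
        name = f"{prefix}{i}"
        names.append(name)
        tags[name] = tag

    n_states = {class_name: config.n_disease_states}
    for name in names:
        n_states[name] = int(rng.integers(lo, hi + 1))

    # -- structure: class -> findings core, optional finding chains ------
    parents = {class_name: []}
    for i, name in enumerate(names):
        direct = i == 0 or rng.random() < config.direct_child_fraction
        if direct:
            parents[name] = [class_name]
        else:
            j = int(rng.integers(0, i))
            parents[name] = [names[j]]  # class stays an ancestor transitively
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if len(parents[names[j]]) >= 3:
                break
            if rng.random() < config.extra_edge_density:
                if names[i] not in parents[names[j]]:
                    parents[names[j]].append(names[i])

    variables = [
        Variable(
            class_name,
            tuple(f"D{s}" for s in range(config.n_disease_states)),
            tag="disease",
        )
    ]
    for name in names:
        variables.append(
            Variable(
                name,
                tuple(f"s{s}" for s in range(n_states[name])),
                tag=tags[name],
            )
        )

    cpts = []
    for v in variables:
        pars = tuple(parents[v.name])
        n_cfg = int(np.prod([n_states[p] for p in pars])) if pars else 1
        table = _dirichlet_table(rng, n_cfg, v.n_states, config.concentration)
        if tags[v.name] == "lab" and config.lab_boost != 1.0:
            table = table ** config.lab_boost
            table /= table.sum(axis=1, keepdims=True)
        cpts.append(CPT(v.name, pars, table))

    return GroundTruth(
        network=Network(variables, cpts),
        tags=tags,
        class_variable=class_name,
        config=config,
    )


def bayes_optimal_accuracy(
    truth: GroundTruth,
    method: str = "auto",
    n_samples: int = 20000,
    seed: int = 0,
) -> BayesAccuracy:
    """Probability that the argmax class posterior of the generating network
    recovers the sampled class — the accuracy ceiling of any model learned
    from its data.

    Exact by joint enumeration when the joint table fits in memory,
    otherwise Monte Carlo with a reported binomial standard error.
    """
    net = truth.network
    sizes = [v.n_states for v in net.variables]
    cells = int(np.prod(sizes, dtype=np.int64))
    if method == "auto":
        method = "exact" if cells <= _ENUM_CELL_LIMIT else "montecarlo"

    if method == "exact":
        value = _exact_bayes_accuracy(truth)
        return BayesAccuracy(value=value, se=0.0, method="exact")
    if method != "montecarlo":
        raise ValueError(f"unknown method {method!r}")

    from .evaluation import class_posterior_batch

    rng = np.random.default_rng(seed)
    frame = forward_sample(net, n_samples, rng)
    codes = {
        v.name: np.asarray(
            [v.states.index(s) for s in frame[v.name]], dtype=np.int64
        )
        for v in net.variables
    }
    post, ok = class_posterior_batch(net, codes, truth.class_variable)
    pred = np.argmax(post, axis=1)
    correct = (pred == codes[truth.class_variable]) & ok
    acc = float(correct.mean())
    se = float(np.sqrt(acc * (1 - acc) / n_samples))
    return BayesAccuracy(value=acc, se=se, method="montecarlo")


def _exact_bayes_accuracy(truth: GroundTruth) -> float:
    """Sum over finding configurations of max_c P(class=c, findings)."""
    net = truth.network
    order = list(net.names)
    axis = {name: i for i, name in enumerate(order)}
    shape = [net.variable(n).n_states for n in order]
    log_joint = np.zeros(shape)
    for v in net.variables:
        pars = net.parents(v.name)
        f_shape = [net.variable(p).n_states for p in pars] + [v.n_states]
        vals = net.cpts[v.name].table.reshape(f_shape)
        expand = [1] * len(order)
        src = [axis[p] for p in pars] + [axis[v.name]]
        vals = np.transpose(vals, np.argsort(src))
        for ax_len, full_ax in zip(vals.shape, sorted(src)):
            expand[full_ax] = ax_len
        with np.errstate(divide="ignore"):
            log_joint = log_joint + np.log(vals.reshape(expand))
    joint = np.exp(log_joint)
    cls_ax = axis[truth.class_variable]
    return float(joint.max(axis=cls_ax).sum())


def make_benchmark(truth: GroundTruth, n: int, missing_rate: float = None, seed: int = 0):
    """Forward-sample ``n`` patient records from the gold standard, blank
    non-class cells completely at random at ``missing_rate``, and return the
    dataset together with the normal-state map (state 0 of every finding is
    designated the normal/absent state)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if missing_rate is None:
        missing_rate = truth.config.missing_rate if truth.config else 0.0
    rng = np.random.default_rng(seed)
    frame = forward_sample(truth.network, n, rng)
    if missing_rate > 0:
        for name in frame.columns:
            if name == truth.class_variable:
                continue
            mask = rng.random(n) < missing_rate
            frame.loc[mask, name] = MISSING
    normals = {
        v.name: v.states[0]
        for v in truth.network.variables
        if v.name != truth.class_variable
    }
    data = RecordDataset(frame=frame, class_variable=truth.class_variable)
    return data, normals
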