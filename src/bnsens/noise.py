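"""Log-odds noise operators for Bayesian network parameters.

Three perturbations of a discrete probability distribution, all driven by
Gaussian draws in base-10 log-odds space:

* **symmetric** — every entry p is independently mapped to
  ``Lo^-1[Lo(p) + Normal(0, sigma)]`` where ``Lo(p) = log10(p / (1 - p))``,
  and the whole vector is then renormalized to sum to 1 (needed for
  distributions with more than two states).
* **overconfidence** — the smallest entry pS is shrunk to
  ``Lo^-1[Lo(pS) - |Normal(0, sigma)|]`` and the removed mass is added to the
  largest entry, sharpening the distribution (entropy can only decrease).
  Emulates an expert whose probabilities drift toward 0 and 1.
* **underconfidence** — the largest entry pL is shrunk the same way and the
  removed mass is added to the smallest entry, flattening the distribution.

The biased operators transfer mass exactly, so the sum is preserved without
renormalization.  Entries exactly 0 or 1 are fixed points of the log-odds
transform and pass through every operator unchanged; deterministic CPT
columns are therefore immune to this noise model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import CPT, Network

NOISE_TYPES = ("symmetric", "overconfidence", "underconfidence")

__all__ = [
    "NOISE_TYPES",
    "NoiseSpec",
    "NoiseSource",
    "FixedNoiseSource",
    "log_odds",
    "inverse_log_odds",
    "perturb_symmetric",
    "perturb_overconfident",
    "perturb_underconfident",
    "perturb_table",
    "perturb_network",
]


def log_odds(p):
    """Base-10 log-odds ``log10(p / (1 - p))``.

    Accepts scalars or arrays in [0, 1]; 0 maps to -inf and 1 to +inf.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        out = np.log10(p) - np.log10(1.0 - p)
    return out if out.ndim else float(out)


def inverse_log_odds(x):
    """Inverse of :func:`log_odds`: ``10**x / (1 + 10**x)``.

    ±inf map to 1 and 0; the round trip is exact to ~1e-12 on (0, 1).
    """
    x = np.asarray(x, dtype=float)
    # logistic in base 10, computed stably on both tails
    with np.errstate(over="ignore"):
        pos = 1.0 / (1.0 + np.power(10.0, -x))
    out = np.where(np.isneginf(x), 0.0, pos)
    return out if out.ndim else float(out)


class NoiseSource:
    """Seedable stream of independent Normal(0, sigma) draws.

    ``sigma = 0`` yields exact zeros, making every operator the identity.
    """

    def __init__(self, sigma: float, rng=None):
        if sigma < 0:
            raise ValueError("sigma must be non-negative")
        self.sigma = float(sigma)
        self.rng = np.random.default_rng(rng)

    def draws(self, n: int) -> np.ndarray:
        if self.sigma == 0.0:
            return np.zeros(n)
        return self.rng.normal(0.0, self.sigma, size=n)


class FixedNoiseSource(NoiseSource):
    """Noise source replaying a fixed sequence of draws (for worked examples
    and tests with hand-computed arithmetic)."""

    def __init__(self, sequence):
        self.sigma = None
        self._seq = list(sequence)
        self._pos = 0

    def draws(self, n: int) -> np.ndarray:
        if self._pos + n > len(self._seq):
            raise RuntimeError("fixed noise sequence exhausted")
        out = np.asarray(self._seq[self._pos:self._pos + n], dtype=float)
        self._pos += n
        return out


@dataclass(frozen=True)
class NoiseSpec:
    """What to perturb: noise type, magnitude and target node subset.

    ``targets=None`` means every variable in the network.
    """

    noise_type: str
    sigma: float
    targets: frozenset = None

    def __post_init__(self):
        if self.noise_type not in NOISE_TYPES:
            raise ValueError(
                f"unknown noise type {self.noise_type!r}; expected {NOISE_TYPES}"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.targets is not None:
            object.__setattr__(self, "targets", frozenset(self.targets))


# ---------------------------------------------------------------------------
# single-distribution operators


def perturb_symmetric(dist, noise: NoiseSource) -> np.ndarray:
    """Independent log-odds noise on every entry, then renormalization."""
    dist = np.asarray(dist, dtype=float)
    draws = noise.draws(dist.size).reshape(dist.shape)
    if not np.any(draws):  # exact identity, renormalization included
        return dist.copy()
    with np.errstate(invalid="ignore"):
        moved = inverse_log_odds(log_odds(dist) + draws)
    # 0 and 1 are ±inf fixed points; a zero draw is an exact identity
    moved = np.where(dist == 0.0, 0.0, np.where(dist == 1.0, 1.0, moved))
    moved = np.where(draws == 0.0, dist, moved)
    z = moved.sum()
    if z <= 0.0:
        raise ValueError("perturbed distribution sums to 0")
    return moved / z


def _min_max_indices(dist: np.ndarray):
    """First index attaining the minimum; first index attaining the maximum
    among the remaining indices.  Always two distinct states for len >= 2."""
    i_s = int(np.argmin(dist))
    masked = dist.copy()
    masked[i_s] = -np.inf
    i_l = int(np.argmax(masked))
    return i_s, i_l


def perturb_overconfident(dist, noise: NoiseSource) -> np.ndarray:
    """Shrink the smallest entry in log-odds space by |Normal(0, sigma)| and
    give the removed mass to the largest entry.  Sum preserved exactly."""
    dist = np.asarray(dist, dtype=float)
    if dist.size < 2:
        raise ValueError("distribution needs at least 2 entries")
    i_s, i_l = _min_max_indices(dist)
    d = abs(float(noise.draws(1)[0]))
    if d == 0.0:
        return dist.copy()
    p_s = dist[i_s]
    p_s_new = inverse_log_odds(log_odds(p_s) - d)
    out = dist.copy()
    out[i_s] = p_s_new
    out[i_l] = dist[i_l] + (p_s - p_s_new)
    return out


def perturb_underconfident(dist, noise: NoiseSource) -> np.ndarray:
    """Shrink the largest entry in log-odds space by |Normal(0, sigma)| and
    give the removed mass to the smallest entry.  Sum preserved exactly."""
    dist = np.asarray(dist, dtype=float)
    if dist.size < 2:
        raise ValueError("distribution needs at least 2 entries")
    i_s, i_l = _min_max_indices(dist)
    d = abs(float(noise.draws(1)[0]))
    if d == 0.0:
        return dist.copy()
    p_l = dist[i_l]
    p_l_new = inverse_log_odds(log_odds(p_l) - d)
    out = dist.copy()
    out[i_l] = p_l_new
    out[i_s] = dist[i_s] + (p_l - p_l_new)
    return out


_OPERATORS = {
    "symmetric": perturb_symmetric,
    "overconfidence": perturb_overconfident,
    "underconfidence": perturb_underconfident,
}


# ---------------------------------------------------------------------------
# vectorized whole-table operators


def perturb_table(table: np.ndarray, noise_type: str, noise: NoiseSource) -> np.ndarray:
    """Perturb every row (= CPT column, one distribution per parent
    configuration) of a 2-D table.  Draw order is row-major, matching the
    equivalent sequence of single-distribution calls exactly."""
    table = np.asarray(table, dtype=float)
    n_rows, k = table.shape
    if noise_type == "symmetric":
        draws = noise.draws(n_rows * k).reshape(n_rows, k)
        if not np.any(draws):
            return table.copy()
        with np.errstate(invalid="ignore"):
            moved = inverse_log_odds(log_odds(table) + draws)
        moved = np.where(table == 0.0, 0.0, np.where(table == 1.0, 1.0, moved))
        moved = np.where(draws == 0.0, table, moved)
        z = moved.sum(axis=1, keepdims=True)
        if np.any(z <= 0.0):
            raise ValueError("perturbed column sums to 0")
        return moved / z

    if noise_type not in _OPERATORS:
        raise ValueError(f"unknown noise type {noise_type!r}")
    d = np.abs(noise.draws(n_rows))
    rows = np.arange(n_rows)
    i_s = np.argmin(table, axis=1)
    masked = table.copy()
    masked[rows, i_s] = -np.inf
    i_l = np.argmax(masked, axis=1)
    out = table.copy()
    if noise_type == "overconfidence":
        p = table[rows, i_s]
        p_new = np.where(d == 0.0, p, inverse_log_odds(log_odds(p) - d))
        out[rows, i_s] = p_new
        out[rows, i_l] = table[rows, i_l] + (p - p_new)
    else:
        p = table[rows, i_l]
        p_new = np.where(d == 0.0, p, inverse_log_odds(log_odds(p) - d))
        out[rows, i_l] = p_new
        out[rows, i_s] = table[rows, i_s] + (p - p_new)
    return out


def perturb_network(net: Network, spec: NoiseSpec, noise: NoiseSource) -> Network:
    """Return a new network with every CPT column of every target variable
    perturbed with fresh draws; non-target CPTs are shared-value copies.

    Draw order is fixed: target variables in declared variable order, columns
    in row-major configuration order, entries in state order.
    """
    targets = set(net.names) if spec.targets is None else set(spec.targets)
    unknown = targets - set(net.names)
    if unknown:
        raise KeyError(f"unknown target variables: {sorted(unknown)}")
    new_cpts = []
    for v in net.variables:
        c = net.cpts[v.name]
        if v.name in targets:
            new_cpts.append(
                CPT(c.owner, c.parents, perturb_table(c.table, spec.noise_type, noise))
            )
        else:
            new_cpts.append(CPT(c.owner, c.parents, c.table.copy()))
    return Network(net.variables, new_cpts)
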