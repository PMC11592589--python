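"""Patient-record datasets and CPT parameter estimation.

Records are categorical state labels, one row per case, with an optional
missing-value marker.  Missing findings are imputed with the state that
denotes absence of the symptom or a normal value — the convention commonly
used when preparing clinical datasets for Bayesian network learning, since
an unrecorded test usually means it was not indicated.  Parameters are
estimated by relative frequency with an optional Dirichlet pseudocount
(Laplace smoothing by default, so that leave-one-out evidence never has
probability zero under the learned model).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import CPT, Network

MISSING = ""

__all__ = ["RecordDataset", "MISSING", "impute_missing", "estimate_cpts", "loo_split"]


@dataclass
class RecordDataset:
    """A table of categorical observations plus the name of the class
    (diagnosis) variable.

    ``frame`` holds state labels as strings; cells equal to ``missing_marker``
    are treated as unobserved.  The class column must be fully observed.
    """

    frame: pd.DataFrame
    class_variable: str
    missing_marker: str = MISSING

    def __post_init__(self):
        if self.class_variable not in self.frame.columns:
            raise ValueError(
                f"class variable {self.class_variable!r} not in dataset columns"
            )
        if (self.frame[self.class_variable] == self.missing_marker).any():
            raise ValueError("class column contains missing values")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def variables(self) -> tuple:
        return tuple(self.frame.columns)

    def is_missing(self) -> pd.DataFrame:
        return self.frame == self.missing_marker

    def record(self, i: int) -> dict:
        return self.frame.iloc[i].to_dict()


def impute_missing(data: RecordDataset, normals: dict) -> RecordDataset:
    """Replace every missing cell with the column's designated normal/absent
    state.  ``normals`` maps variable name -> state label; it must cover every
    column that actually contains missing values."""
    mask = data.is_missing()
    cols_with_missing = [c for c in data.variables if mask[c].any()]
    uncovered = [c for c in cols_with_missing if c not in normals]
    if uncovered:
        raise KeyError(
            f"missing values in columns without a normal state: {uncovered}"
        )
    frame = data.frame.copy()
    for c in cols_with_missing:
        frame.loc[mask[c], c] = normals[c]
    return replace(data, frame=frame)


def _encode(data: RecordDataset, structure: Network) -> dict:
    """Integer state codes per variable, validating labels against the
    structure's declared state sets."""
    codes = {}
    for name in data.variables:
        v = structure.variable(name)
        cat = pd.Categorical(data.frame[name], categories=list(v.states))
        if (cat.codes < 0).any():
            bad = sorted(set(data.frame[name][cat.codes < 0]))
            raise ValueError(f"illegal states {bad} in column {name!r}")
        codes[name] = cat.codes.astype(np.int64)
    return codes


def estimate_cpts(structure: Network, data: RecordDataset, pseudocount: float = 1.0) -> Network:
    """Estimate every CPT from complete records given a fixed structure.

    Each column entry is ``(count + pseudocount) / (config count +
    pseudocount * n_states)``.  With ``pseudocount = 0`` this is maximum
    likelihood; columns whose parent configuration never occurs then fall
    back to uniform.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    missing_cols = [n for n in structure.names if n not in data.variables]
    if missing_cols:
        raise ValueError(f"dataset lacks variables {missing_cols}")
    if data.is_missing().any().any():
        raise ValueError("dataset contains missing values; impute first")

    codes = _encode(data, structure)
    cpts = []
    for v in structure.variables:
        c = structure.cpts[v.name]
        counts, cfg_counts = _loo_counts(structure, v.name, codes)
        table = _counts_to_table(counts, cfg_counts, pseudocount)
        cpts.append(CPT(c.owner, c.parents, table))
    return Network(structure.variables, cpts)


def _loo_counts(structure: Network, name: str, codes: dict):
    """Joint (config, state) counts and per-config totals for one variable."""
    v = structure.variable(name)
    pars = structure.parents(name)
    n = len(next(iter(codes.values()))) if codes else 0
    if pars:
        strides = structure.parent_strides(name)
        cfg = np.zeros(n, dtype=np.int64)
        for j, p in enumerate(pars):
            cfg += codes[p] * strides[j]
        n_cfg = int(np.prod([structure.variable(p).n_states for p in pars]))
    else:
        cfg = np.zeros(n, dtype=np.int64)
        n_cfg = 1
    counts = np.zeros((n_cfg, v.n_states))
    np.add.at(counts, (cfg, codes[name]), 1.0)
    return counts, counts.sum(axis=1)


def _counts_to_table(counts: np.ndarray, cfg_counts: np.ndarray, pseudocount: float) -> np.ndarray:
    k = counts.shape[1]
    num = counts + pseudocount
    den = cfg_counts + pseudocount * k
    table = np.empty_like(counts)
    empty = den <= 0
    table[~empty] = num[~empty] / den[~empty, None]
    table[empty] = 1.0 / k  # unseen configuration, no prior: uniform
    return table


def loo_split(data: RecordDataset, i: int):
    """Leave-one-out split: all records except ``i``, and record ``i``."""
    if not 0 <= i < data.n:
        raise IndexError(f"record index {i} out of range for n={data.n}")
    train = replace(
        data, frame=data.frame.drop(data.frame.index[i]).reset_index(drop=True)
    )
    return train, data.record(i)
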