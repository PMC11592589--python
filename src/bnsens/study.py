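"""High-level model object for noise-sensitivity studies.

:class:`NoiseSensitivityStudy` bundles a network structure, a record dataset
and an :class:`~bnsens.evaluation.EvaluationConfig`; its :meth:`fit` runs one
of the experimental protocols and returns the
:class:`~bnsens.evaluation.SweepResult` results object (tables, per-case
detail, ``summary()`` and ``plot()``).

Example
-------
>>> from bnsens import synthetic, study, evaluation
>>> truth = synthetic.generate_network(synthetic.GeneratorConfig(seed=7))
>>> data, normals = synthetic.make_benchmark(truth, n=200, seed=7)
>>> st = study.NoiseSensitivityStudy(
...     truth.network, data, tags=truth.tags, normals=normals,
...     config=evaluation.EvaluationConfig(base_seed=7),
... )
>>> res = st.fit()            # Experiment-1 style sigma sweep
>>> print(res.summary())      # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .evaluation import (
    EvaluationConfig,
    loo_accuracy,
    markov_blanket_experiment,
    pradhan_experiment,
    semantic_experiment,
    sigma_sweep,
    SweepResult,
)
from .learning import RecordDataset, impute_missing
from .network import Network
from .noise import NoiseSpec

PROTOCOLS = ("sweep", "markov_blanket", "semantic", "pradhan")

__all__ = ["NoiseSensitivityStudy", "PROTOCOLS"]


class NoiseSensitivityStudy:
    """Noise-sensitivity study of one diagnostic BN on one dataset.

    Parameters
    ----------
    structure : Network
        The gold-standard structure; its parameters are re-learned inside the
        leave-one-out protocol, so only the graph and state spaces are used.
    data : RecordDataset
        Categorical patient records including the class column.  If the
        dataset has missing cells a ``normals`` map must be supplied and the
        data are imputed on construction.
    config : EvaluationConfig, optional
    tags : dict, optional
        Variable -> semantic class, required by the ``semantic`` protocol.
    normals : dict, optional
        Variable -> normal/absent state used for imputation.
    """

    def __init__(self, structure: Network, data: RecordDataset, config: EvaluationConfig = None,
                 tags: dict = None, normals: dict = None):
        self.structure = structure
        if data.is_missing().any().any():
            if normals is None:
                raise ValueError("dataset has missing values; provide normals")
            data = impute_missing(data, normals)
        self.data = data
        self.config = config or EvaluationConfig()
        self.tags = tags

    @classmethod
    def from_dataframe(cls, frame, class_variable: str, structure: Network,
                       config: EvaluationConfig = None, tags: dict = None,
                       normals: dict = None, missing_marker: str = ""):
        data = RecordDataset(
            frame=frame, class_variable=class_variable, missing_marker=missing_marker
        )
        return cls(structure, data, config=config, tags=tags, normals=normals)

    def fit(self, protocol: str = "sweep", **config_overrides) -> SweepResult:
        """Run a protocol and return its results object.

        ``protocol`` is one of ``sweep`` (sigma grid x noise types),
        ``markov_blanket`` (blanket / complement / all-node conditions),
        ``semantic`` (per node-class conditions) or ``pradhan``
        (average-posterior trajectory under symmetric noise).
        """
        config = replace(self.config, **config_overrides) if config_overrides else self.config
        if protocol == "sweep":
            return sigma_sweep(self.structure, self.data, config, self.tags)
        if protocol == "markov_blanket":
            return markov_blanket_experiment(self.structure, self.data, config)
        if protocol == "semantic":
            if self.tags is None:
                raise ValueError("semantic protocol requires a tag map")
            return semantic_experiment(self.structure, self.data, config, self.tags)
        if protocol == "pradhan":
            return pradhan_experiment(self.structure, self.data, config)
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")

    def baseline(self):
        """Noise-free leave-one-out accuracy and per-case results."""
        spec = NoiseSpec("symmetric", 0.0)
        return loo_accuracy(self.structure, self.data, spec, self.config)
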