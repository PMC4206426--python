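"""Synthetic labeled feature tables with planted statistical structure.

The generator emulates the shape of a per-site alignment-feature table
for editing-site classification: two classes, continuous features, and
three ground-truth feature roles encoded in the column names —

* ``inf_*``    informative: Normal(0, 1) in the negative class and
  Normal(δ, 1) in the positive class (δ = class mean shift in sd units);
* ``red_*``    redundant: a copy of an informative column plus
  Normal(0, redundant_noise_sd) jitter — relevant but carrying almost no
  new information, exactly what the redundancy penalty should demote;
* ``noise_*``  pure noise: Normal(0, 1) in both classes.

Defaults mirror the real study's dimensions: 127 samples per class and
77 features (3 informative + 2 redundant + 72 noise) with δ = 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import FeatureTable, LabeledDataset

__all__ = ["SyntheticSpec", "generate", "ground_truth_roles"]


@dataclass
class SyntheticSpec:
    n_per_class: int = 127
    n_informative: int = 3
    n_redundant: int = 2
    n_noise: int = 72
    delta: float = 2.0
    redundant_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if min(self.n_informative, self.n_redundant, self.n_noise) < 0:
            raise ValueError("feature counts must be >= 0")
        if self.n_informative + self.n_redundant + self.n_noise < 1:
            raise ValueError("need at least one feature")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant features need an informative source")
        if self.n_redundant > self.n_informative:
            raise ValueError("n_redundant must not exceed n_informative")
        if self.redundant_noise_sd < 0:
            raise ValueError("redundant_noise_sd must be >= 0")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise

    def feature_names(self) -> list[str]:
        return (
            [f"inf_{i + 1}" for i in range(self.n_informative)]
            + [f"red_{i + 1}" for i in range(self.n_redundant)]
            + [f"noise_{i + 1}" for i in range(self.n_noise)]
        )


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Draw a labeled table from the class-shift model; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    labels = np.repeat([0, 1], spec.n_per_class)
    blocks = []
    inf = rng.standard_normal((n, spec.n_informative))
    inf[labels == 1] += spec.delta
    if spec.n_informative:
        blocks.append(inf)
    if spec.n_redundant:
        src = np.column_stack(
            [inf[:, j % spec.n_informative] for j in range(spec.n_redundant)]
        )
        blocks.append(src + rng.normal(0.0, spec.redundant_noise_sd, src.shape))
    if spec.n_noise:
        blocks.append(rng.standard_normal((n, spec.n_noise)))
    values = np.concatenate(blocks, axis=1)
    table = FeatureTable(values, spec.feature_names())
    return LabeledDataset(table, labels)


def ground_truth_roles(spec: SyntheticSpec) -> dict[str, list[str]]:
    """Feature names grouped by planted role, for sidecar truth files."""
    names = spec.feature_names()
    return {
        "informative": names[: spec.n_informative],
        "redundant": names[spec.n_informative : spec.n_informative + spec.n_redundant],
        "noise": names[spec.n_informative + spec.n_redundant :],
    }
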