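"""Parallel integration of per-layer component scores.

All omics layers are treated equivalently: the per-block component score
vectors of every layer are column-bound into one samples x K* matrix
(K* = sum of per-layer block counts), keeping provenance so each column
can be traced back to its layer, block and supporting variables.  Scores
are deliberately not re-standardized, so Cox coefficients downstream are
on the component-score scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SurvivalOutcome
from .spca import SparseComponent

__all__ = ["IntegratedDataset", "merge_components"]


@dataclass
class IntegratedDataset:
    """Samples x components score matrix with provenance per column."""

    scores: pd.DataFrame
    provenance: dict[str, SparseComponent]

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def labels(self) -> list[str]:
        return self.scores.columns.tolist()

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def subset(self, labels: list[str]) -> "IntegratedDataset":
        missing = set(labels) - set(self.labels)
        if missing:
            raise KeyError(f"unknown component labels: {sorted(missing)}")
        return IntegratedDataset(self.scores[list(labels)],
                                 {l: self.provenance[l] for l in labels})


def merge_components(
    per_layer: list[list[SparseComponent]], survival: SurvivalOutcome
) -> IntegratedDataset:
    """Column-bind component scores from every layer, aligned to survival order.

    Layers must already share the aligned sample set; component labels must
    be unique across layers.
    """
    if not per_layer or all(len(cs) == 0 for cs in per_layer):
        raise ValueError("no components to merge")
    order = survival.sample_ids
    order_set = set(order)
    cols: dict[str, pd.Series] = {}
    for components in per_layer:
        for c in components:
            if c.label in cols:
                raise ValueError(f"duplicate component label across layers: {c.label!r}")
            if set(c.scores.index) != order_set:
                raise ValueError(
                    f"component {c.label!r} sample set does not match the survival table; "
                    "run align_samples first"
                )
            cols[c.label] = c.scores.loc[order]
    scores = pd.DataFrame(cols, index=pd.Index(order))
    provenance = {c.label: c for components in per_layer for c in components}
    return IntegratedDataset(scores, provenance)
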