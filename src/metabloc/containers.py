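"""Shared in-memory containers used across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Allowed processing states of a feature matrix, in normalization order.
STATES = ("raw", "pqn", "autoscaled")

MAX_FUNCTIONS_PER_METABOLITE = 3


@dataclass
class FeatureMatrix:
    """A samples x metabolites intensity table with a processing-state flag.

    Rows of ``data`` are samples (index = sample ids), columns are
    metabolite ids.  ``state`` tracks where the matrix sits in the
    normalization chain: ``raw`` -> ``pqn`` -> ``autoscaled``.
    """

    data: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if not self.data.index.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.data.columns.is_unique:
            raise ValueError("metabolite ids must be unique")

    @property
    def samples(self) -> list:
        return list(self.data.index)

    @property
    def metabolites(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self, state: str | None = None) -> "FeatureMatrix":
        return FeatureMatrix(self.data.copy(), state if state is not None else self.state)


@dataclass
class BlockAnnotation:
    """Metabolite -> set of biological-function labels (at most three).

    Metabolites sharing a function label form a candidate functional
    block; blocks with fewer than three members are discarded downstream.
    """

    mapping: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for met, labels in dict(self.mapping).items():
            labels = tuple(str(l) for l in labels if l is not None and str(l).strip() != "")
            if len(labels) > MAX_FUNCTIONS_PER_METABOLITE:
                raise ValueError(
                    f"metabolite {met!r} carries {len(labels)} function labels; "
                    f"at most {MAX_FUNCTIONS_PER_METABOLITE} are allowed"
                )
            if len(set(labels)) != len(labels):
                raise ValueError(f"metabolite {met!r} has duplicate function labels")
            clean[str(met)] = labels
        self.mapping = clean

    @property
    def metabolites(self) -> list[str]:
        return list(self.mapping)

    @property
    def functions(self) -> list[str]:
        seen: dict[str, None] = {}
        for labels in self.mapping.values():
            for l in labels:
                seen.setdefault(l)
        return list(seen)

    def labels_for(self, metabolite: str) -> tuple[str, ...]:
        return self.mapping.get(metabolite, ())

    def to_frame(self) -> pd.DataFrame:
        """Wide table: metabolite_id plus function1..function3 (blank-padded)."""
        rows = []
        for met, labels in self.mapping.items():
            padded = list(labels) + [""] * (MAX_FUNCTIONS_PER_METABOLITE - len(labels))
            rows.append([met, *padded])
        cols = ["metabolite_id"] + [f"function{i+1}" for i in range(MAX_FUNCTIONS_PER_METABOLITE)]
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BlockAnnotation":
        frame = frame.fillna("")
        label_cols = [c for c in frame.columns if c != "metabolite_id"]
        mapping = {
            str(row["metabolite_id"]): tuple(
                str(row[c]) for c in label_cols if str(row[c]).strip() != ""
            )
            for _, row in frame.iterrows()
        }
        return cls(mapping)


def require_two_groups(groups: pd.Series) -> tuple[str, str]:
    """Validate a binary group labelling and return its sorted level pair."""
    levels = sorted(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise ValueError(f"exactly two group labels required, got {levels}")
    return levels[0], levels[1]
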