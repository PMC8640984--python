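"""In-memory container for expression-style sample x variable matrices."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class ExpressionDataset:
    """A samples x variables numeric matrix with identifiers.

    ``values`` holds one row per sample and one column per variable (gene,
    miRNA probe, ...).  The container is deliberately thin: preprocessing and
    modelling operate on the raw ndarray, while identifiers travel alongside
    so that column subsets remain traceable.

    Attributes
    ----------
    values:
        ``(n_samples, n_variables)`` float array.  Must be finite.
    sample_ids, variable_ids:
        Row / column identifiers; ``variable_ids`` must be unique.
    provenance:
        Free text describing origin (an accession, or a synthetic seed).
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    variable_ids: list[str] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x variables array")
        n, p = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if not self.variable_ids:
            self.variable_ids = [f"v{j}" for j in range(p)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_ids = [str(v) for v in self.variable_ids]
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.variable_ids) != p:
            raise ValueError(f"{len(self.variable_ids)} variable ids for {p} columns")
        if len(set(self.variable_ids)) != p:
            dupes = pd.Index(self.variable_ids)
            raise ValueError(
                "duplicate variable ids: "
                f"{sorted(set(dupes[dupes.duplicated()]))[:5]}"
            )
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"variable {self.variable_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def column_index(self, variable_id: str) -> int:
        try:
            return self.variable_ids.index(variable_id)
        except ValueError:
            raise KeyError(f"unknown variable id {variable_id!r}") from None

    def subset_variables(self, variable_ids: list[str]) -> "ExpressionDataset":
        """Return a new dataset restricted to ``variable_ids`` (in that order)."""
        idx = [self.column_index(v) for v in variable_ids]
        return replace(
            self,
            values=self.values[:, idx].copy(),
            variable_ids=list(variable_ids),
            sample_ids=list(self.sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.variable_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "") -> "ExpressionDataset":
        return cls(
            values=frame.to_numpy(dtype=float),
            sample_ids=[str(s) for s in frame.index],
            variable_ids=[str(c) for c in frame.columns],
            provenance=provenance,
        )
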