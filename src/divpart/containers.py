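"""Core in-memory containers shared across the pipeline.

Three tabular objects flow through every analysis stage: the site-by-genus
abundance matrix (``CommunityMatrix``), the site-by-variable environment
table with its predictor-set labels (``PredictorTable``), and symmetric
pairwise site dissimilarities (``DistanceMatrix``).  All three validate
their invariants at construction so downstream code can assume clean data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The three predictor sets every environment variable must belong to.
PREDICTOR_SETS = ("climatic", "soil", "historical")


class ValidationError(ValueError):
    """Raised when a container's invariants are violated at construction."""


def _check_unique(labels, what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass
class CommunityMatrix:
    """Site x genus abundance matrix.

    Abundances are non-negative reals: raw plot counts are integers, but
    site-level values may be fractional after averaging plots.
    """

    sites: list[str]
    genera: list[str]
    abundance: np.ndarray  # shape (n_sites, n_genera)

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.sites), len(self.genera)):
            raise ValidationError(
                f"abundance shape {self.abundance.shape} does not match "
                f"{len(self.sites)} sites x {len(self.genera)} genera"
            )
        _check_unique(self.sites, "site")
        _check_unique(self.genera, "genus")
        if not np.all(np.isfinite(self.abundance)):
            raise ValidationError("abundance contains non-finite values")
        if (self.abundance < 0).any():
            i, j = np.argwhere(self.abundance < 0)[0]
            raise ValidationError(
                f"negative abundance at site {self.sites[i]!r}, genus {self.genera[j]!r}"
            )
        empty = np.where(self.abundance.sum(axis=1) <= 0)[0]
        if empty.size:
            raise ValidationError(f"site {self.sites[empty[0]]!r} has no positive abundance")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_genera(self) -> int:
        return len(self.genera)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundance, index=self.sites, columns=self.genera)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CommunityMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(dtype=float))


@dataclass
class PredictorTable:
    """Site x variable numeric matrix, each variable tagged with a predictor set.

    ``set_labels`` maps variable name -> one of :data:`PREDICTOR_SETS`.
    """

    sites: list[str]
    values: pd.DataFrame
    set_labels: dict[str, str]

    def __post_init__(self) -> None:
        if list(self.values.index) != list(self.sites):
            self.values = self.values.copy()
            self.values.index = list(self.sites)
        _check_unique(self.sites, "site")
        _check_unique(self.values.columns, "variable")
        for var in self.values.columns:
            if var not in self.set_labels:
                raise ValidationError(f"variable {var!r} has no set label")
            if self.set_labels[var] not in PREDICTOR_SETS:
                raise ValidationError(
                    f"variable {var!r} has unknown set label {self.set_labels[var]!r}"
                )
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"missing/non-finite value at site {self.sites[i]!r}, "
                f"variable {self.values.columns[j]!r}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def variables(self, pset: str | None = None) -> list[str]:
        """Variable names, optionally restricted to one predictor set."""
        if pset is None:
            return list(self.values.columns)
        if pset not in PREDICTOR_SETS:
            raise ValueError(f"unknown predictor set {pset!r}")
        return [v for v in self.values.columns if self.set_labels[v] == pset]

    def subset(self, psets) -> np.ndarray:
        """Numeric matrix of all variables belonging to the given sets, in table order."""
        if isinstance(psets, str):
            psets = (psets,)
        cols = [v for v in self.values.columns if self.set_labels[v] in psets]
        return self.values[cols].to_numpy(dtype=float)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise site dissimilarity with zero diagonal."""

    labels: list[str]
    d: np.ndarray
    metric: str = field(default="unknown")

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        _check_unique(self.labels, "site")
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("distance matrix contains non-finite values")
        if (self.d < 0).any():
            raise ValidationError("distance matrix has negative entries")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries in row-major order (scipy condensed order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)
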