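"""Shared data containers: phenotype tables and covariance/correlation matrices.

Phenotype matrices are stored as units x traits :class:`pandas.DataFrame`
objects wrapped in :class:`TraitTable`, which enforces identifier uniqueness
and finiteness.  Square trait-by-trait matrices are wrapped in
:class:`CovarianceMatrix` / :class:`CorrelationMatrix`, which enforce symmetry,
positive-semidefiniteness (up to round-off) and, for correlations, a unit
diagonal and entries in [-1, 1].
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("coevotest")

SYMMETRY_TOL = 1e-10
PSD_TOL = 1e-8


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.duplicated().any():
        dupes = labels[labels.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dupes}")


class TraitTable:
    """Units (mutant lines or natural strains) x traits matrix of phenotypes.

    Values are dimensionless log-ratios relative to a reference phenotype.
    Missing cells (NaN) are tolerated at the container level; analysis
    functions drop incomplete rows and log how many were removed so that all
    pairwise statistics share a single sample size.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("TraitTable expects a pandas DataFrame (units x traits)")
        if data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError(
                f"need at least 2 units and 2 traits, got shape {data.shape}"
            )
        _check_unique(data.index, "unit")
        _check_unique(data.columns, "trait")
        data = data.astype(float)
        if np.isinf(data.to_numpy()).any():
            raise ValueError("trait table contains infinite values")
        self.data = data
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def unit_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def n_traits(self) -> int:
        return self.data.shape[1]

    def dropna_rows(self) -> "TraitTable":
        """Drop units with any missing trait value (listwise deletion)."""
        complete = self.data.dropna(axis=0)
        n_dropped = self.data.shape[0] - complete.shape[0]
        if n_dropped:
            logger.info("dropped %d unit(s) with missing trait values", n_dropped)
        return TraitTable(complete)

    @classmethod
    def from_tsv(cls, path) -> "TraitTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")

    def __repr__(self) -> str:  # pragma: no cover
        return f"TraitTable({self.n_units} units x {self.n_traits} traits)"


class _SquareTraitMatrix:
    """Symmetric trait-by-trait matrix with labelled axes."""

    _kind = "square"

    def __init__(self, entries, trait_ids: Sequence[str] | None = None):
        if isinstance(entries, pd.DataFrame):
            if trait_ids is None:
                trait_ids = list(entries.columns)
            entries = entries.to_numpy(dtype=float)
        entries = np.asarray(entries, dtype=float)
        if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
            raise ValueError(f"{self._kind} matrix must be square, got {entries.shape}")
        if trait_ids is None:
            trait_ids = [f"trait_{i + 1}" for i in range(entries.shape[0])]
        trait_ids = [str(t) for t in trait_ids]
        if len(trait_ids) != entries.shape[0]:
            raise ValueError("trait_ids length does not match matrix size")
        if len(set(trait_ids)) != len(trait_ids):
            raise ValueError("duplicate trait identifiers")
        finite = np.isfinite(entries)
        both = finite & finite.T
        if np.nanmax(np.abs(np.where(both, entries - entries.T, 0.0)), initial=0.0) > SYMMETRY_TOL:
            raise ValueError(f"{self._kind} matrix is not symmetric within {SYMMETRY_TOL}")
        # exact symmetrization to kill round-off
        entries = np.where(both, (entries + entries.T) / 2.0, entries)
        self._validate(entries)
        self.entries = entries
        self.trait_ids = trait_ids

    def _validate(self, entries: np.ndarray) -> None:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_traits(self) -> int:
        return self.entries.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=self.trait_ids, columns=self.trait_ids)

    @classmethod
    def from_tsv(cls, path):
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def reindex(self, trait_ids: Sequence[str]):
        """Return the same matrix with rows/columns in the given trait order."""
        idx = [self.trait_ids.index(t) for t in trait_ids]
        return type(self)(self.entries[np.ix_(idx, idx)], trait_ids)

    def __repr__(self) -> str:  # pragma: no cover
        return f"{type(self).__name__}({self.n_traits} traits)"


class CovarianceMatrix(_SquareTraitMatrix):
    """Trait covariance matrix (e.g. the mutational M matrix).

    Units are squared standardized phenotype.  Positive-semidefinite up to a
    -1e-8 eigenvalue tolerance; NaN entries (undefined covariances) are
    allowed and skip the PSD check.
    """

    _kind = "covariance"

    def _validate(self, entries: np.ndarray) -> None:
        finite = np.isfinite(entries)
        diag = np.diag(entries)
        if np.any(diag[np.isfinite(diag)] < 0):
            raise ValueError("covariance matrix has a negative diagonal entry")
        if finite.all():
            min_eig = float(np.linalg.eigvalsh(entries)[0])
            if min_eig < -PSD_TOL:
                raise ValueError(
                    f"covariance matrix is not positive semidefinite "
                    f"(minimum eigenvalue {min_eig:.3e})"
                )


class CorrelationMatrix(_SquareTraitMatrix):
    """Trait correlation matrix with unit diagonal and entries in [-1, 1].

    NaN off-diagonal entries mark undefined correlations (e.g. a trait with
    zero variance in the sample); the diagonal must still be 1.
    """

    _kind = "correlation"

    def _validate(self, entries: np.ndarray) -> None:
        diag = np.diag(entries)
        if not np.allclose(diag, 1.0, atol=1e-8, rtol=0):
            raise ValueError("correlation matrix diagonal must be 1")
        np.fill_diagonal(entries, 1.0)
        off = entries[~np.eye(entries.shape[0], dtype=bool)]
        off = off[np.isfinite(off)]
        if off.size and (off.min() < -1 - 1e-10 or off.max() > 1 + 1e-10):
            raise ValueError("correlation entries must lie in [-1, 1]")
        np.clip(entries, -1.0, 1.0, out=entries)
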