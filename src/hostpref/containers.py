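"""Typed containers for the pipeline's tabular objects.

All containers wrap pandas objects and validate their structural
invariants on construction, so downstream code can assume well-formed
input.  Samples are always rows; fungal OTUs are always columns of the
sample-level matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Host clustering cutoff levels, finest to coarsest (% rbcL similarity).
LEVELS: tuple[str, ...] = ("99.8", "99", "98", "97")


def level_column(level) -> str:
    """Column name of a host clustering level in a host table."""
    lv = str(level)
    if lv not in LEVELS:
        raise ValidationError(f"unknown clustering level {level!r}; expected one of {LEVELS}")
    return f"otu_{lv}"


@dataclass
class CountMatrix:
    """Sample x fungal-OTU read counts, raw or rarefied.

    The `state` flag enforces the pipeline order: presence/absence
    conversion only accepts rarefied matrices.
    """

    data: pd.DataFrame
    state: str = "raw"
    depth: int | None = None

    def __post_init__(self):
        if self.state not in ("raw", "rarefied"):
            raise ValidationError(f"unknown count-matrix state {self.state!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate fungal OTU id {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValidationError("read counts must be integers")
            self.data = self.data.astype(np.int64)
            values = self.data.to_numpy()
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.data.index[i]!r}, OTU {self.data.columns[j]!r}"
            )
        if self.state == "rarefied":
            if self.depth is None:
                raise ValidationError("rarefied matrix must record its depth")
            sums = values.sum(axis=1)
            if (sums != self.depth).any():
                bad = self.data.index[int(np.argmax(sums != self.depth))]
                raise ValidationError(
                    f"rarefied sample {bad!r} has row sum {sums[sums != self.depth][0]}, "
                    f"expected depth {self.depth}"
                )

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def otu_ids(self) -> pd.Index:
        return self.data.columns


@dataclass
class OccurrenceMatrix:
    """Binary sample x fungal-OTU presence/absence matrix.

    `empty_otus` lists OTU columns that were all-zero on conversion and
    are excluded from `data`.
    """

    data: pd.DataFrame
    empty_otus: list = field(default_factory=list)

    def __post_init__(self):
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("occurrence matrix entries must be 0/1")
        self.data = self.data.astype(np.int8)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def otu_ids(self) -> pd.Index:
        return self.data.columns

    def subset_otus(self, otu_ids) -> "OccurrenceMatrix":
        keep = [o for o in self.data.columns if o in set(otu_ids)]
        return OccurrenceMatrix(self.data[keep].copy())

    def subset_samples(self, sample_ids) -> "OccurrenceMatrix":
        return OccurrenceMatrix(self.data.loc[list(sample_ids)].copy())


@dataclass
class HostAssignment:
    """Sample -> plant OTU labels at each cutoff level, with family flags.

    Columns: ``otu_99.8``, ``otu_99``, ``otu_98``, ``otu_97``, ``family``,
    ``is_dipterocarp``; index = sample id.  Partitions must be nested:
    the label at a coarser level is a function of the finest-level label.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = [level_column(lv) for lv in LEVELS] + ["family", "is_dipterocarp"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"host table missing columns {missing}")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r} in host table")
        # chain nesting: each level's label must determine the next coarser one
        for finer, coarser in zip(LEVELS, LEVELS[1:]):
            n_images = self.table.groupby(level_column(finer), observed=True)[
                level_column(coarser)
            ].nunique()
            if (n_images > 1).any():
                bad = n_images.index[int(np.argmax(n_images.to_numpy() > 1))]
                raise ValidationError(
                    f"nesting violation: plant OTU {bad!r} at level {finer} maps to "
                    f"multiple labels at level {coarser}"
                )

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def labels(self, level) -> pd.Series:
        return self.table[level_column(level)]

    def plant_otus(self, level) -> list:
        return sorted(self.table[level_column(level)].unique())


@dataclass
class AssociationMatrix:
    """Plant-taxon x fungal-OTU association counts at one cutoff level.

    ``y.loc[i, j]`` is the number of samples of plant OTU ``j`` in which
    fungal OTU ``i`` occurred.  ``T[j]`` is the number of samples of plant
    OTU ``j``; ``N[i] = sum_j y[i, j]``.
    """

    y: pd.DataFrame  # fungal OTUs (rows) x plant OTUs (columns)
    T: pd.Series  # samples per plant OTU
    level: str

    def __post_init__(self):
        if not self.y.columns.equals(self.T.index):
            self.T = self.T.reindex(self.y.columns)
            if self.T.isna().any():
                raise ValidationError("T margin does not cover all plant OTUs")
        yv = self.y.to_numpy()
        if (yv < 0).any():
            raise ValidationError("association counts must be non-negative")
        if (yv > self.T.to_numpy()[None, :]).any():
            i, j = np.argwhere(yv > self.T.to_numpy()[None, :])[0]
            raise ValidationError(
                f"y[{self.y.index[i]!r}, {self.y.columns[j]!r}] exceeds T_j"
            )

    @property
    def N(self) -> pd.Series:
        return self.y.sum(axis=1)

    @property
    def J(self) -> int:
        return self.y.shape[1]

    @property
    def fungal_otus(self) -> pd.Index:
        return self.y.index

    @property
    def plant_otus(self) -> pd.Index:
        return self.y.columns


@dataclass
class DistanceMatrix:
    """Symmetric, non-negative, zero-diagonal labelled distance matrix."""

    data: pd.DataFrame
    kind: str = "generic"  # genetic | geographic | community | generic

    def __post_init__(self):
        if not self.data.index.equals(self.data.columns):
            raise ValidationError("distance matrix row and column labels differ")
        v = self.data.to_numpy(dtype=float)
        asym = np.abs(v - v.T)
        if asym.max(initial=0.0) > 1e-12:
            i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
            raise ValidationError(
                f"asymmetric distances between {self.data.index[i]!r} and "
                f"{self.data.columns[j]!r}: {v[i, j]!r} vs {v[j, i]!r}"
            )
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            i = int(np.argmax(np.abs(np.diag(v))))
            raise ValidationError(f"non-zero diagonal at label {self.data.index[i]!r}")
        if (v < 0).any():
            raise ValidationError("negative distances")

    @property
    def labels(self) -> pd.Index:
        return self.data.index

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries (row-major, i > j), as a flat vector."""
        v = self.data.to_numpy(dtype=float)
        return v[np.tril_indices_from(v, k=-1)]

    def reindex(self, labels) -> "DistanceMatrix":
        labels = list(labels)
        missing = [l for l in labels if l not in self.data.index]
        if missing:
            raise ValidationError(f"labels missing from distance matrix: {missing[:5]}")
        return DistanceMatrix(self.data.loc[labels, labels].copy(), kind=self.kind)
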