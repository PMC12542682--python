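"""Core in-memory containers: the OTU count table and per-sample metadata.

The :class:`OtuTable` is the pipeline's central object — a samples × OTUs
matrix of non-negative integer counts with stable row/column order.
:class:`SampleMetadata` carries the per-sample design (season, site),
pairwise dendritic distances along the river network, and the measured
environmental variables, of which eight nutrient parameters form a fixed,
validated vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The eight nutrient parameters entering the multi-nutrient cycling index:
#: total carbon, total organic carbon, total nitrogen, ammonium, nitrate,
#: nitrite, total phosphorus and phosphate.
NUTRIENT_VARS: tuple[str, ...] = (
    "TC", "TOC", "TN", "NH4-N", "NO3-N", "NO2-N", "TP", "PO4-P",
)

SEASONS: tuple[str, ...] = ("wet", "dry")


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = sorted(ids[ids.duplicated()].unique().tolist())
        raise ValueError(f"duplicate {what} identifier(s): {dups}")


class OtuTable:
    """A samples × OTUs matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with one column per OTU id, or a
        2-D integer array combined with ``sample_ids`` / ``otu_ids``.

    Raises
    ------
    ValueError
        On duplicate identifiers, negative counts or non-numeric entries.
    """

    def __init__(self, counts, sample_ids=None, otu_ids=None):
        if isinstance(counts, pd.DataFrame):
            df = counts
        else:
            arr = np.asarray(counts)
            df = pd.DataFrame(arr, index=list(sample_ids), columns=list(otu_ids))
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "OTU")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric counts in OTU table: {exc}") from None
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "invalid count at sample "
                f"{df.index[i]!r}, OTU {df.columns[j]!r}: {df.iat[i, j]!r}"
            )
        if not np.allclose(values, np.round(values)):
            i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise ValueError(
                "non-integer count at sample "
                f"{df.index[i]!r}, OTU {df.columns[j]!r}: {df.iat[i, j]!r}"
            )
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValueError("OTU table needs at least one sample and one OTU")
        self._df = pd.DataFrame(
            values.astype(np.int64), index=df.index.astype(str),
            columns=df.columns.astype(str),
        )

    # -- basic views ---------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return self._df.index.tolist()

    @property
    def otu_ids(self) -> list[str]:
        return self._df.columns.tolist()

    @property
    def counts(self) -> np.ndarray:
        """Counts as an int64 array (samples × OTUs); a defensive copy."""
        return self._df.to_numpy().copy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    @property
    def n_samples(self) -> int:
        return self._df.shape[0]

    @property
    def n_otus(self) -> int:
        return self._df.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    def sample_sums(self) -> pd.Series:
        return self._df.sum(axis=1)

    # -- subsetting (order-preserving) ---------------------------------

    def select_otus(self, otu_ids) -> "OtuTable":
        otu_ids = list(otu_ids)
        missing = set(otu_ids) - set(self._df.columns)
        if missing:
            raise KeyError(f"unknown OTU id(s): {sorted(missing)}")
        return OtuTable(self._df.loc[:, otu_ids])

    def select_samples(self, sample_ids) -> "OtuTable":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self._df.index)
        if missing:
            raise KeyError(f"unknown sample id(s): {sorted(missing)}")
        return OtuTable(self._df.loc[sample_ids, :])

    def drop_empty_otus(self) -> "OtuTable":
        keep = self._df.columns[(self._df > 0).any(axis=0)]
        return OtuTable(self._df.loc[:, keep])

    def __eq__(self, other) -> bool:
        return isinstance(other, OtuTable) and self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"OtuTable({self.n_samples} samples x {self.n_otus} OTUs)"


@dataclass
class SampleMetadata:
    """Per-sample design, environment, and pairwise dendritic distances.

    ``table`` is indexed by sample id and holds ``season`` (wet/dry),
    ``site_id`` and numeric environmental columns including any of the
    eight nutrient variables.  ``dendritic_km`` is the symmetric matrix of
    pairwise along-network distances in kilometres.
    """

    table: pd.DataFrame
    dendritic_km: pd.DataFrame = field(default=None)

    def __post_init__(self):
        _check_unique(self.table.index, "sample")
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)
        if "season" in self.table.columns:
            bad = set(self.table["season"]) - set(SEASONS)
            if bad:
                raise ValueError(f"unknown season value(s): {sorted(bad)}")
        if self.dendritic_km is not None:
            d = self.dendritic_km
            vals = d.to_numpy(dtype=float)
            if list(d.index) != list(d.columns):
                raise ValueError("dendritic distance matrix ids mismatch")
            if not np.allclose(vals, vals.T, atol=1e-9):
                raise ValueError("dendritic distance matrix is not symmetric")
            if not np.allclose(np.diag(vals), 0.0):
                raise ValueError("dendritic distance diagonal must be zero")
            if (vals < 0).any():
                raise ValueError("dendritic distances must be non-negative")
            self.dendritic_km = pd.DataFrame(
                vals, index=d.index.astype(str), columns=d.columns.astype(str)
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def env(self) -> pd.DataFrame:
        """All numeric environmental columns (nutrients included)."""
        drop = [c for c in ("season", "site_id") if c in self.table.columns]
        return self.table.drop(columns=drop).select_dtypes("number")

    @property
    def nutrients(self) -> pd.DataFrame:
        """The eight-nutrient submatrix, in canonical column order."""
        missing = [v for v in NUTRIENT_VARS if v not in self.table.columns]
        if missing:
            raise KeyError(f"missing nutrient column(s): {missing}")
        return self.table.loc[:, list(NUTRIENT_VARS)].astype(float)

    def validate_against(self, table: OtuTable) -> None:
        """Every sample in ``table`` must have a metadata row (and distances)."""
        missing = set(table.sample_ids) - set(self.table.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if self.dendritic_km is not None:
            missing = set(table.sample_ids) - set(self.dendritic_km.index)
            if missing:
                raise ValueError(
                    f"samples without dendritic distances: {sorted(missing)}"
                )

    def subset(self, sample_ids) -> "SampleMetadata":
        sample_ids = list(sample_ids)
        dk = None
        if self.dendritic_km is not None:
            dk = self.dendritic_km.loc[sample_ids, sample_ids]
        return SampleMetadata(self.table.loc[sample_ids], dk)
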