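"""Reading, writing and batch normalisation of GC peak-area tables.

A peak table is a samples x peaks matrix of non-negative areas (0 means
"not detected") together with per-sample design metadata: line, locality,
generation, replicate cage, sex, mating status and analytical batch.
Tables travel as CSV in the dialect of the deposited datasets: metadata
columns first, then one column per peak headed by its retention time
(minutes, for FID data) or Kovats index (integer, for MS data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default metadata column names in the deposited-CSV dialect
DEFAULT_DIALECT = {
    "sample_id": "Sample",
    "line": "Line",
    "locality": "Locality",
    "generation": "Gen",
    "cage": "Cage",
    "sex": "Sex",
    "mating": "Mating",
    "batch": "Batch",
}

#: metadata fields that a table can carry; sample_id is the index
METADATA_FIELDS = ("line", "locality", "generation", "cage", "sex", "mating", "batch")

SEXES = ("male", "female")
MATINGS = ("virgin", "mixed")


class PeakTableError(ValueError):
    """Raised when a peak table violates its invariants."""


@dataclass
class PeakTable:
    """Samples x peaks matrix of peak areas with sample metadata.

    Parameters
    ----------
    samples : pandas.DataFrame
        One row per sample, indexed by unique sample id; columns are a
        subset of :data:`METADATA_FIELDS`.
    areas : pandas.DataFrame
        Non-negative peak areas, same index as ``samples``; columns are
        float peak labels (retention times in minutes or Kovats indices),
        strictly increasing.
    dataset_tag : str
        Free-text tag identifying the dataset (e.g. ``"minor-mixed-males"``).
    """

    samples: pd.DataFrame
    areas: pd.DataFrame
    dataset_tag: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if not self.samples.index.equals(self.areas.index):
            raise PeakTableError("sample metadata and area matrix indexes differ")
        if self.samples.index.has_duplicates:
            dups = self.samples.index[self.samples.index.duplicated()].tolist()
            raise PeakTableError(f"duplicate sample ids: {dups}")
        vals = self.areas.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise PeakTableError("missing values in area matrix; encode non-detection as 0")
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise PeakTableError(
                f"negative area at sample {self.areas.index[r]!r}, peak {self.areas.columns[c]}"
            )
        labels = np.asarray(self.areas.columns, dtype=float)
        if len(labels) > 1 and not (np.diff(labels) > 0).all():
            raise PeakTableError("peak labels must be strictly increasing")
        if "generation" in self.samples.columns:
            gen = pd.to_numeric(self.samples["generation"], errors="coerce")
            if (gen.dropna() < 1).any():
                raise PeakTableError("generation must be >= 1 when known")

    # -- convenience ---------------------------------------------------
    @property
    def peak_labels(self) -> np.ndarray:
        return np.asarray(self.areas.columns, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.areas)

    @property
    def n_peaks(self) -> int:
        return self.areas.shape[1]

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (area > 0)."""
        return self.areas > 0

    def subset_samples(self, mask) -> "PeakTable":
        return PeakTable(self.samples.loc[mask], self.areas.loc[mask], self.dataset_tag)

    def subset_peaks(self, labels) -> "PeakTable":
        labels = list(labels)
        return PeakTable(self.samples, self.areas[labels], self.dataset_tag)

    def restrict(self, **criteria) -> "PeakTable":
        """Restrict to samples matching metadata equality criteria.

        >>> table.restrict(sex="male", mating="virgin")  # doctest: +SKIP
        """
        mask = pd.Series(True, index=self.samples.index)
        for key, value in criteria.items():
            mask &= self.samples[key] == value
        return self.subset_samples(mask)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakTable):
            return NotImplemented
        return (
            self.dataset_tag == other.dataset_tag
            and self.samples.equals(other.samples)
            and np.allclose(self.areas.to_numpy(float), other.areas.to_numpy(float))
            and list(map(float, self.areas.columns)) == list(map(float, other.areas.columns))
        )


def read_peak_table(path, dialect=None, dataset_tag: str = "") -> PeakTable:
    """Read a peak table from a deposited-dialect CSV.

    Metadata columns are located by name via *dialect* (defaults to
    :data:`DEFAULT_DIALECT`); every remaining column whose header parses
    as a number is a peak column. Empty cells are read as 0 (not
    detected) with a logged warning. Peak columns are sorted ascending.

    Raises
    ------
    PeakTableError
        On negative areas, duplicate sample ids or a non-numeric header
        among the peak columns.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, float_precision="round_trip")
    name_map = {csv_name: field for field, csv_name in dialect.items() if csv_name in raw.columns}
    meta_csv_cols = list(name_map)
    peak_cols = [c for c in raw.columns if c not in meta_csv_cols]

    labels = []
    for c in peak_cols:
        try:
            labels.append(float(c))
        except ValueError:
            raise PeakTableError(f"non-numeric peak column header: {c!r}") from None

    meta = raw[meta_csv_cols].rename(columns=name_map)
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    else:
        meta.index = pd.Index([f"sample{i + 1}" for i in range(len(meta))], name="sample_id")
    meta.index = meta.index.astype(str)

    areas = raw[peak_cols].copy()
    areas.columns = labels
    n_missing = int(areas.isna().sum().sum())
    if n_missing:
        logger.warning("%d missing area cells read as 0 (not detected)", n_missing)
        areas = areas.fillna(0.0)
    areas = areas.astype(float)
    areas.index = meta.index
    areas = areas[sorted(labels)]
    return PeakTable(meta, areas, dataset_tag=dataset_tag)


def write_peak_table(table: PeakTable, path, dialect=None) -> None:
    """Write *table* as CSV in the deposited dialect (inverse of read)."""
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    meta = table.samples.copy()
    meta.insert(0, "sample_id", table.samples.index)
    meta = meta.rename(columns=dialect)
    areas = table.areas.copy()
    areas.columns = [format_label(c) for c in areas.columns]
    areas.index = meta.index
    pd.concat([meta, areas], axis=1).to_csv(path, index=False)


def format_label(label: float) -> str:
    """Render a peak label as printed: Rt to 2 d.p., KI as integer."""
    label = float(label)
    if label >= 600:  # Kovats index scale
        return str(int(round(label)))
    return f"{label:.2f}"


@dataclass
class BatchNormalization:
    """Multiplicative per-batch scaling so all batch totals agree."""

    batch_totals: dict = field(default_factory=dict)
    scale_factors: dict = field(default_factory=dict)


def fit_batch_normalization(table: PeakTable) -> BatchNormalization:
    """Compute per-batch scale factors targeting the grand mean of batch totals."""
    if "batch" not in table.samples.columns:
        raise PeakTableError("table has no batch metadata")
    if table.samples["batch"].isna().any():
        raise PeakTableError("every sample needs a batch label")
    totals = table.areas.groupby(table.samples["batch"]).sum().sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise PeakTableError(f"batch with zero total area: {bad}")
    target = totals.mean()
    return BatchNormalization(
        batch_totals=totals.to_dict(),
        scale_factors=(target / totals).to_dict(),
    )


def normalize_batches(table: PeakTable) -> PeakTable:
    """Rescale each batch so every batch's total area equals the grand mean.

    Zeros stay zero and within-batch peak proportions are unchanged, so
    the detection pattern and within-sample rank order are invariant.
    Idempotent: a second application is a no-op (all factors 1).
    """
    norm = fit_batch_normalization(table)
    factors = table.samples["batch"].map(norm.scale_factors).to_numpy(float)
    scaled = table.areas.mul(factors, axis=0)
    return replace(table, areas=scaled)
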