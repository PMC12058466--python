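"""Core data model and I/O for protein-level intensity tables.

The central container is :class:`ProteomicsDataset`: a proteins x samples
intensity matrix (missing values as NaN), a scale flag (``raw`` or ``log2``),
per-protein boolean annotation flags (e.g. decoy/contaminant marks), and an
ordered list of :class:`SampleMetadata` records.  All downstream modules
(preprocessing, normalization, batch correction, evaluation) consume and
produce this object; the scale flag makes the raw/log2 bookkeeping explicit
so each normalization method can be applied on the scale it expects.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "SampleMetadata",
    "ProteomicsDataset",
    "SpikeInTruth",
    "read_intensity_table",
    "read_metadata",
    "read_spikein_truth",
    "attach_metadata",
    "to_log2",
    "to_raw",
    "write_matrix",
    "write_report",
]


class Scale(str, enum.Enum):
    """Scale of the stored intensities."""

    RAW = "raw"
    LOG2 = "log2"


@dataclass(frozen=True)
class SampleMetadata:
    """Metadata of a single sample (column of the intensity matrix).

    Parameters
    ----------
    sample_id:
        Unique sample name, matching a column of the intensity table.
    condition:
        Biological group label used for DE contrasts and intragroup metrics.
    batch:
        Optional technical batch label (e.g. TMT run).
    is_reference:
        Whether the sample is a pooled reference channel of its batch.
    """

    sample_id: str
    condition: str
    batch: str | None = None
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.is_reference and self.batch is None:
            raise ValueError(
                f"reference sample {self.sample_id!r} must have a batch assigned"
            )


@dataclass
class ProteomicsDataset:
    """Protein intensity matrix plus sample metadata and protein annotations.

    ``intensities`` is a proteins x samples :class:`pandas.DataFrame`
    (index = protein ids, columns = sample ids, NaN = missing).
    ``annotations`` is a boolean DataFrame sharing the protein index; each
    column is a flag (e.g. ``reverse``, ``contaminant``, ``spike_in``).
    """

    intensities: pd.DataFrame
    samples: list[SampleMetadata]
    scale: Scale = Scale.RAW
    annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        idx = self.intensities.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dups}")
        if len(self.samples) != self.intensities.shape[1]:
            raise ValueError(
                f"{self.intensities.shape[1]} intensity columns but "
                f"{len(self.samples)} metadata rows"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in metadata")
        if list(self.intensities.columns) != ids:
            raise ValueError("intensity columns do not match metadata sample order")
        vals = self.intensities.to_numpy(dtype=float)
        if self.scale is Scale.RAW and np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("raw-scale intensities must be non-negative")
        if vals.shape[0] and np.isnan(vals).all(axis=0).any():
            empty = self.intensities.columns[np.isnan(vals).all(axis=0)].tolist()
            raise ValueError(f"columns entirely missing: {empty}")
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=idx)
        else:
            if not self.annotations.index.equals(idx):
                raise ValueError("annotations index must equal the protein index")
            self.annotations = self.annotations.astype(bool)

    # -- convenience accessors -------------------------------------------------

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def conditions(self) -> pd.Series:
        return pd.Series(
            [s.condition for s in self.samples], index=self.sample_ids, name="condition"
        )

    @property
    def batches(self) -> pd.Series:
        return pd.Series(
            [s.batch for s in self.samples], index=self.sample_ids, name="batch"
        )

    @property
    def reference_mask(self) -> pd.Series:
        return pd.Series(
            [s.is_reference for s in self.samples],
            index=self.sample_ids,
            name="is_reference",
        )

    def condition_groups(self, include_reference: bool = True) -> dict[str, list[str]]:
        """Mapping condition -> ordered sample ids of that condition."""
        groups: dict[str, list[str]] = {}
        for s in self.samples:
            if not include_reference and s.is_reference:
                continue
            groups.setdefault(s.condition, []).append(s.sample_id)
        return groups

    def with_matrix(
        self, matrix: pd.DataFrame, scale: Scale | str | None = None
    ) -> "ProteomicsDataset":
        """New dataset with a replaced intensity matrix (same samples).

        Rows of ``matrix`` select/reorder proteins; annotations follow.
        """
        ann = self.annotations.loc[matrix.index]
        return ProteomicsDataset(
            intensities=matrix,
            samples=list(self.samples),
            scale=Scale(scale) if scale is not None else self.scale,
            annotations=ann,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ProteomicsDataset":
        keep = set(sample_ids)
        samples = [s for s in self.samples if s.sample_id in keep]
        return ProteomicsDataset(
            intensities=self.intensities[[s.sample_id for s in samples]],
            samples=samples,
            scale=self.scale,
            annotations=self.annotations,
        )


@dataclass
class SpikeInTruth:
    """Ground-truth labels and concentrations of a spike-in design.

    ``label`` maps every protein to ``"spike_in"`` or ``"background"``;
    ``concentration`` holds the known per-condition concentration of every
    spike-in protein (NaN for background proteins).
    """

    label: pd.Series
    concentration: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.label.unique()) - {"spike_in", "background"}
        if bad:
            raise ValueError(f"unknown truth labels: {sorted(bad)}")
        if not self.concentration.index.equals(self.label.index):
            raise ValueError("concentration index must equal label index")
        spikes = self.label == "spike_in"
        if spikes.any() and self.concentration.loc[spikes].isna().any().any():
            missing = self.concentration.loc[spikes].isna().any(axis=1)
            raise ValueError(
                "spike-in proteins without a concentration in every condition: "
                f"{self.concentration.index[spikes][missing].tolist()[:5]}"
            )
        if (~spikes).any() and self.concentration.loc[~spikes].notna().any().any():
            raise ValueError("background proteins must not carry concentrations")

    @property
    def spike_ids(self) -> pd.Index:
        return self.label.index[self.label == "spike_in"]

    @property
    def background_ids(self) -> pd.Index:
        return self.label.index[self.label == "background"]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

#: annotation columns of the MaxQuant proteinGroups.txt dialect and the flag
#: names they map to (cells contain "+" when flagged)
_MAXQUANT_FLAG_COLUMNS = {
    "Reverse": "reverse",
    "Potential contaminant": "contaminant",
    "Only identified by site": "only_identified_by_site",
}

_NA_STRINGS = ["", "NA", "NaN", "nan"]


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_intensity_table(
    path: str | Path,
    dialect: str = "generic",
    id_column: str = "protein",
    zeros_as_missing: bool | None = None,
    sample_columns: Sequence[str] | None = None,
) -> ProteomicsDataset:
    """Read a wide protein x sample intensity table (TSV/CSV).

    Parameters
    ----------
    dialect:
        ``"generic"`` (plain matrix) or ``"maxquant"`` (proteinGroups.txt
        style: tab-separated, ``+``-valued flag columns such as ``Reverse``
        and ``Potential contaminant``, zero intensities are non-detections).
    id_column:
        Name of the protein-id column.
    zeros_as_missing:
        Convert zero intensities to missing.  Defaults to True for the
        maxquant dialect and False for generic tables.
    sample_columns:
        Explicit sample-column selection; by default every numeric non-flag
        column other than ``id_column`` is treated as a sample.

    The returned dataset has ``scale=raw`` and placeholder metadata
    (condition ``"unspecified"``); use :func:`attach_metadata` to attach real
    sample metadata.
    """
    if dialect not in ("generic", "maxquant"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if zeros_as_missing is None:
        zeros_as_missing = dialect == "maxquant"
    sep = "\t" if dialect == "maxquant" else _sep_for(path)
    table = pd.read_csv(
        path, sep=sep, na_values=_NA_STRINGS, keep_default_na=False, dtype=object
    )
    if id_column not in table.columns:
        raise ValueError(f"id column {id_column!r} not found in {path}")
    ids = table[id_column].astype(str)
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein ids in {path}: {dups}")

    flags: dict[str, pd.Series] = {}
    flag_sources: list[str] = []
    if dialect == "maxquant":
        for col, name in _MAXQUANT_FLAG_COLUMNS.items():
            if col in table.columns:
                flags[name] = table[col].fillna("").astype(str).str.strip() == "+"
                flag_sources.append(col)

    candidates = [
        c for c in table.columns if c != id_column and c not in flag_sources
    ]
    numeric = {}
    for c in candidates:
        converted = pd.to_numeric(table[c], errors="coerce")
        # a sample column must be numeric wherever a value is present
        present = table[c].notna()
        if present.any() and converted[present].notna().all():
            numeric[c] = converted
    if sample_columns is not None:
        missing = [c for c in sample_columns if c not in numeric]
        if missing:
            raise ValueError(f"requested sample columns not numeric/found: {missing}")
        numeric = {c: numeric[c] for c in sample_columns}
    if not numeric:
        raise ValueError(f"no numeric sample column found in {path}")

    matrix = pd.DataFrame(numeric)
    matrix.index = pd.Index(ids, name="protein")
    if zeros_as_missing:
        matrix = matrix.mask(matrix == 0)
    samples = [
        SampleMetadata(sample_id=c, condition="unspecified") for c in matrix.columns
    ]
    annotations = pd.DataFrame(flags).set_axis(matrix.index) if flags else None
    return ProteomicsDataset(
        intensities=matrix, samples=samples, scale=Scale.RAW, annotations=annotations
    )


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a sample metadata table with columns ``sample``, ``condition``
    and optional ``batch``, ``reference``."""
    table = pd.read_csv(path, sep=_sep_for(path))
    for col in ("sample", "condition"):
        if col not in table.columns:
            raise ValueError(f"metadata file {path} lacks required column {col!r}")
    out = []
    for _, row in table.iterrows():
        batch = row.get("batch")
        if pd.isna(batch):
            batch = None
        ref = row.get("reference", False)
        ref = bool(ref) and not pd.isna(ref)
        out.append(
            SampleMetadata(
                sample_id=str(row["sample"]),
                condition=str(row["condition"]),
                batch=None if batch is None else str(batch),
                is_reference=ref,
            )
        )
    return out


def read_spikein_truth(path: str | Path) -> SpikeInTruth:
    """Read a spike-in truth table: columns ``protein``, ``label`` and one
    ``concentration_<condition>`` column per condition."""
    table = pd.read_csv(path, sep=_sep_for(path))
    for col in ("protein", "label"):
        if col not in table.columns:
            raise ValueError(f"truth file {path} lacks required column {col!r}")
    table = table.set_index("protein")
    conc_cols = [c for c in table.columns if c.startswith("concentration_")]
    conc = table[conc_cols].rename(
        columns={c: c[len("concentration_"):] for c in conc_cols}
    )
    return SpikeInTruth(label=table["label"], concentration=conc)


def attach_metadata(
    ds: ProteomicsDataset, samples: Sequence[SampleMetadata]
) -> ProteomicsDataset:
    """Attach sample metadata to a dataset read from file.

    Columns are reordered to the metadata order; every metadata sample must
    exist in the intensity table (extra intensity columns are dropped).
    """
    available = set(ds.intensities.columns)
    for s in samples:
        if s.sample_id not in available:
            raise ValueError(
                f"metadata sample {s.sample_id!r} absent from the intensity table"
            )
    matrix = ds.intensities[[s.sample_id for s in samples]]
    return ProteomicsDataset(
        intensities=matrix,
        samples=list(samples),
        scale=ds.scale,
        annotations=ds.annotations,
    )


# ---------------------------------------------------------------------------
# Scale conversion
# ---------------------------------------------------------------------------


def to_log2(ds: ProteomicsDataset) -> ProteomicsDataset:
    """Element-wise log2 transform (raw -> log2); missing values preserved."""
    if ds.scale is Scale.LOG2:
        return ds
    vals = ds.intensities.to_numpy(dtype=float)
    if np.nanmin(vals, initial=np.inf) <= 0:
        raise ValueError(
            "non-positive observed raw intensity; convert zeros to missing "
            "(zeros_as_missing) or filter before log2 transform"
        )
    return ds.with_matrix(np.log2(ds.intensities), scale=Scale.LOG2)


def to_raw(ds: ProteomicsDataset) -> ProteomicsDataset:
    """Element-wise 2**x back-transform (log2 -> raw)."""
    if ds.scale is Scale.RAW:
        return ds
    return ds.with_matrix(2.0 ** ds.intensities, scale=Scale.RAW)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_matrix(ds: ProteomicsDataset, path: str | Path) -> None:
    """Write the intensity matrix as TSV (missing serialized as ``NA``).

    Round-trips through :func:`read_intensity_table` with equal values and
    an identical missingness mask.
    """
    ds.intensities.to_csv(path, sep="\t", na_rep="NA", index_label="protein")


def write_metadata(samples: Sequence[SampleMetadata], path: str | Path) -> None:
    """Write sample metadata as TSV readable by :func:`read_metadata`."""
    pd.DataFrame(
        {
            "sample": [s.sample_id for s in samples],
            "condition": [s.condition for s in samples],
            "batch": [s.batch for s in samples],
            "reference": [s.is_reference for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def write_truth(truth: SpikeInTruth, path: str | Path) -> None:
    """Write a spike-in truth table readable by :func:`read_spikein_truth`."""
    out = pd.DataFrame({"label": truth.label})
    for cond in truth.concentration.columns:
        out[f"concentration_{cond}"] = truth.concentration[cond]
    out.to_csv(path, sep="\t", na_rep="NA", index_label="protein")


def write_report(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write one TSV per result table into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, table in tables.items():
        p = out_dir / f"{name}.tsv"
        table.to_csv(p, sep="\t", na_rep="NA")
        paths.append(p)
    return paths
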