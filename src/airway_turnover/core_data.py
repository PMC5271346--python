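"""Count-table data model, readers, and relative-abundance rules.

The universal input is a taxon-by-sample count table (samples as rows,
taxa as columns) joined to per-sample metadata carrying the subject id,
collection day (days of age), outcome group, and optionally the total
bacterial load (log10 copies/reaction).  Everything downstream — alpha
diversity, within-subject turnover, and the longitudinal models — is
computed from these two objects.

Counts stay integers throughout; relative abundance (percent of the
sample's total) is always derived on demand because the count models
need the raw depths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTableError",
    "MetadataError",
    "TaxonCountTable",
    "SampleMetadata",
    "SubjectSeries",
    "read_count_table",
    "read_metadata",
    "relative_abundance",
    "collapse_rare",
    "build_subject_series",
    "RARE_LABEL",
]

#: Label of the pseudo-taxon that aggregates consistently-rare taxa.
RARE_LABEL = "rare"


class CountTableError(ValueError):
    """Raised when a count table violates its invariants or cannot be parsed."""


class MetadataError(ValueError):
    """Raised when sample metadata is malformed or inconsistent with a table."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TaxonCountTable:
    """Integer counts, samples x taxa.

    Invariants (enforced on construction): unique sample and taxon ids,
    all counts non-negative integers, every sample row sum > 0.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    #: True for taxa produced by :func:`collapse_rare` (the "rare" column).
    rare_flags: list[bool] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise CountTableError("counts must be a 2-D matrix (samples x taxa)")
        if counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise CountTableError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise CountTableError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise CountTableError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"taxon {self.taxon_ids[bad[1]]!r}"
            )
        dup = _duplicates(self.sample_ids)
        if dup:
            raise CountTableError(f"duplicate sample ids: {sorted(dup)}")
        dup = _duplicates(self.taxon_ids)
        if dup:
            raise CountTableError(f"duplicate taxon ids: {sorted(dup)}")
        empty = np.flatnonzero(counts.sum(axis=1) == 0)
        if empty.size:
            names = [self.sample_ids[i] for i in empty]
            raise CountTableError(f"samples with zero total counts: {names}")
        self.counts = counts
        if self.rare_flags is None:
            self.rare_flags = [False] * len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_totals(self) -> np.ndarray:
        """Per-sample sequencing depth (row sums)."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def write_tsv(self, path, header_comment: str | None = None) -> None:
        """Write as TSV: first column ``sample_id``, header row of taxon ids."""
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("sample_id\t" + "\t".join(self.taxon_ids) + "\n")
            for sid, row in zip(self.sample_ids, self.counts):
                fh.write(sid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


@dataclass
class SampleMetadata:
    """Per-sample annotations joining samples to subjects.

    ``frame`` is indexed by sample_id with columns ``subject_id``,
    ``collection_day`` (integer days of age), ``group`` (categorical outcome
    label) and optionally ``bacterial_load_log10``.
    """

    frame: pd.DataFrame
    group_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"subject_id", "collection_day", "group"}
        missing = required - set(self.frame.columns)
        if missing:
            raise MetadataError(f"metadata missing required columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].tolist()
            raise MetadataError(f"duplicate sample ids in metadata: {dups}")
        days = self.frame["collection_day"]
        if (days < 0).any():
            bad = self.frame.index[days < 0].tolist()
            raise MetadataError(f"negative collection_day for samples: {bad}")
        if not self.group_labels:
            self.group_labels = tuple(pd.unique(self.frame["group"]))
        unknown = set(self.frame["group"]) - set(self.group_labels)
        if unknown:
            raise MetadataError(
                f"group labels {sorted(unknown)} not in declared set {self.group_labels}"
            )

    @property
    def has_load(self) -> bool:
        return "bacterial_load_log10" in self.frame.columns and (
            self.frame["bacterial_load_log10"].notna().any()
        )

    def write_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.frame.rename_axis("sample_id").to_csv(fh)


@dataclass
class SubjectSeries:
    """One subject's time-ordered samples over a shared taxon index.

    This is the unit over which the multi-sample Shannon beta diversity and
    the pairwise Morisita-Horn turnover statistics are computed.
    """

    subject_id: str
    group: str
    days: np.ndarray  # strictly increasing collection days
    counts: np.ndarray  # (n_samples, n_taxa)
    taxon_ids: list[str]
    sample_ids: list[str] = None  # type: ignore[assignment]
    load_log10: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.days) == 0:
            raise CountTableError(f"subject {self.subject_id}: empty series")
        if len(self.days) != self.counts.shape[0]:
            raise CountTableError(f"subject {self.subject_id}: days/counts mismatch")
        if np.any(np.diff(self.days) <= 0):
            raise CountTableError(
                f"subject {self.subject_id}: collection days must be strictly increasing"
            )
        if self.sample_ids is None:
            self.sample_ids = [f"{self.subject_id}_d{d}" for d in self.days]

    @property
    def n_samples(self) -> int:
        return len(self.days)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_count_table(path, format_name: str = "tsv", transposed: bool = False) -> TaxonCountTable:
    """Read a taxon count table from ``tsv`` or ``biom`` (BIOM 1.0 JSON).

    The TSV dialect is: first column sample id, header row of taxon ids,
    one row per sample.  A taxa-as-rows file is read only when
    ``transposed=True`` is passed explicitly; the orientation is never
    guessed.  Comment lines starting with ``#`` are skipped.
    """
    if format_name == "tsv":
        return _read_tsv(path, transposed=transposed)
    if format_name == "biom":
        return _read_biom_json(path)
    raise CountTableError(f"unknown count-table format {format_name!r} (use 'tsv' or 'biom')")


def _read_tsv(path, transposed: bool = False) -> TaxonCountTable:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CountTableError(f"cannot parse {path}: {exc}") from exc
    if frame.empty:
        raise CountTableError(f"{path}: no data rows")
    for col in frame.columns:
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            bad = frame.index[vals.isna()][0]
            raise CountTableError(
                f"{path}: non-numeric count in column {col!r}, row {bad!r}"
            )
        frame[col] = vals
    values = frame.to_numpy()
    if not np.allclose(values, np.round(values)):
        idx = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise CountTableError(
            f"{path}: non-integer count at row {frame.index[idx[0]]!r}, "
            f"column {frame.columns[idx[1]]!r}"
        )
    if transposed:
        frame = frame.T
    return TaxonCountTable(
        sample_ids=list(frame.index),
        taxon_ids=list(frame.columns),
        counts=frame.to_numpy(),
    )


def _read_biom_json(path) -> TaxonCountTable:
    """Minimal reader for the BIOM 1.0 JSON sparse/dense OTU-table format."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        n_rows, n_cols = doc["shape"]
        mat_type = doc["matrix_type"]
        data = doc["data"]
    except KeyError as exc:
        raise CountTableError(f"{path}: not a BIOM 1.0 JSON table (missing {exc})") from exc
    counts = np.zeros((n_rows, n_cols), dtype=np.int64)
    if mat_type == "sparse":
        for row, col, val in data:
            counts[row, col] = val
    elif mat_type == "dense":
        counts = np.asarray(data, dtype=np.int64)
    else:
        raise CountTableError(f"{path}: unsupported matrix_type {mat_type!r}")
    # BIOM stores observations (taxa) as rows; our convention is samples x taxa.
    return TaxonCountTable(sample_ids=samples, taxon_ids=taxa, counts=counts.T)


def read_metadata(path, group_labels: tuple[str, ...] = ()) -> SampleMetadata:
    """Read a sample metadata CSV (columns: sample_id, subject_id,
    collection_day, group[, bacterial_load_log10])."""
    frame = pd.read_csv(path, comment="#", dtype={"sample_id": str, "subject_id": str})
    if "sample_id" not in frame.columns:
        raise MetadataError(f"{path}: missing sample_id column")
    frame = frame.set_index("sample_id")
    return SampleMetadata(frame=frame, group_labels=tuple(group_labels))


# ---------------------------------------------------------------------------
# Relative abundance and the rare-taxon rule
# ---------------------------------------------------------------------------


def relative_abundance(table: TaxonCountTable) -> np.ndarray:
    """Percent relative abundance: count / sample total * 100, per sample.

    Each row of the result sums to 100 within numerical tolerance.
    """
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(totals == 0)]
        raise CountTableError(f"zero total count for samples: {bad}")
    return table.counts / totals[:, None] * 100.0


def collapse_rare(table: TaxonCountTable, threshold_pct: float = 1.0) -> TaxonCountTable:
    """Aggregate consistently-rare taxa into a single ``rare`` pseudo-taxon.

    A taxon is rare when its relative abundance is below ``threshold_pct``
    in *every* sample; rare taxa are summed into one column appended last
    and flagged, so diversity statistics may treat it as an ordinary taxon.
    Per-sample totals are conserved exactly (integer arithmetic).
    """
    if threshold_pct <= 0:
        raise ValueError("threshold_pct must be positive")
    ra = relative_abundance(table)
    rare_mask = (ra < threshold_pct).all(axis=0)
    if not rare_mask.any():
        return table
    keep = ~rare_mask
    rare_col = table.counts[:, rare_mask].sum(axis=1)
    counts = np.column_stack([table.counts[:, keep], rare_col])
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k] + [RARE_LABEL]
    flags = [f for f, k in zip(table.rare_flags, keep) if k] + [True]
    return TaxonCountTable(
        sample_ids=list(table.sample_ids), taxon_ids=taxa, counts=counts, rare_flags=flags
    )


# ---------------------------------------------------------------------------
# Subject series construction
# ---------------------------------------------------------------------------


def build_subject_series(
    table: TaxonCountTable,
    metadata: SampleMetadata,
    min_samples: int = 2,
) -> list[SubjectSeries]:
    """Partition the table's samples into per-subject time-ordered series.

    Every sample in the table must appear in the metadata; two samples of
    one subject on the same day are rejected (the turnover statistics
    assume distinct time points).  Subjects with fewer than ``min_samples``
    samples are dropped (default 2: turnover needs at least a pair).
    """
    meta = metadata.frame
    orphans = [s for s in table.sample_ids if s not in meta.index]
    if orphans:
        raise MetadataError(f"samples missing from metadata: {orphans}")
    sample_pos = {s: i for i, s in enumerate(table.sample_ids)}
    series: list[SubjectSeries] = []
    sub = meta.loc[table.sample_ids]
    for subject_id, rows in sub.groupby("subject_id", sort=False):
        days = rows["collection_day"].to_numpy()
        if len(np.unique(days)) != len(days):
            dup_day = int(pd.Series(days).mode().iloc[0])
            raise MetadataError(
                f"subject {subject_id}: multiple samples on day {dup_day} "
                "(ambiguous ordering)"
            )
        order = np.argsort(days)
        sids = [rows.index[i] for i in order]
        idx = [sample_pos[s] for s in sids]
        groups = rows["group"].unique()
        if len(groups) > 1:
            raise MetadataError(f"subject {subject_id}: inconsistent group labels {groups}")
        load = None
        if "bacterial_load_log10" in rows.columns:
            load = rows["bacterial_load_log10"].to_numpy()[order]
        s = SubjectSeries(
            subject_id=str(subject_id),
            group=str(groups[0]),
            days=days[order],
            counts=table.counts[idx],
            taxon_ids=list(table.taxon_ids),
            sample_ids=sids,
            load_log10=load,
        )
        if s.n_samples >= min_samples:
            series.append(s)
    return series


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup
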