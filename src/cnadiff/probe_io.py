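"""Readers and writers for the on-disk artifacts of the pipeline.

Three table families are supported:

* probe tables — tab-delimited two-channel array extractions (one row per
  oligonucleotide probe, with raw test/reference intensities and GC fraction),
  1-based inclusive coordinates on disk;
* SEG tables — the standard 6-column IGV segment format, 1-based inclusive;
* BED-like annotation tables (cytobands, genes), 0-based half-open.

Internally all coordinates are uniformly 0-based half-open; the converters at
the file boundary own the off-by-one bookkeeping.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

#: Canonical autosome + sex chromosome order; unknown names sort after these,
#: lexicographically.
DEFAULT_CHROM_ORDER: tuple[str, ...] = tuple(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
)

PROBE_COLUMNS = (
    "probe_id",
    "chrom",
    "start",
    "end",
    "intensity_test",
    "intensity_ref",
    "gc",
)

SEG_COLUMNS = ("ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean")


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class EmptyInputError(ValueError):
    """The input file contains no data rows."""


def chrom_sort_key(chrom_order: tuple[str, ...] | list[str]):
    """Return a callable mapping chromosome names to sortable tuples."""
    rank = {c: i for i, c in enumerate(chrom_order)}
    n = len(chrom_order)

    def key(chrom: str):
        return (rank.get(chrom, n), chrom)

    return key


def sort_genome_order(df: pd.DataFrame, chrom_order) -> pd.DataFrame:
    key = chrom_sort_key(chrom_order)
    ranks = df["chrom"].map(lambda c: key(c))
    order = sorted(range(len(df)), key=lambda i: (ranks.iloc[i], df["start"].iloc[i]))
    return df.iloc[order].reset_index(drop=True)


@dataclass
class ProbeSet:
    """Genome-ordered probe-level raw intensities for one hybridization.

    ``probes`` holds one row per probe with columns :data:`PROBE_COLUMNS`
    (coordinates 0-based half-open). ``steps`` records which normalization
    steps have been applied to the channels, in order.
    """

    sample_id: str
    probes: pd.DataFrame
    chrom_order: tuple[str, ...] = DEFAULT_CHROM_ORDER
    n_dropped: int = 0
    steps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in PROBE_COLUMNS if c not in self.probes.columns]
        if missing:
            raise SchemaError(f"probe table missing columns: {missing}")
        if self.probes["probe_id"].duplicated().any():
            dupes = self.probes.loc[self.probes["probe_id"].duplicated(), "probe_id"]
            raise ValueError(f"duplicate probe ids, e.g. {dupes.iloc[0]!r}")

    def __len__(self) -> int:
        return len(self.probes)

    def copy(self) -> "ProbeSet":
        return replace(self, probes=self.probes.copy(), steps=list(self.steps))

    def equals(self, other: "ProbeSet", atol: float = 0.0) -> bool:
        if self.sample_id != other.sample_id or len(self) != len(other):
            return False
        a, b = self.probes, other.probes
        if not (
            a["probe_id"].tolist() == b["probe_id"].tolist()
            and a["chrom"].tolist() == b["chrom"].tolist()
            and (a["start"].to_numpy() == b["start"].to_numpy()).all()
            and (a["end"].to_numpy() == b["end"].to_numpy()).all()
        ):
            return False
        for col in ("intensity_test", "intensity_ref", "gc"):
            if not np.allclose(a[col].to_numpy(), b[col].to_numpy(), atol=atol, rtol=1e-9):
                return False
        return True


def read_probe_table(
    path,
    schema: dict[str, str] | None = None,
    sample_id: str | None = None,
    chrom_order=DEFAULT_CHROM_ORDER,
) -> ProbeSet:
    """Read a tab-delimited probe table into a genome-sorted :class:`ProbeSet`.

    ``schema`` maps the canonical column names (:data:`PROBE_COLUMNS`) to the
    file's header names; identity mapping by default.  Rows with non-positive
    intensities or missing coordinates are dropped and counted in
    ``ProbeSet.n_dropped``.  On-disk coordinates are 1-based inclusive.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise EmptyInputError(f"no data rows in {path!r}")
    schema = schema or {}
    rename = {schema.get(c, c): c for c in PROBE_COLUMNS}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise SchemaError(f"columns not found in {path!r}: {missing}")
    df = df.rename(columns=rename)[list(PROBE_COLUMNS)]

    n0 = len(df)
    df = df.dropna(subset=["chrom", "start", "end", "intensity_test", "intensity_ref"])
    df = df[(df["intensity_test"] > 0) & (df["intensity_ref"] > 0)]
    n_dropped = n0 - len(df)
    if df.empty:
        raise EmptyInputError(f"all {n0} rows dropped from {path!r}")

    df = df.astype(
        {"start": np.int64, "end": np.int64, "intensity_test": float,
         "intensity_ref": float, "gc": float}
    )
    # 1-based inclusive on disk -> 0-based half-open in memory.
    df["start"] = df["start"] - 1
    df = sort_genome_order(df, chrom_order)
    if sample_id is None:
        sample_id = str(getattr(path, "stem", path))
    return ProbeSet(sample_id, df, tuple(chrom_order), n_dropped=n_dropped)


def write_probe_table(probeset: ProbeSet, path) -> None:
    """Write a probe table (1-based inclusive coordinates, 6-decimal floats)."""
    df = probeset.probes.copy()
    df["start"] = df["start"] + 1
    for col in ("intensity_test", "intensity_ref", "gc"):
        df[col] = df[col].map(lambda v: f"{v:.6f}")
    df.to_csv(path, sep="\t", index=False)


def write_seg(profile, path, extra_call_column: bool = True) -> None:
    """Write a segmented profile as a standard IGV SEG table.

    Columns ``ID chrom loc.start loc.end num.mark seg.mean`` with 1-based
    inclusive coordinates; if the profile carries gain/neutral/loss calls a
    seventh ``call`` column is appended (documented extension).
    """
    segments = profile.segments
    if not segments:
        raise ValueError("profile has no segments")
    calls = getattr(profile, "calls", None)
    rows = []
    for i, seg in enumerate(segments):
        row = {
            "ID": profile.sample_id,
            "chrom": seg.chrom,
            "loc.start": seg.start + 1,
            "loc.end": seg.end,
            "num.mark": seg.n_probes,
            "seg.mean": f"{seg.mean:.6f}",
        }
        if calls is not None and extra_call_column:
            row["call"] = calls[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    """Read a SEG table back into a DataFrame (0-based half-open coordinates)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"SEG file missing columns: {missing}")
    df = df.rename(
        columns={"ID": "sample_id", "loc.start": "start", "loc.end": "end",
                 "num.mark": "n_probes", "seg.mean": "mean"}
    )
    df["start"] = df["start"].astype(np.int64) - 1
    df["end"] = df["end"].astype(np.int64)
    df["mean"] = df["mean"].astype(float)
    return df


@dataclass
class GenomeAnnotation:
    """Cytoband and gene interval tables with point/range lookup.

    Intervals are stored 0-based half-open in per-chromosome
    :class:`~intervaltree.IntervalTree` objects; overlapping intervals are all
    retained and all returned by queries.
    """

    cytobands: dict[str, IntervalTree] = field(default_factory=dict)
    genes: dict[str, IntervalTree] = field(default_factory=dict)

    def _trees(self, kind: str) -> dict[str, IntervalTree]:
        if kind == "cytoband":
            return self.cytobands
        if kind == "gene":
            return self.genes
        raise ValueError(f"unknown annotation kind {kind!r}")

    def overlapping(self, kind: str, chrom: str, start: int, end: int) -> list[tuple[int, int, str]]:
        """All ``kind`` intervals overlapping [start, end) on ``chrom`` by >= 1 bp."""
        tree = self._trees(kind).get(chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(start, end))
        return [(iv.begin, iv.end, iv.data) for iv in hits]

    def names(self, kind: str, chrom: str, start: int, end: int) -> list[str]:
        return [name for _, _, name in self.overlapping(kind, chrom, start, end)]

    def all_intervals(self, kind: str) -> list[tuple[str, int, int, str]]:
        out = []
        for chrom, tree in self._trees(kind).items():
            out.extend((chrom, iv.begin, iv.end, iv.data) for iv in tree)
        return sorted(out)

    def merged_with(self, other: "GenomeAnnotation") -> "GenomeAnnotation":
        merged = GenomeAnnotation(dict(self.cytobands), dict(self.genes))
        merged.cytobands.update(other.cytobands)
        merged.genes.update(other.genes)
        return merged


def read_annotation_bed(path, kind: str) -> GenomeAnnotation:
    """Read a BED4 table (0-based half-open) into a :class:`GenomeAnnotation` slice.

    ``kind`` selects which slot ("cytoband" or "gene") the intervals populate.
    An empty file yields an empty annotation; a malformed coordinate raises a
    :class:`ValueError` naming the offending line.
    """
    ann = GenomeAnnotation()
    trees = ann._trees(kind)
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns, got {len(fields)}")
        chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed coordinate ({start_s!r}, {end_s!r})") from exc
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
        trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    return ann


def load_annotation(cytoband_path=None, gene_path=None) -> GenomeAnnotation:
    """Load cytoband and/or gene BED tables into one annotation object."""
    ann = GenomeAnnotation()
    if cytoband_path is not None:
        ann = ann.merged_with(read_annotation_bed(cytoband_path, "cytoband"))
    if gene_path is not None:
        ann = ann.merged_with(read_annotation_bed(gene_path, "gene"))
    return ann
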