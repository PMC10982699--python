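"""Interval and coverage file formats for strand-resolved nascent-chromatin analysis.

All coordinates are 0-based, half-open (BED convention). The two reference
strands are named Watson (``W``, BED ``+``) and Crick (``C``, BED ``-``)
throughout; nascent-DNA fragment strand identity encodes which daughter
strand the fragment derives from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("espan")

WATSON = "W"
CRICK = "C"
#: BED strand column -> internal strand label ("−" tolerated from copy-paste)
_BED_STRAND = {"+": WATSON, "-": CRICK, "−": CRICK}

VALID_MARKS = ("BrdU", "H3K4me3", "H3K9me3", "H3K56ac")
#: histone class each mark reports: parental (recycled) vs new tetramers
PARENTAL_MARKS = ("H3K4me3", "H3K9me3")
NEW_MARKS = ("H3K56ac",)


class EspanError(Exception):
    """Base class for all package errors."""


class ParseError(EspanError):
    """A file could not be parsed (malformed record)."""


class ValidationError(EspanError):
    """A record violates coordinate or contract constraints."""


class ConfigError(EspanError):
    """Invalid configuration parameter."""


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome names and lengths; the coordinate authority.

    Every interval handled downstream must lie within ``[0, length)`` of a
    declared chromosome; readers reject out-of-range records rather than
    clamping them.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ConfigError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ConfigError("duplicate chromosome names")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if int(length) < 1:
                raise ConfigError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise ValidationError(f"chromosome {chrom!r} not declared in genome") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeSpec":
        """Read a two-column ``chrom.sizes`` TSV."""
        names: list[str] = []
        lengths: list[int] = []
        for i, line in enumerate(_data_lines(path), start=1):
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{i}: expected 'chrom<TAB>length', got {line!r}")
            try:
                length = int(parts[1])
            except ValueError:
                raise ParseError(f"{path}:{i}: non-integer length {parts[1]!r}") from None
            names.append(parts[0])
            lengths.append(length)
        return cls(tuple(names), tuple(lengths))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.chrom_names, self.chrom_lengths):
                fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# Origins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Origin:
    chrom: str
    position: int  # 0-based bp point
    origin_id: str


@dataclass(frozen=True)
class OriginSet:
    """Replication origins as points, sorted by (chrom, position)."""

    origins: tuple[Origin, ...]
    provenance_label: str = ""

    def __post_init__(self) -> None:
        ids = [o.origin_id for o in self.origins]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate origin ids: {dup}")
        key = [(o.chrom, o.position) for o in self.origins]
        if key != sorted(key):
            raise ValidationError("origins not sorted by (chrom, position)")

    def __len__(self) -> int:
        return len(self.origins)

    def __iter__(self):
        return iter(self.origins)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, str]], provenance_label: str = ""
    ) -> "OriginSet":
        origins = sorted(
            (Origin(c, int(p), str(i)) for c, p, i in records),
            key=lambda o: (o.chrom, o.position),
        )
        return cls(tuple(origins), provenance_label)

    def validate(self, genome: GenomeSpec) -> "OriginSet":
        for o in self.origins:
            n = genome.length_of(o.chrom)
            if not (0 <= o.position < n):
                raise ValidationError(
                    f"origin {o.origin_id!r} at {o.chrom}:{o.position} outside [0, {n})"
                )
        return self

    def subset(self, keep_ids: Sequence[str]) -> "OriginSet":
        keep = set(keep_ids)
        return OriginSet(
            tuple(o for o in self.origins if o.origin_id in keep), self.provenance_label
        )

    def to_bed(self, path: str | Path, point: bool = True) -> None:
        """Write origins as 1-bp BED intervals at the point position."""
        with open(path, "w") as fh:
            for o in self.origins:
                fh.write(f"{o.chrom}\t{o.position}\t{o.position + 1}\t{o.origin_id}\n")


def read_origins(path: str | Path, genome: GenomeSpec, provenance_label: str = "") -> OriginSet:
    """Read a BED3+ origin file; each interval becomes its midpoint.

    The point is ``floor((start+end)/2)``. Names come from the BED name
    column when present, else ``origin_<k>`` by record index. Records are
    sorted; empty intervals and off-chromosome records are rejected.
    """
    records: list[tuple[str, int, str]] = []
    for k, (i, line) in enumerate(_numbered_data_lines(path), start=1):
        parts = line.split()
        if len(parts) < 3:
            raise ParseError(f"{path}:{i}: BED needs >=3 columns, got {line!r}")
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise ParseError(f"{path}:{i}: non-integer coordinates in {line!r}") from None
        if end <= start:
            raise ParseError(f"{path}:{i}: empty or inverted interval [{start}, {end})")
        n = genome.length_of(chrom)
        if start < 0 or end > n:
            raise ValidationError(
                f"{path}:{i}: interval {chrom}:{start}-{end} outside [0, {n})"
            )
        name = parts[3] if len(parts) >= 4 else f"origin_{k}"
        records.append((chrom, (start + end) // 2, name))
    origins = OriginSet.from_records(records, provenance_label or str(path))
    logger.info("read %d origins from %s", len(origins), path)
    return origins.validate(genome)


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

@dataclass
class StrandedFragmentSet:
    """Aligned, deduplicated nascent-DNA fragments with strand labels.

    ``fragments`` is a DataFrame with columns ``chrom`` (str), ``start``,
    ``end`` (0-based half-open int) and ``strand`` (``"W"``/``"C"``).
    One set per sequencing sample: either a BrdU input or a histone-mark
    eSPAN immunoprecipitation.
    """

    sample_id: str
    genotype_label: str
    mark: str
    fragments: pd.DataFrame

    def __post_init__(self) -> None:
        if self.mark not in VALID_MARKS:
            raise ValidationError(f"unknown mark {self.mark!r}; expected one of {VALID_MARKS}")
        cols = {"chrom", "start", "end", "strand"}
        if not cols.issubset(self.fragments.columns):
            raise ValidationError(f"fragment table missing columns {cols - set(self.fragments.columns)}")

    def __len__(self) -> int:
        return len(self.fragments)

    def validate(self, genome: GenomeSpec) -> "StrandedFragmentSet":
        f = self.fragments
        bad_strand = ~f["strand"].isin([WATSON, CRICK])
        if bad_strand.any():
            idx = int(np.flatnonzero(bad_strand.to_numpy())[0])
            raise ValidationError(
                f"sample {self.sample_id!r}: invalid strand {f['strand'].iloc[idx]!r} at record {idx}"
            )
        for chrom, sub in f.groupby("chrom", sort=False, observed=True):
            n = genome.length_of(str(chrom))
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            bad = (starts < 0) | (ends > n) | (starts >= ends)
            if bad.any():
                j = sub.index[np.flatnonzero(bad)[0]]
                raise ValidationError(
                    f"sample {self.sample_id!r}: fragment {chrom}:{starts[np.flatnonzero(bad)[0]]}-"
                    f"{ends[np.flatnonzero(bad)[0]]} (record {j}) violates [0, {n})"
                )
        return self

    def to_bed(self, path: str | Path) -> None:
        """Write BED6; W -> ``+``, C -> ``-``; name column is ``.``."""
        f = self.fragments
        out = pd.DataFrame(
            {
                "chrom": np.asarray(f["chrom"]),
                "start": f["start"].to_numpy(),
                "end": f["end"].to_numpy(),
                "name": ".",
                "score": 0,
                "strand": np.where(np.asarray(f["strand"]) == WATSON, "+", "-"),
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)


def read_fragments(
    path: str | Path,
    genome: GenomeSpec,
    sample_id: str,
    genotype_label: str,
    mark: str,
) -> StrandedFragmentSet:
    """Read a BED6 fragment file into a validated :class:`StrandedFragmentSet`.

    The strand column must be ``+`` (Watson) or ``-`` (Crick); ``.`` is
    rejected with the offending record index.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    for k, (i, line) in enumerate(_numbered_data_lines(path), start=1):
        parts = line.split()
        if len(parts) < 6:
            raise ParseError(f"{path}:{i}: BED6 needs 6 columns, got {line!r}")
        strand = _BED_STRAND.get(parts[5])
        if strand is None:
            raise ParseError(
                f"{path}:{i}: record {k} has strand {parts[5]!r}; expected '+' or '-'"
            )
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise ParseError(f"{path}:{i}: non-integer coordinates in {line!r}") from None
        chroms.append(parts[0])
        starts.append(start)
        ends.append(end)
        strands.append(strand)
    frags = pd.DataFrame(
        {
            "chrom": pd.array(chroms, dtype=str),
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
            "strand": pd.array(strands, dtype=str),
        }
    )
    fs = StrandedFragmentSet(sample_id, genotype_label, mark, frags).validate(genome)
    if len(fs) == 0:
        logger.warning("sample %s: empty fragment file %s", sample_id, path)
    logger.info("read %d fragments for sample %s from %s", len(fs), sample_id, path)
    return fs


# ---------------------------------------------------------------------------
# BedGraph (strand coverage serialization)
# ---------------------------------------------------------------------------

def write_bedgraph_vector(vec: np.ndarray, chrom: str, fh) -> None:
    v = np.asarray(vec)
    if len(v) == 0:
        return
    # run boundaries where the value changes
    change = np.flatnonzero(v[1:] != v[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(v)]))
    for s, e in zip(starts, ends):
        val = v[s]
        if val == 0:
            continue
        txt = repr(float(val)) if not float(val).is_integer() else str(int(val))
        fh.write(f"{chrom}\t{s}\t{e}\t{txt}\n")


def write_bedgraph(cov, path_w: str | Path, path_c: str | Path) -> None:
    """Write run-length-encoded BedGraph per strand; zero runs are omitted.

    Round-tripping through :func:`read_bedgraph` reproduces the coverage
    vectors exactly.
    """
    for path, vecs in ((path_w, cov.w), (path_c, cov.c)):
        with open(path, "w") as fh:
            for chrom in cov.genome.chrom_names:
                write_bedgraph_vector(vecs[chrom], chrom, fh)


def read_bedgraph(path: str | Path, genome: GenomeSpec) -> dict[str, np.ndarray]:
    """Read a BedGraph into dense per-chromosome vectors (absent bases are 0)."""
    vecs = {c: np.zeros(n, dtype=np.float64) for c, n in genome.lengths.items()}
    for i, line in enumerate(_data_lines(path), start=1):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{i}: BedGraph needs 4 columns, got {line!r}")
        chrom = parts[0]
        n = genome.length_of(chrom)
        try:
            start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
        except ValueError:
            raise ParseError(f"{path}:{i}: malformed record {line!r}") from None
        if not (0 <= start < end <= n):
            raise ValidationError(f"{path}:{i}: interval [{start}, {end}) outside [0, {n})")
        vecs[chrom][start:end] = value
    # collapse to int dtype when lossless
    for chrom, v in vecs.items():
        if np.all(v == np.floor(v)):
            vecs[chrom] = v.astype(np.int64)
    return vecs


# ---------------------------------------------------------------------------
# Matrix TSV (per-origin heatmap serialization)
# ---------------------------------------------------------------------------

def write_matrix(
    path: str | Path,
    row_labels: Sequence[str],
    col_centers: Sequence[int | float],
    values: np.ndarray,
) -> None:
    """Write a rectangular origins x bins matrix as TSV.

    Header row holds bin centers (bp relative to origin); each data row is an
    origin id followed by its values; NaN serialized as ``nan``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError(f"matrix must be 2-D, got shape {values.shape}")
    if values.shape != (len(row_labels), len(col_centers)):
        raise ValidationError(
            f"matrix shape {values.shape} does not match {len(row_labels)} rows "
            f"x {len(col_centers)} cols"
        )
    df = pd.DataFrame(values, index=list(row_labels), columns=list(col_centers))
    df.index.name = "origin_id"
    df.to_csv(path, sep="\t", na_rep="nan", float_format="%.10g")


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read a matrix TSV back as (row_labels, col_centers, values)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    centers = np.asarray([float(c) for c in df.columns])
    return [str(r) for r in df.index], centers, df.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Optional BAM ingestion (thin converter; not part of the tested core)
# ---------------------------------------------------------------------------

def bam_to_bed6(bam_path: str | Path, bed_path: str | Path, min_mapq: int = 0) -> int:
    """Convert aligned reads in a BAM to BED6 fragment records.

    Thin convenience shim for users arriving from an aligner; upstream read
    processing (trimming, alignment, duplicate marking) is expected to have
    happened already. Returns the number of records written.
    """
    import pysam  # deferred: optional dependency

    n = 0
    with pysam.AlignmentFile(str(bam_path)) as bam, open(bed_path, "w") as out:
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            strand = "-" if read.is_reverse else "+"
            out.write(
                f"{read.reference_name}\t{read.reference_start}\t{read.reference_end}"
                f"\t{read.query_name}\t0\t{strand}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path):
    for _, line in _numbered_data_lines(path):
        yield line


def _numbered_data_lines(path: str | Path):
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    with open(p) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield i, line
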