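"""Readers/writers for the formats the pipeline touches, and the shared coordinate model.

All coordinates are 0-based half-open internally (BED-native); GFF3 is converted on
read.  ChIP-Exo signal is represented as stranded 5'-end counts: the position stored
for a read is its 5' end, i.e. ``start`` on the forward strand and ``end - 1`` on the
reverse strand.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "GenomeSequence",
    "TagTrack",
    "TssSet",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_tags",
    "write_tags_bedgraph",
    "read_gff_tss",
    "write_results",
    "read_results",
    "revcomp",
]

_VALID = set("ACGTN")


class FormatError(ValueError):
    """A file did not conform to the expected text format."""


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def centre(self) -> int:
        return (self.start + self.end - 1) // 2

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


class GenomeSequence:
    """Mapping chromosome -> uppercase sequence over {A,C,G,T,N}."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            s = seq.upper()
            s = "".join(c if c in _VALID else "N" for c in s)
            self._seqs[name] = s

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def items(self):
        return self._seqs.items()

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of an interval; reverse-complemented for '-' strand intervals."""
        seq = self._seqs[interval.chrom]
        if interval.end > len(seq):
            raise IndexError(
                f"interval [{interval.start}, {interval.end}) exceeds "
                f"{interval.chrom} length {len(seq)}"
            )
        s = seq[interval.start : interval.end]
        return revcomp(s) if interval.strand == "-" else s


class TagTrack:
    """Per-chromosome, per-strand sparse counts of read 5'-end positions."""

    def __init__(self) -> None:
        self._counts: dict[tuple[str, str], Counter] = {}
        self._arrays: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    def add(self, chrom: str, strand: str, pos: int, count: int = 1) -> None:
        if strand not in ("+", "-"):
            raise ValueError(f"invalid strand {strand!r}")
        if pos < 0:
            raise ValueError(f"negative position {pos}")
        if count < 1:
            raise ValueError("count must be >= 1")
        self._counts.setdefault((chrom, strand), Counter())[pos] += count
        self._arrays.pop((chrom, strand), None)

    def add_many(self, chrom: str, strand: str, positions: Iterable[int]) -> None:
        key = (chrom, strand)
        c = self._counts.setdefault(key, Counter())
        c.update(int(p) for p in positions)
        if any(p < 0 for p in c):
            raise ValueError("negative position")
        self._arrays.pop(key, None)

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._counts)

    def chroms(self) -> list[str]:
        return sorted({c for c, _ in self._counts})

    def total(self) -> int:
        return sum(sum(c.values()) for c in self._counts.values())

    def arrays(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (positions, counts) arrays for one chromosome/strand."""
        key = (chrom, strand)
        if key not in self._arrays:
            c = self._counts.get(key, Counter())
            pos = np.array(sorted(c), dtype=np.int64)
            cnt = np.array([c[p] for p in pos], dtype=np.int64)
            self._arrays[key] = (pos, cnt)
        return self._arrays[key]

    def count_in(self, chrom: str, strand: str, start: int, end: int) -> int:
        """Total tags with 5' end in [start, end) on one strand."""
        pos, cnt = self.arrays(chrom, strand)
        i, j = np.searchsorted(pos, [start, end])
        return int(cnt[i:j].sum())

    def count_window(self, chrom: str, start: int, end: int) -> int:
        """Total tags in [start, end) on both strands."""
        return self.count_in(chrom, "+", start, end) + self.count_in(chrom, "-", start, end)

    def positions_in(
        self, chrom: str, strand: str, start: int, end: int
    ) -> tuple[np.ndarray, np.ndarray]:
        pos, cnt = self.arrays(chrom, strand)
        i, j = np.searchsorted(pos, [start, end])
        return pos[i:j], cnt[i:j]


@dataclass
class TssSet:
    """Transcription start sites: (chrom, position, strand, gene id) records."""

    records: list[tuple[str, int, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def by_chrom(self) -> dict[str, list[tuple[int, str, str]]]:
        out: dict[str, list[tuple[int, str, str]]] = {}
        for chrom, pos, strand, gid in self.records:
            out.setdefault(chrom, []).append((pos, strand, gid))
        for v in out.values():
            v.sort()
        return out


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (multi-record) FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased and non-ACGT letters are mapped to N.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs[rec.id] = str(rec.seq)
    except (ValueError, AttributeError) as exc:  # pragma: no cover - Bio raises rarely
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc
    if not seqs:
        with open(path) as fh:
            first = fh.readline()
        if not first.startswith(">"):
            raise FormatError(f"{path} line 1: expected FASTA header, got {first[:40]!r}")
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_tags(
    path: str | Path,
    dialect: str = "bed6",
    reverse_path: str | Path | None = None,
) -> TagTrack:
    """Read stranded 5'-end tag positions.

    dialect "bed6": each row is one read; the stored position is the 5' end
    (``start`` on +, ``end - 1`` on -).  dialect "bedgraph_pair": ``path`` and
    ``reverse_path`` are forward/reverse bedGraph files of 5'-end counts.
    """
    track = TagTrack()
    if dialect == "bed6":
        rejected = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise FormatError(f"{path} line {lineno}: expected >=6 BED fields")
                chrom, start, end, _name, _score, strand = parts[:6]
                start, end = int(start), int(end)
                if start < 0 or strand not in ("+", "-"):
                    rejected += 1
                    continue
                track.add(chrom, strand, start if strand == "+" else end - 1)
        if rejected:
            warnings.warn(f"{path}: rejected {rejected} rows (bad coordinate or strand)")
    elif dialect == "bedgraph_pair":
        if reverse_path is None:
            raise ValueError("bedgraph_pair dialect needs reverse_path")
        for p, strand in ((path, "+"), (reverse_path, "-")):
            with open(p) as fh:
                for lineno, line in enumerate(fh, 1):
                    line = line.rstrip("\n")
                    if not line or line.startswith(("#", "track")):
                        continue
                    parts = line.split("\t")
                    if len(parts) < 4:
                        raise FormatError(f"{p} line {lineno}: expected 4 bedGraph fields")
                    chrom, start, end, value = parts[:4]
                    start, end, value = int(start), int(end), int(float(value))
                    if value <= 0:
                        continue
                    for pos in range(start, end):
                        track.add(chrom, strand, pos, value)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return track


def write_tags_bedgraph(track: TagTrack, fwd_path: str | Path, rev_path: str | Path) -> None:
    """Write a TagTrack as a forward/reverse bedGraph pair of 5'-end counts."""
    for path, strand in ((fwd_path, "+"), (rev_path, "-")):
        with open(path, "w") as fh:
            for chrom in track.chroms():
                pos, cnt = track.arrays(chrom, strand)
                for p, c in zip(pos, cnt):
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t{c}\n")


def read_gff_tss(path: str | Path) -> TssSet:
    """Extract TSS positions from gene features of a GFF3 file.

    TSS = ``start`` (0-based) for + genes and ``end - 1`` for - genes; GFF3's
    1-based inclusive coordinates are converted on read.  Records without a
    usable strand are skipped with a warning.
    """
    records: list[tuple[str, int, str, str]] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
            if ftype != "gene":
                continue
            if strand not in ("+", "-"):
                skipped += 1
                continue
            start0 = int(start) - 1
            end0 = int(end)  # GFF end is 1-based inclusive == 0-based exclusive
            gid = "."
            for kv in attrs.split(";"):
                if kv.startswith(("ID=", "gene_id=")):
                    gid = kv.split("=", 1)[1]
                    break
            tss = start0 if strand == "+" else end0 - 1
            records.append((chrom, tss, strand, gid))
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} gene records without strand")
    return TssSet(records)


def write_results(records: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write a results table as TSV (with header) or BED (0-based half-open).

    BED output requires ``chrom``/``start``/``end`` columns; ``name``, ``score``
    and ``strand`` are used when present.
    """
    if format == "tsv":
        records.to_csv(path, sep="\t", index=False)
    elif format == "bed":
        cols = ["chrom", "start", "end"]
        missing = [c for c in cols if c not in records.columns]
        if missing:
            raise ValueError(f"BED output needs columns {missing}")
        df = records.copy()
        for c, default in (("name", "."), ("score", 0), ("strand", ".")):
            if c not in df.columns:
                df[c] = default
        df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            path, sep="\t", index=False, header=False
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
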