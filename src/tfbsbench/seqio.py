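"""Sequence and interval plumbing for ChIP-Seq peak analysis.

FASTA and peak-table readers/writers, IUPAC-aware strand operations, and
the peak filters used throughout the pipeline (coverage-height cut-off and
promoter-interval overlap).  Coordinates are 0-based half-open (BED
convention) everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "Interval",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "read_peak_table",
    "write_peak_table",
    "read_intervals",
    "filter_peaks_by_height",
    "overlap_filter",
    "reverse_complement",
    "encode",
    "decode",
    "matches_iupac",
    "IUPAC_SETS",
]

# Standard IUPAC nucleotide codes and their complements.
IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}
IUPAC_ALPHABET = frozenset(IUPAC_COMPLEMENT)

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMP_TABLE = str.maketrans(IUPAC_COMPLEMENT)

# A=0 C=1 G=2 T=3; every other IUPAC letter encodes to 4 ("unscorable").
_ENCODE = np.full(256, -1, dtype=np.int8)
for _c in IUPAC_ALPHABET:
    _ENCODE[ord(_c)] = 4
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
_DECODE = np.array(list("ACGTN"))


class FastaFormatError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


def _validate_seq(seq: str, context: str = "sequence") -> str:
    up = seq.upper()
    bad = set(up) - IUPAC_ALPHABET
    if bad:
        raise ValueError(
            f"invalid character {sorted(bad)[0]} in {context} "
            f"(allowed: IUPAC nucleotide codes)"
        )
    return up


@dataclass
class Peak:
    """One ChIP-Seq locus: sequence, summary coverage height, optional
    genomic coordinates and per-base coverage profile (the "peak shape")."""

    id: str
    seq: str
    height: float
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    profile: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"peak {self.id}: empty sequence")
        self.seq = _validate_seq(self.seq, f"peak {self.id}")
        if self.height < 0:
            raise ValueError(f"peak {self.id}: negative height")
        if (self.start is None) != (self.end is None):
            raise ValueError(f"peak {self.id}: start/end must come together")
        if self.start is not None and self.end - self.start != len(self.seq):
            raise ValueError(
                f"peak {self.id}: end - start != sequence length"
            )
        if self.profile is not None:
            if len(self.profile) != len(self.seq):
                raise ValueError(f"peak {self.id}: profile length mismatch")
            if min(self.profile) < 0:
                raise ValueError(f"peak {self.id}: negative profile value")
            if not math.isclose(max(self.profile), self.height, rel_tol=1e-9):
                raise ValueError(
                    f"peak {self.id}: max(profile) must equal height"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("interval requires start < end")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0 C=1 G=2 T=3, other IUPAC=4."""
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        pos = int(np.argmax(codes < 0))
        raise ValueError(f"invalid character {seq[pos]} at position {pos}")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(_DECODE[codes])


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet (an involution)."""
    up = _validate_seq(seq)
    return up.translate(_COMP_TABLE)[::-1]


def matches_iupac(seq: str, pattern: str) -> bool:
    """True iff `seq` matches the degenerate IUPAC `pattern` letterwise."""
    if len(seq) != len(pattern):
        return False
    return all(s in IUPAC_SETS[p] for s, p in zip(seq.upper(), pattern.upper()))


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly line-wrapped) FASTA file.

    Sequences are uppercased and validated against the IUPAC alphabet;
    malformed headers or empty records raise :class:`FastaFormatError`
    naming the line number.
    """
    records: list[tuple[str, str]] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        if not chunks:
            raise FastaFormatError(
                f"line {header_line}: record {header!r} has no sequence"
            )
        records.append((header, "".join(chunks)))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FastaFormatError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                try:
                    chunks.append(_validate_seq(line))
                except ValueError as exc:
                    raise FastaFormatError(f"line {lineno}: {exc}") from None
        flush()
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int | None = None) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            if width is None:
                fh.write(seq + "\n")
            else:
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def read_peak_table(path: str | Path, fasta_path: str | Path) -> list[Peak]:
    """Join a peak table with its companion FASTA.

    Accepts either a minimal 2-column TSV (id, height) or BED6+1
    (chrom, start, end, id, score, strand, height).  Every table row must
    have a sequence in the FASTA; missing ids are reported together.
    """
    seqs = dict(read_fasta(fasta_path))
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] == 2:
        df.columns = ["id", "height"]
        df["chrom"] = None
    elif df.shape[1] == 7:
        df.columns = ["chrom", "start", "end", "id", "score", "strand", "height"]
    else:
        raise ValueError(
            f"{path}: expected 2 (id, height) or 7 (BED6+1) columns, "
            f"got {df.shape[1]}"
        )
    missing = [i for i in df["id"] if i not in seqs]
    if missing:
        raise ValueError(f"peak ids missing from FASTA: {', '.join(missing)}")
    peaks = []
    for row in df.itertuples(index=False):
        kwargs = {}
        if row.chrom is not None:
            kwargs = {"chrom": row.chrom, "start": int(row.start),
                      "end": int(row.end)}
        peaks.append(Peak(id=row.id, seq=seqs[row.id],
                          height=float(row.height), **kwargs))
    return peaks


def write_peak_table(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write BED6+1 when coordinates are present, else a 2-column TSV."""
    with open(path, "w") as fh:
        for p in peaks:
            if p.chrom is not None:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\t0\t.\t"
                         f"{p.height:g}\n")
            else:
                fh.write(f"{p.id}\t{p.height:g}\n")


def read_intervals(path: str | Path) -> list[Interval]:
    """Read BED3/BED6 intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        strand = row[5] if df.shape[1] >= 6 else "."
        out.append(Interval(row[0], int(row[1]), int(row[2]), strand))
    return out


def filter_peaks_by_height(peaks: Sequence[Peak], min_height: float) -> list[Peak]:
    """Keep peaks with coverage height >= min_height, order preserved."""
    if min_height < 0:
        raise ValueError("min_height must be >= 0")
    return [p for p in peaks if p.height >= min_height]


def overlap_filter(peaks: Sequence[Peak], intervals: Sequence[Interval]) -> list[Peak]:
    """Keep peaks sharing >= 1 bp with any interval (half-open semantics).

    Peaks must carry genomic coordinates.
    """
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    kept = []
    for p in peaks:
        if p.chrom is None:
            raise ValueError(f"peak {p.id} has no genomic coordinates")
        for iv in by_chrom.get(p.chrom, ()):
            if p.start < iv.end and iv.start < p.end:
                kept.append(p)
                break
    return kept
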