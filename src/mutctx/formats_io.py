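"""Readers and writers for the plain-text formats the pipeline touches.

Formats: multi-record FASTA for reference sequences and clone sets, BED3
(0-based half-open) for exonic intervals, and tab-separated mutation tables in
two dialects — a minimal ``simple_tsv`` (sample, seq_name, pos, ref, alt) and a
``maf_like`` dialect mapping the usual MAF column names.

Coordinate convention: mutation tables are 1-based inclusive, as in MAF/VCF
practice.  :class:`MutationRecord` stores that 1-based position and exposes a
0-based ``pos0`` property; ``pos0`` is the single conversion point and every
internal computation uses it.  BED intervals are 0-based half-open throughout.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
ALPHABET = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file violates the format contract (not recoverable row-by-row)."""


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(COMPLEMENT)[::-1]


Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping/adjacent 0-based half-open intervals."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class ReferenceSet:
    """A named set of reference sequences with optional exonic intervals.

    ``sequences`` maps name -> uppercase string over {A,C,G,T,N}; ``intervals``
    (optional) maps name -> merged, sorted 0-based half-open intervals marking
    exonic regions.
    """

    sequences: dict[str, str]
    intervals: dict[str, list[Interval]] | None = None

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - ALPHABET
            if bad:
                raise FormatError(
                    f"sequence {name!r} contains letters outside A/C/G/T/N: {sorted(bad)}"
                )
        if self.intervals is not None:
            for name, ivs in self.intervals.items():
                if name not in self.sequences:
                    raise FormatError(f"intervals refer to unknown sequence {name!r}")
                n = len(self.sequences[name])
                merged = merge_intervals(ivs)
                for start, end in merged:
                    if not (0 <= start < end <= n):
                        raise FormatError(
                            f"interval ({start},{end}) outside [0,{n}) on {name!r}"
                        )
                self.intervals[name] = merged

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def base_at(self, name: str, pos0: int) -> str:
        return self.sequences[name][pos0]

    def window(self, name: str, pos0: int, flank: int) -> str | None:
        """The (2*flank+1)-mer centred on ``pos0``, or None if truncated."""
        seq = self.sequences[name]
        lo, hi = pos0 - flank, pos0 + flank + 1
        if lo < 0 or hi > len(seq):
            return None
        return seq[lo:hi]


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-nucleotide variant.

    ``pos`` is 1-based (the mutation-table convention); use ``pos0`` internally.
    """

    sample_id: str
    seq_name: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"ref/alt must be single A/C/G/T bases, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.seq_name}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")

    @property
    def pos0(self) -> int:
        """0-based position; the single 1-based -> 0-based conversion point."""
        return self.pos - 1

    def key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.seq_name, self.pos, self.ref, self.alt)

    def site_key(self) -> tuple[str, int, str, str]:
        return (self.seq_name, self.pos, self.ref, self.alt)


def _clean_sequence(name: str, raw: str) -> str:
    seq = raw.upper().replace("U", "T")
    if set(seq) - ALPHABET:
        bad = sorted(set(seq) - ALPHABET)
        logger.warning("sequence %r: mapping unknown letters %s to N", name, bad)
        seq = "".join(b if b in ALPHABET else "N" for b in seq)
    return seq


def read_fasta(path: str | Path) -> ReferenceSet:
    """Read a multi-record FASTA into a :class:`ReferenceSet`.

    Sequences are uppercased, U is mapped to T and any other non-A/C/G/T letter
    to N (with a logged warning).  Record order is preserved.  An empty file or
    a duplicate header raises :class:`FormatError`.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate FASTA header {rec.id!r} in {path}")
        sequences[rec.id] = _clean_sequence(rec.id, str(rec.seq))
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    return ReferenceSet(sequences=sequences)


def write_fasta(ref: ReferenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_SIMPLE_COLS = {"sample": "sample", "seq_name": "seq_name", "pos": "pos", "ref": "ref", "alt": "alt"}
_MAF_COLS = {
    "sample": "Tumor_Sample_Barcode",
    "seq_name": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
}


def read_mutation_table(
    path: str | Path,
    dialect: str = "simple_tsv",
    reference: ReferenceSet | None = None,
) -> tuple[list[MutationRecord], int]:
    """Read a tab-separated somatic mutation table.

    ``dialect`` is ``simple_tsv`` (columns sample, seq_name, pos, ref, alt) or
    ``maf_like`` (Tumor_Sample_Barcode / Chromosome / Start_Position /
    Reference_Allele / Tumor_Seq_Allele2; Tumor_Seq_Allele1 is ignored).

    Rows whose ref or alt is not a single A/C/G/T base (indels, MNVs, ``-``)
    are dropped; returns ``(records, n_dropped)``.  A missing required column
    raises :class:`FormatError`; a non-integer position raises with the
    offending line number.  When ``reference`` is given, each surviving row's
    ref base is checked against the sequence.
    """
    if dialect == "simple_tsv":
        colmap = _SIMPLE_COLS
    elif dialect == "maf_like":
        colmap = _MAF_COLS
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing} for dialect {dialect}")

    records: list[MutationRecord] = []
    dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        ref = str(d[colmap["ref"]]).upper()
        alt = str(d[colmap["alt"]]).upper()
        if ref not in VALID_BASES or alt not in VALID_BASES or ref == alt:
            dropped += 1
            continue
        raw_pos = d[colmap["pos"]]
        try:
            pos = int(raw_pos)
        except (TypeError, ValueError):
            raise FormatError(f"{path} line {i}: non-integer position {raw_pos!r}") from None
        rec = MutationRecord(
            sample_id=str(d[colmap["sample"]]),
            seq_name=str(d[colmap["seq_name"]]),
            pos=pos,
            ref=ref,
            alt=alt,
        )
        if reference is not None and rec.seq_name in reference:
            actual = reference.base_at(rec.seq_name, rec.pos0)
            if actual != rec.ref:
                raise FormatError(
                    f"{path} line {i}: ref {rec.ref} does not match reference "
                    f"base {actual} at {rec.seq_name}:{rec.pos}"
                )
        records.append(rec)
    if dropped:
        logger.info("read_mutation_table: dropped %d non-SNV row(s)", dropped)
    return records, dropped


def write_mutation_table(records: Sequence[MutationRecord], path: str | Path) -> None:
    """Write records in the ``simple_tsv`` dialect."""
    df = pd.DataFrame(
        [(r.sample_id, r.seq_name, r.pos, r.ref, r.alt) for r in records],
        columns=["sample", "seq_name", "pos", "ref", "alt"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_intervals(path: str | Path) -> dict[str, list[Interval]]:
    """Read a BED3 file into per-sequence sorted, merged interval lists."""
    out: dict[str, list[Interval]] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise FormatError(f"{path} line {lineno}: expected >=3 BED columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(f"{path} line {lineno}: non-integer coordinates") from None
        if end <= start:
            raise FormatError(f"{path} line {lineno}: end ({end}) <= start ({start})")
        out.setdefault(chrom, []).append((start, end))
    return {chrom: merge_intervals(ivs) for chrom, ivs in out.items()}


def write_intervals(intervals: dict[str, list[Interval]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in intervals:
            for start, end in intervals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")
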