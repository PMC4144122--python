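"""Substitution calling from per-clone sequences with a non-clonal filter.

Reporter-gene mutagenesis experiments (an EGFP transgene, bacterial rpoB, the
BCR-ABL1 imatinib-binding region) are read out by cloning an amplicon from a
cell population and Sanger-sequencing independent bacterial clones.  Clones
descended from the same mutated cell share its mutations, so a raw count
double-counts clonal expansions: the non-clonal filter counts each distinct
(position, ref, alt) once per population.  This deliberately *under*estimates
mutation load at preferred hotspots, where independent recurrences are folded
into one event.

Sequences arrive pre-aligned (equal length to the reference region); clones of
a different length — indel carriers — are excluded with a logged count, since
the analysis is restricted to point mutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

from mutctx.formats_io import ReferenceSet, read_fasta
from mutctx.spectrum import SpectrumTable, spectrum_counts
from mutctx.formats_io import MutationRecord

logger = logging.getLogger(__name__)

Call = tuple[int, str, str]  # (1-based pos, ref, alt)


@dataclass
class CloneSet:
    """Clone sequences from one cell population against one reference region."""

    population: str
    ref_name: str
    ref_seq: str
    clones: list[tuple[str, str]]  # (clone_id, sequence)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError("clone ids must be unique")
        for cid, seq in self.clones:
            if len(seq) != len(self.ref_seq):
                raise ValueError(
                    f"clone {cid!r} length {len(seq)} != reference length {len(self.ref_seq)}"
                )


@dataclass
class CloneMutationCalls:
    """Per-clone substitution calls for one population."""

    population: str
    ref_name: str
    per_clone: dict[str, list[Call]]
    bases_surveyed: int  # clones x region length, minus N positions
    nonclonal: list[Call] | None = None  # set after nonclonal_filter

    def all_calls(self) -> list[Call]:
        return [c for calls in self.per_clone.values() for c in calls]


def call_substitutions(clone_seq: str, ref_seq: str) -> tuple[list[Call], int]:
    """Mismatch calls between one clone and the reference -> (calls, unsurveyed).

    One call per mismatching position (1-based); positions where either base
    is N are skipped and counted as unsurveyed.
    """
    if len(clone_seq) != len(ref_seq):
        raise ValueError(
            "clone and reference lengths differ; align (and strip indels) upstream"
        )
    calls: list[Call] = []
    unsurveyed = 0
    for i, (r, c) in enumerate(zip(ref_seq, clone_seq)):
        if r == "N" or c == "N":
            unsurveyed += 1
            continue
        if r != c:
            calls.append((i + 1, r, c))
    return calls, unsurveyed


def call_clone_set(clone_set: CloneSet) -> CloneMutationCalls:
    """Call substitutions for every clone in a population."""
    per_clone: dict[str, list[Call]] = {}
    surveyed = 0
    for cid, seq in clone_set.clones:
        calls, unsurveyed = call_substitutions(seq, clone_set.ref_seq)
        per_clone[cid] = calls
        surveyed += len(clone_set.ref_seq) - unsurveyed
    return CloneMutationCalls(
        population=clone_set.population,
        ref_name=clone_set.ref_name,
        per_clone=per_clone,
        bases_surveyed=surveyed,
    )


def read_clone_set(
    ref_path: str | Path, clones_path: str | Path, population: str | None = None
) -> CloneSet:
    """Load a reference FASTA (single record) and a multi-FASTA of clones.

    Clones whose length differs from the reference (indel carriers) are
    excluded with a logged count.
    """
    ref = read_fasta(ref_path)
    if len(ref.sequences) != 1:
        raise ValueError("reference FASTA must hold exactly one region")
    (ref_name, ref_seq), = ref.sequences.items()
    clones_ref = read_fasta(clones_path)
    kept, excluded = [], 0
    for cid, seq in clones_ref.sequences.items():
        if len(seq) != len(ref_seq):
            excluded += 1
            continue
        kept.append((cid, seq))
    if excluded:
        logger.warning(
            "read_clone_set: excluded %d clone(s) with length != reference (indels)", excluded
        )
    return CloneSet(
        population=population or Path(clones_path).stem,
        ref_name=ref_name,
        ref_seq=ref_seq,
        clones=kept,
    )


def nonclonal_filter(calls: CloneMutationCalls) -> CloneMutationCalls:
    """Collapse clonal expansions: each distinct (pos, ref, alt) counted once.

    Clonality is defined per population; distinct co-occurring mutations in one
    clone are all retained.  Idempotent.
    """
    seen: set[Call] = set()
    nonclonal: list[Call] = []
    for calls_list in calls.per_clone.values():
        for c in calls_list:
            if c not in seen:
                seen.add(c)
                nonclonal.append(c)
    nonclonal.sort()
    return replace(calls, nonclonal=nonclonal)


def pattern_table(calls: CloneMutationCalls) -> tuple[SpectrumTable, float]:
    """Substitution spectrum of the non-clonal calls plus mutations per base.

    Mutation frequency = #non-clonal mutations / total bases surveyed.
    Requires :func:`nonclonal_filter` to have been applied.
    """
    if calls.nonclonal is None:
        raise ValueError("apply nonclonal_filter before building the pattern table")
    if calls.bases_surveyed <= 0:
        raise ValueError("zero surveyed bases")
    records = [
        MutationRecord(
            sample_id=calls.population, seq_name=calls.ref_name, pos=pos, ref=ref, alt=alt
        )
        for pos, ref, alt in calls.nonclonal
    ]
    table = spectrum_counts(records, group=calls.population, total_bases=calls.bases_surveyed)
    freq = len(calls.nonclonal) / calls.bases_surveyed
    return table, freq


def nonclonal_records(calls: CloneMutationCalls) -> list[MutationRecord]:
    """Non-clonal calls as MutationRecords, ready for context analysis."""
    if calls.nonclonal is None:
        raise ValueError("apply nonclonal_filter first")
    return [
        MutationRecord(
            sample_id=calls.population, seq_name=calls.ref_name, pos=pos, ref=ref, alt=alt
        )
        for pos, ref, alt in calls.nonclonal
    ]
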