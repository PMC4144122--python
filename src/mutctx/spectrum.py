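"""Substitution-class statistics.

Deduplication of recurrent calls within a sample, transition/transversion
classification, 12-class and strand-collapsed 6-class spectrum tables, and
two-group spectrum comparison (Fisher exact on a C/G-vs-A/T contingency table,
or chi-square over the 6-class vectors).

Duplicate policy: the same mutation reported twice by one tumor sample is one
event; identical mutations from *different* samples are independent events and
all retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from mutctx.formats_io import COMPLEMENT, MutationRecord, ReferenceSet, VALID_BASES

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: the six strand-collapsed (pyrimidine-reference) substitution classes
SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TWELVE_CLASSES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)


def _complement(base: str) -> str:
    return base.translate(COMPLEMENT)


def collapse_class(ref: str, alt: str) -> str:
    """Map a substitution to its pyrimidine-reference (6-class) label."""
    if ref in PURINES:
        ref, alt = _complement(ref), _complement(alt)
    return f"{ref}>{alt}"


@dataclass
class SpectrumTable:
    """Counts of each substitution class for one sample group."""

    group: str
    counts12: dict[str, int] = field(default_factory=lambda: {k: 0 for k in TWELVE_CLASSES})
    total_bases: int | None = None

    def __post_init__(self) -> None:
        full = {k: 0 for k in TWELVE_CLASSES}
        for k, v in self.counts12.items():
            if k not in full:
                raise ValueError(f"unknown substitution class {k!r}")
            if v < 0:
                raise ValueError(f"negative count for {k}")
            full[k] = int(v)
        self.counts12 = full

    @property
    def counts6(self) -> dict[str, int]:
        out = {k: 0 for k in SIX_CLASSES}
        for k, v in self.counts12.items():
            ref, alt = k.split(">")
            out[collapse_class(ref, alt)] += v
        return out

    @property
    def total(self) -> int:
        return sum(self.counts12.values())

    @property
    def cg_at_split(self) -> tuple[int, int]:
        """(mutations at C/G reference bases, mutations at A/T)."""
        cg = sum(v for k, v in self.counts12.items() if k[0] in "CG")
        return cg, self.total - cg


def dedupe_mutations(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Keep at most one record per (sample, seq, pos, ref, alt).

    Identical mutations from different samples are all retained; input order of
    first occurrences is preserved.  Idempotent.
    """
    seen: set[tuple] = set()
    out: list[MutationRecord] = []
    for rec in records:
        k = rec.key()
        if k not in seen:
            seen.add(k)
            out.append(rec)
    return out


def classify_change(ref: str, alt: str) -> str:
    """Classify a substitution as ``transition`` or ``transversion``."""
    if ref not in VALID_BASES or alt not in VALID_BASES:
        raise ValueError(f"bases must be A/C/G/T, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref equals alt; not a substitution")
    same_family = (ref in PURINES) == (alt in PURINES)
    return "transition" if same_family else "transversion"


def _oriented_plus1(rec: MutationRecord, ref: ReferenceSet) -> str | None:
    """The base 3' of the mutated base on the cytosine-oriented strand.

    Only meaningful for C/G-reference records; returns None when the neighbour
    is missing (sequence edge) or N.
    """
    seq = ref[rec.seq_name]
    if rec.ref == "C":
        i = rec.pos0 + 1
        nxt = seq[i] if i < len(seq) else None
    else:  # G: cytosine is on the minus strand; 3' neighbour is pos0-1 complemented
        i = rec.pos0 - 1
        nxt = _complement(seq[i]) if i >= 0 else None
    if nxt is None or nxt == "N":
        return None
    return nxt


def tstv_ratio(
    records: Sequence[MutationRecord],
    site_class: str = "all",
    ref: ReferenceSet | None = None,
) -> float:
    """Transition/transversion ratio, optionally restricted to CpG or CpH sites.

    Site classes are evaluated on the cytosine-oriented strand: a site is CpG
    when the +1 base is G, CpH otherwise; records not at a C/G reference base
    do not qualify for either, and sites whose +1 neighbour is N or missing are
    excluded.  Returns ``inf`` when there are transitions but no transversions;
    raises when no record qualifies.
    """
    if site_class not in ("all", "CpG", "CpH"):
        raise ValueError(f"unknown site_class {site_class!r}")
    if site_class != "all" and ref is None:
        raise ValueError("a ReferenceSet is required for CpG/CpH site classes")

    ts = tv = 0
    for rec in records:
        if site_class != "all":
            if rec.ref not in "CG":
                continue
            plus1 = _oriented_plus1(rec, ref)
            if plus1 is None:
                continue
            if site_class == "CpG" and plus1 != "G":
                continue
            if site_class == "CpH" and plus1 == "G":
                continue
        if classify_change(rec.ref, rec.alt) == "transition":
            ts += 1
        else:
            tv += 1
    if ts == 0 and tv == 0:
        raise ValueError(f"no qualifying records for site_class={site_class}")
    if tv == 0:
        return math.inf
    return ts / tv


def spectrum_counts(
    records: Sequence[MutationRecord],
    group: str = "all",
    total_bases: int | None = None,
) -> SpectrumTable:
    """Tally records into a 12-class spectrum (6-class derived by collapse)."""
    counts = {k: 0 for k in TWELVE_CLASSES}
    for rec in records:
        counts[f"{rec.ref}>{rec.alt}"] += 1
    return SpectrumTable(group=group, counts12=counts, total_bases=total_bases)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table -> (odds ratio, p).

    Two-sided p is the conventional sum over all tables with the fixed margins
    whose hypergeometric probability does not exceed the observed table's.
    """
    odds, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)


def compare_spectra(
    a: SpectrumTable, b: SpectrumTable, mode: str = "cg_vs_at"
) -> tuple[float, float]:
    """Compare two spectra -> (statistic, p-value).

    ``cg_vs_at`` builds the 2x2 table [mutations at C/G, at A/T] x [group a,
    group b] and runs a two-sided Fisher exact test (statistic = odds ratio);
    this is a reconstruction of a figure-level contingency layout and is
    labelled as such in CLI output.  ``full`` runs a chi-square test of
    homogeneity over the two 6-class vectors (statistic = chi-square), with a
    logged warning when any expected cell is below 5.
    """
    if a.total == 0 or b.total == 0:
        raise ValueError("both spectra must have nonzero totals")
    if mode == "cg_vs_at":
        table = [list(a.cg_at_split), list(b.cg_at_split)]
        return fisher_exact_2x2(table)
    if mode == "full":
        obs = np.array([
            [a.counts6[k] for k in SIX_CLASSES],
            [b.counts6[k] for k in SIX_CLASSES],
        ])
        keep = obs.sum(axis=0) > 0
        obs = obs[:, keep]
        chi2, p, dof, expected = stats.chi2_contingency(obs)
        if (expected < 5).any():
            logger.warning("compare_spectra(full): expected cell(s) < 5; chi-square approximate")
        return float(chi2), float(p)
    raise ValueError(f"unknown mode {mode!r}")


def reverse_complement_record(rec: MutationRecord) -> MutationRecord:
    """The same substitution written on the opposite strand (position kept)."""
    return MutationRecord(
        sample_id=rec.sample_id,
        seq_name=rec.seq_name,
        pos=rec.pos,
        ref=_complement(rec.ref),
        alt=_complement(rec.alt),
    )
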