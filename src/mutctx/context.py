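"""Local sequence context of mutations at cytosines, strand-collapsed.

This is the core analysis: every mutation whose reference base is C or G is
re-expressed on the strand where the mutated base is a cytosine (a G>A on the
plus strand becomes a C>T on the minus strand, its context window reverse
complemented), the surrounding (2*flank+1)-mer is extracted, and the observed
per-position base composition is compared against the background distribution
of cytosine contexts in the (exonic) reference.  Mutated cytosines are
stratified by CpG status — the base immediately 3' on the oriented strand —
because CpG transitions arise from deamination of methylated cytosine and
would otherwise swamp the deaminase signature, which lives at non-CpG sites
(AID/APOBEC enzymes prefer specific 5' neighbours, e.g. a thymine at -1 with
avoidance of adenine for APOBEC1).

Position convention: 0 is the mutated base, negative positions are 5' on the
oriented strand.  "Position -1" is the base directly upstream of the mutated C.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mutctx.formats_io import MutationRecord, ReferenceSet, revcomp

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
STRATA = ("all_C", "CpG", "non_CpG")


@dataclass(frozen=True)
class OrientedMutation:
    """A C/G mutation re-expressed on the strand where the mutated base is C."""

    source: MutationRecord
    strand: str  # '+' if the genomic ref base was C, '-' if G
    oriented_alt: str
    context: str  # (2*flank+1)-mer on the oriented strand, centre = C

    oriented_ref: str = "C"

    def __post_init__(self) -> None:
        flank, rem = divmod(len(self.context), 2)
        if rem != 1:
            raise ValueError("context length must be odd")
        if self.context[flank] != "C":
            raise ValueError(f"context centre must be C, got {self.context!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def flank(self) -> int:
        return len(self.context) // 2

    def base_at(self, position: int) -> str:
        """Base at an oriented-strand position (0 = mutated C, negative = 5')."""
        return self.context[self.flank + position]


def collapse_to_cytosine(
    record: MutationRecord, ref: ReferenceSet, flank: int = 1
) -> OrientedMutation | None:
    """Orient a C/G mutation so the mutated base reads as a cytosine.

    A record with ref C keeps its genomic window and strand '+'; a record with
    ref G takes the reverse complement of the window (and of its alt) and
    strand '-'.  Returns None, with a logged skip, when the context window
    runs off the sequence or contains N.  Records at A/T reference bases are a
    caller error — filter to C/G first.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if record.ref not in "CG":
        raise ValueError(
            f"context analysis applies to mutations at C/G only, got ref {record.ref}"
        )
    window = ref.window(record.seq_name, record.pos0, flank)
    if window is None or "N" in window:
        logger.debug(
            "skipping %s:%d (window truncated or contains N)", record.seq_name, record.pos
        )
        return None
    if record.ref == "C":
        return OrientedMutation(
            source=record, strand="+", oriented_alt=record.alt, context=window
        )
    return OrientedMutation(
        source=record,
        strand="-",
        oriented_alt=revcomp(record.alt),
        context=revcomp(window),
    )


def collapse_all(
    records: Iterable[MutationRecord], ref: ReferenceSet, flank: int = 1
) -> list[OrientedMutation]:
    """Collapse every C/G-reference record; A/T records and N/edge windows skipped."""
    out = []
    skipped_at = 0
    for rec in records:
        if rec.ref not in "CG":
            skipped_at += 1
            continue
        om = collapse_to_cytosine(rec, ref, flank)
        if om is not None:
            out.append(om)
    if skipped_at:
        logger.info("collapse_all: %d mutation(s) at A/T excluded from context analysis", skipped_at)
    return out


def classify_cpg(m: OrientedMutation) -> str:
    """``CpG`` when the oriented +1 base is G, else ``non_CpG``."""
    return "CpG" if m.base_at(+1) == "G" else "non_CpG"


def _iter_regions(ref: ReferenceSet, restrict_to_intervals: bool):
    """Yield (sequence, centre-position range) pairs honouring exon intervals.

    Interval restriction requires the *centre* cytosine inside a merged
    interval; flanking bases may extend outside it.
    """
    for name, seq in ref.sequences.items():
        if restrict_to_intervals and ref.intervals is not None:
            for start, end in ref.intervals.get(name, []):
                yield seq, range(start, end)
        else:
            yield seq, range(len(seq))


def expected_context(
    ref: ReferenceSet, flank: int = 1, restrict_to_intervals: bool = False
) -> dict[str, float]:
    """Background distribution of cytosine contexts in the reference.

    Every cytosine occurrence on both strands contributes: each C on the plus
    strand as its window, each G as a C on the minus strand with the window
    reverse complemented.  Windows containing N or truncated by sequence ends
    are skipped.  Returns k-mer -> frequency summing to 1.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    counts: dict[str, int] = {}
    for seq, positions in _iter_regions(ref, restrict_to_intervals):
        n = len(seq)
        for i in positions:
            base = seq[i]
            if base not in "CG":
                continue
            lo, hi = i - flank, i + flank + 1
            if lo < 0 or hi > n:
                continue
            window = seq[lo:hi]
            if "N" in window:
                continue
            kmer = window if base == "C" else revcomp(window)
            counts[kmer] = counts.get(kmer, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no qualifying cytosine site in the reference")
    return {k: v / total for k, v in sorted(counts.items())}


def _stratum_of_kmer(kmer: str) -> str:
    flank = len(kmer) // 2
    return "CpG" if kmer[flank + 1] == "G" else "non_CpG"


def _renormalize_expected(expected: Mapping[str, float], stratum: str) -> dict[str, float]:
    if stratum == "all_C":
        sub = dict(expected)
    else:
        sub = {k: v for k, v in expected.items() if _stratum_of_kmer(k) == stratum}
    total = sum(sub.values())
    if total <= 0:
        raise ValueError(f"expected distribution has no mass in stratum {stratum}")
    return {k: v / total for k, v in sub.items()}


@dataclass
class ContextProfile:
    """Observed context k-mer counts with an optional background distribution."""

    flank: int
    stratum: str
    observed: dict[str, int]
    expected: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}")
        k = 2 * self.flank + 1
        for kmer in self.observed:
            if len(kmer) != k or kmer[self.flank] != "C":
                raise ValueError(f"observed k-mer {kmer!r} inconsistent with flank {self.flank}")
        if self.expected is not None:
            s = sum(self.expected.values())
            if not math.isclose(s, 1.0, abs_tol=1e-9):
                raise ValueError(f"expected frequencies sum to {s}, not 1")

    @property
    def n(self) -> int:
        return sum(self.observed.values())

    @property
    def positions(self) -> list[int]:
        return list(range(-self.flank, self.flank + 1))

    def position_counts(self, position: int) -> dict[str, int]:
        """Observed base counts at one oriented position."""
        if abs(position) > self.flank:
            raise ValueError(f"position {position} outside flank {self.flank}")
        idx = self.flank + position
        out = {b: 0 for b in BASES}
        for kmer, c in self.observed.items():
            out[kmer[idx]] += c
        return out

    def expected_position_freqs(self, position: int) -> dict[str, float]:
        """Background base frequencies marginalised to one position."""
        if self.expected is None:
            raise ValueError("profile has no expected distribution")
        idx = self.flank + position
        out = {b: 0.0 for b in BASES}
        for kmer, f in self.expected.items():
            out[kmer[idx]] += f
        return out

    @property
    def composition(self) -> pd.DataFrame:
        """Row-normalised per-position base frequencies (rows = positions).

        This is the position frequency matrix a sequence-logo tool consumes.
        """
        rows = []
        for pos in self.positions:
            counts = self.position_counts(pos)
            total = sum(counts.values())
            rows.append(
                {b: (counts[b] / total if total else 0.0) for b in BASES}
            )
        return pd.DataFrame(rows, index=self.positions, columns=list(BASES))

    def to_frame(self) -> pd.DataFrame:
        """Long table of k-mer counts (and background frequency if present)."""
        recs = [
            {"kmer": k, "observed": c}
            | ({"expected_freq": self.expected.get(k, 0.0)} if self.expected else {})
            for k, c in sorted(self.observed.items())
        ]
        return pd.DataFrame(recs)


def build_profile(
    mutations: Sequence[OrientedMutation],
    expected: Mapping[str, float] | None = None,
    stratum: str = "all_C",
) -> ContextProfile:
    """Tally oriented-mutation contexts for one CpG stratum.

    For CpG / non_CpG strata the background is renormalised over the k-mers of
    that stratum, so the comparison is within-stratum (otherwise CpG depletion
    among observed non-CpG mutations would be a bookkeeping artifact, not a
    signature).
    """
    if stratum not in STRATA:
        raise ValueError(f"stratum must be one of {STRATA}")
    if not mutations:
        raise ValueError("no mutations supplied")
    flank = mutations[0].flank
    kept = [
        m
        for m in mutations
        if stratum == "all_C" or classify_cpg(m) == stratum
    ]
    if not kept:
        raise ValueError(f"no mutations in stratum {stratum}")
    if any(m.flank != flank for m in kept):
        raise ValueError("mixed context lengths in input")
    observed: dict[str, int] = {}
    for m in kept:
        observed[m.context] = observed.get(m.context, 0) + 1
    exp = None
    if expected is not None:
        klen = {len(k) for k in expected}
        if klen != {2 * flank + 1}:
            raise ValueError("expected distribution built with a different flank")
        exp = _renormalize_expected(expected, stratum)
    return ContextProfile(flank=flank, stratum=stratum, observed=observed, expected=exp)


def chi_square_position(
    profile: ContextProfile, position: int
) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square of one position against the background.

    Observed base counts at ``position`` are tested against the expected base
    frequencies marginalised from the background k-mer distribution; degrees
    of freedom = (number of bases with nonzero expected frequency) - 1.
    Returns (statistic, dof, p).
    """
    if position == 0:
        raise ValueError("position 0 is the mutated base (always C); test a flanking position")
    if abs(position) > profile.flank:
        raise ValueError(f"position {position} outside flank {profile.flank}")
    obs = profile.position_counts(position)
    if sum(obs.values()) == 0:
        raise ValueError("no observed mutations")
    exp_freq = profile.expected_position_freqs(position)
    support = [b for b in BASES if exp_freq[b] > 0]
    for b in BASES:
        if exp_freq[b] == 0 and obs[b] > 0:
            raise ValueError(
                f"base {b} observed at position {position} but has zero expected frequency"
            )
    n = sum(obs.values())
    f_obs = np.array([obs[b] for b in support], dtype=float)
    f_exp = np.array([exp_freq[b] * n for b in support], dtype=float)
    stat, p = stats.chisquare(f_obs, f_exp)
    dof = len(support) - 1
    return float(stat), dof, float(p)


def pypu_ratio(profile: ContextProfile, position: int = -2) -> float:
    """Pyrimidine/purine ratio, (C+T)/(A+G), at one oriented position.

    The -2 position distinguishes deaminase signatures across tumour types;
    requires flank >= 2 at the default position.  Returns ``inf`` when there
    are pyrimidines but no purines; raises when the position is empty.
    """
    counts = profile.position_counts(position)
    py = counts["C"] + counts["T"]
    pu = counts["A"] + counts["G"]
    if py == 0 and pu == 0:
        raise ValueError(f"no observed bases at position {position}")
    if pu == 0:
        return math.inf
    return py / pu


def fraction_non_cpg(mutations: Sequence[OrientedMutation]) -> float:
    """Fraction of oriented mutations at non-CpG sites."""
    if not mutations:
        raise ValueError("no mutations supplied")
    non = sum(1 for m in mutations if classify_cpg(m) == "non_CpG")
    return non / len(mutations)
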