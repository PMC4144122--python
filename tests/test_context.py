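import math

import pytest

from conftest import make_record
from helpers import revcomp_str
from mutctx.context import (
    ContextProfile,
    build_profile,
    chi_square_position,
    classify_cpg,
    collapse_all,
    collapse_to_cytosine,
    expected_context,
    fraction_non_cpg,
    pypu_ratio,
)
from mutctx.formats_io import MutationRecord, ReferenceSet
from mutctx import synthetic_data as synth


class TestCollapse:
    def test_g_mutation_reverse_complemented(self):
        # genomic window TGGCA around a G>A: oriented C>T with context TGCCA
        ref = ReferenceSet(sequences={"r": "TGGCA"})
        om = collapse_to_cytosine(make_record("r", 3, "G", "A"), ref, flank=2)
        assert om.strand == "-"
        assert om.oriented_alt == "T"
        assert om.context == "TGCCA"

    def test_c_mutation_kept_as_is(self):
        ref = ReferenceSet(sequences={"r": "CCCTG"})
        om = collapse_to_cytosine(make_record("r", 3, "C", "A"), ref, flank=2)
        assert om.strand == "+"
        assert om.oriented_alt == "A"
        assert om.context == "CCCTG"

    def test_minus_strand_context_revcomps_to_genomic_window(self):
        ref = ReferenceSet(sequences={"r": "AAGTT"})
        om = collapse_to_cytosine(make_record("r", 3, "G", "C"), ref, flank=2)
        assert revcomp_str(om.context) == "AAGTT"

    def test_truncated_window_returns_none(self):
        ref = ReferenceSet(sequences={"r": "CG"})
        assert collapse_to_cytosine(make_record("r", 1, "C", "T"), ref, flank=1) is None

    def test_window_with_n_returns_none(self):
        ref = ReferenceSet(sequences={"r": "NCG"})
        assert collapse_to_cytosine(make_record("r", 2, "C", "T"), ref, flank=1) is None

    def test_at_reference_base_rejected(self):
        ref = ReferenceSet(sequences={"r": "AAA"})
        with pytest.raises(ValueError):
            collapse_to_cytosine(make_record("r", 2, "A", "T"), ref, flank=1)

    def test_collapse_all_skips_at_records(self, random_ref):
        seq = random_ref.sequences["chr1"]
        recs = []
        for i, base in enumerate(seq[1:50], start=2):
            alt = "A" if base != "A" else "C"
            recs.append(make_record("chr1", i, base, alt))
        oriented = collapse_all(recs, random_ref, flank=1)
        assert all(om.context[1] == "C" for om in oriented)
        n_cg = sum(1 for r in recs if r.ref in "CG")
        assert len(oriented) == n_cg  # no N in this reference, no edge windows


class TestClassifyCpg:
    @pytest.mark.parametrize(
        "context,expected",
        [("ACG", "CpG"), ("TCA", "non_CpG"), ("TGCCA", "non_CpG")],
    )
    def test_plus_one_base_decides(self, context, expected):
        om = _oriented(context)
        assert classify_cpg(om) == expected


def _oriented(context, alt="T"):
    flank = len(context) // 2
    rec = MutationRecord("s", "x", flank + 1, "C", alt)
    return collapse_to_cytosine(rec, ReferenceSet(sequences={"x": context}), flank=flank)


class TestExpectedContext:
    def test_acgt_single_context(self):
        # the C (plus strand) and the G (minus strand) both read ACG
        ref = ReferenceSet(sequences={"x": "ACGT"})
        assert expected_context(ref, flank=1) == {"ACG": 1.0}

    def test_frequencies_sum_to_one(self, random_ref):
        exp = expected_context(random_ref, flank=1)
        assert sum(exp.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(k[1] == "C" for k in exp)

    def test_no_cytosine_is_error(self):
        with pytest.raises(ValueError):
            expected_context(ReferenceSet(sequences={"x": "AAAATTTT"}), flank=1)

    def test_invariant_under_sequence_order(self, random_ref):
        seq = random_ref.sequences["chr1"]
        a = ReferenceSet(sequences={"p": seq[:2000], "q": seq[2000:]})
        b = ReferenceSet(sequences={"q": seq[2000:], "p": seq[:2000]})
        assert expected_context(a, 1) == expected_context(b, 1)

    def test_interval_restriction_limits_sites(self):
        seq = "AAACGAAACGAAA"
        full = ReferenceSet(sequences={"x": seq})
        restricted = ReferenceSet(sequences={"x": seq}, intervals={"x": [(2, 4)]})
        exp = expected_context(restricted, 1, restrict_to_intervals=True)
        # only the C at 0-based position 3 has its centre inside the interval
        assert exp == {"ACG": 1.0}
        # unrestricted: each CpG contributes ACG (plus strand) and TCG (minus strand)
        assert expected_context(full, 1) == {"ACG": 0.5, "TCG": 0.5}


class TestBuildProfile:
    def test_uniform_context_composition(self):
        muts = [_oriented("TCA") for _ in range(4)]
        prof = build_profile(muts)
        assert prof.composition.loc[-1, "T"] == 1.0
        assert prof.composition.loc[0, "C"] == 1.0

    def test_stratum_filter_matches_classifier(self):
        muts = [_oriented("ACG"), _oriented("TCA"), _oriented("GCG")]
        prof = build_profile(muts, stratum="CpG")
        assert prof.n == 2
        assert all(k[2] == "G" for k in prof.observed)

    def test_empty_stratum_error(self):
        with pytest.raises(ValueError):
            build_profile([_oriented("ACG")], stratum="non_CpG")

    def test_expected_renormalized_within_stratum(self):
        expected = {"ACG": 0.25, "TCG": 0.25, "TCA": 0.3, "GCT": 0.2}
        prof = build_profile([_oriented("TCA")], expected, stratum="non_CpG")
        assert sum(prof.expected.values()) == pytest.approx(1.0)
        assert prof.expected == {"TCA": pytest.approx(0.6), "GCT": pytest.approx(0.4)}

    def test_flank_mismatch_error(self):
        with pytest.raises(ValueError):
            build_profile([_oriented("TCA")], {"TTCAA": 1.0})


class TestChiSquare:
    def uniform_profile(self, counts):
        observed = dict(zip(["ACA", "CCA", "GCA", "TCA"], counts))
        expected = {f"{b1}C{b2}": 1 / 16 for b1 in "ACGT" for b2 in "ACGT"}
        return ContextProfile(flank=1, stratum="all_C", observed=observed, expected=expected)

    def test_observed_equal_expected_stat_zero(self):
        prof = self.uniform_profile([10, 10, 10, 10])
        stat, dof, p = chi_square_position(prof, -1)
        assert stat == pytest.approx(0.0)
        assert dof == 3
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # observed (30,10,5,5) vs uniform e=12.5: sum((o-e)^2/e) = 425/12.5
        prof = self.uniform_profile([30, 10, 5, 5])
        stat, dof, p = chi_square_position(prof, -1)
        assert stat == pytest.approx(425 / 12.5)
        assert dof == 3

    def test_position_zero_rejected(self):
        with pytest.raises(ValueError):
            chi_square_position(self.uniform_profile([1, 1, 1, 1]), 0)

    def test_zero_expected_with_observed_names_base(self):
        observed = {"ACA": 5}
        expected = {"TCA": 0.5, "CCA": 0.5}
        prof = ContextProfile(flank=1, stratum="all_C", observed=observed, expected=expected)
        with pytest.raises(ValueError, match="A"):
            chi_square_position(prof, -1)


class TestPyPuRatio:
    def make(self, counts):
        # counts keyed by -2 base over 5-mers xNCAA
        observed = {f"{b}ACAA": c for b, c in counts.items() if c}
        return ContextProfile(flank=2, stratum="all_C", observed=observed)

    def test_balanced_counts(self):
        assert pypu_ratio(self.make({"A": 5, "G": 5, "C": 5, "T": 5})) == 1.0

    def test_no_purines_is_inf(self):
        assert pypu_ratio(self.make({"C": 3, "T": 7})) == math.inf

    def test_arithmetic(self):
        assert pypu_ratio(self.make({"A": 2, "G": 3, "C": 4, "T": 6})) == pytest.approx(2.0)

    def test_empty_is_error(self):
        prof = ContextProfile(flank=2, stratum="all_C", observed={})
        with pytest.raises(ValueError):
            pypu_ratio(prof)


class TestFractionNonCpg:
    def test_all_cpg_zero(self):
        assert fraction_non_cpg([_oriented("ACG")] * 3) == 0.0

    def test_mixture(self):
        muts = [_oriented("TCA")] * 11 + [_oriented("ACG")] * 9
        assert fraction_non_cpg(muts) == pytest.approx(0.55)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            fraction_non_cpg([])


class TestStrandSymmetry:
    def test_pipeline_invariant_under_reverse_complement(self, random_ref):
        """Mirroring the genome (and remapping the records) leaves profiles unchanged."""
        seq = random_ref.sequences["chr1"]
        mirror = ReferenceSet(sequences={"chr1": revcomp_str(seq)})
        muts = synth.gen_mutations(random_ref, 300, sig=synth.apobec1_like_signature(), seed=11)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        mirrored = [
            MutationRecord(
                m.sample_id, m.seq_name, len(seq) - m.pos + 1, comp[m.ref], comp[m.alt]
            )
            for m in muts
        ]
        a = build_profile(collapse_all(muts, random_ref, 1))
        b = build_profile(collapse_all(mirrored, mirror, 1))
        assert a.observed == b.observed


class TestSignatureRecovery:
    def test_planted_t_enrichment_at_minus_one(self, random_ref):
        sig = synth.apobec1_like_signature()
        muts = synth.gen_mutations(random_ref, 500, sig=sig, seed=5)
        oriented = collapse_all(muts, random_ref, 1)
        expected = expected_context(random_ref, 1)
        prof = build_profile(oriented, expected, stratum="non_CpG")
        t_obs = prof.composition.loc[-1, "T"]
        t_exp = prof.expected_position_freqs(-1)["T"]
        assert t_obs > t_exp
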