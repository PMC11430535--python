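"""AS-PCR primer construction, Wallace Tm, and the in-silico PCR model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asmark.design import (
    HaplotypeTemplate,
    PrimerParams,
    TRANSVERSION_MAP,
    apply_secondary_mismatch,
    blocked_loci,
    design_as_forward,
    design_common_reverse,
    design_control_pair,
    design_marker_set,
    insilico_pcr,
    melting_temp,
    validate_marker,
)
from asmark.errors import DesignError, UsageError
from asmark.formats import VariantRecord, revcomp
from asmark.synthetic import simulate_genome

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestMeltingTemp:
    def test_wallace_examples(self):
        assert melting_temp("AAAA") == 8
        assert melting_temp("GGGG") == 16
        assert melting_temp("GC" * 5 + "AT" * 5) == 60

    @settings(max_examples=200, derandomize=True)
    @given(dna)
    def test_wallace_equals_count_oracle(self, seq):
        gc = sum(seq.count(b) for b in "GC")
        at = len(seq) - gc
        assert melting_temp(seq) == 2 * at + 4 * gc

    @settings(max_examples=50, derandomize=True)
    @given(dna, st.sampled_from("ACGT"))
    def test_wallace_monotone_extension(self, seq, base):
        delta = 4 if base in "GC" else 2
        assert melting_temp(seq + base) == melting_temp(seq) + delta

    def test_nn_monotone_in_gc_at_fixed_length(self):
        tms = [melting_temp("A" * (20 - k) + "G" * k, method="nn") for k in (5, 10, 15)]
        assert tms == sorted(tms)

    def test_empty_sequence_rejected(self):
        with pytest.raises(UsageError):
            melting_temp("")


class TestSecondaryMismatch:
    def test_penultimate_default(self):
        assert apply_secondary_mismatch("TTAG") == "TTCG"
        assert apply_secondary_mismatch("TTTG") == "TTGG"

    def test_offset_three(self):
        assert apply_secondary_mismatch("TTAG", offset=3) == "TGAG"

    def test_out_of_range(self):
        with pytest.raises(UsageError):
            apply_secondary_mismatch("ACG", offset=4)

    @settings(max_examples=100, derandomize=True)
    @given(dna, st.integers(1, 5))
    def test_map_is_involution_and_always_differs(self, seq, offset):
        if offset > len(seq):
            return
        once = apply_secondary_mismatch(seq, offset)
        assert once != seq
        assert apply_secondary_mismatch(once, offset) == seq
        for b, m in TRANSVERSION_MAP.items():
            assert b != m


class _Cand:
    vtype = "SNP"

    def __init__(self, chrom, pos, ref, alt):
        self.chrom, self.pos, self.ref, self.mut_allele = chrom, pos, ref, alt


@pytest.fixture(scope="module")
def toy():
    genome = simulate_genome(3, chrom_lengths=(10_000,))
    pos = 5_000
    ref = genome["chr1"][pos - 1]
    alt = "G" if ref != "G" else "A"
    cand = _Cand("chr1", pos, ref, alt)
    mut = [VariantRecord("chr1", pos, ref, alt, alt, alt, 30)]
    return genome, cand, mut


class TestASForward:
    def test_construction_rule(self, toy):
        genome, cand, _ = toy
        p = design_as_forward(genome, cand)
        assert p.strand == "+" and p.three_prime_pos == cand.pos
        assert 18 <= len(p) <= 30
        assert p.sequence[-1] == cand.mut_allele
        assert p.tm == melting_temp(p.sequence) >= 58
        # exactly one engineered mismatch at the penultimate base
        flank = genome.fetch("chr1", cand.pos - len(p) + 1, cand.pos)
        template_like = flank[:-1] + cand.mut_allele
        diffs = [i for i, (a, b) in enumerate(zip(p.sequence, template_like)) if a != b]
        assert diffs == [len(p) - 2]
        off, new, old = p.engineered_mismatch
        assert off == 2 and new == TRANSVERSION_MAP[old] != old

    def test_configurable_offset(self, toy):
        genome, cand, _ = toy
        p = design_as_forward(genome, cand, PrimerParams(mismatch_offset=3))
        assert p.engineered_mismatch[0] == 3
        flank = genome.fetch("chr1", cand.pos - len(p) + 1, cand.pos)
        diffs = [i for i, (a, b) in enumerate(zip(p.sequence, flank[:-1] + cand.mut_allele)) if a != b]
        assert diffs == [len(p) - 3]

    def test_insufficient_flank(self, toy):
        genome, *_ = toy
        with pytest.raises(DesignError, match="flank"):
            design_as_forward(genome, _Cand("chr1", 10, "A", "G"))


class TestCommonReverse:
    def test_contract_and_optimality(self, toy):
        genome, cand, mut = toy
        blocked = blocked_loci(mut)
        fwd = design_as_forward(genome, cand)
        rev = design_common_reverse(genome, cand, blocked, forward_tm=fwd.tm)
        product = rev.three_prime_pos - cand.pos + 1
        assert 100 <= product <= 300
        assert rev.strand == "-"
        s, e = rev.footprint
        assert not np.isin(np.arange(s, e + 1), blocked["chr1"]).any()
        assert rev.sequence == revcomp(genome.fetch("chr1", s, e))
        # brute-force optimality: no feasible window is strictly better
        params = PrimerParams()
        best = (abs(rev.tm - fwd.tm), product)
        for r3 in range(cand.pos + 99, cand.pos + 300):
            for L in range(params.min_len, params.max_len + 1):
                seq = revcomp(genome.fetch("chr1", r3, r3 + L - 1))
                tm = melting_temp(seq)
                if tm >= params.target_tm:
                    key = (abs(tm - fwd.tm), r3 - cand.pos + 1)
                    assert key >= best
                    break

    def test_all_windows_blocked(self, toy):
        genome, cand, _ = toy
        blocked = {"chr1": np.arange(cand.pos + 1, cand.pos + 400)}
        with pytest.raises(DesignError, match="reverse-primer window"):
            design_common_reverse(genome, cand, blocked)


class TestControlPair:
    def test_variant_free_pair(self, toy):
        genome, _, mut = toy
        fwd, rev = design_control_pair(genome, blocked_loci(mut))
        product = rev.three_prime_pos - fwd.three_prime_pos + 1
        assert 100 <= product <= 300
        span = np.arange(fwd.footprint[0], rev.footprint[1] + 1)
        assert not np.isin(span, blocked_loci(mut)["chr1"]).any()

    def test_fully_blocked_genome(self, toy):
        genome, *_ = toy
        blocked = {"chr1": np.arange(1, 10_001, 5)}
        with pytest.raises(DesignError, match="control"):
            design_control_pair(genome, blocked)


class TestInsilicoPCR:
    def test_discrimination_of_single_planted_snp(self, toy):
        genome, cand, mut = toy
        ps = design_marker_set(genome, cand, blocked_loci(mut))
        rep = validate_marker(genome, [], mut, ps)
        # mutant template: only the engineered internal mismatch -> amplified
        assert rep.as_mut.amplified
        assert rep.as_mut.forward_mismatch_offsets == (2,)
        assert rep.as_mut.product_len == ps.expected_product_len
        # WT template: terminal allele mismatch blocks extension
        assert not rep.as_wt.amplified
        assert 1 in rep.as_wt.forward_mismatch_offsets
        # control amplifies both templates with zero mismatches
        for res in (rep.control_wt, rep.control_mut):
            assert res.amplified
            assert res.forward_mismatch_offsets == () == res.reverse_mismatch_offsets
            assert res.product_len == ps.control_product_len
        assert rep.discriminating

    def test_swapped_templates_flip_the_AS_product(self, toy):
        genome, cand, mut = toy
        ps = design_marker_set(genome, cand, blocked_loci(mut))
        rep = validate_marker(genome, mut, [], ps)  # samples swapped
        assert rep.as_wt.amplified and not rep.as_mut.amplified
        assert not rep.discriminating

    def test_terminal_engineered_mismatch_breaks_discrimination(self, toy):
        genome, cand, mut = toy
        params = PrimerParams(mismatch_offset=1)  # misconfigured on purpose
        ps = design_marker_set(genome, cand, blocked_loci(mut), params)
        rep = validate_marker(genome, [], mut, ps, params)
        assert not rep.as_mut.amplified and not rep.discriminating

    def test_indel_shifts_are_mapped(self, toy):
        genome, cand, _ = toy
        # mutant carries an upstream 4 bp deletion plus the candidate SNP
        ref4 = genome.fetch("chr1", 2_000, 2_004)
        mut = [
            VariantRecord("chr1", 2_000, ref4, ref4[0], ref4[0], ref4[0], 30),
            VariantRecord("chr1", cand.pos, cand.ref, cand.mut_allele,
                          cand.mut_allele, cand.mut_allele, 30),
        ]
        tmpl = HaplotypeTemplate("mutant", genome, mut)
        assert tmpl.shift("chr1", cand.pos) == cand.pos - 4
        ps = design_marker_set(genome, cand, blocked_loci(mut))
        rep = validate_marker(genome, [], mut, ps)
        assert rep.discriminating

    def test_footprint_outside_template_rejected(self, toy):
        genome, cand, mut = toy
        ps = design_marker_set(genome, cand, blocked_loci(mut))
        bad = ps.as_forward.__class__(
            name="x", sequence="A" * 20, chrom="chr1", strand="+",
            three_prime_pos=10_005, tm=60.0,
        )
        tmpl = HaplotypeTemplate("WT", genome, [])
        with pytest.raises(UsageError, match="outside"):
            insilico_pcr(tmpl, bad, ps.common_reverse)


class TestPipelineDesignInvariants:
    def test_every_designed_marker_obeys_defaults(self, pipeline_results):
        res = pipeline_results
        assert len(res.primer_sets) == 50 and not res.design_failures
        by_id = {(c.chrom, c.pos): c for c in res.candidates}
        for set_id, ps in res.primer_sets:
            cand = by_id[(ps.as_forward.chrom, ps.as_forward.three_prime_pos)]
            f = ps.as_forward
            assert 18 <= len(f) <= 30
            assert f.sequence[-1] == cand.mut_allele
            assert f.engineered_mismatch[0] == 2
            assert 100 <= ps.expected_product_len <= 300
        assert all(rep.discriminating for _, rep in res.validations)

    def test_reverse_and_control_match_both_templates_exactly(self, pipeline_results):
        for _, rep in pipeline_results.validations:
            for res in (rep.as_wt, rep.as_mut):
                assert res.reverse_mismatch_offsets == ()
            for res in (rep.control_wt, rep.control_mut):
                assert res.forward_mismatch_offsets == ()
                assert res.reverse_mismatch_offsets == ()
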