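"""Simulator: sampling, the error walk, truth consistency, determinism."""

import numpy as np
import pytest

import smrtsim as sm
from smrtsim.edits import apply_script, revcomp, script_error_counts
from smrtsim.profile import EmpiricalDistribution, PassLengthModel
from smrtsim.simulate import (
    SimulationConfig,
    SimulationError,
    TemplateDraw,
    apply_context_errors,
    apply_uniform_errors,
    generate_polymerase_read,
    replace_ns,
    sample_pass_and_length,
    sample_template,
    simulate_run,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestSamplePassAndLength:
    def test_degenerate_model(self):
        model = PassLengthModel(
            EmpiricalDistribution.point_mass(3),
            {3: EmpiricalDistribution.from_values([9000], bin_width=100)})
        g = _rng(1)
        for _ in range(20):
            n, length = sample_pass_and_length(model, g)
            assert n == 3 and 9000 <= length < 9100

    def test_pass_frequencies_within_binomial_error(self):
        model = PassLengthModel(
            EmpiricalDistribution([1.0, 2.0], [0.5, 0.5]),
            {1: EmpiricalDistribution.point_mass(1000),
             2: EmpiricalDistribution.point_mass(1000)})
        g = _rng(2)
        n_draws = 20_000
        ones = sum(sample_pass_and_length(model, g)[0] == 1 for _ in range(n_draws))
        se = np.sqrt(0.25 * n_draws)
        assert abs(ones - n_draws / 2) < 3 * se

    def test_caps_clip_lengths(self):
        model = PassLengthModel(
            EmpiricalDistribution.point_mass(1),
            {1: EmpiricalDistribution.point_mass(9000)})
        assert sample_pass_and_length(model, _rng(), max_length=5000)[1] == 5000
        assert sample_pass_and_length(model, _rng(), min_length=10_000)[1] == 10_000


class TestSampleTemplate:
    def test_template_is_a_slice_or_its_revcomp(self):
        ref = {"c": "".join(_rng(3).choice(list("ACGT"), 1000))}
        g = _rng(4)
        for _ in range(20):
            td = sample_template(ref, 100, 1, g)
            assert 0 <= td.start < td.end <= 1000 and td.end - td.start == 100
            piece = ref["c"][td.start:td.end]
            assert td.sequence == (piece if td.strand == "+" else revcomp(piece))

    def test_only_eligible_contig_is_used(self):
        ref = {"big": "A" * 900, "small": "C" * 100}
        g = _rng(5)
        assert all(sample_template(ref, 200, 1, g).contig == "big" for _ in range(30))

    def test_contig_choice_proportional_to_eligible_positions(self):
        ref = {"a": "A" * 3000, "b": "C" * 1000}
        g = _rng(6)
        n = 10_000
        picks = sum(sample_template(ref, 100, 1, g).contig == "a" for _ in range(n))
        p = (3000 - 99) / ((3000 - 99) + (1000 - 99))
        se = np.sqrt(p * (1 - p) * n)
        assert abs(picks - p * n) < 3 * se

    def test_infeasible_length_raises_with_the_length(self):
        with pytest.raises(SimulationError, match="500"):
            sample_template({"c": "ACGT" * 25}, 500, 1, _rng())


class TestReplaceNs:
    def test_no_n_is_identity(self):
        assert replace_ns("ACGT", _rng()) == "ACGT"

    def test_ns_become_bases_elsewhere_untouched(self):
        out = replace_ns("ANCGNT", _rng(7))
        assert len(out) == 6 and set(out) <= set("ACGT")
        assert out[0] == "A" and out[2:4] == "CG" and out[5] == "T"

    def test_replacement_is_uniform(self):
        out = replace_ns("N" * 10_000, _rng(0))
        counts = {b: out.count(b) for b in "ACGT"}
        se = np.sqrt(0.25 * 0.75 * 10_000)
        for b in "ACGT":
            assert abs(counts[b] - 2500) < 3 * se

    def test_other_letters_rejected(self):
        with pytest.raises(SimulationError):
            replace_ns("ACGU", _rng())


class TestErrorWalks:
    def test_error_free_walk_is_identity(self):
        p = sm.uniform_profile(0, 0, 0, 100)
        seq = "ACGT" * 100
        read, script = apply_context_errors(seq, p, _rng(9))
        assert read == seq and script == [("=", 400, "")]

    def test_forced_substitution_changes_every_base(self):
        p = sm.uniform_profile(0, 0, 0.999999, 100)
        seq = "ACGT" * 50
        read, script = apply_context_errors(seq, p, _rng(10))
        assert len(read) == len(seq)
        assert all(a != b for a, b in zip(read, seq))

    def test_realized_event_frequencies_match_rates(self):
        # binomial oracle, plus the documented O(p^2) adjacency-exclusion bias
        rates = (0.09, 0.04, 0.01)
        p = sm.uniform_profile(*rates, 100)
        seq = "".join(_rng(11).choice(list("ACGT"), 300_000))
        _, script = apply_context_errors(seq, p, _rng(12))
        c = script_error_counts(script)
        n_match = sum(l for op, l, _ in script if op == "=")
        total = n_match + c["ins_events"] + c["del_events"] + c["sub_events"]
        for rate, events in zip(rates, (c["ins_events"], c["del_events"], c["sub_events"])):
            se = np.sqrt(rate * (1 - rate) / total)
            assert abs(events / total - rate) < 3 * se + rate ** 2

    def test_uniform_rate_zero_is_identity(self):
        p = sm.uniform_profile(0.09, 0.04, 0.01, 100)
        seq = "ACGT" * 100
        read, script = apply_uniform_errors(seq, 0.0, p, _rng(13))
        assert read == seq and script == [("=", 400, "")]

    def test_uniform_rate_recovered(self):
        p = sm.uniform_profile(0.09, 0.04, 0.01, 100)
        seq = "".join(_rng(14).choice(list("ACGT"), 200_000))
        _, script = apply_uniform_errors(seq, 0.4, p, _rng(15))
        c = script_error_counts(script)
        events = c["ins_events"] + c["del_events"] + c["sub_events"]
        n = len(seq)
        se = np.sqrt(0.4 * 0.6 / n)
        assert abs(events / n - 0.4) < 3 * se

    def test_insertion_only_marginal_yields_only_insertions(self):
        p = sm.uniform_profile(0.1, 0, 0, 100)
        seq = "ACGT" * 2000
        _, script = apply_uniform_errors(seq, 0.4, p, _rng(16))
        c = script_error_counts(script)
        assert c["ins_events"] > 0 and c["del_events"] == 0 and c["sub_events"] == 0


class TestGeneratePolymeraseRead:
    def test_error_free_two_passes_alternate_strand(self):
        p = sm.uniform_profile(0, 0, 0, 8, {2: 1.0})
        td = TemplateDraw("c", 0, 4, "+", "AAAC")
        subs, truths = generate_polymerase_read(
            td, 2, p, SimulationConfig(n_reads=1, seed=0), _rng(17))
        assert [s for _, s in subs] == ["AAAC", "GTTT"]
        assert [t.strand for t in truths] == ["+", "-"]
        assert truths[0].name.endswith("/0_4") and truths[1].name.endswith("/4_8")

    def test_single_pass_error_free_equals_template(self):
        p = sm.uniform_profile(0, 0, 0, 10, {1: 1.0})
        td = TemplateDraw("c", 0, 10, "+", "ACGTACGTAC")
        subs, truths = generate_polymerase_read(
            td, 1, p, SimulationConfig(n_reads=1, seed=0), _rng(18))
        assert subs[0][1] == "ACGTACGTAC"
        assert truths[0].head_len == 0 and truths[0].tail_len == 0

    def test_truth_scripts_reproduce_subreads(self, sim_corpus, small_genome):
        _, truths, _ = sim_corpus
        for tr in truths:
            template = small_genome[tr.contig][tr.start:tr.end]
            if tr.template_strand == "-":
                template = revcomp(template)
            oriented = template if tr.pass_index % 2 == 0 else revcomp(template)
            assert apply_script(tr.script, oriented) == tr.read


class TestSimulateRun:
    def test_read_counts(self, small_genome, baseline_profile):
        reads, truths, report = simulate_run(
            small_genome, baseline_profile, SimulationConfig(n_reads=5, seed=1))
        assert report["n_polymerase_reads"] == 5
        assert len(truths) == sum(t.n_pass for t in truths if t.pass_index == 0)
        assert len(reads) == len(truths)

    def test_same_seed_is_bit_identical(self, small_genome, baseline_profile):
        a = simulate_run(small_genome, baseline_profile, SimulationConfig(n_reads=10, seed=5))
        b = simulate_run(small_genome, baseline_profile, SimulationConfig(n_reads=10, seed=5))
        assert a[0] == b[0]
        assert [t.script for t in a[1]] == [t.script for t in b[1]]

    def test_depth_stopping_rule(self, small_genome):
        # error-free single-pass profile: walked bases land in
        # [target, target + max template length)
        p = sm.uniform_profile(0, 0, 0, 2000, {1: 1.0})
        genome_size = sum(len(s) for s in small_genome.values())
        _, _, report = simulate_run(small_genome, p, SimulationConfig(depth=2.0, seed=2))
        target = 2.0 * genome_size
        assert target <= report["template_bases"] < target + 2000

    def test_exclusive_config_rejected(self, small_genome, baseline_profile):
        with pytest.raises(SimulationError):
            simulate_run(small_genome, baseline_profile,
                         SimulationConfig(n_reads=5, depth=1.0))
        with pytest.raises(SimulationError):
            simulate_run(small_genome, baseline_profile, SimulationConfig())
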