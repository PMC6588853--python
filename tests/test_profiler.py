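"""Profile estimation: name parsing, grouping, event extraction, tallies."""

from collections import Counter
from types import SimpleNamespace

import numpy as np
import pytest

from smrtsim import fixtures as fx
from smrtsim.edits import AlignmentRecord
from smrtsim.profile import KMERS, NOCTX
from smrtsim.profiler import (
    EstimationError,
    ErrorEvent,
    ReadNameError,
    ZmwGroup,
    alignment_to_events,
    build_profile,
    estimate_pass_length_model,
    estimate_unaligned_ratio,
    group_by_zmw,
    parse_read_name,
    tally_events,
)


class TestParseReadName:
    def test_standard_subread_name(self):
        assert parse_read_name("m54007_170101/4325/0_11435") == \
            ("m54007_170101", 4325, 0, 11435)

    @pytest.mark.parametrize("bad", ["read17", "m1/7/100_50", "m1/x/0_5", "m1/7/5"])
    def test_malformed_names_raise_with_the_name(self, bad):
        with pytest.raises(ReadNameError) as err:
            parse_read_name(bad)
        assert bad in str(err.value)


class TestGroupByZmw:
    def test_two_subreads_one_hole(self):
        groups, skipped = group_by_zmw(["m1/5/0_900", "m1/5/950_1900"])
        assert skipped == [] and len(groups) == 1
        assert groups[0].n_pass == 2 and groups[0].polymerase_length == 1900

    def test_distinct_holes_stay_apart(self):
        groups, _ = group_by_zmw(["m1/5/0_900", "m1/6/0_500"])
        assert sorted((g.zmw, g.n_pass) for g in groups) == [(5, 1), (6, 1)]

    def test_group_sizes_match_planted_multiplicities(self):
        # counting oracle over generated names with known ZMW multiplicities
        rng = np.random.default_rng(1)
        multiplicity = {z: int(rng.integers(1, 6)) for z in range(250)}
        names = []
        for z, m in multiplicity.items():
            q = 0
            for _ in range(m):
                names.append(f"mv/{z}/{q}_{q + 100}")
                q += 100
        rng.shuffle(names)
        groups, skipped = group_by_zmw(names)
        assert not skipped
        assert {g.zmw: g.n_pass for g in groups} == multiplicity


class TestPassLengthModel:
    def test_degenerate_input(self):
        groups = [ZmwGroup("m", z, [(0, 3000), (3000, 6000), (6000, 9000)])
                  for z in range(10)]
        model = estimate_pass_length_model(groups)
        assert model.pass_distribution.support.tolist() == [3.0]
        d = model.length_by_pass[3]
        assert d.support.tolist() == [9050.0] and d.probabilities.tolist() == [1.0]

    def test_pass_frequencies(self):
        groups = [ZmwGroup("m", z, [(0, 100), (100, 200)]) for z in range(6)]
        groups += [ZmwGroup("m", 10 + z, [(i * 50, (i + 1) * 50) for i in range(4)])
                   for z in range(4)]
        model = estimate_pass_length_model(groups)
        assert dict(zip(model.pass_distribution.support,
                        model.pass_distribution.probabilities)) == {2.0: 0.6, 4.0: 0.4}

    def test_marginals_recover_generating_frequencies(self):
        # recount oracle: frequencies are exact on finite input
        rng = np.random.default_rng(2)
        passes = rng.choice([1, 2, 3], size=400, p=[0.5, 0.3, 0.2])
        groups = []
        for z, n in enumerate(passes):
            length = int(rng.integers(2000, 12000))
            step = length // n
            groups.append(ZmwGroup("m", z, [(i * step, (i + 1) * step) for i in range(n)]))
        model = estimate_pass_length_model(groups)
        counted = Counter(int(n) for n in passes)
        est = dict(zip(model.pass_distribution.support, model.pass_distribution.probabilities))
        for n, c in counted.items():
            assert est[float(n)] == pytest.approx(c / 400)

    def test_empty_input_is_an_error(self):
        with pytest.raises(EstimationError):
            estimate_pass_length_model([])


class TestAlignmentToEvents:
    def test_merged_deletion_with_context(self):
        rec = AlignmentRecord("m/1/0_4", 4, "c", 0, 6, "+",
                              [("=", 2, ""), ("D", 2, ""), ("=", 2, "")])
        events = alignment_to_events(rec, "ACGTAC")
        kinds = [(e.type, e.size, e.context) for e in events]
        assert kinds == [
            ("match", 1, NOCTX), ("match", 1, NOCTX),
            ("deletion", 2, "ACG"),
            ("match", 1, "GTA"), ("match", 1, "TAC"),
        ]

    def test_identity_alignment_is_all_matches(self):
        rec = AlignmentRecord("m/1/0_10", 10, "c", 0, 10, "+", [("=", 10, "")])
        events = alignment_to_events(rec, "ACGTACGTAC")
        assert len(events) == 10 and all(e.type == "match" for e in events)

    def test_insertion_anchored_at_preceding_base(self):
        rec = AlignmentRecord("m/1/0_8", 8, "c", 0, 6, "+",
                              [("=", 4, ""), ("I", 2, "GG"), ("=", 2, "")])
        events = alignment_to_events(rec, "ACGTAC")
        ins = [e for e in events if e.type == "insertion"]
        # preceding reference base is position 3, so the 3-mer ends there
        assert len(ins) == 1 and ins[0].context == "CGT" and ins[0].read_bases == "GG"

    def test_events_reconstruct_the_read(self):
        # apply-events oracle: emitting event read bases re-creates the read
        from tests.test_edits import random_script_and_template
        from smrtsim.edits import apply_script

        rng = np.random.default_rng(9)
        for _ in range(50):
            script, template = random_script_and_template(rng)
            read = apply_script(script, template)
            rec = AlignmentRecord("m/1/0_1", len(read), "c", 0, len(template), "+", script)
            rec.read_length = len(read)
            events = alignment_to_events(rec, template)
            rebuilt = "".join(
                e.read_bases for e in events if e.type in ("match", "substitution", "insertion"))
            assert rebuilt == read


class TestUnalignedRatio:
    def test_clipped_single_subread(self):
        g = ZmwGroup("m", 1, [(0, 1000)])
        rec = SimpleNamespace(read_name="m/1/0_1000", clip_head=100, clip_tail=100)
        model = estimate_unaligned_ratio([rec], {"m/1": g})
        assert model.head.mean() == pytest.approx(0.105, abs=1e-9)  # bin center of 0.10
        assert model.tail.mean() == pytest.approx(0.105, abs=1e-9)

    def test_fully_aligned_read_has_zero_ratios(self):
        g = ZmwGroup("m", 1, [(0, 1000)])
        rec = SimpleNamespace(read_name="m/1/0_1000", clip_head=0, clip_tail=0)
        model = estimate_unaligned_ratio([rec], {"m/1": g})
        assert model.head.mean() == pytest.approx(0.005)
        assert model.tail.mean() == pytest.approx(0.005)

    def test_planted_fractions_recovered(self):
        # recount oracle over planted unaligned fractions
        rng = np.random.default_rng(3)
        records, groups, planted_heads = [], {}, []
        for z in range(300):
            plen = 10_000
            head = int(rng.integers(0, 3000))
            tail = int(rng.integers(0, 3000))
            groups[f"m/{z}"] = ZmwGroup("m", z, [(0, plen)])
            records.append(SimpleNamespace(
                read_name=f"m/{z}/0_{plen}", clip_head=head, clip_tail=tail))
            planted_heads.append(head / plen)
        model = estimate_unaligned_ratio(records, groups)
        planted_bins = Counter(int(h / 0.01) for h in planted_heads)
        est = dict(zip(model.head.support, model.head.probabilities))
        for b, count in planted_bins.items():
            assert est[(b + 0.5) * 0.01] == pytest.approx(count / 300)


class TestTallyEvents:
    def test_single_context_frequencies(self):
        events = [ErrorEvent("match", 1, "AAC", "C", "C")] * 97
        events += [ErrorEvent("deletion", 1, "AAC", "C", "")] * 3
        table, sizes, ins, subs = tally_events(events)
        assert np.allclose(table.rows["AAC"], [0.97, 0, 0.03, 0])
        # all other rows fall back to the marginal (= the only observed row)
        assert set(table.fallback_contexts) == set(KMERS) - {"AAC"}
        assert np.allclose(table.rows["GGG"], [0.97, 0, 0.03, 0])

    def test_insertion_bases_per_context(self):
        events = [ErrorEvent("insertion", 2, "TTT", "", "AG"),
                  ErrorEvent("match", 1, "TTT", "T", "T")]
        _, _, ins, _ = tally_events(events)
        assert np.allclose(ins.rows["TTT"], [0.5, 0, 0.5, 0])

    def test_recovery_from_sampled_events(self):
        # multinomial oracle: events drawn from a known table
        rng = np.random.default_rng(4)
        gen_rows = {k: np.array([0.85, 0.08, 0.05, 0.02]) for k in KMERS}
        events = []
        for k in KMERS:
            n = int(rng.integers(800, 2000))
            draws = rng.choice(4, size=n, p=gen_rows[k])
            for d in draws:
                t = ["match", "insertion", "deletion", "substitution"][d]
                events.append(ErrorEvent(t, 1, k, "A" if t != "insertion" else "",
                                         "C" if t != "deletion" else ""))
        table, _, _, _ = tally_events(events)
        for k in KMERS:
            assert np.abs(table.rows[k] - gen_rows[k]).max() < 0.05
        assert table.fallback_contexts == ()

    def test_zero_events_is_an_error(self):
        with pytest.raises(EstimationError):
            tally_events([])


class TestBuildProfile:
    def test_error_free_corpus_gives_pure_match_rows(self, tmp_path, small_genome):
        _, truths = fx.oracle_reads(small_genome, (0, 0, 0), 20, 2000, seed=5)
        sam = tmp_path / "clean.sam"
        fx.truth_to_sam(truths, small_genome, sam)
        profile = build_profile(sam, small_genome)
        observed = set(KMERS) - set(profile.context_table.fallback_contexts)
        assert observed  # plenty of contexts seen on 40 kb of alignment
        for k in observed:
            assert np.allclose(profile.context_table.rows[k], [1, 0, 0, 0])

    def test_planted_insertion_rate_recovered(self, tmp_path, small_genome):
        # binomial oracle: 5% insertions, ~3e5 template bases
        _, truths = fx.oracle_reads(small_genome, (0.05, 0, 0), 30, 10_000, seed=6)
        sam = tmp_path / "ins.sam"
        fx.truth_to_sam(truths, small_genome, sam)
        profile = build_profile(sam, small_genome)
        meta = profile.metadata
        n = meta["template_bases"]
        rate = meta["error_base_counts"]["insertion"] / n
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) < 3 * se

    def test_empty_sam_is_an_error(self, tmp_path, small_genome):
        sam = tmp_path / "empty.sam"
        fx.truth_to_sam([], small_genome, sam)
        with pytest.raises(EstimationError):
            build_profile(sam, small_genome)

    def test_fast_tally_matches_event_stream_tally(self, tmp_path, small_genome):
        # dual-route check: the vectorized per-record tally used by
        # build_profile must agree with streaming alignment_to_events
        from smrtsim import io as sio

        _, truths = fx.oracle_reads(small_genome, (0.08, 0.05, 0.02), 10, 3000, passes=2, seed=8)
        sam = tmp_path / "dual.sam"
        fx.truth_to_sam(truths, small_genome, sam)
        profile = build_profile(sam, small_genome)
        events = []
        for rec in sio.read_alignments(sam, small_genome):
            events.extend(alignment_to_events(rec, small_genome[rec.ref_name]))
        table, sizes, ins, subs = tally_events(events)
        assert table == profile.context_table
        assert sizes.dist("deletion") == profile.sizes.dist("deletion")
        assert ins == profile.insertion_bases
        assert subs == profile.substitutions

    def test_estimation_is_deterministic(self, tmp_path, small_genome):
        _, truths = fx.oracle_reads(small_genome, (0.05, 0.02, 0.01), 10, 2000, seed=9)
        sam = tmp_path / "det.sam"
        fx.truth_to_sam(truths, small_genome, sam)
        p1 = build_profile(sam, small_genome)
        p2 = build_profile(sam, small_genome)
        assert p1.context_table == p2.context_table
        assert p1.to_dict() == p2.to_dict()
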