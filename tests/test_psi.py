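"""Read assignment, PSI arithmetic, filtering and coverage counting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from spliceprobe import events, simulate
from spliceprobe.events import compute_unique_regions, enumerate_events, TranscriptModel
from spliceprobe.psi import (
    Assignment,
    EventCounts,
    PsiRecord,
    SplicedAlignment,
    assign_read,
    blocks_from_cigar,
    compute_psi,
    compute_rpkm,
    count_splice_site_spanning,
    counts_table,
    delta_psi,
    filter_events,
    quantify_event,
    read_sam,
)


def _tm(tid, exons, gene="g", chrom="chr1", strand="+"):
    return TranscriptModel(tid, gene, chrom, strand, tuple(exons))


@pytest.fixture
def cassette_event():
    """Cassette exon (500, 620) between flanks ending 300 / starting 1000."""
    t1 = _tm("t1", [(0, 100), (200, 300), (500, 620), (1000, 1100), (1200, 1300)])
    t2 = _tm("t2", [(0, 100), (200, 300), (1000, 1100), (1200, 1300)])
    (ev,) = enumerate_events([t1, t2])
    return ev, compute_unique_regions(ev)


def _aln(blocks, read_id="r", frag=None, chrom="chr1"):
    return SplicedAlignment(read_id, "S1", chrom, "+", tuple(blocks), fragment_id=frag)


# ---------------------------------------------------------------------------
# SAM / CIGAR
# ---------------------------------------------------------------------------

class TestCigar:
    def test_plain_match_is_one_block(self):
        assert blocks_from_cigar(100, [(0, 50)]) == ((100, 150),)

    def test_n_gap_splits_blocks(self):
        # 25M300N25M
        assert blocks_from_cigar(100, [(0, 25), (3, 300), (0, 25)]) == (
            (100, 125),
            (425, 450),
        )

    def test_soft_clip_and_insertion_ignored_deletion_bridged(self):
        # 5S20M2I5M2D23M
        blocks = blocks_from_cigar(100, [(4, 5), (0, 20), (1, 2), (0, 5), (2, 2), (0, 23)])
        assert blocks == ((100, 150),)

    def test_unsupported_op_raises(self):
        with pytest.raises(ValueError):
            blocks_from_cigar(0, [(9, 10)])  # B operation

    def test_sam_round_trip_matches_generator_truth(self, tmp_path):
        models, truth = simulate.gen_transcriptome(2, {"CASSETTE": 1})
        alignments, _ = simulate.gen_reads(models, {truth["genes"][0]["gene_id"]: 0.5},
                                           depth=50, seed=4)
        path = tmp_path / "r.sam"
        simulate.write_sam(alignments, models, str(path))
        back = read_sam(str(path), sample_id="S1")
        assert len(back) == len(alignments)
        orig = {a.read_id: a.blocks for a in alignments}
        for aln in back:
            assert aln.blocks == orig[aln.read_id]


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

class TestAssignRead:
    def test_skip_junction_read_supports_skipping(self, cassette_event):
        ev, ur = cassette_event
        # spans (300, 1000) with 10 nt on each side
        aln = _aln([(290, 300), (1000, 1040)])
        assert assign_read(ev, ur, aln, min_overhang=1) is Assignment.ALT2

    def test_inclusion_junction_read_supports_inclusion(self, cassette_event):
        ev, ur = cassette_event
        aln = _aln([(280, 300), (500, 530)])
        assert assign_read(ev, ur, aln) is Assignment.ALT1

    def test_read_inside_flanking_exon_is_neither(self, cassette_event):
        ev, ur = cassette_event
        assert assign_read(ev, ur, _aln([(210, 260)])) is Assignment.NEITHER

    def test_read_inside_cassette_exon_is_inclusion(self, cassette_event):
        ev, ur = cassette_event
        assert assign_read(ev, ur, _aln([(520, 570)])) is Assignment.ALT1

    def test_insufficient_overhang_is_neither(self, cassette_event):
        ev, ur = cassette_event
        aln = _aln([(295, 300), (1000, 1045)])
        assert assign_read(ev, ur, aln, min_overhang=6) is Assignment.NEITHER

    def test_boundary_touching_read_has_no_junction_evidence(self, cassette_event):
        # start exactly on the splice site: zero left overhang
        ev, ur = cassette_event
        aln = _aln([(300, 350)])
        assert assign_read(ev, ur, aln) is Assignment.NEITHER

    def test_other_chromosome_is_neither(self, cassette_event):
        ev, ur = cassette_event
        aln = _aln([(290, 300), (1000, 1040)], chrom="chr2")
        assert assign_read(ev, ur, aln) is Assignment.NEITHER

    def test_simulated_reads_match_their_source_isoform(self, cassette_fixture):
        models, truth, event, regions = cassette_fixture
        gene = truth["genes"][0]["gene_id"]
        alignments, read_truth = simulate.gen_reads(models, {gene: 0.5}, 400, seed=9)
        from_inclusion = {f: inc for f, _, inc in read_truth["fragments"]}
        for aln in alignments:
            a = assign_read(event, regions, aln)
            if a is Assignment.ALT1:
                assert from_inclusion[aln.fragment_id]
            elif a is Assignment.ALT2:
                assert not from_inclusion[aln.fragment_id]


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

class TestQuantify:
    def test_normalized_count_arithmetic(self):
        c = EventCounts("e", "s", n1=10, n2=5, c1=10 / 200, c2=5 / 50)
        assert c.c1 == pytest.approx(0.05)
        assert c.c2 == pytest.approx(0.1)
        assert compute_psi(c) == pytest.approx(1 / 3)

    def test_zero_reads_give_zero_counts_and_nan_psi(self, cassette_event):
        ev, ur = cassette_event
        counts = quantify_event(ev, ur, [], "S1")
        assert (counts.n1, counts.n2) == (0, 0)
        assert counts.density == 0
        assert math.isnan(compute_psi(counts))

    def test_conflicting_mates_contribute_nothing(self, cassette_event):
        ev, ur = cassette_event
        frag = [
            _aln([(280, 300), (500, 530)], read_id="f/1", frag="f"),
            _aln([(290, 300), (1000, 1040)], read_id="f/2", frag="f"),
        ]
        counts = quantify_event(ev, ur, frag, "S1")
        assert (counts.n1, counts.n2) == (0, 0)

    def test_agreeing_mates_both_count(self, cassette_event):
        ev, ur = cassette_event
        frag = [
            _aln([(280, 300), (500, 530)], read_id="f/1", frag="f"),
            _aln([(520, 570)], read_id="f/2", frag="f"),
        ]
        counts = quantify_event(ev, ur, frag, "S1")
        assert (counts.n1, counts.n2) == (2, 0)

    def test_counting_is_order_invariant_and_additive(self, cassette_fixture):
        models, truth, event, regions = cassette_fixture
        gene = truth["genes"][0]["gene_id"]
        a1, _ = simulate.gen_reads(models, {gene: 0.3}, 150, seed=1)
        a2, _ = simulate.gen_reads(models, {gene: 0.8}, 150, seed=2, sample_id="S2")
        c_all = quantify_event(event, regions, a1 + a2, "S")
        c_rev = quantify_event(event, regions, list(reversed(a1 + a2)), "S")
        c1 = quantify_event(event, regions, a1, "S")
        c2 = quantify_event(event, regions, a2, "S")
        assert (c_all.n1, c_all.n2) == (c_rev.n1, c_rev.n2)
        assert c_all.n1 == c1.n1 + c2.n1 and c_all.n2 == c1.n2 + c2.n2

    def test_psi_estimate_near_simulated_value(self, cassette_fixture):
        models, truth, event, regions = cassette_fixture
        gene = truth["genes"][0]["gene_id"]
        alignments, _ = simulate.gen_reads(models, {gene: 0.7}, 2000, seed=5)
        counts = quantify_event(event, regions, alignments, "S1")
        assert compute_psi(counts) == pytest.approx(0.7, abs=0.05)

    def test_psi_error_shrinks_with_depth(self, cassette_fixture):
        models, truth, event, regions = cassette_fixture
        gene = truth["genes"][0]["gene_id"]
        errors = []
        for depth in (200, 2000, 20000):
            errs = []
            for rep in range(4):
                alignments, _ = simulate.gen_reads(
                    models, {gene: 0.4}, depth, seed=1000 * depth + rep
                )
                counts = quantify_event(event, regions, alignments, "S1")
                errs.append(abs(compute_psi(counts) - 0.4))
            errors.append(np.mean(errs))
        assert errors[0] > errors[2]


class TestPsiProperties:
    @given(
        c1=st.floats(0, 10, allow_nan=False),
        c2=st.floats(0, 10, allow_nan=False),
    )
    def test_psi_complement_sums_to_one(self, c1, c2):
        if c1 + c2 == 0:
            return
        a = compute_psi(EventCounts("e", "s", 0, 0, c1, c2))
        b = compute_psi(EventCounts("e", "s", 0, 0, c2, c1))
        assert a + b == pytest.approx(1.0)
        assert 0.0 <= a <= 1.0

    @given(
        n1=st.integers(0, 1000),
        n2=st.integers(0, 1000),
        scale=st.integers(2, 9),
    )
    def test_psi_invariant_under_joint_rescaling(self, n1, n2, scale):
        u1, u2 = 200, 50
        if n1 + n2 == 0:
            return
        a = compute_psi(EventCounts("e", "s", n1, n2, n1 / u1, n2 / u2))
        b = compute_psi(
            EventCounts("e", "s", n1 * scale, n2 * scale, n1 * scale / u1, n2 * scale / u2)
        )
        assert a == pytest.approx(b)

    def test_boundaries(self):
        assert compute_psi(EventCounts("e", "s", 1, 0, 0.1, 0.0)) == 1.0
        assert compute_psi(EventCounts("e", "s", 1, 1, 0.2, 0.2)) == 0.5


# ---------------------------------------------------------------------------
# filtering, delta PSI, rpkm, splice-site spanning
# ---------------------------------------------------------------------------

class TestFilterEvents:
    def test_threshold_is_at_least_on_either_variant(self):
        df = pd.DataFrame(
            [
                {"event_id": "kept", "sample_id": "a", "c1": 0.004, "c2": 0.001},
                {"event_id": "dropped", "sample_id": "a", "c1": 0.0029, "c2": 0.0029},
                {"event_id": "edge", "sample_id": "a", "c1": 0.003, "c2": 0.0},
            ]
        )
        assert filter_events(df) == ["edge", "kept"]

    def test_any_sample_retains_event(self):
        df = pd.DataFrame(
            [
                {"event_id": "e", "sample_id": "a", "c1": 0.0, "c2": 0.0},
                {"event_id": "e", "sample_id": "b", "c1": 0.01, "c2": 0.0},
            ]
        )
        assert filter_events(df) == ["e"]

    def test_matches_brute_force_on_random_table(self):
        rng = np.random.default_rng(0)
        rows = [
            {
                "event_id": f"e{i}",
                "sample_id": f"s{j}",
                "c1": float(rng.choice([0, 0.001, 0.0029, 0.003, 0.0031, 0.02])),
                "c2": float(rng.choice([0, 0.001, 0.0029, 0.003, 0.0031, 0.02])),
            }
            for i in range(200)
            for j in range(4)
        ]
        df = pd.DataFrame(rows)
        brute = sorted(
            {
                r["event_id"]
                for r in rows
                if r["c1"] >= 0.003 or r["c2"] >= 0.003
            }
        )
        assert filter_events(df) == brute


class TestDeltaPsi:
    def test_shift_and_flagging(self):
        t = PsiRecord("e", "treated", (0.9, 0.9, 0.9))
        c = PsiRecord("e", "control", (0.2, 0.2, 0.2))
        delta, flagged = delta_psi(t, c)
        assert delta == pytest.approx(0.7)
        assert flagged

    def test_identical_records_not_flagged(self):
        r = PsiRecord("e", "x", (0.5, 0.6))
        delta, flagged = delta_psi(r, r)
        assert delta == 0.0 and not flagged

    def test_nan_samples_dropped_from_mean(self):
        t = PsiRecord("e", "t", (0.8, math.nan, 0.6))
        c = PsiRecord("e", "c", (0.2,))
        delta, flagged = delta_psi(t, c)
        assert delta == pytest.approx(0.5)
        assert flagged

    def test_undefined_side_propagates_missing(self):
        t = PsiRecord("e", "t", (math.nan,))
        c = PsiRecord("e", "c", (0.5,))
        delta, flagged = delta_psi(t, c)
        assert math.isnan(delta) and not flagged

    def test_event_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delta_psi(PsiRecord("a", "t", (0.1,)), PsiRecord("b", "c", (0.1,)))


class TestRpkm:
    def test_hand_computed_value(self):
        assert compute_rpkm(1000, 2000, 10_000_000) == pytest.approx(50.0)

    def test_zero_count(self):
        assert compute_rpkm(0, 2000, 10_000_000) == 0.0

    def test_doubling_library_halves_rpkm(self):
        a = compute_rpkm(500, 1500, 1_000_000)
        b = compute_rpkm(500, 1500, 2_000_000)
        assert a == pytest.approx(2 * b)

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            compute_rpkm(10, 0, 1000)
        with pytest.raises(ValueError):
            compute_rpkm(10, 1000, 0)


class TestSpliceSiteSpanning:
    def test_strict_containment_counts(self):
        assert count_splice_site_spanning([_aln([(90, 140)])], 100) == 1

    def test_read_starting_exactly_on_site_excluded(self):
        assert count_splice_site_spanning([_aln([(100, 150)])], 100) == 0
        assert count_splice_site_spanning([_aln([(50, 100)])], 100) == 0

    def test_junction_gap_does_not_cover(self):
        aln = _aln([(50, 100), (200, 250)])
        assert count_splice_site_spanning([aln], 150) == 0
        assert count_splice_site_spanning([aln], 75) == 1

    def test_matches_exhaustive_scan_on_read_fixture(self):
        rng = np.random.default_rng(3)
        reads = []
        for i in range(500):
            start = int(rng.integers(0, 300))
            if rng.random() < 0.3:
                b1 = int(rng.integers(20, 60))
                gap = int(rng.integers(50, 200))
                reads.append(_aln([(start, start + b1), (start + b1 + gap, start + b1 + gap + 50 - b1)]))
            else:
                reads.append(_aln([(start, start + 50)]))
        for site in (100, 150, 200, 250):
            brute = 0
            for r in reads:
                covered = any(s < site < e for s, e in r.blocks)
                brute += covered
            assert count_splice_site_spanning(reads, site) == brute
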