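"""Anchoring, chaining, gap-arithmetic SV calls, and the catalog merge."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from introscan import asmdiff, synth
from introscan.asmdiff import Anchor, AnchorParams, SVRecord


class TestN50:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([5, 4, 3, 2, 1], 4), ([10], 10), ([1, 1, 1, 1], 1), ([9, 1], 9)],
    )
    def test_known_values(self, lengths, expected):
        assert asmdiff.compute_n50(lengths) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            asmdiff.compute_n50([])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(min_value=1, max_value=1000), min_size=1, max_size=30))
    def test_matches_definition(self, lengths):
        # brute force: largest L among contig lengths whose >=L sum covers half
        total = sum(lengths)
        feasible = [
            L for L in sorted(set(lengths), reverse=True)
            if sum(x for x in lengths if x >= L) >= total / 2
        ]
        assert asmdiff.compute_n50(lengths) == max(feasible)


class TestFindAnchors:
    def test_identity_single_anchor(self):
        seq = synth.generate_reference(1_000, 0.5, 1)
        anchors = asmdiff.find_anchors(seq, seq)
        assert len(anchors) == 1
        a = anchors[0]
        assert (a.ref_start, a.ref_end, a.qry_start, a.qry_end) == (0, 1_000, 0, 1_000)

    def test_insertion_produces_two_anchors(self):
        ref = synth.generate_reference(1_000, 0.5, 2)
        insert = synth.generate_reference(300, 0.5, 99)
        qry = ref[:500] + insert + ref[500:]
        anchors = asmdiff.find_anchors(ref, qry)
        assert len(anchors) == 2
        left, right = anchors
        assert (left.ref_start, left.qry_start) == (0, 0)
        assert left.ref_end == left.qry_end
        assert right.ref_end - right.ref_start == right.qry_end - right.qry_start
        # query side of the right anchor is displaced by the insert length
        assert right.qry_start - right.ref_start == 300

    def test_unrelated_sequences_yield_nothing(self):
        ref = synth.generate_reference(1_000, 0.5, 11)
        qry = synth.generate_reference(1_000, 0.5, 12)
        assert asmdiff.find_anchors(ref, qry) == []

    def test_short_matches_dropped(self):
        ref = synth.generate_reference(2_000, 0.5, 3)
        # 60-bp shared block below min_match_len=100 inside unrelated context
        qry = synth.generate_reference(900, 0.5, 4) + ref[1_000:1_060] + synth.generate_reference(900, 0.5, 5)
        assert asmdiff.find_anchors(ref, qry) == []


def _mk(rs, re, qs, qe):
    return Anchor(rs, re, qs, qe)


def _brute_force_best_chain(anchors, max_overlap=0):
    best_weight, best = 0, []
    for r in range(1, len(anchors) + 1):
        for combo in itertools.permutations(anchors, r):
            ok = all(
                a.ref_end <= b.ref_start + max_overlap
                and a.qry_end <= b.qry_start + max_overlap
                and a.ref_start < b.ref_start
                and a.qry_start < b.qry_start
                and a.ref_end < b.ref_end
                and a.qry_end < b.qry_end
                for a, b in zip(combo, combo[1:])
            )
            if ok:
                w = sum(x.length for x in combo)
                if w > best_weight:
                    best_weight, best = w, list(combo)
    return best_weight


class TestChainAnchors:
    def test_two_collinear_anchors_one_chain(self):
        anchors = [_mk(0, 300, 0, 300), _mk(400, 800, 500, 900)]
        chains = asmdiff.chain_anchors(anchors)
        assert chains == [anchors]

    def test_crossing_anchors_keep_heavier(self):
        heavy = _mk(0, 600, 500, 1_100)
        light = _mk(700, 900, 0, 200)  # crosses the heavy anchor in qry
        chains = asmdiff.chain_anchors([heavy, light])
        assert chains == [[heavy]]

    def test_min_cluster_threshold(self):
        short = _mk(0, 400, 0, 400)
        assert asmdiff.chain_anchors([short], AnchorParams(min_cluster_len=500)) == []
        assert asmdiff.chain_anchors([short], AnchorParams(min_cluster_len=400)) == [[short]]

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 40), st.integers(1, 25), st.integers(0, 40), st.integers(1, 25)
            ),
            min_size=1,
            max_size=7,
        )
    )
    def test_matches_brute_force_weight(self, raw):
        anchors = [
            _mk(rs * 100, rs * 100 + ln * 4, qs * 100, qs * 100 + ln * 4)
            for rs, ln, qs, _ in raw
        ]
        chains = asmdiff.chain_anchors(anchors, AnchorParams(min_cluster_len=1))
        got = max((sum(a.length for a in c) for c in chains), default=0)
        assert got == _brute_force_best_chain(anchors, max_overlap=50)


class TestCallSVs:
    def _setup(self, seed=1):
        ref = synth.generate_reference(2_000, 0.5, seed)
        return ref

    def test_planted_insertion_exact(self):
        ref = self._setup()
        insert = synth.generate_reference(300, 0.5, 77)
        qry = ref[:1_000] + insert + ref[1_000:]
        records = asmdiff.discover_svs(ref, qry, source_genome="g")
        assert len(records) == 1
        rec = records[0]
        assert rec.type == "insertion" and rec.length == 300
        # micro-homology can shift the breakpoint by a few bases
        assert abs(rec.ref_start - 1_000) <= 5
        assert len(rec.alt_sequence) == 300

    def test_planted_deletion_exact(self):
        ref = self._setup(2)
        qry = ref[:600] + ref[850:]
        records = asmdiff.discover_svs(ref, qry)
        assert len(records) == 1
        assert records[0].type == "deletion" and records[0].length == 250

    def test_adjacent_anchors_no_record(self):
        chain = [_mk(0, 500, 0, 500), _mk(500, 1_000, 500, 1_000)]
        ref = qry = synth.generate_reference(1_000, 0.5, 5)
        assert asmdiff.call_svs(chain, ref, qry) == []

    def test_oversize_sv_dropped(self):
        ref = self._setup(3)
        insert = synth.generate_reference(12_000, 0.5, 88)
        qry = ref[:1_000] + insert + ref[1_000:]
        records = asmdiff.discover_svs(ref, qry)
        assert records == []

    def test_indel_gap_difference(self):
        ref = self._setup(4)
        # replace 100 bp with 160 unrelated bp: both gaps positive, indel 60
        qry = ref[:900] + synth.generate_reference(160, 0.5, 55) + ref[1_000:]
        records = asmdiff.discover_svs(ref, qry)
        assert len(records) == 1
        assert records[0].type == "indel" and records[0].length == 60

    def test_containment_overlap_rejected(self):
        ref = synth.generate_reference(1_000, 0.5, 6)
        chain = [_mk(0, 500, 0, 500), _mk(450, 500, 450, 500)]
        with pytest.raises(ValueError):
            asmdiff.call_svs(chain, ref, ref)

    def test_size_bounds_enforced_on_records(self):
        with pytest.raises(ValueError):
            SVRecord("chr", 0, 0, "insertion", 10_001, "A" * 10_001)
        with pytest.raises(ValueError):
            SVRecord("chr", 5, 5, "insertion", 0)


def _rec(start, length, type_="deletion", chrom="chr", genome="g", alt=""):
    end = start if type_ == "insertion" else start + length
    return SVRecord(chrom, start, end, type_, length, alt, genome)


class TestMergeCatalog:
    def test_single_genome_identity(self):
        recs = [_rec(100, 50), _rec(500, 30, "insertion", alt="A" * 30)]
        cat = asmdiff.merge_catalog({"g1": recs})
        assert len(cat.records) == 2
        assert cat.presence.values.all()

    def test_identical_lists_collapse(self):
        recs = [_rec(100, 50)]
        cat = asmdiff.merge_catalog({"g1": recs, "g2": recs})
        assert len(cat.records) == 1
        assert cat.presence.loc["g1", "sv0"] and cat.presence.loc["g2", "sv0"]

    def test_disjoint_records_union(self):
        cat = asmdiff.merge_catalog({"g1": [_rec(100, 50)], "g2": [_rec(900, 40)]})
        assert len(cat.records) == 2
        assert cat.presence.values.sum() == 2
        assert cat.presence.loc["g1"].tolist() == [True, False]

    def test_reciprocal_overlap_rule(self):
        # 50% reciprocal overlap boundary: [100,200) vs [150,250) -> 50/100 = 0.5
        cat = asmdiff.merge_catalog({"g1": [_rec(100, 100)], "g2": [_rec(150, 100)]})
        assert len(cat.records) == 1
        # [100,200) vs [160,260): 40% < 0.5 -> separate
        cat2 = asmdiff.merge_catalog({"g1": [_rec(100, 100)], "g2": [_rec(160, 100)]})
        assert len(cat2.records) == 2

    def test_insertion_tolerance_rule(self):
        a = _rec(100, 300, "insertion", alt="A" * 300)
        near = _rec(108, 250, "insertion", alt="C" * 250)  # within 10 bp, 17% shorter
        far = _rec(150, 300, "insertion", alt="G" * 300)  # breakpoint too far
        cat = asmdiff.merge_catalog({"g1": [a], "g2": [near], "g3": [far]})
        assert len(cat.records) == 2

    def test_representative_is_longest(self):
        cat = asmdiff.merge_catalog({"g1": [_rec(100, 100)], "g2": [_rec(110, 120)]})
        assert cat.records[0].length == 120

    def test_permutation_invariance_and_idempotence(self):
        per_genome = {
            "g1": [_rec(100, 50), _rec(400, 60)],
            "g2": [_rec(120, 45), _rec(900, 80, "insertion", alt="T" * 80)],
            "g3": [_rec(905, 78, "insertion", alt="G" * 78)],
        }
        cat = asmdiff.merge_catalog(per_genome)
        reordered = asmdiff.merge_catalog(dict(reversed(list(per_genome.items()))))
        assert cat.records == reordered.records
        assert cat.presence.equals(reordered.presence)
        # idempotence: re-merging the representatives changes nothing
        again = asmdiff.merge_catalog(
            {g: [r for r, keep in zip(cat.records, cat.presence.loc[g]) if keep] for g in cat.presence.index}
        )
        assert again.records == cat.records


def test_round_trip_recovers_planted_svs():
    """Planted insertions/deletions come back with exact type and length."""
    cfg = synth.SimConfig(seed=31)
    data = synth.simulate_dataset(cfg, n_per_pattern=2, sv_length_range=(80, 3_000))
    ref = data["reference"]
    per_genome = {}
    for pop in cfg.populations:
        for i, g in enumerate(data["genomes"][pop.name]):
            per_genome[f"{pop.name}_g{i}"] = asmdiff.discover_svs(ref, g)
    cat = asmdiff.merge_catalog(per_genome)
    recovered = 0
    for sv in data["panel"]:
        recovered += any(
            r.type == sv.type and r.length == sv.length and abs(r.ref_start - sv.ref_position) <= 25
            for r in cat.records
        )
    assert recovered == len(data["panel"])
    for r in cat.records:
        assert asmdiff.SV_MIN_LEN <= r.length <= asmdiff.SV_MAX_LEN
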