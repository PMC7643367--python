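"""Read QC, local references, mapping, the coverage criteria, concordance."""

import numpy as np
import pytest

from introscan import genotyper, synth
from introscan.genotyper import Placement, QCParams
from introscan.synth import Read


def _read(seq, q=40, name="r"):
    return Read(name, seq, chr(q + 33) * len(seq))


class TestQCReads:
    def test_clean_read_unchanged(self):
        r = _read("ACGT" * 25)
        assert genotyper.qc_reads([r]) == [r]

    def test_many_n_bases_discarded(self):
        r = _read("N" * 40 + "ACGT" * 15)
        assert genotyper.qc_reads([r]) == []

    def test_three_prime_low_quality_trimmed(self):
        seq = "ACGT" * 25
        qual = chr(40 + 33) * 90 + chr(15 + 33) * 10
        out = genotyper.qc_reads([Read("r", seq, qual)])
        assert len(out) == 1
        assert out[0].sequence == seq[:90]

    def test_lowq_fraction_boundary(self):
        # exactly 30% at Q20 is kept (strict >)
        qual = chr(20 + 33) * 30 + chr(40 + 33) * 70
        kept = genotyper.qc_reads([Read("r", "A" * 100, qual)])
        assert len(kept) == 1
        qual_over = chr(20 + 33) * 31 + chr(40 + 33) * 69
        assert genotyper.qc_reads([Read("r", "A" * 100, qual_over)]) == []

    def test_adapter_removal(self):
        adapter = "AGATCGGAAGAG"
        r = _read("ACGT" * 10 + adapter + "ACGT" * 10)
        params = QCParams(adapters=(adapter,))
        assert genotyper.qc_reads([r], params) == []

    def test_all_low_quality_discarded(self):
        r = Read("r", "ACGT" * 10, chr(10 + 33) * 40)
        assert genotyper.qc_reads([r]) == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            Read("r", "ACGT", "III")


class TestBuildLocalReference:
    def test_layout_300bp_sv(self):
        genome = synth.generate_reference(2_000, 0.5, 1)
        seq, regions = genotyper.build_local_reference(genome, 800, 300)
        assert len(seq) == 700
        assert regions.R3 == (200, 500)
        assert regions.R1 == (0, 195) and regions.R2 == (195, 200)
        assert regions.R4 == (500, 505) and regions.R5 == (505, 700)

    def test_minimal_sv(self):
        genome = synth.generate_reference(1_000, 0.5, 1)
        seq, regions = genotyper.build_local_reference(genome, 500, 1)
        assert len(seq) == 401
        assert regions.R3 == (200, 201)

    def test_insufficient_flank_rejected(self):
        genome = synth.generate_reference(1_000, 0.5, 1)
        with pytest.raises(ValueError):
            genotyper.build_local_reference(genome, 150, 300)

    def test_insertion_local_reference_splices_alt(self):
        ref = synth.generate_reference(2_000, 0.5, 2)
        alt = "ACGT" * 50
        seq, regions = genotyper.local_reference_for_sv(ref, 1_000, 1_000, alt)
        assert seq == ref[800:1_000] + alt + ref[1_000:1_200]
        assert regions.R3 == (200, 400)


class TestMapReads:
    def _brute_force(self, reads, ref, max_mm):
        out = []
        for read in reads:
            L = len(read.sequence)
            if L > len(ref):
                continue
            for pos in range(len(ref) - L + 1):
                mm = sum(a != b for a, b in zip(ref[pos : pos + L], read.sequence))
                if mm <= max_mm:
                    out.append((read.name, pos, mm))
        return sorted(out, key=lambda t: (t[1], t[0]))

    def test_exact_substring_maps_at_origin(self):
        ref = synth.generate_reference(700, 0.5, 3)
        r = _read(ref[100:200])
        placements = genotyper.map_reads([r], ref)
        assert any(p.start == 100 and p.mismatches == 0 for p in placements)

    def test_three_mismatches_unmapped(self):
        ref = synth.generate_reference(700, 0.5, 4)
        seq = list(ref[100:200])
        for i in (10, 50, 90):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        assert genotyper.map_reads([_read("".join(seq))], ref, max_mismatches=2) == []

    def test_multi_locus_read_reports_both(self):
        block = synth.generate_reference(120, 0.5, 5)
        ref = block + synth.generate_reference(200, 0.5, 6) + block
        r = _read(block[:100])
        placements = genotyper.map_reads([r], ref)
        assert {p.start for p in placements} == {0, 320}

    def test_matches_brute_force(self):
        ref = synth.generate_reference(500, 0.5, 7)
        rng = np.random.default_rng(8)
        reads = []
        for i in range(30):
            s = int(rng.integers(0, 400))
            seq = list(ref[s : s + 80])
            for pos in rng.choice(80, size=int(rng.integers(0, 4)), replace=False):
                seq[pos] = "ACGT"[int(rng.integers(0, 4))]
            reads.append(_read("".join(seq), name=f"r{i}"))
        got = [(p.read_name, p.start, p.mismatches) for p in genotyper.map_reads(reads, ref)]
        assert got == self._brute_force(reads, ref, 2)

    def test_read_longer_than_reference_skipped(self):
        assert genotyper.map_reads([_read("A" * 50)], "ACGTACGT") == []


def _regions(sv_len=100, flank=200):
    return genotyper.build_local_reference("A" * (sv_len + 2 * flank), flank, sv_len, flank)[1]


def _cover(intervals):
    return [Placement(f"p{i}", lo, 0, hi - lo) for i, (lo, hi) in enumerate(intervals)]


class TestGenotypeCriteria:
    def test_full_coverage_present(self):
        regions = _regions()
        call = genotyper.genotype(_cover([(0, 600)]), regions)
        assert call.call == "present"
        assert call.covered_fractions == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_uncovered_breakpoint_absent(self):
        regions = _regions()
        # everything except one base of R2 (positions 195..200)
        call = genotyper.genotype(_cover([(0, 199), (200, 600)]), regions)
        assert call.covered_fractions[1] == pytest.approx(0.8)
        assert call.call == "absent"

    def test_r3_exactly_60_percent_inclusive(self):
        regions = _regions(sv_len=100)
        # R3 = [200,300); cover exactly 60 bases of it
        call = genotyper.genotype(_cover([(0, 260), (300, 600)]), regions)
        assert call.covered_fractions[2] == pytest.approx(0.60)
        assert call.call == "present"
        under = genotyper.genotype(_cover([(0, 259), (300, 600)]), regions)
        assert under.call == "absent"

    def test_r1_r5_50_percent_inclusive(self):
        regions = _regions(sv_len=100)
        # R1 = [0,195): cover 98/195 > 0.5; exactly half is impossible on 195
        call = genotyper.genotype(_cover([(97, 600)]), regions)
        assert call.covered_fractions[0] == pytest.approx(98 / 195)
        assert call.call == "present"
        under = genotyper.genotype(_cover([(98, 600)]), regions)
        assert under.call == "absent"

    def test_monotone_in_reads(self):
        """Adding placements never flips present -> absent."""
        regions = _regions(sv_len=100)
        base = _cover([(0, 260), (300, 600)])
        call = genotyper.genotype(base, regions)
        assert call.call == "present"
        for extra in [(100, 250), (250, 350), (0, 600)]:
            more = genotyper.genotype(base + _cover([extra]), regions)
            assert more.call == "present"
            assert all(
                b >= a
                for a, b in zip(call.covered_fractions, more.covered_fractions)
            )


class TestConcordance:
    def _calls(self, matrix):
        calls = []
        for ind, svs in matrix.items():
            for sv_id, present in svs.items():
                calls.append(
                    genotyper.GenotypeCall(ind, sv_id, "present" if present else "absent", (1,) * 5)
                )
        return calls

    def test_perfect_matrix(self):
        calls = self._calls({"e1": {"sv0": True}, "a1": {"sv0": False}})
        rep = genotyper.concordance(calls, {"sv0": "A-a"}, {"e1": "EUR", "a1": "ASIA_N"})
        assert rep["overall"]["rate"] == 1.0

    def test_half_flipped(self):
        calls = self._calls(
            {"e1": {"sv0": True, "sv1": False}, "a1": {"sv0": False, "sv1": False}}
        )
        # sv1 is A-a: expected present for EUR (e1 wrong), absent for Asia (a1 right)
        rep = genotyper.concordance(
            calls, {"sv0": "A-a", "sv1": "A-a"}, {"e1": "EUR", "a1": "ASIA_N"}
        )
        assert rep["overall"]["rate"] == 0.75
        assert rep["per_group"]["EUR"]["rate"] == 0.5

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            genotyper.concordance([], {}, {})

    def test_unassigned_individual_rejected(self):
        calls = self._calls({"x": {"sv0": True}})
        with pytest.raises(ValueError, match="group"):
            genotyper.concordance(calls, {"sv0": "A-p"}, {})


class TestEndToEnd:
    def test_carrier_present_noncarrier_absent(self, small_dataset, small_config):
        """Error-free 20x reads: carriers present, non-carriers absent."""
        panel = small_dataset["panel"]
        ref = small_dataset["reference"]
        truth = small_dataset["truth"]
        pop2grp = dict(truth[["population", "group"]].drop_duplicates().values)
        sv = next(s for s in panel if s.type == "insertion")
        lref, regions = genotyper.local_reference_for_sv(
            ref, sv.ref_position, sv.ref_position, sv.sequence
        )
        carrier_pop = sorted(sv.carrier_populations)[0]
        non_pop = next(
            p.name for p in small_config.populations if p.name not in sv.carrier_populations
        )
        for pop, expected in [(carrier_pop, "present"), (non_pop, "absent")]:
            reads = small_dataset["reads"][f"{pop}_g0"]
            placements = genotyper.map_reads(genotyper.qc_reads(reads), lref)
            call = genotyper.genotype(placements, regions)
            assert call.call == expected, (pop, call.covered_fractions)

    def test_concordance_degrades_with_error_rate(self, small_config):
        """Rising per-base error pushes carrier coverage down, never up."""
        import dataclasses

        rates = []
        for err in (0.0, 0.05, 0.10):
            cfg = dataclasses.replace(small_config, error_rate=err, depth=8.0, seed=77)
            data = synth.simulate_dataset(cfg, n_per_pattern=1, sv_length_range=(150, 400))
            sv = next(s for s in data["panel"] if s.type == "insertion")
            lref, regions = genotyper.local_reference_for_sv(
                data["reference"], sv.ref_position, sv.ref_position, sv.sequence
            )
            carrier = sorted(sv.carrier_populations)[0]
            reads = data["reads"][f"{carrier}_g0"]
            placements = genotyper.map_reads(reads, lref)
            call = genotyper.genotype(placements, regions)
            rates.append(np.mean(call.covered_fractions))
        assert rates[0] >= rates[1] >= rates[2]
        assert rates[0] > rates[2]
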