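"""Sequence profiles: hydropathy, scans, consensus score, mutations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fibrilmetrics as fm
from fibrilmetrics import profiles
from fibrilmetrics.exceptions import InputError, ParameterError, ParseError
from fibrilmetrics.scales import KYTE_DOOLITTLE


class TestHydropathy:
    def test_single_residue_values(self):
        np.testing.assert_allclose(fm.hydropathy_profile("III"), [4.5] * 3)
        np.testing.assert_allclose(fm.hydropathy_profile("R"), [-4.5])

    def test_profile_mean_independent_of_window(self):
        seq = "GASTRIC"
        full = fm.hydropathy_profile(seq, window=len(seq))
        # full-length window: every position sees the whole-sequence mean at
        # the centre; compare overall means instead of positions
        assert fm.hydropathy_profile(seq, window=1).mean() == pytest.approx(
            np.mean([KYTE_DOOLITTLE[c] for c in seq]))
        assert full[len(seq) // 2] == pytest.approx(
            np.mean([KYTE_DOOLITTLE[c] for c in seq]))

    def test_unknown_letter_rejected(self):
        with pytest.raises(InputError):
            fm.hydropathy_profile("ACXDE")

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            fm.hydropathy_profile("ACDE", window=2)


class TestScaleScan:
    SCALE = {c: 0.0 for c in KYTE_DOOLITTLE}

    def test_run_shorter_than_min_run_ignored(self):
        scale = dict(self.SCALE, I=10.0)
        hits = fm.scale_scan("AIIIIA", scale, threshold=5.0, min_run=5)
        assert hits.positions == frozenset()

    def test_run_of_five_reported(self):
        scale = dict(self.SCALE, I=10.0)
        hits = fm.scale_scan("AIIIIIA", scale, threshold=5.0, min_run=5)
        assert hits.positions == frozenset({2, 3, 4, 5, 6})

    def test_all_below_threshold_empty(self):
        hits = fm.scale_scan("ACDEF", self.SCALE, threshold=1.0, min_run=1)
        assert hits.positions == frozenset()

    def test_extreme_thresholds(self):
        seq = "ACDEFGHIKL"
        everything = fm.scale_scan(seq, KYTE_DOOLITTLE, threshold=-np.inf)
        nothing = fm.scale_scan(seq, KYTE_DOOLITTLE, threshold=np.inf)
        assert everything.positions == frozenset(range(1, len(seq) + 1))
        assert nothing.positions == frozenset()

    def test_below_mode(self):
        hits = fm.scale_scan("IIRII", KYTE_DOOLITTLE, threshold=0.0, mode="below")
        assert hits.positions == frozenset({3})


class TestParsePredictorOutput:
    def _write(self, tmp_path, lines):
        p = tmp_path / "pred.tsv"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_waltz_strictly_above_zero(self, tmp_path):
        path = self._write(tmp_path, ["1\t-0.1", "2\t0.0", "3\t0.2"])
        hits = fm.parse_predictor_output(path, "WALTZ", 5)
        assert hits.positions == frozenset({3})

    def test_foldamyloid_requires_run_of_five(self, tmp_path):
        path = self._write(tmp_path, [f"{i}\t30.0" for i in range(1, 5)])
        assert fm.parse_predictor_output(path, "FoldAmyloid", 10).positions == frozenset()
        path = self._write(tmp_path, [f"{i}\t30.0" for i in range(1, 6)])
        assert fm.parse_predictor_output(path, "FoldAmyloid", 10).positions == frozenset(
            {1, 2, 3, 4, 5})

    def test_amylpred_flag_column(self, tmp_path):
        path = self._write(tmp_path, ["1\t0", "2\t1", "3\t1"])
        assert fm.parse_predictor_output(path, "AmylPred", 3).positions == frozenset({2, 3})

    def test_empty_file_empty_hits(self, tmp_path):
        path = self._write(tmp_path, ["# header only"])
        assert fm.parse_predictor_output(path, "TANGO", 4).positions == frozenset()

    def test_position_out_of_bounds_reports_line(self, tmp_path):
        path = self._write(tmp_path, ["1\t0.5", "9\t0.5"])
        with pytest.raises(ParseError, match="line 2"):
            fm.parse_predictor_output(path, "WALTZ", 5)

    def test_malformed_row_reports_line(self, tmp_path):
        path = self._write(tmp_path, ["1\t0.5", "oops"])
        with pytest.raises(ParseError, match="line 2"):
            fm.parse_predictor_output(path, "WALTZ", 5)


class TestConsensusScore:
    def _hits(self, name, positions, n):
        return fm.PredictorHits(name, frozenset(positions), n)

    def test_extremes_and_counting(self):
        seq = "ACDEF"
        names = profiles.PREDICTOR_NAMES
        hit_sets = [self._hits(names[0], {1, 2}, 5),
                    self._hits(names[1], {1, 2}, 5),
                    self._hits(names[2], {1, 2}, 5),
                    self._hits(names[3], {1}, 5),
                    self._hits(names[4], {1}, 5)]
        prof = fm.consensus_amyloid_score(hit_sets, seq)
        assert prof.scores.tolist() == [5, 3, 0, 0, 0]
        assert prof.contributors[2] == ()

    def test_duplicate_predictor_rejected(self):
        hs = [self._hits("WALTZ", set(), 3)] * 5
        with pytest.raises(InputError):
            fm.consensus_amyloid_score(hs, "ACD")

    def test_score_equals_indicator_sum_on_random_hit_sets(self):
        """The consensus equals the sum of per-predictor indicators on 1000
        random hit-set draws (exhaustive counting oracle)."""
        rng = np.random.default_rng(0)
        seq = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(1000):
            hit_sets = [fm.PredictorHits(name,
                                         frozenset(np.flatnonzero(
                                             rng.random(len(seq)) < 0.3) + 1),
                                         len(seq))
                        for name in profiles.PREDICTOR_NAMES]
            prof = fm.consensus_amyloid_score(hit_sets, seq)
            oracle = sum(h.indicator() for h in hit_sets)
            np.testing.assert_array_equal(prof.scores, oracle)


class TestMutations:
    def test_identical_sequences_no_records(self):
        assert fm.list_mutations("ACDEF", "ACDEF") == []

    def test_template_plus_ten_substitutions(self):
        patient = fm.patient_sequence_synthetic()
        records = fm.list_mutations(patient, fm.GERMLINE_TEMPLATE_SYNTHETIC)
        assert [r.position for r in records] == [25, 31, 33, 35, 40, 53, 76,
                                                 94, 95, 98]
        assert records[0].label == "S25R"

    def test_single_substitution_from_to(self):
        (rec,) = fm.list_mutations("ACDEF", "AADEF")
        assert (rec.position, rec.germline, rec.patient) == (2, "A", "C")

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            fm.list_mutations("ACDE", "ACDEF")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_roundtrip_count_matches_applied_mutations(self, data):
        letters = "ACDEFGHIKLMNPQRSTVWY"
        seq = "".join(data.draw(st.lists(st.sampled_from(letters),
                                         min_size=10, max_size=30)))
        positions = data.draw(st.lists(
            st.integers(1, len(seq)), unique=True, max_size=5))
        muts = []
        for pos in positions:
            new = data.draw(st.sampled_from(
                [c for c in letters if c != seq[pos - 1]]))
            muts.append((seq[pos - 1], pos, new))
        mutated = fm.apply_mutations(seq, muts)
        assert len(fm.list_mutations(mutated, seq)) == len(muts)


class TestClassifyMutation:
    def _record(self, label):
        from fibrilmetrics.synthetic import parse_mutation
        frm, pos, to = parse_mutation(label)
        return fm.MutationRecord(position=pos, germline=frm, patient=to)

    def test_charge_gain_and_loss(self):
        layer = fm.generate_beta_arch_layer(100)
        gained = fm.classify_mutation(self._record("N53D"), layer)
        lost = fm.classify_mutation(self._record("D94A"), layer)
        assert gained.charge_change == -1   # 0 -> -1: acquires a negative charge
        assert lost.charge_change == +1     # -1 -> 0: charge removed
        assert fm.classify_mutation(self._record("S31R"), layer).charge_change == +1

    def test_exposed_residue_on_sparse_layer_is_surface(self):
        layer = fm.generate_beta_arch_layer(30)
        rec = fm.classify_mutation(self._record("A5V"), layer)
        assert rec.exposure == "surface"
        assert rec.charge_change == 0

    def test_buried_residue_in_dense_cluster(self):
        rng = np.random.default_rng(1)
        cloud = rng.normal(scale=4.0, size=(60, 3))
        cloud[0] = 0.0
        model = fm.AtomicModel.from_arrays(cloud)
        rec = fm.classify_mutation(self._record("A1V"), model)
        assert rec.exposure == "buried"

    def test_cdr_and_cavity_annotations(self):
        layer = fm.generate_beta_arch_layer(100)
        rec = fm.classify_mutation(self._record("D94A"), layer,
                                   cdr_ranges=[(89, 97)],
                                   cavity_linings={"C": {94, 95}})
        assert rec.in_cdr and rec.cavity_lining == ["C"]

    def test_missing_residue_warns_not_raises(self):
        layer = fm.generate_beta_arch_layer(10)
        rec = fm.classify_mutation(self._record("D94A"), layer)
        assert rec.exposure is None and rec.warnings


def test_ordered_core_is_91_residues():
    assert fm.ordered_core_residue_count() == 91
    assert fm.ordered_core_residue_count(fm.ORDERED_CORE_RANGE) == 91
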