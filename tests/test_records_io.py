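"""Record container, WFDB round trips, resampling and record selection."""

import numpy as np
import pandas as pd
import pytest

import pvcnet as pv
from pvcnet.records import MITBIH_EXCLUDED_RECORDS, SelectionPolicy
from pvcnet.wfdb_io import WFDBFormatError, read_record, write_record


def _small_record(seed=2, n_beats=10, fs=360.0):
    rec, gt = pv.generate_record(
        pv.RhythmSpec(n_beats=n_beats, pvc_fraction=0.3, seed=seed, sampling_rate_hz=fs)
    )
    return rec, gt


class TestWfdbRoundTrip:
    def test_two_lead_round_trip_is_bit_exact(self, tmp_path):
        rec, _ = _small_record()
        base = write_record(tmp_path, rec, extra_leads={"V1": rec.samples * 0.5})
        back = read_record(base, "MLII")
        assert np.array_equal(back.samples, rec.samples)
        assert [(a.sample_index, a.symbol, a.label) for a in back.annotations] == [
            (a.sample_index, a.symbol, a.label) for a in rec.annotations
        ]
        assert back.sampling_rate_hz == rec.sampling_rate_hz
        assert back.subject_id == rec.subject_id

    def test_long_inter_annotation_gaps_survive_round_trip(self, tmp_path):
        # gaps beyond 1023 samples exercise the long-interval (SKIP) encoding
        samples = np.zeros(200000)
        anns = [
            pv.BeatAnnotation.from_symbol(i, s)
            for i, s in [(10, "N"), (5000, "V"), (150000, "N"), (199999, "A")]
        ]
        rec = pv.AnnotatedRecord("G1", "G1", "MLII", 360.0, samples, anns)
        back = read_record(write_record(tmp_path, rec), "MLII")
        assert [(a.sample_index, a.symbol) for a in back.annotations] == [
            (10, "N"), (5000, "V"), (150000, "N"), (199999, "A")
        ]

    def test_missing_file_error_names_the_file(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="missing.hea"):
            read_record(tmp_path / "missing", "MLII")

    def test_absent_lead_error_lists_available_leads(self, tmp_path):
        rec, _ = _small_record()
        base = write_record(tmp_path, rec, extra_leads={"V1": rec.samples})
        with pytest.raises(WFDBFormatError, match="MLII.*V1"):
            read_record(base, "lead II")

    def test_fixture_manifest_matches_read_annotations(self, tmp_path):
        rec, gt = _small_record(n_beats=10)
        pv.synthetic.write_dataset(tmp_path, [(rec, gt)])
        manifest = pd.read_csv(tmp_path / "manifest.csv")
        back = read_record(tmp_path / rec.record_id, "MLII")
        assert len(back.annotations) == 10
        assert list(manifest["r_index"]) == [a.sample_index for a in back.annotations]
        assert list(manifest["label"]) == [a.label.value for a in back.annotations]


class TestRecordInvariants:
    def test_annotation_index_beyond_signal_is_rejected(self):
        with pytest.raises(ValueError, match="150"):
            pv.AnnotatedRecord(
                "X", "X", "MLII", 360.0, np.zeros(100),
                [pv.BeatAnnotation.from_symbol(150, "N")],
            )

    def test_non_increasing_annotation_indices_are_rejected(self):
        anns = [pv.BeatAnnotation.from_symbol(i, "N") for i in [10, 10]]
        with pytest.raises(ValueError, match="strictly increasing"):
            pv.AnnotatedRecord("X", "X", "MLII", 360.0, np.zeros(100), anns)

    def test_nonpositive_rate_and_empty_signal_are_rejected(self):
        with pytest.raises(ValueError):
            pv.AnnotatedRecord("X", "X", "MLII", 0.0, np.zeros(10))
        with pytest.raises(ValueError):
            pv.AnnotatedRecord("X", "X", "MLII", 360.0, np.array([]))


class TestResample:
    def test_identity_when_target_equals_source(self):
        rec, _ = _small_record()
        out = pv.resample_record(rec, rec.sampling_rate_hz)
        assert np.array_equal(out.samples, rec.samples)
        assert [a.sample_index for a in out.annotations] == [
            a.sample_index for a in rec.annotations
        ]

    def test_exact_ratio_index_rescaling(self):
        samples = np.sin(np.arange(720) / 10.0)
        rec = pv.AnnotatedRecord(
            "X", "X", "MLII", 360.0, samples, [pv.BeatAnnotation.from_symbol(360, "N")]
        )
        out = pv.resample_record(rec, 200.0)
        assert out.annotations[0].sample_index == 200

    def test_sinusoid_against_closed_form(self):
        # 5 Hz tone sampled at 360 Hz, resampled to 200 Hz, must match the
        # analytically sampled tone on the interior 90 %
        t360 = np.arange(3600) / 360.0
        rec = pv.AnnotatedRecord("X", "X", "MLII", 360.0, np.sin(2 * np.pi * 5 * t360))
        out = pv.resample_record(rec, 200.0)
        t200 = np.arange(out.samples.size) / 200.0
        oracle = np.sin(2 * np.pi * 5 * t200)
        n = out.samples.size
        sl = slice(n // 20, n - n // 20)
        r = np.corrcoef(out.samples[sl], oracle[sl])[0, 1]
        assert r > 0.999

    def test_annotation_count_and_order_preserved(self):
        rec, _ = _small_record(n_beats=20)
        for target in (90.0, 200.0, 500.0):
            out = pv.resample_record(rec, target)
            idx = [a.sample_index for a in out.annotations]
            assert len(idx) == len(rec.annotations)
            assert all(b > a for a, b in zip(idx, idx[1:]))

    def test_invalid_target_rate(self):
        rec, _ = _small_record()
        with pytest.raises(ValueError):
            pv.resample_record(rec, -1.0)


class TestSelection:
    def _records(self, ids, pvc_flags):
        out = []
        for rid, has_pvc in zip(ids, pvc_flags):
            frac = 0.5 if has_pvc else 0.0
            rec, _ = pv.generate_record(
                pv.RhythmSpec(n_beats=6, pvc_fraction=frac, seed=1), record_id=rid
            )
            out.append(rec)
        return out

    def test_exclusion_list(self):
        recs = self._records(["101", "102", "106"], [True, True, True])
        kept = pv.select_records(recs, SelectionPolicy(exclude_ids=MITBIH_EXCLUDED_RECORDS))
        assert [r.record_id for r in kept] == ["101", "106"]

    def test_pvc_presence_requirement(self):
        recs = self._records(["a", "b"], [True, False])
        kept = pv.select_records(recs, SelectionPolicy(require_pvc=True))
        assert [r.record_id for r in kept] == ["a"]

    def test_truncation_is_deterministic_by_record_id(self):
        ids = [f"I{k:02d}" for k in range(61)]
        recs = self._records(ids[::-1], [True] * 61)  # shuffled input order
        kept = pv.select_records(recs, SelectionPolicy(max_records=22))
        assert [r.record_id for r in kept] == sorted(ids)[:22]

    def test_output_is_subset_and_idempotent(self):
        recs = self._records(["r1", "r2", "r3"], [True, False, True])
        policy = SelectionPolicy(exclude_ids=frozenset({"r2"}), require_pvc=True)
        once = pv.select_records(recs, policy)
        assert set(r.record_id for r in once) <= set(r.record_id for r in recs)
        assert pv.select_records(once, policy) == once


class TestSymbolMapping:
    @pytest.mark.parametrize(
        "symbol,label",
        [("V", pv.BeatLabel.PVC), ("N", pv.BeatLabel.NORMAL), ("A", pv.BeatLabel.OTHER),
         ("/", pv.BeatLabel.OTHER), ("?", pv.BeatLabel.OTHER)],
    )
    def test_default_mapping(self, symbol, label):
        assert pv.map_annotation_symbol(symbol) is label

    def test_mapping_is_configurable(self):
        table = {"N": pv.BeatLabel.NORMAL, "L": pv.BeatLabel.NORMAL, "V": pv.BeatLabel.PVC}
        assert pv.map_annotation_symbol("L", table) is pv.BeatLabel.NORMAL
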