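"""Cohort manifest, WAV, lexicon, and feature-table I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy.io import wavfile

from speechstate.corpus_io import (
    AudioFormatError,
    AudioSegment,
    CallRecord,
    Cohort,
    MalformedCallError,
    ResponseRecord,
    SchemaError,
    read_category_lexicon,
    read_cohort,
    read_norm_lexicon,
    read_wav,
    write_cohort,
    write_feature_table,
    write_norm_lexicon,
    NORM_NAMES,
)
from speechstate.feature_assembly import CallFeatureRow, default_manifest


def _manifest_frame(n_calls=2, pid="P1", rating=5):
    rows = []
    times = ["2024-01-05T10:00:00", "2024-01-02T10:00:00"][:n_calls]
    for t in times:
        for q in (1, 2, 3):
            rows.append(
                {
                    "participant_id": pid,
                    "call_time": t,
                    "prompt_index": q,
                    "transcript": f"hello world {q}",
                    "audio_path": "",
                    "provider_rating": rating,
                    "diagnosis": "bipolar",
                    "rejected": 0,
                }
            )
    return pd.DataFrame(rows)


class TestReadCohort:
    def test_groups_rows_into_calls(self, tmp_path):
        path = tmp_path / "manifest.csv"
        _manifest_frame().to_csv(path, index=False)
        cohort = read_cohort(path)
        assert cohort.participant_ids == ["P1"]
        assert len(cohort.participants["P1"]) == 2
        assert all(len(c.responses) == 3 for c in cohort.participants["P1"])
        assert cohort.diagnoses["P1"] == "bipolar"

    def test_calls_sorted_by_time(self, tmp_path):
        path = tmp_path / "manifest.csv"
        _manifest_frame().to_csv(path, index=False)  # out-of-order times
        calls = read_cohort(path).participants["P1"]
        assert calls[0].call_time < calls[1].call_time

    def test_missing_column_is_schema_error(self, tmp_path):
        frame = _manifest_frame().drop(columns=["provider_rating"])
        path = tmp_path / "manifest.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="provider_rating"):
            read_cohort(path)

    def test_wrong_prompt_count_names_call(self, tmp_path):
        frame = _manifest_frame().iloc[:-1]  # drop one prompt row
        path = tmp_path / "manifest.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(MalformedCallError, match="2 prompt rows"):
            read_cohort(path)

    def test_jsonl_manifest(self, tmp_path):
        path = tmp_path / "manifest.jsonl"
        _manifest_frame().to_json(path, orient="records", lines=True)
        assert read_cohort(path).n_calls == 2

    def test_round_trip_identity(self, tmp_path):
        path = tmp_path / "manifest.csv"
        _manifest_frame().to_csv(path, index=False)
        cohort = read_cohort(path)
        out = write_cohort(cohort, tmp_path / "out", write_audio=False)
        again = read_cohort(out)
        assert again.participant_ids == cohort.participant_ids
        for a, b in zip(cohort.participants["P1"], again.participants["P1"]):
            assert a.call_time == b.call_time
            assert a.provider_rating == b.provider_rating
            assert [r.transcript for r in a.responses] == [
                r.transcript for r in b.responses
            ]


class TestReadWav:
    def test_mono_int16(self, tmp_path):
        path = tmp_path / "a.wav"
        wavfile.write(path, 8000, np.zeros(8000, dtype=np.int16))
        seg = read_wav(path)
        assert seg.samples.size == 8000 and seg.sample_rate == 8000

    def test_stereo_identical_channels_averages(self, tmp_path):
        path = tmp_path / "a.wav"
        chan = (np.sin(np.linspace(0, 10, 800)) * 10000).astype(np.int16)
        wavfile.write(path, 8000, np.stack([chan, chan], axis=1))
        seg = read_wav(path)
        np.testing.assert_allclose(seg.samples, chan / 32768.0, atol=1e-12)

    def test_full_scale_rescaling(self, tmp_path):
        path = tmp_path / "a.wav"
        wavfile.write(path, 8000, np.array([32767, -32768], dtype=np.int16))
        seg = read_wav(path)
        assert seg.samples[0] == pytest.approx(32767 / 32768)
        assert seg.samples[1] == pytest.approx(-1.0)

    def test_non_wav_is_format_error(self, tmp_path):
        path = tmp_path / "a.wav"
        path.write_bytes(b"not audio at all")
        with pytest.raises(AudioFormatError):
            read_wav(path)

    def test_empty_segment_rejected(self):
        with pytest.raises(AudioFormatError):
            AudioSegment(samples=np.array([]), sample_rate=8000)


class TestNormLexicon:
    def test_read_and_case_folding(self, tmp_path):
        path = tmp_path / "norms.csv"
        frame = pd.DataFrame(
            [
                {"word": "Happy", **{n: 0.5 for n in NORM_NAMES}},
                {"word": "sad", **{n: 0.3 for n in NORM_NAMES}},
            ]
        )
        frame.to_csv(path, index=False)
        lex = read_norm_lexicon(path)
        assert len(lex) == 2
        assert lex.get("happy") is not None and lex.get("HAPPY") is not None

    def test_missing_norm_column(self, tmp_path):
        path = tmp_path / "norms.csv"
        cols = {n: 0.5 for n in NORM_NAMES if n != "valence"}
        pd.DataFrame([{"word": "happy", **cols}]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="valence"):
            read_norm_lexicon(path)

    def test_duplicate_last_wins(self, tmp_path, caplog):
        path = tmp_path / "norms.csv"
        rows = [
            {"word": "happy", **{n: 0.1 for n in NORM_NAMES}},
            {"word": "happy", **{n: 0.9 for n in NORM_NAMES}},
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
        with caplog.at_level("WARNING"):
            lex = read_norm_lexicon(path)
        assert lex.get("happy")[0] == pytest.approx(0.9)
        assert "duplicate" in caplog.text

    def test_round_trip(self, tmp_path, norm_lexicon):
        path = write_norm_lexicon(norm_lexicon, tmp_path / "norms.csv")
        again = read_norm_lexicon(path)
        assert len(again) == len(norm_lexicon)
        np.testing.assert_allclose(again.get("happy"), norm_lexicon.get("happy"))


class TestCategoryLexicon:
    def test_liwc_style_dic(self, tmp_path):
        path = tmp_path / "cats.dic"
        path.write_text("%\n1 posemo\n2 negemo\n%\nhappy 1\njoy* 1\nsad 2\n")
        lex = read_category_lexicon(path)
        assert lex.matches("posemo", "joyful")  # wildcard prefix
        assert lex.matches("posemo", "happy")
        assert not lex.matches("negemo", "happy")

    def test_yaml_alternative(self, tmp_path):
        path = tmp_path / "cats.yaml"
        path.write_text("posemo: [happy, joy*]\nnegemo: [sad]\n")
        lex = read_category_lexicon(path)
        assert lex.matches("posemo", "joyous")

    def test_empty_category_is_schema_error(self, tmp_path):
        path = tmp_path / "cats.dic"
        path.write_text("%\n1 posemo\n2 negemo\n%\nhappy 1\n")
        with pytest.raises(SchemaError, match="negemo"):
            read_category_lexicon(path)


class TestFeatureTable:
    def _rows(self, manifest, n=2):
        rng = np.random.default_rng(0)
        return [
            CallFeatureRow(
                participant_id="P1",
                call_time=pd.Timestamp("2024-01-01") + pd.Timedelta(days=i),
                provider_rating=5,
                values=rng.normal(size=210),
                manifest=manifest,
            )
            for i in range(n)
        ]

    def test_shape_and_round_trip(self, tmp_path, manifest):
        rows = self._rows(manifest)
        path = write_feature_table(rows, tmp_path / "f.csv")
        frame = pd.read_csv(path)
        assert frame.shape == (2, 213)  # 3 metadata + 210 features
        np.testing.assert_allclose(
            frame[manifest.call_feature_names()].to_numpy()[0],
            rows[0].values,
            atol=1e-9,
        )

    def test_inconsistent_manifests_rejected(self, tmp_path, manifest):
        other = default_manifest(
            categories=tuple(c.upper() for c in manifest.categories)
        )
        rows = self._rows(manifest, 1) + [
            CallFeatureRow(
                participant_id="P2",
                call_time=pd.Timestamp("2024-01-01"),
                provider_rating=4,
                values=np.zeros(210),
                manifest=other,
            )
        ]
        with pytest.raises(SchemaError):
            write_feature_table(rows, tmp_path / "f.csv")


def test_call_record_requires_three_prompts():
    responses = [
        ResponseRecord(prompt_index=i, transcript="x") for i in (1, 2)
    ]
    with pytest.raises(MalformedCallError):
        CallRecord(
            participant_id="P1",
            call_time="2024-01-01",
            responses=responses,
            provider_rating=5,
        )


def test_rating_bounds_enforced():
    responses = [ResponseRecord(prompt_index=i, transcript="x") for i in (1, 2, 3)]
    with pytest.raises(ValueError):
        CallRecord(
            participant_id="P1",
            call_time="2024-01-01",
            responses=responses,
            provider_rating=11,
        )
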