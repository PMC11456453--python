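"""Data model and file-format round trips."""

import json
import math

import pytest

from speechmarker.corpus import (
    DEFAULT_TAG_MAPPING,
    AnnotatedTranscript,
    CoarseClass,
    CohortRow,
    FrequencyLexicon,
    ImageResponse,
    ParseError,
    TagMapping,
    Token,
    Utterance,
    ValidationError,
    read_cohort,
    read_feature_table,
    read_lexicon,
    read_transcript,
    write_cohort,
    write_feature_table,
    write_transcript,
)
from speechmarker.features import FEATURE_NAMES


class TestToken:
    def test_filled_pause_must_be_other_class(self):
        with pytest.raises(ValidationError):
            Token(surface="呃", char_count=1, coarse_class=CoarseClass.VERB,
                  flags=frozenset({"filled_pause"}))

    def test_cjk_char_count_checked_against_surface(self):
        with pytest.raises(ValidationError, match="char_count"):
            Token(surface="好喝", char_count=1)

    def test_romanized_surface_char_count_authoritative(self):
        t = Token(surface="haohe", char_count=2)
        assert t.char_count == 2

    @pytest.mark.parametrize("bad_count", [0, -1])
    def test_char_count_positive(self, bad_count):
        with pytest.raises(ValidationError):
            Token(surface="茶", char_count=bad_count)


class TestTagMapping:
    @pytest.mark.parametrize(
        "raw,surface,expected",
        [
            ("Nh", "他", CoarseClass.PRON),
            ("Na", "茶", CoarseClass.NOUN),
            ("Nb", "王", CoarseClass.NOUN),      # prefix fallback N -> NOUN
            ("VC", "泡", CoarseClass.VERB),
            ("A", "好", CoarseClass.ADJ),
            ("D", "很", CoarseClass.ADV),
            ("P", "被", CoarseClass.PASSIVE_MARKER_BEI),
            ("P", "把", CoarseClass.PASSIVE_MARKER_BA),
            ("Caa", "和", CoarseClass.OTHER),    # unknown tag -> OTHER
        ],
    )
    def test_default_ckip_mapping(self, raw, surface, expected):
        assert DEFAULT_TAG_MAPPING.resolve(raw, surface) == expected

    def test_filled_pause_flag_wins(self):
        assert DEFAULT_TAG_MAPPING.resolve("VC", "喝", {"filled_pause"}) == CoarseClass.OTHER

    def test_bei_ba_lists_must_be_disjoint(self):
        with pytest.raises(ValidationError):
            TagMapping(tag_map={}, bei_forms=("被",), ba_forms=("被",))


class TestTranscriptIO:
    def _sample(self):
        return {
            "participant_id": "p1",
            "responses": [
                {
                    "image_id": 1,
                    "utterances": [
                        {"tokens": [{"surface": "他", "char_count": 1, "raw_tag": "Nh"},
                                    {"surface": "泡", "char_count": 1, "raw_tag": "VC"}],
                         "trailing_pause_s": 0.8},
                        {"tokens": [{"surface": "茶", "char_count": 1, "raw_tag": "Na"}]},
                    ],
                }
            ],
        }

    def test_read_valid_transcript(self, tmp_path):
        p = tmp_path / "t.json"
        p.write_text(json.dumps(self._sample()), encoding="utf-8")
        t = read_transcript(p)
        assert t.participant_id == "p1"
        assert len(t.responses[0].utterances) == 2
        assert t.responses[0].utterances[0].tokens[0].coarse_class == CoarseClass.PRON

    def test_negative_pause_rejected(self, tmp_path):
        data = self._sample()
        data["responses"][0]["utterances"][0]["trailing_pause_s"] = -1
        p = tmp_path / "t.json"
        p.write_text(json.dumps(data), encoding="utf-8")
        with pytest.raises(ValidationError, match="trailing_pause_s"):
            read_transcript(p)

    def test_malformed_json_names_line(self, tmp_path):
        p = tmp_path / "t.json"
        p.write_text("{not json", encoding="utf-8")
        with pytest.raises(ParseError, match="line"):
            read_transcript(p)

    def test_write_read_round_trip(self, tmp_path, any_fixture):
        transcript, _, _ = any_fixture
        p = tmp_path / "t.json"
        write_transcript(transcript, p)
        again = read_transcript(p)
        assert again.participant_id == transcript.participant_id
        for r0, r1 in zip(transcript.responses, again.responses):
            for u0, u1 in zip(r0.utterances, r1.utterances):
                assert u0.surfaces == u1.surfaces
                assert u0.trailing_pause_s == u1.trailing_pause_s
                assert [t.flags for t in u0.tokens] == [t.flags for t in u1.tokens]

    def test_duplicate_image_id_rejected(self):
        u = Utterance(tokens=(Token(surface="茶", char_count=1),))
        with pytest.raises(ValidationError, match="image_id"):
            AnnotatedTranscript(
                participant_id="p",
                responses=(ImageResponse(1, (u,)), ImageResponse(1, (u,))),
            )


class TestLexiconIO:
    def test_basic_read(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("茶\t500\n泡\t200\n", encoding="utf-8")
        lex = read_lexicon(p)
        assert len(lex) == 2 and lex.lookup("茶") == 500

    def test_duplicate_last_wins(self, tmp_path, caplog):
        p = tmp_path / "lex.tsv"
        p.write_text("茶\t500\n茶\t600\n", encoding="utf-8")
        with caplog.at_level("WARNING", logger="speechmarker.corpus"):
            lex = read_lexicon(p)
        assert lex.lookup("茶") == 600
        assert any("duplicate" in r.message for r in caplog.records)

    def test_non_numeric_frequency_names_row(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("茶\tabc\n", encoding="utf-8")
        with pytest.raises(ParseError, match="row 1"):
            read_lexicon(p)

    def test_oov_policies(self):
        lex = FrequencyLexicon(entries={"a": 10.0, "b": 2.0}, oov_policy="skip")
        assert lex.lookup("zzz") is None
        lex2 = FrequencyLexicon(entries={"a": 10.0, "b": 2.0}, oov_policy="min_frequency")
        assert lex2.lookup("zzz") == 2.0


class TestCohortIO:
    def _rows(self):
        return [
            CohortRow("p1", "NC", 70.0, 12.0, "F", suvr=1.1, hippocampus_cm3=5.0,
                      scores={"MMSE": 29.0}),
            CohortRow("p2", "early_AD", 78.0, 9.0, "M"),
        ]

    def test_round_trip(self, tmp_path):
        p = tmp_path / "cohort.csv"
        write_cohort(self._rows(), p)
        rows = read_cohort(p)
        assert [r.participant_id for r in rows] == ["p1", "p2"]
        assert rows[0].scores["MMSE"] == 29.0
        assert rows[1].suvr is None  # empty optional cell stays unset

    def test_group_counts_preserved(self, tmp_path):
        rows = [CohortRow(f"n{i}", "NC", 70.0, 12.0, "F") for i in range(32)]
        rows += [CohortRow(f"a{i}", "early_AD", 75.0, 10.0, "M") for i in range(48)]
        p = tmp_path / "cohort.csv"
        write_cohort(rows, p)
        again = read_cohort(p)
        groups = [r.group for r in again]
        assert len(again) == 80
        assert groups.count("NC") == 32 and groups.count("early_AD") == 48

    def test_missing_age_rejected(self, tmp_path):
        p = tmp_path / "cohort.csv"
        p.write_text("participant_id,group,age,education,gender\np1,NC,,12,F\n")
        with pytest.raises(ValidationError, match="age"):
            read_cohort(p)

    def test_unknown_group_rejected(self, tmp_path):
        p = tmp_path / "cohort.csv"
        p.write_text("participant_id,group,age,education,gender\np1,MCI,70,12,F\n")
        with pytest.raises(ValidationError):
            read_cohort(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "cohort.csv"
        p.write_text(
            "participant_id,group,age,education,gender\np1,NC,70,12,F\np1,NC,71,12,F\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_cohort(p)


class TestFeatureTable:
    def test_round_trip_bit_exact(self, tmp_path):
        vec = {n: 0.1 * i for i, n in enumerate(FEATURE_NAMES)}
        vec2 = {n: float(i) for i, n in enumerate(FEATURE_NAMES)}
        p = tmp_path / "features.csv"
        write_feature_table({"p1": vec, "p2": vec2}, p)
        assert len(p.read_text().splitlines()) == 3
        again = read_feature_table(p)
        assert again["p1"] == vec and again["p2"] == vec2

    def test_header_in_canonical_order(self, tmp_path):
        p = tmp_path / "features.csv"
        write_feature_table({"p1": {n: 0.0 for n in FEATURE_NAMES}}, p)
        header = p.read_text().splitlines()[0].split(",")
        assert header == ["participant_id", *FEATURE_NAMES]

    def test_missing_feature_named_in_error(self, tmp_path):
        vec = {n: 0.0 for n in FEATURE_NAMES if n != "LPR"}
        with pytest.raises(ValueError, match="LPR"):
            write_feature_table({"p1": vec}, tmp_path / "f.csv")

    def test_nan_round_trips_as_missing(self, tmp_path):
        vec = {n: 1.0 for n in FEATURE_NAMES}
        vec["MLS"] = float("nan")
        p = tmp_path / "f.csv"
        write_feature_table({"p1": vec}, p)
        assert math.isnan(read_feature_table(p)["p1"]["MLS"])
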