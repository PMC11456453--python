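"""Feature extraction against hand-computed oracles and structural invariants."""

import math

import pytest

from speechmarker.corpus import CoarseClass, FrequencyLexicon, Token, Utterance
from speechmarker.features import (
    FEATURE_NAMES,
    RATIO_FEATURES,
    aggregate_images,
    disfluency_features,
    extract_features,
    lexical_features,
    syntactic_features,
)
from speechmarker.normalize import NormalizedResponse, normalize_response

C = CoarseClass


def _normalized(transcript, image=0):
    return normalize_response(transcript.responses[image].utterances)


class TestHandComputedFixtures:
    def test_all_fifteen_features_match_oracle(self, any_fixture):
        """Extraction equals the hand count exactly; ratios to 1e-12."""
        transcript, lex, expected = any_fixture
        got = extract_features(transcript, lex)
        assert set(got) == set(FEATURE_NAMES)
        for name in FEATURE_NAMES:
            if isinstance(expected[name], float) and math.isnan(expected[name]):
                assert math.isnan(got[name]), name
            elif name in RATIO_FEATURES or name in ("MLU", "MLS", "CWF"):
                assert got[name] == pytest.approx(expected[name], abs=1e-12), name
            else:
                assert got[name] == expected[name], name


class TestLexicalFeatures:
    def test_all_distinct_gives_ttr_one(self):
        resp = NormalizedResponse(
            utterances=(Utterance(tokens=(
                Token(surface="a", char_count=1, coarse_class=C.NOUN),
                Token(surface="b", char_count=1, coarse_class=C.VERB),
            )),),
            filled_pause_count=0, long_pause_count=0,
        )
        lex = FrequencyLexicon(entries={"a": 1.0, "b": 2.0})
        out = lexical_features(resp, lex)
        assert out["TTR"] == 1.0 and out["UW"] == out["TW"] == 2

    def test_cwf_token_wise_vs_type_wise(self):
        toks = tuple(
            Token(surface=s, char_count=1, coarse_class=C.NOUN) for s in ("a", "a", "b")
        )
        resp = NormalizedResponse(utterances=(Utterance(tokens=toks),),
                                  filled_pause_count=0, long_pause_count=0)
        lex = FrequencyLexicon(entries={"a": 100.0, "b": 10.0})
        assert lexical_features(resp, lex)["CWF"] == pytest.approx(70.0)
        assert lexical_features(resp, lex, cwf_over_tokens=False)["CWF"] == pytest.approx(55.0)

    def test_empty_response_ratios_missing(self):
        resp = NormalizedResponse(utterances=(), filled_pause_count=0, long_pause_count=0)
        out = lexical_features(resp, FrequencyLexicon(entries={}))
        assert out["TW"] == 0 and math.isnan(out["TTR"]) and math.isnan(out["CD"])


class TestSyntacticFeatures:
    def test_single_noun_utterance(self):
        resp = NormalizedResponse(
            utterances=(Utterance(tokens=(Token(surface="茶", char_count=1,
                                                coarse_class=C.NOUN),)),),
            filled_pause_count=0, long_pause_count=0,
        )
        out = syntactic_features(resp)
        assert out["U"] == 1 and out["S"] == 0 and out["MLU"] == 1.0
        assert math.isnan(out["MLS"])

    def test_no_content_words_vr_pr_missing(self):
        resp = NormalizedResponse(
            utterances=(Utterance(tokens=(Token(surface="了", char_count=1,
                                                coarse_class=C.OTHER),)),),
            filled_pause_count=0, long_pause_count=0,
        )
        out = syntactic_features(resp)
        assert math.isnan(out["VR"]) and math.isnan(out["PR"])


class TestDisfluencyFeatures:
    @pytest.mark.parametrize("tw,fillers,longs,fr,lpr", [
        (10, 1, 1, 1 / 11, 1 / 11),
        (8, 2, 0, 0.2, 0.0),
        (5, 0, 0, 0.0, 0.0),
    ])
    def test_verbal_output_denominator(self, tw, fillers, longs, fr, lpr):
        toks = tuple(Token(surface=f"w{i}", char_count=1, coarse_class=C.NOUN)
                     for i in range(tw))
        resp = NormalizedResponse(utterances=(Utterance(tokens=toks),),
                                  filled_pause_count=fillers, long_pause_count=longs)
        out = disfluency_features(resp)
        assert out["FR"] == pytest.approx(fr) and out["LPR"] == pytest.approx(lpr)

    def test_zero_verbal_output_missing(self):
        resp = NormalizedResponse(utterances=(), filled_pause_count=0, long_pause_count=0)
        out = disfluency_features(resp)
        assert math.isnan(out["FR"]) and math.isnan(out["LPR"])


class TestAggregateImages:
    def test_plain_mean(self):
        vecs = [{n: v for n in FEATURE_NAMES} for v in (8.0, 6.0, 7.0)]
        assert aggregate_images(vecs)["MLU"] == pytest.approx(7.0)

    def test_single_image_identity(self):
        vec = {n: float(i) for i, n in enumerate(FEATURE_NAMES)}
        assert aggregate_images([vec]) == vec

    def test_missing_values_excluded_from_mean(self):
        vecs = [{n: 4.0 for n in FEATURE_NAMES},
                {n: float("nan") for n in FEATURE_NAMES},
                {n: 6.0 for n in FEATURE_NAMES}]
        assert aggregate_images(vecs)["MLS"] == pytest.approx(5.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_images([])


class TestInvariants:
    def test_bounds_on_every_fixture(self, any_fixture):
        transcript, lex, _ = any_fixture
        got = extract_features(transcript, lex)
        assert got["UW"] <= got["TW"] and got["CW"] <= got["TW"]
        assert got["S"] <= got["U"] and got["MLU"] >= 1.0
        for name in RATIO_FEATURES:
            if not math.isnan(got[name]):
                assert 0.0 <= got[name] <= 1.0, name

    def test_utterance_order_invariance(self, fixture_a):
        """Permuting utterances (gaps travelling with them) changes nothing."""
        transcript, lex, _ = fixture_a
        base = extract_features(transcript, lex)
        resp = transcript.responses[0]
        # move each utterance's trailing gap with it, then reverse the order;
        # gap list is [2.5, 0.4, None] -> reversed pairing keeps multiset
        utts = list(resp.utterances)
        gaps = [u.trailing_pause_s for u in utts]
        reordered = [
            Utterance(tokens=utts[i].tokens, trailing_pause_s=gaps[j])
            for (i, j) in ((2, 0), (0, 1), (1, 2))
        ]
        from speechmarker.corpus import AnnotatedTranscript, ImageResponse

        permuted = AnnotatedTranscript(
            participant_id="perm",
            responses=(ImageResponse(image_id=1, utterances=tuple(reordered)),),
        )
        got = extract_features(permuted, lex)
        for name in FEATURE_NAMES:
            if math.isnan(base[name]):
                assert math.isnan(got[name])
            else:
                assert got[name] == pytest.approx(base[name], abs=1e-12), name

    def test_duplicating_distinct_utterances_doubles_counts(self):
        """Doubling the (distinct) token stream doubles TW/CW and lowers TTR."""
        from speechmarker.corpus import AnnotatedTranscript, ImageResponse

        u1 = Utterance(tokens=(Token(surface="a", char_count=1, coarse_class=C.NOUN),
                               Token(surface="b", char_count=1, coarse_class=C.VERB)),
                       trailing_pause_s=0.5)
        u2 = Utterance(tokens=(Token(surface="c", char_count=1, coarse_class=C.NOUN),
                               Token(surface="d", char_count=1, coarse_class=C.OTHER)))
        lex = FrequencyLexicon(entries={s: 1.0 for s in "abcd"})
        single = AnnotatedTranscript("s", (ImageResponse(1, (u1, u2)),))
        # interleave a distinct copy so no adjacent utterances are identical
        u1b = Utterance(tokens=u2.tokens, trailing_pause_s=0.5)
        u2b = Utterance(tokens=u1.tokens)
        double = AnnotatedTranscript("d", (ImageResponse(1, (u1, u1b, u2b, u2)),))
        f1, f2 = extract_features(single, lex), extract_features(double, lex)
        assert f2["TW"] == 2 * f1["TW"] and f2["CW"] == 2 * f1["CW"]
        assert f2["TTR"] < f1["TTR"]
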