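"""Hand-computed fixture transcripts for the feature-extraction oracle tests.

Each fixture supplies a raw (pre-normalization) transcript, the lexicon it is
scored against, and the expected image-averaged values of all 15 features,
worked out by hand from the feature definitions.  Counts are exact integers;
ratios are exact fractions written as Python expressions.  Fixtures cover:
repetition collapsing (words and whole utterances), filler separation with
gap merging, bei/ba passives (realized and bare), the 2-second long-pause
threshold boundary, incomplete-token exclusion from content words,
out-of-vocabulary content words, multi-image averaging with missing values,
and an image emptied by cleaning.
"""

from __future__ import annotations

from speechmarker.corpus import (
    AnnotatedTranscript,
    CoarseClass,
    FrequencyLexicon,
    ImageResponse,
    Token,
    Utterance,
)

C = CoarseClass
NAN = float("nan")


def tok(surface, chars, cls, *flags):
    return Token(surface=surface, char_count=chars, raw_tag="",
                 coarse_class=cls, flags=frozenset(flags))


def utt(tokens, gap=None):
    return Utterance(tokens=tuple(tokens), trailing_pause_s=gap)


def filler(surface="呃"):
    return tok(surface, 1, C.OTHER, "filled_pause")


def transcript(pid, *images):
    return AnnotatedTranscript(
        participant_id=pid,
        responses=tuple(
            ImageResponse(image_id=i + 1, utterances=tuple(utts))
            for i, utts in enumerate(images)
        ),
    )


def lexicon(**entries):
    return FrequencyLexicon(entries=dict(entries), oov_policy="skip")


FIXTURES = {}


def fixture(fn):
    FIXTURES[fn.__name__.removeprefix("fixture_")] = fn
    return fn


@fixture
def fixture_a():
    """The worked single-image example: 1 filler, one bei passive, one long gap.

    Cleaned utterances: [他 泡 茶], [很 好喝], [茶 被 喝 完 了]; gaps 2.5 / 0.4 s.
    TW 10, UW 9 (茶 twice), CW 8 content tokens, CWF = 15450/8 = 1931.25,
    U 3, S 2, MLU 11/3, MLS (3+5)/2, PCR 1/3, VR 3/8, PR 1/8, FR = LPR = 1/11.
    """
    t = transcript(
        "fixA",
        [
            utt([tok("他", 1, C.PRON), filler(), tok("泡", 1, C.VERB), tok("茶", 1, C.NOUN)], 2.5),
            utt([tok("很", 1, C.ADV), tok("好喝", 2, C.ADJ)], 0.4),
            utt([tok("茶", 1, C.NOUN), tok("被", 1, C.PASSIVE_MARKER_BEI),
                 tok("喝", 1, C.VERB), tok("完", 1, C.VERB), tok("了", 1, C.OTHER)]),
        ],
    )
    lex = lexicon(他=5000, 泡=200, 茶=500, 很=8000, 好喝=50, 喝=900, 完=300)
    expected = {
        "TW": 10, "UW": 9, "TTR": 0.9, "CW": 8, "CD": 0.8, "CWF": 1931.25,
        "U": 3, "S": 2, "MLU": 11 / 3, "MLS": 4.0, "PCR": 1 / 3,
        "VR": 3 / 8, "PR": 1 / 8, "FR": 1 / 11, "LPR": 1 / 11,
    }
    return t, lex, expected


@fixture
def fixture_word_repetition():
    """An immediate word repetition collapses to one copy before counting."""
    t = transcript(
        "fixB",
        [
            utt([tok("mao", 2, C.NOUN), tok("mao", 2, C.NOUN, "repetition"),
                 tok("pao", 1, C.VERB)], 1.0),
            utt([tok("ta", 1, C.PRON), tok("he", 1, C.VERB), tok("cha", 1, C.NOUN)]),
        ],
    )
    lex = lexicon(mao=250, pao=200, ta=5000, he=900, cha=500)
    expected = {
        "TW": 5, "UW": 5, "TTR": 1.0, "CW": 5, "CD": 1.0, "CWF": 6850 / 5,
        "U": 2, "S": 2, "MLU": 6 / 2, "MLS": 5 / 2, "PCR": 0.0,
        "VR": 2 / 5, "PR": 1 / 5, "FR": 0.0, "LPR": 0.0,
    }
    return t, lex, expected


@fixture
def fixture_filler_only_utterance():
    """A filler-only utterance is dropped and its gap merges additively.

    1.2 s + 0.9 s = 2.1 s, which crosses the 2-second long-pause threshold.
    """
    t = transcript(
        "fixC",
        [
            utt([tok("ta", 1, C.PRON), tok("pao", 1, C.VERB)], 1.2),
            utt([filler("uh")], 0.9),
            utt([tok("cha", 1, C.NOUN)]),
        ],
    )
    lex = lexicon(ta=5000, pao=200, cha=500)
    expected = {
        "TW": 3, "UW": 3, "TTR": 1.0, "CW": 3, "CD": 1.0, "CWF": 5700 / 3,
        "U": 2, "S": 1, "MLU": 3 / 2, "MLS": 2.0, "PCR": 0.0,
        "VR": 1 / 3, "PR": 1 / 3, "FR": 1 / 4, "LPR": 1 / 4,
    }
    return t, lex, expected


@fixture
def fixture_passives():
    """Realized bei and ba constructions count once; a bare marker does not.

    The 2.0 s gap sits exactly on the threshold and counts as a long pause.
    """
    t = transcript(
        "fixD",
        [
            utt([tok("cha", 1, C.NOUN), tok("bei", 1, C.PASSIVE_MARKER_BEI),
                 tok("he", 1, C.VERB)], 2.0),
            utt([tok("ba", 1, C.PASSIVE_MARKER_BA), tok("cha", 1, C.NOUN),
                 tok("he", 1, C.VERB), tok("wan", 1, C.VERB)], 0.5),
            utt([tok("bei", 1, C.PASSIVE_MARKER_BEI)]),
        ],
    )
    lex = lexicon(cha=500, he=900, wan=300)
    expected = {
        "TW": 8, "UW": 5, "TTR": 5 / 8, "CW": 5, "CD": 5 / 8, "CWF": 3100 / 5,
        "U": 3, "S": 2, "MLU": 8 / 3, "MLS": 7 / 2, "PCR": 2 / 3,
        "VR": 3 / 5, "PR": 0.0, "FR": 0.0, "LPR": 1 / 8,
    }
    return t, lex, expected


@fixture
def fixture_two_image_average():
    """Image averaging: MLS missing for a one-noun image is excluded."""
    t = transcript(
        "fixE",
        [utt([tok("ta", 1, C.PRON), tok("hao", 1, C.ADJ)])],
        [utt([tok("shu", 1, C.NOUN)])],
    )
    lex = lexicon(ta=5000, hao=400, shu=100)
    expected = {
        "TW": 1.5, "UW": 1.5, "TTR": 1.0, "CW": 1.5, "CD": 1.0,
        "CWF": (2700 + 100) / 2,
        "U": 1, "S": 0.5, "MLU": 1.5, "MLS": 2.0, "PCR": 0.0,
        "VR": 0.0, "PR": 0.25, "FR": 0.0, "LPR": 0.0,
    }
    return t, lex, expected


@fixture
def fixture_incomplete_token():
    """Incomplete tokens count as words/characters but not content words."""
    t = transcript(
        "fixF",
        [
            utt([tok("ta", 1, C.PRON), tok("le", 1, C.OTHER),
                 tok("shu", 1, C.NOUN, "incomplete"), tok("kan", 1, C.VERB)], 2.5),
            utt([tok("mao", 2, C.NOUN), tok("de", 1, C.OTHER)]),
        ],
    )
    lex = lexicon(ta=5000, kan=600, mao=250, shu=100)
    expected = {
        "TW": 6, "UW": 6, "TTR": 1.0, "CW": 3, "CD": 0.5, "CWF": 5850 / 3,
        "U": 2, "S": 1, "MLU": 7 / 2, "MLS": 4.0, "PCR": 0.0,
        "VR": 1 / 3, "PR": 1 / 3, "FR": 0.0, "LPR": 1 / 6,
    }
    return t, lex, expected


@fixture
def fixture_utterance_repetition():
    """An immediately repeated utterance collapses; 1.9 s is not a long pause."""
    u = [tok("ta", 1, C.PRON), filler("uh"), tok("pao", 1, C.VERB), tok("cha", 1, C.NOUN)]
    t = transcript(
        "fixG",
        [
            utt(list(u), 0.3),
            utt(list(u), 1.9),
            utt([tok("hen", 1, C.ADV), tok("hao", 1, C.ADJ)]),
        ],
    )
    lex = lexicon(ta=5000, pao=200, cha=500, hen=8000, hao=400)
    expected = {
        "TW": 5, "UW": 5, "TTR": 1.0, "CW": 5, "CD": 1.0, "CWF": 14100 / 5,
        "U": 2, "S": 1, "MLU": 5 / 2, "MLS": 3.0, "PCR": 0.0,
        "VR": 1 / 5, "PR": 1 / 5, "FR": 1 / 6, "LPR": 0.0,
    }
    return t, lex, expected


@fixture
def fixture_word_run():
    """A run of three identical words keeps one copy."""
    t = transcript(
        "fixH",
        [
            utt([tok("he", 1, C.VERB), tok("he", 1, C.VERB, "repetition"),
                 tok("he", 1, C.VERB), tok("cha", 1, C.NOUN)], 2.2),
            utt([tok("ta", 1, C.PRON), tok("shuo", 1, C.VERB)]),
        ],
    )
    lex = lexicon(he=900, cha=500, ta=5000, shuo=700)
    expected = {
        "TW": 4, "UW": 4, "TTR": 1.0, "CW": 4, "CD": 1.0, "CWF": 7100 / 4,
        "U": 2, "S": 1, "MLU": 2.0, "MLS": 2.0, "PCR": 0.0,
        "VR": 2 / 4, "PR": 1 / 4, "FR": 0.0, "LPR": 1 / 4,
    }
    return t, lex, expected


@fixture
def fixture_oov_and_empty_image():
    """OOV content words are skipped from CWF; an all-filler image is excluded."""
    t = transcript(
        "fixI",
        [utt([tok("ta", 1, C.PRON), tok("ai", 1, C.VERB), tok("gou", 1, C.NOUN)])],
        [utt([filler("uh")])],
    )
    lex = lexicon(ta=5000, gou=350)  # "ai" deliberately absent
    expected = {
        "TW": 3, "UW": 3, "TTR": 1.0, "CW": 3, "CD": 1.0, "CWF": 5350 / 2,
        "U": 1, "S": 1, "MLU": 3.0, "MLS": 3.0, "PCR": 0.0,
        "VR": 1 / 3, "PR": 1 / 3, "FR": 0.0, "LPR": 0.0,
    }
    return t, lex, expected


@fixture
def fixture_ba_without_object():
    """A ba marker with no following noun phrase realizes no construction."""
    t = transcript(
        "fixJ",
        [
            utt([tok("ba", 1, C.PASSIVE_MARKER_BA), tok("he", 1, C.VERB)], 0.5),
            utt([tok("shu", 1, C.NOUN), tok("bei", 1, C.PASSIVE_MARKER_BEI),
                 tok("na", 1, C.VERB), tok("zou", 1, C.VERB)]),
        ],
    )
    lex = lexicon(he=900, shu=100, na=150, zou=450)
    expected = {
        "TW": 6, "UW": 6, "TTR": 1.0, "CW": 4, "CD": 4 / 6, "CWF": 1600 / 4,
        "U": 2, "S": 1, "MLU": 3.0, "MLS": 4.0, "PCR": 1 / 2,
        "VR": 3 / 4, "PR": 0.0, "FR": 0.0, "LPR": 0.0,
    }
    return t, lex, expected


@fixture
def fixture_two_char_words():
    """Two-character words and a double gap merge that stays one long pause."""
    t = transcript(
        "fixK",
        [
            utt([tok("laoren", 2, C.NOUN), tok("zuo", 1, C.VERB), filler("eh"),
                 tok("chuan", 2, C.NOUN)], 2.0),
            utt([filler("eh")], 2.0),
            utt([tok("haizi", 2, C.NOUN), tok("wan", 1, C.VERB), tok("shui", 1, C.NOUN)]),
        ],
    )
    lex = lexicon(laoren=800, zuo=1200, chuan=150, haizi=950, wan=300, shui=2000)
    expected = {
        "TW": 6, "UW": 6, "TTR": 1.0, "CW": 6, "CD": 1.0, "CWF": 5400 / 6,
        "U": 2, "S": 2, "MLU": 9 / 2, "MLS": 3.0, "PCR": 0.0,
        "VR": 2 / 6, "PR": 0.0, "FR": 2 / 8, "LPR": 1 / 8,
    }
    return t, lex, expected
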