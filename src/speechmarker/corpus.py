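"""Data model and file formats for annotated picture-description transcripts.

The package analyzes connected speech elicited by a three-image picture
description task.  A transcript is a participant's tokenized speech: tokens
carry the surface form, the number of Chinese characters, the upstream
part-of-speech tag, a coarse word class resolved through a :class:`TagMapping`,
and disfluency flags (filled pause, repetition, revision, incomplete).
Utterances carry the silent pause (seconds) that separates them from the next
utterance.  Part-of-speech tagging and utterance-level annotation happen
upstream (human transcribers plus the CKIP tagger); this module only consumes
their output.

File formats
------------
* transcript — JSON, see :func:`read_transcript`
* frequency lexicon — two-column TSV ``word<TAB>frequency``
* cohort — CSV with the header documented at :func:`read_cohort`
* tag mapping — JSON ``{tag_map, bei_forms, ba_forms, filler_forms}``
"""

from __future__ import annotations

import csv
import json
import logging
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "CoarseClass",
    "Token",
    "Utterance",
    "ImageResponse",
    "AnnotatedTranscript",
    "FrequencyLexicon",
    "CohortRow",
    "TagMapping",
    "ParseError",
    "ValidationError",
    "DEFAULT_TAG_MAPPING",
    "SCORE_NAMES",
    "read_transcript",
    "write_transcript",
    "read_lexicon",
    "write_lexicon",
    "read_cohort",
    "write_cohort",
    "read_tag_mapping",
    "write_feature_table",
    "read_feature_table",
]


class ParseError(ValueError):
    """A file could not be parsed at all (malformed JSON, bad number)."""


class ValidationError(ValueError):
    """A file parsed but violated the data model's invariants."""


class CoarseClass(str, Enum):
    """Coarse word classes used by the feature definitions.

    NOUN/VERB/ADJ/PRON/ADV are the content-word classes; the two passive
    markers flag the Mandarin *bèi* and *ba* constructions; everything else
    (particles, fillers, numerals, ...) is OTHER.
    """

    NOUN = "NOUN"
    VERB = "VERB"
    ADJ = "ADJ"
    PRON = "PRON"
    ADV = "ADV"
    PASSIVE_MARKER_BEI = "PASSIVE_MARKER_BEI"
    PASSIVE_MARKER_BA = "PASSIVE_MARKER_BA"
    OTHER = "OTHER"


CONTENT_CLASSES = frozenset(
    {CoarseClass.NOUN, CoarseClass.VERB, CoarseClass.ADJ, CoarseClass.PRON, CoarseClass.ADV}
)

VALID_FLAGS = frozenset({"filled_pause", "repetition", "revision", "incomplete"})

#: Cognitive-score columns recognized in a cohort file.
SCORE_NAMES = ("MMSE", "CDR_SB", "WLM_I", "WLM_II", "DS", "CTT1", "CTT2", "VF", "BNT")


def _is_cjk(text: str) -> bool:
    return bool(text) and all(
        unicodedata.category(ch) == "Lo" and "㐀" <= ch <= "鿿" for ch in text
    )


@dataclass(frozen=True)
class Token:
    """One spoken word (or filler / marker) with its annotations.

    ``char_count`` is the number of Chinese characters in ``surface``; for
    fully CJK surfaces it must equal ``len(surface)``, for romanized fixture
    surfaces the supplied count is authoritative.
    """

    surface: str
    char_count: int
    raw_tag: str = ""
    coarse_class: CoarseClass = CoarseClass.OTHER
    flags: frozenset = frozenset()

    def __post_init__(self):
        if not self.surface:
            raise ValidationError("token surface must be nonempty")
        if self.char_count < 1:
            raise ValidationError(f"char_count must be >= 1, got {self.char_count}")
        if _is_cjk(self.surface) and self.char_count != len(self.surface):
            raise ValidationError(
                f"char_count {self.char_count} does not match surface {self.surface!r}"
            )
        bad = set(self.flags) - VALID_FLAGS
        if bad:
            raise ValidationError(f"unknown flags {sorted(bad)}")
        object.__setattr__(self, "flags", frozenset(self.flags))
        if "filled_pause" in self.flags and self.coarse_class != CoarseClass.OTHER:
            raise ValidationError("a filled_pause token must have coarse_class OTHER")

    @property
    def is_filler(self) -> bool:
        return "filled_pause" in self.flags


@dataclass(frozen=True)
class Utterance:
    """An ordered run of tokens bounded by pauses or prosodic boundaries.

    ``trailing_pause_s`` is the silent gap (seconds) before the *next*
    utterance; ``None`` for the last utterance of an image.
    """

    tokens: tuple
    trailing_pause_s: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if not self.tokens:
            raise ValidationError("utterance must contain at least one token")
        if self.trailing_pause_s is not None and self.trailing_pause_s < 0:
            raise ValidationError(
                f"trailing_pause_s must be >= 0, got {self.trailing_pause_s}"
            )

    @property
    def surfaces(self) -> tuple:
        return tuple(t.surface for t in self.tokens)


@dataclass(frozen=True)
class ImageResponse:
    """All utterances a participant produced for one of the three images."""

    image_id: int
    utterances: tuple

    def __post_init__(self):
        if self.image_id not in (1, 2, 3):
            raise ValidationError(f"image_id must be 1..3, got {self.image_id}")
        object.__setattr__(self, "utterances", tuple(self.utterances))


@dataclass(frozen=True)
class AnnotatedTranscript:
    """One participant's annotated speech over up to three images."""

    participant_id: str
    responses: tuple

    def __post_init__(self):
        if not self.participant_id:
            raise ValidationError("participant_id must be nonempty")
        object.__setattr__(self, "responses", tuple(self.responses))
        if not self.responses:
            raise ValidationError("transcript must contain at least one image response")
        ids = [r.image_id for r in self.responses]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate image_id in transcript {self.participant_id}")


@dataclass
class FrequencyLexicon:
    """Word -> corpus frequency lookup emulating a large reference corpus.

    ``oov_policy`` controls out-of-vocabulary content words in the frequency
    feature: ``"skip"`` drops them from the mean, ``"min_frequency"`` imputes
    the smallest frequency in the lexicon.
    """

    entries: dict
    oov_policy: str = "skip"

    def __post_init__(self):
        if self.oov_policy not in ("skip", "min_frequency"):
            raise ValidationError(f"unknown oov_policy {self.oov_policy!r}")
        for w, f in self.entries.items():
            if f < 0:
                raise ValidationError(f"negative frequency for {w!r}")

    def lookup(self, word: str) -> float | None:
        """Exact-match frequency, or the policy fallback (None means skip)."""
        freq = self.entries.get(word)
        if freq is not None:
            return freq
        if self.oov_policy == "min_frequency" and self.entries:
            return min(self.entries.values())
        return None

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CohortRow:
    """One participant's demographics, optional biomarkers and scores."""

    participant_id: str
    group: str
    age: float
    education: float
    gender: str
    suvr: float | None = None
    hippocampus_cm3: float | None = None
    scores: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in ("NC", "early_AD"):
            raise ValidationError(f"group must be NC or early_AD, got {self.group!r}")
        if self.gender not in ("F", "M"):
            raise ValidationError(f"gender must be F or M, got {self.gender!r}")
        if self.age is None or self.education is None:
            raise ValidationError("age and education are required")
        for k in self.scores:
            if k not in SCORE_NAMES:
                raise ValidationError(f"unknown score {k!r}")
        if self.suvr is not None and self.suvr <= 0:
            raise ValidationError("suvr must be positive")
        if self.hippocampus_cm3 is not None and self.hippocampus_cm3 <= 0:
            raise ValidationError("hippocampus_cm3 must be positive")


@dataclass
class TagMapping:
    """Resolution of upstream POS tags to coarse classes.

    ``tag_map`` maps raw tags to coarse class names.  Lookup tries the exact
    tag first, then progressively shorter prefixes, so a single ``"V"`` entry
    covers the whole CKIP verb family (VA, VC, VH, ...).  Surface forms listed
    in ``bei_forms`` / ``ba_forms`` are promoted to the corresponding passive
    marker class (unless flagged as filled pauses, which always resolve to
    OTHER).
    """

    tag_map: dict
    bei_forms: tuple = ("被",)
    ba_forms: tuple = ("把",)
    filler_forms: tuple = ("呃", "嗯", "啊", "唉")

    def __post_init__(self):
        self.bei_forms = tuple(self.bei_forms)
        self.ba_forms = tuple(self.ba_forms)
        self.filler_forms = tuple(self.filler_forms)
        if set(self.bei_forms) & set(self.ba_forms):
            raise ValidationError("bei_forms and ba_forms must be disjoint")
        self.tag_map = {
            k: (v if isinstance(v, CoarseClass) else CoarseClass(v))
            for k, v in self.tag_map.items()
        }

    def resolve(self, raw_tag: str, surface: str, flags: Iterable[str] = ()) -> CoarseClass:
        flags = set(flags)
        if "filled_pause" in flags:
            return CoarseClass.OTHER
        if surface in self.bei_forms:
            return CoarseClass.PASSIVE_MARKER_BEI
        if surface in self.ba_forms:
            return CoarseClass.PASSIVE_MARKER_BA
        for i in range(len(raw_tag), 0, -1):
            cls = self.tag_map.get(raw_tag[:i])
            if cls is not None:
                return cls
        if raw_tag:
            logger.debug("unknown raw_tag %r mapped to OTHER", raw_tag)
        return CoarseClass.OTHER


#: Approximation of the CKIP tagset: N* are nouns except the pronoun tag Nh,
#: V* are verbs, A adjectives, D adverbs; 被/把 are promoted by surface form.
DEFAULT_TAG_MAPPING = TagMapping(
    tag_map={
        "N": CoarseClass.NOUN,
        "Nh": CoarseClass.PRON,
        "V": CoarseClass.VERB,
        "A": CoarseClass.ADJ,
        "D": CoarseClass.ADV,
    }
)


# ---------------------------------------------------------------------------
# transcript JSON


def _token_from_dict(d: Mapping, mapping: TagMapping, where: str) -> Token:
    for key in ("surface", "char_count"):
        if key not in d:
            raise ValidationError(f"{where}: token missing field {key!r}")
    flags = frozenset(d.get("flags", ()))
    raw_tag = d.get("raw_tag", "")
    return Token(
        surface=d["surface"],
        char_count=int(d["char_count"]),
        raw_tag=raw_tag,
        coarse_class=mapping.resolve(raw_tag, d["surface"], flags),
        flags=flags,
    )


def read_transcript(path, mapping: TagMapping = DEFAULT_TAG_MAPPING) -> AnnotatedTranscript:
    """Read and validate one transcript JSON file.

    Raises :class:`ParseError` on malformed JSON and :class:`ValidationError`
    (naming the offending field) on schema violations.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed JSON at line {exc.lineno}: {exc.msg}") from exc
    if "participant_id" not in data or "responses" not in data:
        raise ValidationError(f"{path}: missing participant_id or responses")
    responses = []
    for r in data["responses"]:
        if "image_id" not in r:
            raise ValidationError(f"{path}: response missing image_id")
        utterances = []
        utt_list = r.get("utterances", [])
        for j, u in enumerate(utt_list):
            where = f"{path} image {r['image_id']} utterance {j}"
            pause = u.get("trailing_pause_s")
            if pause is not None and pause < 0:
                raise ValidationError(f"{where}: trailing_pause_s must be >= 0, got {pause}")
            tokens = [_token_from_dict(t, mapping, where) for t in u.get("tokens", [])]
            if not tokens:
                raise ValidationError(f"{where}: utterance has no tokens")
            utterances.append(Utterance(tokens=tuple(tokens), trailing_pause_s=pause))
        responses.append(ImageResponse(image_id=int(r["image_id"]), utterances=utterances))
    return AnnotatedTranscript(participant_id=str(data["participant_id"]), responses=responses)


def write_transcript(transcript: AnnotatedTranscript, path) -> None:
    """Write a transcript to the package's JSON format (UTF-8)."""
    data = {
        "participant_id": transcript.participant_id,
        "responses": [
            {
                "image_id": r.image_id,
                "utterances": [
                    {
                        "tokens": [
                            {
                                "surface": t.surface,
                                "char_count": t.char_count,
                                "raw_tag": t.raw_tag,
                                "flags": sorted(t.flags),
                            }
                            for t in u.tokens
                        ],
                        **(
                            {"trailing_pause_s": u.trailing_pause_s}
                            if u.trailing_pause_s is not None
                            else {}
                        ),
                    }
                    for u in r.utterances
                ],
            }
            for r in transcript.responses
        ],
    }
    Path(path).write_text(
        json.dumps(data, ensure_ascii=False, indent=1), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# lexicon TSV


def read_lexicon(path, oov_policy: str = "skip") -> FrequencyLexicon:
    """Read a two-column ``word<TAB>frequency`` TSV.

    Duplicate words: the last entry wins (a warning is logged).  Non-numeric
    frequencies raise :class:`ParseError` with the 1-based row number.
    """
    entries: dict = {}
    path = Path(path)
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: row {i}: expected 2 tab-separated columns")
        word, freq_str = parts
        try:
            freq = float(freq_str)
        except ValueError:
            raise ParseError(f"{path}: row {i}: non-numeric frequency {freq_str!r}") from None
        if word in entries:
            logger.warning("%s: duplicate lexicon entry %r at row %d; last wins", path, word, i)
        entries[word] = freq
    return FrequencyLexicon(entries=entries, oov_policy=oov_policy)


def write_lexicon(lexicon: FrequencyLexicon, path) -> None:
    lines = [f"{w}\t{f:g}" for w, f in lexicon.entries.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# cohort CSV

_COHORT_COLUMNS = [
    "participant_id",
    "group",
    "age",
    "education",
    "gender",
    "suvr",
    "hippocampus_cm3",
    *SCORE_NAMES,
]


def read_cohort(path) -> list:
    """Read the cohort CSV into a list of :class:`CohortRow`.

    Optional cells (biomarkers, scores) left empty stay unset.  Unknown group
    labels and duplicate participant ids raise :class:`ValidationError`.
    """
    rows: list = []
    seen: set = set()
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for i, rec in enumerate(reader, start=2):
            pid = (rec.get("participant_id") or "").strip()
            if not pid:
                raise ValidationError(f"{path}: row {i}: missing participant_id")
            if pid in seen:
                raise ValidationError(f"{path}: duplicate participant_id {pid!r}")
            seen.add(pid)

            def _opt(name):
                v = (rec.get(name) or "").strip()
                return float(v) if v else None

            age = _opt("age")
            education = _opt("education")
            if age is None:
                raise ValidationError(f"{path}: row {i} ({pid}): missing age")
            if education is None:
                raise ValidationError(f"{path}: row {i} ({pid}): missing education")
            scores = {s: _opt(s) for s in SCORE_NAMES}
            scores = {k: v for k, v in scores.items() if v is not None}
            rows.append(
                CohortRow(
                    participant_id=pid,
                    group=(rec.get("group") or "").strip(),
                    age=age,
                    education=education,
                    gender=(rec.get("gender") or "").strip(),
                    suvr=_opt("suvr"),
                    hippocampus_cm3=_opt("hippocampus_cm3"),
                    scores=scores,
                )
            )
    return rows


def write_cohort(rows: Sequence[CohortRow], path) -> None:
    """Write cohort rows to CSV in the canonical column order."""

    def _fmt(v):
        return "" if v is None else repr(float(v))

    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COHORT_COLUMNS)
        for r in rows:
            writer.writerow(
                [
                    r.participant_id,
                    r.group,
                    _fmt(r.age),
                    _fmt(r.education),
                    r.gender,
                    _fmt(r.suvr),
                    _fmt(r.hippocampus_cm3),
                    *[_fmt(r.scores.get(s)) for s in SCORE_NAMES],
                ]
            )


def cohort_to_frame(rows: Sequence[CohortRow]):
    """Cohort rows as a pandas DataFrame (one column per score, NaN if unset)."""
    import pandas as pd

    recs = []
    for r in rows:
        rec = {
            "participant_id": r.participant_id,
            "group": r.group,
            "age": r.age,
            "education": r.education,
            "gender": r.gender,
            "suvr": r.suvr,
            "hippocampus_cm3": r.hippocampus_cm3,
        }
        for s in SCORE_NAMES:
            rec[s] = r.scores.get(s)
        recs.append(rec)
    return pd.DataFrame.from_records(recs, columns=_COHORT_COLUMNS)


# ---------------------------------------------------------------------------
# tag-mapping JSON


def read_tag_mapping(path) -> TagMapping:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return TagMapping(
        tag_map=data["tag_map"],
        bei_forms=tuple(data.get("bei_forms", ("被",))),
        ba_forms=tuple(data.get("ba_forms", ("把",))),
        filler_forms=tuple(data.get("filler_forms", ())),
    )


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(rows: Mapping, path) -> None:
    """Write participant -> feature-vector rows to CSV.

    Columns follow the canonical feature order.  Every vector must contain
    exactly the 15 feature names; a missing name raises ``ValueError`` naming
    it.  Missing *values* (NaN) are written as empty cells.
    """
    from .features import FEATURE_NAMES
    import math

    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", *FEATURE_NAMES])
        for pid, vec in rows.items():
            missing = [n for n in FEATURE_NAMES if n not in vec]
            if missing:
                raise ValueError(f"feature vector for {pid!r} missing {missing[0]!r}")
            out = []
            for n in FEATURE_NAMES:
                v = vec[n]
                out.append("" if v is None or (isinstance(v, float) and math.isnan(v)) else repr(float(v)))
            writer.writerow([pid, *out])


def read_feature_table(path) -> dict:
    """Inverse of :func:`write_feature_table` (empty cells -> NaN)."""
    from .features import FEATURE_NAMES

    out: dict = {}
    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for rec in reader:
            vec = {}
            for n in FEATURE_NAMES:
                v = (rec.get(n) or "").strip()
                vec[n] = float(v) if v else float("nan")
            out[rec["participant_id"]] = vec
    return out
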