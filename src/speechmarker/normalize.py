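"""Transcript cleaning and structural rules applied before feature extraction.

The pipeline order is fixed: immediate repetitions are collapsed first, then
filled pauses are separated out and counted, and only then are sentence,
passive and pause statistics computed.  Pause thresholds are inclusive: an
inter-token silence of at least 120 ms marks a potential utterance boundary,
and an inter-utterance silence of 2 s or more counts as a long pause.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .corpus import CoarseClass, Utterance, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedResponse",
    "collapse_repetitions",
    "separate_fillers",
    "segment_utterances",
    "is_sentence",
    "count_passives",
    "count_long_pauses",
    "normalize_response",
    "MIN_PAUSE_S",
    "LONG_PAUSE_S",
]

#: Inclusive silence threshold (s) for an automatic utterance boundary.
MIN_PAUSE_S = 0.12
#: Inclusive silence threshold (s) for a long pause between utterances.
LONG_PAUSE_S = 2.0

SUBJECT_CLASSES = (CoarseClass.NOUN, CoarseClass.PRON)
PREDICATE_CLASSES = (CoarseClass.VERB, CoarseClass.ADJ)


@dataclass
class NormalizedResponse:
    """One image's utterances after cleaning, plus the disfluency tallies."""

    utterances: tuple
    filled_pause_count: int
    long_pause_count: int

    @property
    def word_tokens_per_utterance(self) -> tuple:
        return tuple(len(u.tokens) for u in self.utterances)


def _collapse_words(utterance: Utterance) -> Utterance:
    kept = []
    for tok in utterance.tokens:
        if kept and tok.surface == kept[-1].surface:
            # run of an identical word: keep one copy (the first)
            continue
        kept.append(tok)
    if len(kept) == len(utterance.tokens):
        return utterance
    return Utterance(tokens=tuple(kept), trailing_pause_s=utterance.trailing_pause_s)


def collapse_repetitions(utterances) -> list:
    """Drop immediate repetitions of the same word or whole utterance.

    Runs of k identical adjacent words within an utterance keep one copy;
    runs of k identical adjacent utterances (same surface sequence) keep the
    last copy, so the surviving utterance carries the gap to the next distinct
    utterance.  Word repeats qualify whether or not they carry the repetition
    flag.  Idempotent; order otherwise preserved.
    """
    collapsed = [_collapse_words(u) for u in utterances]
    kept: list = []
    for u in collapsed:
        if kept and u.surfaces == kept[-1].surfaces:
            kept[-1] = u  # later copy replaces earlier; its trailing pause survives
        else:
            kept.append(u)
    return kept


def separate_fillers(utterances) -> tuple:
    """Remove filled-pause tokens; return (cleaned utterances, count removed).

    Filled pauses are not words.  An utterance emptied by the removal is
    dropped and its trailing pause added to the preceding utterance's gap (a
    leading filler-only utterance simply disappears; its pause has no
    predecessor to merge into).
    """
    cleaned: list = []
    removed = 0
    for u in utterances:
        words = tuple(t for t in u.tokens if not t.is_filler)
        removed += len(u.tokens) - len(words)
        if words:
            cleaned.append(Utterance(tokens=words, trailing_pause_s=u.trailing_pause_s))
        else:
            # merge this gap into the predecessor additively
            if cleaned and u.trailing_pause_s is not None:
                prev = cleaned[-1]
                merged = (prev.trailing_pause_s or 0.0) + u.trailing_pause_s
                cleaned[-1] = Utterance(tokens=prev.tokens, trailing_pause_s=merged)
    return cleaned, removed


def segment_utterances(tokens, silences, min_pause_s: float = MIN_PAUSE_S) -> list:
    """Segment a timed token stream into utterances by the duration rule.

    ``silences[i]`` is the silent gap (s) between ``tokens[i]`` and
    ``tokens[i+1]``; a boundary is placed wherever the silence is at least
    ``min_pause_s`` (inclusive).  Intended for transcripts that arrive
    unsegmented; pre-segmented input is taken verbatim elsewhere.
    """
    tokens = list(tokens)
    silences = list(silences)
    if len(silences) != max(len(tokens) - 1, 0):
        raise ValidationError(
            f"expected {max(len(tokens) - 1, 0)} silences for {len(tokens)} tokens"
        )
    if any(s < 0 for s in silences):
        raise ValidationError("silence durations must be >= 0")
    if not tokens:
        return []
    utterances: list = []
    current: list = [tokens[0]]
    for tok, gap in zip(tokens[1:], silences):
        if gap >= min_pause_s:
            utterances.append(Utterance(tokens=tuple(current), trailing_pause_s=gap))
            current = [tok]
        else:
            current.append(tok)
    utterances.append(Utterance(tokens=tuple(current), trailing_pause_s=None))
    return utterances


def is_sentence(utterance: Utterance) -> bool:
    """True iff the utterance has a subject-predicate skeleton.

    A sentence requires a noun or pronoun followed (not necessarily
    adjacently) by a main verb or an adjective.  Filled pauses are ignored;
    any verb-class token counts as a potential main verb.
    """
    seen_subject = False
    for tok in utterance.tokens:
        if tok.is_filler:
            continue
        if tok.coarse_class in SUBJECT_CLASSES:
            seen_subject = True
        elif seen_subject and tok.coarse_class in PREDICATE_CLASSES:
            return True
    return False


def count_passives(utterance: Utterance) -> int:
    """Count realized *bèi*/*ba* constructions in one utterance.

    A *bèi* marker counts when a noun/pronoun occurs somewhere before it and a
    verb somewhere after (NP + bèi + VP); a *ba* marker counts when a
    noun/pronoun occurs after it with a verb after that (ba + NP + VP).  Each
    marker is counted at most once; a bare marker with no flanking structure
    does not count.
    """
    classes = [t.coarse_class for t in utterance.tokens if not t.is_filler]
    n = 0
    for i, cls in enumerate(classes):
        if cls == CoarseClass.PASSIVE_MARKER_BEI:
            if any(c in SUBJECT_CLASSES for c in classes[:i]) and any(
                c == CoarseClass.VERB for c in classes[i + 1 :]
            ):
                n += 1
        elif cls == CoarseClass.PASSIVE_MARKER_BA:
            for j in range(i + 1, len(classes)):
                if classes[j] in SUBJECT_CLASSES and any(
                    c == CoarseClass.VERB for c in classes[j + 1 :]
                ):
                    n += 1
                    break
    return n


def count_long_pauses(utterances, threshold_s: float = LONG_PAUSE_S) -> int:
    """Number of inter-utterance gaps of ``threshold_s`` seconds or more."""
    return sum(
        1
        for u in utterances[:-1]
        if u.trailing_pause_s is not None and u.trailing_pause_s >= threshold_s
    )


def normalize_response(utterances, long_pause_threshold_s: float = LONG_PAUSE_S) -> NormalizedResponse:
    """Run the fixed cleaning pipeline on one image's utterances."""
    collapsed = collapse_repetitions(utterances)
    cleaned, n_fillers = separate_fillers(collapsed)
    n_long = count_long_pauses(cleaned, threshold_s=long_pause_threshold_s)
    return NormalizedResponse(
        utterances=tuple(cleaned),
        filled_pause_count=n_fillers,
        long_pause_count=n_long,
    )
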