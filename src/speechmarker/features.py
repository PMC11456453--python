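"""The 15 connected-speech features, computed per image and image-averaged.

Three groups of measures are extracted from each cleaned image response and
averaged over the (up to three) images a participant described:

lexical content
    TW total words, UW unique words, TTR = UW/TW, CW content words (nouns,
    verbs, adjectives, pronouns, adverbs; incomplete tokens excluded),
    CD = CW/TW, CWF mean corpus frequency over content-word tokens.
syntactic complexity
    U utterances, S sentences, MLU total characters / U, MLS words per
    sentence, PCR passive constructions / U, VR verbs / CW, PR pronouns / CW.
disfluency
    FR filled pauses / verbal output and LPR long pauses / verbal output,
    where verbal output = TW + filled pauses.

A "word" is any non-filler token, passive markers and particles included.
Undefined ratios (zero denominator) are reported as NaN, never as 0, so they
drop out of group means instead of biasing them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .corpus import (
    CONTENT_CLASSES,
    AnnotatedTranscript,
    CoarseClass,
    FrequencyLexicon,
)
from .normalize import (
    LONG_PAUSE_S,
    NormalizedResponse,
    count_passives,
    is_sentence,
    normalize_response,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "lexical_features",
    "syntactic_features",
    "disfluency_features",
    "image_features",
    "aggregate_images",
    "extract_features",
    "extract_cohort_features",
]

#: Canonical feature order (lexical, syntactic, disfluency).
FEATURE_NAMES = (
    "TW", "UW", "TTR", "CW", "CD", "CWF",
    "U", "S", "MLU", "MLS", "PCR", "VR", "PR",
    "FR", "LPR",
)

RATIO_FEATURES = frozenset({"TTR", "CD", "PCR", "VR", "PR", "FR", "LPR"})


@dataclass
class FeatureConfig:
    """Extraction thresholds; defaults follow the study protocol."""

    long_pause_threshold_s: float = LONG_PAUSE_S
    min_pause_s: float = 0.12
    #: averages corpus frequency over content-word tokens; set False for types
    cwf_over_tokens: bool = True


def _content_tokens(response: NormalizedResponse):
    return [
        t
        for u in response.utterances
        for t in u.tokens
        if t.coarse_class in CONTENT_CLASSES and "incomplete" not in t.flags
    ]


def lexical_features(response: NormalizedResponse, lexicon: FrequencyLexicon,
                     cwf_over_tokens: bool = True) -> dict:
    """TW, UW, TTR, CW, CD, CWF for one cleaned image response."""
    tokens = [t for u in response.utterances for t in u.tokens]
    tw = len(tokens)
    uw = len({t.surface for t in tokens})
    content = _content_tokens(response)
    cw = len(content)
    if tw == 0:
        logger.warning("empty response: lexical ratios undefined")
        return {"TW": 0, "UW": 0, "TTR": np.nan, "CW": 0, "CD": np.nan, "CWF": np.nan}
    if cwf_over_tokens:
        cwf_words = [t.surface for t in content]
    else:
        cwf_words = sorted({t.surface for t in content})
    freqs = []
    for w in cwf_words:
        f = lexicon.lookup(w)
        if f is None:
            logger.debug("content word %r not in lexicon; skipped from CWF", w)
        else:
            freqs.append(f)
    cwf = float(np.mean(freqs)) if freqs else np.nan
    return {
        "TW": tw,
        "UW": uw,
        "TTR": uw / tw,
        "CW": cw,
        "CD": cw / tw,
        "CWF": cwf,
    }


def syntactic_features(response: NormalizedResponse) -> dict:
    """U, S, MLU, MLS, PCR, VR, PR for one cleaned image response."""
    utts = response.utterances
    n_u = len(utts)
    if n_u == 0:
        return {k: np.nan for k in ("U", "S", "MLU", "MLS", "PCR", "VR", "PR")} | {"U": 0, "S": 0}
    sentences = [u for u in utts if is_sentence(u)]
    n_s = len(sentences)
    total_chars = sum(t.char_count for u in utts for t in u.tokens)
    mlu = total_chars / n_u
    if n_s == 0:
        logger.warning("no sentences: MLS undefined")
        mls = np.nan
    else:
        mls = sum(len(u.tokens) for u in sentences) / n_s
    pcr = sum(count_passives(u) for u in utts) / n_u
    content = _content_tokens(response)
    cw = len(content)
    if cw == 0:
        logger.warning("no content words: VR/PR undefined")
        vr = pr = np.nan
    else:
        vr = sum(1 for t in content if t.coarse_class == CoarseClass.VERB) / cw
        pr = sum(1 for t in content if t.coarse_class == CoarseClass.PRON) / cw
    return {"U": n_u, "S": n_s, "MLU": mlu, "MLS": mls, "PCR": pcr, "VR": vr, "PR": pr}


def disfluency_features(response: NormalizedResponse) -> dict:
    """FR and LPR, both over verbal output (words + filled pauses)."""
    tw = sum(len(u.tokens) for u in response.utterances)
    verbal_output = tw + response.filled_pause_count
    if verbal_output == 0:
        logger.warning("no verbal output: FR/LPR undefined")
        return {"FR": np.nan, "LPR": np.nan}
    return {
        "FR": response.filled_pause_count / verbal_output,
        "LPR": response.long_pause_count / verbal_output,
    }


def image_features(response: NormalizedResponse, lexicon: FrequencyLexicon,
                   config: FeatureConfig | None = None) -> dict:
    """All 15 features for one cleaned image response."""
    config = config or FeatureConfig()
    vec = lexical_features(response, lexicon, cwf_over_tokens=config.cwf_over_tokens)
    vec.update(syntactic_features(response))
    vec.update(disfluency_features(response))
    return {k: vec[k] for k in FEATURE_NAMES}


def aggregate_images(vectors) -> dict:
    """Unweighted mean of each feature over the available per-image vectors.

    A feature missing (NaN) for some image is excluded from that feature's
    mean; if it is missing everywhere the average is NaN too.
    """
    vectors = list(vectors)
    if not vectors:
        raise ValueError("aggregate_images requires at least one per-image vector")
    out = {}
    for name in FEATURE_NAMES:
        vals = [v[name] for v in vectors if not _is_missing(v[name])]
        if len(vals) < len(vectors):
            logger.warning(
                "feature %s present for %d/%d images", name, len(vals), len(vectors)
            )
        out[name] = float(np.mean(vals)) if vals else np.nan
    return out


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def extract_features(transcript: AnnotatedTranscript, lexicon: FrequencyLexicon,
                     config: FeatureConfig | None = None) -> dict:
    """Normalization pipeline + all three feature groups, image-averaged.

    Each image response is cleaned (repetition collapsing, filler separation),
    its 15 features computed, and the per-image vectors averaged.  Raises
    ``ValueError`` when no image yields any tokens.
    """
    config = config or FeatureConfig()
    per_image = []
    for resp in transcript.responses:
        norm = normalize_response(
            resp.utterances, long_pause_threshold_s=config.long_pause_threshold_s
        )
        if not norm.utterances:
            logger.warning(
                "participant %s image %d empty after cleaning; excluded",
                transcript.participant_id, resp.image_id,
            )
            continue
        per_image.append(image_features(norm, lexicon, config))
    if not per_image:
        raise ValueError(
            f"participant {transcript.participant_id}: no usable image responses"
        )
    return aggregate_images(per_image)


def extract_cohort_features(transcripts, lexicon: FrequencyLexicon,
                            config: FeatureConfig | None = None) -> dict:
    """participant_id -> feature vector for an iterable of transcripts."""
    return {t.participant_id: extract_features(t, lexicon, config) for t in transcripts}
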