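"""Synthetic cohorts: transcripts, biomarkers and scores with planted structure.

No public dataset of annotated Mandarin picture-description speech with
matched amyloid-PET and MRI biomarkers exists, so every stage of the pipeline
is exercised against synthetic cohorts whose *generating parameters* are the
published group statistics: utterance counts and lengths, lexical
concentration, passive/filler/long-pause rates per group, biomarker means and
SDs, and a latent severity factor that ties long pauses and utterance length
to hippocampal volume and SUVR so the reported feature-biomarker correlations
are realized.

Generation is parametric-by-construction: the generator emits token streams
with fillers, repetitions, passive constructions and timed gaps, so the full
normalization + extraction pipeline is exercised rather than bypassed.  Key
identities the generator maintains:

* utterance word counts are ``1 + Poisson(mlu_i / mu_char - 1)`` with words
  marginally distributed as the stationary law of the no-immediate-repeat
  sampling chain, making the extracted mean length of utterance an unbiased
  estimate of the planted participant-level value ``mlu_i``;
* each passive utterance realizes exactly one bei/ba construction, so the
  expected passive-construction ratio equals the insertion probability;
* participant-level parameters are drawn with symmetric clipping around the
  group mean, so planted group means are preserved exactly.

Quantities without a closed form under the full pipeline (type-token ratio,
long-pause ratio, the feature-biomarker correlation) are calibrated by the
Monte-Carlo routines in :func:`calibrate_defaults`; the shipped defaults are
the output of that calibration at the published targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .corpus import (
    AnnotatedTranscript,
    CoarseClass,
    CohortRow,
    FrequencyLexicon,
    ImageResponse,
    Token,
    Utterance,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LexiconSpec",
    "GroupParams",
    "ScoreModel",
    "SyntheticConfig",
    "SyntheticCohort",
    "TaggedLexicon",
    "default_config",
    "generate_lexicon",
    "generate_transcript",
    "generate_cohort",
    "planted_truth",
    "calibrate_defaults",
]

CONTENT_ORDER = ("NOUN", "VERB", "ADJ", "PRON", "ADV", "OTHER")
RAW_TAGS = {"NOUN": "Na", "VERB": "VC", "ADJ": "A", "PRON": "Nh", "ADV": "D", "OTHER": "T"}
TWO_CHAR_PROB = {"NOUN": 0.75, "VERB": 0.55, "ADJ": 0.70, "PRON": 0.20, "ADV": 0.50, "OTHER": 0.15}
FILLER_SURFACES = ("呃", "嗯", "啊")

# surfaces reserved for the passive markers; never generated as vocabulary
BEI, BA = "被", "把"


@dataclass
class LexiconSpec:
    """Synthetic vocabulary: Zipf-ranked words with fixed class assignments."""

    vocab_size: int = 3000
    zipf_exponent: float = 1.05
    top_frequency: float = 3209.0
    #: long-run share of each class among *lexicon entries* (not tokens)
    class_proportions: dict = field(
        default_factory=lambda: {
            "NOUN": 0.40, "VERB": 0.22, "ADJ": 0.10, "PRON": 0.03, "ADV": 0.12, "OTHER": 0.13,
        }
    )


@dataclass
class ScoreModel:
    """Planted linear generator for one cognitive score.

    ``score = mean_g + sd_g * (sum_l w_l * latent_l + noise)`` with
    standardized latents (severity z, utterance-length deviate, long-pause
    deviate) and ``noise = sqrt(1 - sum w_l^2) * eps``.
    """

    mean_nc: float
    mean_ad: float
    sd_nc: float
    sd_ad: float
    loadings: dict = field(default_factory=dict)  # keys: severity, mlu, lpr
    floor: float | None = None

    def noise_scale(self) -> float:
        s = 1.0 - sum(w * w for w in self.loadings.values())
        if s < 0:
            raise ValueError("score loadings imply negative noise variance")
        return float(np.sqrt(s))


@dataclass
class GroupParams:
    """Generative parameters for one diagnostic group.

    Counts are per image; the picture-description task uses three images.
    ``concentration`` is the exponent applied to lexicon frequencies when
    sampling words — larger values concentrate speech on common words,
    lowering the type-token ratio and raising mean content-word frequency.
    """

    # transcript structure
    n_utterances_mean: float = 21.68
    n_utterances_sd: float = 9.85
    mlu_mean: float = 8.11            # characters per utterance
    mlu_sd: float = 3.02              # participant-level SD
    mlu_severity_loading: float = 0.5
    concentration: float = 1.0        # calibrated for the TTR target
    class_mixture: dict = field(
        default_factory=lambda: {
            "NOUN": 0.26, "VERB": 0.106, "ADJ": 0.05, "PRON": 0.014, "ADV": 0.05, "OTHER": 0.52,
        }
    )
    passive_prob: float = 0.03        # per utterance -> expected PCR
    bei_fraction: float = 0.5
    filler_rate: float = 0.0526       # per word -> FR = rate/(1+rate)
    long_pause_prob: float = 0.02     # per inter-utterance gap; calibrated
    long_pause_sd: float = 0.01
    long_pause_severity_loading: float = 0.6
    repeat_word_prob: float = 0.02
    repeat_utterance_prob: float = 0.01
    revision_prob: float = 0.01
    incomplete_prob: float = 0.005
    # demographics / biomarkers
    age_mean: float = 72.23
    age_sd: float = 6.03
    education_mean: float = 13.66
    education_sd: float = 3.49
    female_prob: float = 0.44
    suvr_mean: float = 1.08
    suvr_sd: float = 0.08
    suvr_severity_loading: float = 0.3
    hippocampus_mean: float = 5.12
    hippocampus_sd: float = 0.48
    hippocampus_severity_loading: float = -0.6

    def __post_init__(self):
        for name in ("n_utterances_sd", "mlu_sd", "age_sd", "education_sd",
                     "suvr_sd", "hippocampus_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("passive_prob", "filler_rate", "long_pause_prob",
                     "repeat_word_prob", "repeat_utterance_prob", "female_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.class_mixture.values()) - 1.0) > 1e-6:
            raise ValueError("class_mixture must sum to 1")


def _default_score_models() -> dict:
    return {
        "MMSE": ScoreModel(28.94, 21.19, 1.27, 5.30,
                           {"severity": -0.45, "mlu": 0.30, "lpr": -0.20}),
        "CDR_SB": ScoreModel(0.02, 3.20, 0.09, 2.49,
                             {"severity": 0.45, "mlu": -0.15, "lpr": 0.35}, floor=0.0),
        "WLM_I": ScoreModel(13.59, 5.63, 2.42, 3.48,
                            {"severity": -0.50, "mlu": 0.20, "lpr": -0.25}),
        "WLM_II": ScoreModel(13.56, 4.82, 2.59, 3.52,
                             {"severity": -0.50, "mlu": 0.25, "lpr": -0.15}),
        "DS": ScoreModel(12.06, 7.03, 2.91, 4.18,
                         {"severity": -0.40, "mlu": 0.25, "lpr": -0.15}),
        "CTT1": ScoreModel(59.13, 159.82, 19.45, 103.19,
                           {"severity": 0.40, "mlu": -0.25, "lpr": 0.30}, floor=15.0),
        "CTT2": ScoreModel(123.89, 262.03, 37.04, 131.21,
                           {"severity": 0.40, "mlu": -0.30, "lpr": 0.25}, floor=30.0),
        "VF": ScoreModel(17.19, 9.88, 4.42, 4.40,
                         {"severity": -0.45, "mlu": 0.20, "lpr": -0.15}, floor=0.0),
        "BNT": ScoreModel(24.88, 19.31, 2.73, 4.71,
                          {"severity": -0.45, "mlu": 0.20, "lpr": -0.15}, floor=0.0),
    }


@dataclass
class SyntheticConfig:
    """Full recipe for a synthetic cohort; ``seed`` fixes everything."""

    n_per_group: dict = field(default_factory=lambda: {"NC": 32, "early_AD": 48})
    seed: int = 0
    n_images: int = 3
    lexicon: LexiconSpec = field(default_factory=LexiconSpec)
    groups: dict = field(default_factory=dict)
    score_models: dict = field(default_factory=_default_score_models)
    #: planted feature-biomarker dependences, realized through the latent
    #: severity factor and verified by calibration
    target_correlations: dict = field(
        default_factory=lambda: {("hippocampus_cm3", "LPR"): -0.489,
                                 ("hippocampus_cm3", "UW"): 0.321}
    )

    def __post_init__(self):
        if not self.groups:
            self.groups = default_group_params()
        for g, n in self.n_per_group.items():
            if n < 0:
                raise ValueError(f"n_per_group[{g!r}] must be >= 0")


def default_group_params() -> dict:
    """Group parameters calibrated to the published cohort statistics.

    Structure and biomarker values are the published group means/SDs; the
    long-pause rates and lexical concentrations are the output of
    :func:`calibrate_defaults` run at the published targets (NC long-pause
    ratio 0.0035, early-AD 0.02; type-token ratio 0.56 vs 0.51).
    """
    nc = GroupParams(
        n_utterances_mean=21.68, n_utterances_sd=9.85,
        mlu_mean=8.11, mlu_sd=3.02,
        concentration=1.07095,
        passive_prob=0.03,
        filler_rate=0.0526,
        long_pause_prob=0.018655, long_pause_sd=0.012,
        age_mean=72.23, age_sd=6.03,
        education_mean=13.66, education_sd=3.49,
        female_prob=14 / 32,
        suvr_mean=1.08, suvr_sd=0.08,
        hippocampus_mean=5.12, hippocampus_sd=0.48,
        class_mixture={"NOUN": 0.26, "VERB": 0.106, "ADJ": 0.05,
                       "PRON": 0.014, "ADV": 0.05, "OTHER": 0.52},
    )
    ad = GroupParams(
        n_utterances_mean=29.81, n_utterances_sd=15.0,
        mlu_mean=5.53, mlu_sd=1.62,
        concentration=1.14513,
        passive_prob=0.01,
        filler_rate=0.0638,
        long_pause_prob=0.077657, long_pause_sd=0.035,
        age_mean=75.02, age_sd=6.58,
        education_mean=10.03, education_sd=4.86,
        female_prob=31 / 48,
        suvr_mean=1.47, suvr_sd=0.19,
        hippocampus_mean=4.36, hippocampus_sd=0.72,
        class_mixture={"NOUN": 0.23, "VERB": 0.101, "ADJ": 0.045,
                       "PRON": 0.023, "ADV": 0.06, "OTHER": 0.541},
    )
    return {"NC": nc, "early_AD": ad}


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    return SyntheticConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# lexicon


@dataclass
class TaggedLexicon:
    """Vocabulary arrays plus per-group sampling tables."""

    surfaces: np.ndarray
    char_counts: np.ndarray
    classes: np.ndarray          # strings from CONTENT_ORDER
    frequencies: np.ndarray      # Zipf by rank

    def to_frequency_lexicon(self, oov_policy: str = "skip") -> FrequencyLexicon:
        return FrequencyLexicon(
            entries={s: float(f) for s, f in zip(self.surfaces, self.frequencies)},
            oov_policy=oov_policy,
        )


def _unique_surfaces(rng: np.random.Generator, lengths: np.ndarray) -> np.ndarray:
    """Deterministic unique pseudo-CJK surfaces of the requested lengths."""
    # fixed alphabet inside the URO block, excluding the passive markers and
    # the filler surfaces
    banned = {ord(BEI), ord(BA)} | {ord(s) for s in FILLER_SURFACES}
    alphabet = np.array(
        [cp for cp in range(0x4E00, 0x4E00 + 4000) if cp not in banned], dtype=np.int64
    )
    seen: set = set()
    out = []
    for L in lengths:
        while True:
            cps = rng.choice(alphabet, size=int(L))
            w = "".join(chr(c) for c in cps)
            if w not in seen:
                seen.add(w)
                out.append(w)
                break
    return np.array(out, dtype=object)


def _apportion_classes(names, shares, n: int) -> np.ndarray:
    """Deterministically interleave class labels over ranks 1..n.

    Greedy largest-deficit assignment keeps every class spread evenly across
    the frequency spectrum and makes the class-by-rank structure identical
    for every seed, so group-level calibrations (type-token ratio in
    particular) transfer across lexicon realizations.
    """
    shares = np.asarray(shares, dtype=float)
    shares = shares / shares.sum()
    assigned = np.zeros(len(names))
    out = []
    for r in range(1, n + 1):
        deficit = shares * r - assigned
        k = int(np.argmax(deficit))
        assigned[k] += 1
        out.append(names[k])
    return np.array(out, dtype=object)


def generate_lexicon(spec: LexiconSpec, seed: int = 0) -> TaggedLexicon:
    """Zipf-ranked synthetic vocabulary with fixed coarse-class assignments."""
    if spec.vocab_size < 50:
        raise ValueError("vocab_size must be >= 50")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1e1c]))
    ranks = np.arange(1, spec.vocab_size + 1)
    freqs = spec.top_frequency / ranks**spec.zipf_exponent
    names = list(spec.class_proportions)
    classes = _apportion_classes(
        names, [spec.class_proportions[c] for c in names], spec.vocab_size
    )
    # deterministic 1/2-character assignment, stratified within each class,
    # so the characters-per-word expectation is stable across realizations
    lengths = np.ones(spec.vocab_size, dtype=int)
    for cls in names:
        idx = np.flatnonzero(classes == cls)
        pattern = _apportion_classes(
            [2, 1], [TWO_CHAR_PROB[cls], 1 - TWO_CHAR_PROB[cls]], len(idx)
        )
        lengths[idx] = pattern.astype(int)
    surfaces = _unique_surfaces(rng, lengths)
    return TaggedLexicon(
        surfaces=surfaces,
        char_counts=lengths.astype(int),
        classes=np.asarray(classes, dtype=object),
        frequencies=freqs,
    )


class _GroupSampler:
    """Word sampling tables for one group.

    The combined word law is ``p_w ∝ mixture[class(w)] * f_w^concentration``
    (normalized within class).  Tokens are drawn with immediate repeats
    rejected; the first token of each utterance is drawn from the stationary
    law ``π_w ∝ p_w (1 - p_w)`` of that chain, which makes *every* token
    marginally π-distributed, so per-token expectations (mean characters per
    word in particular) have the closed form used for calibration.
    """

    def __init__(self, lexicon: TaggedLexicon, params: GroupParams):
        self.lexicon = lexicon
        p = np.zeros(len(lexicon.surfaces))
        for cls, weight in params.class_mixture.items():
            mask = lexicon.classes == cls
            if not mask.any():
                raise ValueError(f"lexicon has no words of class {cls}")
            w = lexicon.frequencies[mask] ** params.concentration
            p[mask] = weight * w / w.sum()
        p /= p.sum()
        self.p = p
        pi = p * (1 - p)
        self.pi = pi / pi.sum()
        self.p_cdf = np.cumsum(p)
        self.pi_cdf = np.cumsum(pi / pi.sum())
        #: expected characters per word under the stationary law
        self.mu_char = float(self.pi @ lexicon.char_counts)
        # class-conditional tables for passive templates
        self.class_idx = {}
        self.class_cdf = {}
        for cls in ("NOUN", "VERB"):
            mask = lexicon.classes == cls
            idx = np.flatnonzero(mask)
            w = lexicon.frequencies[idx] ** params.concentration
            self.class_idx[cls] = idx
            self.class_cdf[cls] = np.cumsum(w / w.sum())
        self.template_chars = (
            float(np.mean(lexicon.char_counts[self.class_idx["NOUN"]]))
            + 1.0
            + float(np.mean(lexicon.char_counts[self.class_idx["VERB"]]))
        )

    def draw_words(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = np.searchsorted(self.p_cdf, rng.random(n))
        idx[0] = np.searchsorted(self.pi_cdf, rng.random())
        for k in range(1, n):
            while idx[k] == idx[k - 1]:
                idx[k] = np.searchsorted(self.p_cdf, rng.random())
        return idx

    def draw_class_word(self, cls: str, rng: np.random.Generator) -> int:
        j = np.searchsorted(self.class_cdf[cls], rng.random())
        return int(self.class_idx[cls][j])


# ---------------------------------------------------------------------------
# transcripts


@dataclass
class _ParticipantLatents:
    severity: float
    mlu: float             # planted characters per utterance
    long_pause_prob: float

    @property
    def mlu_z(self):
        return self._mlu_z

    _mlu_z: float = 0.0
    _lpr_z: float = 0.0

    @property
    def lpr_z(self):
        return self._lpr_z


MLU_FLOOR = 2.4  # characters; symmetric clip bound preserving the mean


def _draw_latents(params: GroupParams, rng: np.random.Generator) -> _ParticipantLatents:
    z = rng.standard_normal()
    w = params.mlu_severity_loading
    mlu_dev = -w * z + np.sqrt(max(0.0, 1 - w * w)) * rng.standard_normal()
    mlu = float(
        np.clip(params.mlu_mean + params.mlu_sd * mlu_dev,
                MLU_FLOOR, 2 * params.mlu_mean - MLU_FLOOR)
    )
    c = params.long_pause_severity_loading
    lp_dev = c * z + np.sqrt(max(0.0, 1 - c * c)) * rng.standard_normal()
    lp = float(
        np.clip(params.long_pause_prob + params.long_pause_sd * lp_dev,
                0.0, 2 * params.long_pause_prob)
    )
    lat = _ParticipantLatents(severity=z, mlu=mlu, long_pause_prob=lp)
    lat._mlu_z = float(mlu_dev)
    lat._lpr_z = float(lp_dev)
    return lat


def _make_token(sampler: _GroupSampler, idx: int, params: GroupParams,
                rng: np.random.Generator) -> Token:
    lex = sampler.lexicon
    cls = lex.classes[idx]
    flags = set()
    if rng.random() < params.revision_prob:
        flags.add("revision")
    if rng.random() < params.incomplete_prob:
        flags.add("incomplete")
    return Token(
        surface=lex.surfaces[idx],
        char_count=int(lex.char_counts[idx]),
        raw_tag=RAW_TAGS[cls],
        coarse_class=CoarseClass(cls),
        flags=frozenset(flags),
    )


def _gap(long_prob: float, rng: np.random.Generator) -> float:
    if rng.random() < long_prob:
        return float(2.0 + rng.exponential(1.0))
    return float(rng.uniform(0.15, 1.5))


def _build_utterance(sampler: _GroupSampler, params: GroupParams,
                     lat: _ParticipantLatents, rng: np.random.Generator) -> list:
    """Word tokens for one utterance (no fillers yet)."""
    if rng.random() < params.passive_prob:
        marker = BEI if rng.random() < params.bei_fraction else BA
        noun = _make_token(sampler, sampler.draw_class_word("NOUN", rng), params, rng)
        verb = _make_token(sampler, sampler.draw_class_word("VERB", rng), params, rng)
        mk = Token(
            surface=marker, char_count=1, raw_tag="P",
            coarse_class=(CoarseClass.PASSIVE_MARKER_BEI if marker == BEI
                          else CoarseClass.PASSIVE_MARKER_BA),
        )
        tokens = [noun, mk, verb] if marker == BEI else [mk, noun, verb]
        lam = max(0.05, (lat.mlu - sampler.template_chars) / sampler.mu_char)
        extra = int(rng.poisson(lam))
        if extra:
            for idx in sampler.draw_words(extra, rng):
                tokens.append(_make_token(sampler, int(idx), params, rng))
        return tokens
    lam = max(0.05, lat.mlu / sampler.mu_char - 1.0)
    n_words = 1 + int(rng.poisson(lam))
    return [_make_token(sampler, int(i), params, rng)
            for i in sampler.draw_words(n_words, rng)]


def _decorate(tokens: list, params: GroupParams, rng: np.random.Generator,
              filler_rate: float) -> list:
    """Insert repetition duplicates and filled pauses into a word list."""
    out: list = []
    for tok in tokens:
        out.append(tok)
        if rng.random() < params.repeat_word_prob:
            out.append(Token(tok.surface, tok.char_count, tok.raw_tag,
                             tok.coarse_class, tok.flags | {"repetition"}))
        if rng.random() < filler_rate:
            surf = FILLER_SURFACES[rng.integers(len(FILLER_SURFACES))]
            out.append(Token(surface=surf, char_count=1, raw_tag="I",
                             coarse_class=CoarseClass.OTHER,
                             flags=frozenset({"filled_pause"})))
    return out


def _generate_image(image_id: int, sampler: _GroupSampler, params: GroupParams,
                    lat: _ParticipantLatents, rng: np.random.Generator) -> ImageResponse:
    n_utt = max(3, int(round(rng.normal(params.n_utterances_mean, params.n_utterances_sd))))
    utterances: list = []
    for k in range(n_utt):
        words = _build_utterance(sampler, params, lat, rng)
        tokens = _decorate(words, params, rng, params.filler_rate)
        gap = _gap(lat.long_pause_prob, rng) if k < n_utt - 1 else None
        utt = Utterance(tokens=tuple(tokens), trailing_pause_s=gap)
        if rng.random() < params.repeat_utterance_prob:
            # immediate repetition of the whole utterance; the copy precedes
            # the real one so the surviving utterance keeps the real gap
            utterances.append(Utterance(tokens=utt.tokens,
                                        trailing_pause_s=float(rng.uniform(0.15, 0.8))))
        utterances.append(utt)
    return ImageResponse(image_id=image_id, utterances=tuple(utterances))


def generate_transcript(group: str, config: SyntheticConfig, seed: int,
                        participant_id: str | None = None,
                        _sampler: _GroupSampler | None = None,
                        _latents: _ParticipantLatents | None = None) -> AnnotatedTranscript:
    """One participant's annotated transcript drawn at the group calibration."""
    params = config.groups[group]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed, 0x7a9]))
    sampler = _sampler or _GroupSampler(generate_lexicon(config.lexicon, config.seed), params)
    lat = _latents or _draw_latents(params, rng)
    responses = [
        _generate_image(i + 1, sampler, params, lat, rng) for i in range(config.n_images)
    ]
    return AnnotatedTranscript(
        participant_id=participant_id or f"{group}-{seed:04d}", responses=responses
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SyntheticCohort:
    """A generated cohort: rows, transcripts and the lexicon used."""

    rows: list
    transcripts: list
    lexicon: FrequencyLexicon
    truth: dict

    def frame(self):
        from .corpus import cohort_to_frame

        return cohort_to_frame(self.rows)


def _symmetric_normal(mean, sd, rng, lo=None):
    """Normal draw clipped symmetrically about the mean (mean-preserving)."""
    x = rng.normal(mean, sd)
    if lo is None:
        return float(x)
    return float(np.clip(x, lo, 2 * mean - lo))


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate the full cohort: transcripts, biomarkers and scores.

    A per-participant seed sequence derived from the master seed makes the
    cohort reproducible, including under partial regeneration of single
    participants.
    """
    lexicon = generate_lexicon(config.lexicon, config.seed)
    rows: list = []
    transcripts: list = []
    counter = 0
    for group in ("NC", "early_AD"):
        n = config.n_per_group.get(group, 0)
        if n == 0:
            continue
        params = config.groups[group]
        sampler = _GroupSampler(lexicon, params)
        for i in range(n):
            counter += 1
            pid = f"{'nc' if group == 'NC' else 'ad'}{i + 1:04d}"
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, counter, 0x5eed]))
            lat = _draw_latents(params, rng)
            transcript = generate_transcript(
                group, config, counter, participant_id=pid,
                _sampler=sampler, _latents=lat,
            )
            z = lat.severity
            suvr = _symmetric_normal(
                params.suvr_mean,
                params.suvr_sd * np.sqrt(1 - params.suvr_severity_loading**2),
                rng, lo=0.5,
            ) + params.suvr_sd * params.suvr_severity_loading * z
            wh = params.hippocampus_severity_loading
            hipp = params.hippocampus_mean + params.hippocampus_sd * (
                wh * z + np.sqrt(max(0.0, 1 - wh * wh)) * rng.standard_normal()
            )
            hipp = float(np.clip(hipp, 1.0, 2 * params.hippocampus_mean - 1.0))
            age = _symmetric_normal(params.age_mean, params.age_sd, rng, lo=50.0)
            edu = _symmetric_normal(params.education_mean, params.education_sd, rng, lo=0.0)
            gender = "F" if rng.random() < params.female_prob else "M"
            latents = {"severity": z, "mlu": lat.mlu_z, "lpr": lat.lpr_z}
            scores = {}
            for name, model in config.score_models.items():
                mean = model.mean_nc if group == "NC" else model.mean_ad
                sd = model.sd_nc if group == "NC" else model.sd_ad
                lin = sum(w * latents[k] for k, w in model.loadings.items())
                val = mean + sd * (lin + model.noise_scale() * rng.standard_normal())
                if model.floor is not None:
                    val = max(model.floor, val)
                scores[name] = float(val)
            rows.append(
                CohortRow(
                    participant_id=pid, group=group, age=age, education=edu,
                    gender=gender, suvr=float(max(suvr, 0.5)),
                    hippocampus_cm3=hipp, scores=scores,
                )
            )
            transcripts.append(transcript)
    return SyntheticCohort(
        rows=rows,
        transcripts=transcripts,
        lexicon=lexicon.to_frequency_lexicon(),
        truth=planted_truth(config),
    )


# ---------------------------------------------------------------------------
# planted truth


def planted_truth(config: SyntheticConfig, mc_n: int = 0, mc_seed: int = 12345) -> dict:
    """Expected values implied by the configuration.

    Closed-form entries (planted means, insertion probabilities, biomarker
    parameters) are always present.  With ``mc_n > 0`` the derived features
    without a closed form (TTR, LPR, CWF, UW, ...) are added as Monte-Carlo
    expectations over ``mc_n`` transcripts per group, using ``mc_seed``
    independently of any cohort seed.
    """
    truth: dict = {}
    lexicon = None
    for group, params in config.groups.items():
        g: dict = {
            "MLU": params.mlu_mean,
            "U": params.n_utterances_mean,
            "PCR": params.passive_prob,
            "FR": params.filler_rate / (1 + params.filler_rate),
            "suvr": params.suvr_mean,
            "hippocampus_cm3": params.hippocampus_mean,
            "age": params.age_mean,
            "education": params.education_mean,
        }
        if mc_n > 0:
            from .features import extract_features

            if lexicon is None:
                lexicon = generate_lexicon(config.lexicon, config.seed)
            sampler = _GroupSampler(lexicon, params)
            freq = lexicon.to_frequency_lexicon()
            mc_cfg = replace(config, seed=mc_seed)
            vecs = []
            for i in range(mc_n):
                t = generate_transcript(group, mc_cfg, i + 1, _sampler=sampler)
                vecs.append(extract_features(t, freq))
            for name in ("TW", "UW", "TTR", "CW", "CD", "CWF", "S", "MLS", "VR", "PR", "LPR"):
                g[name] = float(np.nanmean([v[name] for v in vecs]))
        truth[group] = g
    truth["correlations"] = dict(config.target_correlations)
    return truth


# ---------------------------------------------------------------------------
# calibration


def _measure_group(config: SyntheticConfig, group: str, n: int, seed: int,
                   features=("TTR", "LPR", "MLU")) -> dict:
    from .features import extract_features

    lexicon = generate_lexicon(config.lexicon, config.seed)
    params = config.groups[group]
    sampler = _GroupSampler(lexicon, params)
    freq = lexicon.to_frequency_lexicon()
    cfg = replace(config, seed=seed)
    vals = {f: [] for f in features}
    for i in range(n):
        t = generate_transcript(group, cfg, i + 1, _sampler=sampler)
        vec = extract_features(t, freq)
        for f in features:
            vals[f].append(vec[f])
    return {f: float(np.nanmean(v)) for f, v in vals.items()}


def calibrate_defaults(targets: dict | None = None, n: int = 200, seed: int = 777,
                       max_iter: int = 12, config: SyntheticConfig | None = None) -> dict:
    """Solve the generator's free parameters for the published targets.

    Returns per-group ``concentration`` (bisection on the Monte-Carlo mean
    type-token ratio with common random numbers) and ``long_pause_prob``
    (fixed-point iteration on the Monte-Carlo mean long-pause ratio).  The
    shipped :func:`default_group_params` values are the output of this
    routine at the published group means.
    """
    targets = targets or {
        "NC": {"TTR": 0.56, "LPR": 0.0035},
        "early_AD": {"TTR": 0.51, "LPR": 0.02},
    }
    config = config or default_config()
    out: dict = {}
    for group, t in targets.items():
        lo, hi = 0.5, 2.0
        params = config.groups[group]
        # interleave: concentration moves TTR, long-pause rate moves LPR;
        # the two are nearly orthogonal so a short alternation converges
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            config.groups[group] = replace(params, concentration=mid)
            m = _measure_group(config, group, n, seed, features=("TTR",))
            if m["TTR"] > t["TTR"]:
                lo = mid  # too diverse -> concentrate more
            else:
                hi = mid
        conc = 0.5 * (lo + hi)
        params = replace(params, concentration=conc)
        rho = params.long_pause_prob
        for _ in range(4):
            config.groups[group] = replace(params, long_pause_prob=rho,
                                           long_pause_sd=min(0.45 * rho, params.long_pause_sd))
            m = _measure_group(config, group, n, seed, features=("LPR",))
            if m["LPR"] <= 0:
                rho *= 2
                continue
            rho = float(np.clip(rho * t["LPR"] / m["LPR"], 1e-5, 0.45))
        out[group] = {"concentration": conc, "long_pause_prob": rho}
        config.groups[group] = replace(params, long_pause_prob=rho)
    return out
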