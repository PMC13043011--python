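"""Linguistic features from the timed agent/participant transcript.

25 session-level features: speaking fluency (word rate, filler frequency,
inter-word pauses, response latency), readability (automated readability
index, Flesch-Kincaid grade, Gunning Fog), lexicon-based affect (valence
and emotion-keyword proportions) and lexical structure (length, diversity,
pronoun/negation/content-word usage, syllable statistics).

Ratio- and proportion-type features are computed over the concatenated
participant responses, which makes them invariant to duplicating responses;
genuinely per-response quantities (response lengths, latencies, per-response
sentiment) are averaged across responses.

Syllables are counted with a vowel-group heuristic (with a silent-e rule),
documented so readability values are bit-reproducible on fixture texts.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources

import numpy as np

from .config import AnalysisConfig, TextConfig
from .registry import TEXT_FEATURES
from .session import Transcript

_WORD_RE = re.compile(r"[a-zA-Z']+")
_SENT_RE = re.compile(r"[.!?]+")

_FIRST_PERSON = frozenset({"i", "me", "my", "mine", "myself", "i'm", "i've",
                           "i'll", "i'd"})
_NEGATIONS = frozenset({"not", "no", "never", "none", "nothing", "nobody",
                        "neither", "nor", "cannot", "can't", "don't",
                        "doesn't", "didn't", "won't", "wouldn't", "couldn't",
                        "shouldn't", "isn't", "aren't", "wasn't", "weren't",
                        "haven't", "hasn't"})


@lru_cache(maxsize=None)
def _lexicon(name: str) -> frozenset[str]:
    """Word set from a shipped plain-text lexicon (one word per line)."""
    text = resources.files("convodx.lexicons").joinpath(f"{name}.txt") \
        .read_text()
    return frozenset(w.strip().lower() for w in text.splitlines()
                     if w.strip() and not w.startswith("#"))


def positive_lexicon() -> frozenset[str]:
    return _lexicon("positive")


def negative_lexicon() -> frozenset[str]:
    return _lexicon("negative")


def stopwords() -> frozenset[str]:
    return _lexicon("stopwords")


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens (letters and apostrophes)."""
    return [w for w in _WORD_RE.findall(text.lower()) if w != "'"]


def sentences(text: str) -> list[str]:
    """Punctuation-based sentence split; unpunctuated text is one sentence."""
    parts = [s.strip() for s in _SENT_RE.split(text)]
    parts = [s for s in parts if tokenize(s)]
    return parts if parts else ([text] if tokenize(text) else [])


def count_syllables(word: str) -> int:
    """Heuristic syllable count: vowel groups, with a silent final 'e'.

    A trailing 'e' is dropped unless the word ends in a consonant + 'le'
    (e.g. "table"); every word has at least one syllable.
    """
    w = re.sub(r"[^a-z]", "", word.lower())
    if not w:
        return 1
    if w.endswith("e") and not (len(w) >= 3 and w.endswith("le")
                                and w[-3] not in "aeiouy"):
        w2 = w[:-1]
        if re.search(r"[aeiouy]", w2):
            w = w2
    groups = re.findall(r"[aeiouy]+", w)
    return max(len(groups), 1)


# ---------------------------------------------------------------------------
# readability

def readability(text: str,
                config: TextConfig | None = None) -> dict[str, float]:
    """ARI, Flesch-Kincaid grade and Gunning Fog from the published formulas.

    ARI = 4.71 (chars/words) + 0.5 (words/sentences) - 21.43;
    FK  = 0.39 (words/sentences) + 11.8 (syllables/words) - 15.59;
    Fog = 0.4 [(words/sentences) + 100 (complex/words)], complex meaning
    three or more syllables (no proper-noun exclusions: transcribed speech
    lacks reliable casing).
    """
    cfg = config or TextConfig()
    toks = tokenize(text)
    sents = sentences(text)
    if not toks or not sents:
        return {"ari_complexity": np.nan, "fk_complexity": np.nan,
                "gunning_fog_complexity": np.nan}
    n_words = len(toks)
    n_sents = len(sents)
    n_chars = sum(len(re.sub(r"[^a-z']", "", t)) for t in toks)
    syls = [count_syllables(t) for t in toks]
    n_syl = sum(syls)
    n_complex = sum(s >= cfg.long_word_syllables for s in syls)
    return {
        "ari_complexity": 4.71 * n_chars / n_words
        + 0.5 * n_words / n_sents - 21.43,
        "fk_complexity": 0.39 * n_words / n_sents
        + 11.8 * n_syl / n_words - 15.59,
        "gunning_fog_complexity": 0.4 * (n_words / n_sents
                                         + 100.0 * n_complex / n_words),
    }


# ---------------------------------------------------------------------------
# fluency

def fluency_features(transcript: Transcript,
                     config: TextConfig | None = None) -> dict[str, float]:
    """Word rate, fillers, transcript pauses and response latency."""
    cfg = config or TextConfig()
    fillers = frozenset(cfg.fillers)
    p_turns = transcript.participant_turns
    if not p_turns:
        raise ValueError("transcript has no participant turns")

    speak_time = sum(t.end - t.start for t in p_turns)
    all_tokens = [tok for t in p_turns for tok in tokenize(t.text)]
    n_words = len(all_tokens)
    n_fill = sum(tok in fillers for tok in all_tokens)

    out: dict[str, float] = {
        "words_per_s": n_words / speak_time if speak_time > 0 else np.nan,
        "hesitations_per_s": (n_fill / speak_time if speak_time > 0
                              else np.nan),
        "hesitation_prop": n_fill / n_words if n_words else np.nan,
    }

    # inter-word pauses within turns (need word timings)
    have_timings = all(t.words for t in p_turns)
    if have_timings and speak_time > 0:
        gaps = []
        for t in p_turns:
            for (_, _, e0), (_, s1, _) in zip(t.words[:-1], t.words[1:]):
                if s1 - e0 >= cfg.gap_min:
                    gaps.append(s1 - e0)
        out["transcript_pause_rate"] = len(gaps) / speak_time
        out["transcript_pause_mean_len"] = (float(np.mean(gaps))
                                            if gaps else 0.0)
    else:
        out["transcript_pause_rate"] = np.nan
        out["transcript_pause_mean_len"] = np.nan

    # response latency: participant turn start minus preceding agent turn end
    latencies = []
    turns = transcript.turns
    for i, t in enumerate(turns):
        if t.speaker != "participant":
            continue
        prev_agent = next((u for u in reversed(turns[:i])
                           if u.speaker == "agent"), None)
        if prev_agent is not None:
            latencies.append(t.start - prev_agent.end)
    if latencies:
        out["response_latency_mean"] = float(np.mean(latencies))
        out["response_latency_std"] = float(np.std(latencies))
    else:
        out["response_latency_mean"] = np.nan
        out["response_latency_std"] = np.nan
    return out


# ---------------------------------------------------------------------------
# lexicon affect

def affect_lexicon_features(response_texts: list[str]) -> dict[str, float]:
    """Valence and emotion-keyword proportions from the shipped lexicons.

    Each response's valence is (positive - negative) / (positive + negative)
    keyword counts, in [-1, 1]; a response without emotion keywords scores
    0.  Proportions are keyword counts over all participant tokens.
    """
    pos_lex, neg_lex = positive_lexicon(), negative_lexicon()
    valences = []
    n_pos = n_neg = n_tok = 0
    for text in response_texts:
        toks = tokenize(text)
        if not toks:
            continue
        p = sum(t in pos_lex for t in toks)
        n = sum(t in neg_lex for t in toks)
        valences.append((p - n) / (p + n) if p + n else 0.0)
        n_pos += p
        n_neg += n
        n_tok += len(toks)
    if n_tok == 0:
        return {k: np.nan for k in
                ("sentiment_mean", "sentiment_std", "emotion_keyword_prop",
                 "positive_emotion_prop", "negative_emotion_prop")}
    return {
        "sentiment_mean": float(np.mean(valences)),
        "sentiment_std": float(np.std(valences)),
        "emotion_keyword_prop": (n_pos + n_neg) / n_tok,
        "positive_emotion_prop": n_pos / n_tok,
        "negative_emotion_prop": n_neg / n_tok,
    }


# ---------------------------------------------------------------------------
# lexical structure

def lexical_features(response_texts: list[str],
                     config: TextConfig | None = None) -> dict[str, float]:
    cfg = config or TextConfig()
    stops = stopwords()
    all_tokens: list[str] = []
    resp_lens = []
    ttrs = []          # per response, so repetitive sessions are comparable
    n_sents = 0
    for text in response_texts:
        toks = tokenize(text)
        if toks:
            resp_lens.append(len(toks))
            ttrs.append(len(set(toks)) / len(toks))
            n_sents += len(sentences(text))
        all_tokens.extend(toks)
    if not all_tokens:
        return {k: np.nan for k in
                ("transcript_len_words", "mean_response_len_words",
                 "type_token_ratio", "mean_word_len", "mean_sentence_len",
                 "first_person_singular_prop", "negation_prop",
                 "content_word_prop", "syllables_per_word", "long_word_prop")}
    n = len(all_tokens)
    syls = [count_syllables(t) for t in all_tokens]
    return {
        "transcript_len_words": float(n),
        "mean_response_len_words": float(np.mean(resp_lens)),
        "type_token_ratio": float(np.mean(ttrs)),
        "mean_word_len": float(np.mean(
            [len(re.sub(r"[^a-z']", "", t)) for t in all_tokens])),
        "mean_sentence_len": n / n_sents if n_sents else np.nan,
        "first_person_singular_prop": sum(
            t in _FIRST_PERSON for t in all_tokens) / n,
        "negation_prop": sum(t in _NEGATIONS for t in all_tokens) / n,
        "content_word_prop": sum(t not in stops for t in all_tokens) / n,
        "syllables_per_word": float(np.mean(syls)),
        "long_word_prop": sum(
            s >= cfg.long_word_syllables for s in syls) / n,
    }


# ---------------------------------------------------------------------------
# session aggregation

def extract_text(transcript: Transcript,
                 config: AnalysisConfig | None = None) -> dict[str, float]:
    """All 25 linguistic features for one session transcript."""
    cfg = (config or AnalysisConfig()).text
    p_turns = transcript.participant_turns
    if not p_turns:
        raise ValueError("transcript has no participant turns")
    texts = [t.text for t in p_turns]

    # per-response readability averaged across responses
    read_rows = [readability(t, cfg) for t in texts]
    read = {
        k: (float(np.nanmean([r[k] for r in read_rows]))
            if np.isfinite([r[k] for r in read_rows]).any() else np.nan)
        for k in ("ari_complexity", "fk_complexity", "gunning_fog_complexity")
    }

    out: dict[str, float] = {}
    out.update(fluency_features(transcript, cfg))
    out.update(read)
    out.update(affect_lexicon_features(texts))
    out.update(lexical_features(texts, cfg))
    assert set(out) == set(TEXT_FEATURES)
    return out
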