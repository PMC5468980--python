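"""Narrative text normalization and token refinement.

Pipeline: normalize -> whitespace tokenize -> drop stop words -> drop tokens
shorter than 2 characters -> lemmatize (dictionary + plural rules) -> stem
(Porter). Deterministic and stateless; every stage can be switched off via
:class:`PreprocessConfig`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .corpus import IncidentReport

__all__ = [
    "TokenDoc",
    "PreprocessConfig",
    "normalize_text",
    "tokenize",
    "lemmatize",
    "porter_stem",
    "preprocess_report",
    "preprocess_corpus",
    "load_stopwords",
]

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


@dataclass(frozen=True)
class TokenDoc:
    """A report reduced to an ordered list of refined lowercase tokens."""

    report_id: str
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)


def load_stopwords(path: Optional[str | Path] = None) -> frozenset[str]:
    """Load the stop-word list; defaults to the vendored English list."""
    if path is None:
        text = (
            resources.files("incident_triage")
            .joinpath("data/stopwords_en.txt")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    return frozenset(
        w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#")
    )


@dataclass(frozen=True)
class PreprocessConfig:
    stopwords: frozenset[str] = field(default_factory=load_stopwords)
    min_token_len: int = 2
    lemmatize: bool = True
    stem: bool = True


def normalize_text(text: str) -> str:
    """Lowercase and strip everything but alphanumerics; idempotent."""
    return _NON_ALNUM.sub(" ", text.lower()).strip()


def tokenize(text: str) -> list[str]:
    return normalize_text(text).split()


# --- dictionary lemmatizer -------------------------------------------------
# Irregular forms mapped explicitly; regular plurals handled by rules. Verb
# inflections (-ed, -ing) are left to the stemmer, which conflates them anyway.

_IRREGULAR = {
    "was": "be", "were": "be", "is": "be", "are": "be", "been": "be", "being": "be",
    "am": "be", "has": "have", "had": "have", "having": "have",
    "given": "give", "gave": "give", "taken": "take", "took": "take",
    "fell": "fall", "fallen": "fall", "found": "find", "went": "go", "gone": "go",
    "done": "do", "did": "do", "said": "say", "seen": "see", "saw": "see",
    "got": "get", "left": "leave", "made": "make", "came": "come",
    "children": "child", "feet": "foot", "men": "man", "women": "woman",
    "teeth": "tooth", "people": "person",
}

_NO_SINGULAR = frozenset({"this", "his", "its", "was", "has", "is", "us", "gas", "bus"})


def lemmatize(token: str) -> str:
    if token in _IRREGULAR:
        return _IRREGULAR[token]
    if token in _NO_SINGULAR or len(token) < 4:
        return token
    if token.endswith("ies"):
        return token[:-3] + "y"
    if token.endswith(("sses", "xes", "zes", "ches", "shes")):
        return token[:-2]
    if token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    return token


# --- Porter stemmer --------------------------------------------------------

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel->consonant transitions (the m of C?(VC)^m V?)."""
    runs: list[bool] = []
    for i in range(len(stem)):
        c = _is_cons(stem, i)
        if not runs or runs[-1] != c:
            runs.append(c)
    return sum(1 for a, b in zip(runs, runs[1:]) if a is False and b is True)


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return len(word) >= 2 and word[-1] == word[-2] and _is_cons(word, len(word) - 1)


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _replace_suffix(word: str, rules: Sequence[tuple[str, str]], min_m: int) -> str:
    for suf, rep in rules:
        if word.endswith(suf):
            stem = word[: len(word) - len(suf)]
            if _measure(stem) > min_m:
                return stem + rep
            return word
    return word


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]
_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]
_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def porter_stem(word: str) -> str:
    """Classic Porter (1980) suffix-stripping stemmer."""
    if len(word) <= 2:
        return word
    w = word

    # step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif not w.endswith("ss") and w.endswith("s"):
        w = w[:-1]

    # step 1b
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        flag = False
        if w.endswith("ed") and _has_vowel(w[:-2]):
            w, flag = w[:-2], True
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            w, flag = w[:-3], True
        if flag:
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_cons(w) and w[-1] not in "lsz":
                w = w[:-1]
            elif _measure(w) == 1 and _ends_cvc(w):
                w += "e"

    # step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    w = _replace_suffix(w, _STEP2, 0)
    w = _replace_suffix(w, _STEP3, 0)

    # step 4
    for suf in _STEP4:
        if w.endswith(suf):
            stem = w[: len(w) - len(suf)]
            if _measure(stem) > 1 and (suf != "ion" or stem.endswith(("s", "t"))):
                w = stem
            break

    # step 5a
    if w.endswith("e"):
        m = _measure(w[:-1])
        if m > 1 or (m == 1 and not _ends_cvc(w[:-1])):
            w = w[:-1]
    # step 5b
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]
    return w


# --- pipeline --------------------------------------------------------------

def refine_tokens(tokens: Iterable[str], config: Optional[PreprocessConfig] = None) -> list[str]:
    cfg = config or PreprocessConfig()
    out = []
    for tok in tokens:
        if tok in cfg.stopwords or len(tok) < cfg.min_token_len:
            continue
        if cfg.lemmatize:
            tok = lemmatize(tok)
        if cfg.stem:
            tok = porter_stem(tok)
        # re-check: lemmatization/stemming may shorten or create a stop word
        if len(tok) >= cfg.min_token_len and tok not in cfg.stopwords:
            out.append(tok)
    return out


def preprocess_report(
    report: IncidentReport, config: Optional[PreprocessConfig] = None
) -> TokenDoc:
    return TokenDoc(
        report_id=report.report_id,
        tokens=tuple(refine_tokens(tokenize(report.narrative), config)),
    )


def preprocess_corpus(
    reports: Sequence[IncidentReport], config: Optional[PreprocessConfig] = None
) -> list[TokenDoc]:
    cfg = config or PreprocessConfig()
    return [preprocess_report(r, cfg) for r in reports]
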