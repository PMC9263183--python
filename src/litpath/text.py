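"""Tokenization and phrase matching shared by lexicon loading and annotation.

All dictionary matching in the pipeline runs on a single normalized token
representation so that terms stored in lexicon files and free text from
abstracts are compared consistently.
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from typing import Iterable, Sequence

# Greek letters are transliterated in place (no token split), so that e.g.
# "Aβ42" becomes the single token "abeta42".
GREEK_MAP = {
    "α": "alpha",
    "β": "beta",
    "γ": "gamma",
    "δ": "delta",
    "ε": "epsilon",
    "ζ": "zeta",
    "η": "eta",
    "θ": "theta",
    "κ": "kappa",
    "λ": "lambda",
    "μ": "mu",
    "ν": "nu",
    "π": "pi",
    "ρ": "rho",
    "σ": "sigma",
    "τ": "tau",
    "φ": "phi",
    "χ": "chi",
    "ψ": "psi",
    "ω": "omega",
}

# Tokens are runs of alphanumerics; internal hyphens are kept so that
# hyphenated vocabulary ("long-term", "amyloid-beta") stays one token.
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


def normalize_text(text: str) -> list[str]:
    """Normalize free text to a token sequence.

    Lowercases, applies Unicode NFKC normalization, transliterates Greek
    letters, then splits on non-alphanumeric characters while keeping
    internal hyphens.
    """
    if not text:
        return []
    s = unicodedata.normalize("NFKC", text).lower()
    if any(ch in GREEK_MAP for ch in s):
        s = "".join(GREEK_MAP.get(ch, ch) for ch in s)
    return _TOKEN_RE.findall(s)


def normalize_phrase(phrase: str | Sequence[str]) -> tuple[str, ...]:
    """Normalize a dictionary phrase to its token tuple."""
    if isinstance(phrase, str):
        return tuple(normalize_text(phrase))
    return tuple(t for part in phrase for t in normalize_text(part))


class PhraseMatcher:
    """Greedy longest-match-first matcher over normalized token sequences.

    Multi-token phrases match contiguous token runs.  When phrases nest
    (e.g. "mild cognitive impairment" and "cognitive impairment") the
    longest phrase starting at a position wins and its tokens are consumed,
    so sub-phrases are not re-counted.
    """

    def __init__(self, phrases: Iterable[str | Sequence[str]]):
        self._index: dict[str, list[tuple[str, ...]]] = {}
        self.phrases: set[tuple[str, ...]] = set()
        for phrase in phrases:
            tup = normalize_phrase(phrase)
            if not tup:
                continue
            self.phrases.add(tup)
        for tup in self.phrases:
            self._index.setdefault(tup[0], []).append(tup)
        for bucket in self._index.values():
            bucket.sort(key=len, reverse=True)

    def match(self, tokens: Sequence[str]) -> Counter:
        """Count phrase occurrences; returns Counter keyed by token tuple."""
        counts: Counter = Counter()
        i, n = 0, len(tokens)
        index = self._index
        while i < n:
            bucket = index.get(tokens[i])
            if bucket:
                for phrase in bucket:
                    L = len(phrase)
                    if i + L <= n and tuple(tokens[i : i + L]) == phrase:
                        counts[phrase] += 1
                        i += L
                        break
                else:
                    i += 1
            else:
                i += 1
        return counts

    def match_spans(self, tokens: Sequence[str]) -> list[tuple[int, int, tuple[str, ...]]]:
        """Like :meth:`match` but returns (start, end, phrase) half-open spans."""
        spans = []
        i, n = 0, len(tokens)
        while i < n:
            bucket = self._index.get(tokens[i])
            if bucket:
                for phrase in bucket:
                    L = len(phrase)
                    if i + L <= n and tuple(tokens[i : i + L]) == phrase:
                        spans.append((i, i + L, phrase))
                        i += L
                        break
                else:
                    i += 1
            else:
                i += 1
        return spans


def match_terms(tokens: Sequence[str], term_set: Iterable[str | Sequence[str]]) -> Counter:
    """Match a term set against tokens (longest-match-first, no re-counting)."""
    return PhraseMatcher(term_set).match(tokens)
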