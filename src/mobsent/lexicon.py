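"""Happiness lexicon: word -> average happiness score on the 1 (sad) to 9 (happy) scale.

The scoring instrument excludes near-neutral words: with filter width
``neutral_delta`` (default 1), words whose score lies in the *open* interval
(5 - delta, 5 + delta) are ignored when scoring a text.  Scores of exactly
4.0 or 6.0 are therefore retained at the default width.

A 15-word labMT-style fixture is packaged (``mobsent/data/labmt_table1.tsv``)
so that the full pipeline runs and is testable without any external word list.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict

__all__ = ["Lexicon", "read_lexicon", "load_packaged_lexicon"]

NEUTRAL_SCORE = 5.0


@dataclass(frozen=True)
class Lexicon:
    """Immutable word -> happiness score map with a neutral-band filter."""

    entries: Dict[str, float]
    neutral_delta: float = 1.0

    def __post_init__(self):
        if self.neutral_delta < 0:
            raise ValueError("neutral_delta must be >= 0")
        for word, score in self.entries.items():
            if not (1.0 <= score <= 9.0):
                raise ValueError(f"score for {word!r} outside [1, 9]: {score}")

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def score_of(self, word: str) -> float:
        return self.entries[word]

    def is_neutral(self, word: str, delta: float | None = None) -> bool:
        """True if the word's score lies strictly inside the neutral band."""
        d = self.neutral_delta if delta is None else delta
        h = self.entries[word]
        return NEUTRAL_SCORE - d < h < NEUTRAL_SCORE + d

    def is_scorable(self, word: str, delta: float | None = None) -> bool:
        """Known word outside the neutral band."""
        return word in self.entries and not self.is_neutral(word, delta)

    def scorable_words(self, delta: float | None = None) -> list[str]:
        return [w for w in self.entries if not self.is_neutral(w, delta)]

    def special_tokens(self) -> list[str]:
        """Lexicon entries (emoticons etc.) that plain word splitting would destroy.

        Longest first, for longest-match tokenization.
        """
        import re

        plain = re.compile(r"[a-z0-9']+")
        out = [w for w in self.entries if not plain.fullmatch(w)]
        return sorted(out, key=len, reverse=True)


def read_lexicon(path: str | Path, neutral_delta: float = 1.0) -> Lexicon:
    """Read a 2-column tab-separated ``word<TAB>score`` file (no header).

    Raises
    ------
    ValueError
        On a duplicate word (ambiguous score) or a score outside [1, 9].
    """
    entries: Dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                word, raw = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected 'word<TAB>score'") from exc
            word = word.strip().lower()
            score = float(raw)
            if word in entries:
                raise ValueError(f"{path}:{lineno}: duplicate word {word!r}")
            if not (1.0 <= score <= 9.0):
                raise ValueError(f"{path}:{lineno}: score outside [1, 9]: {score}")
            entries[word] = score
    return Lexicon(entries=entries, neutral_delta=neutral_delta)


def load_packaged_lexicon(neutral_delta: float = 1.0) -> Lexicon:
    """Load the packaged 15-word labMT-style fixture."""
    ref = resources.files("mobsent").joinpath("data/labmt_table1.tsv")
    with resources.as_file(ref) as path:
        return read_lexicon(path, neutral_delta=neutral_delta)
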