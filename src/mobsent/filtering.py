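"""Quality-control filters for geolocated message corpora.

Three independent rules:

* **Bot removal** — authors for whom at least half (inclusive) of messages
  contain any of a small set of telltale keywords (weather, earthquake,
  traffic, coupon feeds) are dropped entirely.  Matching is on lowercased
  *tokens*, not substrings: 'humid' and 'humidity' are separate keywords.
* **Check-in tagging** — messages carrying a Foursquare share URL
  (substring ``4sq.com``, case-insensitive) are flagged.  Flagged messages are
  *retained* for mobility analysis but excluded from happiness scoring, since
  their templated text does not reflect sentiment.
* **Activity threshold** — only authors with at least ``min_messages``
  geolocated messages (default 30) are kept; the trajectory-shape analyses use
  a strictly-greater-than-50 variant and the locale analyses an at-least-800
  variant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .corpus import Corpus

__all__ = [
    "BOT_KEYWORDS",
    "FilterReport",
    "detect_bots",
    "detect_checkin",
    "flag_checkins",
    "apply_activity_threshold",
    "sentiment_eligible",
    "apply_filters",
]

BOT_KEYWORDS = frozenset(
    {"pressure", "humid", "humidity", "earthquake", "traffic", "coupon"}
)

_TOKEN_RE = re.compile(r"[a-z0-9']+")
_CHECKIN_RE = re.compile(r"4sq\.com", re.IGNORECASE)


@dataclass
class FilterReport:
    """Outcome of a filtering pass."""

    bot_user_ids: set
    n_checkins: int
    n_users_below_threshold: int
    corpus: Corpus  # surviving corpus

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"metric": "n_bot_users", "value": len(self.bot_user_ids)},
                {"metric": "n_checkins", "value": self.n_checkins},
                {"metric": "n_users_below_threshold", "value": self.n_users_below_threshold},
                {"metric": "n_surviving_users", "value": self.corpus.n_users},
                {"metric": "n_surviving_messages", "value": self.corpus.n_messages},
            ]
        )


def _contains_keyword(text: str, keywords: frozenset) -> bool:
    return any(tok in keywords for tok in _TOKEN_RE.findall(text.lower()))


def detect_bots(
    corpus: Corpus,
    keywords: frozenset = BOT_KEYWORDS,
    fraction: float = 0.5,
) -> set:
    """User ids for whom >= ``fraction`` of messages contain a bot keyword token."""
    if corpus.n_messages == 0:
        return set()
    hits = corpus.frame["text"].map(lambda t: _contains_keyword(t, keywords))
    per_user = hits.groupby(corpus.frame["user_id"]).mean()
    return set(per_user.index[per_user >= fraction])


def detect_checkin(text: str) -> bool:
    """True iff the text carries a Foursquare share URL marker."""
    return bool(_CHECKIN_RE.search(text))


def flag_checkins(corpus: Corpus) -> Corpus:
    """Return a corpus with ``is_checkin`` set from the text marker."""
    out = Corpus(corpus.frame)
    out.frame = out.frame.assign(is_checkin=out.frame["text"].map(detect_checkin))
    return out


def apply_activity_threshold(
    corpus: Corpus, min_messages: int = 30, strict: bool = False
) -> Corpus:
    """Keep users with N >= min_messages (or N > min_messages when strict)."""
    counts = corpus.message_counts()
    keep = counts.index[counts > min_messages] if strict else counts.index[counts >= min_messages]
    return corpus.subset_users(keep)


def sentiment_eligible(frame: pd.DataFrame, bot_ids: set) -> pd.Series:
    """Boolean mask over message rows: not a check-in and author not a bot.

    Mobility analyses ignore this mask (check-ins still carry positions);
    happiness analyses apply it.
    """
    return ~frame["is_checkin"] & ~frame["user_id"].isin(bot_ids)


def apply_filters(
    corpus: Corpus,
    min_messages: int = 30,
    strict_threshold: bool = False,
    bot_keywords: frozenset = BOT_KEYWORDS,
    bot_fraction: float = 0.5,
) -> FilterReport:
    """Full quality-control pass: flag check-ins, drop bots, apply activity threshold."""
    flagged = flag_checkins(corpus)
    bots = detect_bots(flagged, keywords=bot_keywords, fraction=bot_fraction)
    no_bots = flagged.subset_users([u for u in flagged.users if u not in bots])
    survived = apply_activity_threshold(no_bots, min_messages, strict=strict_threshold)
    n_below = no_bots.n_users - survived.n_users
    return FilterReport(
        bot_user_ids=bots,
        n_checkins=int(flagged.frame["is_checkin"].sum()),
        n_users_below_threshold=n_below,
        corpus=survived,
    )
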