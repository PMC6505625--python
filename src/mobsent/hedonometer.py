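"""Lexicon-based happiness scoring and binned happiness trends.

The instrument assigns a text T the frequency-weighted mean score

    h_avg(T) = sum_i h(w_i) f_i / sum_i f_i

over the words w_i of T that are in the lexicon and outside the open neutral
band (5 - delta, 5 + delta), delta = 1 by default.  Scoring is done on pooled
bags of words, never per message: for a trend, all words written in a bin are
gathered and scored once.  Bins are equal-population: tweets binned by
distance from the author's expected location, or users binned by gyradius.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .lexicon import Lexicon

logger = logging.getLogger(__name__)

__all__ = [
    "tokenize",
    "count_words",
    "score",
    "equal_count_bins",
    "BinnedTrend",
    "happiness_by_distance",
    "happiness_by_gyradius",
    "fit_log_linear",
]

_STRIP_CHARS = "!\"#$%&()*+,-./:;<=>?@[\\]^_`{|}~'‘’“”…"


def _special_token_re(lexicon: Lexicon | None) -> re.Pattern | None:
    if lexicon is None:
        return None
    specials = lexicon.special_tokens()
    if not specials:
        return None
    return re.compile("|".join(re.escape(t) for t in specials))


def tokenize(text: str, lexicon: Lexicon | None = None) -> list[str]:
    """Lowercase and split a text into word tokens.

    Lexicon tokens that plain splitting would destroy (emoticons such as
    ':(' ) are extracted first, longest match first; the remainder is split
    on whitespace with leading/trailing punctuation stripped (internal
    apostrophes survive: "I'm" -> "i'm").
    """
    text = text.lower()
    out: list[tuple[int, str]] = []
    pat = _special_token_re(lexicon)
    if pat is not None:
        def grab(m: re.Match) -> str:
            out.append((m.start(), m.group(0)))
            return " " * len(m.group(0))  # keep downstream offsets aligned

        text = pat.sub(grab, text)
    for m in re.finditer(r"\S+", text):
        tok = m.group(0).strip(_STRIP_CHARS)
        if tok:
            out.append((m.start(), tok))
    out.sort(key=lambda p: p[0])
    return [t for _, t in out]


def count_words(texts, lexicon: Lexicon | None = None) -> Counter:
    """Pooled word counts over an iterable of texts."""
    counts: Counter = Counter()
    for t in texts:
        counts.update(tokenize(t, lexicon))
    return counts


def score(counts, lexicon: Lexicon, delta: float | None = None) -> float | None:
    """Average happiness of a bag of words; None if no word is scorable.

    Only lexicon words outside the open neutral band contribute.  The result,
    when defined, lies in [1, 9].  A text with no scorable words yields an
    explicit None, never a silent 0.
    """
    num = 0.0
    den = 0
    for word, f in counts.items():
        if f <= 0:
            continue
        if lexicon.is_scorable(word, delta):
            num += lexicon.score_of(word) * f
            den += f
    if den == 0:
        return None
    return num / den


def scorable_total(counts, lexicon: Lexicon, delta: float | None = None) -> int:
    return sum(f for w, f in counts.items() if f > 0 and lexicon.is_scorable(w, delta))


def equal_count_bins(values, k: int, ids=None) -> np.ndarray:
    """Assign entities to k equal-population bins by ascending value.

    Stable on ties (original order preserved); bin sizes differ by at most
    one, with the remainder going to the lowest bins.  Returns an integer
    array of bin indices 0..k-1 aligned with the input order.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"cannot split {n} entities into {k} equal-population bins")
    order = np.argsort(v, kind="mergesort")  # stable: ties by original order
    bins = np.empty(n, dtype=int)
    for b, chunk in enumerate(np.array_split(order, k)):
        bins[chunk] = b
    return bins


@dataclass
class BinnedTrend:
    """Equal-population binned happiness trend."""

    table: pd.DataFrame  # bin, value bounds/median, populations, n_words, h_avg
    word_counts: list[Counter]  # pooled scorable+unscorable counts per bin
    by: str  # "distance" or "gyradius"


def _trend_from_groups(
    groups: list[tuple[float, float, float, int, Counter]],
    lexicon: Lexicon,
    delta: float | None,
    by: str,
) -> BinnedTrend:
    rows = []
    counts_per_bin = []
    for b, (lo, hi, med, pop, counts) in enumerate(groups, start=1):
        h = score(counts, lexicon, delta)
        if h is None:
            logger.warning("bin %d has no scorable words; no score recorded", b)
        rows.append(
            {
                "bin": b,
                f"{by}_min": lo,
                f"{by}_max": hi,
                f"{by}_median": med,
                "population": pop,
                "n_scorable_words": scorable_total(counts, lexicon, delta),
                "h_avg": np.nan if h is None else h,
            }
        )
        counts_per_bin.append(counts)
    return BinnedTrend(table=pd.DataFrame(rows), word_counts=counts_per_bin, by=by)


def happiness_by_distance(
    texts,
    distances_m,
    lexicon: Lexicon,
    k: int = 10,
    delta: float | None = None,
) -> BinnedTrend:
    """Bin messages into k equal-population distance bins and score pooled words.

    Parameters
    ----------
    texts : sequence of str
        Sentiment-eligible message texts.
    distances_m : sequence of float
        Distance of each message from its author's expected location.
    """
    d = np.asarray(distances_m, dtype=float)
    if len(d) != len(texts):
        raise ValueError("texts and distances must align")
    bins = equal_count_bins(d, k)
    texts = list(texts)
    groups = []
    for b in range(k):
        sel = np.flatnonzero(bins == b)
        counts = count_words((texts[i] for i in sel), lexicon)
        db = d[sel]
        groups.append((float(db.min()), float(db.max()), float(np.median(db)), len(sel), counts))
    return _trend_from_groups(groups, lexicon, delta, by="distance")


def happiness_by_gyradius(
    user_texts: dict[str, list],
    user_gyradius: dict[str, float],
    lexicon: Lexicon,
    k: int = 10,
    delta: float | None = None,
) -> BinnedTrend:
    """Bin users into k equal-population gyradius groups; pool each group's words."""
    uids = [u for u in user_texts if u in user_gyradius]
    rg = np.array([user_gyradius[u] for u in uids])
    bins = equal_count_bins(rg, k, ids=uids)
    groups = []
    for b in range(k):
        sel = np.flatnonzero(bins == b)
        counts: Counter = Counter()
        for i in sel:
            counts.update(count_words(user_texts[uids[i]], lexicon))
        rb = rg[sel]
        groups.append((float(rb.min()), float(rb.max()), float(np.median(rb)), len(sel), counts))
    return _trend_from_groups(groups, lexicon, delta, by="gyradius")


def fit_log_linear(distances_m, h_values, min_distance: float | None = None):
    """OLS of happiness on log10 distance: h = intercept + slope * log10(d).

    ``min_distance`` excludes bins below the trend's minimum (e.g. the
    commute-scale dip) from the fit.  Returns a fitted statsmodels results
    object; slope is ``res.params[1]``.
    """
    d = np.asarray(distances_m, dtype=float)
    h = np.asarray(h_values, dtype=float)
    keep = np.isfinite(d) & np.isfinite(h) & (d > 0)
    if min_distance is not None:
        keep &= d >= min_distance
    d, h = d[keep], h[keep]
    if len(d) < 2:
        raise ValueError("need at least 2 bins with scores for the log-linear fit")
    X = sm.add_constant(np.log10(d))
    return sm.OLS(h, X).fit()
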