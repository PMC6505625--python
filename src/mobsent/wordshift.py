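"""Word shift decomposition of a happiness difference between two texts.

Given a reference text T_ref and a comparison text T_comp with filtered
scores h_ref and h_comp, each word's contribution is

    delta(w) = (h(w) - h_ref) * (p_comp(w) - p_ref(w))

where p are normalized frequencies over the *scorable* words of each text
(lexicon words outside the neutral band; an absent word has p = 0).  With
this convention the decomposition is exact: sum_w delta(w) = h_comp - h_ref.

Each word is classified by two signs: +/- according to whether its score is
above or below h_ref (happy or sad relative to the reference text), and
up/down according to whether it is used more or less in T_comp than in
T_ref.  The four class sums partition the total difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hedonometer import score, scorable_total
from .lexicon import Lexicon

__all__ = ["WordShiftResult", "word_shift", "rank_contributions", "type_balance"]

TYPES = ("+up", "-up", "+down", "-down")


@dataclass
class WordShiftResult:
    table: pd.DataFrame  # word, h, p_ref, p_comp, delta, percent, type
    h_ref: float
    h_comp: float
    delta_h: float
    ref_size: int  # scorable word total of T_ref
    comp_size: int


def word_shift(
    ref_counts, comp_counts, lexicon: Lexicon, delta: float | None = None
) -> WordShiftResult:
    """Decompose h(T_comp) - h(T_ref) into per-word contributions."""
    h_ref = score(ref_counts, lexicon, delta)
    h_comp = score(comp_counts, lexicon, delta)
    if h_ref is None or h_comp is None:
        raise ValueError("both texts must contain at least one scorable word")
    n_ref = scorable_total(ref_counts, lexicon, delta)
    n_comp = scorable_total(comp_counts, lexicon, delta)

    words = sorted(
        {
            w
            for counts in (ref_counts, comp_counts)
            for w, f in counts.items()
            if f > 0 and lexicon.is_scorable(w, delta)
        }
    )
    rows = []
    dh = h_comp - h_ref
    for w in words:
        h = lexicon.score_of(w)
        p_ref = ref_counts.get(w, 0) / n_ref
        p_comp = comp_counts.get(w, 0) / n_comp
        contrib = (h - h_ref) * (p_comp - p_ref)
        wtype = ("+" if h > h_ref else "-") + ("up" if p_comp > p_ref else "down")
        rows.append(
            {
                "word": w,
                "h": h,
                "p_ref": p_ref,
                "p_comp": p_comp,
                "delta": contrib,
                "percent": 100.0 * contrib / dh if dh != 0 else np.nan,
                "type": wtype,
            }
        )
    table = pd.DataFrame(
        rows, columns=["word", "h", "p_ref", "p_comp", "delta", "percent", "type"]
    )
    return WordShiftResult(
        table=table,
        h_ref=h_ref,
        h_comp=h_comp,
        delta_h=dh,
        ref_size=n_ref,
        comp_size=n_comp,
    )


def rank_contributions(result: WordShiftResult, top_n: int | None = None) -> pd.DataFrame:
    """Words ranked by |percent contribution| (ties alphabetical), with the
    cumulative signed-percent curve."""
    t = result.table.copy()
    t["abs_percent"] = t["percent"].abs()
    t = t.sort_values(["abs_percent", "word"], ascending=[False, True], kind="mergesort")
    t = t.drop(columns="abs_percent").reset_index(drop=True)
    t["rank"] = np.arange(1, len(t) + 1)
    t["cumulative_percent"] = t["percent"].cumsum()
    if top_n is not None:
        t = t.head(top_n)
    return t


def type_balance(result: WordShiftResult) -> pd.DataFrame:
    """Total contribution of the four word types; the sums add to delta_h."""
    sums = result.table.groupby("type")["delta"].sum()
    return pd.DataFrame(
        {"type": list(TYPES), "total": [float(sums.get(t, 0.0)) for t in TYPES]}
    )
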