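"""Happiness scoring: tokenization, the neutral-band filter, pooled binning, log fits."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobsent import hedonometer as hd
from mobsent.lexicon import load_packaged_lexicon


class TestTokenize:
    def test_case_and_punctuation(self, lexicon):
        assert hd.tokenize("I'm HAPPY!", lexicon) == ["i'm", "happy"]

    def test_emoticon_survives(self, lexicon):
        assert hd.tokenize("so sad :(", lexicon) == ["so", "sad", ":("]

    def test_empty(self, lexicon):
        assert hd.tokenize("", lexicon) == []

    def test_emoticon_adjacent_to_punctuation(self, lexicon):
        assert ":(" in hd.tokenize("bad day... :(!!", lexicon)


class TestScore:
    def test_single_word(self, lexicon):
        assert hd.score(Counter({"happy": 1}), lexicon) == pytest.approx(8.30)

    def test_all_neutral_gives_no_score(self, lexicon):
        assert hd.score(Counter({"and": 5, "the": 3}), lexicon) is None

    def test_two_word_average(self, lexicon):
        got = hd.score(Counter({"happy": 1, "jail": 1}), lexicon)
        assert got == pytest.approx((8.30 + 1.76) / 2)

    def test_unknown_words_ignored(self, lexicon):
        got = hd.score(Counter({"happy": 1, "zzzz": 10}), lexicon)
        assert got == pytest.approx(8.30)

    def test_count_scale_invariance(self, lexicon):
        c = Counter({"happy": 2, "war": 3, "down": 1})
        c10 = Counter({w: 10 * f for w, f in c.items()})
        assert hd.score(c10, lexicon) == pytest.approx(hd.score(c, lexicon), rel=1e-12)

    def test_monotone_in_word_score(self, lexicon):
        base = Counter({"worse": 3, "fresh": 2})
        better = Counter({"happy": 3, "fresh": 2})  # worse (2.70) -> happy (8.30)
        assert hd.score(better, lexicon) > hd.score(base, lexicon)

    def test_delta_zero_keeps_all_lexicon_words(self, lexicon):
        got = hd.score(Counter({"and": 1}), lexicon, delta=0.0)
        assert got == pytest.approx(5.22)

    def test_result_in_score_range(self, lexicon):
        words = list(lexicon.entries)
        rng = np.random.default_rng(3)
        for _ in range(20):
            c = Counter(
                {w: int(k) for w, k in zip(words, rng.integers(0, 5, len(words)))}
            )
            got = hd.score(c, lexicon)
            if got is not None:
                assert 1.0 <= got <= 9.0


class TestEqualCountBins:
    def test_one_per_bin(self):
        bins = hd.equal_count_bins(np.arange(10), 10)
        assert sorted(bins.tolist()) == list(range(10))

    def test_remainder_goes_to_low_bins(self):
        bins = hd.equal_count_bins(np.arange(11), 10)
        sizes = np.bincount(bins, minlength=10)
        assert sizes.tolist() == [2] + [1] * 9

    def test_bins_respect_order(self):
        vals = np.array([5.0, 1.0, 3.0, 2.0, 4.0, 0.0])
        bins = hd.equal_count_bins(vals, 3)
        # bin index must be non-decreasing in value
        order = np.argsort(vals)
        assert (np.diff(bins[order]) >= 0).all()

    def test_too_few_entities_fatal(self):
        with pytest.raises(ValueError):
            hd.equal_count_bins(np.arange(5), 10)


class TestBinnedTrends:
    def test_identical_texts_give_equal_bins(self, lexicon):
        texts = ["happy war"] * 40
        d = np.linspace(1, 1000, 40)
        trend = hd.happiness_by_distance(texts, d, lexicon, k=4)
        assert trend.table["h_avg"].nunique() == 1

    def test_pooled_bin_equals_concatenation_oracle(self, lexicon, rng):
        words = list(lexicon.entries)
        texts = [
            " ".join(rng.choice(words, size=rng.integers(1, 8)).tolist())
            for _ in range(60)
        ]
        d = rng.uniform(1, 1e6, 60)
        trend = hd.happiness_by_distance(texts, d, lexicon, k=5)
        bins = hd.equal_count_bins(d, 5)
        for b in range(5):
            concatenated = " ".join(texts[i] for i in np.flatnonzero(bins == b))
            oracle = hd.score(hd.count_words([concatenated], lexicon), lexicon)
            got = trend.table["h_avg"].iloc[b]
            if oracle is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(oracle, abs=1e-12)

    def test_gyradius_single_bin_equals_corpus_score(self, lexicon, rng):
        words = list(lexicon.entries)
        user_texts = {
            f"u{i}": [" ".join(rng.choice(words, size=5).tolist())] for i in range(8)
        }
        user_rg = {f"u{i}": float(i + 1) for i in range(8)}
        trend = hd.happiness_by_gyradius(user_texts, user_rg, lexicon, k=1)
        all_texts = [t for ts in user_texts.values() for t in ts]
        oracle = hd.score(hd.count_words(all_texts, lexicon), lexicon)
        assert trend.table["h_avg"].iloc[0] == pytest.approx(oracle, abs=1e-12)


class TestFitLogLinear:
    def test_exact_recovery(self):
        d = np.array([1e2, 1e3, 1e4, 1e5, 1e6])
        h = 5.9 + 0.05 * np.log10(d)
        fit = hd.fit_log_linear(d, h)
        assert fit.params[1] == pytest.approx(0.05, abs=1e-12)
        assert fit.params[0] == pytest.approx(5.9, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        d = rng.uniform(10, 1e6, 20)
        h = rng.normal(6, 0.1, 20)
        fit = hd.fit_log_linear(d, h)
        x = np.log10(d)
        slope = np.cov(x, h, bias=True)[0, 1] / np.var(x)
        intercept = h.mean() - slope * x.mean()
        assert fit.params[1] == pytest.approx(slope, rel=1e-9)
        assert fit.params[0] == pytest.approx(intercept, rel=1e-9)

    def test_min_distance_excludes_bins(self):
        d = np.array([1e2, 1e3, 1e4, 1e5])
        h = np.array([9.0, 5.9, 6.0, 6.1])  # outlier below the cut
        fit = hd.fit_log_linear(d, h, min_distance=1e3)
        assert fit.nobs == 3
        assert fit.params[1] > 0

    def test_too_few_points_fatal(self):
        with pytest.raises(ValueError):
            hd.fit_log_linear([100.0], [6.0])


@given(
    counts=st.dictionaries(
        st.sampled_from(sorted(load_packaged_lexicon().entries)),
        st.integers(1, 50),
        min_size=1,
    ),
    c=st.integers(2, 7),
)
@settings(max_examples=60, deadline=None)
def test_score_scale_invariance_property(counts, c):
    lexicon = load_packaged_lexicon()
    base = hd.score(Counter(counts), lexicon)
    scaled = hd.score(Counter({w: c * f for w, f in counts.items()}), lexicon)
    if base is None:
        assert scaled is None
    else:
        assert scaled == pytest.approx(base, rel=1e-12)
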