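"""Locale extraction, rank probabilities, Zipf fit and diurnal cycles."""

import numpy as np
import pandas as pd
import pytest

from mobsent import locales
from mobsent.geo import haversine_m, unproject_local

from .conftest import make_corpus


def corpus_from_xy(xy, lat0=40.0, lon0=-74.0, uid="u", hours=None):
    lat, lon = unproject_local(xy[:, 0], xy[:, 1], lat0, lon0)
    rows = []
    for i in range(len(xy)):
        rows.append(
            {
                "user_id": uid,
                "lat": float(lat[i]),
                "lon": float(lon[i]),
                "text": "x",
                "time_utc": pd.Timestamp("2011-01-03 12:00:00", tz="UTC")
                + pd.Timedelta(hours=0 if hours is None else hours[i], minutes=i),
            }
        )
    return make_corpus(rows)


class TestExtractLocales:
    def test_ten_coincident_messages_one_locale(self):
        corpus = corpus_from_xy(np.zeros((10, 2)))
        locs = locales.extract_locales(corpus.frame)
        assert len(locs) == 1
        assert locs[0].count == 10
        assert locs[0].radius_m == pytest.approx(0.0, abs=1e-6)

    def test_nine_messages_no_locale(self):
        corpus = corpus_from_xy(np.zeros((9, 2)))
        assert locales.extract_locales(corpus.frame) == []

    def test_two_separated_clusters(self, rng):
        a = rng.normal(0, 5, (15, 2))
        b = rng.normal(0, 5, (15, 2)) + [1000.0, 0.0]
        corpus = corpus_from_xy(np.vstack([a, b]))
        locs = locales.extract_locales(corpus.frame)
        assert len(locs) == 2
        # membership oracle: every message belongs to the nearest center
        centers = np.array(
            [[loc.center_lat, loc.center_lon] for loc in locs]
        )
        for loc in locs:
            assert loc.count == 15
            assert loc.radius_m <= 100.0
        all_ids = sorted(
            int(mid[1:].split("-")[0] if "-" in mid else mid[1:])
            for loc in locs
            for mid in loc.member_ids
        )
        assert len(all_ids) == 30

    def test_center_is_member_mean_and_members_within_radius(self, rng):
        xy = rng.normal(0, 20, (40, 2))
        corpus = corpus_from_xy(xy)
        locs = locales.extract_locales(corpus.frame)
        assert len(locs) >= 1
        frame = corpus.frame.set_index("message_id")
        for loc in locs:
            mlat = frame.loc[loc.member_ids, "lat"].to_numpy()
            mlon = frame.loc[loc.member_ids, "lon"].to_numpy()
            d = haversine_m(loc.center_lat, loc.center_lon, mlat, mlon)
            assert d.max() <= loc.radius_m + 1e-6
            assert haversine_m(
                loc.center_lat, loc.center_lon, mlat.mean(), mlon.mean()
            ) < 1.0

    def test_deterministic(self, rng):
        xy = rng.normal(0, 200, (120, 2))
        corpus = corpus_from_xy(xy)
        a = locales.extract_locales(corpus.frame)
        b = locales.extract_locales(corpus.frame)
        assert len(a) == len(b)
        for la, lb in zip(a, b):
            assert la.center_lat == lb.center_lat
            assert np.array_equal(la.member_ids, lb.member_ids)

    def test_disjoint_membership(self, rng):
        xy = rng.normal(0, 150, (200, 2))
        corpus = corpus_from_xy(xy)
        locs = locales.extract_locales(corpus.frame)
        ids = [m for loc in locs for m in loc.member_ids]
        assert len(ids) == len(set(ids))


class TestProbabilities:
    def make_locale(self, count, t, lat=40.0, lon=-74.0):
        return locales.Locale(
            center_lat=lat,
            center_lon=lon,
            radius_m=10.0,
            member_ids=np.array([f"m{t}-{i}" for i in range(count)]),
            count=count,
            first_time=pd.Timestamp(f"2011-01-0{t} 00:00:00", tz="UTC"),
        )

    def test_simple_probability(self):
        prof = locales.locale_probabilities([self.make_locale(10, 1)], 20)
        assert prof.probabilities.tolist() == [0.5]

    def test_empty_profile(self):
        prof = locales.locale_probabilities([], 10)
        assert prof.probabilities.sum() == 0.0
        assert prof.mode is None

    def test_probabilities_may_not_sum_to_one(self):
        locs = [self.make_locale(30, 1), self.make_locale(20, 2), self.make_locale(10, 3)]
        prof = locales.locale_probabilities(locs, 100)
        assert prof.probabilities.tolist() == [0.3, 0.2, 0.1]
        assert prof.probabilities.sum() <= 1.0

    def test_rank_tie_broken_by_first_visit(self):
        newer = self.make_locale(30, 2, lat=41.0)
        older = self.make_locale(30, 1)
        prof = locales.locale_probabilities([newer, older], 100)
        assert prof.locales[0].first_time < prof.locales[1].first_time

    def test_zero_messages_fatal(self):
        with pytest.raises(ValueError):
            locales.locale_probabilities([], 0)


class TestModeLocation:
    def test_single_locale(self):
        p = TestProbabilities()
        prof = locales.locale_probabilities([p.make_locale(12, 1)], 20)
        assert locales.mode_location(prof) == (40.0, -74.0)

    def test_higher_count_wins(self):
        p = TestProbabilities()
        prof = locales.locale_probabilities(
            [p.make_locale(29, 1, lat=41.0), p.make_locale(30, 2)], 100
        )
        assert locales.mode_location(prof) == (40.0, -74.0)

    def test_no_locales_absent(self):
        prof = locales.locale_probabilities([], 5)
        assert locales.mode_location(prof) is None


class TestFitZipf:
    def test_exact_power_law_minus_1_3(self):
        r = np.arange(1, 21)
        df = pd.DataFrame({"rank": r, "probability": 0.5 * r ** -1.3})
        fit = locales.fit_zipf(df)
        assert fit.params[1] == pytest.approx(-1.3, abs=1e-12)

    def test_exact_power_law_minus_1(self):
        r = np.arange(1, 11)
        df = pd.DataFrame({"rank": r, "probability": 0.3 * r ** -1.0})
        fit = locales.fit_zipf(df)
        assert fit.params[1] == pytest.approx(-1.0, abs=1e-12)

    def test_too_few_points_fatal(self):
        df = pd.DataFrame({"rank": [1], "probability": [0.5]})
        with pytest.raises(ValueError):
            locales.fit_zipf(df)


class TestDiurnal:
    def test_mode_hours_counted_in_morning_bins(self, rng):
        # 20 messages in a tight cluster, all at local hour 9
        xy = rng.normal(0, 2, (20, 2))
        corpus = corpus_from_xy(xy)
        # force local hour 9: offset -300 min, so utc hour 14
        f = corpus.frame.copy()
        f["time_utc"] = pd.Timestamp("2011-01-03 14:00:00", tz="UTC") + pd.to_timedelta(
            np.arange(20), unit="D"
        )
        corpus = type(corpus)(f)
        profiles = {"u": locales.locale_probabilities(
            locales.extract_locales(corpus.frame), 20, "u"
        )}
        out = locales.diurnal_profiles(corpus, profiles)
        assert out["mode"].sum() == pytest.approx(1.0)
        # every message is mode-locale at local hour 9; mass is confined to
        # the seven hour-9 bins, split in proportion to day-of-week counts
        nine_am = out["week_hour"] % 24 == 9
        assert out.loc[nine_am, "mode"].sum() == pytest.approx(1.0)
        assert out.loc[~nine_am, "mode"].sum() == pytest.approx(0.0)

    def test_curves_sum_to_one(self, rng):
        xy = np.vstack([rng.normal(0, 2, (15, 2)), rng.normal(0, 2, (15, 2)) + [2000, 0]])
        hours = rng.integers(0, 24, 30)
        corpus = corpus_from_xy(xy, hours=hours)
        locs = locales.extract_locales(corpus.frame)
        profiles = {"u": locales.locale_probabilities(locs, 30, "u")}
        out = locales.diurnal_profiles(corpus, profiles)
        assert out["mode"].sum() == pytest.approx(1.0)
        assert out["other"].sum() == pytest.approx(1.0)
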