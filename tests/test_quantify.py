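import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from pvsquant.io_formats import PvsTrack
from pvsquant.quantify import (
    bland_altman,
    count_in_slice,
    dsc_points,
    icc,
    tortuosity,
    track_length,
)


class TestLengthTortuosity:
    def test_segment_and_polyline_lengths(self):
        assert track_length([[0, 0, 0], [3, 0, 0]]) == 3.0
        assert track_length([[0, 0, 0], [3, 0, 0], [3, 4, 0]]) == 7.0

    def test_quarter_circle_arc_length(self):
        # quarter circle of radius 10 mm discretized at ~0.1 mm steps
        n = int(round(5 * np.pi / 0.1))
        t = np.linspace(0, np.pi / 2, n)
        sk = np.stack([10 * np.cos(t), 10 * np.sin(t), np.zeros_like(t)], axis=1)
        assert abs(track_length(sk) - 5 * np.pi) / (5 * np.pi) < 0.005

    def test_tortuosity_examples(self):
        assert tortuosity([[0, 0, 0], [1, 0, 0], [5, 0, 0]]) == 1.0
        assert np.isclose(tortuosity([[0, 0, 0], [3, 0, 0], [3, 4, 0]]), 7.0 / 5.0)

    def test_helix_turn_tortuosity_closed_form(self):
        # one full helix turn: radius 2 mm, pitch 10 mm
        r, pitch = 2.0, 10.0
        t = np.linspace(0, 2 * np.pi, 4000)
        sk = np.stack([r * np.cos(t), r * np.sin(t), pitch * t / (2 * np.pi)], axis=1)
        expected = np.hypot(4 * np.pi, 10.0) / 10.0
        assert np.isclose(tortuosity(sk), expected, rtol=1e-4)

    def test_closed_loop_flagged(self):
        t = np.linspace(0, 2 * np.pi, 100)
        sk = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
        sk[-1] = sk[0]
        with pytest.raises(ValueError, match="coincident"):
            tortuosity(sk)


def _icc_oracle(x):
    """Independent two-way ANOVA variance-components route (explicit sums)."""
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    cons = (msr - mse) / (msr + (k - 1) * mse)
    absol = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    return absol, cons


class TestIcc:
    def test_identical_raters(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc(x) == (1.0, 1.0)

    def test_constant_offset_breaks_absolute_only(self):
        r1 = np.array([3.0, 7.0, 5.0, 9.0, 4.0])
        a, c = icc(np.column_stack([r1, r1 + 2.0]))
        assert np.isclose(c, 1.0)
        assert a < 1.0

    def test_matches_anova_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.normal(size=(10, 2)) * 3 + rng.normal(size=(1, 2))
            assert np.allclose(icc(x), _icc_oracle(x), atol=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(11)
        subj = rng.normal(0, 3, size=(12, 1))
        x = subj + rng.normal(size=(12, 2)) + np.array([[0.0, 0.7]])
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 2),
                "raters": np.tile([0, 1], 12),
                "ratings": x.ravel(),
            }
        )
        res = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
        a, c = icc(x)
        assert np.isclose(a, res.loc[res.Type == "ICC(A,1)", "ICC"].item(), atol=1e-8)
        assert np.isclose(c, res.loc[res.Type == "ICC(C,1)", "ICC"].item(), atol=1e-8)

    @settings(deadline=None, max_examples=25)
    @given(
        magnitude=st.floats(0.5, 5, allow_nan=False),
        negate=st.booleans(),
        seed=st.integers(0, 10_000),
    )
    def test_consistency_at_least_absolute_under_offsets(self, magnitude, negate, seed):
        # a systematic rater offset inflates the rater mean square, which only
        # the absolute-agreement ICC penalizes
        offset = -magnitude if negate else magnitude
        rng = np.random.default_rng(seed)
        r1 = rng.normal(size=8)
        x = np.column_stack([r1, r1 + offset + rng.normal(0, 0.05, 8)])
        a, c = icc(x)
        assert c >= a - 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((5, 2)))


def _dsc_bruteforce(a, b, radius):
    """Enumerate all one-to-one matchings; best achievable DSC."""
    if len(a) == 0 and len(b) == 0:
        return 1.0
    if len(a) == 0 or len(b) == 0:
        return 0.0
    d = cdist(a, b)
    best = 0
    idx_b = range(len(b))
    for k in range(min(len(a), len(b)), 0, -1):
        for subset_a in itertools.combinations(range(len(a)), k):
            for perm_b in itertools.permutations(idx_b, k):
                if all(d[i, j] <= radius for i, j in zip(subset_a, perm_b)):
                    best = max(best, k)
        if best:
            break
    return 2 * best / (len(a) + len(b))


class TestDsc:
    def test_identical_sets(self):
        pts = np.array([[0, 0, 0], [5, 5, 5]], float)
        dsc, matches = dsc_points(pts, pts, 0.5)
        assert dsc == 1.0 and len(matches) == 2

    def test_partial_match_example(self):
        a = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0]], float)
        b = np.array([[0.3, 0, 0], [10.2, 0, 0], [40, 0, 0]], float)
        dsc, matches = dsc_points(a, b, 1.0)
        assert np.isclose(dsc, 2 * 2 / 6)
        assert len(matches) == 2

    def test_empty_conventions(self):
        assert dsc_points(np.empty((0, 3)), np.empty((0, 3)), 1.0)[0] == 1.0
        assert dsc_points(np.array([[0.0, 0, 0]]), np.empty((0, 3)), 1.0)[0] == 0.0

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            dsc_points(np.zeros((1, 3)), np.zeros((1, 3)), -1.0)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.uniform(0, 4, size=(rng.integers(0, 6), 3))
            b = rng.uniform(0, 4, size=(rng.integers(0, 6), 3))
            dsc, _ = dsc_points(a, b, 1.5)
            assert np.isclose(dsc, _dsc_bruteforce(a, b, 1.5))

    def test_symmetric_and_monotone_in_radius(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 5, size=(5, 3))
        b = rng.uniform(0, 5, size=(6, 3))
        prev = -1.0
        for r in (0.1, 0.5, 1.0, 2.0, 5.0, 20.0):
            dab, _ = dsc_points(a, b, r)
            dba, _ = dsc_points(b, a, r)
            assert np.isclose(dab, dba)
            assert dab >= prev
            prev = dab


class TestBlandAltman:
    def test_identical_pairs(self):
        x = np.column_stack([np.arange(4.0), np.arange(4.0)])
        res = bland_altman(x)
        assert res["mean_difference"] == 0.0
        assert res["limits_of_agreement"] == (0.0, 0.0)

    def test_symmetric_differences(self):
        res = bland_altman(np.array([[1.0, 2.0], [2.0, 1.0]]))
        lim = 1.96 * np.sqrt(2.0)
        assert res["mean_difference"] == 0.0
        assert np.allclose(res["limits_of_agreement"], (-lim, lim))

    def test_random_pairs_match_definition(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 2))
        res = bland_altman(x)
        d = x[:, 0] - x[:, 1]
        assert np.isclose(res["mean_difference"], d.mean())
        assert np.allclose(
            res["limits_of_agreement"],
            (d.mean() - 1.96 * d.std(ddof=1), d.mean() + 1.96 * d.std(ddof=1)),
        )


class TestCountInSlice:
    def _track(self, pts):
        pts = np.asarray(pts, float)
        return PvsTrack(skeleton=pts, radii=np.full(len(pts), 0.3))

    def test_track_outside_not_counted(self):
        t = self._track([[0, 0, 0], [0, 0, 1]])
        assert count_in_slice([t], [0, 0, 10], [0, 0, 1], 2.0) == 0

    def test_double_crossing_counted_once(self):
        t = self._track([[0, 0, 2.3], [0, 0, 5], [0, 1, 2.4]])
        assert count_in_slice([t], [0, 0, 2.5], [0, 0, 1], 1.0) == 1

    def test_matches_bruteforce_on_random_tracks(self):
        rng = np.random.default_rng(6)
        tracks = [
            self._track(rng.uniform(0, 10, size=(5, 3))) for _ in range(30)
        ]
        point, normal, thick = np.array([0, 0, 5.0]), np.array([0, 0, 1.0]), 1.4
        expected = sum(
            1
            for t in tracks
            if (np.abs((t.skeleton - point) @ normal) <= thick / 2).any()
        )
        assert count_in_slice(tracks, point, normal, thick) == expected
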