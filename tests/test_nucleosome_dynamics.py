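import math
from decimal import Decimal, getcontext

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from nucleolink.nucleosome_dynamics import (
    FOOTPRINT,
    NucleosomeParams,
    call_nucleosomes,
    classify_dynamic,
    compare_maps,
    fuzziness_test,
    map_statistics,
    match_nucleosomes,
    occupancy_test,
    reads_by_chrom,
    summarize_alterations,
)


def _calls(summits, chrom="c"):
    """Minimal call frame with constant occupancy/fuzziness."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": [s - 73 for s in summits],
            "end": [s + 74 for s in summits],
            "summit": summits,
            "n_reads": 30,
            "fuzziness": 15.0,
        }
    )


class TestCallNucleosomes:
    def test_single_pileup(self):
        reads = {"c": np.full(200, 500)}
        calls = call_nucleosomes(reads, {"c": 1000})
        assert len(calls) == 1
        assert calls.loc[0, "summit"] == 500
        assert calls.loc[0, "n_reads"] == 200
        assert calls.loc[0, "fuzziness"] == pytest.approx(0.0)
        assert calls.loc[0, "end"] - calls.loc[0, "start"] == FOOTPRINT

    def test_two_clusters(self):
        rng = np.random.default_rng(0)
        reads = {
            "c": np.concatenate(
                [
                    np.rint(rng.normal(500, 15, 100)),
                    np.rint(rng.normal(800, 15, 100)),
                ]
            ).astype(np.int64)
        }
        calls = call_nucleosomes(reads, {"c": 2000})
        assert len(calls) == 2
        assert abs(calls.loc[0, "summit"] - 500) <= 5
        assert abs(calls.loc[1, "summit"] - 800) <= 5

    def test_uniform_reads_fuzziness(self):
        # uniform over a 100 bp window: sd = sqrt((100^2 - 1) / 12) ~ 28.87
        reads = {"c": np.repeat(np.arange(1000, 1100), 10)}
        calls = call_nucleosomes(reads, {"c": 3000})
        assert len(calls) == 1
        assert calls.loc[0, "fuzziness"] == pytest.approx(
            math.sqrt((100**2 - 1) / 12), abs=0.1
        )

    def test_min_reads_filter(self):
        calls = call_nucleosomes({"c": np.array([500, 500])}, {"c": 1000})
        assert len(calls) == 0

    def test_exclusion_spans(self):
        reads = {"c": np.full(50, 500)}
        calls = call_nucleosomes(
            reads, {"c": 1000}, exclude={"c": [(400, 600)]}
        )
        assert len(calls) == 0

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            call_nucleosomes({"c": np.array([1])}, {"c": 0})

    def test_dataframe_and_dict_inputs_agree(self):
        pos = np.array([500] * 10 + [900] * 10)
        df = pd.DataFrame({"chrom": "c", "pos": pos})
        a = call_nucleosomes(df, {"c": 2000})
        b = call_nucleosomes({"c": pos}, {"c": 2000})
        pd.testing.assert_frame_equal(a, b)


class TestMatchNucleosomes:
    def test_identical_maps(self):
        calls = _calls([500, 700, 900])
        pairs = match_nucleosomes(calls, calls.copy())
        assert (pairs["shift_bp"] == 0).all()
        assert (pairs["wt_idx"] >= 0).all() and (pairs["mut_idx"] >= 0).all()

    def test_single_shift(self):
        pairs = match_nucleosomes(_calls([500]), _calls([570]))
        assert len(pairs) == 1
        assert pairs.loc[0, "shift_bp"] == 70

    def test_beyond_window_unpaired(self):
        pairs = match_nucleosomes(_calls([500]), _calls([650]))
        assert len(pairs) == 2
        assert set(pairs["mut_idx"]) == {-1, 0}
        assert set(pairs["wt_idx"]) == {-1, 0}
        assert pairs["shift_bp"].isna().all()

    def test_rescue_of_non_mutual_pair(self):
        # the shifted call at 588 is nearer the unshifted neighbour at 535
        # than its own origin at 500; the leftover pass must still pair it
        wt = _calls([500, 665])
        mut = _calls([588, 668])
        pairs = match_nucleosomes(wt, mut)
        by_wt = pairs.set_index("wt_summit")
        assert by_wt.loc[500, "mut_summit"] == 588
        assert by_wt.loc[500, "shift_bp"] == 88
        assert by_wt.loc[665, "mut_summit"] == 668

    @given(
        st.lists(st.integers(0, 50), min_size=0, max_size=12, unique=True),
        st.lists(st.integers(0, 50), min_size=0, max_size=12, unique=True),
    )
    def test_pairing_is_injective_and_windowed(self, wt_raw, mut_raw):
        wt_s = sorted(200 + 40 * x for x in wt_raw)
        mut_s = sorted(200 + 40 * x for x in mut_raw)
        if not wt_s and not mut_s:
            return
        pairs = match_nucleosomes(_calls(wt_s) if wt_s else _calls([]), _calls(mut_s) if mut_s else _calls([]))
        paired = pairs[(pairs["wt_idx"] >= 0) & (pairs["mut_idx"] >= 0)]
        assert paired["wt_idx"].is_unique and paired["mut_idx"].is_unique
        assert (paired["shift_bp"] <= 100).all()
        # every call appears exactly once
        assert sorted(pairs.loc[pairs["wt_idx"] >= 0, "wt_summit"]) == wt_s
        assert sorted(pairs.loc[pairs["mut_idx"] >= 0, "mut_summit"]) == mut_s


def _poisson_tails(lam, kmax):
    """Exact Poisson cdf values P(X <= k) for k = 0..kmax, 60-digit decimals."""
    getcontext().prec = 60
    lam_d = Decimal(lam)
    term = (-lam_d).exp()
    cdf = [term]
    for k in range(1, kmax + 1):
        term = term * lam_d / k
        cdf.append(cdf[-1] + term)
    return cdf


class TestOccupancyTest:
    def test_gain_example(self):
        log10p, direction = occupancy_test(4, 10)
        assert direction == "up"
        assert 10**log10p == pytest.approx(float(1 - _poisson_tails(4, 9)[9]), rel=1e-9)
        assert log10p == pytest.approx(math.log10(8.1e-3), abs=0.01)

    def test_equal_counts(self):
        assert occupancy_test(7, 7) == (0.0, "none")

    def test_total_loss(self):
        log10p, direction = occupancy_test(100, 0)
        assert direction == "down"
        assert log10p == pytest.approx(-100 / math.log(10), abs=1e-6)

    def test_zero_wt_floored(self):
        log10p, direction = occupancy_test(0, 12)
        assert direction == "up"
        assert np.isfinite(log10p) and log10p < -8

    def test_depth_factor_scales_rate(self):
        # at depth 2, a doubled mutant count is exactly the expectation
        assert occupancy_test(10, 20, 2.0)[1] == "none"
        with pytest.raises(ValueError):
            occupancy_test(10, 20, 0.0)

    def test_weak_direction_suppressed(self):
        # observed just below a non-integer rate: lower tail > 0.5, no call
        assert occupancy_test(10.4, 10)[1] == "none"

    def test_exact_poisson_enumeration_oracle(self):
        """Tails match a 60-digit decimal enumeration to 1e-12 for rates <= 50."""
        for lam in range(1, 51):
            cdf = _poisson_tails(lam, 160)
            for obs in range(0, 161):
                log10p, direction = occupancy_test(lam, obs)
                p = 10**log10p
                if obs > lam:
                    exact = float(1 - cdf[obs - 1])
                elif obs < lam:
                    exact = float(cdf[obs])
                else:
                    continue
                assert abs(p - exact) < 1e-12, (lam, obs, p, exact)


class TestFuzzinessTest:
    def test_equal_variances_large_n(self):
        assert fuzziness_test(15.0, 500, 15.0, 500) == pytest.approx(0.0, abs=0.01)

    def test_strong_difference(self):
        assert fuzziness_test(2.0, 100, 1.0, 100) < -10

    def test_symmetric_in_arguments(self):
        a = fuzziness_test(2.0, 80, 1.0, 60)
        b = fuzziness_test(1.0, 60, 2.0, 80)
        assert a == pytest.approx(b, rel=1e-12)

    def test_tiny_samples(self):
        assert fuzziness_test(1.0, 2, 1.0, 2) == pytest.approx(0.0)
        assert math.isnan(fuzziness_test(1.0, 1, 2.0, 50))

    def test_matches_f_distribution(self):
        got = fuzziness_test(3.0, 40, 2.0, 30)
        expect = math.log10(2 * stats.f.sf((3 / 2) ** 2, 39, 29))
        assert got == pytest.approx(expect, rel=1e-9)


class TestClassifyDynamic:
    def _row(self, **kw):
        base = {
            "chrom": "c",
            "wt_summit": 500,
            "mut_summit": 570,
            "shift_bp": 70.0,
            "wt_reads": 30.0,
            "mut_reads": 30.0,
            "occ_log10p": 0.0,
            "occ_direction": "none",
            "fuzz_log10p": 0.0,
            "point_log10p": 0.0,
        }
        base.update(kw)
        return pd.DataFrame([base])

    def test_shift_in_range_with_point_support(self):
        out = classify_dynamic(self._row(shift_bp=70.0, point_log10p=-20.0))
        assert bool(out.loc[0, "position_shift"])
        assert bool(out.loc[0, "altered"])

    def test_shift_below_range_not_flagged(self):
        out = classify_dynamic(self._row(shift_bp=40.0, point_log10p=-20.0))
        assert not bool(out.loc[0, "position_shift"])

    def test_shift_without_point_support_not_flagged(self):
        out = classify_dynamic(self._row(shift_bp=70.0, point_log10p=-3.0))
        assert not bool(out.loc[0, "position_shift"])

    def test_occupancy_increase(self):
        out = classify_dynamic(self._row(occ_log10p=-16.0, occ_direction="up"))
        assert bool(out.loc[0, "occupancy_change"])
        assert out.loc[0, "occupancy_subtype"] == "increase"

    def test_occupancy_decrease_subtype(self):
        out = classify_dynamic(self._row(occ_log10p=-16.0, occ_direction="down"))
        assert out.loc[0, "occupancy_subtype"] == "decrease"

    def test_fuzziness_nan_not_flagged(self):
        out = classify_dynamic(self._row(fuzz_log10p=float("nan")))
        assert not bool(out.loc[0, "fuzziness_change"])

    def test_cutoff_is_configurable(self):
        row = self._row(occ_log10p=-5.0, occ_direction="up")
        assert not bool(classify_dynamic(row, -15.0).loc[0, "occupancy_change"])
        assert bool(classify_dynamic(row, -3.0).loc[0, "occupancy_change"])


class TestSummarizeAlterations:
    def _classified(self, n_altered, n_total_rows):
        df = pd.DataFrame(
            {
                "position_shift": False,
                "fuzziness_change": False,
                "occupancy_change": [i < n_altered for i in range(n_total_rows)],
                "occupancy_subtype": [
                    "increase" if i < n_altered else "" for i in range(n_total_rows)
                ],
                "altered": [i < n_altered for i in range(n_total_rows)],
            }
        )
        return df

    def test_percentages(self):
        out = summarize_alterations(self._classified(4431, 5000), 66_278)
        assert out["altered"] == 4431
        assert out["percent_altered"] == pytest.approx(100 * 4431 / 66_278)

    def test_no_flags(self):
        out = summarize_alterations(self._classified(0, 100), 100)
        assert out["altered"] == 0 and out["percent_altered"] == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            summarize_alterations(self._classified(0, 100), 0)
        with pytest.raises(ValueError):
            summarize_alterations(self._classified(0, 100), 50)


class TestCompareMaps:
    def test_identical_maps_mostly_unflagged(self):
        rng = np.random.default_rng(3)
        pos = np.rint(
            rng.normal(np.repeat(np.arange(300, 3000, 165), 30), 15)
        ).astype(np.int64)
        reads = {"c": pos}
        comp = compare_maps(reads, {"c": pos.copy()}, {"c": 3500})
        assert (comp["shift_bp"] == 0).all()
        assert comp.attrs["depth_factor"] == pytest.approx(1.0)
        out = classify_dynamic(comp)
        assert not out["altered"].any()

    def test_depth_normalization(self):
        rng = np.random.default_rng(4)
        base = np.rint(
            rng.normal(np.repeat(np.arange(300, 3000, 165), 30), 15)
        ).astype(np.int64)
        doubled = np.concatenate([base, base + 1])
        comp = compare_maps({"c": base}, {"c": doubled}, {"c": 3500})
        assert comp.attrs["depth_factor"] == pytest.approx(2.0)
        out = classify_dynamic(comp, -10.0)
        # uniform doubling is absorbed by the depth factor
        assert not out["occupancy_change"].any()


class TestMapStatistics:
    def test_even_spacing(self):
        stats_out = map_statistics(_calls(list(range(500, 2000, 165))))
        assert (stats_out["distances"] == 165).all()
        assert stats_out["distance_summary"]["median"] == 165

    def test_single_call(self):
        stats_out = map_statistics(_calls([500]))
        assert len(stats_out["distances"]) == 0
        assert stats_out["distance_summary"] == {"n": 0}
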