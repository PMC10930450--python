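import itertools

import numpy as np
import pandas as pd
import pytest

import pervimap as pm
from pervimap.cohort import (
    SCHEMES,
    assign_group,
    compare_groups,
    delay_bias_check,
    holm_adjust,
    mann_whitney_u,
    nihss_scheme,
    passes_scheme,
    tici_merged_scheme,
    tici_scheme,
)
from pervimap.errors import InputError
from pervimap.io import PatientRecord, TICI_TOKENS


def exact_p_by_enumeration(x, y):
    """Full enumeration of rank labelings: the independent exact-p oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = pd.Series(pooled).rank().to_numpy()  # midranks
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for combo in itertools.combinations(range(n), nx):
        us.append(ranks[list(combo)].sum() - nx * (nx + 1) / 2)
    us = np.asarray(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


def record(pid="p", nihss=10, tici="III", passes=2, delay=70.0):
    return PatientRecord(pid, nihss, tici, passes, delay)


class TestMannWhitney:
    def test_worked_exact_case(self):
        """Fully separated samples of 3: U = 0, exact two-sided p = 2/20."""
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_tied_samples_give_p_one(self):
        res = mann_whitney_u([5, 7, 9], [5, 7, 9])
        assert res.p_value == pytest.approx(1.0)

    def test_u_statistics_sum_to_product_of_sizes(self, rng):
        for _ in range(20):
            x = rng.choice(np.arange(30), size=rng.integers(3, 10), replace=True)
            y = rng.choice(np.arange(30), size=rng.integers(3, 10), replace=True)
            ux = mann_whitney_u(x, y, mode="approx").u_statistic
            uy = mann_whitney_u(y, x, mode="approx").u_statistic
            assert ux + uy == pytest.approx(len(x) * len(y))

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            nx = int(rng.integers(2, 6))
            ny = int(rng.integers(2, 11 - nx))
            pooled = rng.permutation(rng.normal(0, 1, nx + ny))
            x, y = pooled[:nx], pooled[nx:]
            res = mann_whitney_u(x, y, mode="exact")
            assert res.method == "exact"
            assert res.p_value == pytest.approx(exact_p_by_enumeration(x, y), abs=1e-12)

    def test_exact_and_approx_agree_for_moderate_samples(self, rng):
        """Spec'd sanity margin between the exact and normal-approx p."""
        for _ in range(200):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.3, 1, 8)
            pe = mann_whitney_u(x, y, mode="exact").p_value
            pa = mann_whitney_u(x, y, mode="approx").p_value
            assert abs(pe - pa) < 0.02

    def test_exact_mode_with_ties_warns_and_falls_back(self):
        with pytest.warns(UserWarning, match="tie"):
            res = mann_whitney_u([1, 2, 2], [2, 3, 4], mode="exact")
        assert res.method == "normal_tie_corrected"

    def test_empty_sample_is_input_error(self):
        with pytest.raises(InputError):
            mann_whitney_u([], [1.0])

    def test_auto_switches_to_approx_for_large_samples(self, rng):
        res = mann_whitney_u(rng.normal(0, 1, 20), rng.normal(0, 1, 20))
        assert res.method == "normal_tie_corrected"


class TestGrouping:
    @pytest.mark.parametrize(
        "scheme_f,rec,label",
        [
            (nihss_scheme, record(nihss=22), "21-42"),
            (nihss_scheme, record(nihss=21), "21-42"),
            (nihss_scheme, record(nihss=4), "0-4"),
            (nihss_scheme, record(nihss=16), "16-20"),
            (passes_scheme, record(passes=3), "<4"),
            (passes_scheme, record(passes=4), ">=4"),
            (tici_scheme, record(tici="IIb"), "IIa,b"),
            (tici_scheme, record(tici="IIc"), "IIc"),
            (tici_merged_scheme, record(tici="IIa"), "IIa,b,c"),
            (tici_merged_scheme, record(tici="III"), "III"),
        ],
    )
    def test_examples(self, scheme_f, rec, label):
        assert assign_group(rec, scheme_f()) == label

    def test_every_valid_record_maps_to_exactly_one_bin(self):
        """Totality sweep: NIHSS 0-42 x passes 1-10 x all TICI tokens."""
        for name, factory in SCHEMES.items():
            scheme = factory()
            for nihss in range(43):
                for passes in range(1, 11):
                    for tici in TICI_TOKENS:
                        label = assign_group(record(nihss=nihss, tici=tici, passes=passes), scheme)
                        assert label in scheme.labels


class TestCompareGroups:
    def _frame(self, values_a, values_b):
        n_a, n_b = len(values_a), len(values_b)
        return pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n_a + n_b)],
                "mean_P2": list(values_a) + list(values_b),
                "group": ["<4"] * n_a + [">=4"] * n_b,
            }
        )

    def test_constant_shift_is_detected(self, rng):
        """+8 HU shift at noise SD 4, n = 20 per group: decisive effect."""
        base = rng.normal(10, 4, 20)
        df = self._frame(base + 8.0, rng.normal(10, 4, 20))
        comps = compare_groups(df, "mean_P2", passes_scheme())
        assert len(comps) == 1 and comps[0].significant
        assert 0 <= comps[0].u_statistic <= 400

    def test_tiny_group_skipped_with_warning(self, rng, caplog):
        df = self._frame([5.0], rng.normal(5, 1, 10))
        with caplog.at_level("WARNING"):
            comps = compare_groups(df, "mean_P2", passes_scheme())
        assert comps == []
        assert "skipped" in caplog.text and "<4" in caplog.text

    def test_group_assignment_from_records(self, rng):
        recs = [record(f"p{i}", passes=(2 if i < 8 else 6)) for i in range(16)]
        df = pd.DataFrame(
            {"patient_id": [r.patient_id for r in recs], "mean_P2": rng.normal(5, 1, 16)}
        )
        comps = compare_groups(df, "mean_P2", passes_scheme(), records=recs)
        assert comps[0].n_a == 8 and comps[0].n_b == 8

    def test_nihss_contrasts_are_top_bin_versus_each(self, rng):
        recs = [record(f"p{i}", nihss=n) for i, n in enumerate([2] * 3 + [10] * 3 + [18] * 3 + [30] * 3)]
        df = pd.DataFrame(
            {"patient_id": [r.patient_id for r in recs], "mean_P2": rng.normal(5, 1, 12)}
        )
        comps = compare_groups(df, "mean_P2", nihss_scheme(), records=recs)
        assert [(c.group_a, c.group_b) for c in comps] == [
            ("21-42", "16-20"),
            ("21-42", "5-15"),
            ("21-42", "0-4"),
        ]

    def test_holm_column_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(0, 1, 7).tolist()
        ours = holm_adjust(p)
        theirs = sm.multipletests(p, method="holm")[1]
        assert np.allclose(ours, theirs)


class TestDelayBias:
    def test_identical_delays_give_p_one(self):
        recs = [record(f"p{i}", passes=(2 if i < 5 else 6), delay=70.0) for i in range(10)]
        comps = delay_bias_check(recs, passes_scheme())
        assert comps[0].p_value == pytest.approx(1.0)

    def test_planted_delay_shift_is_detected(self, rng):
        delays_a = rng.normal(130, 28, 20)
        delays_b = rng.normal(70, 28, 20)
        recs = [
            record(f"a{i}", passes=2, delay=max(10.0, d)) for i, d in enumerate(delays_a)
        ] + [record(f"b{i}", passes=6, delay=max(10.0, d)) for i, d in enumerate(delays_b)]
        comps = delay_bias_check(recs, passes_scheme())
        assert comps[0].significant
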