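"""Experiment-table statistics and the exact rank test."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import bonemap as bm
from bonemap.errors import ValidationError
from bonemap.study import STATUS_CODING


def test_fixture_loads_fifteen_records(records):
    assert len(records) == 15
    assert sum(r.group == "unguided" for r in records) == 5
    assert sum(r.group == "guided" for r in records) == 10
    assert [r.experiment for r in records] == list(range(1, 16))


def test_known_record_contents(records):
    r2 = records[1]
    assert (r2.specimen, r2.side, r2.age, r2.sex) == ("K02", "R", 98, "F")
    assert (r2.dm, r2.ss) == ("U", "U")
    assert all(r.fn == "I" for r in records)  # facial nerve intact throughout


def test_corrupted_fixture_detected(monkeypatch):
    monkeypatch.setattr(bm.study, "_TABLE1_SHA256", "0" * 64)
    with pytest.raises(ValidationError, match="checksum"):
        bm.study.load_table1()


def test_exposure_rates_are_exact_rationals(records):
    dm_u = bm.exposure_rates(records, "unguided", "dm")
    assert dm_u == {"I": 0, "S": 0, "U": 1}
    dm_g = bm.exposure_rates(records, "guided", "dm")
    assert dm_g["U"] == Fraction(1, 5) and dm_g["I"] == Fraction(2, 5)
    ss_u = bm.exposure_rates(records, "unguided", "ss")
    assert (ss_u["I"], ss_u["S"], ss_u["U"]) == (Fraction(2, 5), Fraction(1, 5),
                                                 Fraction(2, 5))
    assert bm.exposure_rates(records, "guided", "ss")["I"] == 1
    for group in ("unguided", "guided"):
        for st in ("dm", "ss", "fn"):
            assert sum(bm.exposure_rates(records, group, st).values()) == 1


def test_unknown_structure_and_empty_group_rejected(records):
    with pytest.raises(ValidationError):
        bm.exposure_rates(records, "unguided", "tm")
    with pytest.raises(ValidationError):
        bm.exposure_rates([], "unguided", "dm")


def test_unguided_demographics(records):
    s = bm.specimen_demographics(records, "unguided")
    assert s.n_records == s.n_specimens == 5
    assert round(s.age_mean, 1) == 78.6
    assert round(s.age_sd, 1) == 17.9
    assert s.side_proportions["R"] == 1
    assert s.sex_proportions["M"] == Fraction(1, 5)


def test_guided_demographics_aggregate_unique_specimens(records):
    """The guided arm reuses heads across ears: 10 surgeries on 7 specimens.
    Only per-specimen aggregation reproduces the published 83.3 +/- 4.5."""
    s = bm.specimen_demographics(records, "guided")
    assert s.n_records == 10 and s.n_specimens == 7
    assert round(s.age_mean, 1) == 83.3
    assert round(s.age_sd, 1) == 4.5
    assert s.sex_proportions["M"] == Fraction(3, 7)
    assert s.side_proportions == {"L": Fraction(2, 5), "R": Fraction(3, 5)}


def test_single_record_group_reports_sd_unavailable(records):
    s = bm.specimen_demographics([records[0]], "unguided")
    assert s.age_sd is None


def test_identical_groups_give_p_one():
    assert bm.exact_rank_test([1, 1, 1], [1, 1], "two-sided") == 1.0


def test_hand_enumerated_two_vs_two_case():
    """a={2,2} vs b={0,0}: only 1 of C(4,2)=6 assignments is as extreme."""
    assert bm.exact_rank_test([2, 2], [0, 0], "greater") == pytest.approx(1 / 6)


def test_rank_test_group_swap_symmetry():
    a, b = [3, 1, 4, 1], [5, 9, 2, 6, 5]
    assert bm.exact_rank_test(a, b, "greater") == \
        pytest.approx(bm.exact_rank_test(b, a, "less"))
    assert bm.exact_rank_test(a, b, "two-sided") == \
        pytest.approx(bm.exact_rank_test(b, a, "two-sided"))


def _pair_count_enumeration_p(a, b):
    """Independent oracle: enumerate assignments and compare the tie-adjusted
    Mann-Whitney U statistic (pair counts), not rank sums."""
    pooled = list(a) + list(b)
    n, k = len(pooled), len(a)

    def u_stat(xs, ys):
        return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in xs for y in ys)

    u_obs = u_stat(a, b)
    hits = total = 0
    for comb in combinations(range(n), k):
        sel = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(n) if i not in sel]
        hits += u_stat(xs, ys) >= u_obs - 1e-9
        total += 1
    return hits / total


@pytest.mark.parametrize("seed", range(6))
def test_rank_test_matches_pair_count_enumeration(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 4, size=rng.integers(2, 5)).tolist()
    b = rng.integers(0, 4, size=rng.integers(2, 6)).tolist()
    assert bm.exact_rank_test(a, b, "greater") == \
        pytest.approx(_pair_count_enumeration_p(a, b))


def test_rank_test_matches_scipy_exact_without_ties():
    a, b = [1.0, 4.0, 7.0, 10.0], [2.0, 3.0, 5.0, 6.0, 8.0]
    ours = bm.exact_rank_test(a, b, "greater")
    ref = mannwhitneyu(a, b, alternative="greater", method="exact").pvalue
    assert ours == pytest.approx(ref)


def test_dm_exposure_test_reproduces_published_significance(records):
    """With I<S<U coding the one-sided exact p is 21/3003 < 0.01; the
    two-sided (doubled-tail) p exceeds 0.01 — both are reported since the
    published test does not state its sidedness."""
    res = bm.dm_exposure_test(records)
    assert res["p_one_sided"] == pytest.approx(21 / 3003)
    assert res["p_one_sided"] < 0.01
    assert res["p_two_sided"] == pytest.approx(42 / 3003)
    assert res["p_two_sided"] > 0.01


def test_rank_test_input_validation():
    with pytest.raises(ValidationError):
        bm.exact_rank_test([], [1.0])
    with pytest.raises(ValidationError):
        bm.exact_rank_test([np.nan], [1.0])
    with pytest.raises(ValidationError):
        bm.exact_rank_test([1.0], [2.0], "sideways")


def test_full_report_percentages(records):
    rep = bm.table1_report(records)
    assert rep["unguided"]["structures"]["dm"]["U"] == 100.0
    assert rep["guided"]["structures"]["dm"]["U"] == 20.0
    assert rep["unguided"]["structures"]["ss"]["I"] == 40.0
    assert rep["guided"]["structures"]["ss"]["I"] == 100.0
    assert rep["guided"]["structures"]["fn"]["I"] == 100.0
    assert rep["unguided"]["age_mean"] == 78.6
    assert rep["guided"]["age_sd"] == 4.5
    # 3/7 male at one decimal; the published row shows a truncated 42.8
    assert rep["guided"]["sex_pct"]["M"] == 42.9
    assert STATUS_CODING == {"I": 0, "S": 1, "U": 2}
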