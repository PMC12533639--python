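"""Cohort statistics: t/ANOVA closed forms, stratification, correlation, report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from eccpipe.caller import CircleCall, CircleCatalog
from eccpipe.cohort import (
    compare_groups,
    correlate,
    per_sample_summary,
    render_report,
    stratify_high_low,
)


def catalog(sample_id, lengths):
    calls = [
        CircleCall("chr1", 1000 * i, 1000 * i + length, 2, 0, 10.0, 100.0)
        for i, length in enumerate(lengths, start=1)
    ]
    return CircleCatalog(sample_id, calls)


def make_table(values, groups=None):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(values))],
            "group": groups or ["all"] * len(values),
            "n_eccDNA": values,
        }
    )


# --- closed-form oracles (independent of scipy) ----------------------------


def pooled_t(a, b):
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def anova_f(groups):
    all_v = np.concatenate(groups)
    grand = all_v.mean()
    k, n = len(groups), len(all_v)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = stats.f.sf(f, k - 1, n - k)
    return f, p


# --- per-sample summary -----------------------------------------------------


def test_per_sample_summary_mean_length():
    t = per_sample_summary([catalog("a", [1000, 2000]), catalog("b", [])])
    assert list(t["sample_id"]) == ["a", "b"]
    assert t.loc[0, "mean_length"] == pytest.approx(1500.0)
    assert t.loc[1, "n_eccDNA"] == 0 and np.isnan(t.loc[1, "mean_length"])


def test_per_sample_summary_duplicate_ids():
    with pytest.raises(ValueError):
        per_sample_summary([catalog("a", [500]), catalog("a", [600])])


def test_per_sample_summary_row_count():
    cats = [catalog(f"s{i}", [500] * (i + 1)) for i in range(10)]
    assert len(per_sample_summary(cats)) == 10


# --- group comparisons ------------------------------------------------------


def test_t_identical_groups():
    t = make_table([5, 5, 5, 5, 5, 5], ["a"] * 3 + ["b"] * 3)
    cmp = compare_groups(t, "n_eccDNA")
    assert cmp.statistic == pytest.approx(0.0)
    assert cmp.p_value == pytest.approx(1.0)


def test_t_textbook_example():
    """{1..5} vs {2..6}: pooled t = -1.0 at 8 df (hand-computed)."""
    t = make_table([1, 2, 3, 4, 5, 2, 3, 4, 5, 6], ["ref"] * 5 + ["trt"] * 5)
    cmp = compare_groups(t, "n_eccDNA", reference="ref")
    assert cmp.test == "students_t"
    assert cmp.statistic == pytest.approx(1.0)  # trt - ref = +1
    exp_t, exp_p = pooled_t(np.array([2, 3, 4, 5, 6]), np.array([1, 2, 3, 4, 5]))
    assert cmp.statistic == pytest.approx(exp_t, abs=1e-12)
    assert cmp.p_value == pytest.approx(exp_p, abs=1e-12)


def test_fold_change_exceeds_ten():
    """Group mean circle burdens 1353 vs 14835: a >10-fold difference."""
    wt = [1353.0] * 3
    mut = [14_835.0] * 3
    t = make_table(wt + mut, ["wt"] * 3 + ["mut"] * 3)
    cmp = compare_groups(t, "n_eccDNA", reference="wt")
    assert cmp.fold_change is not None and cmp.fold_change > 10


def test_t_and_anova_match_closed_forms_on_random_tables():
    rng = np.random.default_rng(12)
    for _ in range(100):
        na, nb = rng.integers(2, 12, size=2)
        a, b = rng.normal(10, 3, na), rng.normal(12, 3, nb)
        t = make_table(list(a) + list(b), ["a"] * na + ["b"] * nb)
        cmp = compare_groups(t, "n_eccDNA", reference="a")
        exp_t, exp_p = pooled_t(b, a)
        assert abs(cmp.statistic - exp_t) < 1e-10
        assert abs(cmp.p_value - exp_p) < 1e-10
        sizes = rng.integers(2, 10, size=3)
        gs = [rng.normal(5, 2, n) for n in sizes]
        labels = sum([[f"g{i}"] * len(g) for i, g in enumerate(gs)], [])
        t3 = make_table(np.concatenate(gs), labels)
        cmp3 = compare_groups(t3, "n_eccDNA")
        exp_f, exp_fp = anova_f(gs)
        assert cmp3.test == "one_way_anova"
        assert abs(cmp3.statistic - exp_f) < 1e-10
        assert abs(cmp3.p_value - exp_fp) < 1e-10


def test_two_group_anova_f_equals_t_squared():
    rng = np.random.default_rng(13)
    for _ in range(50):
        na, nb = rng.integers(2, 10, size=2)
        a, b = rng.normal(0, 1, na), rng.normal(1, 1, nb)
        t = make_table(list(a) + list(b), ["a"] * na + ["b"] * nb)
        cmp_t = compare_groups(t, "n_eccDNA")
        f, _ = anova_f([a, b])
        assert f == pytest.approx(cmp_t.statistic**2, rel=1e-9)


def test_single_sample_group_rejected():
    t = make_table([1, 2, 3], ["a", "a", "b"])
    with pytest.raises(ValueError):
        compare_groups(t, "n_eccDNA")


# --- stratification ---------------------------------------------------------


def test_stratify_even_split():
    s = stratify_high_low(make_table([1, 2, 3, 4]), "n_eccDNA")
    assert [s.labels[f"s{i}"] for i in range(4)] == [
        "eccDNA_low", "eccDNA_low", "eccDNA_high", "eccDNA_high",
    ]


def test_stratify_ties_alternate():
    s = stratify_high_low(make_table([1, 2, 2, 4]), "n_eccDNA")
    tie_labels = [s.labels["s1"], s.labels["s2"]]
    assert sorted(tie_labels) == ["eccDNA_high", "eccDNA_low"]
    assert s.n_high == 2 and s.n_low == 2


def test_stratify_degenerate_rejected():
    with pytest.raises(ValueError):
        stratify_high_low(make_table([7, 7, 7]), "n_eccDNA")


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=50))
def test_stratify_balanced_within_one(values):
    if max(values) == min(values):
        return
    s = stratify_high_low(make_table(values), "n_eccDNA")
    assert abs(s.n_high - s.n_low) <= 1
    assert s.n_high + s.n_low == len(values)


def test_stratify_group_sizes_invariant_to_row_order():
    """Shuffling rows never changes the high/low group sizes (labels of
    tied samples may move, per the declared tie rule)."""
    rng = np.random.default_rng(14)
    for _ in range(20):
        values = list(rng.integers(0, 20, size=15))
        if max(values) == min(values):
            continue
        base = stratify_high_low(make_table(values), "n_eccDNA")
        perm = list(rng.permutation(len(values)))
        shuffled = make_table([values[i] for i in perm])
        s2 = stratify_high_low(shuffled, "n_eccDNA")
        assert (s2.n_high, s2.n_low) == (base.n_high, base.n_low)
        assert s2.median == base.median


# --- correlation ------------------------------------------------------------


def test_correlate_perfect_line():
    t = make_table([1, 2, 3, 4, 5])
    t["expr"] = 3.0 * t["n_eccDNA"] + 7.0
    r, r2, p = correlate(t, "n_eccDNA", "expr")
    assert r == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0)
    assert p < 1e-6


def test_correlate_matches_closed_form():
    rng = np.random.default_rng(15)
    t = make_table(list(rng.normal(10, 2, 40)))
    t["expr"] = rng.normal(5, 1, 40) + 0.3 * t["n_eccDNA"]
    r, r2, p = correlate(t, "n_eccDNA", "expr")
    x, y = t["n_eccDNA"].to_numpy(), t["expr"].to_numpy()
    xc, yc = x - x.mean(), y - y.mean()
    exp_r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    tt = exp_r * np.sqrt(38 / (1 - exp_r**2))
    exp_p = 2 * stats.t.sf(abs(tt), 38)
    assert r == pytest.approx(exp_r, abs=1e-12)
    assert p == pytest.approx(exp_p, abs=1e-10)
    assert r2 == pytest.approx(r * r)


def test_correlate_zero_variance_rejected():
    t = make_table([3, 3, 3, 3])
    t["expr"] = [1.0, 2.0, 3.0, 4.0]
    with pytest.raises(ValueError):
        correlate(t, "n_eccDNA", "expr")


# --- report -----------------------------------------------------------------


def test_report_round_trip_and_determinism(tmp_path):
    t = make_table([10, 20, 30, 40, 100, 120], ["wt"] * 3 + ["mut"] * 3)
    t["mean_length"] = [900.0, 1000.0, 1100.0, 1200.0, 800.0, 850.0]
    cmp = compare_groups(t, "n_eccDNA", reference="wt")
    strat = stratify_high_low(t, "n_eccDNA")
    corr = {"n_eccDNA~marker1": correlate(t.assign(m=t["n_eccDNA"] * 2.0), "n_eccDNA", "m")}
    outs = []
    for run in range(2):
        j = str(tmp_path / f"r{run}.json")
        m = str(tmp_path / f"r{run}.md")
        render_report(j, m, summaries=t, comparisons=[cmp],
                      stratification=strat, correlations=corr)
        outs.append(open(j, "rb").read() + open(m, "rb").read())
    assert outs[0] == outs[1]
    import json

    report = json.loads(open(str(tmp_path / "r0.json")).read())
    assert set(report) == {"samples", "comparisons", "stratification", "correlations"}


def test_report_requires_a_section(tmp_path):
    with pytest.raises(ValueError):
        render_report(str(tmp_path / "x.json"), str(tmp_path / "x.md"))


def test_report_omits_empty_sections(tmp_path):
    t = make_table([1, 2, 3])
    j, m = str(tmp_path / "o.json"), str(tmp_path / "o.md")
    report = render_report(j, m, summaries=t, comparisons=[])
    assert "comparisons" not in report and "samples" in report
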