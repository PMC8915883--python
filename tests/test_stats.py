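"""t-tests, Holm–Šídák correction and two-way ANOVA against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import special
from statsmodels.stats.multitest import multipletests

from conftest import repertoire_from_aa
from _oracles import brute_two_way_anova_ss

from tcrprof.simulate import EnrichmentSpec, SimulationConfig, simulate_cohort
from tcrprof.io import filter_functional
from tcrprof.stats import (
    DesignError,
    InsufficientReplicationError,
    StratificationError,
    compare_composition,
    comparison_to_frame,
    holm_sidak_adjust,
    multiple_t_tests,
    two_way_anova,
)


# ---------------------------------------------------------------------------
# holm_sidak_adjust
# ---------------------------------------------------------------------------

def test_holm_sidak_single_p_is_identity():
    assert holm_sidak_adjust([0.2]) == pytest.approx([0.2])


def test_holm_sidak_two_p_hand_example():
    adj = holm_sidak_adjust([0.01, 0.04])
    assert adj[0] == pytest.approx(1 - 0.99**2)  # 0.0199
    assert adj[1] == pytest.approx(0.04)


def test_holm_sidak_all_ones():
    assert holm_sidak_adjust([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])


def test_holm_sidak_rejects_out_of_range():
    with pytest.raises(ValueError):
        holm_sidak_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        holm_sidak_adjust([-0.1])


def test_holm_sidak_permutation_equivariance_and_bounds():
    rng = np.random.default_rng(3)
    for _ in range(20):
        p = rng.random(int(rng.integers(1, 30)))
        adj = holm_sidak_adjust(p)
        perm = rng.permutation(len(p))
        assert holm_sidak_adjust(p[perm]) == pytest.approx(adj[perm])
        # raw <= holm-sidak <= bonferroni, elementwise
        bonf = np.minimum(1, p * len(p))
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= bonf + 1e-12)
        # monotone in the raw ordering
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


def test_holm_sidak_matches_statsmodels():
    rng = np.random.default_rng(10)
    for _ in range(20):
        p = rng.random(int(rng.integers(1, 50)))
        expected = multipletests(p, method="holm-sidak")[1]
        assert holm_sidak_adjust(p) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# multiple_t_tests
# ---------------------------------------------------------------------------

def _pooled_t_p(case, control):
    """Closed-form pooled two-sample t-test via the t CDF (stdtr)."""
    case, control = np.asarray(case, float), np.asarray(control, float)
    n1, n2 = len(case), len(control)
    sp2 = ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * control.var(ddof=1)) / (n1 + n2 - 2)
    t = (case.mean() - control.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    return 2 * special.stdtr(df, -abs(t))


def test_single_feature_matches_closed_form_t():
    case, control = [10, 12, 11], [5, 6, 7]
    (comp,) = multiple_t_tests({"K": case}, {"K": control})
    assert comp.p_raw == pytest.approx(_pooled_t_p(case, control))
    assert comp.p_adj == pytest.approx(comp.p_raw)  # family of one
    assert comp.difference == pytest.approx(5.0)


def test_identical_arms_yield_null_results():
    values = {"K": [10.0, 12.0], "W": [3.0, 4.0]}
    comps = multiple_t_tests(values, {k: list(v) for k, v in values.items()})
    for comp in comps:
        assert comp.difference == 0
        assert comp.p_adj == pytest.approx(1.0)


def test_swapping_arms_negates_differences_preserves_p():
    rng = np.random.default_rng(21)
    case = {f: rng.normal(10, 2, 4).tolist() for f in "AKW"}
    control = {f: rng.normal(8, 2, 5).tolist() for f in "AKW"}
    fwd = multiple_t_tests(case, control)
    rev = multiple_t_tests(control, case)
    for f, r in zip(fwd, rev):
        assert r.difference == pytest.approx(-f.difference)
        assert r.p_raw == pytest.approx(f.p_raw)
        assert r.p_adj == pytest.approx(f.p_adj)


def test_zero_variance_conventions(caplog):
    with caplog.at_level("INFO"):
        comps = multiple_t_tests(
            {"A": [5.0, 5.0], "B": [5.0, 5.0]},
            {"A": [5.0, 5.0], "B": [7.0, 7.0]},
        )
    by_feature = {c.feature: c for c in comps}
    assert by_feature["A"].p_raw == 1.0  # equal means, no variance
    assert by_feature["B"].p_raw == 0.0  # different means, no variance


def test_insufficient_replication_names_feature():
    with pytest.raises(InsufficientReplicationError, match="K"):
        multiple_t_tests({"K": [1.0]}, {"K": [1.0, 2.0]})


def test_welch_flag_changes_p_under_unequal_variance():
    case = {"K": [10.0, 30.0, 20.0, 25.0]}
    control = {"K": [5.0, 5.1, 5.2, 4.9]}
    pooled = multiple_t_tests(case, control)[0].p_raw
    welch = multiple_t_tests(case, control, equal_var=False)[0].p_raw
    assert pooled != pytest.approx(welch)


# ---------------------------------------------------------------------------
# two_way_anova
# ---------------------------------------------------------------------------

def _frame(cells, factors=("condition", "chain")):
    rows = []
    for (a, b), values in cells.items():
        for v in values:
            rows.append({factors[0]: a, factors[1]: b, "value": v})
    return pd.DataFrame(rows)


def test_anova_zero_ss_when_all_cells_equal():
    cells = {(a, b): [5.0, 5.0] for a in "xy" for b in "uv"}
    res = two_way_anova(_frame(cells))
    assert res.sum_sq("condition") == pytest.approx(0, abs=1e-12)
    assert res.sum_sq("chain") == pytest.approx(0, abs=1e-12)
    assert res.sum_sq("condition:chain") == pytest.approx(0, abs=1e-12)


@pytest.mark.parametrize("n_b", [2, 3])
def test_anova_matches_literal_ss_oracle(n_b):
    rng = np.random.default_rng(17)
    cells = {
        (a, b): rng.normal(10 + 2 * (a == "case"), 1.5, 3).tolist()
        for a in ("case", "control")
        for b in [f"lvl{i}" for i in range(n_b)]
    }
    res = two_way_anova(_frame(cells, ("cond", "grp")), factors=("cond", "grp"))
    oracle = brute_two_way_anova_ss(cells)
    assert res.sum_sq("cond") == pytest.approx(oracle["A"], rel=1e-9)
    assert res.sum_sq("grp") == pytest.approx(oracle["B"], rel=1e-9)
    assert res.sum_sq("cond:grp") == pytest.approx(oracle["AB"], rel=1e-9)
    assert res.sum_sq("Residual") == pytest.approx(oracle["residual"], rel=1e-9)
    # decomposition adds up to the total
    total = sum(res.sum_sq(t) for t in ("cond", "grp", "cond:grp", "Residual"))
    assert total == pytest.approx(oracle["total"], rel=1e-9)
    assert res.table.loc["cond", "df"] == oracle["df"]["A"]


def test_anova_empty_cell_is_design_error():
    cells = {("x", "u"): [1.0, 2.0], ("x", "v"): [1.0, 2.0], ("y", "u"): [1.0, 2.0]}
    with pytest.raises(DesignError):
        two_way_anova(_frame(cells))


def test_anova_single_replicate_falls_back_to_additive():
    cells = {(a, b): [float(hash((a, b)) % 7)] for a in "xy" for b in "uv"}
    with pytest.warns(UserWarning, match="additive"):
        res = two_way_anova(_frame(cells))
    assert "condition:chain" not in res.table.index


def test_anova_null_p_values_are_calibrated():
    """Under a pure-noise 2x2 design the factor p-values are uniform."""
    rng = np.random.default_rng(99)
    hits = 0
    n_sim = 400
    for _ in range(n_sim):
        cells = {(a, b): rng.normal(0, 1, 3).tolist() for a in "xy" for b in "uv"}
        res = two_way_anova(_frame(cells))
        if res.p_value("condition") < 0.05:
            hits += 1
    # binomial 99% band around 0.05 at 400 runs
    assert 0.02 <= hits / n_sim <= 0.085


# ---------------------------------------------------------------------------
# compare_composition
# ---------------------------------------------------------------------------

def _identical_cohort():
    reps = []
    for i, condition in enumerate(["case", "case", "control", "control"]):
        rep = repertoire_from_aa(
            ["CASSF", "CAKKF", "CWSSF"],
            donor_id=f"d{i}", subset="CD4", chain="TRB", condition=condition,
        )
        reps.append(rep)
    return reps


def test_identical_repertoires_give_zero_differences():
    comps = compare_composition(_identical_cohort(), min_clonotypes=1)
    assert all(c.difference == 0 for c in comps)
    assert all(c.p_adj == 1.0 for c in comps)


def test_mixed_strata_raise():
    cohort = _identical_cohort()
    cohort[0] = cohort[0].with_metadata(subset="CD8")
    with pytest.raises(StratificationError):
        compare_composition(cohort, min_clonotypes=1)


def test_min_clonotype_gate_excludes_small_samples(caplog):
    cohort = _identical_cohort()
    with caplog.at_level("WARNING"):
        with pytest.raises(InsufficientReplicationError):
            compare_composition(cohort, min_clonotypes=10)
    assert any("excluding" in r.message for r in caplog.records)


def test_containment_enrichment_is_top_ranked():
    config = SimulationConfig(
        n_donors_case=4, n_donors_control=4, clonotypes_per_repertoire=1500,
        enrichments=(EnrichmentSpec("containment", "K", 15.0),), seed=123,
    )
    cohort = [filter_functional(r) for r in simulate_cohort(config)]
    comps = compare_composition(cohort, "aa_occurrence")
    assert comps[0].feature == "K"
    assert comps[0].difference > 0
    assert comps[0].p_adj < 0.05


def test_comparison_report_frame_has_stars():
    comps = compare_composition(_identical_cohort(), min_clonotypes=1)
    frame = comparison_to_frame(comps)
    assert set(frame.columns) >= {
        "feature", "case_mean", "control_mean", "difference",
        "percent_change", "p_raw", "p_adj", "significance",
    }
    assert (frame["significance"] == "").all()
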