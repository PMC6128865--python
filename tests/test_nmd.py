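import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import chi2_contingency

from spliceoscope.events import compute_psi
from spliceoscope.nmd import (
    chx_response_test,
    classify_nmd_sensitivity,
    cmh_test,
    discover_chx_specific_events,
    nmd_crosstab,
)
from spliceoscope.simulate import (
    PlantedEffect,
    SimulationConfig,
    simulate_chx_experiment,
    simulate_cohort,
    simulate_reference,
)


def test_cmh_single_stratum_equals_score_chisquare():
    """On one stratum the CMH statistic is the score (Pearson) chi-square
    scaled by (n-1)/n — the hypergeometric-variance form."""
    tab = np.array([[30, 70], [10, 90]])
    stat, p, dropped = cmh_test([tab])
    pearson = chi2_contingency(tab, correction=False).statistic
    n = tab.sum()
    assert stat == pytest.approx(pearson * (n - 1) / n, rel=1e-12)
    assert dropped == 0


def test_cmh_matches_statsmodels_stratified_table():
    rng = np.random.default_rng(3)
    strata = [rng.integers(5, 60, size=(2, 2)) for _ in range(4)]
    stat, p, _ = cmh_test(strata)
    ref = sm.stats.StratifiedTable([s for s in strata]).test_null_odds(
        correction=False)
    assert stat == pytest.approx(ref.statistic, rel=1e-10)
    assert p == pytest.approx(ref.pvalue, rel=1e-10)


def test_cmh_stratum_order_invariant():
    rng = np.random.default_rng(4)
    strata = [rng.integers(1, 40, size=(2, 2)) for _ in range(5)]
    s1 = cmh_test(strata)[0]
    s2 = cmh_test(strata[::-1])[0]
    assert s1 == pytest.approx(s2)


def test_cmh_pooling_strata_differs_from_stratified():
    """Pooling heterogeneous strata into one table changes the statistic
    (Simpson-style aggregation); verified against the brute-force pooled
    computation."""
    strata = [np.array([[40, 10], [20, 30]]), np.array([[5, 45], [2, 48]])]
    stratified = cmh_test(strata)[0]
    pooled_tab = strata[0] + strata[1]
    pooled = cmh_test([pooled_tab])[0]
    n = pooled_tab.sum()
    assert pooled == pytest.approx(
        chi2_contingency(pooled_tab, correction=False).statistic * (n - 1) / n)
    assert pooled != pytest.approx(stratified)


def test_cmh_zero_margin_strata_dropped():
    stat, p, dropped = cmh_test([np.array([[0, 0], [5, 5]]),
                                 np.array([[10, 10], [10, 10]])])
    assert dropped == 1
    assert p == pytest.approx(1.0)  # remaining stratum is balanced


@pytest.fixture(scope="module")
def chx_study():
    cfg = SimulationConfig(
        seed=31,
        effects=[
            PlantedEffect("alt_3ss", "SF3B1", 20, 40.0, 0.0, "truncating_ptc",
                          nmd_d=0.25),
            PlantedEffect("alt_3ss", "SF3B1", 10, 40.0, 0.0, "non_truncating"),
        ],
        n_null_events=60, n_chx_specific=8,
        chx_pairs={"SF3B1:K700E": 4}, chx_depth=500.0)
    ref = simulate_reference(cfg)
    table, sheet, truth = simulate_chx_experiment(ref)
    psi = compute_psi([s.event for s in ref.sites], table)
    return ref, cfg, table, sheet, truth, psi


def test_treated_equals_untreated_gives_null_results(chx_study):
    """An event with identical counts in both arms gives CMH statistic 0,
    p=1, and an undefined paired-t (zero differences)."""
    ref, cfg, table, sheet, truth, psi = chx_study
    eid = psi.event_ids[0]
    pairs = sheet.chx_pairs()
    pm = psi.psi.copy()
    inc, exc = psi.inclusion.copy(), psi.exclusion.copy()
    for u, t in pairs:
        pm.loc[eid, t] = pm.loc[eid, u]
        inc.loc[eid, t] = inc.loc[eid, u]
        exc.loc[eid, t] = exc.loc[eid, u]
    psi2 = dataclasses.replace(psi, psi=pm, inclusion=inc, exclusion=exc)
    res = chx_response_test(psi2, sheet).set_index("event_id")
    assert res.loc[eid, "cmh_stat"] == pytest.approx(0.0)
    assert res.loc[eid, "p_cmh"] == pytest.approx(1.0)
    assert np.isnan(res.loc[eid, "p_paired_t"])


def test_nmd_sensitive_recovery(chx_study):
    """d=0.25 truncating events are flagged nmd_sensitive at q<0.01;
    d=1 events are not."""
    ref, cfg, table, sheet, truth, psi = chx_study
    res = chx_response_test(psi, sheet, method="cmh").set_index("event_id")
    tr = truth.events.set_index("event_id")
    sensitive = tr[(tr.consequence == "truncating") & (tr.nmd_d == 0.25)].index
    insensitive = tr[tr.nmd_d == 1.0].index
    assert res.loc[sensitive, "nmd_sensitive"].mean() >= 0.9
    assert res.loc[insensitive, "nmd_sensitive"].mean() <= 0.01
    # fold change direction: rescued events increase after CHX
    assert (res.loc[sensitive, "psi_fold_change_chx"] > 1.5).all()


def test_paired_t_agrees_qualitatively(chx_study):
    ref, cfg, table, sheet, truth, psi = chx_study
    res = chx_response_test(psi, sheet, method="paired_t").set_index("event_id")
    tr = truth.events.set_index("event_id")
    sensitive = tr[(tr.consequence == "truncating") & (tr.nmd_d == 0.25)].index
    insensitive = tr[tr.nmd_d == 1.0].index
    assert (res.loc[sensitive, "p_paired_t"] < 0.05).mean() >= 0.8
    assert (res.loc[insensitive, "nmd_sensitive"]).mean() <= 0.05


def test_sensitivity_concentrates_in_truncating_events(chx_study):
    """Every nmd_sensitive call is a truncating event (by construction of
    the simulator truth), and non-truncating fold changes stay near 1."""
    ref, cfg, table, sheet, truth, psi = chx_study
    res = chx_response_test(psi, sheet)
    cons = truth.events.rename(columns={"consequence": "consequence"})[
        ["event_id", "consequence"]]
    merged = classify_nmd_sensitivity(res, cons)
    called = merged[merged["nmd_sensitive"]]
    assert (called["consequence"] == "truncating").all()
    non_trunc = merged[merged["consequence"] == "non_truncating"]
    assert 0.9 <= non_trunc["psi_fold_change_chx"].median() <= 1.1
    xt = nmd_crosstab(merged)
    assert xt.loc["truncating", True] == len(called)


def test_chx_specific_discovery(chx_study):
    """All planted d=0 events (and only they) are recovered as
    CHX-specific against the primary cohort."""
    ref, cfg, table, sheet, truth, psi = chx_study
    primary_table, _, _, _ = simulate_cohort(ref)
    primary_psi = compute_psi([s.event for s in ref.sites], primary_table)
    found = discover_chx_specific_events(primary_psi, psi, sheet)
    d0 = set(truth.events.loc[truth.events.nmd_d == 0, "event_id"])
    assert found == d0 and len(d0) == 8


def test_event_defined_in_primary_excluded(chx_study):
    """An event with nonzero PSI in one primary sample is not CHX-specific."""
    ref, cfg, table, sheet, truth, psi = chx_study
    primary_table, _, _, _ = simulate_cohort(ref)
    primary_psi = compute_psi([s.event for s in ref.sites], primary_table)
    d0 = sorted(truth.events.loc[truth.events.nmd_d == 0, "event_id"])
    eid = d0[0]
    primary_psi.psi.loc[eid, primary_psi.sample_ids[0]] = 12.0
    found = discover_chx_specific_events(primary_psi, psi, sheet)
    assert eid not in found


def test_no_pairs_raises(chx_study, small_study):
    ref, cfg, table, sheet, truth, psi = chx_study
    _, _, primary_sheet, _ = small_study
    with pytest.raises(ValueError, match="pairs"):
        chx_response_test(psi, primary_sheet)
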