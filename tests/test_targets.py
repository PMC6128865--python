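import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spliceoscope.events import compute_psi
from spliceoscope.simulate import (
    PlantedEffect,
    SimulationConfig,
    simulate_clones,
    simulate_reference,
)
from spliceoscope.targets import (
    TargetFilterConfig,
    expression_psi_association,
    functional_target_filter,
    mutual_exclusivity_test,
    recapitulation_test,
    select_specific_events,
)
from tests.oracles import fisher_two_sided_bruteforce


# ---------------------------------------------------------------------------
# Fisher mutual exclusivity
# ---------------------------------------------------------------------------


def test_fisher_printed_table():
    """13/66 Q157-mutated vs 0/32 S34-mutated patients with EZH2 lesions:
    two-sided p = 0.008 at printed precision."""
    odds, p = mutual_exclusivity_test([[13, 53], [0, 32]])
    assert round(p, 3) == 0.008
    assert np.isfinite(odds) and odds > 1


def test_fisher_exhaustive_example():
    """[[5,0],[0,5]] -> p = 2/252 by exhaustive hypergeometric enumeration."""
    _, p = mutual_exclusivity_test([[5, 0], [0, 5]])
    assert p == pytest.approx(2 / 252)
    _, p1 = mutual_exclusivity_test([[1, 1], [1, 1]])
    assert p1 == pytest.approx(1.0)


def test_fisher_zero_margin_convention():
    odds, p = mutual_exclusivity_test([[0, 0], [3, 5]])
    assert p == 1.0 and np.isnan(odds)


@given(st.tuples(*[st.integers(min_value=0, max_value=12)] * 4))
def test_fisher_matches_bruteforce_enumeration(cells):
    """Two-sided Fisher p equals brute-force enumeration over margin-fixed
    tables for every small 2x2 table."""
    a, b, c, d = cells
    tab = [[a, b], [c, d]]
    if min(a + b, c + d, a + c, b + d) == 0:
        return
    _, p = mutual_exclusivity_test(tab)
    assert p == pytest.approx(fisher_two_sided_bruteforce(tab), rel=1e-9)


def test_fisher_rejects_bad_tables():
    with pytest.raises(ValueError):
        mutual_exclusivity_test([[1, -2], [3, 4]])


# ---------------------------------------------------------------------------
# Functional-target cascade
# ---------------------------------------------------------------------------


def _diff_frame(rows):
    return pd.DataFrame(rows, columns=["event_id", "q", "mean_psi_ctrl"])


def _psi_for(means, samples):
    from spliceoscope.events import PsiMatrix

    df = pd.DataFrame(means, columns=samples)
    df.index = [f"e{i}" for i in range(len(df))]
    return PsiMatrix(psi=df, inclusion=df * 0, exclusion=df * 0)


def _sheet(samples, genotype="SF3B1:K700E"):
    from spliceoscope.core_io import SampleSheet

    return SampleSheet(pd.DataFrame({
        "sample_id": samples,
        "cell_fraction": ["BMMNC"] * len(samples),
        "genotype": [genotype] * len(samples),
        "chx_status": ["untreated"] * len(samples),
        "pair_id": [""] * len(samples),
        "clone_id": [""] * len(samples),
    }))


def test_target_filter_threshold_rules():
    """mutant 12% / control 5% passes; 8% fails the PSI floor; 15% vs 9%
    fails the 2-fold rule."""
    samples = ["m1", "m2"]
    psi = _psi_for([[12.0, 12.0], [8.0, 8.0], [15.0, 15.0]], samples)
    sheet = _sheet(samples)
    diff = _diff_frame([("e0", 0.001, 5.0), ("e1", 0.001, 1.0),
                        ("e2", 0.001, 9.0)])
    res = functional_target_filter(diff, psi, sheet, "SF3B1").set_index("event_id")
    assert bool(res.loc["e0", "passed"])
    assert not res.loc["e1", "passed"] and not res.loc["e1", "psi_floor_ok"]
    assert not res.loc["e2", "passed"] and not res.loc["e2", "fold_ok"]
    assert (res["recapitulation_provenance"] == "clones_unavailable").all()


def test_target_filter_chx_rescue():
    """An event below the floor in primary samples but above it after CHX
    passes via the rescue clause (ABCB7-style)."""
    samples = ["m1", "m2"]
    psi = _psi_for([[3.0, 4.0]], samples)
    diff = _diff_frame([("e0", 0.001, 0.2)])
    chx_samples = ["c_u", "c_t"]
    chx_psi = _psi_for([[5.0, 30.0]], chx_samples)
    from spliceoscope.core_io import SampleSheet

    chx_sheet = SampleSheet(pd.DataFrame({
        "sample_id": chx_samples,
        "cell_fraction": ["BMMNC"] * 2,
        "genotype": ["SF3B1:K700E"] * 2,
        "chx_status": ["untreated", "treated"],
        "pair_id": ["P1", "P1"],
        "clone_id": ["", ""],
    }))
    res = functional_target_filter(diff, psi, _sheet(samples), "SF3B1",
                                   psi_chx=chx_psi, sheet_chx=chx_sheet)
    assert bool(res.loc[0, "passed"]) and bool(res.loc[0, "psi_floor_via_chx"])
    strict = TargetFilterConfig(allow_chx_rescue=False)
    res2 = functional_target_filter(diff, psi, _sheet(samples), "SF3B1",
                                    psi_chx=chx_psi, sheet_chx=chx_sheet,
                                    config=strict)
    assert not res2.loc[0, "passed"]


def test_target_filter_monotone_in_thresholds():
    """Relaxing any threshold never removes a previously passing event."""
    rng = np.random.default_rng(8)
    samples = [f"m{i}" for i in range(4)]
    psi = _psi_for(rng.uniform(0, 40, size=(30, 4)), samples)
    diff = _diff_frame([(f"e{i}", rng.uniform(0, 0.05), rng.uniform(0, 15))
                        for i in range(30)])
    sheet = _sheet(samples)
    base_cfg = TargetFilterConfig()
    base = functional_target_filter(diff, psi, sheet, "SF3B1",
                                    config=base_cfg)
    relaxed_cfgs = [
        TargetFilterConfig(min_mean_psi=5.0),
        TargetFilterConfig(min_fold=1.5),
        TargetFilterConfig(q_primary=0.05),
    ]
    passed_base = set(base.loc[base["passed"], "event_id"])
    for cfg in relaxed_cfgs:
        r = functional_target_filter(diff, psi, sheet, "SF3B1", config=cfg)
        assert passed_base <= set(r.loc[r["passed"], "event_id"])


# ---------------------------------------------------------------------------
# Recapitulation in isogenic clones
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def clone_study():
    cfg = SimulationConfig(
        seed=51,
        effects=[PlantedEffect("alt_3ss", "SF3B1", 25, 10.0, 30.0)],
        n_null_events=25)
    ref = simulate_reference(cfg)
    table, sheet = simulate_clones(ref)
    psi = compute_psi([s.event for s in ref.sites], table)
    return ref, psi, sheet


def test_recapitulation_recovers_planted_clone_effects(clone_study):
    """Planted +30% clone shifts are called consistent (3v3, low
    within-clone noise); null events stay below the nominal 5% rate."""
    ref, psi, sheet = clone_study
    truth = ref.truth_frame().set_index("event_id")
    directions = pd.DataFrame({
        "event_id": truth.index,
        "direction": np.where(truth["delta_psi"] > 0, "up_in_mutant",
                              "down_in_mutant")})
    res = recapitulation_test(psi, sheet, directions).set_index("event_id")
    planted = truth[truth["delta_psi"] > 0].index
    nulls = truth[truth["delta_psi"] == 0].index
    assert res.loc[planted, "consistent"].mean() >= 0.95
    assert res.loc[nulls, "consistent"].mean() <= 0.08


def test_recapitulation_requires_matching_direction(clone_study):
    """Significant clone shifts in the opposite direction are inconsistent."""
    ref, psi, sheet = clone_study
    truth = ref.truth_frame().set_index("event_id")
    flipped = pd.DataFrame({
        "event_id": truth.index,
        "direction": np.where(truth["delta_psi"] > 0, "down_in_mutant",
                              "up_in_mutant")})
    res = recapitulation_test(psi, sheet, flipped).set_index("event_id")
    planted = truth[truth["delta_psi"] > 0].index
    assert not res.loc[planted, "consistent"].any()


# ---------------------------------------------------------------------------
# Expression–PSI association
# ---------------------------------------------------------------------------


def _assoc_inputs(rng, slope, n_events=26, n_samples=16, snr=2.0):
    from spliceoscope.events import PsiMatrix, SpliceEvent

    samples = [f"s{i}" for i in range(n_samples)]
    genes = [f"G{i}" for i in range(n_events)]
    expr = pd.DataFrame(rng.normal(8, 1.5, size=(n_events, n_samples)),
                        index=genes, columns=samples)
    noise_sd = abs(slope) * 1.5 / snr if slope else 1.0
    psi_rows = []
    events = {}
    for i, g in enumerate(genes):
        eid = f"e{i}"
        psi_rows.append(20 + slope * expr.loc[g].to_numpy()
                        + rng.normal(0, noise_sd, n_samples))
        events[eid] = SpliceEvent(eid, "alt_3ss", "chr1", "+", g, f"{g}.t",
                                  ("i",), ("x",), offset=-21,
                                  intron=(1, 100), alt_intron=(1, 79))
    psi_df = pd.DataFrame(psi_rows, index=list(events), columns=samples)
    pm = PsiMatrix(psi=psi_df, inclusion=psi_df * 0, exclusion=psi_df * 0,
                   events=events)
    return expr, pm, list(events), samples


def test_association_null_slope_covered():
    """With PSI independent of expression the pooled Wald p is non-extreme
    and per-event slope CIs cover 0 at about the nominal rate."""
    hits = 0
    ps = []
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        expr, pm, eids, samples = _assoc_inputs(rng, slope=0.0)
        per_event, pooled_p = expression_psi_association(expr, pm, eids, samples)
        ps.append(pooled_p)
        hits += (per_event["p"] < 0.05).sum()
    assert 0.01 <= np.mean(ps)  # no systematic association
    assert hits / (10 * 26) == pytest.approx(0.05, abs=0.04)


def test_association_detects_planted_slope():
    """PSI = 0.5*log2(expr) + noise gives a positive pooled slope with
    p < 0.01 at n=16 per event and SNR >= 2."""
    rng = np.random.default_rng(77)
    expr, pm, eids, samples = _assoc_inputs(rng, slope=0.5)
    per_event, pooled_p = expression_psi_association(expr, pm, eids, samples)
    assert pooled_p < 0.01
    assert per_event["slope"].median() > 0.2


def test_association_constant_expression_skipped():
    rng = np.random.default_rng(3)
    expr, pm, eids, samples = _assoc_inputs(rng, slope=0.0)
    expr.loc["G0"] = 5.0
    per_event, _ = expression_psi_association(expr, pm, eids, samples)
    assert bool(per_event.set_index("event_id").loc["e0", "skipped"])


def test_select_specific_events():
    diff = pd.DataFrame({
        "event_id": ["a", "b", "c"],
        "mean_psi_mut": [30.0, 30.0, 8.0],
        "mean_psi_ctrl": [1.0, 9.0, 0.1],
    })
    cons = pd.DataFrame({"event_id": ["a", "b", "c"],
                         "consequence": ["non_truncating"] * 3})
    nmd = pd.DataFrame({"event_id": ["a", "b", "c"],
                        "nmd_sensitive": [False, False, False]})
    picked = select_specific_events(diff, cons, nmd)
    assert picked == ["a"]  # b fails specificity fold, c fails the floor
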