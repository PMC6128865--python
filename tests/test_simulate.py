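import dataclasses

import numpy as np
import pandas as pd
import pytest

from spliceoscope.core_io import write_gtf
from spliceoscope.events import compute_psi
from spliceoscope.simulate import (
    ConfigError,
    PlantedEffect,
    SimulationConfig,
    count_motif,
    simulate_chx_experiment,
    simulate_cohort,
    simulate_reference,
)


def test_reference_is_deterministic(tmp_path):
    """Two runs at the same seed emit byte-identical FASTA and GTF."""
    cfg = SimulationConfig(seed=1, n_genes=10, n_null_events=6, effects=[])
    refs = [simulate_reference(cfg) for _ in range(2)]
    assert refs[0].genome == refs[1].genome
    paths = []
    for i, ref in enumerate(refs):
        p = tmp_path / f"g{i}.gtf"
        write_gtf(ref.models, p)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_cohort_is_deterministic(small_reference):
    t1, c1, _, _ = simulate_cohort(small_reference)
    t2, c2, _, _ = simulate_cohort(small_reference)
    pd.testing.assert_frame_equal(t1.junctions, t2.junctions)
    pd.testing.assert_frame_equal(c1, c2)


def test_gene_count_matches_config():
    cfg = SimulationConfig(seed=3, n_genes=25, effects=[], n_null_events=10)
    ref = simulate_reference(cfg)
    assert len(ref.models.genes) == 25  # n_genes is a floor above site count


@pytest.mark.parametrize("bad", [
    dict(rho=1.5),
    dict(effects=[PlantedEffect("alt_3ss", "SF3B1", 1, 90.0, 20.0)]),
    dict(cohort={"BMMNC": {"SF3B1:K700E": 1, "control": 40}}),
    dict(effects=[PlantedEffect("alt_3ss", "SF3B1", 1, 10.0, 5.0, nmd_d=2.0)]),
])
def test_invalid_configs_rejected(bad):
    with pytest.raises(ConfigError):
        SimulationConfig(seed=0, **bad).validate()


def test_effect_group_must_exist_in_design(small_reference):
    cfg = dataclasses.replace(
        small_reference.config,
        effects=[PlantedEffect("alt_3ss", "ZRSR2", 1, 10.0, 5.0)])
    with pytest.raises(ConfigError, match="ZRSR2"):
        simulate_cohort(small_reference, cfg)


def test_intron_regimes_realize_configured_medians():
    """Realized medians of the two intron-length regimes stay within 20%
    of the configured 0.41 kb and 1.8 kb at n_genes=500."""
    cfg = SimulationConfig(seed=9, n_genes=500, effects=[
        PlantedEffect("intron_retention", "SF3B1", 500, 15.0, -3.0)],
        n_null_events=0, frac_short_introns=0.0)
    ref = simulate_reference(cfg)
    retained = {s.event.intron for s in ref.sites
                if s.event.etype == "intron_retention"}
    short_lens, long_lens = [], []
    for t in ref.models.transcripts.values():
        for intr in t.introns:
            L = intr[1] - intr[0] + 1
            (short_lens if intr in retained else long_lens).append(L)
    assert len(short_lens) >= 400 and len(long_lens) >= 1000
    assert abs(np.median(short_lens) - 410) / 410 < 0.20
    assert abs(np.median(long_lens) - 1800) / 1800 < 0.20


def test_null_cohort_group_difference_is_small(small_reference):
    """With no planted effect and d=1 the group PSI means agree within 2%."""
    cfg = dataclasses.replace(
        small_reference.config, seed=21, effects=[], n_null_events=40,
        cohort={"BMMNC": {"SF3B1:K700E": 30, "control": 30}})
    ref = simulate_reference(cfg)
    table, _, sheet, _ = simulate_cohort(ref, cfg)
    psi = compute_psi([s.event for s in ref.sites], table)
    mut = sheet.samples_with_mutation("SF3B1")
    ctrl = sheet.control_samples()
    delta = (psi.psi[mut].mean(axis=1) - psi.psi[ctrl].mean(axis=1)).abs()
    assert delta.mean() < 2.0


def test_planted_delta_recovered_within_sampling_error():
    """A +30% PSI shift in the mutated group is recovered within +-5% of
    truth at n=30 (beta-binomial sampling error bound)."""
    cfg = SimulationConfig(
        seed=13, effects=[PlantedEffect("alt_3ss", "SF3B1", 10, 20.0, 30.0)],
        n_null_events=0,
        cohort={"BMMNC": {"SF3B1:K700E": 30, "control": 30}})
    ref = simulate_reference(cfg)
    table, _, sheet, truth = simulate_cohort(ref)
    psi = compute_psi([s.event for s in ref.sites], table)
    mut = sheet.samples_with_mutation("SF3B1")
    planted = truth.events[truth.events.delta_psi > 0]
    for eid in planted.event_id:
        assert abs(psi.psi.loc[eid, mut].mean() - 50.0) < 5.0


def test_truth_ledger_is_complete(small_reference, small_study):
    """Every nonzero planted effect appears exactly once in the ledger."""
    truth = small_study[3].events
    nonzero = truth[truth.delta_psi != 0]
    assert not nonzero.event_id.duplicated().any()
    planted = sum(e.n_events for e in small_reference.config.effects)
    assert len(nonzero) == planted
    site_ids = {s.event.event_id for s in small_reference.sites}
    assert set(truth.event_id) <= site_ids


def test_chx_d0_event_invisible_untreated(small_reference):
    cfg = dataclasses.replace(small_reference.config, n_chx_specific=5)
    ref = simulate_reference(cfg)
    table, sheet, truth = simulate_chx_experiment(ref, cfg)
    psi = compute_psi([s.event for s in ref.sites], table)
    d0 = truth.events[truth.events.nmd_d == 0].event_id
    untreated = [u for u, _ in sheet.chx_pairs()]
    treated = [t for _, t in sheet.chx_pairs()]
    assert len(d0) == 5
    for eid in d0:
        assert (psi.psi.loc[eid, untreated].fillna(0) == 0).all()
        assert (psi.psi.loc[eid, treated] > 0).any()


def test_chx_observed_psi_matches_mixture_arithmetic():
    """With survival d=0.25 and true aberrant fraction 40%, the untreated
    observed PSI is d*40/(d*40+60) ~ 14.3%, recovered within +-3% at
    depth 500."""
    cfg = SimulationConfig(
        seed=17,
        effects=[PlantedEffect("alt_3ss", "SF3B1", 20, 40.0, 0.0,
                               "truncating_ptc", nmd_d=0.25)],
        n_null_events=0, chx_pairs={"SF3B1:K700E": 4}, chx_depth=500.0)
    ref = simulate_reference(cfg)
    table, sheet, _ = simulate_chx_experiment(ref)
    psi = compute_psi([s.event for s in ref.sites], table)
    untreated = [u for u, _ in sheet.chx_pairs()]
    treated = [t for _, t in sheet.chx_pairs()]
    expected = 100 * (0.25 * 40) / (0.25 * 40 + 60)
    assert abs(psi.psi[untreated].to_numpy().mean() - expected) < 3.0
    assert abs(psi.psi[treated].to_numpy().mean() - 40.0) < 3.0


def test_chx_null_events_identical_in_distribution(small_reference):
    """d=1 events show no systematic treated/untreated PSI shift."""
    table, sheet, truth = simulate_chx_experiment(small_reference)
    psi = compute_psi([s.event for s in small_reference.sites], table)
    d1 = truth.events[truth.events.nmd_d == 1].event_id
    untreated = [u for u, _ in sheet.chx_pairs()]
    treated = [t for _, t in sheet.chx_pairs()]
    diff = (psi.psi.loc[d1, treated].mean(axis=1)
            - psi.psi.loc[d1, untreated].mean(axis=1))
    assert abs(diff.mean()) < 2.0


def test_count_motif_examples():
    assert count_motif("CCAGCCTG", "CCNG") == 2
    assert count_motif("GGGG", "SSNG") == 1  # overlapping counted from base 1
    assert count_motif("ACGTACGT", "CCNG") == 0
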