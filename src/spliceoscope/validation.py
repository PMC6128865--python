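"""End-to-end validation suites on seeded synthetic cohorts.

Each function runs one self-contained study — generate a synthetic
reference and cohort under the stated conditions, execute the relevant
pipeline stages, and measure recovery or calibration — and returns a dict
of summary numbers. They are used by the test suite and by
``scripts/acceptance.py``.

Problem sizes are chosen for desk-scale runs: a fixed reference is reused
across cohort seeds where only counts vary, and cohort sizes follow the
package defaults (30 mutated vs 40 control per fraction).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from spliceoscope.consequence import classify_consequence
from spliceoscope.diffsplice import differential_splicing_groups
from spliceoscope.events import compute_psi
from spliceoscope.expression import canonical_count_adjust, nb_glm_lrt, tmm_normalize
from spliceoscope.motifs import (
    compare_intron_features,
    exon_sequences,
    motif_segment_enrichment,
)
from spliceoscope.nmd import chx_response_test, discover_chx_specific_events
from spliceoscope.simulate import (
    PlantedEffect,
    SimulationConfig,
    simulate_chx_experiment,
    simulate_cohort,
    simulate_reference,
)
from spliceoscope.targets import mutual_exclusivity_test

TWO_GROUP = {"BMMNC": {"SF3B1:K700E": 30, "control": 40}}


def _sub_seed(seed: int, k: int) -> int:
    return int((seed * 1009 + k) % (2**31 - 1))


def fisher_worked_example() -> dict:
    """EZH2 lesions across U2AF1 variant groups: 13/66 Q157-mutated vs
    0/32 S34-mutated patients; two-sided Fisher exact test."""
    odds, p = mutual_exclusivity_test([[13, 53], [0, 32]])
    return {"p": p, "odds_ratio": odds, "n": 98}


def fdr_calibration(seed: int, n_events: int = 5000, n_seeds: int = 20) -> dict:
    """Null cohort (no planted effects): discoveries at q<0.01 over cohort
    seeds and KS uniformity of raw Welch p-values."""
    cfg = SimulationConfig(seed=_sub_seed(seed, 1), effects=[],
                           n_null_events=n_events, cohort=dict(TWO_GROUP))
    ref = simulate_reference(cfg)
    events = [s.event for s in ref.sites]
    zero_seeds = 0
    total_disc = 0
    ks_p = np.nan
    for k in range(n_seeds):
        ccfg = dataclasses.replace(cfg, seed=_sub_seed(seed, 100 + k))
        table, _, sheet, _ = simulate_cohort(ref, ccfg)
        psi = compute_psi(events, table)
        res = differential_splicing_groups(
            psi, sheet.samples_with_mutation("SF3B1"),
            sheet.control_samples(), "SF3B1", "BMMNC")
        disc = int((res["q"] < 0.01).sum())
        total_disc += disc
        zero_seeds += disc == 0
        if k == 0:
            ks_p = float(stats.kstest(res["p"].dropna(), "uniform").pvalue)
    return {"frac_seeds_zero_discoveries": zero_seeds / n_seeds,
            "total_discoveries": total_disc, "ks_uniform_p": ks_p,
            "n": n_events * n_seeds}


def power_at_design_target(seed: int, n_events: int = 200) -> dict:
    """Detection of a 10-percentage-point PSI shift at two-sided α=0.001
    with within-group SD ≈ 8% (ρ=0.02 plus counting noise at depth 175),
    n = 30 vs 40 — the cohort's design target."""
    cfg = SimulationConfig(
        seed=_sub_seed(seed, 2),
        effects=[PlantedEffect("alt_3ss", "SF3B1", n_events, 40.0, 10.0)],
        n_null_events=0, cohort=dict(TWO_GROUP), depth=175.0)
    ref = simulate_reference(cfg)
    table, _, sheet, truth = simulate_cohort(ref)
    psi = compute_psi([s.event for s in ref.sites], table)
    res = differential_splicing_groups(
        psi, sheet.samples_with_mutation("SF3B1"), sheet.control_samples(),
        "SF3B1", "BMMNC").set_index("event_id")
    planted = truth.events.loc[truth.events.delta_psi > 0, "event_id"]
    sub = res.loc[planted]
    ctrl_sd = psi.psi[sheet.control_samples()].std(axis=1).mean()
    return {"power": float((sub["p"] < 1e-3).mean()),
            "within_group_sd": float(ctrl_sd), "n": n_events}


def consequence_archetype_config(seed: int, scale: int = 1) -> SimulationConfig:
    effects = [
        PlantedEffect("alt_3ss", "SF3B1", 150 * scale, 1, 25, "truncating_ptc",
                      offset=-21),
        PlantedEffect("alt_3ss", "SF3B1", 150 * scale, 1, 25,
                      "truncating_frameshift", offset=-20),
        PlantedEffect("alt_3ss", "SF3B1", 150 * scale, 1, 25, "non_truncating",
                      offset=-21),
        PlantedEffect("alt_3ss", "SF3B1", 150 * scale, 1, 25, "non_coding_utr",
                      offset=-21),
        PlantedEffect("alt_5ss", "SF3B1", 100 * scale, 2, 10, offset=18),
        PlantedEffect("intron_retention", "SF3B1", 150 * scale, 15, -3),
        PlantedEffect("cassette_exon", "SRSF2", 150 * scale, 40, 15),
        PlantedEffect("alt_first_exon", "SRSF2", 25 * scale, 5, 10),
        PlantedEffect("alt_last_exon", "SRSF2", 25 * scale, 5, 10),
    ]
    return SimulationConfig(seed=seed, effects=effects, n_null_events=0)


def consequence_truth_recovery(seed: int) -> dict:
    """Classifier agreement with the constructed truth labels over ≥1000
    events spanning all five consequence classes."""
    ref = simulate_reference(consequence_archetype_config(_sub_seed(seed, 3)))
    agree = 0
    classes = {}
    for s in ref.sites:
        tx = ref.models.transcripts[s.event.transcript_id]
        lab = classify_consequence(s.event, tx, ref.genome)
        agree += (lab.consequence == s.consequence
                  and lab.mechanism == s.mechanism)
        classes[s.consequence] = classes.get(s.consequence, 0) + 1
    return {"agreement": agree / len(ref.sites), "n": len(ref.sites),
            "classes": classes, "reference": ref}


def nmd_recovery(seed: int, n_seeds: int = 6) -> dict:
    """CHX-pair recovery: d=0.25 truncating events flagged nmd_sensitive at
    q<0.01, d=1 events not, and all d=0 events found CHX-specific, with 4
    pairs at depth 500."""
    cfg = SimulationConfig(
        seed=_sub_seed(seed, 4),
        effects=[
            PlantedEffect("alt_3ss", "SF3B1", 50, 40.0, 0.0, "truncating_ptc",
                          nmd_d=0.25),
            PlantedEffect("alt_3ss", "SF3B1", 25, 40.0, 0.0, "non_truncating"),
        ],
        n_null_events=375, n_chx_specific=50,
        chx_pairs={"SF3B1:K700E": 4}, chx_depth=500.0,
        cohort=dict(TWO_GROUP))
    ref = simulate_reference(cfg)
    events = [s.event for s in ref.sites]
    truth = ref.truth_frame().set_index("event_id")
    sensitive = truth[(truth.consequence == "truncating")
                      & (truth.nmd_d == 0.25)].index
    insensitive = truth[truth.nmd_d == 1.0].index
    d0 = set(truth[truth.nmd_d == 0.0].index)

    sens_rates, insens_rates, d0_found = [], [], []
    for k in range(n_seeds):
        ccfg = dataclasses.replace(cfg, seed=_sub_seed(seed, 400 + k))
        chx_table, chx_sheet, _ = simulate_chx_experiment(ref, ccfg)
        psi_chx = compute_psi(events, chx_table)
        res = chx_response_test(psi_chx, chx_sheet).set_index("event_id")
        sens_rates.append(res.loc[sensitive, "nmd_sensitive"].mean())
        insens_rates.append(res.loc[insensitive, "nmd_sensitive"].mean())
        ptable, _, _, _ = simulate_cohort(ref, ccfg)
        primary_psi = compute_psi(events, ptable)
        found = discover_chx_specific_events(primary_psi, psi_chx, chx_sheet)
        d0_found.append(len(found & d0))
    return {"d025_sensitivity": float(np.mean(sens_rates)),
            "d1_false_rate": float(np.mean(insens_rates)),
            "d0_recovered_min": int(min(d0_found)),
            "n_d0_planted": len(d0), "n": n_seeds}


def expression_coupling(seed: int, n_null_genes: int = 2000) -> dict:
    """Canonical-expression pipeline: genes with planted truncating PSI
    increases plus NMD depletion show negative log2FC after PSI
    adjustment; NB-GLM type-I error measured on null genes."""
    effects = [
        PlantedEffect("alt_3ss", "SF3B1", 12, 1.0, float(d), "truncating_ptc",
                      nmd_d=0.25, offset=-21, couple_expression=True)
        for d in (10, 15, 20, 25, 30)
    ]
    cfg = SimulationConfig(seed=_sub_seed(seed, 5), effects=effects,
                           n_null_events=n_null_genes, cohort=dict(TWO_GROUP))
    ref = simulate_reference(cfg)
    table, counts, sheet, truth = simulate_cohort(ref)
    events = [s.event for s in ref.sites]
    psi = compute_psi(events, table)
    mut = sheet.samples_with_mutation("SF3B1")
    ctrl = sheet.control_samples()
    diff = differential_splicing_groups(psi, mut, ctrl, "SF3B1", "BMMNC")
    cons = pd.DataFrame([{"event_id": s.event.event_id,
                          "consequence": s.consequence or ""}
                         for s in ref.sites])
    adjusted = canonical_count_adjust(counts, psi, cons, diff)
    factors = tmm_normalize(adjusted)
    groups = pd.Series([1 if s in set(mut) else 0 for s in adjusted.columns],
                       index=adjusted.columns)
    res = nb_glm_lrt(adjusted, factors, groups).set_index("gene_id")

    coupled = truth.events[truth.events.couple_expression]
    rows = [(r.delta_psi, res.loc[r.gene_id, "log2_fc"])
            for r in coupled.itertuples() if r.gene_id in res.index]
    arr = np.array(rows)
    rho = stats.spearmanr(arr[:, 0], arr[:, 1]).statistic
    nulls = res.drop(index=[g for g in coupled.gene_id if g in res.index])
    return {"spearman_delta_vs_logfc": float(rho),
            "n_coupled_genes": len(arr),
            "frac_negative_logfc": float((arr[:, 1] < 0).mean()),
            "null_type1_at_0.05": float((nulls["p"] < 0.05).mean()),
            "null_q01": int((nulls["q"] < 0.01).sum()),
            "n": int(len(res))}


def motif_recovery(seed: int, n_seeds: int = 25, n_exons: int = 380) -> dict:
    """Positional CCNG recovery: a 2x planted rate confined to the 3'-most
    quarter of included exons, against constitutive exons."""
    q4_rr, q4_excludes_1, cover = [], [], []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            seed=_sub_seed(seed, 600 + k), n_genes=n_exons,
            exon_length=(120, 260),
            effects=[PlantedEffect("cassette_exon", "SRSF2", n_exons, 40.0,
                                   -15.0, motif_class="included")],
            n_null_events=0)
        ref = simulate_reference(cfg)
        seqs = exon_sequences(ref.genome, ref.exon_classes)
        enr = motif_segment_enrichment(seqs["included"], seqs["constitutive"],
                                       "CCNG", "included")
        q4_rr.append(enr[3].relative_frequency)
        q4_excludes_1.append(enr[3].ci_low > 1.0)
        for seg in enr[:3]:
            cover.append(seg.ci_low <= 1.0 <= seg.ci_high)
    return {"q4_relative_frequency": float(np.mean(q4_rr)),
            "q4_ci_excludes_1_rate": float(np.mean(q4_excludes_1)),
            "q123_ci_coverage": float(np.mean(cover)),
            "n": n_seeds}


def intron_feature_contrast(seed: int, n_introns: int = 400) -> dict:
    """Retention-prone vs constitutive intron features (length in kb, GC
    in percent) with Mann–Whitney p-values."""
    cfg = SimulationConfig(
        seed=_sub_seed(seed, 7), n_genes=n_introns,
        effects=[PlantedEffect("intron_retention", "SF3B1", n_introns,
                               15.0, -3.0)],
        n_null_events=0, frac_short_introns=0.0)
    ref = simulate_reference(cfg)
    affected = {(s.event.chrom, *s.event.intron) for s in ref.sites}
    aff, con = [], []
    for t in ref.models.transcripts.values():
        for intr in t.introns:
            item = (t.chrom, intr[0], intr[1], t.strand)
            (aff if (t.chrom, *intr) in affected else con).append(item)
    res = compare_intron_features(aff, con[:1200], ref.genome).set_index("feature")
    return {
        "affected_median_length_kb": res.loc["length", "median_affected"] / 1e3,
        "constitutive_median_length_kb":
            res.loc["length", "median_constitutive"] / 1e3,
        "affected_median_gc_pct": res.loc["gc", "median_affected"] * 100,
        "constitutive_median_gc_pct":
            res.loc["gc", "median_constitutive"] * 100,
        "length_p": float(res.loc["length", "p"]),
        "gc_p": float(res.loc["gc", "p"]),
        "n": len(aff) + min(len(con), 1200),
    }
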