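"""Functional-target nomination and supporting tests.

A differentially spliced event is nominated as a functional target when it
is (i) significant in the primary cohort (q < 0.01), (ii) recapitulated in
isogenic mutant clones (Welch p < 0.05 with the same direction as the
primary cohort, when clone data are available), and (iii) quantitatively
substantial: mutant mean PSI more than 2-fold above controls and above 10%
in either primary or CHX-treated samples.

The module also provides the expression–PSI association test (Gaussian GLM
with event fixed effects, Wald p for the expression coefficient, on events
almost specifically detected in mutated samples) and the Fisher-exact
mutation mutual-exclusivity test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from spliceoscope.core_io import SampleSheet
from spliceoscope.diffsplice import welch_test
from spliceoscope.events import PsiMatrix

PSI_PSEUDOCOUNT = 1.0


@dataclass
class TargetFilterConfig:
    """Thresholds of the functional-target cascade."""

    min_mean_psi: float = 10.0      # % — floor on mutant mean PSI
    min_fold: float = 2.0           # mutant vs control mean PSI
    specificity_fold: float = 10.0  # "almost specifically detected"
    recapitulation_p: float = 0.05
    q_primary: float = 0.01
    allow_chx_rescue: bool = True   # PSI floor may be met in CHX samples

    def __post_init__(self) -> None:
        for name in ("min_mean_psi", "min_fold", "specificity_fold",
                     "recapitulation_p", "q_primary"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def recapitulation_test(
    psi_clones: PsiMatrix,
    sheet_clones: SampleSheet,
    primary_directions: pd.DataFrame,
    genotype: str = "SF3B1",
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Per-event Welch t between mutant and wild-type isogenic clones.

    ``primary_directions`` needs columns (event_id, direction). An event is
    consistent when p < cutoff and the clone-mean direction matches the
    primary-cohort direction; events with PSI undefined in all clones of a
    genotype are flagged not assessable."""
    mut = psi_clones.psi[sheet_clones.samples_with_mutation(genotype)]
    wt = psi_clones.psi[sheet_clones.control_samples()]
    if mut.shape[1] < 2 or wt.shape[1] < 2:
        raise ValueError("need at least 2 clones per genotype")
    direction = primary_directions.set_index("event_id")["direction"]
    rows = []
    for eid in psi_clones.event_ids:
        x = mut.loc[eid].to_numpy(dtype=float)
        y = wt.loc[eid].to_numpy(dtype=float)
        nx, ny = (~np.isnan(x)).sum(), (~np.isnan(y)).sum()
        if nx < 2 or ny < 2:
            rows.append({"event_id": eid, "t": np.nan, "p": np.nan,
                         "clone_delta_psi": np.nan, "consistent": False,
                         "assessable": False})
            continue
        t, df, p = welch_test(x, y)
        delta = np.nanmean(x) - np.nanmean(y)
        clone_dir = "up_in_mutant" if delta > 0 else "down_in_mutant"
        consistent = (np.isfinite(p) and p < p_cutoff
                      and direction.get(eid, "") == clone_dir)
        rows.append({"event_id": eid, "t": t, "p": p,
                     "clone_delta_psi": delta, "consistent": bool(consistent),
                     "assessable": True})
    return pd.DataFrame(rows)


def functional_target_filter(
    diff: pd.DataFrame,
    psi_primary: PsiMatrix,
    sheet: SampleSheet,
    mutation: str,
    psi_chx: PsiMatrix | None = None,
    sheet_chx: SampleSheet | None = None,
    recapitulation: pd.DataFrame | None = None,
    config: TargetFilterConfig | None = None,
) -> pd.DataFrame:
    """Apply the multi-criteria target cascade to differential results.

    Returns one row per event with per-criterion flags, a provenance
    column recording whether recapitulation was assessed, and ``passed``.
    Relaxing any threshold never removes a passing event (monotone)."""
    cfg = config or TargetFilterConfig()
    mut_samples = sheet.samples_with_mutation(mutation)
    mean_mut = psi_primary.psi[
        [s for s in mut_samples if s in psi_primary.psi.columns]].mean(axis=1)

    chx_mean = None
    if cfg.allow_chx_rescue and psi_chx is not None and sheet_chx is not None:
        treated = [t for _, t in sheet_chx.chx_pairs()
                   if t in psi_chx.psi.columns]
        carriers = set(sheet_chx.samples_with_mutation(mutation))
        treated = [t for t in treated if t in carriers]
        if treated:
            chx_mean = psi_chx.psi[treated].mean(axis=1)

    recap = None
    if recapitulation is not None:
        recap = recapitulation.set_index("event_id")

    rows = []
    for r in diff.itertuples(index=False):
        eid = r.event_id
        significant = bool(np.isfinite(r.q) and r.q < cfg.q_primary)
        m_mut = mean_mut.get(eid, np.nan)
        fold_ok = bool(
            np.isfinite(m_mut)
            and (m_mut + PSI_PSEUDOCOUNT)
            > cfg.min_fold * (r.mean_psi_ctrl + PSI_PSEUDOCOUNT))
        psi_primary_ok = bool(np.isfinite(m_mut) and m_mut > cfg.min_mean_psi)
        psi_chx_ok = False
        if chx_mean is not None and eid in chx_mean.index:
            v = chx_mean[eid]
            psi_chx_ok = bool(np.isfinite(v) and v > cfg.min_mean_psi)
        floor_ok = psi_primary_ok or psi_chx_ok
        if recap is not None and eid in recap.index and recap.loc[eid, "assessable"]:
            recap_ok = bool(recap.loc[eid, "consistent"])
            provenance = "clones_assessed"
        else:
            recap_ok = True
            provenance = "clones_unavailable"
        rows.append({
            "event_id": eid,
            "significant": significant,
            "fold_ok": fold_ok,
            "psi_floor_ok": floor_ok,
            "psi_floor_via_chx": psi_chx_ok and not psi_primary_ok,
            "recapitulated": recap_ok,
            "recapitulation_provenance": provenance,
            "mean_psi_mut": m_mut,
            "mean_psi_ctrl": r.mean_psi_ctrl,
            "passed": significant and fold_ok and floor_ok and recap_ok,
        })
    return pd.DataFrame(rows)


def select_specific_events(
    diff: pd.DataFrame,
    consequences: pd.DataFrame | None = None,
    nmd: pd.DataFrame | None = None,
    config: TargetFilterConfig | None = None,
) -> list[str]:
    """Events (i) almost specifically (>specificity_fold) detected in
    mutated samples, (ii) with mutant mean PSI above the floor, and
    optionally (iii) non-truncating and not NMD-sensitive."""
    cfg = config or TargetFilterConfig()
    d = diff.copy()
    spec = ((d["mean_psi_mut"] + PSI_PSEUDOCOUNT)
            >= cfg.specificity_fold * (d["mean_psi_ctrl"] + PSI_PSEUDOCOUNT))
    high = d["mean_psi_mut"] > cfg.min_mean_psi
    keep = spec & high
    d = d[keep]
    if consequences is not None:
        ok = set(consequences.loc[
            consequences["consequence"] == "non_truncating", "event_id"])
        d = d[d["event_id"].isin(ok)]
    if nmd is not None:
        sensitive = set(nmd.loc[nmd["nmd_sensitive"], "event_id"])
        d = d[~d["event_id"].isin(sensitive)]
    return d["event_id"].tolist()


def expression_psi_association(
    expression_log2: pd.DataFrame,
    psi: PsiMatrix,
    event_ids: list[str],
    samples: list[str],
    min_samples: int = 3,
) -> tuple[pd.DataFrame, float]:
    """Regress PSI on log2 expression of the host gene.

    Per event: OLS slope and Wald p. Pooled: PSI ~ log2 expression + event
    fixed effects across all selected events; returns (per-event table,
    pooled Wald p for the expression coefficient). Events with fewer than
    ``min_samples`` informative samples or constant expression are
    skipped."""
    rows = []
    pooled_y, pooled_x, pooled_event = [], [], []
    for eid in event_ids:
        ev = psi.events.get(eid)
        if ev is None or ev.gene_id not in expression_log2.index:
            continue
        expr = expression_log2.loc[ev.gene_id, samples].to_numpy(dtype=float)
        y = psi.psi.loc[eid, samples].to_numpy(dtype=float)
        ok = ~np.isnan(y) & ~np.isnan(expr)
        if ok.sum() < min_samples or np.allclose(expr[ok].std(), 0.0):
            rows.append({"event_id": eid, "slope": np.nan, "p": np.nan,
                         "n": int(ok.sum()), "skipped": True})
            continue
        x = sm.add_constant(expr[ok])
        fit = sm.OLS(y[ok], x).fit()
        rows.append({"event_id": eid, "slope": float(fit.params[1]),
                     "p": float(fit.pvalues[1]), "n": int(ok.sum()),
                     "skipped": False})
        pooled_y.extend(y[ok])
        pooled_x.extend(expr[ok])
        pooled_event.extend([eid] * int(ok.sum()))
    per_event = pd.DataFrame(rows)
    if not pooled_y or len(set(pooled_event)) == 0:
        return per_event, np.nan
    dm = pd.get_dummies(pd.Series(pooled_event), drop_first=False).astype(float)
    X = np.column_stack([np.asarray(pooled_x, dtype=float), dm.to_numpy()])
    fit = sm.OLS(np.asarray(pooled_y, dtype=float), X).fit()
    return per_event, float(fit.pvalues[0])


def mutual_exclusivity_test(table) -> tuple[float, float]:
    """Two-sided Fisher exact test of a 2×2 mutation co-occurrence table.

    Returns (odds ratio with Haldane 0.5 correction when a zero cell
    exists, two-sided p by the point-probability method). A zero margin
    yields p = 1 by convention."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any() or not np.allclose(tab % 1, 0):
        raise ValueError("need a 2×2 table of non-negative integers")
    if min(tab.sum(axis=0).min(), tab.sum(axis=1).min()) == 0:
        return (np.nan, 1.0)
    p = float(stats.fisher_exact(tab.astype(int), alternative="two-sided")[1])
    if (tab == 0).any():
        tab = tab + 0.5
    odds = float(tab[0, 0] * tab[1, 1] / (tab[0, 1] * tab[1, 0]))
    return (odds, p)
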