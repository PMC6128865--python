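"""NMD sensitivity from paired CHX-treated/untreated samples.

An aberrant isoform is called NMD-sensitive when its PSI increases after
cycloheximide (CHX) treatment at q < 0.01 (two-sided test + sign
requirement). The default test is the Cochran–Mantel–Haenszel (CMH) test
on inclusion/exclusion read counts stratified by patient pair, without
continuity correction; a paired t-test on PSI values is computed
alongside. Events detectable only after CHX treatment ("CHX-specific",
complete physiological degradation) are discovered separately.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from spliceoscope.core_io import SampleSheet
from spliceoscope.diffsplice import bh_adjust
from spliceoscope.events import PsiMatrix

logger = logging.getLogger(__name__)

PSI_PSEUDOCOUNT = 1.0


def cmh_test(strata: list[np.ndarray]) -> tuple[float, float, int]:
    """Cochran–Mantel–Haenszel chi-square over 2×2 strata
    [[a, b], [c, d]] (rows: treated/untreated; cols: inclusion/exclusion),
    without continuity correction.

    Zero-margin strata are dropped (counted in the third return value).
    Returns (statistic, p, n_dropped); statistic 0 / p 1 when nothing is
    testable.
    """
    num = 0.0
    e_sum = 0.0
    var = 0.0
    dropped = 0
    for tab in strata:
        tab = np.asarray(tab, dtype=float)
        r1, r2 = tab.sum(axis=1)
        c1, c2 = tab.sum(axis=0)
        n = tab.sum()
        if min(r1, r2, c1, c2) == 0 or n < 2:
            dropped += 1
            continue
        num += tab[0, 0]
        e_sum += r1 * c1 / n
        var += r1 * r2 * c1 * c2 / (n**2 * (n - 1))
    if var == 0:
        return (0.0, 1.0, dropped)
    stat = (num - e_sum) ** 2 / var
    return (float(stat), float(stats.chi2.sf(stat, 1)), dropped)


def chx_response_test(
    psi: PsiMatrix,
    sheet: SampleSheet,
    method: str = "cmh",
    q_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Per-event CHX response across patient pairs.

    Computes, per event: mean PSI untreated/treated, PSI fold change after
    CHX (pseudocount 1 pp), the CMH statistic/p on read counts stratified
    by pair, the paired-t p on PSI values, and BH q-values over events for
    the chosen ``method`` ('cmh' or 'paired_t'). ``nmd_sensitive`` requires
    q < cutoff and a PSI increase under CHX."""
    if method not in ("cmh", "paired_t"):
        raise ValueError(f"unknown method {method!r}")
    pairs = sheet.chx_pairs()
    if not pairs:
        raise ValueError("sample sheet defines no complete CHX pairs")
    untreated = [u for u, _ in pairs]
    treated = [t for _, t in pairs]

    rows = []
    dropped_total = 0
    for eid in psi.event_ids:
        pu = psi.psi.loc[eid, untreated].to_numpy(dtype=float)
        pt = psi.psi.loc[eid, treated].to_numpy(dtype=float)
        iu = psi.inclusion.loc[eid, untreated].to_numpy(dtype=float)
        eu = psi.exclusion.loc[eid, untreated].to_numpy(dtype=float)
        it = psi.inclusion.loc[eid, treated].to_numpy(dtype=float)
        et = psi.exclusion.loc[eid, treated].to_numpy(dtype=float)

        strata = [np.array([[it[k], et[k]], [iu[k], eu[k]]])
                  for k in range(len(pairs))]
        stat, p_cmh, dropped = cmh_test(strata)
        dropped_total += dropped

        both = ~np.isnan(pu) & ~np.isnan(pt)
        if both.sum() >= 2:
            diffs = pt[both] - pu[both]
            if np.allclose(diffs.std(ddof=1), 0.0):
                p_t = np.nan if np.allclose(diffs, 0.0) else 0.0
            else:
                p_t = float(stats.ttest_rel(pt[both], pu[both]).pvalue)
        else:
            p_t = np.nan
        mu = np.nanmean(pu) if (~np.isnan(pu)).any() else np.nan
        mt = np.nanmean(pt) if (~np.isnan(pt)).any() else np.nan
        rows.append({
            "event_id": eid,
            "mean_psi_untreated": mu,
            "mean_psi_treated": mt,
            "psi_fold_change_chx": (mt + PSI_PSEUDOCOUNT) / (mu + PSI_PSEUDOCOUNT)
            if np.isfinite(mu) and np.isfinite(mt) else np.nan,
            "cmh_stat": stat,
            "p_cmh": p_cmh,
            "p_paired_t": p_t,
            "n_pairs": int(both.sum()),
        })
    if dropped_total:
        logger.info("dropped %d zero-margin CMH strata", dropped_total)
    out = pd.DataFrame(rows)
    pcol = "p_cmh" if method == "cmh" else "p_paired_t"
    out["q"] = bh_adjust(out[pcol].to_numpy())
    increase = out["mean_psi_treated"] > out["mean_psi_untreated"]
    out["nmd_sensitive"] = (out["q"] < q_cutoff) & increase
    out["method"] = method
    return out


def classify_nmd_sensitivity(results: pd.DataFrame,
                             consequences: pd.DataFrame) -> pd.DataFrame:
    """Join NMD calls with consequence classes and cross-tabulate.

    Returns the merged table; the crosstab of nmd_sensitive × consequence
    is available via :func:`nmd_crosstab`."""
    merged = results.merge(
        consequences[["event_id", "consequence"]], on="event_id", how="left")
    merged["consequence"] = merged["consequence"].fillna("unknown")
    return merged


def nmd_crosstab(merged: pd.DataFrame) -> pd.DataFrame:
    return pd.crosstab(merged["consequence"], merged["nmd_sensitive"])


def discover_chx_specific_events(
    primary_psi: PsiMatrix,
    chx_psi: PsiMatrix,
    sheet_chx: SampleSheet,
) -> set[str]:
    """Events detected only after CHX treatment.

    Detection in a sample = PSI defined and > 0. An event is CHX-specific
    when it is detected in ≥1 treated sample and in zero untreated and
    zero primary samples."""
    pairs = sheet_chx.chx_pairs()
    untreated = [u for u, _ in pairs]
    treated = [t for _, t in pairs]

    def detected(psi: PsiMatrix, cols: list[str]) -> pd.Series:
        cols = [c for c in cols if c in psi.psi.columns]
        if not cols:
            return pd.Series(0, index=psi.psi.index)
        sub = psi.psi[cols]
        return ((sub.notna()) & (sub > 0)).sum(axis=1)

    det_treated = detected(chx_psi, treated)
    det_untreated = detected(chx_psi, untreated)
    det_primary = detected(primary_psi, primary_psi.sample_ids)

    out = set()
    for eid in chx_psi.event_ids:
        if det_treated[eid] >= 1 and det_untreated[eid] == 0:
            if eid not in det_primary.index or det_primary[eid] == 0:
                out.add(eid)
    return out
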