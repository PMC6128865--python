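"""Differential splicing between mutation-defined groups.

Per-event PSI values are compared with a two-sided Welch (unequal-variance)
t-test within each cell fraction, with Benjamini–Hochberg adjustment per
(comparison × fraction) family and a q < 0.01 significance cutoff. No
minimum ΔPSI is imposed at the testing stage. Events where both group
variances are zero are excluded (reason-coded) rather than assigned p = 0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from spliceoscope.core_io import SampleSheet
from spliceoscope.events import PsiMatrix

#: pseudocount (percentage points) for PSI fold changes
PSI_PSEUDOCOUNT = 1.0


def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test.

    Returns (t, Welch–Satterthwaite df, two-sided p). NaNs are dropped;
    each vector needs ≥2 defined values. If both sample variances are zero
    the test is undefined and (nan, nan, nan) is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 defined values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        return (np.nan, np.nan, np.nan)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return (float(t), float(df), float(p))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement.

    NaN p-values are excluded from the family and get q = NaN."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return q
    ps = p[ok]
    m = len(ps)
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q


def _welch_matrix(a: np.ndarray, b: np.ndarray):
    """Row-wise Welch test between two events × samples matrices (NaN-aware).

    Returns arrays (t, df, p, mean_a, mean_b, n_a, n_b, both_var_zero)."""
    na = (~np.isnan(a)).sum(axis=1)
    nb = (~np.isnan(b)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        ma = np.nanmean(np.where(na[:, None] > 0, a, np.nan), axis=1)
        mb = np.nanmean(np.where(nb[:, None] > 0, b, np.nan), axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
        se2 = va / na + vb / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    both_zero = (va == 0) & (vb == 0)
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df), np.nan)
    return t, df, p, ma, mb, na, nb, both_zero


def differential_splicing_groups(
    psi: PsiMatrix,
    group_a: list[str],
    group_b: list[str],
    comparison: str = "A_vs_B",
    fraction: str = "",
    q_cutoff: float = 0.01,
    min_defined: int = 3,
) -> pd.DataFrame:
    """Welch + BH differential splicing between two explicit sample groups
    (group_a = mutated, group_b = control). One BH family per call."""
    if not group_a or not group_b:
        raise ValueError(f"comparison {comparison}: empty group")
    a = psi.psi[group_a].to_numpy(dtype=float)
    b = psi.psi[group_b].to_numpy(dtype=float)
    t, df, p, ma, mb, na, nb, both_zero = _welch_matrix(a, b)

    reason = np.full(len(psi.psi), "", dtype=object)
    testable = (na >= min_defined) & (nb >= min_defined)
    reason[~testable] = "too_few_defined"
    reason[testable & both_zero] = "zero_variance"
    p = np.where(testable & ~both_zero, p, np.nan)
    q = bh_adjust(p)

    delta = ma - mb
    fold = (ma + PSI_PSEUDOCOUNT) / (mb + PSI_PSEUDOCOUNT)
    out = pd.DataFrame({
        "event_id": psi.psi.index,
        "event_type": [psi.event_type(e) if e in psi.events else ""
                       for e in psi.psi.index],
        "comparison": comparison,
        "fraction": fraction,
        "mean_psi_mut": ma,
        "mean_psi_ctrl": mb,
        "delta_psi": delta,
        "psi_fold_change": fold,
        "t": np.where(np.isnan(p), np.nan, t),
        "df": np.where(np.isnan(p), np.nan, df),
        "p": p,
        "q": q,
        "n_mut": na,
        "n_ctrl": nb,
        "direction": np.where(delta > 0, "up_in_mutant", "down_in_mutant"),
        "significant": q < q_cutoff,
        "reason": reason,
    })
    return out.reset_index(drop=True)


def differential_splicing(
    psi: PsiMatrix,
    sheet: SampleSheet,
    comparisons: list[str],
    fractions: list[str] | None = None,
    q_cutoff: float = 0.01,
    min_defined: int = 3,
) -> pd.DataFrame:
    """Run every (mutation comparison × cell fraction) contrast.

    ``comparisons`` holds mutation specs ("SF3B1", "U2AF1:S34", ...);
    controls are the samples without any splicing-factor mutation. Each
    contrast is its own BH family.
    """
    if fractions is None:
        fractions = sorted(sheet.table["cell_fraction"].unique())
    available = set(psi.sample_ids)
    results = []
    for spec in comparisons:
        for fraction in fractions:
            mut = [s for s in sheet.samples_with_mutation(spec, fraction)
                   if s in available]
            ctrl = [s for s in sheet.control_samples(fraction) if s in available]
            if not mut or not ctrl:
                raise ValueError(
                    f"comparison {spec} in {fraction}: empty group after filtering")
            results.append(differential_splicing_groups(
                psi, mut, ctrl, comparison=spec, fraction=fraction,
                q_cutoff=q_cutoff, min_defined=min_defined))
    return pd.concat(results, ignore_index=True)


def associated_events(results: pd.DataFrame, q_cutoff: float = 0.01) -> set[str]:
    """Events significant (q < cutoff) in at least one cell fraction for a
    given comparison family (the cross-fraction union rule)."""
    sig = results[results["q"] < q_cutoff]
    return set(sig["event_id"])


def tally_by_type(results: pd.DataFrame, q_cutoff: float = 0.01) -> pd.DataFrame:
    """Counts of significant events by event type and direction."""
    sig = results[results["q"] < q_cutoff]
    if sig.empty:
        return pd.DataFrame(columns=["event_type", "direction", "n"])
    tal = (sig.groupby(["event_type", "direction"]).size()
           .rename("n").reset_index())
    return tal.sort_values(["event_type", "direction"]).reset_index(drop=True)
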