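"""Validation-stage statistics: qPCR relative quantification and exact group tests.

Relative expression follows the comparative-Ct logic: one PCR cycle is one
doubling, so with dCt = Ct_target - Ct_reference the target abundance
relative to the reference is 2**(-dCt) and the reference/target orientation
is 2**dCt. Both orientations are reported because sign conventions are the
dominant failure mode of dCt analyses. Fold expression versus a calibrator
sample (untreated = 1) is the usual 2**(-ddCt).

Group comparisons mirror the two tests applied throughout the validation
assays: an exact two-sided Mann-Whitney test (full enumeration of all
C(n, n_x) group assignments on midranks when total n <= 12, tie-corrected
normal approximation above) and the pooled-variance unpaired Student t-test.
Significance tiers use the strict-inequality map § (p<0.001), # (p<0.01),
* (p<0.05), ns otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

TIERS = ("ns", "*", "#", "§")
TIER_ORDER = {t: i for i, t in enumerate(TIERS)}

#: largest total sample size for which the Mann-Whitney p is computed by
#: full enumeration (C(12,6) = 924 assignments; exact even with ties)
EXACT_LIMIT = 12


def significance_tier(p: float) -> str:
    """Map a two-sided p-value to the tier symbols § / # / * / ns.

    Boundaries are exclusive: p = 0.05 is 'ns'.
    """
    if not (0.0 <= p <= 1.0) or math.isnan(p):
        raise ValidationError(f"p-value outside [0, 1]: {p!r}")
    if p < 0.001:
        return "§"
    if p < 0.01:
        return "#"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    """Outcome of a two-group test: statistic, two-sided p, significance tier."""

    statistic_name: str
    statistic: float
    p: float
    tier: str
    note: str = ""


def mann_whitney_exact(x, y) -> GroupComparison:
    """Two-sided Mann-Whitney U test, exact by enumeration for small samples.

    For total n <= 12 the p-value is the proportion of all C(n, n_x)
    assignments of the pooled values to the groups whose rank-sum deviates
    from its null mean at least as much as the observed one (midranks under
    ties, so the enumeration stays exact with tied data). Larger samples use
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    w_obs = float(ranks[:nx].sum())
    u_obs = w_obs - nx * (nx + 1) / 2.0

    if n <= EXACT_LIMIT:
        mean_w = ranks.sum() * nx / n
        dev_obs = abs(w_obs - mean_w)
        count = total = 0
        for idx in combinations(range(n), nx):
            w = ranks[list(idx)].sum()
            total += 1
            if abs(w - mean_w) >= dev_obs - 1e-9:
                count += 1
        p = count / total
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    p = min(1.0, p)
    return GroupComparison("mann_whitney_U", u_obs, p, significance_tier(p))


def t_test_unpaired(x, y, welch: bool = False) -> GroupComparison:
    """Two-sided unpaired t-test (pooled-variance Student form by default).

    Zero pooled variance is handled without exceptions: equal means give
    p = 1, unequal means give p = 0 with a flag in ``note``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs n >= 2 for a t-test")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if x.mean() == y.mean():
            return GroupComparison("t", 0.0, 1.0, "ns", note="zero variance, equal means")
        p = 0.0
        t = math.inf if x.mean() > y.mean() else -math.inf
        return GroupComparison("t", t, p, significance_tier(p),
                               note="zero variance, unequal means")
    import warnings

    with warnings.catch_warnings():
        # near-identical small samples trip scipy's precision-loss warning;
        # the zero-variance case is already handled explicitly above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(x, y, equal_var=not welch)
    p = float(res.pvalue)
    return GroupComparison("t", float(res.statistic), p, significance_tier(p))


# ---------------------------------------------------------------------------
# qPCR relative quantification

CT_COLUMNS = ["sample_id", "gene", "replicate_id", "ct"]


def _check_ct_table(cts: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in cts.columns]
    if missing:
        raise ValidationError(f"Ct table missing column(s) {missing}")
    ct = pd.to_numeric(cts["ct"], errors="raise")
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValidationError("Ct values must be finite and positive")
    out = cts.loc[:, CT_COLUMNS].copy()
    out["ct"] = ct.astype(float)
    return out


def _mean_ct(sub: pd.DataFrame, sample: str, gene: str) -> float:
    vals = sub.loc[sub["gene"] == gene, "ct"]
    if not len(vals):
        raise ValidationError(f"sample {sample!r}: no Ct for gene {gene!r}")
    return float(vals.mean())


def relative_expression(cts: pd.DataFrame, target: str, references) -> pd.DataFrame:
    """Per-sample relative abundance of ``target`` versus reference gene(s).

    Replicate Cts are averaged per gene; multiple reference genes are
    combined as the arithmetic mean of their mean Cts (the geometric mean of
    their abundances). Returns one row per sample with delta_ct and both
    ratio orientations: ratio_target_over_reference = 2**(-delta_ct) and
    ratio_reference_over_target = 2**delta_ct.
    """
    if isinstance(references, str):
        references = [references]
    references = list(references)
    if not references:
        raise ValidationError("at least one reference gene required")
    cts = _check_ct_table(cts)
    rows = []
    for sample, sub in cts.groupby("sample_id", sort=True):
        ct_t = _mean_ct(sub, sample, target)
        ct_r = float(np.mean([_mean_ct(sub, sample, g) for g in references]))
        dct = ct_t - ct_r
        rows.append({
            "sample_id": sample,
            "target": target,
            "reference": "+".join(references),
            "ct_target": ct_t,
            "ct_reference": ct_r,
            "delta_ct": dct,
            "ratio_target_over_reference": 2.0 ** (-dct),
            "ratio_reference_over_target": 2.0 ** dct,
        })
    return pd.DataFrame(rows)


def normalized_fold_expression(cts: pd.DataFrame, target: str, references,
                               calibrator_sample: str) -> pd.DataFrame:
    """Fold expression 2**(-ddCt) of every sample versus a calibrator sample.

    The calibrator's own fold is exactly 1. Adds delta_delta_ct and nfe
    columns to the :func:`relative_expression` output.
    """
    rel = relative_expression(cts, target, references)
    cal = rel[rel["sample_id"] == calibrator_sample]
    if not len(cal):
        raise ValidationError(f"calibrator sample {calibrator_sample!r} not in Ct table")
    dct_cal = float(cal["delta_ct"].iloc[0])
    rel = rel.copy()
    rel["calibrator"] = calibrator_sample
    rel["delta_delta_ct"] = rel["delta_ct"] - dct_cal
    rel["nfe"] = 2.0 ** (-rel["delta_delta_ct"])
    return rel


def normalize_per_cell(activity, n_cells):
    """Activity per cell: total signal divided by the automated nuclei count."""
    n = np.asarray(n_cells, dtype=float)
    if np.any(n <= 0):
        raise ValidationError("cell count must be positive")
    out = np.asarray(activity, dtype=float) / n
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# condition summaries (dose series / time courses)


def summarize_conditions(table: pd.DataFrame, value_col: str, condition_col: str,
                         vehicle: str, stratum_col: str | None = None) -> pd.DataFrame:
    """Per-condition mean/sd on the vehicle = 100 scale, with tests vs vehicle.

    Within each stratum (dose series, time point) values are rescaled so the
    vehicle group's mean is 100; every other condition is compared to the
    vehicle with both the exact Mann-Whitney and the Student t-test.
    """
    work = table.copy()
    if stratum_col is None:
        stratum_col = "_stratum"
        work[stratum_col] = "all"
    rows = []
    for stratum, sub in work.groupby(stratum_col, sort=True):
        veh = sub.loc[sub[condition_col] == vehicle, value_col].to_numpy(float)
        if veh.size == 0:
            raise ValidationError(f"stratum {stratum!r} has no vehicle ({vehicle!r}) entries")
        scale = 100.0 / veh.mean()
        for cond, grp in sub.groupby(condition_col, sort=True):
            vals = grp[value_col].to_numpy(float)
            rec = {
                "stratum": stratum,
                "condition": cond,
                "mean_pct": float(vals.mean() * scale),
                "sd_pct": float(vals.std(ddof=1) * scale) if vals.size >= 2 else math.nan,
                "n": int(vals.size),
            }
            if cond == vehicle:
                rec.update(mw_p=math.nan, mw_tier="", t_p=math.nan, t_tier="")
            else:
                mw = mann_whitney_exact(vals, veh)
                rec.update(mw_p=mw.p, mw_tier=mw.tier)
                if vals.size >= 2 and veh.size >= 2:
                    tt = t_test_unpaired(vals, veh)
                    rec.update(t_p=tt.p, t_tier=tt.tier)
                else:
                    rec.update(t_p=math.nan, t_tier="")
            rows.append(rec)
    cols = ["stratum", "condition", "mean_pct", "sd_pct", "n",
            "mw_p", "mw_tier", "t_p", "t_tier"]
    out = pd.DataFrame(rows, columns=cols)
    if stratum_col == "_stratum":
        out = out.drop(columns=["stratum"])
    return out
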