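"""Primary-screen analytics: normalization, Z'-factor QC, viability-gated hit calling.

Each well of the screen yields two readings: a fluorescence signal ``fluo``
proportional to the number of viable cells and a luminescence signal ``lum``
from a promoter-driven luciferase reporter. Three per-well quantities drive
the analysis, each normalized against the DMSO vehicle wells of the same
plate run:

* viability        Vi  = 100 * fluo / mean(fluo_vehicle)
* normalized activity N_x = lum / fluo
* effect           E   = 100 * N_x / mean(N_x_vehicle)

so vehicle wells average to Vi = E = 100 on every run by construction, and
any multiplicative plate effect on lum cancels out of E exactly.

Assay quality is monitored with the Z'-factor,

    Z' = 1 - 3 * (sd_s + sd_c) / |mean_s - mean_c|,

computed between each control class (transcriptional activator / inhibitor)
and the vehicle on the E scale. A compound is called a hit when its effect
clears a fold-change threshold (default E <= 40 for inhibitors, E >= 240 for
activators, boundaries inclusive) in every replicate at some concentration,
with viability above a cytotoxicity gate, on a plate that passed QC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError, PlateError
from .plate import ScreenDataset

log = logging.getLogger(__name__)

#: a physical plate run: one plate read at one concentration in one replicate.
#: Normalization (vehicle anchoring) is strictly within this group.
RUN_KEYS = ["plate_id", "concentration_uM", "replicate_id"]


# ---------------------------------------------------------------------------
# per-well formulas


def compute_viability(fluo, mean_fluo_vehicle):
    """Viability index Vi = 100 * fluo / mean vehicle fluo (percent).

    Not clamped: values above 100 are preserved (and flagged downstream).
    """
    if np.any(np.asarray(mean_fluo_vehicle) <= 0):
        raise PlateError("mean vehicle fluorescence must be positive")
    return 100.0 * np.asarray(fluo, dtype=float) / mean_fluo_vehicle


def normalize_activity(lum, fluo):
    """Per-well normalized activity N_x = lum / fluo.

    Wells with fluo <= 0 yield NaN (they are flagged invalid upstream and
    excluded downstream).
    """
    lum = np.asarray(lum, dtype=float)
    fluo = np.asarray(fluo, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(fluo > 0, lum / np.where(fluo > 0, fluo, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def compute_effect(n_x, mean_n_vehicle):
    """Effect E = 100 * N_x / mean vehicle N_x (percent of vehicle)."""
    if np.any(np.asarray(mean_n_vehicle) <= 0):
        raise PlateError("mean vehicle normalized activity must be positive")
    return 100.0 * np.asarray(n_x, dtype=float) / mean_n_vehicle


def zprime(mu_s, sd_s, mu_c, sd_c) -> float:
    """Screening-window coefficient Z' = 1 - 3(sd_s + sd_c)/|mu_s - mu_c|.

    Z' <= 1 always; it may be negative for poor assays. Equal means make the
    statistic undefined: NaN is returned (a QC failure sentinel), never an
    exception, so one degenerate plate cannot abort a screen.
    """
    if sd_s < 0 or sd_c < 0:
        raise ValueError("standard deviations must be non-negative")
    denom = abs(mu_s - mu_c)
    if denom == 0:
        return math.nan
    return 1.0 - 3.0 * (sd_s + sd_c) / denom


# ---------------------------------------------------------------------------
# dataset-level metrics


def compute_well_metrics(dataset: ScreenDataset, run_keys=None) -> pd.DataFrame:
    """Per-well Vi, N_x and E for every well of the dataset.

    Vehicle statistics are taken from the well's own plate run (``run_keys``,
    default plate x concentration x replicate), so vehicle wells average to
    Vi = E = 100 within every run and plate-level scale effects cancel.

    Raises :class:`PlateError` if a run has no usable vehicle wells or a
    non-positive vehicle mean.
    """
    run_keys = list(run_keys or RUN_KEYS)
    wells = dataset.wells.copy()
    if not len(wells):
        for c in ("N_x", "Vi", "E", "vi_over_100"):
            wells[c] = []
        return wells

    wells["N_x"] = normalize_activity(wells["lum"].to_numpy(), wells["fluo"].to_numpy())

    veh = wells[(wells["role"] == "vehicle") & wells["valid"]]
    runs = wells.loc[wells["role"] != "empty", run_keys].drop_duplicates()
    have = veh[run_keys].drop_duplicates()
    missing = runs.merge(have, on=run_keys, how="left", indicator=True)
    missing = missing[missing["_merge"] == "left_only"]
    if len(missing):
        raise PlateError(
            "run(s) without usable vehicle wells: "
            + "; ".join(str(tuple(r)) for r in missing[run_keys].itertuples(index=False))
        )
    stats = veh.groupby(run_keys).agg(
        mean_fluo_vehicle=("fluo", "mean"), mean_n_vehicle=("N_x", "mean")
    )
    if (stats["mean_fluo_vehicle"] <= 0).any():
        raise PlateError("non-positive mean vehicle fluorescence in a run")
    if (stats["mean_n_vehicle"] <= 0).any():
        raise PlateError("non-positive mean vehicle activity in a run")

    wells = wells.merge(stats, left_on=run_keys, right_index=True, how="left")
    wells["Vi"] = compute_viability(wells["fluo"].to_numpy(), wells["mean_fluo_vehicle"].to_numpy())
    wells["E"] = compute_effect(wells["N_x"].to_numpy(), wells["mean_n_vehicle"].to_numpy())
    wells["vi_over_100"] = wells["Vi"] > 100.0
    return wells.drop(columns=["mean_fluo_vehicle", "mean_n_vehicle"])


# ---------------------------------------------------------------------------
# plate QC


@dataclass
class HitCallingConfig:
    """Thresholds and rules for QC and hit calling.

    low_threshold / high_threshold are on the E scale (vehicle = 100): the
    default 40 / 240 encode "at least a 0.4-fold reduction or a 2.4-fold
    upregulation", boundaries inclusive. viability_min gates out cytotoxic
    wells; replicate_rule 'all' demands every replicate at a concentration to
    agree (conservative), 'any' accepts a single replicate. qc_threshold is
    the minimum Z' for a plate to contribute.
    """

    low_threshold: float = 40.0
    high_threshold: float = 240.0
    viability_min: float = 70.0
    replicate_rule: str = "all"
    qc_threshold: float = 0.5

    def __post_init__(self):
        if not (0 < self.low_threshold < 100 < self.high_threshold):
            raise ConfigError(
                "thresholds must satisfy 0 < low < 100 < high, got "
                f"{self.low_threshold}/{self.high_threshold}"
            )
        if self.replicate_rule not in ("all", "any"):
            raise ConfigError(f"replicate_rule must be 'all' or 'any', got {self.replicate_rule!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "HitCallingConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown hit-calling key(s): {sorted(unknown)}")
        return cls(**d)


def qc_screen(metrics: pd.DataFrame, qc_threshold: float = 0.5,
              group_keys=("plate_id",)) -> pd.DataFrame:
    """Z'-factor QC per plate.

    For each group (default: the plate, pooling its runs on the already
    run-normalized E scale) computes Z' for positive-control vs vehicle and
    negative-control vs vehicle. A missing control class leaves that Z'
    absent (NaN, status 'absent') with a warning; equal means yield status
    'degenerate'. ``pass`` requires every *available* Z' >= qc_threshold and
    no degenerate pair; a plate with no control pair at all fails.
    """
    group_keys = list(group_keys)
    rows = []
    valid = metrics[metrics["valid"]]
    for key, sub in valid.groupby(group_keys, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        veh = sub.loc[sub["role"] == "vehicle", "E"]
        rec = dict(zip(group_keys, key))
        ok, any_pair = True, False
        for cls_name, col in (("positive_control", "zprime_positive"),
                              ("negative_control", "zprime_negative")):
            ctl = sub.loc[sub["role"] == cls_name, "E"]
            if len(ctl) < 2 or len(veh) < 2:
                rec[col], rec[col + "_status"] = math.nan, "absent"
                log.warning("%s: %s pair absent from QC", key, cls_name)
                continue
            z = zprime(ctl.mean(), ctl.std(ddof=1), veh.mean(), veh.std(ddof=1))
            any_pair = True
            if math.isnan(z):
                rec[col], rec[col + "_status"] = math.nan, "degenerate"
                ok = False
            else:
                rec[col], rec[col + "_status"] = z, "ok"
                ok = ok and (z >= qc_threshold)
        rec["pass"] = bool(ok and any_pair)
        rows.append(rec)
    cols = group_keys + ["zprime_positive", "zprime_positive_status",
                         "zprime_negative", "zprime_negative_status", "pass"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# hit calling


@dataclass
class HitTable:
    """Hit-calling result.

    ``calls``: one row per compound (direction in {inhibitor, activator,
    none}, conflict/no-data flags). ``observations``: one row per compound x
    concentration x replicate with E, Vi and the QC status of the plate that
    produced it.
    """

    calls: pd.DataFrame
    observations: pd.DataFrame
    config: HitCallingConfig = field(default_factory=HitCallingConfig)

    @property
    def hits(self) -> pd.DataFrame:
        return self.calls[self.calls["direction"] != "none"]

    def counts(self) -> dict:
        vc = self.calls["direction"].value_counts()
        return {"activator": int(vc.get("activator", 0)),
                "inhibitor": int(vc.get("inhibitor", 0)),
                "none": int(vc.get("none", 0))}


def call_hits(dataset: ScreenDataset, config: HitCallingConfig | None = None,
              metrics: pd.DataFrame | None = None,
              qc: pd.DataFrame | None = None) -> HitTable:
    """Threshold-based hit calling with viability gating.

    A well observation is a candidate inhibitor iff E <= low_threshold and
    Vi >= viability_min (candidate activator: E >= high_threshold), on a
    QC-passing plate. Under replicate_rule='all' every replicate at that
    concentration must agree; a compound is a hit if the rule is satisfied at
    >= 1 concentration. Opposite directions at different concentrations
    cancel to 'none' with a conflict flag; compounds with no valid
    observation on a passing plate are 'none' with a no-data flag.
    """
    config = config or HitCallingConfig()
    if metrics is None:
        metrics = compute_well_metrics(dataset)
    if qc is None:
        qc = qc_screen(metrics, qc_threshold=config.qc_threshold)

    qc_pass = dict(zip(qc["plate_id"], qc["pass"]))
    obs = metrics[(metrics["role"] == "compound") & metrics["valid"]].copy()
    obs["qc_pass"] = obs["plate_id"].map(qc_pass).fillna(False).astype(bool)
    obs["viable"] = obs["Vi"] >= config.viability_min
    obs["cand_inhibitor"] = (obs["E"] <= config.low_threshold) & obs["viable"]
    obs["cand_activator"] = (obs["E"] >= config.high_threshold) & obs["viable"]

    usable = obs[obs["qc_pass"]]
    agg = usable.groupby(["compound_id", "concentration_uM"]).agg(
        n_obs=("E", "size"),
        inh_n=("cand_inhibitor", "sum"),
        act_n=("cand_activator", "sum"),
    ).reset_index()
    need_all = config.replicate_rule == "all"
    inh_ok = (agg["inh_n"] == agg["n_obs"]) if need_all else (agg["inh_n"] > 0)
    act_ok = (agg["act_n"] == agg["n_obs"]) if need_all else (agg["act_n"] > 0)
    # a concentration cannot be both (a single well cannot be both; under the
    # 'any' rule mixed candidates across replicates are treated as a conflict)
    both = inh_ok & act_ok
    agg["direction"] = np.select(
        [both, inh_ok, act_ok], ["conflict", "inhibitor", "activator"], default="none"
    )

    all_compounds = pd.unique(pd.Series(dataset.compound_ids, dtype=object))
    calls = []
    by_compound = {cid: sub for cid, sub in agg.groupby("compound_id")}
    n_valid_obs = usable.groupby("compound_id").size().to_dict()
    for cid in all_compounds:
        sub = by_compound.get(cid)
        dirs = set(sub["direction"]) - {"none"} if sub is not None else set()
        conflict = "conflict" in dirs or dirs >= {"inhibitor", "activator"}
        if conflict:
            direction = "none"
        elif dirs:
            direction = dirs.pop()
        else:
            direction = "none"
        calls.append({
            "compound_id": cid,
            "direction": direction,
            "conflict": bool(conflict),
            "no_data": int(n_valid_obs.get(cid, 0)) == 0,
            "n_obs": int(n_valid_obs.get(cid, 0)),
        })
    calls = pd.DataFrame(calls, columns=["compound_id", "direction", "conflict",
                                         "no_data", "n_obs"])

    obs_cols = ["compound_id", "plate_id", "concentration_uM", "replicate_id",
                "E", "Vi", "qc_pass"]
    observations = obs.loc[:, obs_cols].sort_values(
        ["compound_id", "concentration_uM", "replicate_id"]).reset_index(drop=True)
    return HitTable(calls=calls, observations=observations, config=config)


def hit_config_to_dict(config: HitCallingConfig) -> dict:
    return asdict(config)
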