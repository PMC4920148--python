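"""Ground-truth simulators for every input the pipeline consumes.

Every generator is a deterministic function of (config, seed) and returns
the synthetic dataset together with the ground truth that produced it, so
analysis-recovers-generation tests need no external data.

The screen simulator emulates a 1280-compound FDA-approved library screened
in 16 96-well plates (80 compounds each, columns 1 and 12 reserved for
8 DMSO vehicle + 4 positive-control + 4 negative-control wells), in
duplicate at 20 and 2 uM. The generative model per well:

* fluo  ~ Normal(fluo_mean * tox, cv) — viable-cell signal; cytotoxic
  compounds shrink it by a toxicity factor.
* lum   = fluo * lum_per_fluo * plate_effect * multiplier * (1 + cv_lum * z)
  — the reporter signal is proportional to the same viable-cell signal
  (dead cells emit neither), carries a per-plate multiplicative scale
  effect (lognormal), the compound's true effect multiplier, and an
  independent luminescence measurement noise.

Because lum is proportional to the well's own fluo draw, cell-number
variation cancels from N_x = lum/fluo and only the measurement cv survives
on the effect scale; the plate effect cancels from E by vehicle
normalization. At the default cv of 5% the per-plate Z' lands near
0.63-0.66 for control multipliers 2.4x/0.4x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .imaging import HUVolume
from .plate import ROWS, PlateLayout, ScreenDataset

# drug content of the control wells, uM (vehicle wells carry no drug)
POSITIVE_CONTROL_UM = 10.0
NEGATIVE_CONTROL_UM = 20.0


# ---------------------------------------------------------------------------
# screen


@dataclass
class ScreenSimConfig:
    """Structure and noise of the simulated screen.

    ``active_compounds`` maps compound_id -> true effect multiplier at the
    highest concentration; at every other concentration the multiplier is
    attenuated to multiplier ** potency_exponent. ``toxic_fraction`` of the
    inactive compounds get a toxicity factor ``toxic_viability`` (< the
    viability gate) on both readouts.
    """

    n_plates: int = 16
    compounds_per_plate: int = 80
    n_vehicle: int = 8
    n_positive: int = 4
    n_negative: int = 4
    concentrations: tuple = (20.0, 2.0)
    replicates: int = 2
    fluo_mean: float = 1000.0
    fluo_cv: float = 0.05
    lum_per_fluo: float = 5.0
    lum_cv: float = 0.05
    plate_effect_sd: float = 0.15
    positive_multiplier: float = 2.4
    negative_multiplier: float = 0.4
    toxic_fraction: float = 0.05
    toxic_viability: float = 0.3
    potency_exponent: float = 0.5
    active_compounds: dict = field(default_factory=dict)

    def __post_init__(self):
        n_ctl = self.n_vehicle + self.n_positive + self.n_negative
        if self.compounds_per_plate > 80 or n_ctl > 16 or self.compounds_per_plate < 1:
            raise ConfigError(
                f"layout does not fit a 96-well plate: {self.compounds_per_plate} "
                f"compounds + {n_ctl} controls"
            )
        if self.fluo_cv < 0 or self.lum_cv < 0 or self.plate_effect_sd < 0:
            raise ConfigError("noise parameters must be non-negative")
        for name in ("positive_multiplier", "negative_multiplier"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if any(m <= 0 for m in self.active_compounds.values()):
            raise ConfigError("active-compound multipliers must be positive")
        if not (0 <= self.toxic_fraction <= 1):
            raise ConfigError("toxic_fraction must be in [0, 1]")
        self.concentrations = tuple(float(c) for c in self.concentrations)

    @property
    def n_compounds(self) -> int:
        return self.n_plates * self.compounds_per_plate

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenSimConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown screen-simulation key(s): {sorted(unknown)}")
        d = dict(d)
        if "concentrations" in d:
            d["concentrations"] = tuple(d["concentrations"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["concentrations"] = list(self.concentrations)
        return d


@dataclass
class SyntheticTruth:
    """Ground truth emitted with a simulated screen."""

    compounds: pd.DataFrame  # compound_id, plate_id, multiplier per conc, toxic
    plates: pd.DataFrame  # plate_id, plate_effect
    seed: int
    config: ScreenSimConfig

    @property
    def active_ids(self) -> list:
        act = self.compounds[self.compounds["multiplier_high"] != 1.0]
        return act["compound_id"].tolist()

    @property
    def inhibitor_ids(self) -> list:
        sel = self.compounds["multiplier_high"] < 1.0
        return self.compounds.loc[sel, "compound_id"].tolist()

    @property
    def activator_ids(self) -> list:
        sel = self.compounds["multiplier_high"] > 1.0
        return self.compounds.loc[sel, "compound_id"].tolist()

    @property
    def toxic_ids(self) -> list:
        return self.compounds.loc[self.compounds["toxic"], "compound_id"].tolist()


def default_layout(plate_id: str, compound_ids, n_vehicle=8, n_positive=4,
                   n_negative=4) -> PlateLayout:
    """Build the generator's plate layout.

    Compounds fill columns 2-11 row-major (A2..A11, B2..). Controls occupy
    column 1 top-down then column 12: vehicle first, then positive, then
    negative controls; remaining wells are empty. The within-column control
    arrangement is this generator's documented convention — the layout file
    is always authoritative for real data.
    """
    compound_ids = list(compound_ids)
    if len(compound_ids) > 80:
        raise ConfigError("at most 80 compound wells per plate")
    rows = []
    slots = [(r, c) for r in ROWS for c in range(2, 12)]
    for (r, c), cid in zip(slots, compound_ids):
        rows.append({"row": r, "column": c, "role": "compound", "compound_id": cid})
    for r, c in slots[len(compound_ids):]:
        rows.append({"row": r, "column": c, "role": "empty", "compound_id": None})
    control_slots = [(r, 1) for r in ROWS] + [(r, 12) for r in ROWS]
    roles = (["vehicle"] * n_vehicle + ["positive_control"] * n_positive
             + ["negative_control"] * n_negative)
    roles += ["empty"] * (len(control_slots) - len(roles))
    for (r, c), role in zip(control_slots, roles):
        rows.append({"row": r, "column": c, "role": role, "compound_id": None})
    return PlateLayout(plate_id, pd.DataFrame(rows))


def simulate_screen(config: ScreenSimConfig | None = None,
                    seed: int = 0) -> tuple[ScreenDataset, SyntheticTruth]:
    """Simulate a full dual-readout screen; returns (dataset, truth).

    The ``concentration_uM`` column of the measurement table labels the
    screening pass (the concentration at which the plate run was screened);
    control wells appear in every pass. Cytotoxic compounds are drawn among
    the inactive ones.
    """
    config = config or ScreenSimConfig()
    rng = np.random.default_rng(seed)

    plate_ids = [f"PL{i + 1:02d}" for i in range(config.n_plates)]
    all_ids = [f"PW-{i + 1:04d}" for i in range(config.n_compounds)]
    unknown_actives = set(config.active_compounds) - set(all_ids)
    if unknown_actives:
        raise ConfigError(f"active compounds not in library: {sorted(unknown_actives)}")

    plate_effects = rng.lognormal(0.0, config.plate_effect_sd, config.n_plates) \
        if config.plate_effect_sd > 0 else np.ones(config.n_plates)

    inactive = [c for c in all_ids if c not in config.active_compounds]
    n_toxic = int(round(config.toxic_fraction * len(inactive)))
    toxic = set(rng.choice(inactive, size=n_toxic, replace=False)) if n_toxic else set()

    layouts = {}
    frames = []
    c_high = max(config.concentrations)
    for pi, pid in enumerate(plate_ids):
        ids = all_ids[pi * config.compounds_per_plate:(pi + 1) * config.compounds_per_plate]
        lay = default_layout(pid, ids, config.n_vehicle, config.n_positive,
                             config.n_negative)
        layouts[pid] = lay
        base = lay.wells.copy()
        base["plate_id"] = pid
        base["plate_effect"] = plate_effects[pi]
        frames.append(base)
    grid = pd.concat(frames, ignore_index=True)

    runs = pd.DataFrame(
        [(c, r) for c in config.concentrations for r in range(1, config.replicates + 1)],
        columns=["concentration_uM", "replicate_id"],
    )
    wells = grid.merge(runs, how="cross")

    mult_high = wells["compound_id"].map(config.active_compounds).fillna(1.0).to_numpy()
    att = np.where(wells["concentration_uM"].to_numpy() == c_high, 1.0,
                   config.potency_exponent)
    mult = mult_high ** att
    role = wells["role"].to_numpy()
    mult = np.where(role == "positive_control", config.positive_multiplier, mult)
    mult = np.where(role == "negative_control", config.negative_multiplier, mult)
    mult = np.where(role == "vehicle", 1.0, mult)

    tox = np.where(wells["compound_id"].isin(toxic).to_numpy(),
                   config.toxic_viability, 1.0)
    n = len(wells)
    fluo_mu = config.fluo_mean * tox
    fluo = fluo_mu * (1.0 + config.fluo_cv * rng.standard_normal(n)) \
        if config.fluo_cv > 0 else fluo_mu.astype(float).copy()
    fluo = np.clip(fluo, 1e-9, None)
    lum_noise = 1.0 + config.lum_cv * rng.standard_normal(n) \
        if config.lum_cv > 0 else np.ones(n)
    lum = fluo * config.lum_per_fluo * wells["plate_effect"].to_numpy() * mult \
        * np.clip(lum_noise, 0.0, None)
    empty = role == "empty"
    fluo[empty] = 0.0
    lum[empty] = 0.0

    wells["fluo"] = fluo
    wells["lum"] = lum
    wells["valid"] = ~empty
    cols = ["plate_id", "row", "column", "replicate_id", "concentration_uM",
            "lum", "fluo", "role", "compound_id", "valid"]
    dataset = ScreenDataset(layouts, wells.loc[:, cols])
    dataset.validate()

    plate_of = {}
    for pid, lay in layouts.items():
        for cid in lay.compound_ids:
            plate_of[cid] = pid
    comp = pd.DataFrame({"compound_id": all_ids})
    comp["plate_id"] = comp["compound_id"].map(plate_of)
    comp["multiplier_high"] = comp["compound_id"].map(config.active_compounds).fillna(1.0)
    comp["multiplier_low"] = comp["multiplier_high"] ** config.potency_exponent
    comp["toxic"] = comp["compound_id"].isin(toxic)
    plates = pd.DataFrame({"plate_id": plate_ids, "plate_effect": plate_effects})
    return dataset, SyntheticTruth(comp, plates, seed, config)


def paperlike_config(n_activators: int = 4, n_inhibitors: int = 18,
                     activator_multiplier: float = 3.0,
                     inhibitor_multiplier: float = 0.3,
                     **overrides) -> ScreenSimConfig:
    """Default screen structure with a hit list of 4 activators + 18
    inhibitors injected at deterministic, evenly spread library positions.

    A structural fixture mirroring the shape of a reported hit list, not a
    reproduction of any actual compound list.
    """
    cfg = ScreenSimConfig(**overrides) if overrides else ScreenSimConfig()
    n = cfg.n_compounds
    act_idx = np.linspace(0.07, 0.93, n_activators) * n if n_activators else []
    inh_idx = np.linspace(0.03, 0.97, n_inhibitors) * n if n_inhibitors else []
    active = {}
    taken = set()
    for idx_list, mult in ((act_idx, activator_multiplier),
                           (inh_idx, inhibitor_multiplier)):
        for i in np.asarray(idx_list, dtype=int):
            while i in taken:  # avoid collisions between the two lists
                i += 1
            taken.add(i)
            active[f"PW-{i + 1:04d}"] = mult
    cfg.active_compounds = active
    return cfg


# ---------------------------------------------------------------------------
# qPCR


def simulate_ct_table(true_folds: dict, references=("GAPDH", "B2M"),
                      target: str = "ACVR1", base_ct: float = 15.0,
                      ct_noise_sd: float = 0.1, replicates: int = 3,
                      seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Simulate a Ct table with known fold changes per sample.

    Reference genes sit near ``base_ct`` (offset by 0.5 cycles per gene);
    the target Ct is the mean reference Ct minus log2(fold), so zero noise
    makes :func:`~htsrepurpose.validate.relative_expression` recover each
    fold exactly.
    """
    if any(f <= 0 for f in true_folds.values()):
        raise ValidationError("fold changes must be positive")
    references = list(references)
    rng = np.random.default_rng(seed)
    offsets = {g: base_ct + 0.5 * i for i, g in enumerate(references)}
    mean_ref = float(np.mean(list(offsets.values())))
    rows = []
    for sample in sorted(true_folds):
        fold = true_folds[sample]
        for gene, mu in [(g, offsets[g]) for g in references] \
                + [(target, mean_ref - math.log2(fold))]:
            for rep in range(1, replicates + 1):
                noise = ct_noise_sd * rng.standard_normal() if ct_noise_sd > 0 else 0.0
                rows.append({"sample_id": sample, "gene": gene,
                             "replicate_id": rep, "ct": mu + noise})
    table = pd.DataFrame(rows, columns=["sample_id", "gene", "replicate_id", "ct"])
    truth = {"true_folds": dict(true_folds), "target": target,
             "references": references, "base_ct": base_ct,
             "ct_noise_sd": ct_noise_sd, "replicates": replicates, "seed": seed}
    return table, truth


# ---------------------------------------------------------------------------
# microCT phantom


def simulate_hu_volume(shape=(48, 48, 48), spacing=(0.075, 0.075, 0.075),
                       semiaxes_mm=(1.0, 1.0, 1.0), center_mm=None,
                       hu_inside: float = 1200.0,
                       hu_background: float = 0.0, noise_sd: float = 0.0,
                       seed: int = 0) -> tuple[HUVolume, dict]:
    """Ellipsoid phantom in a HU volume; truth carries the analytic volume.

    The ellipsoid sits at ``center_mm`` (default: center of the field); a
    voxel belongs to it when its center lies inside. The ellipsoid must fit
    inside the field.
    """
    if any(a <= 0 for a in semiaxes_mm):
        raise ValidationError("semi-axes must be positive")
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in spacing)
    extent = [n * s for n, s in zip(shape, spacing)]
    center = [e / 2.0 for e in extent] if center_mm is None \
        else [float(c) for c in center_mm]
    for a, c, e in zip(semiaxes_mm, center, extent):
        if c - a < 0 or c + a > e:
            raise ValidationError("ellipsoid does not fit inside the field")
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    inside = (((xx - center[0]) / semiaxes_mm[0]) ** 2
              + ((yy - center[1]) / semiaxes_mm[1]) ** 2
              + ((zz - center[2]) / semiaxes_mm[2]) ** 2) <= 1.0
    vox = np.where(inside, hu_inside, hu_background).astype(float)
    if noise_sd > 0:
        vox += np.random.default_rng(seed).normal(0.0, noise_sd, shape)
    a, b, c = semiaxes_mm
    truth = {"analytic_volume_mm3": 4.0 / 3.0 * math.pi * a * b * c,
             "n_inside": int(inside.sum()), "hu_inside": hu_inside,
             "hu_background": hu_background, "spacing": spacing,
             "noise_sd": noise_sd, "seed": seed}
    return HUVolume(vox, spacing), truth


# ---------------------------------------------------------------------------
# histology images

# generator palette chosen so the default StainConfig classifies exactly:
# background is non-tissue, tissue is non-positive, stain is positive.
_BACKGROUND_RGB = (250, 250, 250)
_TISSUE_RGB = (170, 180, 200)
_STAIN_RGB = (200, 30, 45)


def simulate_stain_image(size=(256, 256), true_fraction: float = 0.25,
                         tissue_rows: int | None = None,
                         seed: int = 0) -> tuple[np.ndarray, dict]:
    """RGB section image with an exactly known stain-positive fraction.

    A rectangular tissue band on a white background; an exact number of
    randomly chosen tissue pixels (no anti-aliasing) is painted in the stain
    color. Truth records the exact painted fraction (requested fraction
    rounded to a whole pixel count).
    """
    if not (0.0 <= true_fraction <= 1.0):
        raise ValidationError("fraction must be in [0, 1]")
    h, w = int(size[0]), int(size[1])
    if tissue_rows is None:
        tissue_rows = max(1, int(round(0.7 * h)))
    if tissue_rows > h:
        raise ValidationError("tissue_rows exceeds image height")
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[...] = _BACKGROUND_RGB
    img[:tissue_rows, :, :] = _TISSUE_RGB
    n_tissue = tissue_rows * w
    n_pos = int(round(true_fraction * n_tissue))
    rng = np.random.default_rng(seed)
    pick = rng.choice(n_tissue, size=n_pos, replace=False)
    rr, cc = np.unravel_index(pick, (tissue_rows, w))
    img[rr, cc, :] = _STAIN_RGB
    truth = {"fraction": n_pos / n_tissue, "positive_pixels": n_pos,
             "tissue_pixels": n_tissue, "seed": seed}
    return img, truth


def simulate_nuclei_image(size=(512, 512), n_nuclei: int = 50, radius: int = 5,
                          foreground: int = 220, background: int = 20,
                          min_gap: int = 3, seed: int = 0,
                          max_tries: int = 10_000) -> tuple[np.ndarray, dict]:
    """Grayscale image of ``n_nuclei`` disjoint bright discs.

    Centers are rejection-sampled so discs keep >= ``min_gap`` pixels of
    separation (no touching components); raises if the packing cannot be
    placed within ``max_tries`` attempts.
    """
    h, w = int(size[0]), int(size[1])
    rng = np.random.default_rng(seed)
    margin = radius + 1
    min_d2 = (2 * radius + min_gap) ** 2
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n_nuclei:
        tries += 1
        if tries > max_tries:
            raise ValidationError(
                f"could not place {n_nuclei} nuclei of radius {radius} "
                f"in a {h}x{w} image within {max_tries} tries"
            )
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_d2 for r0, c0 in centers):
            centers.append((r, c))
    img = np.full((h, w), background, dtype=np.uint8)
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    disc = (yy ** 2 + xx ** 2) <= radius ** 2
    for r, c in centers:
        patch = img[r - radius:r + radius + 1, c - radius:c + radius + 1]
        patch[disc] = foreground
    truth = {"count": n_nuclei, "centers": centers, "radius": radius, "seed": seed}
    return img, truth
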