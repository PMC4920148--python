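import numpy as np
import pandas as pd
import pytest

from htsrepurpose import (
    PlateLayout,
    ScreenDataset,
    paperlike_config,
    simulate_screen,
)
from htsrepurpose.simulate import default_layout


@pytest.fixture(scope="session")
def paperlike_screen():
    """One paperlike screen (4 activators, 18 inhibitors) with its truth."""
    return simulate_screen(paperlike_config(), seed=1)


@pytest.fixture(scope="session")
def noiseless_config():
    """Paperlike structure with every noise source switched off."""
    return paperlike_config(fluo_cv=0.0, lum_cv=0.0, plate_effect_sd=0.0,
                            toxic_fraction=0.0)


def small_layout(plate_id="P1", n_compounds=4):
    ids = [f"{plate_id}-C{i + 1}" for i in range(n_compounds)]
    return default_layout(plate_id, ids)


def manual_dataset(effects, vi=None, plate_id="P1", concentrations=(20.0,),
                   replicates=(1,), n_compounds=4, base_fluo=1000.0,
                   base_ratio=5.0, control_effects=None):
    """Hand-built dataset where compound wells hit exact E and Vi targets.

    ``effects[(compound_id, conc, rep)]`` = target E (percent of vehicle);
    ``vi`` optionally maps the same keys to a target Vi. Vehicle wells sit at
    fluo=base_fluo, lum=base_fluo*base_ratio, so E = lum/fluo / base_ratio *
    100 and Vi = fluo / base_fluo * 100 by construction.
    ``control_effects`` maps role -> E for positive/negative control wells
    (default 240 / 40 exactly, zero spread).
    """
    vi = vi or {}
    control_effects = control_effects or {"positive_control": 240.0,
                                          "negative_control": 40.0}
    layout = small_layout(plate_id, n_compounds)
    rows = []
    for conc in concentrations:
        for rep in replicates:
            for rec in layout.wells.itertuples(index=False):
                role, cid = rec.role, rec.compound_id
                if role == "empty":
                    fluo = lum = 0.0
                elif role == "vehicle":
                    fluo, lum = base_fluo, base_fluo * base_ratio
                elif role == "compound":
                    e = effects.get((cid, conc, rep), 100.0)
                    v = vi.get((cid, conc, rep), 100.0)
                    fluo = base_fluo * v / 100.0
                    lum = fluo * base_ratio * e / 100.0
                else:
                    e = control_effects[role]
                    fluo, lum = base_fluo, base_fluo * base_ratio * e / 100.0
                rows.append({"plate_id": plate_id, "row": rec.row,
                             "column": rec.column, "replicate_id": rep,
                             "concentration_uM": conc, "lum": lum, "fluo": fluo,
                             "role": role, "compound_id": cid,
                             "valid": role != "empty" and fluo > 0})
    wells = pd.DataFrame(rows)
    ds = ScreenDataset({plate_id: layout}, wells)
    ds.validate()
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
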