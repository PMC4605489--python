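"""Construct the SYNTHETIC 27-series analysis panel from the study roster.

Series means are diverged to the worldwide apportionment (Fst = 0.276)
under h² = 0.55; each series then receives its published sample size, sex
counts and MCAR missing-value percentage.  Measurement values are entirely
synthetic.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from study_roster import ROSTER, WORLD_FST  # noqa: E402

from phenostruct import SyntheticConfig, simulate_dataset


def build_panel(seed: int):
    names = [r[0] for r in ROSTER]
    sizes = [r[2] for r in ROSTER]
    cfg = SyntheticConfig(k=len(ROSTER), n=sizes, t=23, fst=WORLD_FST,
                          h2=0.55, seed=seed)
    table, truth = simulate_dataset(cfg)
    rng = np.random.default_rng(seed + 1)

    # relabel generic series ids with the roster, fix regions / sex counts,
    # and apply each series' published MCAR missing rate
    generic = table.series_labels()
    mapping = dict(zip(generic, names))
    table.series = np.array([mapping[s] for s in table.series], dtype=object)
    for (name, region, n, males, females, pct), g in zip(ROSTER, generic):
        rows = np.flatnonzero(table.series == name)
        assert len(rows) == n
        table.region[rows] = region
        sexes = ["M"] * males + ["F"] * females + ["U"] * (n - males - females)
        table.sex[rows] = np.array(sexes, dtype=object)
        if pct > 0:
            target_cells = int(round(pct / 100 * n * 23))
            flat = rng.permutation(n * 23)[:target_cells]
            mask = np.zeros((n, 23), dtype=bool)
            mask[np.unravel_index(flat, (n, 23))] = True
            for r in np.flatnonzero(mask.all(axis=1)):
                mask[r, rng.integers(0, 23)] = False
            table.mask[rows] = mask
    table.validate()
    return table, truth
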