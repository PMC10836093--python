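#!/usr/bin/env python
"""NMR observables on synthetic inputs: secondary-structure propensity from
Hα chemical shifts and ensemble-averaged NOE effective distances.

Builds a synthetic 18-residue shift table whose central segment carries
full-sheet Hα deviations (an extended, aggregation-competent register) and
computes the neighbour-corrected propensity; then back-calculates
<r^-6>^(-1/6) NOE distances for cross-strand Cα pairs of the hairpin and
extended ensembles to show which contacts would be NOESY-observable.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ensemblekit.io import read_ensemble
from ensemblekit.nmr_observables import (
    RANDOM_COIL_HA,
    SHEET_DEV_HA,
    ncsp,
    noe_effective_distances,
    secondary_shifts,
)

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "nmr"

SEQ = "ADNIKHVPGGGSVQIVYK"  # hairpin-like 18-mer: turn motif + amyloid motif


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # full-sheet deviations on the amyloid-motif half, coil elsewhere
    dd = np.zeros(18)
    dd[11:18] = SHEET_DEV_HA
    obs = pd.DataFrame({
        "res_id": np.arange(1, 19),
        "aa": list(SEQ),
        "shift_ppm": [RANDOM_COIL_HA[a] + d for a, d in zip(SEQ, dd)],
    })
    prof = ncsp(secondary_shifts(obs), window=3)
    pd.DataFrame({"res_id": prof.residues, "aa": list(SEQ),
                  "ncSP": prof.ncSP}).to_csv(OUT / "ncsp_profile.csv",
                                             index=False)
    print("ncSP profile (negative = beta-extended):")
    print(np.round(prof.ncSP, 2))
    print(f"mean ncSP over the amyloid motif (12-18): "
          f"{prof.ncSP[11:18].mean():.2f}")

    pairs = [((i, "CA"), (19 - i, "CA")) for i in range(1, 9)]
    rows = []
    for name in ("hairpin_centred", "extended"):
        ens = read_ensemble(BASE / "ensembles" / f"{name}.pdb")
        m = noe_effective_distances(ens, pairs, threshold=5.5)
        for (a, b), r, obs_flag in zip(m.pairs, m.r_eff, m.observable):
            rows.append({"ensemble": name, "pair": f"{a}|{b}",
                         "r_eff_A": r, "observable": obs_flag})
    tbl = pd.DataFrame(rows)
    tbl.to_csv(OUT / "noe_distances.csv", index=False)
    n_hp = tbl.query("ensemble == 'hairpin_centred'")["observable"].sum()
    n_ex = tbl.query("ensemble == 'extended'")["observable"].sum()
    print(f"\ncross-strand contacts below threshold: hairpin {n_hp}/8, "
          f"extended {n_ex}/8 — only the folded register predicts "
          "observable cross-strand NOEs.")


if __name__ == "__main__":
    main()
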