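#!/usr/bin/env python
"""Cross-link mass-spectrometry contact analysis on synthetic replicates.

Generates five replicate link tables over a tauRD-like 243-380 construct
with a known contact-order distribution, then runs the full downstream
chain: identification filters, 5-of-5 consensus, frequency normalization,
contact-order and repeat binning, and hierarchical clustering of link
patterns across two simulated constructs (one depleted of long-range
contacts, mimicking a destabilized mutant).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ensemblekit.synthetic_data import SyntheticLinkSpec, make_crosslink_tables
from ensemblekit.xlms_contacts import (
    bin_by_repeat,
    classify_contact_order,
    cluster_link_patterns,
    consensus,
    contact_class_summary,
    filter_ids,
    normalize_frequency,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "xlms"
SEED = 2028
# lysine positions of tauRD (2N4R numbering), as in the repeat domain
LYSINES = tuple(range(254, 381, 9))


def build_construct(weights, seed):
    spec = SyntheticLinkSpec(n_res=381, lysines=LYSINES,
                             class_weights=weights, n_replicates=5,
                             n_links_per_rep=2000, seed=seed)
    return make_crosslink_tables(spec)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    wt = build_construct((0.45, 0.35, 0.20), SEED)       # long-range intact
    mut = build_construct((0.60, 0.35, 0.05), SEED + 1)  # long-range depleted

    results = {}
    for name, df in (("wt", wt), ("mut", mut)):
        kept, log = filter_ids(df)
        assert len(kept) == int(df["true_pass"].sum())  # generator bookkeeping
        cs = consensus(kept, n_required=5)
        freq = normalize_frequency(kept)
        props = contact_class_summary(kept)
        print(f"{name}: {log['input']} records, {log['retained']} pass "
              f"filters, {len(cs)} links in 5/5 consensus")
        print(f"  contact classes (local/intermediate/long): "
              f"{np.round(props.to_numpy(), 3)}")
        kept = kept.assign(
            contact_class=[classify_contact_order(a, b)
                           for a, b in zip(kept["pos1"], kept["pos2"])],
            repeat1=[bin_by_repeat(int(p)) for p in kept["pos1"]],
            repeat2=[bin_by_repeat(int(p)) for p in kept["pos2"]],
        )
        kept.to_csv(OUT / f"{name}_filtered.csv", index=False)
        cs.to_csv(OUT / f"{name}_consensus.csv", index=False)
        results[name] = freq.set_index(["pos1", "pos2"])["mean_freq"]

    # construct x link matrix on the union of links, cluster link patterns
    mat = pd.DataFrame(results).T.fillna(0.0)
    mat.columns = [f"{int(a)}-{int(b)}" for a, b in mat.columns]
    lc = cluster_link_patterns(mat, n_groups=4)
    pd.DataFrame({"link": lc.columns, "group": lc.labels}).to_csv(
        OUT / "link_groups.csv", index=False)
    print(f"\nclustered {len(lc.columns)} links into {lc.n_groups} groups "
          "by their per-construct frequency pattern")
    print("long-range contact depletion in the mutant shifts its class "
          "balance toward local links, the signature the contact-order "
          "analysis is designed to expose.")


if __name__ == "__main__":
    main()
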