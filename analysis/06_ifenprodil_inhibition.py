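#!/usr/bin/env python
"""Expected ifenprodil inhibition of the mixed receptor populations.

Weights per-subtype inhibition levels (user-supplied; here the published
per-subtype expectations at 3 uM and -80 mV: 2B-2B 87.2%, 2A-2A 14.8%,
2A-2B 41.4%) by each genotype's predicted subtype proportions.
Requires 02_copy_numbers.py.
"""

import json
from pathlib import Path

import pandas as pd

from nmdar_stoich import assembly, inhibition

OUT = Path("results")

# effectively saturating Hill parameters reproducing the stated
# per-subtype inhibition levels at 3 uM
PER_SUBTYPE = {"2A-2A": 0.148, "2B-2B": 0.872, "2A-2B": 0.414}
PHARM = {
    s: inhibition.SubtypePharmacology(subtype=s, ic50=1e-9, hill=1.0, max_inhibition=v)
    for s, v in PER_SUBTYPE.items()
}


def main() -> None:
    cns = pd.read_csv(OUT / "subunit_cn.tsv", sep="\t")
    payload = {}
    for _, row in cns.iterrows():
        props = assembly.subtype_proportions(row["CN2A"], row["CN2B"])
        mix = inhibition.mixed_population_inhibition(props, PHARM, conc=3.0)
        payload[row["group"]] = {
            "per_subtype": mix.per_subtype,
            "total": mix.total,
        }
        print(f"{row['group']}: expected population inhibition "
              f"{100 * mix.total:.1f}% at 3 uM")
    (OUT / "inhibition.json").write_text(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
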