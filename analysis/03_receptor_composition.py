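#!/usr/bin/env python
"""Receptor assembly model on the estimated subunit copy numbers.

Converts each genotype's relative CN triple into predicted proportions of
GluN1/GluN2A and GluN1/GluN2B diheteromers and GluN1/GluN2A/GluN2B
triheteromers, total receptor content and unassembled fractions, scaled
against the wild-type reference.  Requires 02_copy_numbers.py.
"""

from pathlib import Path

import pandas as pd

from nmdar_stoich import assembly
from nmdar_stoich.containers import SubunitCopyNumbers

OUT = Path("results")


def main() -> None:
    cns = pd.read_csv(OUT / "subunit_cn.tsv", sep="\t")
    subunits = {
        row["group"]: SubunitCopyNumbers(row["group"], row["CN1"], row["CN2A"], row["CN2B"])
        for _, row in cns.iterrows()
    }
    reference = subunits["WT"]
    rows = []
    for group, sub in subunits.items():
        comp = assembly.composition_profile(sub, reference)
        print(f"\n{group}: total receptors {100 * comp.total_vs_reference:.1f}% of WT, "
              f"unassembled GluN2 {100 * comp.unassembled_glun2_fraction:.1f}%")
        for subtype in assembly.SUBTYPES:
            print(f"  {subtype}: {comp.scaled_abundance[subtype]:.1f}% "
                  f"(fold vs WT {comp.fold_changes[subtype]:.2f})")
            rows.append({
                "group": group,
                "subtype": subtype,
                "proportion": comp.proportions.as_dict()[subtype],
                "scaled_percent": comp.scaled_abundance[subtype],
                "fold_vs_reference": comp.fold_changes[subtype],
                "total_vs_reference": comp.total_vs_reference,
                "unassembled_glun2_fraction": comp.unassembled_glun2_fraction,
            })
    pd.DataFrame(rows).to_csv(OUT / "receptor_composition.tsv", sep="\t", index=False)
    print(f"\nwrote {OUT / 'receptor_composition.tsv'}")


if __name__ == "__main__":
    main()
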