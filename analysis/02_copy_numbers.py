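#!/usr/bin/env python
"""Histone-ruler copy numbers from the simulated proteome.

Normalizes total signal, estimates copies per cell, and reports the
relative GluN subunit copy numbers per genotype (wild-type GluN1 = 1).
Requires 01_simulate_cohort.py to have run.
"""

from pathlib import Path

import pandas as pd

from nmdar_stoich import ruler
from nmdar_stoich.containers import IntensityMatrix

DATA = Path("results/data/proteome")
OUT = Path("results")
GENE_MAP = {"Grin1": "GluN1", "Grin2a": "GluN2A", "Grin2b": "GluN2B"}


def main() -> None:
    matrix = IntensityMatrix.from_tsv(DATA / "protein_matrix.tsv", DATA / "sample_sheet.tsv")
    cn = ruler.copies_per_cell(ruler.normalize_total(matrix), dna_mass_per_cell=5.5)
    cn.to_tsv(OUT / "copy_numbers.tsv")
    cns = ruler.relative_subunit_cn(cn, GENE_MAP, reference_group="WT")
    frame = pd.DataFrame(
        [{"group": s.group, "CN1": s.cn1, "CN2A": s.cn2a, "CN2B": s.cn2b} for s in cns]
    )
    frame.to_csv(OUT / "subunit_cn.tsv", sep="\t", index=False)
    print("relative subunit copy numbers (wild-type GluN1 = 1):")
    print(frame.round(3).to_string(index=False))
    print(f"reference GluN1: {cns[0].reference_cn1:.3e} copies per cell")


if __name__ == "__main__":
    main()
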