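#!/usr/bin/env python
"""Permutation-FDR differential abundance on the simulated proteome.

Filters to proteins with >= 3 valid values per genotype, runs the
s0-moderated t-test with SAM-style permutation FDR, and classifies hits
passing both q <= 0.05 and a twofold change.  Requires 01_simulate_cohort.py.
"""

from pathlib import Path

from nmdar_stoich import differential, ruler
from nmdar_stoich.containers import IntensityMatrix

DATA = Path("results/data/proteome")
OUT = Path("results")


def main() -> None:
    matrix = IntensityMatrix.from_tsv(DATA / "protein_matrix.tsv", DATA / "sample_sheet.tsv")
    log2, groups = differential.preprocess(ruler.normalize_total(matrix))
    print(f"{len(log2)} of {len(matrix.intensities)} proteins pass the valid-values filter")
    res = differential.permutation_fdr_ttest(log2, groups, s0=0.1, n_permutations=1000, seed=1)
    n_up, n_down, volcano = differential.classify_hits(res, fc_threshold=2.0, fdr=0.05)
    volcano.reset_index().to_csv(OUT / "volcano.tsv", sep="\t", index=False)
    print(f"hits at q<=0.05 and >=2-fold: {n_up} up, {n_down} down")
    subunit_rows = volcano.loc[volcano.index.str.startswith("SUB_")]
    print("GluN subunit fold changes (HET vs WT):")
    print(subunit_rows[["log2_fc", "q_value", "hit_class"]].round(3).to_string())


if __name__ == "__main__":
    main()
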