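#!/usr/bin/env python
"""Supporting quantifications: truncated-subunit fraction from the GluN2B
peptide regions, ddCt relative expression, and the Sanger allele ratio of
the 1:1 control mixture.  Requires 01_simulate_cohort.py.
"""

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from nmdar_stoich import allele, qpcr, ruler, synthetic

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    # --- GluN2B CTD vs no-CTD regions ---------------------------------
    peptides = pd.read_csv(DATA / "proteome" / "glun2b_peptides.tsv", sep="\t")
    samples = pd.read_csv(DATA / "proteome" / "sample_sheet.tsv", sep="\t")
    by_group = samples.groupby("group")["sample_id"].apply(list)
    regions = {
        g: ruler.region_abundance(peptides, synthetic.CTD_BOUNDARY_RES, gene="Grin2b",
                                  intensity_cols=cols)
        for g, cols in by_group.items()
    }
    trunc = ruler.truncated_fraction(regions["HET"], regions["WT"])
    print(f"estimated truncated GluN2B fraction in HET: {100 * trunc:.1f}%")

    # --- ddCt ----------------------------------------------------------
    ct = pd.read_csv(DATA / "qpcr" / "ct_table.tsv", sep="\t")
    rq = qpcr.delta_delta_ct(ct, ["Grin1", "Grin2a", "Grin2b"], ["Gapdh", "B2m"], "WT")
    frame = qpcr.results_to_frame(rq)
    frame.to_csv(OUT / "qpcr_rq.tsv", sep="\t", index=False)
    print("relative expression (RQ, WT = 1):")
    print(frame.round(3).to_string(index=False))

    # --- allele ratio on the 1:1 control trace -------------------------
    records = list(SeqIO.parse(DATA / "sanger" / "alleles.fasta", "fasta"))
    wt_seq, mut_seq = str(records[0].seq), str(records[1].seq)
    trace = synthetic.ChromatogramTrace.from_tsv(DATA / "sanger" / "trace_1to1.tsv")
    positions = allele.find_informative_positions(wt_seq, mut_seq, max_n=5)
    result = allele.estimate_allele_ratio(trace, positions)
    payload = {
        "ratio": result.ratio,
        "n_positions": result.n_positions,
        "per_position": {str(k): round(v, 4) for k, v in result.per_position_ratios.items()},
        "truncated_fraction": trunc,
    }
    (OUT / "allele_ratio.json").write_text(json.dumps(payload, indent=2))
    print(f"mutant allele fraction of the 1:1 mixture: {100 * result.ratio:.1f}% "
          f"over {result.n_positions} informative positions")


if __name__ == "__main__":
    main()
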