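#!/usr/bin/env python
"""Simulate the study inputs: a 5 vs 5 two-genotype TMT proteome with the
published subunit copy-number ratios, a triplicate qPCR Ct table, and a
1:1 two-allele Sanger trace for the 4-nt insertion.

Writes everything under results/data/.
"""

from pathlib import Path

from nmdar_stoich import synthetic

OUT = Path("results/data")

# allele pair with >= 5 informative positions after the insertion at 10
WT_ALLELE = "GATTGCTGCCCTAAGCTATACTAGGCAGCTGCAGCGTCTGGTTTTACTCAGTGTGATCTT"
MUT_ALLELE = WT_ALLELE[:10] + "TTTT" + WT_ALLELE[10:]


def main() -> None:
    # plant 19 up- and 4 down-regulated proteins at >2-fold, mirroring
    # the hit structure such a cohort is expected to show
    planted = [(f"BG{i:04d}", 4.0) for i in range(19)] + [
        (f"BG{i:04d}", 0.25) for i in range(19, 23)
    ]
    cfg = synthetic.ProteomeSimConfig(seed=20240925, de_proteins=planted)
    matrix, peptides, truth = synthetic.generate_proteome(cfg)
    paths = synthetic.write_proteome(OUT / "proteome", matrix, peptides, truth)
    print(f"proteome: {len(matrix.intensities)} proteins x {len(matrix.samples)} samples")
    print(f"  noise CV {cfg.noise_cv}, missing rate {cfg.missing_rate}")
    for name, p in paths.items():
        print(f"  {name}: {p}")

    ct = synthetic.generate_ct_table(
        {"Grin1": (1.0, 1.0), "Grin2a": (1.0, 1.0), "Grin2b": (1.0, 0.8)},
        sd=0.15, seed=20240925,
    )
    (OUT / "qpcr").mkdir(parents=True, exist_ok=True)
    ct.to_csv(OUT / "qpcr" / "ct_table.tsv", sep="\t", index=False)
    print(f"qPCR: {ct['sample_id'].nunique()} samples x {ct['gene'].nunique()} genes, "
          "planted Grin2b RQ 0.8 in HET")

    trace = synthetic.generate_chromatogram(WT_ALLELE, MUT_ALLELE, mix=0.5, seed=20240925)
    (OUT / "sanger").mkdir(parents=True, exist_ok=True)
    trace.to_tsv(OUT / "sanger" / "trace_1to1.tsv")
    synthetic.write_alleles_fasta(OUT / "sanger" / "alleles.fasta", WT_ALLELE, MUT_ALLELE)
    print("Sanger: 1:1 superposed trace and allele FASTA written")


if __name__ == "__main__":
    main()
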