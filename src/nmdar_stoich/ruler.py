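"""Histone proteomic-ruler copy numbers and region-restricted abundance.

The proteomic ruler estimates protein copies per cell from MS intensities
by anchoring the summed histone signal to the DNA mass of a diploid cell:
histone mass tracks DNA content and therefore cell count, so

    copies_i = (I_i / MW_i) * N_A * m_DNA / sum(I_histones)

per sample, with N_A Avogadro's number and m_DNA the DNA mass per cell.
The default m_DNA of 5.5 pg corresponds to a diploid mouse genome
(~2.7 Gbp haploid x 2 x ~615.9 g/mol per bp / N_A).

The module also quantifies a C-terminally truncated subunit by splitting
a gene's unique-peptide intensities at a residue boundary: peptides ending
at or before the boundary report all protein molecules, peptides starting
after it report only full-length molecules, and the ratio of the two
regions relative to a truncation-free control yields the truncated
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from .containers import CopyNumberTable, IntensityMatrix, SubunitCopyNumbers

#: DNA mass of a diploid mouse cell, picograms.
DEFAULT_DNA_PG = 5.5


def normalize_total(matrix: IntensityMatrix) -> IntensityMatrix:
    """Scale every sample to the mean of the per-sample total intensities.

    Mirrors 'total protein amount' scaling: after normalization all
    samples have the same total signal while within-sample proportions
    are untouched.  Missing values are excluded from the totals.
    """
    totals = matrix.intensities.sum(axis=0, skipna=True)
    bad = totals[~(totals > 0)]
    if len(bad):
        raise ValueError(f"sample(s) with zero or missing total intensity: {list(bad.index)}")
    target = totals.mean()
    scaled = matrix.intensities * (target / totals)
    return matrix.with_intensities(scaled)


def copies_per_cell(
    matrix: IntensityMatrix, dna_mass_per_cell: float = DEFAULT_DNA_PG
) -> CopyNumberTable:
    """Proteomic-ruler copies per cell, per sample.

    ``dna_mass_per_cell`` is in picograms.  Each sample is anchored to its
    own histone total, which makes the estimate invariant to per-sample
    scaling (loading, labeling efficiency).
    """
    if not np.isfinite(dna_mass_per_cell) or dna_mass_per_cell <= 0:
        raise ValueError("dna_mass_per_cell must be > 0 picograms")
    hist_mask = matrix.proteins["is_histone"].to_numpy(dtype=bool)
    if not hist_mask.any():
        raise ValueError("no histone rows: the ruler needs at least one is_histone protein")
    hist_totals = matrix.intensities.loc[hist_mask].sum(axis=0, skipna=True)
    bad = hist_totals[~(hist_totals > 0)]
    if len(bad):
        raise ValueError(f"sample(s) without histone signal: {list(bad.index)}")
    m_dna_grams = dna_mass_per_cell * 1e-12
    mw = matrix.proteins["mw_da"].to_numpy(dtype=float)
    molar = matrix.intensities.div(mw, axis=0)  # I_i / MW_i
    copies = molar.div(hist_totals, axis=1) * (Avogadro * m_dna_grams)
    return CopyNumberTable(
        copies=copies, genes=matrix.proteins["gene"].copy(), sample_groups=matrix.sample_groups
    )


def relative_subunit_cn(
    cn: CopyNumberTable,
    gene_map: dict[str, str],
    reference_group: str,
    aggregate: str = "mean",
) -> list[SubunitCopyNumbers]:
    """Relative GluN subunit copy numbers per group.

    ``gene_map`` maps gene symbols in the table to the subunit roles
    ``GluN1``/``GluN2A``/``GluN2B``.  Per group, each subunit's copy
    number is aggregated across that group's samples (mean by default,
    ``aggregate='median'`` optional) and divided by the reference group's
    GluN1 value, so the reference group reports ``cn1 == 1``.
    """
    roles = {"GluN1", "GluN2A", "GluN2B"}
    if set(gene_map.values()) != roles:
        raise ValueError(f"gene_map must cover exactly the roles {sorted(roles)}")
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    by_role: dict[str, pd.Series] = {}
    for gene, role in gene_map.items():
        rows = cn.genes[cn.genes == gene].index
        if len(rows) == 0:
            raise ValueError(f"subunit gene {gene!r} not present in the copy-number table")
        # several protein entries for one gene are summed (isoform groups)
        by_role[role] = cn.copies.loc[rows].sum(axis=0, min_count=1)

    groups: dict[str, list[str]] = {}
    for sample, grp in cn.sample_groups.items():
        groups.setdefault(grp, []).append(sample)
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} has no samples")

    def agg(series: pd.Series, samples: list[str]) -> float:
        vals = series[samples].dropna()
        if vals.empty:
            raise ValueError("group with no valid copy-number values")
        return float(vals.mean() if aggregate == "mean" else vals.median())

    ref_cn1 = agg(by_role["GluN1"], groups[reference_group])
    if ref_cn1 <= 0:
        raise ValueError("reference GluN1 copy number must be > 0")
    out = []
    for grp, samples in groups.items():
        out.append(
            SubunitCopyNumbers(
                group=grp,
                cn1=agg(by_role["GluN1"], samples) / ref_cn1,
                cn2a=agg(by_role["GluN2A"], samples) / ref_cn1,
                cn2b=agg(by_role["GluN2B"], samples) / ref_cn1,
                reference_cn1=ref_cn1,
            )
        )
    return out


@dataclass(frozen=True)
class RegionAbundance:
    """Summed unique-peptide intensity on both sides of a residue boundary."""

    gene: str
    abundance_no_ctd: float
    abundance_ctd: float
    boundary_res: int

    @property
    def ctd_ratio(self) -> float:
        if self.abundance_no_ctd <= 0:
            raise ValueError("no-CTD abundance is zero; ratio undefined")
        return self.abundance_ctd / self.abundance_no_ctd


def region_abundance(
    peptides: pd.DataFrame,
    boundary_res: int,
    gene: str = "",
    intensity_cols: list[str] | None = None,
) -> RegionAbundance:
    """Split summed peptide intensity at a residue boundary.

    Peptides with ``end_res <= boundary_res`` count toward the no-CTD
    region, peptides with ``start_res > boundary_res`` toward the CTD
    region; peptides straddling the boundary are excluded from both.
    ``intensity_cols`` defaults to every numeric column other than the
    coordinates.
    """
    start = peptides["start_res"].to_numpy(dtype=int)
    end = peptides["end_res"].to_numpy(dtype=int)
    if np.any(end < start):
        raise ValueError("peptide with end_res < start_res")
    if intensity_cols is None:
        intensity_cols = [
            c
            for c in peptides.columns
            if c not in ("start_res", "end_res") and pd.api.types.is_numeric_dtype(peptides[c])
        ]
    vals = peptides[intensity_cols].to_numpy(dtype=float)
    per_pep = np.nansum(vals, axis=1)
    no_ctd = float(per_pep[end <= boundary_res].sum())
    ctd = float(per_pep[start > boundary_res].sum())
    return RegionAbundance(
        gene=gene, abundance_no_ctd=no_ctd, abundance_ctd=ctd, boundary_res=boundary_res
    )


def truncated_fraction(sample: RegionAbundance, control: RegionAbundance) -> float:
    """Fraction of molecules lacking the CTD, relative to a control.

    ``control`` must come from a genotype with no truncated protein; the
    estimate is ``1 - (sample CTD/no-CTD) / (control CTD/no-CTD)``,
    clamped to [0, 1].  A fully truncated pool (sample CTD signal zero)
    returns 1.
    """
    if sample.abundance_no_ctd <= 0 or control.abundance_no_ctd <= 0:
        raise ValueError("no-CTD abundances must be > 0")
    if control.abundance_ctd <= 0:
        raise ValueError("control CTD abundance must be > 0")
    frac = 1.0 - sample.ctd_ratio / control.ctd_ratio
    return float(min(1.0, max(0.0, frac)))
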