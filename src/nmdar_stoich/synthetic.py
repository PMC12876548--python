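"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates every input the analysis consumes: a 16-channel TMT-style
two-genotype hippocampal proteome (histone ruler proteins, GluN subunits
at configurable copy numbers, planted differentially abundant proteins,
multiplicative log-normal noise, missing values), a GluN2B peptide table
whose C-terminal-domain peptides report only full-length molecules, qPCR
Ct tables, and four-channel Sanger traces of superposed alleles.

Construction guarantees the analytical identities the estimators rely on:

* total histone mass per cell is fixed at ``N_A * dna_mass_per_cell`` so
  the proteomic ruler recovers configured copy numbers exactly at zero
  noise;
* background protein abundances are scaled so histones carry exactly
  ``histone_fraction`` of the reference group's noiseless total signal;
* CTD-region peptide signal in the second group is scaled by
  ``1 - truncated_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from .containers import IntensityMatrix

# Approximate molecular weights (Da) of the simulated ruler histones and
# GluN subunits (mouse H2A/H2B/H3/H4 and Grin1/Grin2a/Grin2b products).
HISTONE_MW = {"H2A": 14135.0, "H2B": 13906.0, "H3": 15404.0, "H4": 11367.0}
SUBUNIT_MW = {"Grin1": 105510.0, "Grin2a": 165281.0, "Grin2b": 165879.0}

#: First residue of the simulated GluN2B C-terminal domain region; unique
#: peptides ending at or before residue 768 report both alleles.
CTD_BOUNDARY_RES = 768

#: GluN2B protein length used to lay out simulated peptides.
GLUN2B_LENGTH = 1482


@dataclass
class ProteomeSimConfig:
    """Study conditions for the simulated two-genotype TMT proteome.

    Defaults emulate the source study's design: 5 vs 5 hippocampal
    samples, GluN subunit copies in the wild-type ratios 1.00 : 0.79 :
    1.02 (GluN1 anchored at 1e6 copies per cell) against the mutant
    ratios 0.91 : 0.95 : 0.63, and a near-absent truncated GluN2B
    protein (1%).
    """

    n_per_group: int = 5
    n_background_proteins: int = 1000
    histone_fraction: float = 0.05
    subunit_copies: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "Grin1": (1.00e6, 0.91e6),
            "Grin2a": (0.79e6, 0.95e6),
            "Grin2b": (1.02e6, 0.63e6),
        }
    )
    truncated_fraction: float = 0.01
    de_proteins: list[tuple[str, float]] = field(default_factory=list)
    noise_cv: float = 0.1
    missing_rate: float = 0.01
    dna_mass_per_cell: float = 5.5  # picograms, diploid mouse genome
    loading_cv: float = 0.05  # per-sample loading spread (scale-invariant downstream)
    group_names: tuple[str, str] = ("WT", "HET")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_background_proteins < 0:
            raise ValueError("n_background_proteins must be >= 0")
        if not 0.0 < self.histone_fraction < 1.0:
            raise ValueError("histone_fraction must be in (0, 1)")
        for gene, pair in self.subunit_copies.items():
            for v in pair:
                if not np.isfinite(v) or v < 0:
                    raise ValueError(f"subunit_copies[{gene!r}] must be finite and >= 0")
        if not 0.0 <= self.truncated_fraction <= 1.0:
            raise ValueError("truncated_fraction must be in [0, 1]")
        for pid, fold in self.de_proteins:
            if not np.isfinite(fold) or fold <= 0:
                raise ValueError(f"de_proteins fold for {pid!r} must be > 0")
        if not np.isfinite(self.noise_cv) or self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not np.isfinite(self.dna_mass_per_cell) or self.dna_mass_per_cell <= 0:
            raise ValueError("dna_mass_per_cell must be > 0 picograms")
        if not np.isfinite(self.loading_cv) or self.loading_cv < 0:
            raise ValueError("loading_cv must be >= 0")


@dataclass(frozen=True)
class ProteomeGroundTruth:
    """What was actually planted, for downstream tests."""

    copies: pd.DataFrame  # protein x group true copies per cell
    de_folds: dict[str, float]  # planted group2/group1 fold changes
    truncated_fraction: float
    histone_ids: list[str]
    subunit_ids: dict[str, str]  # gene -> protein_id


def _lognormal_noise(rng: np.random.Generator, cv: float, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def generate_proteome(
    config: ProteomeSimConfig,
) -> tuple[IntensityMatrix, pd.DataFrame, ProteomeGroundTruth]:
    """Simulate the protein matrix, the GluN2B peptide table and the truth.

    Per-sample intensity of each protein is ``copies x MW x sample scale
    x log-normal noise``; the four histones jointly carry
    ``histone_fraction`` of the reference group's noiseless signal, and
    their summed mass per cell equals ``N_A x dna_mass_per_cell`` so the
    histone ruler is exact by construction.
    """
    rng = np.random.default_rng(config.seed)
    m_dna_da = Avogadro * config.dna_mass_per_cell * 1e-12  # grams -> daltons

    # --- histones: fixed mass budget, split unevenly across the four ---
    hist_genes = list(HISTONE_MW)
    hist_share = np.array([0.30, 0.28, 0.24, 0.18])
    hist_mw = np.array([HISTONE_MW[g] for g in hist_genes])
    hist_copies = hist_share * m_dna_da / hist_mw

    # --- subunits ------------------------------------------------------
    sub_genes = list(config.subunit_copies)
    sub_mw = np.array([SUBUNIT_MW.get(g, 1.2e5) for g in sub_genes])
    sub_copies = np.array([config.subunit_copies[g] for g in sub_genes], dtype=float)

    # --- background: scaled so histones carry histone_fraction ---------
    n_bg = config.n_background_proteins
    bg_mw = np.exp(rng.normal(11.0, 0.45, size=n_bg)).clip(8e3, 6e5)
    bg_rel = np.exp(rng.normal(0.0, 1.4, size=n_bg))
    hist_mass = m_dna_da
    target_nonhist_mass = hist_mass * (1.0 - config.histone_fraction) / config.histone_fraction
    sub_mass_ref = float((sub_copies[:, 0] * sub_mw).sum())
    bg_budget = target_nonhist_mass - sub_mass_ref
    if bg_budget < 0:
        raise ValueError("histone_fraction too large for the configured subunit copies")
    bg_mass = bg_rel * bg_mw
    bg_copies_ref = bg_rel * (bg_budget / bg_mass.sum()) if n_bg else bg_rel

    # --- assemble the true copies table --------------------------------
    de_folds = dict(config.de_proteins)
    ids = (
        [f"HIST_{g}" for g in hist_genes]
        + [f"SUB_{g}" for g in sub_genes]
        + [f"BG{i:04d}" for i in range(n_bg)]
    )
    genes = hist_genes + sub_genes + [f"bg{i:04d}" for i in range(n_bg)]
    mw = np.concatenate([hist_mw, sub_mw, bg_mw])
    is_hist = np.array([True] * len(hist_genes) + [False] * (len(sub_genes) + n_bg))
    copies_g1 = np.concatenate([hist_copies, sub_copies[:, 0], bg_copies_ref])
    copies_g2 = np.concatenate([hist_copies, sub_copies[:, 1], bg_copies_ref.copy()])
    unknown = set(de_folds) - set(ids)
    if unknown:
        raise ValueError(f"de_proteins reference unknown protein ids: {sorted(unknown)}")
    id_pos = {pid: k for k, pid in enumerate(ids)}
    for pid, fold in de_folds.items():
        copies_g2[id_pos[pid]] *= fold

    # --- samples -------------------------------------------------------
    g1, g2 = config.group_names
    n = config.n_per_group
    sample_ids = [f"{g1}_{i + 1}" for i in range(n)] + [f"{g2}_{i + 1}" for i in range(n)]
    group_labels = [g1] * n + [g2] * n
    scales = _lognormal_noise(rng, config.loading_cv, (2 * n,))

    true_copies = np.column_stack([copies_g1] * n + [copies_g2] * n)
    noise = _lognormal_noise(rng, config.noise_cv, true_copies.shape)
    intens = true_copies * mw[:, None] * scales[None, :] * noise
    if config.missing_rate > 0:
        mask = rng.random(intens.shape) < config.missing_rate
        intens = np.where(mask, np.nan, intens)

    proteins = pd.DataFrame(
        {"gene": genes, "mw_da": mw, "is_histone": is_hist}, index=pd.Index(ids, name="protein_id")
    )
    intensities = pd.DataFrame(intens, index=proteins.index, columns=sample_ids)
    sample_groups = pd.Series(group_labels, index=pd.Index(sample_ids, name="sample_id"))
    matrix = IntensityMatrix(proteins, intensities, sample_groups)

    peptides = _glun2b_peptides(config, rng, scales, sample_ids)

    truth = ProteomeGroundTruth(
        copies=pd.DataFrame(
            {g1: copies_g1, g2: copies_g2}, index=proteins.index
        ),
        de_folds=de_folds,
        truncated_fraction=config.truncated_fraction,
        histone_ids=[f"HIST_{g}" for g in hist_genes],
        subunit_ids={g: f"SUB_{g}" for g in sub_genes},
    )
    return matrix, peptides, truth


def _glun2b_peptides(
    config: ProteomeSimConfig,
    rng: np.random.Generator,
    scales: np.ndarray,
    sample_ids: list[str],
) -> pd.DataFrame:
    """Unique GluN2B peptides on both sides of the CTD boundary.

    Peptide signal follows the GluN2B copy number of each sample's group;
    CTD-region peptides (start > boundary) in the second group are scaled
    by ``1 - truncated_fraction`` because truncated molecules lack that
    region.  One peptide deliberately straddles the boundary.
    """
    bounds: list[tuple[int, int]] = []
    pos = 28  # mature chain after the signal peptide
    while pos + 40 <= CTD_BOUNDARY_RES - 20:  # no-CTD region peptides
        ln = int(rng.integers(8, 25))
        bounds.append((pos, pos + ln - 1))
        pos += ln + int(rng.integers(20, 60))
    bounds.append((CTD_BOUNDARY_RES - 6, CTD_BOUNDARY_RES + 7))  # straddler
    pos = CTD_BOUNDARY_RES + 10
    while pos + 30 <= GLUN2B_LENGTH:  # CTD peptides
        ln = int(rng.integers(8, 25))
        bounds.append((pos, pos + ln - 1))
        pos += ln + int(rng.integers(30, 80))
    starts = np.array([b[0] for b in bounds])
    ends = np.array([b[1] for b in bounds])
    # per-peptide response factors (ionization efficiency), fixed across samples
    response = np.exp(rng.normal(0.0, 0.8, size=len(bounds)))

    cn2b = config.subunit_copies.get("Grin2b", (0.0, 0.0))
    n = config.n_per_group
    per_sample_cn = np.array([cn2b[0]] * n + [cn2b[1]] * n)
    signal = response[:, None] * per_sample_cn[None, :] * scales[None, :]
    ctd_pep = starts > CTD_BOUNDARY_RES
    keep = np.ones_like(signal)
    keep[np.ix_(ctd_pep, np.arange(n, 2 * n))] = 1.0 - config.truncated_fraction
    signal = signal * keep * _lognormal_noise(rng, config.noise_cv, signal.shape)

    table = pd.DataFrame(signal, columns=sample_ids)
    table.insert(0, "peptide_id", [f"GluN2B_pep{k:02d}" for k in range(len(bounds))])
    table.insert(1, "start_res", starts)
    table.insert(2, "end_res", ends)
    return table


# --------------------------------------------------------------------------
# Sanger chromatograms
# --------------------------------------------------------------------------

BASES = ("A", "C", "G", "T")


@dataclass
class ChromatogramTrace:
    """Four-channel trace sampled at ``samples_per_base`` points per base."""

    channels: dict[str, np.ndarray]
    samples_per_base: int

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if set(self.channels) != set(BASES) or len(lengths) != 1:
            raise ValueError("trace needs four equal-length channels keyed A/C/G/T")
        for base, arr in self.channels.items():
            if np.any(arr < 0):
                raise ValueError(f"channel {base} has negative amplitudes")

    @property
    def n_positions(self) -> int:
        return len(self.channels["A"]) // self.samples_per_base

    def window(self, position: int) -> slice:
        """Base-call window (one base spacing wide) around a position."""
        spb = self.samples_per_base
        lo = position * spb
        return slice(max(lo, 0), lo + spb)

    def peak_amplitude(self, position: int, base: str, mode: str = "max") -> float:
        """Channel maximum (or integrated area) inside the call window."""
        seg = self.channels[base][self.window(position)]
        if mode == "max":
            return float(seg.max())
        if mode == "area":
            return float(seg.sum() / self.samples_per_base)
        raise ValueError("mode must be 'max' or 'area'")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({b: self.channels[b] for b in BASES})
        df.insert(0, "sample_index", np.arange(len(df)))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, samples_per_base: int = 10) -> "ChromatogramTrace":
        df = pd.read_csv(path, sep="\t")
        return cls(
            channels={b: df[b].to_numpy(dtype=float) for b in BASES},
            samples_per_base=samples_per_base,
        )


def _render_allele(
    seq: str, length: int, samples_per_base: int, peak_width: float
) -> dict[str, np.ndarray]:
    spb = samples_per_base
    x = np.arange(length * spb, dtype=float)
    sigma = peak_width * spb
    channels = {b: np.zeros(length * spb) for b in BASES}
    for j, base in enumerate(seq):
        center = j * spb + spb // 2  # on-sample center: peak maximum is exact
        channels[base] += np.exp(-0.5 * ((x - center) / sigma) ** 2)
    return channels


def generate_chromatogram(
    wt_seq: str,
    mut_seq: str,
    mix: float,
    peak_width: float = 0.18,
    seed: int = 0,
    samples_per_base: int = 10,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
) -> ChromatogramTrace:
    """Superposed two-allele trace: ``(1-mix)*wt + mix*mut``.

    Each allele is rendered as one Gaussian peak per base in that base's
    channel, with unit spacing between base positions; downstream of an
    insertion the mutant register is shifted, so heterozygous double
    peaks appear naturally.  ``peak_width`` is the Gaussian sigma in base
    units, small enough by default that neighboring peaks do not bleed.
    """
    if not 0.0 <= mix <= 1.0:
        raise ValueError("mix must be in [0, 1]")
    if peak_width <= 0:
        raise ValueError("peak_width must be > 0")
    for name, seq in (("wt_seq", wt_seq), ("mut_seq", mut_seq)):
        bad = set(seq.upper()) - set(BASES)
        if bad:
            raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")
    wt_seq, mut_seq = wt_seq.upper(), mut_seq.upper()
    length = max(len(wt_seq), len(mut_seq))
    wt = _render_allele(wt_seq, length, samples_per_base, peak_width)
    mut = _render_allele(mut_seq, length, samples_per_base, peak_width)
    rng = np.random.default_rng(seed)
    channels = {}
    for b in BASES:
        trace = (1.0 - mix) * wt[b] + mix * mut[b] + baseline
        if noise_sd > 0:
            trace = np.clip(trace + rng.normal(0.0, noise_sd, size=trace.shape), 0.0, None)
        channels[b] = trace
    return ChromatogramTrace(channels=channels, samples_per_base=samples_per_base)


# --------------------------------------------------------------------------
# qPCR Ct tables
# --------------------------------------------------------------------------

DEFAULT_HOUSEKEEPERS = ("Gapdh", "B2m")


def generate_ct_table(
    rq_map: dict[str, tuple[float, float]],
    base_ct: float = 22.0,
    sd: float = 0.0,
    n_triplicates: int = 3,
    n_per_group: int = 5,
    seed: int = 0,
    housekeepers: tuple[str, ...] = DEFAULT_HOUSEKEEPERS,
    group_names: tuple[str, str] = ("WT", "HET"),
) -> pd.DataFrame:
    """Long-format Ct table: one row per sample x gene x replicate.

    ``Ct = base_ct - log2(expression) + N(0, sd)`` with target expression
    proportional to the gene's true relative quantity in each group.
    Housekeeper genes always have relative quantity 1 in both groups.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n_triplicates < 1:
        raise ValueError("n_triplicates must be >= 1")
    rng = np.random.default_rng(seed)
    expr = {g: dict(zip(group_names, pair)) for g, pair in rq_map.items()}
    for hk in housekeepers:
        expr[hk] = {g: 1.0 for g in group_names}
    rows = []
    for group in group_names:
        for i in range(n_per_group):
            sample = f"{group}_{i + 1}"
            for gene, per_group in expr.items():
                rq = per_group[group]
                if rq <= 0:
                    raise ValueError(f"relative quantity for {gene!r} must be > 0")
                ct0 = base_ct - np.log2(rq)
                for rep in range(n_triplicates):
                    ct = ct0 + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                    rows.append((sample, group, gene, rep + 1, ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "replicate", "ct"])


# --------------------------------------------------------------------------
# TSV writers
# --------------------------------------------------------------------------

def write_proteome(
    out_dir: str | Path,
    matrix: IntensityMatrix,
    peptides: pd.DataFrame,
    truth: ProteomeGroundTruth | None = None,
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "protein_matrix.tsv",
        "samples": out / "sample_sheet.tsv",
        "peptides": out / "glun2b_peptides.tsv",
    }
    matrix.to_tsv(paths["matrix"], paths["samples"])
    peptides.to_csv(paths["peptides"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = out / "ground_truth_copies.tsv"
        truth.copies.rename_axis("protein_id").reset_index().to_csv(
            paths["truth"], sep="\t", index=False
        )
    return paths


def write_alleles_fasta(path: str | Path, wt_seq: str, mut_seq: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(wt_seq), id="wt_allele", description="wild-type allele"),
        SeqRecord(Seq(mut_seq), id="mut_allele", description="insertion allele"),
    ]
    SeqIO.write(records, str(path), "fasta")
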