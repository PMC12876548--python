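# Methods

This note documents the models behind each module, the parameters that
matter, what the synthetic data does and does not emulate, and the
design choices made where the procedure admitted more than one sensible
reading.

## Receptor assembly model

An NMDAR is modeled as two obligatory GluN1 subunits plus two GluN2
positions filled independently at random from the GluN2A/GluN2B pool,
with equal preference and with GluN2C/D and GluN3 treated as negligible.
Writing P₂A = CN₂A/(CN₂A+CN₂B), the assembled population is

- P₂A−₂A = P₂A², P₂B−₂B = P₂B², P₂A−₂B = 2·P₂A·P₂B (the factor 2
  because 2A−2B and 2B−2A orders give the same receptor);
- total receptors R = min(CN₁/2, (CN₂A+CN₂B)/2) — assembly consumes the
  limiting pool entirely;
- the surplus pool's unassembled fraction is (pool − 2R)/pool; by
  construction at most one of the GluN1/GluN2 fractions is positive.

**Reference scaling.** Cross-genotype comparisons express each
subtype's abundance as percent of the *reference* group's total:
`scaled(s) = 100 · P_s · R/R_ref`.  Scaled abundances therefore sum to
`100 · R/R_ref`, and fold changes are ratios of scaled abundances.  This
normalization is stated explicitly here because it is what makes subtype
percentages comparable across genotypes with different receptor totals.

**Stochastic oracle.** `simulate_random_assembly` draws receptor pairs
without replacement from a finite GluN2 pool sized so that the continuum
model's assembled fraction is respected.  It converges to the closed
forms as the pool grows (verified at 10⁶ receptors within 3 binomial
standard errors); at small pools, without-replacement sampling deviates
from the squared-proportion formulas, which is expected and is why the
tests demonstrate convergence, not equality, at small n.

**Degenerate inputs.** CN₂A+CN₂B = 0 raises an error rather than
propagating NaN; zero-receptor reference groups are rejected.

**Tolerances.** Published copy-number inputs are printed rounded to two
decimals while the original percentages were computed from unrounded
means; all comparisons against published percentages therefore use a
±0.5 percentage-point band (e.g. the total-receptor reduction recomputes
to 9.0% from (0.91, 0.95, 0.63) vs (1.00, 0.79, 1.02), against a
published 8.6%).

## Histone proteomic ruler

Copies per cell: `copies_i = (I_i/MW_i) · N_A · m_DNA / Σ I_hist`, per
sample, anchored to each sample's own histone total — hence invariant to
per-sample scaling.  Defaults: `m_DNA` = 5.5 pg (diploid mouse genome,
~2.7 Gbp haploid × 2 × ~615.9 g/mol/bp / N_A), configurable since the
appropriate constant depends on organism and ploidy.  Total-signal
normalization (every sample scaled to the mean total) is applied before
the ruler; it changes nothing for the ruler itself but standardizes
downstream differential analysis.  Group aggregation uses the
arithmetic mean of per-sample copies before ratio formation (median
offered); missing intensities are excluded pairwise, not imputed.

**Region-restricted quantification.** The truncated-subunit estimate
splits unique peptides at a residue boundary (GluN2B CTD boundary:
residue 768, CTD peptides start ≥ 769).  Peptides straddling the
boundary are excluded from both regions — the conservative reading,
since a straddler's signal is ambiguous between alleles.  The truncated
fraction is `1 − (CTD/no-CTD)_sample / (CTD/no-CTD)_control`, clamped to
[0, 1]; the control must come from a truncation-free genotype, which
cancels region-specific detection efficiency.  The caller must supply
peptide coordinates in the same numbering as the boundary (full-length
numbering including the signal peptide is used throughout here).

## Differential abundance

Perseus-style: contaminant prefixes removed, log2 transform, and a
valid-values filter requiring ≥ 3 non-missing values **in each** group —
the reading needed for a two-sample test; the "in at least one group"
alternative is available via `min_valid_mode='any'`.  The statistic is
`t = (m₂ − m₁)/(pooled SE + s0)` with s0 = 0.1 by default (Perseus-style
fudge factor; s0 = 0 gives the plain t-test).

The FDR is estimated from group-label permutations: all distinct
balanced assignments, identity excluded and sign-mirrors collapsed.  For
a 5 vs 5 design only C(10,5)/2 − 1 = 125 distinct permutations exist, so
the nominal default of 1000 permutations collapses to full enumeration
with a logged notice.  The q-value of a protein is the median across
permutations of the pooled count of null |t*| at least as large,
divided by the observed rank of |t|, then made monotone non-increasing
in |t| (suffix minimum, as in Benjamini–Hochberg) and clamped to [0, 1].
Per-protein permutation p-values `(b + 1)/(B + 1)` are also reported and
match exhaustive enumeration exactly on small designs.

## ΔΔCt qPCR

Technical replicates are averaged to one Ct per sample × gene; ΔCt
subtracts the arithmetic mean Ct of the housekeepers (equivalent to a
geometric mean of their expression — the natural reading of "normalized
to the levels of" two genes); ΔΔCt subtracts the reference group's mean
ΔCt; RQ = 2^(−ΔΔCt) assumes ideal doubling per cycle
(efficiency-corrected variants are out of scope).  Group RQ averages
per-sample RQ (averaging ΔCt first is available via `aggregate='dct'`;
the two differ only under noise, by Jensen's inequality).

## Allele ratio from chromatograms

The mutant allele fraction is read at *informative positions*: scanning
downstream of the alleles' divergence point, position i qualifies when
the two alleles call different bases there and the set
{wt(i), mut(i)} is disjoint from every base either allele calls at
i−1 and i+1.  This operationalizes "not surrounded by identical
nucleotides": a peak whose base recurs next door would inherit amplitude
from its neighbor's tail.  Amplitude is the channel maximum inside a
one-base-spacing call window (area integration optional); the ratio at
each position is A_mut/(A_mut + A_wt), and the reported estimate is the
arithmetic mean over at most `max_n` (default 5) positions, oriented as
the mutant share.  On noiseless synthetic traces with default peak
width the estimate equals the mixing fraction to < 1e−6.

## Mixed-population antagonist inhibition

Each subtype follows `vi(c) = max_inh · cʰ/(cʰ + IC50ʰ)`; the optional
voltage-dependent component combines by the multiplicative survival
rule `1 − (1 − vd)(1 − vi)` (independent block events), with the
additive-capped alternative `min(1, vd + vi)` selectable since a
"sum" of the two components does not fix the algebra.  Population
inhibition is the proportion-weighted mean over subtypes, assuming
equal single-channel current and open probability unless explicit
weights are supplied.  Per-subtype IC50/Hill/max values are user
inputs; they are not derivable from copy numbers.

## Synthetic data: what it emulates and what it does not

`generate_proteome` emulates a 16-channel TMT-style two-genotype design:
5 vs 5 samples; four histone proteins; three GluN subunits at
configurable copies per cell (defaults: wild type 1.00/0.79/1.02 × 10⁶
for GluN1/GluN2A/GluN2B, mutant 0.91/0.95/0.63 × 10⁶ — the relative
abundances such hippocampal tissue shows, anchored at a plausible 10⁶
GluN1 copies per neuron); ~1000 background proteins with log-normal
abundance and molecular weight; per-sample loading factors (5% CV);
multiplicative log-normal measurement noise (default CV 10%, a typical
between-replicate spread for TMT reporter intensities); and
missing-completely-at-random dropout (default 1%).

Two identities hold by construction: total histone mass per cell equals
`N_A · m_DNA` (the ruler's anchoring assumption), so the ruler recovers
configured copies exactly at zero noise; and the histones carry exactly
`histone_fraction` (default 5%) of the reference group's noiseless
total signal.  The GluN2B peptide table tiles both sides of the CTD
boundary, includes one deliberate straddler, and scales CTD-peptide
signal in the second group by `1 − truncated_fraction` (default 1%, a
near-absent truncated protein).

Not emulated: intensity-dependent (left-censored) missingness, isotopic
impurity/ratio compression, peptide-level identification error,
spectrum-level effects, and correlated protein co-regulation.  Passing
tests therefore show the estimators are correct under multiplicative
log-normal noise with MCAR dropout, not that they are robust to every
artifact of real TMT data.

Chromatograms are rendered as one Gaussian peak per base per allele
(sigma 0.18 base spacings, 10 trace samples per base, peaks centered on
a sample), superposed as `(1 − mix)·wt + mix·mut`, with optional
baseline and additive noise; dye cross-talk and mobility shifts are not
modeled.  Ct tables use `Ct = base_ct − log2(expression) + N(0, sd)`
with housekeepers fixed at expression 1.

## Problem sizes

Test and driver runs use 10⁶ receptors for the Monte Carlo oracle,
100 seeded replicates for the noisy-ruler bias check, and 20 seeded
replicates of 1000-protein matrices for the null/planted FDR
properties — sizes at which the binomial/Monte-Carlo error bands in the
assertions are meaningfully tight while the whole suite stays fast.

## Known limitations

- The assembly model ignores preferential triheteromer assembly,
  compartment (synaptic vs extrasynaptic) differences, and kinetic
  assembly; it is a stoichiometric bound, not a trafficking model.
- The ruler's absolute copies inherit the uncertainty of `m_DNA` and of
  histone quantification; relative copy numbers are the robust output.
- SAM-style global FDR assumes exchangeability of samples under the
  null within the permutation family; strong per-sample batch effects
  would need explicit modeling.
- The allele-ratio estimator assumes comparable incorporation
  efficiency of the dye terminators across channels; real traces need
  the 1:1 plasmid control for calibration, which is why the control
  ratio is part of the workflow.
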