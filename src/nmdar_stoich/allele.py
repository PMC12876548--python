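"""Allele ratios from superposed Sanger chromatograms.

A heterozygous insertion shifts the mutant reading register, so every
downstream position of a direct-sequenced amplicon shows two superposed
peaks, one per allele.  At *informative* positions -- where the two
alleles call different bases and neither base recurs in the immediately
adjacent calls of either allele (which would bias peak amplitudes by
bleed-through) -- the mutant-channel share of the summed peak amplitude
estimates the mutant allele fraction.  The reported ratio is the mean
over the selected positions, oriented as mutant / (mutant + wild type).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .synthetic import ChromatogramTrace

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InformativePosition:
    index: int  # 0-based trace position
    wt_base: str
    mut_base: str

    def __post_init__(self) -> None:
        if self.wt_base == self.mut_base:
            raise ValueError("informative position requires differing allele bases")


@dataclass(frozen=True)
class AlleleRatioResult:
    ratio: float  # mutant / (mutant + wild type), mean over positions
    per_position_ratios: dict[int, float]
    n_positions: int


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def find_informative_positions(
    wt_seq: str, mut_seq: str, max_n: int = 5
) -> list[InformativePosition]:
    """Scan downstream of the divergence point for unbiased positions.

    A candidate position i qualifies when the two alleles' bases differ
    and the set {wt(i), mut(i)} is disjoint from the bases either allele
    calls at positions i-1 and i+1.  Scanning stops after ``max_n``
    positions.
    """
    wt_seq, mut_seq = wt_seq.upper(), mut_seq.upper()
    if wt_seq == mut_seq:
        return []
    divergence = _common_prefix_len(wt_seq, mut_seq)
    limit = min(len(wt_seq), len(mut_seq))
    found: list[InformativePosition] = []
    for i in range(divergence, limit):
        if wt_seq[i] == mut_seq[i]:
            continue
        here = {wt_seq[i], mut_seq[i]}
        neighbors = set()
        for j in (i - 1, i + 1):
            if 0 <= j < limit:
                neighbors.update((wt_seq[j], mut_seq[j]))
            elif 0 <= j < len(wt_seq):
                neighbors.add(wt_seq[j])
            elif 0 <= j < len(mut_seq):
                neighbors.add(mut_seq[j])
        if here & neighbors:
            continue
        found.append(InformativePosition(index=i, wt_base=wt_seq[i], mut_base=mut_seq[i]))
        if len(found) >= max_n:
            break
    if not found:
        logger.info("no informative position found downstream of the divergence")
    return found


def estimate_allele_ratio(
    trace: ChromatogramTrace,
    positions: list[InformativePosition],
    mode: str = "max",
) -> AlleleRatioResult:
    """Mean mutant-allele share of the peak amplitudes at the positions.

    Per position the ratio is ``A_mut / (A_mut + A_wt)`` with amplitudes
    read as the channel maximum (or ``mode='area'``, the integrated
    signal) inside the base-call window.  Positions where both channels
    are flat are dropped with a notice; if all are dropped the estimate
    is undefined.
    """
    if not positions:
        raise ValueError("no informative positions supplied")
    if any(p.index >= trace.n_positions for p in positions):
        raise ValueError("trace does not cover all requested positions")
    per_position: dict[int, float] = {}
    for pos in positions:
        a_mut = trace.peak_amplitude(pos.index, pos.mut_base, mode=mode)
        a_wt = trace.peak_amplitude(pos.index, pos.wt_base, mode=mode)
        if a_mut + a_wt <= 0:
            logger.info("position %d dropped: both channel amplitudes are zero", pos.index)
            continue
        per_position[pos.index] = a_mut / (a_mut + a_wt)
    if not per_position:
        raise ValueError("all positions dropped: no peak signal in either channel")
    ratio = sum(per_position.values()) / len(per_position)
    return AlleleRatioResult(
        ratio=ratio, per_position_ratios=per_position, n_positions=len(per_position)
    )
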