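"""Random-assembly model of NMDA-receptor subunit composition.

An NMDA receptor is a tetramer of two obligatory GluN1 subunits plus two
GluN2 subunits drawn from the available GluN2A/GluN2B pool.  Under the
assumptions that (i) GluN2A and GluN2B occupy the two GluN2 positions at
random with equal preference and (ii) subunits assemble until the limiting
pool (GluN1 or GluN2) is exhausted, the subtype proportions follow from
the relative copy numbers alone:

    P_2A      = CN_2A / (CN_2A + CN_2B)
    P_2A-2A   = P_2A**2
    P_2B-2B   = P_2B**2
    P_2A-2B   = 2 * P_2A * P_2B      (2A-2B and 2B-2A are the same receptor)

and the number of assembled receptors is min(CN_1/2, (CN_2A + CN_2B)/2).
Whichever pool is in excess leaves a corresponding unassembled fraction.
A finite-pool Monte Carlo sampler is provided as a stochastic cross-check
of the closed forms.

GluN2C/D and GluN3 subunits are treated as negligible and have no slot in
the data model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import SubunitCopyNumbers

#: Canonical subtype labels, GluN1 pair implied.
SUBTYPES = ("2A-2A", "2B-2B", "2A-2B")


@dataclass(frozen=True)
class SubtypeProportions:
    """Proportions of GluN2 occupancy and of assembled receptor subtypes."""

    p2a: float
    p2b: float
    p2a2a: float
    p2b2b: float
    p2a2b: float

    def as_dict(self) -> dict[str, float]:
        return {"2A-2A": self.p2a2a, "2B-2B": self.p2b2b, "2A-2B": self.p2a2b}


@dataclass(frozen=True)
class ReceptorComposition:
    """Receptor content of one group, scaled against a reference group."""

    group: str
    proportions: SubtypeProportions
    total_receptors: float
    unassembled_glun2_fraction: float
    unassembled_glun1_fraction: float
    total_vs_reference: float
    scaled_abundance: dict[str, float]  # percent of the reference total
    fold_changes: dict[str, float]  # vs the reference group's subtype share


def subtype_proportions(cn2a: float, cn2b: float) -> SubtypeProportions:
    """Closed-form subtype proportions from GluN2A/GluN2B copy numbers."""
    _check_nonneg(cn2a=cn2a, cn2b=cn2b)
    total = cn2a + cn2b
    if total <= 0:
        raise ValueError("cn2a + cn2b must be > 0: no GluN2 pool to assemble from")
    p2a = cn2a / total
    p2b = cn2b / total
    return SubtypeProportions(
        p2a=p2a, p2b=p2b, p2a2a=p2a**2, p2b2b=p2b**2, p2a2b=2.0 * p2a * p2b
    )


def total_receptors(cn1: float, cn2a: float, cn2b: float) -> float:
    """Assembled receptor count: min of GluN1 pairs and GluN2 pairs."""
    _check_nonneg(cn1=cn1, cn2a=cn2a, cn2b=cn2b)
    return min(cn1 / 2.0, (cn2a + cn2b) / 2.0)


def unassembled_fractions(cn1: float, cn2a: float, cn2b: float) -> tuple[float, float]:
    """Fractions of the GluN2 and GluN1 pools left over after assembly.

    Returns ``(glun2_fraction, glun1_fraction)``; at most one is positive
    because assembly stops when the limiting pool runs out.
    """
    _check_nonneg(cn1=cn1, cn2a=cn2a, cn2b=cn2b)
    if cn1 + cn2a + cn2b <= 0:
        raise ValueError("all copy numbers are zero")
    r = total_receptors(cn1, cn2a, cn2b)
    n2 = cn2a + cn2b
    glun2 = (n2 - 2.0 * r) / n2 if n2 > 0 else 0.0
    glun1 = (cn1 - 2.0 * r) / cn1 if cn1 > 0 else 0.0
    return max(glun2, 0.0), max(glun1, 0.0)


def composition_profile(
    subunits: SubunitCopyNumbers, reference: SubunitCopyNumbers
) -> ReceptorComposition:
    """Receptor composition of ``subunits`` scaled to a reference group.

    Subtype abundances are expressed as percent of the *reference* total
    receptor count, so within the reference group they sum to 100 and in
    another group to ``100 * total_vs_reference``.  Fold changes compare
    each subtype's scaled abundance with the reference's own share.
    """
    ref_total = total_receptors(reference.cn1, reference.cn2a, reference.cn2b)
    if ref_total <= 0:
        raise ValueError("reference group assembles zero receptors")
    props = subtype_proportions(subunits.cn2a, subunits.cn2b)
    ref_props = subtype_proportions(reference.cn2a, reference.cn2b)
    total = total_receptors(subunits.cn1, subunits.cn2a, subunits.cn2b)
    ratio = total / ref_total
    glun2_un, glun1_un = unassembled_fractions(subunits.cn1, subunits.cn2a, subunits.cn2b)
    scaled = {s: 100.0 * p * ratio for s, p in props.as_dict().items()}
    ref_scaled = {s: 100.0 * p for s, p in ref_props.as_dict().items()}
    folds = {s: scaled[s] / ref_scaled[s] if ref_scaled[s] > 0 else math.inf for s in SUBTYPES}
    return ReceptorComposition(
        group=subunits.group,
        proportions=props,
        total_receptors=total,
        unassembled_glun2_fraction=glun2_un,
        unassembled_glun1_fraction=glun1_un,
        total_vs_reference=ratio,
        scaled_abundance=scaled,
        fold_changes=folds,
    )


@dataclass(frozen=True)
class RandomAssemblyResult:
    """Empirical composition from finite-pool Monte Carlo assembly."""

    proportions: SubtypeProportions
    n_receptors: int
    pool_2a: int
    pool_2b: int
    unassembled_glun2: int
    unassembled_glun2_fraction: float


def simulate_random_assembly(
    cn1: float,
    cn2a: float,
    cn2b: float,
    n_receptors: int,
    seed: int | np.random.Generator = 0,
) -> RandomAssemblyResult:
    """Stochastic oracle for the closed-form proportions.

    Builds a finite GluN2 pool whose 2A:2B split matches ``cn2a:cn2b``
    and whose size is chosen so that exactly ``n_receptors`` receptors
    (two GluN2 draws each, without replacement) use up the same fraction
    of the pool as in the continuous model; the leftover subunits give
    the empirical unassembled GluN2 fraction.
    """
    if n_receptors < 1:
        raise ValueError("n_receptors must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    props = subtype_proportions(cn2a, cn2b)
    r = total_receptors(cn1, cn2a, cn2b)
    frac_assembled = 2.0 * r / (cn2a + cn2b)
    pool_size = max(2 * n_receptors, int(round(2 * n_receptors / frac_assembled)))
    n_pool_2a = int(round(pool_size * props.p2a))
    n_pool_2b = pool_size - n_pool_2a
    pool = np.zeros(pool_size, dtype=np.int8)
    pool[:n_pool_2a] = 1  # 1 = GluN2A, 0 = GluN2B
    rng.shuffle(pool)
    pairs = pool[: 2 * n_receptors].reshape(-1, 2).sum(axis=1)
    n_2a2a = int(np.count_nonzero(pairs == 2))
    n_2b2b = int(np.count_nonzero(pairs == 0))
    n_2a2b = n_receptors - n_2a2a - n_2b2b
    drawn = pool[: 2 * n_receptors]
    p2a_emp = float(drawn.mean())
    leftover = pool_size - 2 * n_receptors
    return RandomAssemblyResult(
        proportions=SubtypeProportions(
            p2a=p2a_emp,
            p2b=1.0 - p2a_emp,
            p2a2a=n_2a2a / n_receptors,
            p2b2b=n_2b2b / n_receptors,
            p2a2b=n_2a2b / n_receptors,
        ),
        n_receptors=n_receptors,
        pool_2a=n_pool_2a,
        pool_2b=n_pool_2b,
        unassembled_glun2=leftover,
        unassembled_glun2_fraction=leftover / pool_size,
    )


def _check_nonneg(**values: float) -> None:
    for name, v in values.items():
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
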