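"""Antagonist inhibition of a mixed NMDA-receptor population.

A subtype-selective antagonist such as ifenprodil blocks each receptor
subtype according to its own Hill-type concentration-inhibition curve

    inhibition_vi(c) = max_inhibition * c^h / (c^h + IC50^h)

optionally combined with a voltage-dependent component.  A neuron's
whole-cell response mixes receptor subtypes, so the expected inhibition
of the population is the proportion-weighted sum of the per-subtype
inhibitions (equal single-channel current and open probability assumed
unless explicit weights are supplied).  Per-subtype IC50, Hill slope and
maximal inhibition are user inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .assembly import SUBTYPES, SubtypeProportions


@dataclass(frozen=True)
class SubtypePharmacology:
    subtype: str  # one of "2A-2A", "2B-2B", "2A-2B"
    ic50: float  # concentration units of the query (e.g. uM)
    hill: float
    max_inhibition: float = 1.0
    vd_component: float | None = None  # voltage-dependent fractional inhibition

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"subtype must be one of {SUBTYPES}")
        if self.ic50 <= 0:
            raise ValueError("ic50 must be > 0")
        if self.hill <= 0:
            raise ValueError("hill slope must be > 0")
        if not 0.0 <= self.max_inhibition <= 1.0:
            raise ValueError("max_inhibition must be in [0, 1]")
        if self.vd_component is not None and not 0.0 <= self.vd_component <= 1.0:
            raise ValueError("vd_component must be in [0, 1]")


@dataclass(frozen=True)
class MixedInhibition:
    per_subtype: dict[str, float]
    total: float  # convex combination of the per-subtype inhibitions


def hill_inhibition(
    conc: float, pharm: SubtypePharmacology, combine: str = "survival"
) -> float:
    """Fractional inhibition of one subtype at the given concentration.

    The voltage-dependent component, when present, is combined with the
    concentration-dependent part by the multiplicative survival rule
    ``1 - (1 - vd)(1 - vi)`` (independent blocking events); the
    additive-capped alternative ``min(1, vd + vi)`` is selectable.
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if combine not in ("survival", "additive"):
        raise ValueError("combine must be 'survival' or 'additive'")
    vi = 0.0
    if conc > 0:
        ch = conc**pharm.hill
        vi = pharm.max_inhibition * ch / (ch + pharm.ic50**pharm.hill)
    if pharm.vd_component is None:
        return vi
    vd = pharm.vd_component
    if combine == "survival":
        return 1.0 - (1.0 - vd) * (1.0 - vi)
    return min(1.0, vd + vi)


def mixed_population_inhibition(
    proportions: SubtypeProportions,
    pharm_set: dict[str, SubtypePharmacology],
    conc: float,
    combine: str = "survival",
    weights: dict[str, float] | None = None,
) -> MixedInhibition:
    """Population inhibition as a proportion-weighted mean over subtypes.

    ``weights`` optionally rescales each subtype's contribution to the
    aggregate current (relative conductance x open probability); weights
    are renormalized together with the proportions.
    """
    shares = proportions.as_dict()
    if weights is not None:
        shares = {s: shares[s] * weights.get(s, 1.0) for s in shares}
        total_w = sum(shares.values())
        if total_w <= 0:
            raise ValueError("weighted proportions sum to zero")
        shares = {s: v / total_w for s, v in shares.items()}
    per: dict[str, float] = {}
    for subtype, share in shares.items():
        if share == 0:
            continue
        if subtype not in pharm_set:
            raise ValueError(f"no pharmacology supplied for represented subtype {subtype!r}")
        per[subtype] = hill_inhibition(conc, pharm_set[subtype], combine=combine)
    total = sum(shares[s] * per[s] for s in per)
    return MixedInhibition(per_subtype=per, total=total)
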