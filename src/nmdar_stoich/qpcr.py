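"""ddCt relative quantification with dual housekeeping normalization.

RQ = 2^(-ddCt), where per sample dCt = Ct(target) - mean Ct of the
housekeepers (arithmetic mean of Cts = geometric mean of expression) and
ddCt subtracts the reference group's mean dCt.  Amplification efficiency
is fixed at the ideal doubling of 2 per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample_id", "group", "gene", "ct")


@dataclass(frozen=True)
class RQResult:
    gene: str
    group: str
    rq: float
    percent_change: float  # 100 * (rq - 1)
    per_sample_rq: dict[str, float]


def delta_delta_ct(
    table: pd.DataFrame,
    targets: list[str],
    housekeepers: list[str],
    reference_group: str,
    aggregate: str = "rq",
) -> list[RQResult]:
    """Relative quantities per target gene and group.

    ``table`` is long-format with columns sample_id, group, gene, ct
    (one row per technical replicate; replicates are averaged first).
    ``aggregate='rq'`` averages per-sample RQ within each group (default);
    ``'dct'`` averages dCt first and exponentiates once.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns: {missing}")
    if aggregate not in ("rq", "dct"):
        raise ValueError("aggregate must be 'rq' or 'dct'")
    if not set(housekeepers):
        raise ValueError("at least one housekeeper gene required")

    mean_ct = table.groupby(["sample_id", "group", "gene"])["ct"].mean().reset_index()
    wide = mean_ct.pivot(index=["sample_id", "group"], columns="gene", values="ct")
    for hk in housekeepers:
        if hk not in wide.columns or wide[hk].isna().any():
            raise ValueError(f"housekeeper {hk!r} missing in one or more samples")
    groups_present = wide.index.get_level_values("group")
    if reference_group not in set(groups_present):
        raise ValueError(f"reference group {reference_group!r} has no samples")

    hk_ct = wide[list(housekeepers)].mean(axis=1)
    results: list[RQResult] = []
    for gene in targets:
        if gene not in wide.columns:
            raise ValueError(f"target gene {gene!r} absent from the Ct table")
        dct = wide[gene] - hk_ct
        ref_mean_dct = dct[groups_present == reference_group].mean()
        ddct = dct - ref_mean_dct
        rq = np.power(2.0, -ddct)
        for grp in dict.fromkeys(groups_present):
            sel = groups_present == grp
            if aggregate == "rq":
                grp_rq = float(rq[sel].mean())
            else:
                grp_rq = float(2.0 ** -(ddct[sel].mean()))
            results.append(
                RQResult(
                    gene=gene,
                    group=grp,
                    rq=grp_rq,
                    percent_change=100.0 * (grp_rq - 1.0),
                    per_sample_rq={
                        s: float(v) for (s, _), v in rq[sel].items()
                    },
                )
            )
    return results


def results_to_frame(results: list[RQResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene": r.gene, "group": r.group, "rq": r.rq, "percent_change": r.percent_change}
            for r in results
        ]
    )
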