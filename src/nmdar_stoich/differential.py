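"""Two-group differential abundance with permutation-based FDR.

Perseus-style workflow on TMT protein intensities: contaminant removal
and log2 transform, a valid-values filter, a two-sample t-test with an
s0 fudge factor (the statistic is ``(mean2 - mean1) / (pooled SE + s0)``,
which de-prioritizes tiny fold changes with tiny variances), and a
SAM-style global permutation estimate of the false discovery rate from
group-label permutations.  Hits are additionally required to pass a fold
change cutoff.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import IntensityMatrix

logger = logging.getLogger(__name__)

DEFAULT_CONTAMINANT_PREFIXES = ("CON_", "REV_", "CONT_")


def preprocess(
    matrix: IntensityMatrix,
    min_valid: int = 3,
    min_valid_mode: str = "each",
    contaminant_prefixes: tuple[str, ...] = DEFAULT_CONTAMINANT_PREFIXES,
) -> tuple[pd.DataFrame, pd.Series]:
    """Contaminant removal, log2 transform, valid-values filter.

    ``min_valid_mode='each'`` keeps a protein only if every group has at
    least ``min_valid`` non-missing values (required for the two-sample
    test); ``'any'`` keeps it if at least one group does.
    """
    groups = matrix.sample_groups
    names = groups.unique()
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, got {list(names)}")
    for g in names:
        if not len(matrix.group_samples(g)):
            raise ValueError(f"group {g!r} has no samples")
    if min_valid_mode not in ("each", "any"):
        raise ValueError("min_valid_mode must be 'each' or 'any'")

    keep = ~matrix.proteins.index.str.startswith(tuple(contaminant_prefixes))
    intens = matrix.intensities.loc[keep]
    with np.errstate(divide="ignore"):
        log2 = np.log2(intens.where(intens > 0))

    counts = [log2[matrix.group_samples(g)].notna().sum(axis=1) for g in names]
    enough = [c >= min_valid for c in counts]
    row_ok = enough[0] & enough[1] if min_valid_mode == "each" else enough[0] | enough[1]
    filtered = log2.loc[row_ok]
    logger.info(
        "preprocess: %d proteins in, %d contaminants removed, %d after valid-values filter",
        len(matrix.intensities),
        int((~keep).sum()),
        len(filtered),
    )
    return filtered, groups


def _t_stats(
    values: np.ndarray, idx1: np.ndarray, idx2: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise moderated Welch-free (pooled) t statistics with NaN support.

    Returns (t, log2_fc) where log2_fc = mean(group2) - mean(group1).
    """
    g1, g2 = values[:, idx1], values[:, idx2]
    n1 = np.sum(~np.isnan(g1), axis=1)
    n2 = np.sum(~np.isnan(g2), axis=1)
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(g1, axis=1)
        m2 = np.nanmean(g2, axis=1)
        v1 = np.nanvar(g1, axis=1, ddof=1)
        v2 = np.nanvar(g2, axis=1, ddof=1)
    v1 = np.where(n1 > 1, v1, 0.0)
    v2 = np.where(n2 > 1, v2, 0.0)
    dof = n1 + n2 - 2
    pooled = np.where(dof > 0, ((n1 - 1) * v1 + (n2 - 1) * v2) / np.maximum(dof, 1), np.nan)
    se = np.sqrt(pooled * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)))
    diff = m2 - m1
    denom = se + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    return t, diff


def _distinct_assignments(
    n_samples: int, idx1: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Group-label permutations: balanced, identity excluded, deduplicated.

    For equal group sizes a permutation and its mirror give the same |t|,
    so mirrors are collapsed by anchoring sample 0's side.  If fewer
    distinct permutations exist than requested, all of them are used.
    """
    n1 = len(idx1)
    equal = 2 * n1 == n_samples
    if equal:
        pool = [c for c in combinations(range(1, n_samples), n1 - 1)]
        all_assign = [np.array((0,) + c) for c in pool]
    else:
        all_assign = [np.array(c) for c in combinations(range(n_samples), n1)]
    identity = set(idx1.tolist())
    mirror = set(range(n_samples)) - identity
    all_assign = [
        a for a in all_assign if set(a.tolist()) not in (identity, mirror)
    ]
    if len(all_assign) <= n_permutations:
        if len(all_assign) < n_permutations:
            logger.info(
                "only %d distinct label permutations exist; using all of them "
                "instead of the requested %d",
                len(all_assign),
                n_permutations,
            )
        return all_assign
    chosen = rng.choice(len(all_assign), size=n_permutations, replace=False)
    return [all_assign[k] for k in chosen]


def permutation_fdr_ttest(
    log2_matrix: pd.DataFrame,
    groups: pd.Series,
    s0: float = 0.1,
    n_permutations: int = 1000,
    fdr: float = 0.05,
    seed: int = 0,
    method: str = "sam",
) -> pd.DataFrame:
    """Per-protein t statistics with permutation FDR q-values.

    The SAM-style q-value of a protein with observed ``|t|`` is the
    median, over label permutations, of the number of null statistics at
    least as extreme anywhere in the matrix, divided by the observed
    rank of ``|t|``; q-values are then made monotone non-increasing in
    ``|t|`` and clamped to [0, 1].  ``method='bh'`` instead applies
    Benjamini-Hochberg to the per-protein permutation p-values.
    """
    names = list(dict.fromkeys(groups))
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    samples = list(log2_matrix.columns)
    idx1 = np.array([i for i, s in enumerate(samples) if groups[s] == names[0]])
    idx2 = np.array([i for i, s in enumerate(samples) if groups[s] == names[1]])
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("each group needs >= 2 samples")
    if method not in ("sam", "bh"):
        raise ValueError("method must be 'sam' or 'bh'")

    values = log2_matrix.to_numpy(dtype=float)
    t_obs, log2_fc = _t_stats(values, idx1, idx2, s0)
    abs_t = np.abs(t_obs)

    rng = np.random.default_rng(seed)
    assigns = _distinct_assignments(len(samples), idx1, n_permutations, rng)
    all_idx = np.arange(len(samples))
    m = len(abs_t)

    null_counts = np.empty((len(assigns), m))  # per perm: #(|t*| >= |t_i|) pooled
    own_exceed = np.zeros(m)  # per protein: #perms with own |t*| >= |t_i|
    for b, a1 in enumerate(assigns):
        a2 = np.setdiff1d(all_idx, a1)
        t_null, _ = _t_stats(values, a1, a2, s0)
        abs_null = np.abs(t_null)
        snull = np.sort(abs_null[~np.isnan(abs_null)])
        null_counts[b] = len(snull) - np.searchsorted(snull, abs_t, side="left")
        own_exceed += (abs_null >= abs_t).astype(float)
    p_values = (own_exceed + 1.0) / (len(assigns) + 1.0)

    order = np.argsort(-abs_t, kind="mergesort")
    ranks = np.empty(m)
    sorted_abs = abs_t[order]
    # rank = number of observed |t| >= |t_i| (ties share the deeper rank)
    ranks_sorted = np.searchsorted(-sorted_abs, -sorted_abs, side="right")
    ranks[order] = ranks_sorted

    if method == "sam":
        q_raw = np.median(null_counts, axis=0) / ranks
        q_sorted = q_raw[order]
        # monotone non-increasing in |t|: suffix-minimum along descending |t|
        q_mono = np.minimum.accumulate(q_sorted[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.clip(q_mono, 0.0, 1.0)
    else:
        q = _benjamini_hochberg(p_values)

    out = pd.DataFrame(
        {
            "protein_id": log2_matrix.index,
            "log2_fc": log2_fc,
            "t_stat": t_obs,
            "p_value": p_values,
            "q_value": q,
            "significant": q <= fdr,
        }
    ).set_index("protein_id")
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_mono = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_mono, 0.0, 1.0)
    return q


def classify_hits(
    results: pd.DataFrame, fc_threshold: float = 2.0, fdr: float = 0.05
) -> tuple[int, int, pd.DataFrame]:
    """Two-threshold hit classes: significant AND |fold change| beyond cutoff."""
    if results.empty:
        raise ValueError("empty results table")
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    cut = math.log2(fc_threshold)
    table = results.copy()
    sig = table["q_value"] <= fdr
    up = sig & (table["log2_fc"] >= cut)
    down = sig & (table["log2_fc"] <= -cut)
    table["hit_class"] = np.select([up, down], ["up", "down"], default="none")
    return int(up.sum()), int(down.sum()), table
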