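"""Seed-stratified differential expression and drug-reversal query export.

Samples are stratified into a high arm (expression strictly above the 60th
percentile of the stratifying gene) and a low arm (strictly below the 10th
percentile); the middle band is discarded.  Genes differentially expressed
between the arms (Welch two-sample t, two-sided) are split by direction and
exported as capped up/down GRP lists — the query format of
connectivity-map-style services.  A rank-based reversal score lets the
query be tested against any supplied perturbation profile: negative scores
mean the perturbation moves the query genes opposite to their disease
direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CohortBundle

__all__ = [
    "StratifiedDEResult",
    "ReversalQuery",
    "stratify_by_gene",
    "differential_expression",
    "export_query",
    "reversal_score",
]

logger = logging.getLogger(__name__)

_MIN_ARM = 5


@dataclass(frozen=True)
class StratifiedDEResult:
    """One gene's high-vs-low contrast (delta = mean high − mean low, log2)."""

    gene: str
    t_stat: float
    p: float
    delta: float
    direction: str  # "up" iff delta > 0

    def __post_init__(self) -> None:
        expected = "up" if self.delta > 0 else "down"
        if self.direction != expected:
            raise ValueError("direction inconsistent with delta sign")


@dataclass(frozen=True)
class ReversalQuery:
    """Paired, disjoint up/down gene lists capped at ``max_per_list``."""

    up_list: tuple[str, ...]
    down_list: tuple[str, ...]
    max_per_list: int

    def __post_init__(self) -> None:
        if set(self.up_list) & set(self.down_list):
            raise ValueError("up and down lists must be disjoint")
        if len(self.up_list) > self.max_per_list or len(self.down_list) > self.max_per_list:
            raise ValueError("list exceeds max_per_list")


def stratify_by_gene(
    bundle: CohortBundle, gene: str, high_pct: float = 0.60, low_pct: float = 0.10
) -> tuple[list[str], list[str]]:
    """Split samples on the stratifying gene's expression percentiles.

    high = samples strictly above the ``high_pct`` percentile, low =
    strictly below the ``low_pct`` percentile (ties at a cut point fall
    into the discarded middle band).  Both arms must reach 5 samples.
    """
    if not (0.0 < low_pct < high_pct < 1.0):
        raise ValueError("need 0 < low_pct < high_pct < 1")
    if gene not in bundle.expression.index:
        raise KeyError(f"gene {gene!r} not measured in cohort {bundle.cohort_id}")
    x = bundle.expression.loc[gene]
    hi_cut = float(np.nanquantile(x.to_numpy(dtype=float), high_pct))
    lo_cut = float(np.nanquantile(x.to_numpy(dtype=float), low_pct))
    high = list(x.index[x > hi_cut])
    low = list(x.index[x < lo_cut])
    if len(high) < _MIN_ARM or len(low) < _MIN_ARM:
        raise ValueError(
            f"stratification arms too small (high={len(high)}, low={len(low)}, need >= {_MIN_ARM})"
        )
    return high, low


def differential_expression(
    bundle: CohortBundle,
    high: list[str],
    low: list[str],
    alpha: float = 0.05,
    min_delta: float = 0.0,
    fdr: bool = False,
) -> list[StratifiedDEResult]:
    """Welch two-sample t-test of every gene between the high and low arms.

    Keeps genes with p < ``alpha`` (all testable genes when alpha >= 1) and
    |delta| >= ``min_delta``, sorted by |t| descending.  ``fdr`` applies
    Benjamini–Hochberg adjustment before the alpha filter (off by default,
    matching a raw-p query-building workflow).  Genes with zero variance in
    both arms are skipped and logged.
    """
    if not high or not low:
        raise ValueError("both arms must be non-empty")
    a = bundle.expression.loc[:, high].to_numpy(dtype=float)
    b = bundle.expression.loc[:, low].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    delta = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)

    testable = np.isfinite(t_stat) & np.isfinite(p)
    n_skipped = int((~testable).sum())
    if n_skipped:
        logger.info("differential_expression: skipped %d untestable genes", n_skipped)

    p_filter = np.asarray(p, dtype=float).copy()
    if fdr:
        from statsmodels.stats.multitest import multipletests  # local: optional path

        adj = np.full_like(p_filter, np.nan)
        adj[testable] = multipletests(p_filter[testable], method="fdr_bh")[1]
        p_filter = adj

    keep = testable & (np.abs(delta) >= min_delta)
    if alpha < 1.0:
        keep &= p_filter < alpha
    results = [
        StratifiedDEResult(
            gene=str(g),
            t_stat=float(t),
            p=float(pv),
            delta=float(d),
            direction="up" if d > 0 else "down",
        )
        for g, t, pv, d, k in zip(bundle.expression.index, t_stat, p, delta, keep)
        if k and d != 0
    ]
    results.sort(key=lambda r: abs(r.t_stat), reverse=True)
    return results


def export_query(
    results: list[StratifiedDEResult], max_per_list: int = 500, directory=None
) -> ReversalQuery:
    """Split the DE table by direction into up/down query lists, keeping the
    top |t| genes up to ``max_per_list`` per side (>= 10 genes required each).
    With ``directory`` set, writes ``up.grp`` / ``down.grp`` (one symbol per
    line)."""
    up = [r.gene for r in results if r.direction == "up"][:max_per_list]
    down = [r.gene for r in results if r.direction == "down"][:max_per_list]
    if len(up) < 10 or len(down) < 10:
        raise ValueError(f"too few genes for a query (up={len(up)}, down={len(down)}, need >= 10)")
    query = ReversalQuery(up_list=tuple(up), down_list=tuple(down), max_per_list=max_per_list)
    if directory is not None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "up.grp").write_text("\n".join(query.up_list) + "\n")
        (directory / "down.grp").write_text("\n".join(query.down_list) + "\n")
    return query


def reversal_score(query: ReversalQuery, drug_profile) -> float:
    """Rank-based concordance of a query with a drug perturbation profile.

    ``drug_profile`` is the drug's genes ordered by induced expression
    change, most up-regulated first (an ordered sequence, or a Series of
    change values which is sorted internally).  Each query gene present in
    the profile gets a normalized rank position in [−1, 1] (most
    down-regulated = −1); the score is mean(position of up genes) −
    mean(position of down genes) ∈ [−2, 2].  Negative scores mean the drug
    reverses the query.  At least 50% of the query genes must be present.
    """
    if isinstance(drug_profile, pd.Series):
        ordered = list(drug_profile.sort_values(ascending=False).index)
    else:
        ordered = list(drug_profile)
    m = len(ordered)
    if m < 2:
        raise ValueError("drug profile must rank at least 2 genes")
    position = {g: 1.0 - 2.0 * i / (m - 1) for i, g in enumerate(ordered)}

    up_pos = [position[g] for g in query.up_list if g in position]
    down_pos = [position[g] for g in query.down_list if g in position]
    n_query = len(query.up_list) + len(query.down_list)
    covered = len(up_pos) + len(down_pos)
    if covered < 0.5 * n_query or not up_pos or not down_pos:
        raise ValueError(
            f"insufficient profile coverage of the query ({covered}/{n_query} genes present)"
        )
    return float(np.mean(up_pos) - np.mean(down_pos))
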