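"""Seed-gene co-expression module by correlation meta-analysis.

For every gene, the Pearson correlation with the seed gene is computed
independently within each cohort (pairwise-complete observations), carried
to the Fisher-z scale (z = atanh r, var = 1/(n-3)), pooled with the same
DerSimonian–Laird random-effects machinery as the survival screen, and
back-transformed.  Module membership applies the stringent cut-off on the
pooled estimate: r_pooled >= 0.6 (positive co-expression) with a two-sided
combined p < 0.001, requiring measurement alongside the seed in at least
three cohorts.  Module expression per sample is summarised by the
arithmetic mean of member genes (optionally of per-gene z-scores).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._meta import pool_inverse_variance
from .synthetic import CohortBundle

__all__ = ["CorrStudy", "CorrMetaResult", "ModuleDef", "corr_with_seed", "pool_corr", "define_module", "module_score"]

logger = logging.getLogger(__name__)

_R_CLAMP = 0.999999  # |r| = 1 would make atanh infinite
_MIN_PAIRS = 4
_MIN_COHORTS = 3


@dataclass(frozen=True)
class CorrStudy:
    """Per-cohort Pearson correlation of one gene with the seed gene."""

    cohort_id: str
    gene: str
    r: float
    n: int
    clamped: bool = False

    @property
    def z(self) -> float:
        return float(np.arctanh(self.r))

    @property
    def var_z(self) -> float:
        return 1.0 / (self.n - 3)


@dataclass(frozen=True)
class CorrMetaResult:
    """Pooled Fisher-z summary of one gene's correlation with the seed."""

    gene: str
    r_pooled: float
    z_pooled: float
    se_z: float
    tau2_z: float
    p_combined: float
    k: int
    in_module: bool = False


@dataclass
class ModuleDef:
    """Seed-gene co-expression module (the seed itself is not a member)."""

    seed_gene: str
    threshold_r: float
    threshold_p: float
    members: list[tuple[str, float]] = field(default_factory=list)  # (gene, r_pooled), r descending

    @property
    def member_genes(self) -> list[str]:
        return [g for g, _ in self.members]

    def __len__(self) -> int:
        return len(self.members)


def corr_with_seed(bundle: CohortBundle, seed: str) -> list[CorrStudy]:
    """Pearson correlation of every other gene with the seed in one cohort.

    Uses pairwise-complete observations; genes with fewer than 4 complete
    pairs or zero variance are omitted.  |r| = 1 (e.g. a duplicate of the
    seed row) is clamped just below 1 and flagged so the Fisher transform
    stays finite.
    """
    if seed not in bundle.expression.index:
        raise KeyError(f"seed gene {seed!r} not measured in cohort {bundle.cohort_id}")
    expr = bundle.expression
    s = expr.loc[seed].to_numpy(dtype=float)
    s_ok = np.isfinite(s)
    if s_ok.sum() < _MIN_PAIRS or np.nanstd(s) == 0:
        raise ValueError(f"seed gene {seed!r} constant or too sparse in {bundle.cohort_id}")

    values = expr.to_numpy(dtype=float)
    out: list[CorrStudy] = []
    finite = np.isfinite(values)
    clean = bool(finite.all()) and bool(s_ok.all())
    if clean:
        # vectorised fast path: no missing values anywhere
        sc = s - s.mean()
        ss = float(np.sqrt((sc * sc).sum()))
        centred = values - values.mean(axis=1, keepdims=True)
        norms = np.sqrt((centred * centred).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rs = (centred @ sc) / (norms * ss)
        n = values.shape[1]
        for gene, r, norm in zip(expr.index, rs, norms):
            if gene == seed or norm == 0 or not np.isfinite(r):
                continue
            out.append(_make_study(bundle.cohort_id, gene, float(r), n))
    else:
        for gene, row in zip(expr.index, values):
            if gene == seed:
                continue
            ok = np.isfinite(row) & s_ok
            n = int(ok.sum())
            if n < _MIN_PAIRS:
                continue
            a, b = row[ok], s[ok]
            if a.std() == 0 or b.std() == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            out.append(_make_study(bundle.cohort_id, gene, r, n))
    return out


def _make_study(cohort_id: str, gene: str, r: float, n: int) -> CorrStudy:
    clamped = abs(r) >= 1.0
    if clamped:
        logger.warning("|r| = 1 between %s and the seed in %s; clamped", gene, cohort_id)
        r = float(np.sign(r)) * _R_CLAMP
    return CorrStudy(cohort_id=cohort_id, gene=gene, r=r, n=n, clamped=clamped)


def pool_corr(studies: list[CorrStudy]) -> CorrMetaResult:
    """DerSimonian–Laird pool of per-cohort correlations on the Fisher-z
    scale; r_pooled = tanh(z_pooled), combined p from z_pooled / se_z."""
    studies = [s for s in studies if s.n >= _MIN_PAIRS]
    if not studies:
        raise ValueError("no studies with >= 4 complete pairs")
    pooled = pool_inverse_variance([s.z for s in studies], [s.var_z for s in studies])
    return CorrMetaResult(
        gene=studies[0].gene,
        r_pooled=float(np.tanh(pooled.beta)),
        z_pooled=pooled.beta,
        se_z=pooled.se,
        tau2_z=pooled.tau2,
        p_combined=pooled.p,
        k=pooled.k,
    )


def meta_correlations(
    bundles: list[CohortBundle], seed: str, min_cohorts: int = _MIN_COHORTS
) -> pd.DataFrame:
    """Pooled seed correlations for every gene measured with the seed in at
    least ``min_cohorts`` cohorts (one row per gene)."""
    per_gene: dict[str, list[CorrStudy]] = {}
    n_with_seed = 0
    for bundle in bundles:
        if seed not in bundle.expression.index:
            continue
        n_with_seed += 1
        for study in corr_with_seed(bundle, seed):
            per_gene.setdefault(study.gene, []).append(study)
    if n_with_seed < min_cohorts:
        raise ValueError(
            f"seed gene {seed!r} measured in only {n_with_seed} cohorts (need {min_cohorts})"
        )
    rows = [
        pool_corr(studies).__dict__
        for studies in per_gene.values()
        if len(studies) >= min_cohorts
    ]
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    return table.sort_values("r_pooled", ascending=False, kind="mergesort").reset_index(drop=True)


def define_module(
    bundles: list[CohortBundle],
    seed: str,
    threshold_r: float = 0.6,
    threshold_p: float = 0.001,
    min_cohorts: int = _MIN_COHORTS,
) -> ModuleDef:
    """Derive the seed-gene module: genes whose pooled correlation with the
    seed reaches ``threshold_r`` (positive) with combined p < ``threshold_p``,
    sorted by pooled r descending."""
    table = meta_correlations(bundles, seed, min_cohorts=min_cohorts)
    members: list[tuple[str, float]] = []
    if not table.empty:
        selected = table[
            (table["r_pooled"] >= threshold_r) & (table["p_combined"] < threshold_p)
        ]
        members = list(zip(selected["gene"], selected["r_pooled"]))
    return ModuleDef(seed_gene=seed, threshold_r=threshold_r, threshold_p=threshold_p, members=members)


def module_score(bundle: CohortBundle, module: ModuleDef, standardize: bool = False) -> pd.Series:
    """Per-sample module expression: mean over member genes present in the
    cohort (at least 50% coverage required); with ``standardize`` the mean is
    taken over per-gene z-scores instead of raw values."""
    genes = [g for g in module.member_genes if g in bundle.expression.index]
    if not module.member_genes:
        raise ValueError("empty module")
    coverage = len(genes) / len(module.member_genes)
    if coverage < 0.5:
        raise ValueError(
            f"only {coverage:.0%} of module genes measured in {bundle.cohort_id} (need >= 50%)"
        )
    missing = set(module.member_genes) - set(genes)
    if missing:
        logger.info("module_score: %d module genes missing in %s", len(missing), bundle.cohort_id)
    sub = bundle.expression.loc[genes]
    if standardize:
        sub = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    return sub.mean(axis=0)
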