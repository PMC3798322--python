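"""Gene-level survival screening and random-effects meta-analysis.

The screen fits, for every gene in a locus universe and every cohort, a
univariate Cox proportional-hazards model on the per-cohort-standardised
expression value (log hazard ratio per SD), pools the per-cohort log-HRs
with DerSimonian–Laird inverse-variance random-effects weights, and applies
the consistency cascade: a gene passes when it reaches the per-cohort Wald
threshold (p < 0.005) in at least ``min_sig_cohorts`` cohorts (3) AND its
combined Wald p-value is below ``alpha_combined`` (0.005).

Per-gene fits use an in-package Newton solver on the Efron partial
likelihood specialised to one covariate — the screen fits tens of thousands
of gene×cohort models, so per-fit overhead matters.  Kaplan–Meier curves,
log-rank tests and the uni/multivariate clinical-covariate models are
delegated to lifelines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from ._meta import PooledEstimate, pool_inverse_variance
from .synthetic import CohortBundle

__all__ = [
    "CoxGeneResult",
    "MetaGeneResult",
    "FilterPolicy",
    "cox_per_gene",
    "pool_dl",
    "screen_locus",
    "km_stratify",
    "cox_covariates",
    "forest_data",
]

logger = logging.getLogger(__name__)

_MIN_EVENTS = 10
_BETA_CAP = 50.0


@dataclass(frozen=True)
class CoxGeneResult:
    """One gene, one cohort: univariate Cox fit on standardised expression."""

    cohort_id: str
    gene: str
    beta: float       # log hazard ratio per 1 SD of expression
    se: float
    wald_z: float
    p: float          # two-sided Wald p
    n: int            # samples used (listwise complete)
    events: int
    usable: bool = True


@dataclass(frozen=True)
class MetaGeneResult:
    """Random-effects pooled summary of one gene across cohorts."""

    gene: str
    beta_re: float
    se_re: float
    hr: float
    tau2: float
    q_stat: float
    p_combined: float
    k: int
    n_sig_cohorts: int
    passes: bool


@dataclass(frozen=True)
class FilterPolicy:
    """The cohort-consistency cascade: per-cohort Wald p < ``alpha_cohort``
    in at least ``min_sig_cohorts`` cohorts, combined p < ``alpha_combined``,
    and the gene measured in at least ``min_measured_cohorts`` cohorts."""

    alpha_cohort: float = 0.005
    min_sig_cohorts: int = 3
    alpha_combined: float = 0.005
    min_measured_cohorts: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_cohort < 1.0 and 0.0 < self.alpha_combined < 1.0):
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if self.min_sig_cohorts < 1 or self.min_measured_cohorts < 1:
            raise ValueError("cohort count thresholds must be >= 1")


class CoxDesign:
    """Precomputed risk-set structure of one cohort's (time, event) data.

    Sorting, tie grouping and the Efron fractional-weight layout depend only
    on the outcome, so the screen builds this once per cohort and reuses it
    for every gene.
    """

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        keep = np.isfinite(time)
        self.mask = keep
        time, event = time[keep], event[keep].astype(int)
        order = np.argsort(time, kind="mergesort")
        self.order = order
        t = time[order]
        d = event[order].astype(bool)
        self.n = t.size
        self.n_events = int(d.sum())
        self.death_idx = np.nonzero(d)[0]

        uniq, starts = np.unique(t, return_index=True)
        gid = np.searchsorted(uniq, t)
        death_gid = gid[d]
        death_groups, death_bounds = np.unique(death_gid, return_index=True)
        self.death_bounds = death_bounds              # reduceat boundaries into death arrays
        self.risk_starts = starts[death_groups]       # risk set = sorted[start:]
        counts = np.bincount(death_gid)[death_groups]  # deaths per tied event time

        # Efron pairs: (group k, l = 0..D_k-1) with fraction l / D_k
        total = int(counts.sum())
        self.pair_group = np.repeat(np.arange(death_groups.size), counts)
        offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        self.pair_frac = offsets / np.repeat(counts, counts)

    def fit(self, x: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
        """Newton fit of the single-covariate Efron partial likelihood.

        ``x`` must already be restricted to the design's samples (and is
        typically standardised).  Returns (beta, se, converged).
        """
        xs = x[self.order]
        x_deaths_sum = float(xs[self.death_idx].sum())
        beta = 0.0
        converged = False
        for _ in range(max_iter):
            ll, grad, info = self._derivatives(xs, beta, x_deaths_sum)
            if info <= 0 or not np.isfinite(info):
                break
            step = grad / info
            # step-halving if the likelihood fails to improve
            for _half in range(30):
                new_ll, _, _ = self._derivatives(xs, beta + step, x_deaths_sum)
                if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                    break
                step /= 2.0
            beta += step
            if abs(beta) > _BETA_CAP:
                break
            if abs(step) < tol:
                converged = True
                break
        _, _, info = self._derivatives(xs, beta, x_deaths_sum)
        se = 1.0 / np.sqrt(info) if info > 0 else np.nan
        return beta, se, converged and np.isfinite(se)

    def _derivatives(self, xs, beta, x_deaths_sum):
        z = np.clip(beta * xs, -700.0, 700.0)
        theta = np.exp(z)
        tx = theta * xs
        tx2 = tx * xs
        r0 = np.cumsum(theta[::-1])[::-1][self.risk_starts]
        r1 = np.cumsum(tx[::-1])[::-1][self.risk_starts]
        r2 = np.cumsum(tx2[::-1])[::-1][self.risk_starts]
        d0 = np.add.reduceat(theta[self.death_idx], self.death_bounds)
        d1 = np.add.reduceat(tx[self.death_idx], self.death_bounds)
        d2 = np.add.reduceat(tx2[self.death_idx], self.death_bounds)
        g = self.pair_group
        frac = self.pair_frac
        s0 = r0[g] - frac * d0[g]
        s1 = r1[g] - frac * d1[g]
        s2 = r2[g] - frac * d2[g]
        mean = s1 / s0
        ll = beta * x_deaths_sum - float(np.log(s0).sum())
        grad = x_deaths_sum - float(mean.sum())
        info = float((s2 / s0 - mean * mean).sum())
        return ll, grad, info


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    return (x - x.mean()) / sd


def _fit_gene(design_cache: dict, bundle: CohortBundle, gene: str) -> CoxGeneResult:
    x = bundle.expression.loc[gene].to_numpy(dtype=float)
    time = bundle.clinical["time"].to_numpy(dtype=float)
    event = bundle.clinical["event"].to_numpy()

    complete = np.isfinite(x)
    if complete.all():
        design = design_cache.get(bundle.cohort_id)
        if design is None:
            design = design_cache[bundle.cohort_id] = CoxDesign(time, event)
        xv = x
    else:  # listwise deletion for this gene only
        design = CoxDesign(time[complete], event[complete])
        xv = x[complete]

    unusable = CoxGeneResult(
        cohort_id=bundle.cohort_id, gene=gene, beta=np.nan, se=np.nan,
        wald_z=np.nan, p=np.nan, n=design.n, events=design.n_events, usable=False,
    )
    if design.n_events < _MIN_EVENTS:
        return unusable
    sd = np.std(xv, ddof=1)
    if not np.isfinite(sd) or sd == 0.0:
        return unusable
    beta, se, ok = design.fit((xv - xv.mean()) / sd)
    if not ok or not np.isfinite(beta) or not np.isfinite(se) or se <= 0:
        return unusable
    z = beta / se
    return CoxGeneResult(
        cohort_id=bundle.cohort_id, gene=gene, beta=float(beta), se=float(se),
        wald_z=float(z), p=float(2.0 * stats.norm.sf(abs(z))),
        n=design.n, events=design.n_events, usable=True,
    )


def cox_per_gene(bundle: CohortBundle, gene: str) -> CoxGeneResult:
    """Univariate Cox fit of one gene in one cohort (log-HR per SD).

    Degenerate inputs (constant expression, < 10 events, non-convergence)
    return a result flagged ``usable=False`` rather than raising, so the
    meta-analysis can exclude them.
    """
    if gene not in bundle.expression.index:
        raise KeyError(f"gene {gene!r} not measured in cohort {bundle.cohort_id}")
    return _fit_gene({}, bundle, gene)


def pool_dl(results: list[CoxGeneResult], policy: FilterPolicy | None = None) -> MetaGeneResult:
    """DerSimonian–Laird random-effects pool of one gene's per-cohort log-HRs.

    A single usable study passes through (tau2 = 0).  ``passes`` applies the
    filter cascade of ``policy`` (paper-default thresholds when omitted).
    """
    policy = policy or FilterPolicy()
    usable = [r for r in results if r.usable]
    if not usable:
        raise ValueError("no usable per-cohort results to pool")
    if any(r.se <= 0 for r in usable):
        raise ValueError("all standard errors must be > 0")
    pooled = pool_inverse_variance([r.beta for r in usable], [r.se ** 2 for r in usable])
    n_sig = sum(r.p < policy.alpha_cohort for r in usable)
    passes = (
        len(usable) >= policy.min_measured_cohorts
        and n_sig >= policy.min_sig_cohorts
        and pooled.p < policy.alpha_combined
    )
    return MetaGeneResult(
        gene=usable[0].gene,
        beta_re=pooled.beta,
        se_re=pooled.se,
        hr=float(np.exp(pooled.beta)),
        tau2=pooled.tau2,
        q_stat=pooled.q_stat,
        p_combined=pooled.p,
        k=pooled.k,
        n_sig_cohorts=int(n_sig),
        passes=bool(passes),
    )


def screen_locus(
    bundles: list[CohortBundle],
    gene_universe: list[str],
    policy: FilterPolicy | None = None,
) -> pd.DataFrame:
    """Run the full meta-analytic survival screen over a gene universe.

    Returns the complete table (passers and non-passers) sorted by combined
    p-value, one row per gene measured in at least
    ``policy.min_measured_cohorts`` cohorts, with columns gene, beta_re, hr,
    se_re, tau2, q_stat, p_combined, k, n_sig_cohorts, passes.
    """
    policy = policy or FilterPolicy()
    if not gene_universe:
        raise ValueError("empty gene universe")
    if len(bundles) < policy.min_measured_cohorts:
        raise ValueError(
            f"need >= {policy.min_measured_cohorts} cohorts, got {len(bundles)}"
        )
    design_cache: dict = {}
    rows = []
    for gene in gene_universe:
        per_cohort = [
            _fit_gene(design_cache, b, gene) for b in bundles if gene in b.expression.index
        ]
        usable = [r for r in per_cohort if r.usable]
        if len(usable) < policy.min_measured_cohorts:
            if usable:
                meta = pool_dl(usable, policy)
                rows.append({**meta.__dict__, "passes": False})
            continue
        rows.append(pool_dl(usable, policy).__dict__)
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    return table.sort_values("p_combined", kind="mergesort").reset_index(drop=True)


@dataclass
class KMStratification:
    """Median-split Kaplan–Meier comparison of a per-sample score."""

    curves: dict[str, pd.DataFrame] = field(default_factory=dict)  # label -> KM estimate
    groups: pd.Series | None = None          # per-sample 'high'/'low'
    logrank_stat: float = np.nan
    p: float = np.nan


def km_stratify(clinical, score, split: str = "median", min_per_arm: int = 10) -> KMStratification:
    """Median-split a per-sample score and compare survival between arms.

    ``clinical`` is a CohortBundle or a DataFrame with time/event columns;
    ``score`` is aligned per-sample values.  Ties at the median go to the
    low group.  Returns the two Kaplan–Meier step functions and the
    two-sided log-rank p-value.
    """
    if split != "median":
        raise ValueError("only median split is supported")
    if isinstance(clinical, CohortBundle):
        clinical = clinical.clinical
    score = np.asarray(score, dtype=float)
    time = clinical["time"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=int)
    if score.size != time.size:
        raise ValueError("score length must match the clinical table")
    cut = np.median(score)
    high = score > cut  # ties at the median assigned to the low group
    if high.sum() < min_per_arm or (~high).sum() < min_per_arm:
        raise ValueError("degenerate split: need >= %d samples per arm" % min_per_arm)

    result = KMStratification()
    result.groups = pd.Series(np.where(high, "high", "low"), index=clinical.index)
    for label, mask in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=label)
        result.curves[label] = kmf.survival_function_
    lr = logrank_test(time[high], time[~high], event_observed_A=event[high], event_observed_B=event[~high])
    result.logrank_stat = float(lr.test_statistic)
    result.p = float(lr.p_value)
    return result


_COVARIATE_ENCODERS = {
    "age": lambda c: c["age"].astype(float),
    "size": lambda c: c["size"].astype(float),
    "grade": lambda c: c["grade"].astype(float),
    "er": lambda c: (c["er"] == "pos").astype(float),
    "node": lambda c: (c["node"] == "pos").astype(float),
}


def cox_covariates(
    bundle: CohortBundle,
    score_binary,
    covariates: list[str],
    mode: str = "multivariate",
) -> pd.DataFrame:
    """Uni- or multivariate Cox models of a binary score with clinical covariates.

    ``score_binary`` is the per-sample median-split indicator (0/1).
    Univariate mode fits one model per variable; multivariate fits the joint
    model.  Constant covariates are dropped with a warning.  Returns a table
    with per-term HR, 95% CI and p (columns: variable, mode, hr, ci_lower,
    ci_upper, p).
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    unknown = [c for c in covariates if c not in _COVARIATE_ENCODERS]
    if unknown:
        raise KeyError(f"unknown covariates: {unknown}")
    clin = bundle.clinical
    if int(clin["event"].sum()) < _MIN_EVENTS:
        raise ValueError("need >= %d events" % _MIN_EVENTS)

    data = pd.DataFrame({"time": clin["time"].astype(float), "event": clin["event"].astype(int)})
    data["score"] = np.asarray(score_binary, dtype=float)
    for cov in covariates:
        data[cov] = _COVARIATE_ENCODERS[cov](clin).to_numpy()

    terms = ["score"] + list(covariates)
    kept = []
    for term in terms:
        if data[term].nunique() < 2:
            warnings.warn(f"covariate {term!r} is constant in {bundle.cohort_id}; dropped")
        else:
            kept.append(term)

    def fit(cols: list[str]) -> pd.DataFrame:
        cph = CoxPHFitter()
        cph.fit(data[["time", "event"] + cols], duration_col="time", event_col="event")
        summary = cph.summary
        return pd.DataFrame(
            {
                "variable": summary.index,
                "hr": summary["exp(coef)"].to_numpy(),
                "ci_lower": summary["exp(coef) lower 95%"].to_numpy(),
                "ci_upper": summary["exp(coef) upper 95%"].to_numpy(),
                "p": summary["p"].to_numpy(),
            }
        )

    if mode == "univariate":
        parts = [fit([term]) for term in kept]
        table = pd.concat(parts, ignore_index=True)
    else:
        table = fit(kept)
    table.insert(1, "mode", mode)
    return table


def forest_data(results: list[CoxGeneResult], policy: FilterPolicy | None = None) -> pd.DataFrame:
    """Per-cohort HR + 95% CI rows plus a pooled random-effects row, ready
    for a forest plot of one gene across cohorts."""
    usable = [r for r in results if r.usable]
    rows = [
        {
            "label": r.cohort_id,
            "hr": float(np.exp(r.beta)),
            "ci_lower": float(np.exp(r.beta - 1.959963984540054 * r.se)),
            "ci_upper": float(np.exp(r.beta + 1.959963984540054 * r.se)),
            "weight": 1.0 / r.se ** 2,
            "pooled": False,
        }
        for r in usable
    ]
    meta = pool_dl(usable, policy)
    rows.append(
        {
            "label": "pooled (RE)",
            "hr": meta.hr,
            "ci_lower": float(np.exp(meta.beta_re - 1.959963984540054 * meta.se_re)),
            "ci_upper": float(np.exp(meta.beta_re + 1.959963984540054 * meta.se_re)),
            "weight": np.nan,
            "pooled": True,
        }
    )
    return pd.DataFrame(rows)
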