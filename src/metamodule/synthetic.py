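"""Synthetic multi-cohort expression + survival data.

Emulates the statistical structure of a multi-cohort breast-tumor
meta-analysis: K independent cohorts with heterogeneous sample sizes and
platform scales, a planted seed-centred co-expression module driven by a
shared latent factor, planted prognostic genes under a proportional-hazards
model with censoring, and a background of null genes.  Every downstream
stage (survival screen, correlation meta-analysis, signature scoring,
stratified contrasts) is testable against the planted ground truth without
any external download.

Generative model, per cohort:

* latent factor f ~ N(0,1) per sample;
* module genes (the seed gene is member 0):
  x = lambda * f + sqrt(1 - lambda^2) * eps, eps ~ N(0,1), so every pair of
  module genes (and each member with the seed) has correlation lambda^2;
* null genes: x ~ N(0,1) i.i.d.;
* survival: T ~ Exponential(rate = baseline_hazard * exp(eta)) with linear
  predictor eta = sum_g beta_g * x_g over the planted prognostic genes
  (x on the unit-variance scale, so beta is a log hazard ratio per SD);
* censoring: administrative-uniform C ~ U(0, L), with L solved numerically
  so the expected censored fraction equals ``censoring_rate``;
* platform: single-channel cohorts are shifted/scaled to a log2-intensity-
  like range, dual-channel cohorts are mean-centred per gene (log-ratio-like).
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

__all__ = ["SimConfig", "CohortBundle", "simulate_cohorts", "write_fixture", "locus_table"]

_CLINICAL_COLUMNS = ["time", "event", "endpoint", "age", "size", "grade", "er", "node"]


@dataclass
class CohortBundle:
    """One cohort: genes×samples expression plus per-sample clinical table.

    ``expression`` rows are gene symbols, columns sample identifiers;
    ``clinical`` is indexed by the same sample identifiers with columns
    time (months, > 0), event (0/1), endpoint (RFS/OS), age (years),
    size (mm), grade (1/2/3), er (pos/neg), node (pos/neg).
    """

    cohort_id: str
    expression: pd.DataFrame
    clinical: pd.DataFrame
    channel: str = "single"  # {"single", "dual"}

    def __post_init__(self) -> None:
        if self.channel not in ("single", "dual"):
            raise ValueError(f"channel must be 'single' or 'dual', got {self.channel!r}")
        if self.expression.index.duplicated().any():
            raise ValueError("duplicated gene identifiers in expression matrix")
        if list(self.expression.columns) != list(self.clinical.index):
            raise ValueError("sample identifiers differ between expression and clinical")
        t = self.clinical["time"].to_numpy(dtype=float)
        if np.any(t <= 0):
            raise ValueError("survival times must be strictly positive")
        ev = self.clinical["event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise ValueError("event indicator must be binary")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def endpoint(self) -> str:
        return str(self.clinical["endpoint"].iloc[0])


@dataclass
class SimConfig:
    """Study design of the synthetic multi-cohort experiment.

    Defaults mirror a six-cohort, 1635-sample breast-tumor meta-analysis
    design with a 30-gene seed-centred module (pairwise correlation
    ``module_loading**2`` = 0.7) inside a 2000-gene universe of which a
    quarter is annotated to the screened chromosome arm.
    """

    n_cohorts: int = 6
    samples_per_cohort: list[int] = field(
        default_factory=lambda: [198, 286, 159, 295, 344, 353]
    )
    n_genes: int = 2000
    module_size: int = 30
    module_loading: float = float(np.sqrt(0.7))
    prognostic_genes: dict[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.30
    baseline_hazard: float = 0.01  # events per month
    noise_sd: list[float] = field(
        default_factory=lambda: [1.0, 0.8, 1.2, 0.9, 1.1, 1.0]
    )
    seed: int = 0
    locus_fraction: float = 0.25
    grade_confounding: float = 0.0  # corr(grade latent, module factor); 0 = independent

    def __post_init__(self) -> None:
        if len(self.samples_per_cohort) != self.n_cohorts:
            raise ValueError("samples_per_cohort length must equal n_cohorts")
        if len(self.noise_sd) != self.n_cohorts:
            raise ValueError("noise_sd length must equal n_cohorts")
        if any(n < 10 for n in self.samples_per_cohort):
            raise ValueError("all cohort sample counts must be >= 10")
        if not (0 < self.module_size < self.n_genes):
            raise ValueError("module_size must satisfy 0 < module_size < n_genes")
        if not (0.0 < self.module_loading < 1.0):
            raise ValueError("module_loading must lie in (0, 1)")
        if not (0.0 <= self.censoring_rate <= 1.0):
            raise ValueError("censoring_rate must lie in [0, 1]")
        if not (0.0 < self.locus_fraction <= 1.0):
            raise ValueError("locus_fraction must lie in (0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        unknown = set(self.prognostic_genes) - set(self.gene_names)
        if unknown:
            raise ValueError(f"prognostic genes outside the gene universe: {sorted(unknown)}")

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def module_genes(self) -> list[str]:
        """Planted module membership; the first member is the seed gene."""
        return self.gene_names[: self.module_size]

    @property
    def seed_gene(self) -> str:
        return self.gene_names[0]

    @property
    def n_locus_genes(self) -> int:
        return max(1, int(round(self.locus_fraction * self.n_genes)))

    @property
    def locus_genes(self) -> list[str]:
        """Genes annotated to the screened arm (includes the module)."""
        return self.gene_names[: self.n_locus_genes]

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = {
            k: (list(v) if isinstance(v, list) else dict(v) if isinstance(v, dict) else v)
            for k, v in self.__dict__.items()
        }
        payload = {
            k: float(v) if isinstance(v, numbers.Real) and not isinstance(v, (int, np.integer)) else v
            for k, v in payload.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _censoring_horizon(rates: np.ndarray, target: float) -> float:
    """Upper limit L of U(0, L) censoring giving the requested censored fraction.

    For T ~ Exp(rate_i) and C ~ U(0, L), P(C < T | rate_i) =
    (1 - exp(-rate_i L)) / (rate_i L); the mean over samples is monotone
    decreasing in L, so the root is bracketed and solved with Brent.
    """

    def censored_fraction(horizon: float) -> float:
        z = rates * horizon
        return float(np.mean((1.0 - np.exp(-z)) / z))

    lo, hi = 1e-9, 1.0
    while censored_fraction(hi) > target:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - pathological rates
            return hi
    return float(brentq(lambda L: censored_fraction(L) - target, lo, hi, xtol=1e-10))


def _covariates(rng: np.random.Generator, n: int, factor: np.ndarray, confounding: float) -> pd.DataFrame:
    age = np.clip(rng.normal(57.0, 12.0, n), 25.0, 90.0)
    size = np.clip(rng.lognormal(np.log(22.0), 0.45, n), 2.0, 120.0)
    # grade from a latent score optionally correlated with the module factor
    c = float(np.clip(confounding, 0.0, 0.99))
    latent = c * factor + np.sqrt(1.0 - c * c) * rng.standard_normal(n)
    grade = np.digitize(latent, np.quantile(latent, [0.25, 0.65])) + 1
    er = np.where(rng.random(n) < 0.65, "pos", "neg")
    node = np.where(rng.random(n) < 0.45, "pos", "neg")
    return pd.DataFrame({"age": age, "size": size, "grade": grade, "er": er, "node": node})


def simulate_cohorts(config: SimConfig) -> list[CohortBundle]:
    """Generate the configured cohorts; deterministic under a fixed seed.

    Even-indexed cohorts are written on a single-channel (log2-intensity-like)
    scale, odd-indexed cohorts as mean-centred log-ratio-like values; the last
    cohort records overall survival, all others relapse-free survival.
    """
    genes = config.gene_names
    lam = config.module_loading
    m = config.module_size
    prognostic = list(config.prognostic_genes.items())
    betas = np.array([b for _, b in prognostic], dtype=float)
    prog_idx = np.array([genes.index(g) for g, _ in prognostic], dtype=int)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_cohorts)
    bundles: list[CohortBundle] = []
    for c in range(config.n_cohorts):
        rng = np.random.default_rng(seeds[c])
        n = config.samples_per_cohort[c]
        f = rng.standard_normal(n)
        x = rng.standard_normal((config.n_genes, n))
        x[:m] = lam * f[np.newaxis, :] + np.sqrt(1.0 - lam * lam) * x[:m]

        eta = betas @ x[prog_idx] if len(prognostic) else np.zeros(n)
        rates = config.baseline_hazard * np.exp(eta)
        t_event = rng.exponential(1.0, n) / rates
        if config.censoring_rate > 0:
            horizon = _censoring_horizon(rates, config.censoring_rate)
            t_cens = rng.uniform(0.0, horizon, n)
            time = np.minimum(t_event, t_cens)
            event = (t_event <= t_cens).astype(int)
        else:
            time, event = t_event, np.ones(n, dtype=int)
        time = np.maximum(time, 1e-6)

        cohort_id = f"COHORT_{c + 1}"
        channel = "single" if c % 2 == 0 else "dual"
        scale = config.noise_sd[c]
        values = scale * x
        if channel == "single":
            values = values + 8.0
        else:
            values = values - values.mean(axis=1, keepdims=True)

        samples = [f"{cohort_id}_S{i + 1:04d}" for i in range(n)]
        expression = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
        clinical = _covariates(rng, n, f, config.grade_confounding)
        clinical.insert(0, "endpoint", "OS" if c == config.n_cohorts - 1 else "RFS")
        clinical.insert(0, "event", event)
        clinical.insert(0, "time", time)
        clinical.index = pd.Index(samples, name="sample")
        bundles.append(
            CohortBundle(cohort_id=cohort_id, expression=expression, clinical=clinical, channel=channel)
        )
    return bundles


def locus_table(config: SimConfig, chromosome: str = "1", arm: str = "q") -> pd.DataFrame:
    """Gene→locus annotation placing the first ``locus_fraction`` of the
    universe on the screened arm and the rest elsewhere (columns: gene,
    chrom, arm, start; 1-based coordinates)."""
    genes = config.gene_names
    k = config.n_locus_genes
    chroms, arms, starts = [], [], []
    for i, _ in enumerate(genes):
        if i < k:
            chroms.append(chromosome)
            arms.append(arm)
        else:
            chroms.append(str(2 + (i - k) % 21))
            arms.append("p" if (i - k) % 2 == 0 else "q")
        starts.append(1 + 100_000 * (i + 1))
    return pd.DataFrame({"gene": genes, "chrom": chroms, "arm": arms, "start": starts})


def write_fixture(bundles: list[CohortBundle], directory) -> Path:
    """Write one expression TSV and one clinical TSV per cohort plus a YAML
    manifest; values use full float precision so the ``cohort_io`` readers
    round-trip them exactly.  Returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for bundle in bundles:
        expr_name = f"{bundle.cohort_id}_expression.tsv"
        clin_name = f"{bundle.cohort_id}_clinical.tsv"
        bundle.expression.to_csv(directory / expr_name, sep="\t", float_format="%.17g")
        bundle.clinical.to_csv(directory / clin_name, sep="\t", float_format="%.17g")
        entries.append(
            {
                "cohort_id": bundle.cohort_id,
                "expression": expr_name,
                "clinical": clin_name,
                "channel": bundle.channel,
            }
        )
    manifest = directory / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"cohorts": entries}, fh, sort_keys=False)
    return manifest
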