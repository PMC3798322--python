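#!/usr/bin/env python
"""Meta-analytic survival screen of the chromosome-arm gene universe.

Per cohort, each locus gene is fitted as a univariate Cox covariate
(standardised, log-HR per SD); per-cohort estimates are pooled with
DerSimonian–Laird random effects and the consistency cascade is applied
(p < 0.005 in >= 3 cohorts AND combined p < 0.005).  Also produces the
forest-plot data for the top gene, its median-split Kaplan-Meier contrast,
and uni/multivariate Cox models against the clinical covariates.

Run analysis/01_simulate_cohorts.py first.
"""

from pathlib import Path

from metamodule import (
    SimConfig,
    cox_covariates,
    cox_per_gene,
    forest_data,
    km_stratify,
    load_bundles,
    read_locus_table,
    restrict_to_locus,
    screen_locus,
)

ROOT = Path(__file__).resolve().parents[1]
FIXTURE = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"


def main() -> None:
    bundles = load_bundles(FIXTURE / "manifest.yaml")
    config = SimConfig.from_yaml(FIXTURE / "config.yaml")
    locus = read_locus_table(FIXTURE / "locus.tsv")

    universe = list(
        restrict_to_locus(bundles[0].expression, locus, "1", "q").index
    )
    table = screen_locus(bundles, universe)
    table.round(
        {"beta_re": 5, "se_re": 5, "hr": 4, "tau2": 5, "q_stat": 3}
    ).to_csv(RESULTS / "survival_screen.tsv", sep="\t", index=False)

    passers = table[table["passes"]]
    print(f"screened {len(table)} arm genes across {len(bundles)} cohorts; "
          f"{len(passers)} pass the cascade")
    cols = ["gene", "beta_re", "hr", "p_combined", "tau2", "k", "n_sig_cohorts"]
    print(passers[cols].to_string(index=False))

    top = table.iloc[0]["gene"]
    per_cohort = [cox_per_gene(b, top) for b in bundles if top in b.expression.index]
    forest = forest_data(per_cohort)
    forest.to_csv(RESULTS / f"forest_{top}.tsv", sep="\t", index=False)
    print(f"\ntop gene {top}: forest data -> results/forest_{top}.tsv")

    bundle = bundles[0]
    km = km_stratify(bundle, bundle.expression.loc[top])
    print(f"{top} median split in {bundle.cohort_id}: log-rank p = {km.p:.3g}")

    binary = (km.groups == "high").astype(float)
    for mode in ("univariate", "multivariate"):
        fit = cox_covariates(bundle, binary, ["age", "size", "grade", "er", "node"], mode=mode)
        fit.insert(0, "gene", top)
        fit.to_csv(RESULTS / f"cox_{mode}_{top}.tsv", sep="\t", index=False)
        score_p = fit.loc[fit["variable"] == "score", "p"].iloc[0]
        print(f"{mode} Cox: {top}-high indicator p = {score_p:.3g}")


if __name__ == "__main__":
    main()
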