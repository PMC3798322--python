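#!/usr/bin/env python
"""Score pathway signatures against the tumor profiles and associate their
activation with the seed gene.

Builds a panel of up/down-tag signatures — module-derived "proliferation"
sets that genuinely co-load with the seed factor, plus random null sets —
scores them in one cohort, regresses seed-gene expression on each
signature's activation, projects the samples on the activation PCA, and
tests the module/signature gene-set overlap hypergeometrically.

Run analysis/01_simulate_cohorts.py and 03_coexpression_module.py first.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from metamodule import (
    Signature,
    SimConfig,
    activation_matrix,
    associate_with_gene,
    load_bundles,
    overlap_test,
    write_gmt,
)

ROOT = Path(__file__).resolve().parents[1]
FIXTURE = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"


def build_signatures(config: SimConfig, rng: np.random.Generator) -> list[Signature]:
    module = [g for g in config.module_genes if g != config.seed_gene]
    nulls = [g for g in config.gene_names if g not in set(config.module_genes)]
    sigs = [
        Signature("PROLIFERATION_UP", tuple(module[:15])),
        Signature("CELL_CYCLE_UP", tuple(module[15:]), tuple(rng.choice(nulls, 10, replace=False))),
    ]
    for i in range(6):
        tags = rng.choice(nulls, 25, replace=False)
        sigs.append(Signature(f"NULL_SET_{i + 1}", tuple(tags[:15]), tuple(tags[15:])))
    return sigs


def main() -> None:
    bundles = load_bundles(FIXTURE / "manifest.yaml")
    config = SimConfig.from_yaml(FIXTURE / "config.yaml")
    rng = np.random.default_rng(11)

    sigs = build_signatures(config, rng)
    write_gmt([s for s in sigs], RESULTS / "signatures.gmt")

    bundle = bundles[0]
    act = activation_matrix(bundle.expression, sigs)
    act.scores.round(4).to_csv(RESULTS / "activation_scores.tsv", sep="\t")
    print(f"scored {act.scores.shape[0]} signatures on {act.scores.shape[1]} samples "
          f"of {bundle.cohort_id}; excluded: {act.excluded or 'none'}")

    seed_expr = bundle.expression.loc[config.seed_gene]
    assoc = associate_with_gene(act, seed_expr)
    assoc.table.sort_values("p").to_csv(RESULTS / "activation_vs_seed.tsv", sep="\t", index=False)
    assoc.pca_projection.round(4).to_csv(RESULTS / "activation_pca.tsv", sep="\t")
    print("\nregression of seed expression on signature activation:")
    print(assoc.table.sort_values("p").to_string(index=False))
    print(f"activation PCA explained variance: {assoc.explained_variance_ratio}")

    members = pd.read_csv(RESULTS / "module_members.tsv", sep="\t")["gene"]
    k, p = overlap_test(members, sigs[0].up_tags, config.n_genes)
    print(f"\nmodule vs {sigs[0].name}: overlap {k} of {len(sigs[0].up_tags)} tags, "
          f"hypergeometric p = {p:.3g}")


if __name__ == "__main__":
    main()
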