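"""Reading, normalising and harmonising cohort expression/clinical data.

Pre-processing conventions: single-channel intensities are log2-transformed
unless they already look logged (max <= 30 and min >= -10, in which case the
matrix is passed through unchanged); dual-channel log-ratios are used as
given; probes are collapsed to unique gene symbols by averaging; gene
symbols are upper-cased before any matching.  Genes with more than 20%
missing values in a cohort are dropped from that cohort only; remaining
missing values stay missing (pairwise-complete in correlations, listwise in
Cox fits).  No cross-cohort normalisation is performed — every statistic is
computed within-cohort and then meta-combined.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import CohortBundle

__all__ = [
    "load_expression",
    "collapse_probes",
    "restrict_to_locus",
    "align_samples",
    "read_clinical",
    "read_probe_map",
    "read_locus_table",
    "load_bundles",
]

logger = logging.getLogger(__name__)

_LOGGED_MAX = 30.0
_LOGGED_MIN = -10.0
_MAX_MISSING_FRACTION = 0.20


def read_probe_map(path) -> pd.DataFrame:
    """TSV with columns probe_id, gene_symbol (one probe per row)."""
    pm = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_symbol"}.issubset(pm.columns):
        raise ValueError("probe map needs columns probe_id and gene_symbol")
    return pm


def read_locus_table(path) -> pd.DataFrame:
    """TSV with columns gene, chrom, arm, start (1-based)."""
    locus = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "arm": str})
    if not {"gene", "chrom", "arm", "start"}.issubset(locus.columns):
        raise ValueError("locus table needs columns gene, chrom, arm, start")
    if (locus["start"] <= 0).any():
        raise ValueError("locus start coordinates must be positive (1-based)")
    if locus["gene"].str.upper().duplicated().any():
        raise ValueError("duplicate gene symbols in locus table")
    return locus


def _looks_logged(values: np.ndarray) -> bool:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return True
    return float(finite.max()) <= _LOGGED_MAX and float(finite.min()) >= _LOGGED_MIN


def load_expression(path, probe_map: pd.DataFrame | None = None, channel: str = "single") -> pd.DataFrame:
    """Read a genes×samples (or probes×samples) TSV and normalise it.

    Single-channel matrices that look like raw intensities are transformed
    with log2(x + 1); dual-channel matrices pass through.  If ``probe_map``
    is given, rows are probe identifiers and are collapsed to gene symbols.
    """
    if channel not in ("single", "dual"):
        raise ValueError(f"channel must be 'single' or 'dual', got {channel!r}")
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError(f"empty expression matrix in {path}")
    values = matrix.to_numpy(dtype=float)

    if channel == "single" and not _looks_logged(values):
        if np.nanmin(values) < 0:
            raise ValueError("negative intensities submitted for log2 transform")
        matrix = pd.DataFrame(np.log2(values + 1.0), index=matrix.index, columns=matrix.columns)

    if probe_map is not None:
        matrix = collapse_probes(matrix, probe_map)
    else:
        matrix.index = matrix.index.astype(str).str.upper()
        matrix = matrix[~matrix.index.duplicated(keep="first")]

    # per-cohort missingness filter
    missing = matrix.isna().mean(axis=1)
    dropped = int((missing > _MAX_MISSING_FRACTION).sum())
    if dropped:
        logger.info("dropping %d genes with >%.0f%% missing values", dropped, 100 * _MAX_MISSING_FRACTION)
        matrix = matrix[missing <= _MAX_MISSING_FRACTION]
    if matrix.shape[0] == 0:
        raise ValueError("no genes left after missing-value filtering")
    return matrix


def collapse_probes(matrix: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Average multi-probe genes into one row per gene symbol.

    Probes absent from the map, mapped to an empty symbol, or mapped to more
    than one gene are dropped (logged).  Output rows are sorted
    lexicographically by upper-cased gene symbol.
    """
    pm = probe_map.copy()
    pm["probe_id"] = pm["probe_id"].astype(str)
    pm["gene_symbol"] = pm["gene_symbol"].astype(str).str.upper()
    pm = pm[pm["gene_symbol"].str.len() > 0]

    multi = pm.groupby("probe_id")["gene_symbol"].nunique()
    ambiguous = set(multi[multi > 1].index)
    if ambiguous:
        logger.warning("rejecting %d probes mapped to multiple genes", len(ambiguous))
        pm = pm[~pm["probe_id"].isin(ambiguous)]
    pm = pm.drop_duplicates("probe_id")

    mapping = pm.set_index("probe_id")["gene_symbol"]
    probes = matrix.index.astype(str)
    mapped = probes.isin(mapping.index)
    n_unmapped = int((~mapped).sum())
    if n_unmapped:
        logger.info("dropping %d unmapped probes", n_unmapped)
    if not mapped.any():
        raise ValueError("zero mappable probes")

    sub = matrix.loc[mapped].copy()
    sub.index = mapping.loc[probes[mapped]].to_numpy()
    collapsed = sub.groupby(level=0, sort=True).mean()
    collapsed.index.name = "gene"
    return collapsed


def restrict_to_locus(matrix: pd.DataFrame, locus: pd.DataFrame, chromosome: str, arm: str) -> pd.DataFrame:
    """Keep only genes annotated to ``chromosome``/``arm``; original relative
    row order of the matrix is preserved."""
    wanted = set(
        locus.loc[
            (locus["chrom"].astype(str) == str(chromosome)) & (locus["arm"] == arm),
            "gene",
        ].astype(str).str.upper()
    )
    if not wanted:
        raise ValueError(f"no genes annotated to {chromosome}{arm} in the locus table")
    keep = matrix.index.astype(str).str.upper().isin(wanted)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("restrict_to_locus: dropped %d genes outside %s%s", n_dropped, chromosome, arm)
    out = matrix.loc[keep]
    if out.shape[0] == 0:
        raise ValueError(f"zero genes left after restriction to {chromosome}{arm}")
    return out


def align_samples(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    cohort_id: str = "cohort",
    channel: str = "single",
    min_samples: int = 10,
) -> CohortBundle:
    """Restrict both tables to their sample intersection (expression column
    order) and assemble a CohortBundle; cohorts with fewer than
    ``min_samples`` common samples are rejected."""
    common = [s for s in expression.columns if s in set(clinical.index)]
    if len(common) < min_samples:
        raise ValueError(
            f"only {len(common)} samples shared between expression and clinical "
            f"(minimum {min_samples}); cohort {cohort_id} rejected"
        )
    return CohortBundle(
        cohort_id=cohort_id,
        expression=expression.loc[:, common],
        clinical=clinical.loc[common],
        channel=channel,
    )


def read_clinical(path) -> pd.DataFrame:
    clinical = pd.read_csv(path, sep="\t", index_col=0)
    if not {"time", "event"}.issubset(clinical.columns):
        raise ValueError("clinical table needs at least time and event columns")
    return clinical


def load_bundles(manifest_path) -> list[CohortBundle]:
    """Read a fixture manifest (as written by ``synthetic.write_fixture``)
    back into CohortBundles."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    bundles = []
    for entry in manifest.get("cohorts", []):
        expression = load_expression(manifest_path.parent / entry["expression"], channel=entry["channel"])
        clinical = read_clinical(manifest_path.parent / entry["clinical"])
        bundles.append(
            align_samples(expression, clinical, cohort_id=entry["cohort_id"], channel=entry["channel"])
        )
    return bundles
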