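"""Pathway-activation scoring of up/down-tag gene signatures.

A signature is a named pair of tag lists (up tags required, down tags
optional).  Activation in a sample is the mean z-scored expression of the
present up tags minus the mean of the present down tags, where each gene is
z-scored across the samples of the profile being scanned.  This mean-z
contrast is the package's concretisation of tag-based activation scoring —
it is deliberately simple, affine-invariant per gene, and antisymmetric
under swapping the tag lists; alternative scorers can be plugged in via the
``scorer`` argument of :func:`activation_matrix`.

Also provided: GMT and signed-TSV signature I/O, regression of a gene's
expression on each signature's activation (with a 2-component PCA of the
activation pattern), and the hypergeometric over-representation test used
for gene-set overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "Signature",
    "ScoredSignature",
    "ActivationMatrix",
    "score_signature",
    "activation_matrix",
    "associate_with_gene",
    "overlap_test",
    "read_gmt",
    "write_gmt",
    "read_signed_signature",
]

_MIN_UP_TAGS = 5


@dataclass(frozen=True)
class Signature:
    """Named up/down tag lists; tags are upper-cased and must be disjoint."""

    name: str
    up_tags: tuple[str, ...]
    down_tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        up = tuple(dict.fromkeys(t.upper() for t in self.up_tags))
        down = tuple(dict.fromkeys(t.upper() for t in self.down_tags))
        object.__setattr__(self, "up_tags", up)
        object.__setattr__(self, "down_tags", down)
        if not up:
            raise ValueError(f"signature {self.name!r} has no up tags")
        if set(up) & set(down):
            raise ValueError(f"signature {self.name!r} has overlapping up/down tags")


@dataclass(frozen=True)
class ScoredSignature:
    name: str
    scores: pd.Series           # per-sample activation
    up_coverage: float          # fraction of up tags present in the matrix
    down_coverage: float        # fraction of down tags present (1.0 if none)


@dataclass
class ActivationMatrix:
    """Signatures × samples activation scores plus scoring provenance."""

    scores: pd.DataFrame
    provenance: dict[str, dict] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)


def _zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    values = matrix.to_numpy(dtype=float)
    mean = np.nanmean(values, axis=1, keepdims=True)
    sd = np.nanstd(values, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[~np.isfinite(z)] = 0.0  # constant genes carry no signal
    return pd.DataFrame(z, index=matrix.index.astype(str).str.upper(), columns=matrix.columns)


def score_signature(matrix: pd.DataFrame, sig: Signature) -> ScoredSignature:
    """Activation of one signature in every sample of a genes×samples matrix.

    score(sample) = mean z over present up tags − mean z over present down
    tags (second term 0 when the signature has no down tags).  Requires at
    least 5 up tags present.
    """
    z = _zscore_rows(matrix)
    up = [g for g in sig.up_tags if g in z.index]
    if len(up) < _MIN_UP_TAGS:
        raise ValueError(
            f"signature {sig.name!r}: only {len(up)} up tags present (need >= {_MIN_UP_TAGS})"
        )
    down = [g for g in sig.down_tags if g in z.index]
    scores = z.loc[up].mean(axis=0)
    if down:
        scores = scores - z.loc[down].mean(axis=0)
    return ScoredSignature(
        name=sig.name,
        scores=scores,
        up_coverage=len(up) / len(sig.up_tags),
        down_coverage=len(down) / len(sig.down_tags) if sig.down_tags else 1.0,
    )


def activation_matrix(matrix: pd.DataFrame, sigs: list[Signature], scorer=score_signature) -> ActivationMatrix:
    """Score a list of signatures; unscoreable ones are listed in
    ``excluded`` rather than silently dropped.  Duplicate signature names
    are suffixed deterministically (name, name.2, name.3, ...)."""
    seen: dict[str, int] = {}
    rows, provenance, excluded = {}, {}, []
    for sig in sigs:
        count = seen.get(sig.name, 0) + 1
        seen[sig.name] = count
        label = sig.name if count == 1 else f"{sig.name}.{count}"
        try:
            scored = scorer(matrix, sig)
        except ValueError as exc:
            excluded.append(label)
            provenance[label] = {"scored": False, "reason": str(exc)}
            continue
        rows[label] = scored.scores
        provenance[label] = {
            "scored": True,
            "up_coverage": scored.up_coverage,
            "down_coverage": scored.down_coverage,
        }
    if not rows:
        raise ValueError("no scoreable signatures")
    scores = pd.DataFrame(rows).T
    scores.columns = matrix.columns
    return ActivationMatrix(scores=scores, provenance=provenance, excluded=excluded)


@dataclass
class AssociationResult:
    """Per-signature regression against a gene plus an activation-pattern PCA."""

    table: pd.DataFrame               # signature, slope, r2, p
    pca_projection: pd.DataFrame      # samples × (PC1, PC2)
    explained_variance_ratio: tuple[float, float]


def associate_with_gene(act: ActivationMatrix, gene_expr: pd.Series, min_samples: int = 20) -> AssociationResult:
    """Simple linear regression of a gene's expression on each signature's
    activation score (slope, r², two-sided p), plus the projection of the
    samples on the first two principal components of the activation matrix.

    The sign of each component is fixed by forcing the loading of the first
    signature to be non-negative, so the projection is deterministic.
    """
    scores = act.scores
    if scores.shape[1] < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {scores.shape[1]}")
    y = np.asarray(gene_expr, dtype=float)
    if y.size != scores.shape[1]:
        raise ValueError("gene expression length must match the activation matrix")
    if np.std(y) == 0:
        raise ValueError("constant gene expression")

    rows = []
    for name, row in scores.iterrows():
        fit = stats.linregress(row.to_numpy(dtype=float), y)
        rows.append(
            {"signature": name, "slope": fit.slope, "r2": fit.rvalue ** 2, "p": fit.pvalue}
        )
    table = pd.DataFrame(rows)

    n_comp = min(2, scores.shape[0], scores.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    proj = pca.fit_transform(scores.T.to_numpy(dtype=float))  # samples × components
    loadings = pca.components_  # components × signatures
    for i in range(n_comp):
        if loadings[i, 0] < 0:
            proj[:, i] = -proj[:, i]
            loadings[i] = -loadings[i]
    if n_comp < 2:  # degenerate one-signature matrix
        proj = np.column_stack([proj, np.zeros(proj.shape[0])])
        evr = (float(pca.explained_variance_ratio_[0]), 0.0)
    else:
        evr = tuple(float(v) for v in pca.explained_variance_ratio_[:2])
    projection = pd.DataFrame(proj[:, :2], index=scores.columns, columns=["PC1", "PC2"])
    return AssociationResult(table=table, pca_projection=projection, explained_variance_ratio=evr)


def overlap_test(set_a, set_b, universe_n: int) -> tuple[int, float]:
    """Hypergeometric over-representation test of the overlap of two gene sets.

    Returns (k, p) with k = |A ∩ B| and p = P(X >= k) for
    X ~ Hypergeometric(N=universe_n, K=|A|, n=|B|).
    """
    a = {str(g).upper() for g in set_a}
    b = {str(g).upper() for g in set_b}
    if universe_n < len(a | b):
        raise ValueError("universe smaller than the union of the two sets")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_n, len(a), len(b)))
    return k, min(p, 1.0)


def read_gmt(path) -> list[Signature]:
    """GMT reader for unsigned sets (each line: name, description, genes...);
    sets become up-tag-only signatures."""
    sigs = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sigs.append(Signature(name=parts[0], up_tags=tuple(g for g in parts[2:] if g)))
    return sigs


def write_gmt(sigs: list[Signature], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for sig in sigs:
            fh.write("\t".join([sig.name, description, *sig.up_tags]) + "\n")


def read_signed_signature(path, name: str | None = None) -> Signature:
    """Signed two-column dialect: TSV with columns gene, direction ∈ {up, down}."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "direction"}.issubset(table.columns):
        raise ValueError("signed signature needs columns gene and direction")
    direction = table["direction"].str.lower()
    bad = set(direction) - {"up", "down"}
    if bad:
        raise ValueError(f"unknown directions: {sorted(bad)}")
    return Signature(
        name=name or str(path),
        up_tags=tuple(table.loc[direction == "up", "gene"]),
        down_tags=tuple(table.loc[direction == "down", "gene"]),
    )
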