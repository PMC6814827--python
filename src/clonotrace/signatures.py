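"""Expression preprocessing and combined-Z gene-set signature scoring.

Preprocessing follows the common bulk RNA-seq recipe: drop genes with fewer
than 10 counts in at least 80% of samples, quantile-normalise across
samples, then log2(x + 1).

The combined-Z score of a gene set in a sample is

    Z(sample, set) = sum_{g in set} sign(g) * z_g(sample) / sqrt(|set|)

where z_g standardises gene g's log2 expression across samples (mean 0,
sd 1). On null data the score is approximately standard normal, so it is an
activation index carrying both magnitude and direction. Immune and stromal
infiltration scores are combined-Z surrogates over user-supplied immune and
stromal admixture sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .io_formats import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]
    direction: tuple[int, ...] | None = None  # per-gene +1/-1; None = all +1

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate genes")
        if self.direction is not None and len(self.direction) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r}: direction length mismatch")

    def signs(self) -> dict[str, int]:
        if self.direction is None:
            return {g: 1 for g in self.genes}
        return dict(zip(self.genes, self.direction))


@dataclass(frozen=True)
class SignatureScore:
    sample_id: str
    set_name: str
    z: float


def filter_low_counts(
    counts: pd.DataFrame, min_count: int = 10, frac_samples: float = 0.80
) -> pd.DataFrame:
    """Drop genes with fewer than ``min_count`` counts in >= ``frac_samples``
    of samples (the default reading of the 10-counts-across-80% rule)."""
    low = (counts < min_count).mean(axis=1) >= frac_samples
    if low.any():
        logger.info("filter_low_counts: removed %d/%d genes", int(low.sum()), len(counts))
    return counts.loc[~low]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the mean of the sorted per-sample vectors.

    Ties within a sample receive the average of the reference values they
    span (the averaged-ties convention), which keeps the transform
    idempotent. A single-sample matrix is returned unchanged.
    """
    if matrix.shape[1] <= 1:
        return matrix.copy()
    x = matrix.to_numpy(dtype=float)
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(mean_sorted)
        assigned[order] = mean_sorted
        # average reference values over tied input values
        ranks = rankdata(col, method="dense")
        sums = np.bincount(ranks, weights=assigned)
        counts = np.bincount(ranks)
        assigned = sums[ranks] / counts[ranks]
        out[:, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    return np.log2(matrix + pseudocount)


def preprocess_counts(
    counts: pd.DataFrame, min_count: int = 10, frac_samples: float = 0.80
) -> pd.DataFrame:
    """Count filter -> quantile normalisation -> log2(x+1)."""
    return log2_transform(quantile_normalize(filter_low_counts(counts, min_count, frac_samples)))


def _zscore_genes(log2_expr: pd.DataFrame) -> pd.DataFrame:
    mu = log2_expr.mean(axis=1)
    sd = log2_expr.std(axis=1, ddof=1)
    sd = sd.replace(0.0, np.nan)
    z = log2_expr.sub(mu, axis=0).div(sd, axis=0)
    return z.fillna(0.0)  # constant genes carry no signal


def combined_z_score(log2_expr: pd.DataFrame, gene_set: GeneSet) -> list[SignatureScore]:
    """Combined-Z activation index of one gene set, one score per sample."""
    present = [g for g in gene_set.genes if g in log2_expr.index]
    missing = set(gene_set.genes) - set(present)
    if not present:
        raise ValidationError(f"gene set {gene_set.name!r}: no genes in matrix")
    if missing:
        logger.warning(
            "gene set %s: %d/%d genes absent from matrix",
            gene_set.name, len(missing), len(gene_set.genes),
        )
    z = _zscore_genes(log2_expr.loc[present])
    signs = gene_set.signs()
    sign_vec = np.array([signs[g] for g in present])
    combined = (z.mul(sign_vec, axis=0)).sum(axis=0) / np.sqrt(len(present))
    return [
        SignatureScore(sample_id=str(s), set_name=gene_set.name, z=float(v))
        for s, v in combined.items()
    ]


def score_matrix(log2_expr: pd.DataFrame, gene_sets: list[GeneSet]) -> pd.DataFrame:
    """Samples x sets matrix of combined-Z scores."""
    cols = {}
    for gs in gene_sets:
        scores = combined_z_score(log2_expr, gs)
        cols[gs.name] = pd.Series({s.sample_id: s.z for s in scores})
    return pd.DataFrame(cols)


def cluster_signatures(
    scores: pd.DataFrame, metric: str = "euclidean", method: str = "average"
) -> dict:
    """Hierarchical clustering of the score matrix, rows and columns.

    Inputs are sorted by label before linkage so the dendrogram is invariant
    to the order in which samples or sets arrive.
    """
    scores = scores.sort_index(axis=0).sort_index(axis=1)
    out: dict = {"scores": scores}
    for axis, key in ((0, "rows"), (1, "cols")):
        data = scores.to_numpy() if axis == 0 else scores.to_numpy().T
        labels = list(scores.index if axis == 0 else scores.columns)
        if len(labels) < 2:
            out[key] = {"linkage": None, "order": labels}
            continue
        link = hierarchy.linkage(pdist(data, metric=metric), method=method)
        order = [labels[i] for i in hierarchy.leaves_list(link)]
        out[key] = {"linkage": link, "order": order}
    return out


def infiltration_scores(
    log2_expr: pd.DataFrame, immune_set: GeneSet, stromal_set: GeneSet
) -> pd.DataFrame:
    """Per-sample immune and stromal combined-Z surrogates."""
    imm = {s.sample_id: s.z for s in combined_z_score(log2_expr, immune_set)}
    stro = {s.sample_id: s.z for s in combined_z_score(log2_expr, stromal_set)}
    return pd.DataFrame({"immune": pd.Series(imm), "stromal": pd.Series(stro)})


def infiltration_deltas(
    scores: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Resistant-minus-baseline infiltration deltas for paired samples."""
    rows = []
    for baseline, resistant in pairs:
        rows.append(
            {
                "baseline": baseline,
                "resistant": resistant,
                "immune_delta": scores.at[resistant, "immune"] - scores.at[baseline, "immune"],
                "stromal_delta": scores.at[resistant, "stromal"] - scores.at[baseline, "stromal"],
            }
        )
    return pd.DataFrame(rows)


def emt_gene_shift(
    log2_expr: pd.DataFrame,
    epithelial_set: GeneSet,
    mesenchymal_set: GeneSet,
    sample_pair: tuple[str, str],
    fold_cut: float = 4.0,
) -> tuple[pd.DataFrame, float]:
    """Per-gene EMT fold changes between a baseline/resistant pair.

    Genes whose expression changes more than ``fold_cut``-fold (|delta
    log2| > log2(fold_cut)) are flagged. The summary statistic is the mean
    shift of the mesenchymal set minus the mean shift of the epithelial set:
    positive values indicate mesenchymal conversion at resistance.
    """
    baseline, resistant = sample_pair
    for s in sample_pair:
        if s not in log2_expr.columns:
            raise ValidationError(f"sample {s!r} absent from matrix")
    records = []
    means = {}
    for gs, label in ((epithelial_set, "epithelial"), (mesenchymal_set, "mesenchymal")):
        present = [g for g in gs.genes if g in log2_expr.index]
        deltas = log2_expr.loc[present, resistant] - log2_expr.loc[present, baseline]
        means[label] = float(deltas.mean()) if present else 0.0
        for g in present:
            d = float(deltas[g])
            records.append(
                {
                    "gene_id": g,
                    "set": label,
                    "delta_log2": d,
                    "flagged": abs(d) > np.log2(fold_cut),
                }
            )
    summary = means["mesenchymal"] - means["epithelial"]
    return pd.DataFrame(records), summary


# ---------------------------------------------------------------------------
# GMT gene-set files
# ---------------------------------------------------------------------------


def read_gene_sets_gmt(path: str) -> list[GeneSet]:
    """GMT: one set per line, name <tab> description <tab> gene1 <tab> ...

    A gene prefixed with ``-`` contributes with negative sign (down-genes of
    a directional signature)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            direction = tuple(-1 if g.startswith("-") else 1 for g in genes)
            cleaned = tuple(g.lstrip("-") for g in genes)
            sets.append(GeneSet(name=name, genes=cleaned, direction=direction))
    return sets


def write_gene_sets_gmt(path: str, sets: list[GeneSet]) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            signs = gs.signs()
            genes = [("-" if signs[g] < 0 else "") + g for g in gs.genes]
            fh.write("\t".join([gs.name, "na", *genes]) + "\n")
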