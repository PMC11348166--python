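"""Diagnostic data products for spotting gDNA contamination.

The battery mirrors what an analyst would look at after alignment: where do
fragments land (exon / intron / intergenic — the intergenic read fraction,
IR%, is the primary contamination indicator), how do per-sample expression
distributions look, what share of genes is "expressed", and do contaminated
samples drift away from their group in correlation / distance / PCA space.
Everything is returned as plain tables; rendering is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .summarization import FragmentAssignment

PCT_CATEGORIES = ("exon", "intron", "intergenic", "rRNA_exon", "organellar", "gene")


class DiagnosticsError(ValueError):
    pass


def _as_mapping(assignments) -> Mapping[str, FragmentAssignment]:
    if isinstance(assignments, Mapping):
        return assignments
    return {fa.sample_id: fa for fa in assignments}


def read_distribution(assignments) -> tuple[pd.DataFrame, pd.Series]:
    """Percentage of assigned fragments per genomic feature category.

    The denominator is the number of fragments assigned to the
    exon/intron/intergenic partition, so those three columns sum to 100;
    rRNA_exon, organellar and gene overlap are reported against the same
    denominator but sit outside the sum.  Returns (percent table, IR%).
    """
    assignments = _as_mapping(assignments)
    rows = {}
    for sid, fa in assignments.items():
        denom = sum(fa.totals.get(c, 0) for c in ("exon", "intron", "intergenic"))
        if denom == 0:
            raise DiagnosticsError(f"sample {sid!r}: zero assigned fragments")
        rows[sid] = {c: 100.0 * fa.totals.get(c, 0) / denom for c in PCT_CATEGORIES}
    pct = pd.DataFrame.from_dict(rows, orient="index")[list(PCT_CATEGORIES)]
    pct.index.name = "sample"
    ir = pct["intergenic"].rename("ir_percent")
    return pct, ir


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million mapped fragments."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise DiagnosticsError(f"zero library size for samples: {bad}")
    return counts / lib * 1e6


def tpm_from(counts: pd.DataFrame, lengths) -> pd.DataFrame:
    """Transcripts per million from counts and (effective) gene lengths.

    ``lengths`` may be a per-gene Series or a gene-by-sample DataFrame.
    Columns sum to 1e6 by construction.
    """
    if isinstance(lengths, pd.Series):
        lengths = pd.DataFrame(
            np.repeat(lengths.reindex(counts.index).values[:, None], counts.shape[1], axis=1),
            index=counts.index,
            columns=counts.columns,
        )
    rate = counts / lengths
    denom = rate.sum(axis=0)
    if (denom <= 0).any():
        raise DiagnosticsError("zero length-normalized library size")
    return rate / denom * 1e6


def size_factors_median_ratio(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalization).

    f_s = median over reference genes of counts_gs / geometric-mean_g, where
    reference genes are those with a positive count in every sample.
    """
    X = counts.values.astype(float)
    positive = (X > 0).all(axis=1)
    if not positive.any():
        raise DiagnosticsError("no gene with positive counts in every sample")
    logs = np.log(X[positive])
    geomean = np.exp(logs.mean(axis=1))
    ratios = X[positive] / geomean[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def normalize_median_ratio(counts: pd.DataFrame) -> pd.DataFrame:
    return counts / size_factors_median_ratio(counts)


@dataclass
class ExpressionSummaries:
    """Per-sample quantiles and ECDF of a transformed expression matrix."""

    transformed: pd.DataFrame
    quantiles: pd.DataFrame
    ecdf_grid: np.ndarray
    ecdf: pd.DataFrame
    mode: str


def expression_summaries(
    counts: pd.DataFrame, mode: str = "log2_norm_p1", n_grid: int = 101
) -> ExpressionSummaries:
    """Transformed expression distributions per sample.

    mode 'log2_norm_p1': log2(median-of-ratios-normalized + 1).
    mode 'log2_cpm_ecdf': log2(CPM + p) with pseudocount p = one tenth of the
    smallest positive CPM in the matrix.
    """
    if not (counts.values > 0).any():
        raise DiagnosticsError("all-zero count matrix")
    if mode == "log2_norm_p1":
        trans = np.log2(normalize_median_ratio(counts) + 1.0)
    elif mode == "log2_cpm_ecdf":
        c = cpm(counts)
        pos = c.values[c.values > 0]
        trans = np.log2(c + pos.min() / 10.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    qlevels = [0.0, 0.25, 0.5, 0.75, 1.0]
    quant = trans.quantile(qlevels).T
    quant.columns = [f"q{int(q * 100)}" for q in qlevels]
    grid = np.linspace(trans.values.min(), trans.values.max(), n_grid)
    ecdf = pd.DataFrame(
        {s: np.searchsorted(np.sort(trans[s].values), grid, side="right") / len(trans)
         for s in trans.columns},
        index=grid,
    ).T
    return ExpressionSummaries(
        transformed=trans, quantiles=quant, ecdf_grid=grid, ecdf=ecdf, mode=mode
    )


def percent_expressed(
    expr_matrix: pd.DataFrame, cutoff: float, comparator: str = "gt"
) -> pd.Series:
    """Percentage of genes per sample with expression above the cutoff (strict >)."""
    if cutoff <= 0:
        raise DiagnosticsError("cutoff must be positive")
    if comparator == "gt":
        hits = expr_matrix > cutoff
    elif comparator == "ge":
        hits = expr_matrix >= cutoff
    else:
        raise ValueError(f"unknown comparator {comparator!r}")
    return (100.0 * hits.sum(axis=0) / len(expr_matrix)).rename("pct_expressed")


@dataclass
class SampleSimilarity:
    correlation: pd.DataFrame
    distances: pd.DataFrame
    pca_scores: pd.DataFrame
    variance_explained: np.ndarray
    dendrogram_order: list[str]


def sample_similarity(log_matrix: pd.DataFrame, n_components: int | None = None) -> SampleSimilarity:
    """Pairwise Pearson correlation, Euclidean distances and PCA over samples.

    PCA is run on the gene-wise centered and unit-variance-scaled matrix with
    zero-variance genes dropped; the complete-linkage dendrogram leaf order
    is returned for heatmap display.
    """
    samples = list(log_matrix.columns)
    if len(samples) < 2:
        raise DiagnosticsError("need at least 2 samples")
    corr = log_matrix.corr(method="pearson")
    D = squareform(pdist(log_matrix.values.T, metric="euclidean"))
    distances = pd.DataFrame(D, index=samples, columns=samples)

    X = log_matrix.values.T  # samples x genes
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    if n_components is None:
        n_components = max(1, min(len(samples) - 1, Xs.shape[1], 10))
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Xs)
    pca_scores = pd.DataFrame(
        scores, index=samples, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    )
    order = leaves_list(linkage(pdist(log_matrix.values.T), method="complete"))
    return SampleSimilarity(
        correlation=corr,
        distances=distances,
        pca_scores=pca_scores,
        variance_explained=pca.explained_variance_ratio_,
        dendrogram_order=[samples[i] for i in order],
    )


@dataclass
class DiagnosticsReport:
    """The full diagnostic battery as tables."""

    per_sample_category_pct: pd.DataFrame
    ir_percent: pd.Series
    pct_expressed: dict[str, pd.Series]
    expression: ExpressionSummaries
    similarity: SampleSimilarity


def compute_diagnostics(
    assignments,
    counts: pd.DataFrame,
    lengths=None,
    cpm_cutoff: float = 1.0,
    tpm_cutoff: float = 1.0,
    mode: str = "log2_norm_p1",
) -> DiagnosticsReport:
    """Run the whole battery: read distribution, expression distributions,
    % expressed genes, and sample-similarity summaries."""
    pct, ir = read_distribution(assignments)
    expressed = {"CPM": percent_expressed(cpm(counts), cpm_cutoff)}
    if lengths is not None:
        expressed["TPM"] = percent_expressed(tpm_from(counts, lengths), tpm_cutoff)
    summaries = expression_summaries(counts, mode=mode)
    sim = sample_similarity(summaries.transformed)
    return DiagnosticsReport(
        per_sample_category_pct=pct,
        ir_percent=ir,
        pct_expressed=expressed,
        expression=summaries,
        similarity=sim,
    )
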