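"""Correction of gDNA-contaminated gene-level count matrices.

Four algorithms, all driven by the observation that genomic DNA fragments
fall uniformly (up to GC bias) over the genome, so intergenic coverage
measures the contamination level directly:

Global
    The median fragments-per-base (FPB) over intergenic regions with
    non-zero counts estimates a sample's contamination level; the expected
    contamination of a gene is that level times the gene length, and is
    subtracted from the raw count.
GC%
    Same subtraction, but the per-base level depends on GC content: a
    locally-weighted regression of intergenic FPB on GC is summarized into
    20 equal-width GC bins (median of fitted values per bin), and each gene
    is charged the estimate of its own GC bin.
IR%
    The intergenic read percentage enters a voom-style precision-weighted
    linear model as a covariate; the fitted IR% term is removed from the
    log2CPM matrix.  Output is on the log2CPM scale, not counts.
Stranded
    For stranded libraries, gDNA contributes both strands equally while
    transcription is directional, so the antisense quantification estimates
    the contamination and is subtracted from the sense quantification.

Estimators follow the scikit-learn protocol (``fit`` / ``transform``,
fitted attributes with a trailing underscore); the module-level functions
are thin wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .annotation import GcProfile
from .diagnostics import cpm as _cpm
from .summarization import GeneExpressionSet

N_GC_BINS = 20


class CorrectionError(ValueError):
    pass


def gc_bin_index(gc) -> np.ndarray:
    """Bin index for GC in [0,1] over 20 equal-width bins; the last bin is
    closed (GC = 1.0 maps to bin 19); NaN maps to -1."""
    gc = np.asarray(gc, dtype=float)
    nan = np.isnan(gc)
    idx = np.floor(np.nan_to_num(gc) * N_GC_BINS).astype(int)
    idx = np.clip(idx, 0, N_GC_BINS - 1)
    idx[nan] = -1
    return idx


@dataclass
class ContaminationModel:
    """Per-sample contamination level estimates in fragments per base."""

    sample_id: str
    global_fpb: float
    gc_bin_fpb: np.ndarray | None = None
    loess_span: float | None = None
    n_regions_used: int = 0

    def __post_init__(self) -> None:
        if self.global_fpb < 0:
            raise CorrectionError("negative global FPB")
        if self.gc_bin_fpb is not None:
            self.gc_bin_fpb = np.asarray(self.gc_bin_fpb, dtype=float)
            if self.gc_bin_fpb.size != N_GC_BINS:
                raise CorrectionError(f"expected {N_GC_BINS} GC bins")
            if (self.gc_bin_fpb < 0).any():
                raise CorrectionError("negative GC-bin FPB")
        if self.n_regions_used <= 0:
            raise CorrectionError("n_regions_used must be positive")


@dataclass
class CorrectedExpression:
    """A corrected matrix plus the parameters that produced it.

    ``matrix`` holds counts for the global/gc/stranded methods and adjusted
    log2CPM for the IR% method.
    """

    method: str
    matrix: pd.DataFrame
    covariates: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)


def _as_gc_series(gc) -> pd.Series:
    if isinstance(gc, GcProfile):
        return gc.series
    return pd.Series(gc)


def _counts_lengths(expr, lengths=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    if isinstance(expr, GeneExpressionSet):
        return expr.counts, expr.lengths
    counts = expr
    if lengths is None:
        raise CorrectionError("gene lengths required when passing a bare count matrix")
    if isinstance(lengths, pd.Series):
        lengths = pd.DataFrame(
            np.repeat(lengths.reindex(counts.index).values[:, None], counts.shape[1], axis=1),
            index=counts.index,
            columns=counts.columns,
        )
    return counts, lengths


def _check_lengths(counts: pd.DataFrame, lengths: pd.DataFrame) -> None:
    bad = lengths.index[lengths.isna().any(axis=1)]
    if len(bad):
        raise CorrectionError(f"missing gene lengths for: {list(bad)[:10]}")


def _subtract_and_clamp(counts: pd.DataFrame, contamination: np.ndarray) -> pd.DataFrame:
    corrected = np.rint(np.clip(counts.values - contamination, 0, None)).astype(np.int64)
    return pd.DataFrame(corrected, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# Global


class GlobalCorrector(BaseEstimator):
    """Global-FPB contamination subtraction.

    fit() consumes an intergenic-region-by-sample count matrix and the
    region lengths; transform() subtracts ``global_fpb_ x gene_length`` from
    a gene-by-sample count matrix, clamping at zero and rounding.
    """

    def fit(self, intergenic_counts: pd.DataFrame, region_lengths: pd.Series):
        counts = pd.DataFrame(intergenic_counts)
        lengths = region_lengths.reindex(counts.index)
        if lengths.isna().any():
            bad = list(lengths.index[lengths.isna()])[:10]
            raise CorrectionError(f"missing region lengths: {bad}")
        fpb = {}
        nused = {}
        for s in counts.columns:
            c = counts[s]
            nz = c > 0
            if not nz.any():
                raise CorrectionError(
                    f"sample {s!r}: all intergenic counts are zero — "
                    "no evidence of contamination; correction unnecessary"
                )
            fpb[s] = float(np.median(c[nz] / lengths[nz]))
            nused[s] = int(nz.sum())
        self.global_fpb_ = pd.Series(fpb, name="global_fpb")
        self.n_regions_used_ = pd.Series(nused, name="n_regions_used")
        self.models_ = {
            s: ContaminationModel(sample_id=s, global_fpb=fpb[s], n_regions_used=nused[s])
            for s in counts.columns
        }
        return self

    def transform(self, expr, lengths=None) -> pd.DataFrame:
        counts, L = _counts_lengths(expr, lengths)
        _check_lengths(counts, L)
        fpb = self.global_fpb_.reindex(counts.columns)
        if fpb.isna().any():
            raise CorrectionError(f"no fitted FPB for samples: {list(fpb.index[fpb.isna()])}")
        contamination = L.values * fpb.values[None, :]
        return _subtract_and_clamp(counts, contamination)


def estimate_global_fpb(intergenic_counts, region_lengths: pd.Series):
    """Median FPB over intergenic regions with non-zero counts, per sample.

    Accepts a region-by-sample DataFrame (returns a Series) or a single
    sample's Series (returns a float).
    """
    single = isinstance(intergenic_counts, pd.Series)
    counts = intergenic_counts.to_frame("sample") if single else intergenic_counts
    fpb = GlobalCorrector().fit(counts, region_lengths).global_fpb_
    return float(fpb.iloc[0]) if single else fpb


def global_correction(expr, global_fpb, lengths=None) -> CorrectedExpression:
    """Subtract ``global_fpb x gene_length`` from each count (clamped, rounded)."""
    counts, L = _counts_lengths(expr, lengths)
    est = GlobalCorrector()
    if isinstance(global_fpb, Mapping):
        global_fpb = pd.Series(
            {s: m.global_fpb if isinstance(m, ContaminationModel) else m for s, m in global_fpb.items()}
        )
    est.global_fpb_ = pd.Series(global_fpb).reindex(counts.columns)
    corrected = est.transform(counts, L)
    return CorrectedExpression(
        method="global",
        matrix=corrected,
        provenance={"global_fpb": est.global_fpb_},
    )


# ---------------------------------------------------------------------------
# GC%


def _nearest_fill(values: np.ndarray) -> np.ndarray:
    """Fill NaN bins from the nearest populated bin (ties to the lower bin)."""
    out = values.copy()
    populated = np.flatnonzero(~np.isnan(values))
    if populated.size == 0:
        raise CorrectionError("no populated GC bins")
    for i in np.flatnonzero(np.isnan(values)):
        j = populated[np.argmin(np.abs(populated - i))]
        out[i] = values[j]
    return out


class GCCorrector(BaseEstimator):
    """GC-stratified contamination subtraction.

    Parameters
    ----------
    span : float
        Smoothing span (fraction of points) for the locally-weighted
        regression of intergenic FPB on GC.
    min_regions, min_bins : int
        Minimum non-zero intergenic regions / distinct GC bins required to
        fit the GC trend; below that the sample falls back to its global
        FPB in every bin, with a warning.
    """

    def __init__(self, span: float = 0.75, min_regions: int = 20, min_bins: int = 3):
        self.span = span
        self.min_regions = min_regions
        self.min_bins = min_bins

    def fit(self, intergenic_counts: pd.DataFrame, region_lengths: pd.Series, region_gc):
        counts = pd.DataFrame(intergenic_counts)
        gc = _as_gc_series(region_gc).reindex(counts.index)
        lengths = region_lengths.reindex(counts.index)
        glob = GlobalCorrector().fit(counts, region_lengths)
        self.global_fpb_ = glob.global_fpb_
        bin_fpb = {}
        nused = {}
        for s in counts.columns:
            c = counts[s]
            usable = (c > 0) & gc.notna()
            n = int(usable.sum())
            nused[s] = n
            g = gc[usable].values
            fpb = (c[usable] / lengths[usable]).values
            bins = gc_bin_index(g)
            if n < self.min_regions or len(np.unique(bins)) < self.min_bins:
                warnings.warn(
                    f"sample {s!r}: only {n} usable intergenic regions in "
                    f"{len(np.unique(bins))} GC bins; falling back to the global FPB",
                    stacklevel=2,
                )
                bin_fpb[s] = np.full(N_GC_BINS, self.global_fpb_[s])
                continue
            fitted = sm.nonparametric.lowess(fpb, g, frac=self.span, return_sorted=False)
            est = np.full(N_GC_BINS, np.nan)
            for b in np.unique(bins):
                est[b] = np.median(fitted[bins == b])
            est = np.clip(_nearest_fill(est), 0.0, None)
            bin_fpb[s] = est
        self.gc_bin_fpb_ = pd.DataFrame(bin_fpb, index=pd.RangeIndex(N_GC_BINS, name="gc_bin"))
        self.models_ = {
            s: ContaminationModel(
                sample_id=s,
                global_fpb=float(self.global_fpb_[s]),
                gc_bin_fpb=self.gc_bin_fpb_[s].values,
                loess_span=self.span,
                n_regions_used=max(nused[s], 1),
            )
            for s in counts.columns
        }
        return self

    def transform(self, expr, gene_gc, lengths=None) -> pd.DataFrame:
        counts, L = _counts_lengths(expr, lengths)
        _check_lengths(counts, L)
        gc = _as_gc_series(gene_gc).reindex(counts.index)
        bins = gc_bin_index(gc.values)
        bin_fpb = self.gc_bin_fpb_.reindex(columns=counts.columns)
        if bin_fpb.isna().any().any():
            raise CorrectionError("GC-bin estimates missing for some samples")
        rate = bin_fpb.values[np.clip(bins, 0, N_GC_BINS - 1), :]
        undefined = bins == -1
        if undefined.any():
            # genes whose GC is undefined fall back to the global estimate
            rate[undefined, :] = self.global_fpb_.reindex(counts.columns).values[None, :]
        return _subtract_and_clamp(counts, L.values * rate)


def fit_gc_model(
    intergenic_counts, region_lengths: pd.Series, region_gc, span: float = 0.75
):
    """GC-bin FPB estimates (20 x samples); Series input returns a 20-vector."""
    single = isinstance(intergenic_counts, pd.Series)
    counts = intergenic_counts.to_frame("sample") if single else intergenic_counts
    est = GCCorrector(span=span).fit(counts, region_lengths, region_gc)
    return est.gc_bin_fpb_.iloc[:, 0].values if single else est.gc_bin_fpb_


def gc_correction(
    expr, gc_bin_fpb: pd.DataFrame, gene_gc, lengths=None, global_fpb=None
) -> CorrectedExpression:
    """Subtract GC-bin-specific contamination per gene (clamped, rounded)."""
    counts, L = _counts_lengths(expr, lengths)
    est = GCCorrector()
    est.gc_bin_fpb_ = pd.DataFrame(gc_bin_fpb)
    if global_fpb is None:
        global_fpb = est.gc_bin_fpb_.median(axis=0)
    est.global_fpb_ = pd.Series(global_fpb).reindex(counts.columns)
    corrected = est.transform(counts, gene_gc, L)
    return CorrectedExpression(
        method="gc",
        matrix=corrected,
        provenance={"gc_bin_fpb": est.gc_bin_fpb_},
    )


# ---------------------------------------------------------------------------
# IR%


def _build_design(samples, groups, ir_percent: pd.Series) -> pd.DataFrame:
    ir = ir_percent.reindex(samples)
    if ir.isna().any():
        raise CorrectionError(f"IR% missing for samples: {list(ir.index[ir.isna()])}")
    if float(ir.std(ddof=0)) == 0.0:
        raise CorrectionError("constant IR% across samples: covariate uninformative")
    X = pd.DataFrame({"intercept": 1.0}, index=samples)
    if groups is not None:
        g = pd.Series(groups, index=samples) if not isinstance(groups, pd.Series) else groups.reindex(samples)
        dummies = pd.get_dummies(g, prefix="group", drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    X["ir_centered"] = ir - ir.mean()
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        collinear = []
        for col in X.columns:
            if col == "intercept":
                continue
            if np.linalg.matrix_rank(X.drop(columns=col).values) == rank:
                collinear.append(col)
        raise CorrectionError(f"rank-deficient design; collinear columns: {collinear}")
    return X


class IRPercentCorrector(BaseEstimator):
    """IR%-covariate correction on the log2CPM scale (voom-style weights).

    The count matrix is transformed to ``y = log2((count + 0.5) /
    (libsize + 1) * 1e6)``; a mean-variance trend (lowess of sqrt residual
    SD on mean log2 count) yields per-observation precision weights; each
    gene is fitted by weighted least squares on
    ``[intercept | group dummies | centered IR%]``, and the fitted IR% term
    is subtracted from y.

    Parameters
    ----------
    weight_span : float
        Lowess span of the mean-variance trend.
    """

    def __init__(self, weight_span: float = 0.5):
        self.weight_span = weight_span

    def fit_transform(self, counts: pd.DataFrame, ir_percent: pd.Series, groups=None) -> pd.DataFrame:
        if counts.shape[1] < 2:
            raise CorrectionError("need at least 2 samples")
        samples = counts.columns
        X = _build_design(samples, groups, ir_percent)
        self.design_ = X
        Xv = X.values
        n, p = Xv.shape
        if n <= p:
            raise CorrectionError(f"{n} samples cannot support {p} design columns")

        lib = counts.sum(axis=0).values.astype(float)
        Y = np.log2((counts.values + 0.5) / (lib + 1.0)[None, :] * 1e6)

        # first pass: unweighted fit for the mean-variance trend
        pinv = np.linalg.pinv(Xv)
        B = Y @ pinv.T
        fitted = B @ Xv.T
        resid = Y - fitted
        sigma = np.sqrt((resid**2).sum(axis=1) / (n - p))
        log2_adj = np.log2(lib + 1.0) - np.log2(1e6)
        sx = Y.mean(axis=1) + log2_adj.mean()
        sy = np.sqrt(sigma)
        trend = sm.nonparametric.lowess(sy, sx, frac=self.weight_span, return_sorted=True)
        tx, ty = trend[:, 0], trend[:, 1]
        lam = fitted + log2_adj[None, :]
        lam = np.clip(lam, tx.min(), tx.max())
        pred_sqrt_sd = np.interp(lam, tx, ty)
        pred_sqrt_sd = np.clip(pred_sqrt_sd, 1e-6, None)
        W = pred_sqrt_sd**-4
        self.weights_ = pd.DataFrame(W, index=counts.index, columns=samples)

        beta_ir = np.empty(Y.shape[0])
        for gi in range(Y.shape[0]):
            sw = np.sqrt(W[gi])
            coef, *_ = np.linalg.lstsq(Xv * sw[:, None], Y[gi] * sw, rcond=None)
            beta_ir[gi] = coef[-1]
        self.beta_ir_ = pd.Series(beta_ir, index=counts.index, name="beta_ir")

        ir_c = X["ir_centered"].values
        adjusted = Y - beta_ir[:, None] * ir_c[None, :]
        self.log2cpm_ = pd.DataFrame(Y, index=counts.index, columns=samples)
        return pd.DataFrame(adjusted, index=counts.index, columns=samples)


def ir_percent_correction(counts: pd.DataFrame, groups, ir_percent: pd.Series) -> CorrectedExpression:
    """IR%-adjusted expression matrix on the log2CPM scale.

    Returns the adjusted matrix, the per-sample covariate table (for
    downstream design matrices), and the fitted per-gene IR% coefficient.
    """
    est = IRPercentCorrector()
    adjusted = est.fit_transform(counts, ir_percent, groups=groups)
    cov = pd.DataFrame(
        {
            "ir_percent": pd.Series(ir_percent).reindex(counts.columns),
            "group": pd.Series(groups, index=counts.columns)
            if groups is not None
            else "all",
        }
    )
    return CorrectedExpression(
        method="ir_percent",
        matrix=adjusted,
        covariates=cov,
        provenance={"beta_ir": est.beta_ir_, "weight_span": est.weight_span},
    )


# ---------------------------------------------------------------------------
# Stranded


class StrandedCorrector(BaseEstimator):
    """Sense-minus-antisense subtraction for stranded libraries (stateless)."""

    def transform(self, sense, antisense) -> pd.DataFrame:
        s = sense.counts if isinstance(sense, GeneExpressionSet) else sense
        a = antisense.counts if isinstance(antisense, GeneExpressionSet) else antisense
        if not (s.index.equals(a.index) and s.columns.equals(a.columns)):
            raise CorrectionError("sense and antisense matrices not aligned")
        return pd.DataFrame(
            np.clip(s.values - a.values, 0, None).astype(np.int64),
            index=s.index,
            columns=s.columns,
        )


def stranded_correction(sense, antisense) -> CorrectedExpression:
    """max(0, sense - antisense), elementwise."""
    corrected = StrandedCorrector().transform(sense, antisense)
    return CorrectedExpression(method="stranded", matrix=corrected)


# ---------------------------------------------------------------------------
# optional post-correction gene filters


def _unwrap(corrected):
    if isinstance(corrected, CorrectedExpression):
        return corrected.matrix, corrected
    return corrected, None


def _rewrap(matrix: pd.DataFrame, wrapper: CorrectedExpression | None, note: str):
    if wrapper is None:
        return matrix
    prov = dict(wrapper.provenance)
    prov["filters"] = list(prov.get("filters", [])) + [note]
    return CorrectedExpression(
        method=wrapper.method, matrix=matrix, covariates=wrapper.covariates, provenance=prov
    )


def filter_unsupported_multiexonic(
    corrected, n_exons: pd.Series, junction_support, min_junction_fragments: int = 1
):
    """Drop multi-exonic genes lacking splice-junction support in every sample.

    ``junction_support`` is a gene-by-sample table (or per-gene Series) of
    spliced-fragment counts.  Mono-exonic genes are always retained.
    """
    matrix, wrapper = _unwrap(corrected)
    js = junction_support
    if isinstance(js, pd.Series):
        js = js.to_frame("support")
    support = js.reindex(matrix.index).fillna(0)
    ne = n_exons.reindex(matrix.index)
    if ne.isna().any():
        raise CorrectionError(
            f"exon counts missing for genes: {list(ne.index[ne.isna()])[:10]}"
        )
    unsupported = (ne >= 2) & (support.max(axis=1) < min_junction_fragments)
    return _rewrap(matrix.loc[~unsupported], wrapper, "unsupported_multiexonic")


def filter_low_in_clean(
    corrected,
    condition_labels: pd.Series,
    contaminated_flags: pd.Series,
    cpm_cutoff: float = 1.0,
):
    """Drop genes at or below the CPM cutoff in every uncontaminated sample.

    Every condition must retain at least one uncontaminated sample for the
    comparison to be meaningful.
    """
    matrix, wrapper = _unwrap(corrected)
    cond = pd.Series(condition_labels).reindex(matrix.columns)
    flags = pd.Series(contaminated_flags).reindex(matrix.columns).astype(bool)
    clean = ~flags
    for c, sub in clean.groupby(cond):
        if not sub.any():
            raise CorrectionError(f"condition {c!r} has no uncontaminated sample")
    clean_cpm = _cpm(matrix.loc[:, clean[clean].index])
    keep = (clean_cpm > cpm_cutoff).any(axis=1)
    return _rewrap(matrix.loc[keep], wrapper, "low_in_clean")
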