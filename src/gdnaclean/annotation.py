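"""Gene models, feature catalogs, GC content, and SAF I/O.

Residual genomic DNA in an RNA-seq library produces fragments scattered over
the whole genome rather than concentrated on exons.  Detecting and correcting
that contamination therefore needs a clean partition of each chromosome into
collapsed exonic, intronic and intergenic space, plus auxiliary catalogs
(rRNA exons, organellar chromosomes) whose coverage is diagnostic on its own.
This module derives those catalogs from an Ensembl-dialect GTF and a genome
FASTA, computes per-region and per-gene GC content, and reads/writes the
Simplified Annotation Format (SAF) used by featureCounts-style counters.

Coordinates: GTF and SAF are 1-based inclusive on disk; internal arithmetic
is 0-based half-open (see :mod:`gdnaclean.intervals`); everything public is
1-based inclusive again.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import intervals

CATEGORIES = ("collapsed_exon", "intron", "intergenic", "rRNA_exon", "organellar")
DEFAULT_RRNA_BIOTYPES = ("rRNA", "rRNA_pseudogene", "Mt_rRNA")
DEFAULT_ORGANELLAR_CHROMS = ("MT",)

SAF_COLUMNS = ("GeneID", "Chr", "Start", "End", "Strand")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class Gene:
    """One gene with its exon structure (1-based inclusive intervals)."""

    gene_id: str
    chrom: str
    strand: str  # '+', '-' or '.'
    biotype: str
    exons: tuple[tuple[int, int], ...]

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def union_exons(self) -> list[tuple[int, int]]:
        """Merged exon intervals, 1-based inclusive."""
        s, e = intervals.merge([a - 1 for a, _ in self.exons], [b for _, b in self.exons])
        return [(int(a) + 1, int(b)) for a, b in zip(s, e)]

    @property
    def union_exon_length(self) -> int:
        return sum(b - a + 1 for a, b in self.union_exons())


@dataclass
class GeneModelSet:
    """All gene models of an annotation plus the chromosome sizes they live on."""

    genes: list[Gene]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AnnotationError(f"duplicate gene_ids: {dupes}")
        bad = []
        for g in self.genes:
            if not g.exons:
                raise AnnotationError(f"gene {g.gene_id} has no exons")
            L = self.chrom_lengths.get(g.chrom)
            if L is None:
                bad.append((g.gene_id, g.chrom))
                continue
            for s, e in g.exons:
                if not (1 <= s <= e <= L):
                    raise AnnotationError(
                        f"gene {g.gene_id}: exon [{s},{e}] outside 1..{L} on {g.chrom}"
                    )
        if bad:
            raise AnnotationError(
                "chromosomes absent from the sequence index: "
                + ", ".join(f"{c} (gene {g})" for g, c in bad)
            )
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def union_exon_lengths(self) -> pd.Series:
        """Total bp covered by each gene's exon union (the fallback gene length)."""
        return pd.Series(
            {g.gene_id: g.union_exon_length for g in self.genes}, name="length", dtype=float
        )

    def n_exons(self) -> pd.Series:
        return pd.Series({g.gene_id: g.n_exons for g in self.genes}, dtype=int)


@dataclass
class RegionSet:
    """Strand-annotated intervals of one feature category, SAF-serializable.

    ``regions`` columns: region_id, chrom, start, end, strand — 1-based
    inclusive.  Within a category regions are disjoint (they come out of a
    coordinate collapse); the constructor enforces it.
    """

    category: str
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.regions
        missing = [c for c in ("region_id", "chrom", "start", "end", "strand") if c not in df.columns]
        if missing:
            raise AnnotationError(f"RegionSet missing columns: {missing}")
        if df["region_id"].duplicated().any():
            raise AnnotationError("duplicate region_ids")
        if (df["start"] > df["end"]).any():
            raise AnnotationError("region with start > end")
        if (df["start"] < 1).any():
            raise AnnotationError("region with start < 1")
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            if (sub["start"].values[1:] <= sub["end"].values[:-1]).any():
                raise AnnotationError(f"overlapping regions within category on {chrom}")
        self.regions = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def lengths(self) -> pd.Series:
        df = self.regions
        return pd.Series(
            (df["end"] - df["start"] + 1).values, index=df["region_id"].values, name="length"
        )

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chrom (starts0, ends0, row_index) sorted by start, 0-based half-open."""
        out = {}
        df = self.regions
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            out[chrom] = (
                sub["start"].values.astype(np.int64) - 1,
                sub["end"].values.astype(np.int64),
                sub.index.values.astype(np.int64),
            )
        return out


@dataclass
class GcProfile:
    """GC fraction per region or gene; NaN flags an undefined value (no ACGT bases)."""

    ids: list[str]
    gc: np.ndarray
    ambiguous_base_policy: str = "exclude"

    def __post_init__(self) -> None:
        self.gc = np.asarray(self.gc, dtype=float)
        if len(self.ids) != self.gc.size:
            raise ValueError("ids and gc lengths differ")
        ok = np.isnan(self.gc) | ((self.gc >= 0) & (self.gc <= 1))
        if not ok.all():
            raise ValueError("gc values outside [0, 1]")

    @property
    def series(self) -> pd.Series:
        return pd.Series(self.gc, index=self.ids, name="gc")


def _resolve_chrom_lengths(fasta_index) -> dict[str, int]:
    if isinstance(fasta_index, Mapping):
        return {str(k): int(v) for k, v in fasta_index.items()}
    if isinstance(fasta_index, Fasta):
        return {name: len(rec) for name, rec in fasta_index.items()}
    path = str(fasta_index)
    if path.endswith(".fai"):
        fai = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "length"])
        return dict(zip(fai["chrom"].astype(str), fai["length"].astype(int)))
    fa = Fasta(path)
    return {name: len(rec) for name, rec in fa.items()}


def load_gene_models(gtf_path, fasta_index) -> GeneModelSet:
    """Parse an Ensembl-dialect GTF into gene models, validated against a sequence index.

    Parameters
    ----------
    gtf_path
        GTF with ``exon`` features carrying ``gene_id`` attributes.
    fasta_index
        Chromosome lengths: a mapping, a FASTA path, a ``.fai`` path, or an
        open :class:`pyfaidx.Fasta`.
    """
    chrom_lengths = _resolve_chrom_lengths(fasta_index)
    try:
        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises a mix of its own and ValueError
        raise AnnotationError(f"failed to parse GTF {gtf_path}: {exc}") from exc

    gene_biotype_by_id: dict[str, str] = {}
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("gene_id")
        if gid:
            bt = feat.attributes.get("gene_biotype") or feat.attributes.get("gene_type")
            gene_biotype_by_id[gid[0]] = bt[0] if bt else "unknown"

    exons: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        gid_attr = feat.attributes.get("gene_id")
        if not gid_attr or not gid_attr[0]:
            raise AnnotationError(f"exon feature without gene_id attribute: {feat}")
        gid = gid_attr[0]
        rec = exons.setdefault(
            gid, {"chrom": feat.seqid, "strand": feat.strand or ".", "biotype": None, "exons": []}
        )
        rec["exons"].append((feat.start, feat.end))
        if rec["biotype"] is None:
            bt = feat.attributes.get("gene_biotype") or feat.attributes.get("gene_type")
            if bt:
                rec["biotype"] = bt[0]

    if not exons:
        raise AnnotationError(f"no exon features found in {gtf_path}")

    missing = sorted({r["chrom"] for r in exons.values()} - set(chrom_lengths))
    if missing:
        raise AnnotationError(f"GTF chromosomes absent from FASTA index: {missing}")

    genes = []
    for gid, rec in exons.items():
        biotype = rec["biotype"] or gene_biotype_by_id.get(gid, "unknown")
        genes.append(
            Gene(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"] if rec["strand"] in "+-" else ".",
                biotype=biotype,
                exons=tuple(sorted(rec["exons"])),
            )
        )
    return GeneModelSet(genes=genes, chrom_lengths=chrom_lengths)


def _region_frame(category: str, prefix: str, per_chrom: dict[str, tuple[np.ndarray, np.ndarray]]) -> RegionSet:
    rows = []
    i = 0
    for chrom in per_chrom:
        s0, e0 = per_chrom[chrom]
        for a, b in zip(s0, e0):
            rows.append((f"{prefix}_{i:06d}", chrom, int(a) + 1, int(b), "."))
            i += 1
    df = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "strand"])
    return RegionSet(category=category, regions=df)


def build_feature_catalog(
    models: GeneModelSet,
    organellar_chroms: Sequence[str] = DEFAULT_ORGANELLAR_CHROMS,
    rRNA_biotypes: Sequence[str] = DEFAULT_RRNA_BIOTYPES,
    intergenic_flank: int = 0,
) -> dict[str, RegionSet]:
    """Derive the five coordinate-collapsed feature catalogs.

    With ``intergenic_flank=0`` the collapsed_exon / intron / intergenic
    categories partition every non-organellar chromosome exactly.  The flank
    extends gene spans before complementing, trimming annotation-edge reads
    out of the intergenic space at the cost of breaking the exact partition.
    """
    if not models.genes:
        raise AnnotationError("empty gene model set")
    for chrom in organellar_chroms:
        if chrom not in models.chrom_lengths:
            raise AnnotationError(f"organellar chromosome {chrom!r} not in chrom_lengths")

    exon_s: dict[str, list] = {}
    exon_e: dict[str, list] = {}
    span_s: dict[str, list] = {}
    span_e: dict[str, list] = {}
    intron_s: dict[str, list] = {}
    intron_e: dict[str, list] = {}
    rrna_s: dict[str, list] = {}
    rrna_e: dict[str, list] = {}

    for g in models.genes:
        c = g.chrom
        es = [s - 1 for s, _ in g.exons]
        ee = [e for _, e in g.exons]
        exon_s.setdefault(c, []).extend(es)
        exon_e.setdefault(c, []).extend(ee)
        sp = g.span
        span_s.setdefault(c, []).append(sp[0] - 1)
        span_e.setdefault(c, []).append(sp[1])
        i_s, i_e = intervals.subtract([sp[0] - 1], [sp[1]], es, ee)
        intron_s.setdefault(c, []).extend(i_s.tolist())
        intron_e.setdefault(c, []).extend(i_e.tolist())
        if g.biotype in rRNA_biotypes:
            rrna_s.setdefault(c, []).extend(es)
            rrna_e.setdefault(c, []).extend(ee)

    chrom_order = [c for c in models.chrom_lengths if c in exon_s or c in organellar_chroms]

    collapsed = {
        c: intervals.merge(exon_s.get(c, []), exon_e.get(c, [])) for c in chrom_order if c in exon_s
    }
    introns = {}
    for c in chrom_order:
        if c not in intron_s:
            continue
        ex_s, ex_e = collapsed.get(c, (np.zeros(0, np.int64), np.zeros(0, np.int64)))
        s, e = intervals.subtract(intron_s[c], intron_e[c], ex_s, ex_e)
        if s.size:
            introns[c] = (s, e)
    intergenic = {}
    for c in chrom_order:
        if c in organellar_chroms or c not in span_s:
            continue
        L = models.chrom_lengths[c]
        flanked_s = [max(0, s - intergenic_flank) for s in span_s[c]]
        flanked_e = [min(L, e + intergenic_flank) for e in span_e[c]]
        s, e = intervals.complement(flanked_s, flanked_e, L)
        if s.size:
            intergenic[c] = (s, e)
    rrna = {c: intervals.merge(rrna_s[c], rrna_e[c]) for c in chrom_order if c in rrna_s}

    organellar_rows = [
        (chrom, chrom, 1, models.chrom_lengths[chrom], ".") for chrom in organellar_chroms
    ]
    organellar = RegionSet(
        category="organellar",
        regions=pd.DataFrame(
            organellar_rows, columns=["region_id", "chrom", "start", "end", "strand"]
        ),
    )

    return {
        "collapsed_exon": _region_frame("collapsed_exon", "exon", collapsed),
        "intron": _region_frame("intron", "intron", introns),
        "intergenic": _region_frame("intergenic", "intergenic", intergenic),
        "rRNA_exon": _region_frame("rRNA_exon", "rRNA", rrna),
        "organellar": organellar,
    }


def tile_regions(rs: RegionSet, window: int) -> RegionSet:
    """Split regions into windows of at most ``window`` bp (FPB stabilization)."""
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for _, r in rs.regions.iterrows():
        start = int(r["start"])
        end = int(r["end"])
        j = 0
        while start <= end:
            stop = min(start + window - 1, end)
            rows.append((f"{r['region_id']}_w{j}", r["chrom"], start, stop, r["strand"]))
            start = stop + 1
            j += 1
    df = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "strand"])
    return RegionSet(category=rs.category, regions=df)


def _gc_of_seq(seq: str) -> float:
    up = seq.upper()
    gc = up.count("G") + up.count("C")
    at = up.count("A") + up.count("T")
    denom = gc + at
    return gc / denom if denom else float("nan")


def compute_gc(regions_or_genes, fasta_path) -> GcProfile:
    """GC fraction per region (over the interval) or per gene (over the exon union).

    Bases outside ACGT are excluded from both numerator and denominator; a
    sequence with no ACGT bases yields NaN (flagged undefined).
    """
    fa = Fasta(str(fasta_path))

    def fetch(chrom: str, start1: int, end1: int) -> str:
        if chrom not in fa:
            raise AnnotationError(f"chromosome {chrom!r} not in FASTA")
        if end1 > len(fa[chrom]) or start1 < 1:
            raise AnnotationError(
                f"interval [{start1},{end1}] beyond {chrom} length {len(fa[chrom])}"
            )
        return fa[chrom][start1 - 1 : end1].seq

    ids: list[str] = []
    gc: list[float] = []
    if isinstance(regions_or_genes, RegionSet):
        for _, r in regions_or_genes.regions.iterrows():
            ids.append(r["region_id"])
            gc.append(_gc_of_seq(fetch(r["chrom"], int(r["start"]), int(r["end"]))))
    elif isinstance(regions_or_genes, GeneModelSet):
        for g in regions_or_genes.genes:
            seq = "".join(fetch(g.chrom, s, e) for s, e in g.union_exons())
            ids.append(g.gene_id)
            gc.append(_gc_of_seq(seq))
    else:
        raise TypeError("expected a RegionSet or GeneModelSet")
    return GcProfile(ids=ids, gc=np.asarray(gc))


def write_saf(rs: RegionSet, path) -> None:
    """Write a RegionSet as a 5-column SAF table (1-based inclusive)."""
    df = rs.regions.rename(
        columns={"region_id": "GeneID", "chrom": "Chr", "start": "Start", "end": "End", "strand": "Strand"}
    )[list(SAF_COLUMNS)]
    df.to_csv(path, sep="\t", index=False)


def read_saf(path, category: str = "custom") -> RegionSet:
    """Read a SAF table back into a RegionSet; inverse of :func:`write_saf`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != SAF_COLUMNS:
            raise AnnotationError(f"{path}: expected SAF header {SAF_COLUMNS}, got {tuple(header)}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise AnnotationError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            rows.append(parts)
    df = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "strand"])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return RegionSet(category=category, regions=df)
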