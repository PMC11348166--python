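"""Deterministic synthetic references, fragment sets and contamination truth.

The generator emulates a titration experiment: a shared transcriptional
state is sequenced across sample groups into which genomic DNA was spiked
at mass fractions 0%, 0.01%, 0.1%, 1% and 10% of fragments.  RNA-origin
fragments are drawn from spliced exon space with a configurable library
strandedness purity; gDNA-origin fragments are placed over the whole genome,
uniformly or with a linear GC-density bias, with both strands represented
(random Bernoulli(1/2), or exactly balanced for noiseless stranded tests —
double-stranded DNA templates both strands equally).

Everything is reproducible bit-for-bit from a seed; all counting goes
through the same core as the BAM path (:func:`assign_fragment_table`), and
the truth tables needed to score a correction are kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from . import intervals
from .annotation import (
    Gene,
    GeneModelSet,
    GcProfile,
    RegionSet,
    build_feature_catalog,
    tile_regions,
    write_saf,
)
from .summarization import (
    FragmentAssignment,
    FragmentTable,
    GeneExpressionSet,
    assign_fragment_table,
    expression_from_assignments,
)

DEFAULT_FRACTIONS = (0.0, 1e-4, 1e-3, 1e-2, 1e-1)
GROUP_LABELS = {0.0: "0%", 1e-4: "0.01%", 1e-3: "0.1%", 1e-2: "1%", 1e-1: "10%"}


class SimulationError(ValueError):
    pass


@dataclass
class SimulationTruth:
    """Ground truth of a simulated bundle."""

    seed: int
    contamination_fraction: dict[str, float]
    gc_bias_coeffs: tuple[float, float] | None
    strandedness_purity: float
    true_counts: pd.DataFrame
    true_intergenic_fpb: pd.Series

    def __post_init__(self) -> None:
        for s, c in self.contamination_fraction.items():
            if not 0.0 <= c <= 1.0:
                raise SimulationError(f"sample {s}: contamination fraction {c} outside [0,1]")
        if (self.true_counts.values < 0).any():
            raise SimulationError("negative true counts")


def _gc_cumsums(seq: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
    z = np.zeros(1, dtype=np.int64)
    return (
        np.concatenate([z, np.cumsum(is_gc, dtype=np.int64)]),
        np.concatenate([z, np.cumsum(is_acgt, dtype=np.int64)]),
    )


@dataclass
class Reference:
    """An in-memory toy genome + annotation with derived catalogs."""

    seed: int
    models: GeneModelSet
    sequences: dict[str, str]
    catalog: dict[str, RegionSet]
    intergenic_windows: RegionSet
    window: int
    fragment_length: int = 200
    fasta_path: Path | None = None
    gtf_path: Path | None = None
    _cumsums: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._cumsums = {c: _gc_cumsums(s) for c, s in self.sequences.items()}

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return self.models.chrom_lengths

    def _interval_gc(self, chrom: str, start0: int, end0: int) -> float:
        cg, ca = self._cumsums[chrom]
        gc = cg[end0] - cg[start0]
        acgt = ca[end0] - ca[start0]
        return gc / acgt if acgt else float("nan")

    def region_gc_profile(self, rs: RegionSet) -> GcProfile:
        ids, gc = [], []
        for _, r in rs.regions.iterrows():
            ids.append(r["region_id"])
            gc.append(self._interval_gc(r["chrom"], int(r["start"]) - 1, int(r["end"])))
        return GcProfile(ids=ids, gc=np.asarray(gc))

    def gene_gc_profile(self) -> GcProfile:
        ids, gc = [], []
        for g in self.models.genes:
            tot_gc = tot = 0
            cg, ca = self._cumsums[g.chrom]
            for s1, e1 in g.union_exons():
                tot_gc += cg[e1] - cg[s1 - 1]
                tot += ca[e1] - ca[s1 - 1]
            ids.append(g.gene_id)
            gc.append(tot_gc / tot if tot else float("nan"))
        return GcProfile(ids=ids, gc=np.asarray(gc))


def _simulate_sequence(rng: np.random.Generator, length: int, gc_landscape) -> str:
    """Bases drawn independently; P(G or C) follows the landscape.

    ``gc_landscape``: a constant in [0,1]; 'gradient' for a linear sweep of
    GC from 0.30 to 0.70 along the chromosome; or 'sinusoid' (default) for
    isochore-like oscillation between 0.30 and 0.70 with eight periods per
    chromosome.  The sinusoid keeps GC independent of gene occupancy — genes
    are placed from the chromosome start, so a monotone landscape would
    confound GC with genic position.
    """
    if gc_landscape == "gradient":
        p = np.linspace(0.30, 0.70, length)
    elif gc_landscape == "sinusoid":
        x = np.arange(length)
        p = 0.5 + 0.2 * np.sin(2 * np.pi * 8 * x / length)
    else:
        p = np.full(length, float(gc_landscape))
    is_gc = rng.random(length) < p
    half = rng.integers(0, 2, length).astype(bool)
    codes = np.where(is_gc, np.where(half, ord("G"), ord("C")), np.where(half, ord("A"), ord("T")))
    return codes.astype(np.uint8).tobytes().decode("ascii")


def _place_genes(
    rng: np.random.Generator, chrom: str, chrom_length: int, n_genes: int, start_id: int
) -> list[Gene]:
    genes = []
    cursor = int(rng.integers(2_000, 6_000))
    for k in range(n_genes):
        n_exons = int(rng.integers(1, 6))
        exon_lens = rng.integers(200, 1001, n_exons)
        intron_lens = rng.integers(200, 2001, max(n_exons - 1, 0))
        exons = []
        pos = cursor
        for i in range(n_exons):
            exons.append((pos + 1, pos + int(exon_lens[i])))  # 1-based inclusive
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        if pos > chrom_length - 2_000:
            raise SimulationError(
                f"cannot place gene {start_id + k} on {chrom}: ran past position {pos}"
            )
        strand = "+" if rng.integers(0, 2) else "-"
        genes.append(
            Gene(
                gene_id=f"G{start_id + k:04d}",
                chrom=chrom,
                strand=strand,
                biotype="protein_coding",
                exons=tuple(exons),
            )
        )
        cursor = pos + int(rng.integers(2_000, 12_000))
    return genes


def _write_fasta(sequences: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_gtf(models: GeneModelSet, path: Path) -> None:
    with open(path, "w") as fh:
        for g in models.genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            s, e = g.span
            fh.write(
                f"{g.chrom}\tgdnaclean_sim\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s1, e1 in g.exons:
                fh.write(
                    f"{g.chrom}\tgdnaclean_sim\texon\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                    f'{attrs} transcript_id "{g.gene_id}.t1";\n'
                )


def make_reference(
    seed: int,
    n_chroms: int = 2,
    chrom_length: int = 1_000_000,
    n_genes: int = 150,
    gc_landscape="sinusoid",
    organellar_length: int = 20_000,
    window: int = 500,
    fragment_length: int = 200,
    out_dir=None,
) -> Reference:
    """Build a deterministic toy genome (FASTA) and annotation (GTF).

    Main chromosomes carry mono- and multi-exonic protein-coding genes plus
    one rRNA-biotype gene; an organellar chromosome ``MT`` is appended.  The
    intergenic catalog is tiled into ``window``-bp regions for stable FPB
    estimation.  With ``out_dir`` set, FASTA, GTF and SAF files are written
    (byte-identical across runs with the same seed).
    """
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    genes: list[Gene] = []
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    gid = 1
    for i in range(n_chroms):
        chrom = f"chr{i + 1}"
        sequences[chrom] = _simulate_sequence(rng, chrom_length, gc_landscape)
        genes.extend(_place_genes(rng, chrom, chrom_length, per_chrom[i], gid))
        gid += per_chrom[i]
    # one rRNA-biotype gene: relabel the first mono-exonic gene, else the first gene
    idx = next((i for i, g in enumerate(genes) if g.n_exons == 1), 0)
    g = genes[idx]
    genes[idx] = Gene(g.gene_id, g.chrom, g.strand, "rRNA", g.exons)
    sequences["MT"] = _simulate_sequence(rng, organellar_length, 0.40)
    genes.append(
        Gene(
            gene_id=f"G{gid:04d}",
            chrom="MT",
            strand="+",
            biotype="Mt_rRNA",
            exons=((1_001, 2_500),),
        )
    )
    models = GeneModelSet(genes=genes, chrom_lengths={c: len(s) for c, s in sequences.items()})
    catalog = build_feature_catalog(models, organellar_chroms=("MT",), intergenic_flank=0)
    windows = tile_regions(catalog["intergenic"], window) if window else catalog["intergenic"]
    catalog = dict(catalog)
    catalog["intergenic"] = windows

    fasta_path = gtf_path = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta_path = out / "genome.fa"
        gtf_path = out / "annotation.gtf"
        _write_fasta(sequences, fasta_path)
        _write_gtf(models, gtf_path)
        for cat, rs in catalog.items():
            write_saf(rs, out / f"{cat}.saf")
    return Reference(
        seed=seed,
        models=models,
        sequences=sequences,
        catalog=catalog,
        intergenic_windows=windows,
        window=window,
        fragment_length=fragment_length,
        fasta_path=fasta_path,
        gtf_path=gtf_path,
    )


# ---------------------------------------------------------------------------
# fragment simulation


def _genome_windows(ref: Reference) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Genome-wide window grid (chrom, start0, end0) with GC per window."""
    chroms, starts, ends, gcs = [], [], [], []
    for chrom, L in ref.chrom_lengths.items():
        edges = np.arange(0, L, ref.window)
        for s in edges:
            e = min(s + ref.window, L)
            chroms.append(chrom)
            starts.append(s)
            ends.append(e)
            gcs.append(ref._interval_gc(chrom, s, e))
    return chroms, np.array(starts), np.array(ends), np.array(gcs)


def _rna_blocks(
    rng: np.random.Generator, gene: Gene, n: int, frag_len: int
) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    """Fragment blocks in genomic coordinates for n fragments of one gene.

    Returns (blocks as flat list of (start0, end0)), per-fragment block
    counts, and spliced flags.
    """
    union = gene.union_exons()
    ex_s = np.array([s - 1 for s, _ in union], dtype=np.int64)
    ex_e = np.array([e for _, e in union], dtype=np.int64)
    ex_len = ex_e - ex_s
    cum = np.cumsum(ex_len)
    total = int(cum[-1])
    f = min(frag_len, total)
    start = rng.integers(0, total - f + 1, n)
    blocks: list[tuple[int, int]] = []
    nblocks = np.zeros(n, dtype=np.int64)
    rem = np.full(n, f, dtype=np.int64)
    cur = start.astype(np.int64).copy()
    order = []  # (frag_idx, start0, end0) in emission order
    while (rem > 0).any():
        active = rem > 0
        idx = np.flatnonzero(active)
        ei = np.searchsorted(cum, cur[active], side="right")
        within = cur[active] - np.where(ei > 0, cum[ei - 1], 0)
        g_start = ex_s[ei] + within
        avail = ex_e[ei] - g_start
        take = np.minimum(avail, rem[active])
        for k, fi in enumerate(idx):
            order.append((fi, int(g_start[k]), int(g_start[k] + take[k])))
        nblocks[idx] += 1
        cur[active] += take
        rem[active] -= take
    order.sort()
    blocks = [(s, e) for _, s, e in order]
    return blocks, nblocks, nblocks > 1


@dataclass
class SampleSim:
    """One simulated sample: fragments plus their origin truth."""

    sample_id: str
    fragments: FragmentTable
    origin: np.ndarray  # 0 = RNA, 1 = gDNA, per fragment
    true_gene_counts: pd.Series
    n_gdna: int
    true_intergenic_fpb: float


def simulate_sample(
    ref: Reference,
    sample_id: str,
    rng,
    n_fragments: int = 200_000,
    contamination_fraction: float = 0.0,
    gc_bias_coeffs: tuple[float, float] | None = None,
    strandedness_purity: float = 0.5,
    gdna_strand_mode: str = "random",
    expression: pd.Series | None = None,
) -> SampleSim:
    """Draw one sample's fragments from the reference with known truth.

    RNA fragments are drawn from spliced exon space of the expressed genes
    (multinomial over ``expression`` weights); a fraction
    ``contamination_fraction`` of fragments is of gDNA origin, placed over
    genome windows either uniformly or with density proportional to
    ``a + b * GC``.  ``gdna_strand_mode='balanced'`` emits every gDNA
    position once per strand (exact 50/50) for noiseless stranded tests.
    """
    if not 0.0 <= contamination_fraction <= 1.0:
        raise SimulationError("contamination_fraction outside [0,1]")
    if not 0.0 <= strandedness_purity <= 1.0:
        raise SimulationError("strandedness_purity outside [0,1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    f = ref.fragment_length

    if expression is None:
        main = [g.gene_id for g in ref.models.genes if g.chrom != "MT"]
        expression = pd.Series(1.0, index=main)
    expression = expression / expression.sum()

    n_gdna = int(round(n_fragments * contamination_fraction))
    if gdna_strand_mode == "balanced":
        n_gdna -= n_gdna % 2
    n_rna = n_fragments - n_gdna

    gene_counts = pd.Series(
        rng.multinomial(n_rna, expression.values), index=expression.index
    )
    chrom_index = {c: i for i, c in enumerate(ref.chrom_lengths)}

    blk_frag, blk_chrom, blk_s, blk_e = [], [], [], []
    strand = np.zeros(n_fragments, dtype=np.int8)
    spliced = np.zeros(n_fragments, dtype=bool)
    fi = 0
    for gene_id, c in gene_counts.items():
        if c == 0:
            continue
        gene = ref.models[gene_id]
        blocks, nblocks, spl = _rna_blocks(rng, gene, int(c), f)
        frag_ids = np.repeat(np.arange(fi, fi + c), nblocks)
        blk_frag.append(frag_ids)
        blk_chrom.append(np.full(len(blocks), chrom_index[gene.chrom], dtype=np.int32))
        blk_s.append(np.array([b[0] for b in blocks], dtype=np.int64))
        blk_e.append(np.array([b[1] for b in blocks], dtype=np.int64))
        spliced[fi : fi + c] = spl
        # 'reverse' library convention: read 1 antisense to the transcript
        convention = 1 if gene.strand == "+" else 0
        follow = rng.random(int(c)) < strandedness_purity
        strand[fi : fi + c] = np.where(follow, convention, 1 - convention)
        fi += int(c)

    total_bp = sum(ref.chrom_lengths.values())
    if n_gdna:
        chroms, w_s, w_e, w_gc = _genome_windows(ref)
        w_len = (w_e - w_s).astype(float)
        if gc_bias_coeffs is None:
            weights = w_len
        else:
            a, b = gc_bias_coeffs
            weights = np.clip(a + b * np.nan_to_num(w_gc, nan=0.5), 0.0, None) * w_len
        weights = weights / weights.sum()
        n_pos = n_gdna // 2 if gdna_strand_mode == "balanced" else n_gdna
        widx = rng.choice(len(w_s), size=n_pos, p=weights)
        offset = rng.integers(0, (w_e - w_s)[widx])
        starts = w_s[widx] + offset
        gchrom = np.array([chrom_index[chroms[i]] for i in widx], dtype=np.int32)
        lens = np.array([ref.chrom_lengths[chroms[i]] for i in widx], dtype=np.int64)
        starts = np.minimum(starts, lens - f)
        if gdna_strand_mode == "balanced":
            starts = np.repeat(starts, 2)
            gchrom = np.repeat(gchrom, 2)
            gstrand = np.tile(np.array([0, 1], dtype=np.int8), n_pos)
        elif gdna_strand_mode == "random":
            gstrand = rng.integers(0, 2, n_pos).astype(np.int8)
        else:
            raise SimulationError(f"unknown gdna_strand_mode {gdna_strand_mode!r}")
        blk_frag.append(np.arange(fi, fi + n_gdna))
        blk_chrom.append(gchrom)
        blk_s.append(starts)
        blk_e.append(starts + f)
        strand[fi : fi + n_gdna] = gstrand
        fi += n_gdna

    ft = FragmentTable(
        chrom_names=list(ref.chrom_lengths),
        block_frag=np.concatenate(blk_frag) if blk_frag else np.zeros(0, np.int64),
        block_chrom=np.concatenate(blk_chrom) if blk_chrom else np.zeros(0, np.int32),
        block_start=np.concatenate(blk_s) if blk_s else np.zeros(0, np.int64),
        block_end=np.concatenate(blk_e) if blk_e else np.zeros(0, np.int64),
        strand=strand,
        spliced=spliced,
    )
    origin = np.zeros(n_fragments, dtype=np.int8)
    origin[n_rna:] = 1
    # fragments are assigned exclusively (largest overlap), so the expected
    # count of an interior window is start-density x window length: the true
    # contamination level in FPB units is simply the genome-wide start density
    true_fpb = n_gdna / total_bp if n_gdna else 0.0
    all_genes = pd.Series(0, index=pd.Index(ref.models.gene_ids, name="gene_id"), dtype=np.int64)
    all_genes[gene_counts.index] = gene_counts.values
    return SampleSim(
        sample_id=sample_id,
        fragments=ft,
        origin=origin,
        true_gene_counts=all_genes,
        n_gdna=n_gdna,
        true_intergenic_fpb=true_fpb,
    )


def write_bam(ft: FragmentTable, chrom_lengths: Mapping[str, int], path) -> Path:
    """Write a FragmentTable as a coordinate-sorted, indexed single-end BAM."""
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in ft.chrom_names],
    }
    # gather blocks per fragment
    order = np.argsort(ft.block_frag, kind="stable")
    bf, bc = ft.block_frag[order], ft.block_chrom[order]
    bs, be = ft.block_start[order], ft.block_end[order]
    bounds = np.searchsorted(bf, np.arange(ft.n_fragments + 1))
    tmp = path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(tmp), "wb", header=header) as out:
        for i in range(ft.n_fragments):
            lo, hi = bounds[i], bounds[i + 1]
            if lo == hi:
                continue
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"frag{i:07d}"
            a.reference_id = int(bc[lo])
            a.reference_start = int(bs[lo])
            a.mapping_quality = 60
            a.flag = 16 if ft.strand[i] else 0
            cig = []
            aligned = 0
            for j in range(lo, hi):
                if j > lo:
                    gap = int(bs[j] - be[j - 1])
                    if gap > 0:
                        cig.append((3, gap))  # N
                mlen = int(be[j] - bs[j])
                cig.append((0, mlen))  # M
                aligned += mlen
            a.cigartuples = cig
            a.query_sequence = "A" * aligned
            out.write(a)
    pysam.sort("-o", str(path), str(tmp))
    tmp.unlink()
    pysam.index(str(path))
    return path


# ---------------------------------------------------------------------------
# multi-sample bundle


@dataclass
class DatasetBundle:
    """A full simulated experiment plus everything the corrections consume."""

    reference: Reference
    truth: SimulationTruth
    groups: pd.Series
    assignments: dict[str, FragmentAssignment]
    expression: GeneExpressionSet
    intergenic_counts: pd.DataFrame
    region_lengths: pd.Series
    region_gc: GcProfile
    gene_gc: GcProfile
    ir_percent: pd.Series
    samples: dict[str, SampleSim] | None = None


def make_dataset_I_analog(
    seed: int,
    n_fragments: int = 200_000,
    replicates: int = 3,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    gc_bias_coeffs: tuple[float, float] | None = None,
    strandedness_purity: float = 0.5,
    keep_samples: bool = False,
    out_dir=None,
    **reference_kwargs,
) -> DatasetBundle:
    """Simulate the contamination-titration design on a toy genome.

    ``replicates`` samples per contamination group (default fractions 0%,
    0.01%, 0.1%, 1%, 10% of fragments of gDNA origin), sharing one
    expression truth drawn log-normally over the main-chromosome genes.
    """
    ref = make_reference(seed, out_dir=out_dir, **reference_kwargs)
    ss = np.random.SeedSequence(seed)
    rng_expr = np.random.default_rng(ss.spawn(1)[0])
    main = [g.gene_id for g in ref.models.genes if g.chrom != "MT"]
    expression = pd.Series(rng_expr.lognormal(mean=0.0, sigma=1.5, size=len(main)), index=main)

    group_letters = "BCDEF"
    sims: dict[str, SampleSim] = {}
    groups = {}
    fracs = {}
    k = 0
    child_seeds = ss.spawn(1 + len(fractions) * replicates)[1:]
    for gi, frac in enumerate(fractions):
        label = GROUP_LABELS.get(frac, f"{100 * frac:g}%")
        for rep in range(replicates):
            sid = f"{group_letters[gi % len(group_letters)]}{rep + 1}"
            rng = np.random.default_rng(child_seeds[k])
            k += 1
            sims[sid] = simulate_sample(
                ref,
                sid,
                rng,
                n_fragments=n_fragments,
                contamination_fraction=frac,
                gc_bias_coeffs=gc_bias_coeffs,
                strandedness_purity=strandedness_purity,
                expression=expression,
            )
            groups[sid] = label
            fracs[sid] = frac

    assignments = {
        sid: assign_fragment_table(sim.fragments, ref.catalog, ref.models, sample_id=sid)
        for sid, sim in sims.items()
    }
    expr = expression_from_assignments(assignments, ref.models)
    intergenic_counts = pd.DataFrame(
        {sid: fa.per_region_counts["intergenic"] for sid, fa in assignments.items()}
    )
    region_lengths = ref.intergenic_windows.lengths
    ir = pd.Series(
        {
            sid: 100.0
            * fa.totals["intergenic"]
            / max(fa.totals["exon"] + fa.totals["intron"] + fa.totals["intergenic"], 1)
            for sid, fa in assignments.items()
        },
        name="ir_percent",
    )
    truth = SimulationTruth(
        seed=seed,
        contamination_fraction=fracs,
        gc_bias_coeffs=gc_bias_coeffs,
        strandedness_purity=strandedness_purity,
        true_counts=pd.DataFrame({sid: sims[sid].true_gene_counts for sid in sims}),
        true_intergenic_fpb=pd.Series({sid: sims[sid].true_intergenic_fpb for sid in sims}),
    )
    bundle = DatasetBundle(
        reference=ref,
        truth=truth,
        groups=pd.Series(groups, name="group"),
        assignments=assignments,
        expression=expr,
        intergenic_counts=intergenic_counts,
        region_lengths=region_lengths,
        region_gc=ref.region_gc_profile(ref.intergenic_windows),
        gene_gc=ref.gene_gc_profile(),
        ir_percent=ir,
        samples=sims if keep_samples else None,
    )
    if out_dir is not None:
        out = Path(out_dir)
        expr.counts.to_csv(out / "gene_counts.tsv", sep="\t")
        intergenic_counts.to_csv(out / "intergenic_counts.tsv", sep="\t")
        truth.true_counts.to_csv(out / "true_counts.tsv", sep="\t")
        pd.DataFrame({"group": bundle.groups, "ir_percent": ir}).to_csv(
            out / "samples.tsv", sep="\t"
        )
    return bundle
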