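"""Brute-force oracles, deliberately independent of the package internals."""

import numpy as np
import pandas as pd
import pysam


def bruteforce_assign(bam_path, catalog, models, strand_mode="unstranded"):
    """Exhaustive pairwise-overlap fragment counting straight off a BAM.

    Implements the counting contract with plain Python loops: precedence
    exon > intron > intergenic on any-block overlap, one count per category
    to the largest-overlap region (ties to the first region in table order),
    gene counts by union-exon overlap with the strand rule, junction support
    from N-CIGAR fragments.
    """
    frags = {}
    with pysam.AlignmentFile(str(bam_path)) as bf:
        chroms = bf.references
        for read in bf:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_qcfail
            ):
                continue
            rec = frags.setdefault(
                read.query_name, {"blocks": [], "strand": None, "spliced": False}
            )
            rec["blocks"].extend(
                (chroms[read.reference_id], s, e) for s, e in read.get_blocks()
            )
            if read.cigarstring and "N" in read.cigarstring:
                rec["spliced"] = True
            if read.is_read1 or not read.is_paired:
                rec["strand"] = "-" if read.is_reverse else "+"

    def regions_of(cat):
        df = catalog[cat].regions
        return [
            (row.region_id, row.chrom, int(row.start) - 1, int(row.end))
            for row in df.itertuples()
        ]

    region_lists = {cat: regions_of(cat) for cat in catalog}

    def best_region(blocks, regions):
        overlaps = {}
        for chrom, bs, be in blocks:
            for i, (rid, rchrom, rs, re) in enumerate(regions):
                if rchrom != chrom:
                    continue
                ov = min(be, re) - max(bs, rs)
                if ov > 0:
                    overlaps[i] = overlaps.get(i, 0) + ov
        if not overlaps:
            return None
        best = max(overlaps.items(), key=lambda kv: (kv[1], -kv[0]))
        return regions[best[0]][0]

    genes = [
        (gi, g.gene_id, g.chrom, g.strand, [(s - 1, e) for s, e in g.union_exons()])
        for gi, g in enumerate(models.genes)
    ]

    per_region = {
        cat: {rid: 0 for rid, *_ in region_lists[cat]} for cat in region_lists
    }
    totals = {"total_fragments": len(frags), "exon": 0, "intron": 0, "intergenic": 0,
              "rRNA_exon": 0, "organellar": 0, "unassigned": 0}
    gene_counts = {g.gene_id: 0 for g in models.genes}
    junction = {g.gene_id: 0 for g in models.genes}

    for rec in frags.values():
        blocks = rec["blocks"]
        assigned = None
        for cat, key in (
            ("collapsed_exon", "exon"),
            ("intron", "intron"),
            ("intergenic", "intergenic"),
        ):
            rid = best_region(blocks, region_lists[cat])
            if rid is not None:
                assigned = (cat, rid)
                totals[key] += 1
                break
        if assigned is not None:
            per_region[assigned[0]][assigned[1]] += 1
        else:
            totals["unassigned"] += 1
        for cat in ("rRNA_exon", "organellar"):
            rid = best_region(blocks, region_lists.get(cat, []))
            if rid is not None:
                per_region[cat][rid] += 1
                totals[cat] += 1

        gov = {}
        for gi, gid, gchrom, gstrand, exons in genes:
            ov = 0
            for chrom, bs, be in blocks:
                if chrom != gchrom:
                    continue
                for es, ee in exons:
                    o = min(be, ee) - max(bs, es)
                    if o > 0:
                        ov += o
            if ov > 0:
                gov[gi] = ov
                if rec["spliced"]:
                    junction[gid] += 1
        eligible = {}
        for gi, ov in gov.items():
            gstrand = genes[gi][3]
            if strand_mode == "unstranded" or gstrand == ".":
                eligible[gi] = ov
            elif strand_mode == "forward" and gstrand == rec["strand"]:
                eligible[gi] = ov
            elif strand_mode == "reverse" and gstrand != rec["strand"]:
                eligible[gi] = ov
        if eligible:
            best = max(eligible.items(), key=lambda kv: (kv[1], -kv[0]))
            gene_counts[genes[best[0]][1]] += 1

    return {
        "per_region": {cat: pd.Series(per_region[cat]) for cat in per_region},
        "per_gene": pd.Series(gene_counts),
        "junction": pd.Series(junction),
        "totals": totals,
    }
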