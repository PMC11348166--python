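import numpy as np
import pandas as pd
import pytest

import gdnaclean as gd

# deterministic 1 kb toy chromosome: enough structure for GC tests
_RNG = np.random.default_rng(424242)
TOY_CHR1 = "".join(_RNG.choice(list("ACGT"), size=1000))
TOY_MT = "".join(_RNG.choice(list("ACGT"), size=200))

TOY_GTF = """\
chr1\ttoy\tgene\t1\t300\t.\t+\t.\tgene_id "G1"; gene_biotype "protein_coding";
chr1\ttoy\texon\t1\t100\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t"; gene_biotype "protein_coding";
chr1\ttoy\texon\t201\t300\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t"; gene_biotype "protein_coding";
chr1\ttoy\texon\t401\t500\t.\t-\t.\tgene_id "G2"; transcript_id "G2.t"; gene_biotype "rRNA";
chr1\ttoy\texon\t601\t650\t.\t+\t.\tgene_id "G3"; transcript_id "G3.t"; gene_biotype "lincRNA";
chr1\ttoy\texon\t701\t800\t.\t+\t.\tgene_id "G3"; transcript_id "G3.t"; gene_biotype "lincRNA";
"""


@pytest.fixture(scope="session")
def toy_files(tmp_path_factory):
    d = tmp_path_factory.mktemp("toy")
    fasta = d / "toy.fa"
    with open(fasta, "w") as fh:
        fh.write(">chr1\n")
        for i in range(0, 1000, 60):
            fh.write(TOY_CHR1[i : i + 60] + "\n")
        fh.write(">MT\n")
        for i in range(0, 200, 60):
            fh.write(TOY_MT[i : i + 60] + "\n")
    gtf = d / "toy.gtf"
    gtf.write_text(TOY_GTF)
    return {"fasta": fasta, "gtf": gtf, "chr1": TOY_CHR1, "mt": TOY_MT}


@pytest.fixture(scope="session")
def toy_models(toy_files):
    return gd.load_gene_models(toy_files["gtf"], {"chr1": 1000, "MT": 200})


@pytest.fixture(scope="session")
def small_reference():
    """A compact simulated genome shared by counting/strandedness tests."""
    return gd.make_reference(seed=7, n_chroms=1, chrom_length=300_000, n_genes=18)


@pytest.fixture(scope="session")
def analog_bundle():
    """The contamination-titration experiment at its default scale."""
    return gd.make_dataset_I_analog(seed=101)
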