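"""Shared fixtures: toy VCF/FASTA/GTF fixtures are generated at test time."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from cistrans import SimConfig

G1 = ["AUS1", "AUS2", "AUS3"]
G2 = ["TIM1", "TIM2", "TIM3"]
HYB = ["HYB1", "HYB2", "HYB3"]

# 5 records: 2 qualifying fixed differences, 1 heterozygous parental,
# 1 multiallelic, 1 indel
TOY_VCF_RECORDS = [
    # chrom pos ref alt  AUS genotypes+ADs            TIM                         HYB
    ("chr1", 100, "A", "G",
     ["0/0:9,0", "0/0:12,0", "0/0:7,0"], ["1/1:0,11", "1/1:0,8", "1/1:0,10"],
     ["0/1:7,5", "0/1:6,6", "0/1:8,4"]),
    ("chr1", 250, "C", "T",
     ["0/0:20,0", "0/0:18,0", "0/0:25,0"], ["1/1:0,22", "1/1:0,19", "1/1:0,21"],
     ["0/1:10,11", "0/1:12,9", "0/1:11,10"]),
    ("chr1", 300, "G", "A",  # one heterozygous parental -> excluded
     ["0/0:9,0", "0/1:5,5", "0/0:8,0"], ["1/1:0,9", "1/1:0,7", "1/1:0,8"],
     ["0/1:4,5", "0/1:5,4", "0/1:6,3"]),
    ("chr2", 50, "T", "C,G",  # multiallelic -> excluded
     ["0/0:9,0,0", "0/0:8,0,0", "0/0:7,0,0"], ["1/1:0,9,0", "1/1:0,8,0", "1/1:0,7,0"],
     ["0/1:4,5,0", "0/1:5,4,0", "0/1:6,3,0"]),
    ("chr2", 80, "AT", "A",  # indel -> excluded
     ["0/0:9,0", "0/0:8,0", "0/0:7,0"], ["1/1:0,9", "1/1:0,8", "1/1:0,7"],
     ["0/1:4,5", "0/1:5,4", "0/1:6,3"]),
]


def write_vcf(path, records, samples=None, record_order=None):
    samples = samples or (G1 + G2 + HYB)
    order = record_order if record_order is not None else range(len(records))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chr1,length=10000>\n##contig=<ID=chr2,length=10000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        default = G1 + G2 + HYB
        for i in order:
            chrom, pos, ref, alt, aus, tim, hyb = records[i]
            by_sample = dict(zip(default, aus + tim + hyb))
            cells = [by_sample[s] for s in samples]
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD\t" + "\t".join(cells) + "\n")
    return path


@pytest.fixture
def toy_vcf(tmp_path):
    return write_vcf(tmp_path / "toy.vcf", TOY_VCF_RECORDS)


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "ref.fa"
    path.write_text(">chr1\nACGTACGTAC\n>chr2\nGGGGCCCC\n")
    return path


TOY_GTF = textwrap.dedent("""\
    chr1\tsrc\tgene\t1000\t5000\t.\t+\t.\tgene_id "g1";
    chr1\tsrc\ttranscript\t1000\t5000\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
    chr1\tsrc\texon\t1000\t2000\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
    chr1\tsrc\texon\t3000\t5000\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
    chr1\tsrc\tfive_prime_utr\t1000\t1100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
    chr1\tsrc\tgene\t8000\t9000\t.\t-\t.\tgene_id "g2";
    chr1\tsrc\ttranscript\t8000\t9000\t.\t-\t.\tgene_id "g2"; transcript_id "t2";
    chr1\tsrc\texon\t8000\t9000\t.\t-\t.\tgene_id "g2"; transcript_id "t2";
    chr2\tsrc\tgene\t100\t400\t.\t+\t.\tgene_id "g3";
    chr2\tsrc\ttranscript\t100\t400\t.\t+\t.\tgene_id "g3"; transcript_id "t3";
    chr2\tsrc\texon\t100\t400\t.\t+\t.\tgene_id "g3"; transcript_id "t3";
""")


@pytest.fixture
def toy_gtf(tmp_path):
    path = tmp_path / "models.gtf"
    path.write_text(TOY_GTF)
    return path


@pytest.fixture
def power_site_config():
    """Well-powered site-level configuration: replicated 3+3+3 design,
    parental baseline ~500 reads, |cis| = |trans| = 2 log2 units."""
    def make(n_features, seed, fractions):
        return SimConfig(
            n_features=n_features,
            seed=seed,
            mean_log_baseline=float(np.log2(500)),
            dispersion=0.05,
            fixed_effect_log2=2.0,
            category_fractions=fractions,
        )
    return make
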