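"""Shared fixtures: tiny hand-built panels and a writable VCF fixture."""

import numpy as np
import pytest

from hapedit.panel_io import GenomicInterval, PhasedPanel, SNPSite


def make_sites(positions, chrom="chr8", freqs=None):
    freqs = freqs if freqs is not None else [0.0] * len(positions)
    return [
        SNPSite(f"rs{i + 1}", chrom, int(p), "A", "G", float(f))
        for i, (p, f) in enumerate(zip(positions, freqs))
    ]


def panel_from_haplotype_rows(rows, positions=None, chrom="chr8"):
    """Panel from explicit haplotype rows (list of 0/1 strings), frequencies
    recomputed from the matrix."""
    matrix = np.array([[int(c) for c in row] for row in rows], dtype=np.int8)
    n_sites = matrix.shape[1]
    positions = positions or [1000 * (j + 1) for j in range(n_sites)]
    panel = PhasedPanel(
        make_sites(positions, chrom),
        [f"ind{k + 1}" for k in range(matrix.shape[0] // 2)],
        matrix,
    )
    return panel.with_recomputed_frequencies()


@pytest.fixture
def ten_individual_panel():
    """10 individuals x 4 sites with a mix of het and hom genotypes."""
    rng = np.random.default_rng(42)
    rows = rng.integers(0, 2, size=(20, 4))
    return panel_from_haplotype_rows(["".join(map(str, r)) for r in rows])


@pytest.fixture
def gene_interval():
    return GenomicInterval("chr8", 100_000, 140_000, "GENE")


@pytest.fixture
def vcf_fixture(tmp_path):
    """Hand-written VCF: 2 phased biallelic SNPs, 1 indel, 1 multiallelic
    SNP, and 1 site with an unphased genotype; 3 samples."""
    text = """\
##fileformat=VCFv4.2
##contig=<ID=chr8>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr8\t100\trs_a\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0
chr8\t200\tindel1\tAT\tA\t.\tPASS\t.\tGT\t0|1\t0|0\t0|0
chr8\t300\tmulti1\tA\tG,T\t.\tPASS\t.\tGT\t0|1\t0|2\t0|0
chr8\t400\trs_b\tC\tT\t.\tPASS\t.\tGT\t1|0\t0|0\t0|1
chr8\t500\trs_unph\tG\tA\t.\tPASS\t.\tGT\t0/1\t0|0\t1|1
"""
    path = tmp_path / "fixture.vcf"
    path.write_text(text)
    return str(path)
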