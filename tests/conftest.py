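"""Shared fixtures: a tiny hand-built annotation and small simulator configs."""

from __future__ import annotations

import textwrap

import pytest

from granuleseq.synthetic import PlantedModuleEffect, ProteomicsPlan, SyntheticConfig

# chr1 is "ACGT" repeated: GC fraction 0.5 everywhere.
CHR1 = "ACGT" * 200

# Gene A (+): exons 1-60 and 101-200 (1-based), CDS 31-60 + 101-160
#   -> utr5 30 nt, cds 90 nt, utr3 40 nt, total 160 nt
# Gene B (-): exons 301-360 and 401-500, CDS 341-360 + 401-460
#   -> on minus strand utr3 is the left 40 nt, utr5 the right 40 nt
# Gene C: single-exon lncRNA 601-700
TINY_GTF = textwrap.dedent(
    """\
    ##provenance: hand-built test annotation
    chr1\ttest\texon\t1\t60\t.\t+\t.\tgene_id "GA"; transcript_id "GA.t1"; gene_type "protein_coding";
    chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "GA"; transcript_id "GA.t1"; gene_type "protein_coding";
    chr1\ttest\tCDS\t31\t60\t.\t+\t0\tgene_id "GA"; transcript_id "GA.t1"; gene_type "protein_coding";
    chr1\ttest\tCDS\t101\t160\t.\t+\t0\tgene_id "GA"; transcript_id "GA.t1"; gene_type "protein_coding";
    chr1\ttest\texon\t301\t360\t.\t-\t.\tgene_id "GB"; transcript_id "GB.t1"; gene_type "protein_coding";
    chr1\ttest\texon\t401\t500\t.\t-\t.\tgene_id "GB"; transcript_id "GB.t1"; gene_type "protein_coding";
    chr1\ttest\tCDS\t341\t360\t.\t-\t0\tgene_id "GB"; transcript_id "GB.t1"; gene_type "protein_coding";
    chr1\ttest\tCDS\t401\t460\t.\t-\t0\tgene_id "GB"; transcript_id "GB.t1"; gene_type "protein_coding";
    chr1\ttest\texon\t601\t700\t.\t+\t.\tgene_id "GC"; transcript_id "GC.t1"; gene_type "lncRNA";
    """
)


@pytest.fixture()
def tiny_gtf(tmp_path):
    path = tmp_path / "tiny.gtf"
    path.write_text(TINY_GTF)
    return path


@pytest.fixture()
def tiny_seqs():
    return {"chr1": CHR1}


@pytest.fixture()
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fa"
    lines = [CHR1[i : i + 60] for i in range(0, len(CHR1), 60)]
    path.write_text(">chr1\n" + "\n".join(lines) + "\n")
    return path


def small_plan(**overrides) -> ProteomicsPlan:
    defaults = dict(
        n_control=15,
        n_asymad=15,
        n_ad=15,
        n_modules=5,
        proteins_per_class=3,
        planted_effects=(),
    )
    defaults.update(overrides)
    return ProteomicsPlan(**defaults)


@pytest.fixture()
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        seed=42, n_genes=250, genes_per_chrom=100, proteomics=small_plan()
    )


@pytest.fixture()
def planted_small_config() -> SyntheticConfig:
    plan = small_plan(
        n_control=40,
        n_asymad=40,
        n_ad=40,
        planted_effects=(PlantedModuleEffect("M1", "enriched", (0.0, -0.7, -1.4)),),
    )
    return SyntheticConfig(seed=7, n_genes=250, genes_per_chrom=100, proteomics=plan)
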