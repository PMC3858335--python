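import pytest

from cypscope import allele_catalog, popfreq, textmine_relations as tm

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CSQ_CLASS,Number=.,Type=String,Description="gene|consequence|aa_change per alt">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=19>
"""


def make_vcf(path, rows, samples=("S1", "S2", "S3")):
    """Write a minimal annotated VCF. ``rows`` are (pos, id, ref, alt, info, gts)."""
    lines = [VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)]
    for pos, vid, ref, alt, info, gts in rows:
        lines.append(f"19\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t" + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture(scope="session")
def lexicon():
    return tm.default_lexicon()


@pytest.fixture(scope="session")
def catalog_records():
    return allele_catalog.load_catalog()


@pytest.fixture(scope="session")
def table2_results():
    return popfreq.load_table_results()
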