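import numpy as np
import pandas as pd
import pytest

from triadscope.bias import ExpressionMatrix
from triadscope.fixtures import load_table1_records, load_table3_records
from triadscope.roster import HomoeologRecord, Triad, assemble_triads

ROSTER_HEADER = (
    "homoeolog_id\tgene_name\tsubgenome\tchromosome\tarm\tstart_bp\tend_bp\tgroup_label"
)


def make_record(
    hid="h1",
    gene="g1",
    sub="A",
    chrom=None,
    arm="S",
    start=100,
    end=200,
    group="A",
):
    return HomoeologRecord(
        homoeolog_id=hid,
        gene_name=gene,
        subgenome=sub,
        chromosome=chrom or f"1{sub}",
        arm=arm,
        start_bp=start,
        end_bp=end,
        group_label=group,
    )


def make_triad(gene="g1", placements=(("A", "1A", "S"), ("B", "1B", "S"), ("D", "1D", "S"))):
    """Triad with members at explicit (subgenome, chromosome, arm) placements."""
    t = Triad(gene_name=gene)
    for i, (sub, chrom, arm) in enumerate(placements):
        t.members[sub] = make_record(
            hid=f"{gene}_{sub}", gene=gene, sub=sub, chrom=chrom, arm=arm,
            start=1000 * (i + 1), end=1000 * (i + 1) + 99,
        )
    return t


def make_matrix(tpm_by_homoeolog, samples_meta):
    """ExpressionMatrix from {homoeolog: {sample: tpm}} and {sample: condition}."""
    values = pd.DataFrame(tpm_by_homoeolog).T.astype(float)
    meta = pd.DataFrame(
        {
            "tissue": "leaf",
            "stage": "seedling",
            "condition": pd.Series(samples_meta),
            "replicate": "1",
        }
    )
    meta.index.name = "sample_id"
    return ExpressionMatrix(values=values[list(samples_meta)], sample_meta=meta)


@pytest.fixture(scope="session")
def table1_records():
    return load_table1_records()


@pytest.fixture(scope="session")
def table3_records():
    return load_table3_records()


@pytest.fixture(scope="session")
def table3_triads(table3_records):
    return assemble_triads(table3_records)


@pytest.fixture
def roster_file(tmp_path):
    """Write roster rows (tab-joined tuples) to a TSV and return the path."""

    def _write(rows, header=ROSTER_HEADER):
        path = tmp_path / "roster.tsv"
        lines = [header] + ["\t".join(str(x) for x in r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
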