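import pytest

from endseq.alignments import ExperimentSet
from endseq.cli import run_pipeline
from endseq.scan import ScanConfig
from endseq.simdata import (
    SimSpec,
    simulate_end_reads,
    simulate_transcriptome,
    write_gene_table,
)

#: the 3'-end analysis recipe used throughout: 100-base windows overlapping
#: by 50, 5 kb extension, p <= 0.05 windows, poly(A/T) run filter at 10
RECIPE_3P = dict(
    w_len=100, w_olap=50, w_ext=5000, sig_test=0.05, filt_at=10
)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("fixtures")


@pytest.fixture(scope="session")
def bulk500(fixture_dir):
    """500-gene bulk 3'-end fixture with planted truth."""
    spec = SimSpec(seed=101, n_genes=500)
    sim = simulate_transcriptome(spec)
    table = fixture_dir / "bulk500.genes.txt"
    sam = fixture_dir / "bulk500.sam"
    write_gene_table(sim.records, str(table))
    truth = simulate_end_reads(sim, spec, str(sam))
    return {
        "spec": spec,
        "sim": sim,
        "table": str(table),
        "sam": str(sam),
        "truth": truth,
    }


@pytest.fixture(scope="session")
def pipeline500(bulk500, fixture_dir):
    """Full two-pass run of the 3'-end recipe on the 500-gene fixture."""
    config = ScanConfig(multimap="proper", **RECIPE_3P)
    prefix = str(fixture_dir / "bulk500.out")
    result = run_pipeline(
        ExperimentSet.single(bulk500["sam"], "e1"),
        bulk500["table"],
        "gene_table",
        config,
        prefix,
    )
    return {"result": result, "prefix": prefix, "config": config}


@pytest.fixture(scope="session")
def bulk60(fixture_dir):
    """Smaller bulk fixture for paired filtered/unfiltered runs."""
    spec = SimSpec(seed=202, n_genes=60)
    sim = simulate_transcriptome(spec)
    table = fixture_dir / "bulk60.genes.txt"
    sam = fixture_dir / "bulk60.sam"
    write_gene_table(sim.records, str(table))
    truth = simulate_end_reads(sim, spec, str(sam))
    return {
        "spec": spec,
        "sim": sim,
        "table": str(table),
        "sam": str(sam),
        "truth": truth,
    }
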