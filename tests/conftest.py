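import pytest

from fdefminer.motif_scan import SeedProfile
from fdefminer.pipeline import PipelineConfig, run_pipeline
from fdefminer.synthetic_data import (
    default_benchmark_spec,
    plant_genes,
    write_outputs,
)


@pytest.fixture(scope="session")
def profile():
    return SeedProfile.from_seed_fasta()


@pytest.fixture(scope="session")
def benchmark():
    """A small planted-truth genome shared across module tests."""
    spec = default_benchmark_spec(n_genes=12, seed=7)
    contigs, truth = plant_genes(spec)
    return spec, contigs, truth


@pytest.fixture(scope="session")
def pipeline_run(benchmark, tmp_path_factory):
    """One full pipeline run on the shared benchmark genome."""
    _, contigs, truth = benchmark
    outdir = tmp_path_factory.mktemp("pipeline")
    write_outputs(contigs, truth, outdir)
    config = PipelineConfig(
        genome=outdir / "genome.fna", out_dir=outdir / "out",
        seed=3, bootstrap_reps=50,
    )
    return run_pipeline(config), truth, config


def overlap(a, b):
    return not (a[1] < b[0] or a[0] > b[1])


def match_genes(result, truth):
    """Pair discovered genes with truth genes by contig/strand/span overlap."""
    pairs = []
    used = set()
    for tg in truth.genes:
        if tg.pseudogene:
            continue
        hit = None
        for i, dg in enumerate(result.genes):
            if i in used:
                continue
            if (dg.model.contig == tg.contig
                    and dg.model.strand == tg.strand
                    and overlap(dg.model.span,
                                (tg.exons[0][0], tg.exons[-1][1]))):
                hit = (i, dg)
                break
        if hit is not None:
            used.add(hit[0])
        pairs.append((tg, hit[1] if hit else None))
    return pairs
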