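import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from binsplice import (
    BinSplicingTest,
    GeneModel,
    NBExactTest,
    TranscriptomeModel,
    bins_to_frame,
    flatten_model,
)
from binsplice.simulate import (
    default_profile,
    generate_genome_annotation,
    simulate_counts,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Toy genes (coordinates follow the 1-based inclusive annotation convention
# converted to internal 0-based half-open)
# ---------------------------------------------------------------------------


@pytest.fixture
def toyg1():
    """Two isoforms: intron retained in t2 -> one IR AS-bin."""
    return GeneModel(
        chrom="chr1",
        strand="+",
        transcripts={"t1": [(100, 200), (300, 400)], "t2": [(100, 400)]},
    )


@pytest.fixture
def toyg2():
    """t2 extends the first exon's donor edge -> Alt5SS bin on + strand."""
    return GeneModel(
        chrom="chr1",
        strand="+",
        transcripts={"t1": [(100, 200), (300, 400)], "t2": [(100, 250), (300, 400)]},
    )


@pytest.fixture
def toyg3():
    """Middle exon of t1 absent from t2 -> ES bin."""
    return GeneModel(
        chrom="chr1",
        strand="+",
        transcripts={
            "t1": [(100, 200), (300, 350), (400, 500)],
            "t2": [(100, 200), (400, 500)],
        },
    )


TOY_GFF3 = """##gff-version 3
chr1\ttoy\tgene\t101\t400\t.\t+\t.\tID=TOYG1
chr1\ttoy\tmRNA\t101\t400\t.\t+\t.\tID=TOYG1.t1;Parent=TOYG1
chr1\ttoy\texon\t101\t200\t.\t+\t.\tID=TOYG1.t1.e1;Parent=TOYG1.t1
chr1\ttoy\texon\t301\t400\t.\t+\t.\tID=TOYG1.t1.e2;Parent=TOYG1.t1
chr1\ttoy\tmRNA\t101\t400\t.\t+\t.\tID=TOYG1.t2;Parent=TOYG1
chr1\ttoy\texon\t101\t400\t.\t+\t.\tID=TOYG1.t2.e1;Parent=TOYG1.t2
"""

TOY_GTF = """chr1\ttoy\texon\t101\t200\t.\t+\t.\tgene_id "TOYG1"; transcript_id "TOYG1.t1";
chr1\ttoy\texon\t301\t400\t.\t+\t.\tgene_id "TOYG1"; transcript_id "TOYG1.t1";
chr1\ttoy\texon\t101\t400\t.\t+\t.\tgene_id "TOYG1"; transcript_id "TOYG1.t2";
"""


@pytest.fixture
def toy_gff3_path(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(TOY_GFF3)
    return p


@pytest.fixture
def toy_gtf_path(tmp_path):
    p = tmp_path / "toy.gtf"
    p.write_text(TOY_GTF)
    return p


# ---------------------------------------------------------------------------
# Random gene structures for property tests
# ---------------------------------------------------------------------------


def random_gene_model(rng: np.random.Generator) -> GeneModel:
    """A random valid multi-isoform gene on a 1 kb locus."""
    n_tx = int(rng.integers(1, 5))
    strand = "+" if rng.random() < 0.5 else "-"
    transcripts = {}
    for t in range(n_tx):
        n_exons = int(rng.integers(1, 5))
        pos = np.sort(rng.choice(np.arange(0, 1000), size=2 * n_exons, replace=False))
        transcripts[f"t{t}"] = [
            (int(pos[2 * i]), int(pos[2 * i + 1])) for i in range(n_exons)
        ]
    return GeneModel(chrom="chrR", strand=strand, transcripts=transcripts)


def mirror_gene(gene: GeneModel, span: int = 1000) -> GeneModel:
    """Reflect coordinates (x -> span - x) and flip the strand."""
    return GeneModel(
        chrom=gene.chrom,
        strand="-" if gene.strand == "+" else "+",
        transcripts={
            tid: sorted((span - e, span - s) for s, e in exons)
            for tid, exons in gene.transcripts.items()
        },
    )


# ---------------------------------------------------------------------------
# The default synthetic study, generated once per session
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def default_study():
    """Annotation + bins + counts of the default planted profile."""
    cfg = default_profile()
    ann = generate_genome_annotation(cfg)
    bdf = bins_to_frame(flatten_model(ann.model))
    sim = simulate_counts(ann.model, bdf, cfg, gene_class=ann.gene_class)
    return {"cfg": cfg, "ann": ann, "bins": bdf, "sim": sim}


@pytest.fixture(scope="session")
def default_de_results(default_study):
    return NBExactTest(default_study["sim"].gene_cm).fit()


@pytest.fixture(scope="session")
def default_ds_results(default_study):
    ann = default_study["ann"]
    gene_lengths = pd.Series({g: gm.exonic_length() for g, gm in ann.model.genes.items()})
    model = BinSplicingTest(
        default_study["bins"],
        default_study["sim"].bin_cm,
        default_study["sim"].gene_cm,
        gene_lengths,
        monoexonic=ann.model.monoexonic_genes,
    )
    return model.fit()
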