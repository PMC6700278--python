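"""Synthetic genomes, annotations and NB count matrices with planted effects.

The generator emulates the data a two-genotype RNA-seq splicing study
consumes: a toy genome with canonical GT..AG splice sites and
consensus-weighted flanks, a multi-isoform GFF3 annotation containing
intron-retention, exon-skipping and alternative 5'/3' splice-site events,
and negative-binomial count matrices (variance = mean + phi*mean^2) for two
conditions with replicates.  Expression and splicing effects are planted
with a recorded truth table so recovery can be scored.

Counts are simulated at the bin level and aggregated into gene counts;
an optional read-interval emitter produces BED-style reads consistent with
bin counts for exercising the interval counter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    Bin,
    GeneModel,
    IntronRecord,
    TranscriptomeModel,
    enumerate_introns,
    flatten_model,
)

STRUCTURE_CLASSES = (
    "monoexonic",
    "constitutive_multiexon",
    "IR",
    "ES",
    "Alt5SS",
    "Alt3SS",
)

# consensus weights for splice-site flanks (order A, C, G, T); the GT / AG
# dinucleotides themselves are written verbatim at every intron
_DONOR_EXONIC = [(0.35, 0.30, 0.20, 0.15), (0.55, 0.10, 0.25, 0.10), (0.10, 0.05, 0.80, 0.05)]
_DONOR_INTRONIC = [(0.60, 0.10, 0.15, 0.15), (0.65, 0.10, 0.10, 0.15), (0.10, 0.05, 0.75, 0.10), (0.15, 0.10, 0.15, 0.60)]
_ACCEPTOR_INTRONIC = [(0.15, 0.30, 0.10, 0.45), (0.15, 0.30, 0.10, 0.45), (0.20, 0.30, 0.10, 0.40), (0.15, 0.35, 0.15, 0.35)]
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Lengths are bases; ``baseline_rate`` is exonic reads per base drawn
    log-uniformly per gene; intron and AS bins get reduced rates
    (pre-mRNA background and partial isoform usage).  Planted DS effects
    multiply the target bin's mean in the mutant condition only; planted DE
    effects multiply every bin of the gene.
    """

    n_genes: dict[str, int] = field(
        default_factory=lambda: {
            "monoexonic": 20,
            "constitutive_multiexon": 200,
            "IR": 60,
            "ES": 60,
            "Alt5SS": 60,
            "Alt3SS": 60,
        }
    )
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (120, 800)
    max_intron_length: int = 5_000
    alt_shift: tuple[int, int] = (12, 40)  # Alt5'/3'SS boundary shift
    intergenic: tuple[int, int] = (200, 500)
    chrom: str = "chr1"
    chrom_length: int | None = None  # None: sized to fit; else error if exceeded
    n_replicates: int = 3
    conditions: tuple[str, str] = ("wt", "mut")
    baseline_rate: tuple[float, float] = (0.1, 1.0)
    intron_rate_factor: float = 0.15
    as_rate_factor: float = 0.5
    phi: float = 0.1
    n_planted_de: int = 30
    de_log2fc: float = 2.0
    n_planted_ds: int = 25
    ds_log2fc: float = 1.0
    n_ds_down: int = 5  # of the planted DS bins, how many lose retention
    ds_min_mean: float = 60.0  # wild-type mean floor for planted DS bins
    seed: int = 2024

    def __post_init__(self):
        if self.intron_length[1] > self.max_intron_length:
            raise ValueError("intron length range exceeds max_intron_length")
        for cls in self.n_genes:
            if cls not in STRUCTURE_CLASSES:
                raise ValueError(f"unknown structure class {cls!r}")

    # -- YAML profile I/O --------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("exon_length", "intron_length", "alt_shift", "intergenic", "conditions", "baseline_rate"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def default_profile() -> SimulationConfig:
    """The default planted profile: ~2,000 bins, 25 planted DS bins at
    |log2FC| = 1, 30 planted DE genes, phi = 0.1, 3 replicates per genotype."""
    return SimulationConfig()


def null_profile() -> SimulationConfig:
    """Effect-free profile for calibration / negative controls."""
    return SimulationConfig(n_planted_de=0, n_planted_ds=0)


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticAnnotation:
    """A generated genome + annotation with per-gene structure classes."""

    genome: dict[str, str]
    model: TranscriptomeModel
    gene_class: dict[str, str]

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.genome.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gid, gm in self.model.genes.items():
                lo, hi = gm.span
                fh.write(
                    f"{gm.chrom}\tbinsplice\tgene\t{lo + 1}\t{hi}\t.\t{gm.strand}\t.\tID={gid}\n"
                )
                for tid, exons in gm.transcripts.items():
                    fh.write(
                        f"{gm.chrom}\tbinsplice\tmRNA\t{exons[0][0] + 1}\t{exons[-1][1]}"
                        f"\t.\t{gm.strand}\t.\tID={tid};Parent={gid}\n"
                    )
                    for k, (s, e) in enumerate(exons, 1):
                        fh.write(
                            f"{gm.chrom}\tbinsplice\texon\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t"
                            f"ID={tid}.exon{k};Parent={tid}\n"
                        )


def _gene_structure(cls: str, strand: str, cfg: SimulationConfig, rng) -> dict[str, list[tuple[int, int]]]:
    """Exon intervals (relative to gene start 0) per transcript for one gene."""
    e = lambda: int(rng.integers(*cfg.exon_length, endpoint=True))
    i = lambda: int(rng.integers(*cfg.intron_length, endpoint=True))
    if cls == "monoexonic":
        return {"t1": [(0, e())]}
    if cls == "constitutive_multiexon":
        e1, i1, e2, i2, e3 = e(), i(), e(), i(), e()
        a, b, c = e1, e1 + i1, e1 + i1 + e2
        return {"t1": [(0, a), (b, c), (c + i2, c + i2 + e3)]}
    if cls == "IR":
        e1, i1, e2 = e(), i(), e()
        end = e1 + i1 + e2
        return {"t1": [(0, e1), (e1 + i1, end)], "t2": [(0, end)]}
    if cls == "ES":
        e1, i1, e2, i2, e3 = e(), i(), e(), i(), e()
        a, b = e1 + i1, e1 + i1 + e2
        end = b + i2 + e3
        return {"t1": [(0, e1), (a, b), (b + i2, end)], "t2": [(0, e1), (b + i2, end)]}
    if cls in ("Alt5SS", "Alt3SS"):
        e1, i1, e2 = e(), i(), e()
        d = int(rng.integers(*cfg.alt_shift, endpoint=True))
        b, c = e1, e1 + i1
        end = c + e2
        t1 = [(0, b), (c, end)]
        # a bin flanked by exon/intron is Alt5SS when it extends the donor
        # (transcript-5') exon edge: right edge of the upstream exon on +,
        # left edge of the downstream exon on -
        extend_upstream = (cls == "Alt5SS") == (strand == "+")
        t2 = [(0, b + d), (c, end)] if extend_upstream else [(0, b), (c - d, end)]
        return {"t1": t1, "t2": t2}
    raise ValueError(f"unknown structure class {cls!r}")


def _write_site(seq: list[str], pos: int, weights, rng) -> None:
    for off, w in enumerate(weights):
        seq[pos + off] = str(rng.choice(_BASES, p=np.asarray(w)))


def generate_genome_annotation(
    config: SimulationConfig, seed: int | None = None
) -> SyntheticAnnotation:
    """Generate a random-base genome with canonical splice sites + GFF3 model.

    Genes are placed sequentially along one chromosome with random
    intergenic gaps; every intron of every isoform starts with GT and ends
    with AG, with consensus-weighted flanking bases.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes: dict[str, GeneModel] = {}
    gene_class: dict[str, str] = {}
    prefix = {
        "monoexonic": "MONO",
        "constitutive_multiexon": "CONST",
        "IR": "IR",
        "ES": "ES",
        "Alt5SS": "A5SS",
        "Alt3SS": "A3SS",
    }
    cursor = int(rng.integers(*config.intergenic, endpoint=True))
    for cls in STRUCTURE_CLASSES:
        for k in range(config.n_genes.get(cls, 0)):
            gid = f"{prefix[cls]}{k + 1:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            rel = _gene_structure(cls, strand, config, rng)
            transcripts = {
                f"{gid}.{tid}": [(cursor + s, cursor + e) for s, e in exons]
                for tid, exons in rel.items()
            }
            genes[gid] = GeneModel(chrom=config.chrom, strand=strand, transcripts=transcripts)
            gene_class[gid] = cls
            span_end = max(e for exons in transcripts.values() for _, e in exons)
            cursor = span_end + int(rng.integers(*config.intergenic, endpoint=True))
    length = cursor
    if config.chrom_length is not None:
        if length > config.chrom_length:
            raise ValueError(
                f"genes need {length} bases but chrom_length={config.chrom_length}; "
                "raise chrom_length or reduce gene numbers/lengths"
            )
        length = config.chrom_length

    seq = list(rng.choice(_BASES, size=length))
    model = TranscriptomeModel(genes=genes)
    model.validate()
    for iv in enumerate_introns(model):
        if iv.strand == "+":
            d0, a0 = iv.start, iv.end  # donor at intron start, acceptor at end
            _write_site(seq, d0 - 3, _DONOR_EXONIC, rng)
            seq[d0], seq[d0 + 1] = "G", "T"
            _write_site(seq, d0 + 2, _DONOR_INTRONIC, rng)
            _write_site(seq, a0 - 6, _ACCEPTOR_INTRONIC, rng)
            seq[a0 - 2], seq[a0 - 1] = "A", "G"
        else:
            # transcript orientation is right-to-left: complement on the + strand
            d0, a0 = iv.end, iv.start
            seq[d0 - 1], seq[d0 - 2] = "C", "A"  # revcomp of GT
            _write_site(seq, d0, [w[::-1] for w in _DONOR_EXONIC[::-1]], rng)
            _write_site(seq, d0 - 6, [w[::-1] for w in _DONOR_INTRONIC[::-1]], rng)
            seq[a0], seq[a0 + 1] = "C", "T"  # revcomp of AG
            _write_site(seq, a0 + 2, [w[::-1] for w in _ACCEPTOR_INTRONIC[::-1]], rng)
    return SyntheticAnnotation(
        genome={config.chrom: "".join(seq)}, model=model, gene_class=gene_class
    )


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


@dataclass
class TruthTable:
    """Planted effects: per-gene and per-bin true log2 fold changes.

    ``bin_log2fc`` is the total density effect on the bin (gene effect plus
    any bin-specific splicing effect); unplanted features are 0.
    ``ds_bins`` lists the bins with a bin-specific splicing effect.
    """

    gene_log2fc: pd.Series
    bin_log2fc: pd.Series
    de_genes: list[str]
    ds_bins: list[str]

    def to_tsv(self, gene_path: str | Path, bin_path: str | Path) -> None:
        self.gene_log2fc.rename("true_log2fc").to_csv(gene_path, sep="\t")
        self.bin_log2fc.rename("true_log2fc").to_csv(bin_path, sep="\t")


@dataclass
class SimulatedCounts:
    gene_cm: "CountMatrix"
    bin_cm: "CountMatrix"
    truth: TruthTable
    bin_means: pd.DataFrame  # expected per-condition bin means (pre-sampling)


def _nb_sample(rng, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if phi == 0.0:
        return rng.poisson(mean)
    r = 1.0 / phi
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, r / (r + mean[pos]))
    return out


def simulate_counts(
    model: TranscriptomeModel,
    bins: list[Bin] | pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
    gene_class: dict[str, str] | None = None,
) -> SimulatedCounts:
    """NB counts for bins and genes with planted DE and DS effects.

    Each gene draws a baseline exonic rate (reads/base); a bin's mean is
    rate x length, damped for intron (pre-mRNA background) and AS bins
    (partial isoform usage).  Planted DE genes multiply every bin by
    2**de_log2fc in the mutant; planted DS bins multiply only that bin.
    Gene counts are NB draws around the summed means of the gene's exonic
    (exon + AS) bins.  DE and DS are planted in disjoint gene sets.
    """
    if config.phi < 0:
        raise ValueError("dispersion must be >= 0")
    from .annotation import bins_to_frame
    from .quantify import CountMatrix

    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    bdf = bins if isinstance(bins, pd.DataFrame) else bins_to_frame(bins)
    gene_ids = list(model.genes)
    gene_class = gene_class or {}

    rate = pd.Series(
        np.exp(rng.uniform(np.log(config.baseline_rate[0]), np.log(config.baseline_rate[1]), len(gene_ids))),
        index=gene_ids,
    )

    # --- choose planted features (disjoint gene sets, deterministic) -------
    const_genes = sorted(g for g in gene_ids if gene_class.get(g) == "constitutive_multiexon")
    de_genes = list(rng.choice(const_genes, size=min(config.n_planted_de, len(const_genes)), replace=False)) if config.n_planted_de else []
    de_sign = rng.choice([1.0, -1.0], size=len(de_genes))
    gene_lfc = pd.Series(0.0, index=gene_ids)
    for g, s in zip(de_genes, de_sign):
        gene_lfc[g] = s * config.de_log2fc

    as_candidates = bdf.index[
        (bdf["kind"] == "as")
        & (bdf["length"] >= 100)
        & ~bdf["gene_id"].isin(de_genes)
    ]
    intron_candidates = bdf.index[
        (bdf["kind"] == "intron")
        & (bdf["length"] >= 100)
        & ~bdf["gene_id"].isin(de_genes)
        & ~bdf["gene_id"].isin(set(bdf.loc[as_candidates, "gene_id"]))
    ]
    n_as = min(config.n_planted_ds * 3 // 5, len(as_candidates))
    n_in = min(config.n_planted_ds - n_as, len(intron_candidates))
    ds_bins = (
        list(rng.choice(sorted(as_candidates), size=n_as, replace=False))
        + list(rng.choice(sorted(intron_candidates), size=n_in, replace=False))
        if config.n_planted_ds
        else []
    )
    bin_lfc_own = pd.Series(0.0, index=bdf.index)
    for j, b in enumerate(ds_bins):
        sign = -1.0 if j < config.n_ds_down else 1.0
        bin_lfc_own[b] = sign * config.ds_log2fc

    # --- expected means ----------------------------------------------------
    kind_factor = bdf["kind"].map(
        {"exon": 1.0, "as": config.as_rate_factor, "intron": config.intron_rate_factor}
    )
    base_mean = rate.loc[bdf["gene_id"]].to_numpy() * bdf["length"].to_numpy() * kind_factor.to_numpy()
    base_mean = pd.Series(base_mean, index=bdf.index)
    if ds_bins:
        floor = config.ds_min_mean
        base_mean.loc[ds_bins] = base_mean.loc[ds_bins].clip(lower=floor)
    ref, alt = config.conditions
    lfc_total = bin_lfc_own + gene_lfc.reindex(bdf["gene_id"]).to_numpy()
    bin_means = pd.DataFrame(
        {ref: base_mean, alt: base_mean * np.power(2.0, lfc_total)}, index=bdf.index
    )

    # --- sampling -----------------------------------------------------------
    samples, condition_of = [], {}
    for cond in config.conditions:
        for r_i in range(1, config.n_replicates + 1):
            s = f"{cond}_{r_i}"
            samples.append(s)
            condition_of[s] = cond
    bin_counts = pd.DataFrame(
        {s: _nb_sample(rng, bin_means[condition_of[s]].to_numpy(), config.phi) for s in samples},
        index=bdf.index,
    )
    exonic = bdf["kind"].isin(["exon", "as"])
    gene_means = {
        c: bin_means.loc[exonic, c].groupby(bdf.loc[exonic, "gene_id"]).sum().reindex(gene_ids).fillna(0.0)
        for c in config.conditions
    }
    gene_counts = pd.DataFrame(
        {s: _nb_sample(rng, gene_means[condition_of[s]].to_numpy(), config.phi) for s in samples},
        index=gene_ids,
    )
    truth = TruthTable(
        gene_log2fc=gene_lfc,
        bin_log2fc=lfc_total,
        de_genes=sorted(de_genes),
        ds_bins=sorted(ds_bins),
    )
    return SimulatedCounts(
        gene_cm=CountMatrix(counts=gene_counts, condition_of=condition_of),
        bin_cm=CountMatrix(counts=bin_counts, condition_of=condition_of),
        truth=truth,
        bin_means=bin_means,
    )


def emit_reads(
    features: pd.DataFrame,
    counts: pd.Series,
    rng: np.random.Generator,
    read_length: int = 50,
) -> pd.DataFrame:
    """BED-style read intervals placed fully inside each feature.

    Emits ``counts[f]`` reads inside feature f (shrunk to the feature when
    it is shorter than ``read_length``), so re-counting them with the
    >=1-base overlap rule recovers at least the intended per-feature counts.
    """
    rows = []
    for fid, n in counts.items():
        if n <= 0:
            continue
        chrom = features.at[fid, "chrom"]
        lo, hi = int(features.at[fid, "start"]), int(features.at[fid, "end"])
        L = min(read_length, hi - lo)
        starts = rng.integers(lo, hi - L, size=int(n), endpoint=True)
        rows.extend((chrom, int(s), int(s) + L) for s in starts)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def flatten_and_classify(ann: SyntheticAnnotation) -> pd.DataFrame:
    """Convenience: bins DataFrame (with AS annotation flags) for a synthetic model."""
    from .annotation import bins_to_frame

    return bins_to_frame(flatten_model(ann.model))
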