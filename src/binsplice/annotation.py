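"""Transcript annotation model, bin flattening and AS-event classification.

A gene's isoforms are flattened into "bins": atomic genomic intervals whose
boundaries are the union of every exon start/end across the gene's
transcripts.  Each bin is exonic, intronic, or both ("AS") depending on its
status across isoforms; AS bins are the unit at which splicing change is
tested.  All internal coordinates are 0-based half-open; GFF3/GTF I/O
converts from the 1-based inclusive convention of those formats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

Interval = tuple[int, int]

EVENT_CLASSES = ("IR", "ES", "Alt5SS", "Alt3SS", "undefined", "none")
BIN_KINDS = ("exon", "intron", "as")


@dataclass
class GeneModel:
    """One gene: chromosome, strand and its transcripts' exon intervals.

    ``transcripts`` maps transcript id to an ordered list of 0-based
    half-open exon intervals, sorted by start and non-overlapping.
    """

    chrom: str
    strand: str
    transcripts: dict[str, list[Interval]] = field(default_factory=dict)

    @property
    def span(self) -> Interval:
        starts = [ex[0] for exons in self.transcripts.values() for ex in exons]
        ends = [ex[1] for exons in self.transcripts.values() for ex in exons]
        return (min(starts), max(ends))

    @property
    def monoexonic(self) -> bool:
        """True when every transcript of the gene has a single exon."""
        return all(len(exons) == 1 for exons in self.transcripts.values())

    def exonic_length(self) -> int:
        """Length of the union of all exons (bases)."""
        ivs = sorted(ex for exons in self.transcripts.values() for ex in exons)
        total, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        return total


@dataclass
class TranscriptomeModel:
    """All genes of an annotation, keyed by gene id."""

    genes: dict[str, GeneModel] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def monoexonic_genes(self) -> set[str]:
        return {g for g, gm in self.genes.items() if gm.monoexonic}

    def validate(self) -> None:
        for gid, gm in self.genes.items():
            if gm.strand not in ("+", "-"):
                raise ValueError(f"gene {gid}: invalid strand {gm.strand!r}")
            if not gm.transcripts:
                raise ValueError(f"gene {gid}: no transcripts")
            for tid, exons in gm.transcripts.items():
                if not exons:
                    raise ValueError(f"transcript {tid}: no exons")
                prev_end = None
                for s, e in exons:
                    if e <= s:
                        raise ValueError(f"transcript {tid}: empty exon [{s},{e})")
                    if prev_end is not None and s < prev_end:
                        raise ValueError(
                            f"transcript {tid}: overlapping/unsorted exons at {s}"
                        )
                    prev_end = e


@dataclass
class Bin:
    """A subgenic joint feature produced by flattening one gene."""

    bin_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    kind: str  # exon | intron | as
    event_class: str = "none"  # IR | ES | Alt5SS | Alt3SS | undefined | none
    annotated_as: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IntronRecord:
    """A distinct intron of a gene, with its AS-annotation status.

    ``annotated_as`` is True when the intron's span overlaps sequence that is
    exonic in a sibling isoform (i.e. there is annotated evidence that the
    intron can be at least partially retained or bounded differently).
    ``donor``/``acceptor`` are genomic positions of the first/last intronic
    base in transcript orientation.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    annotated_as: bool
    donor: int
    acceptor: int

    @property
    def intron_id(self) -> str:
        return f"{self.gene_id}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def parse_annotation(path: str | Path) -> TranscriptomeModel:
    """Parse a GFF3 or GTF annotation into a :class:`TranscriptomeModel`.

    Requires a gene -> transcript -> exon hierarchy (explicit in GFF3 via
    ``Parent`` attributes; implicit in GTF via ``gene_id``/``transcript_id``).
    1-based inclusive coordinates are converted to 0-based half-open.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0 or not _has_features(path):
        warnings.warn(f"annotation file {path} contains no features; empty model")
        return TranscriptomeModel()

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # malformed hierarchy / attributes
        raise ValueError(f"failed to parse annotation {path}: {exc}") from exc

    # transcript id -> gene id via Parent links (GFF3) or gene_id tags (GTF)
    tx_gene: dict[str, str] = {}
    tx_meta: dict[str, tuple[str, str]] = {}  # tid -> (chrom, strand)
    for ft in ("mRNA", "transcript"):
        for tx in db.features_of_type(ft):
            gid = _first_attr(tx, "Parent", "gene_id")
            if gid is None:
                raise ValueError(f"transcript {tx.id} has no gene parentage")
            tx_gene[tx.id] = gid
            tx_meta[tx.id] = (tx.seqid, tx.strand)

    genes: dict[str, GeneModel] = {}
    for exon in db.features_of_type("exon"):
        tids = exon.attributes.get("Parent") or exon.attributes.get("transcript_id")
        if not tids:
            raise ValueError(f"exon at {exon.seqid}:{exon.start} has no transcript parent")
        for tid in tids:
            gid = tx_gene.get(tid) or _first_attr(exon, "gene_id")
            if gid is None:
                raise ValueError(f"exon parent {tid} is not a known transcript")
            gm = genes.setdefault(gid, GeneModel(chrom=exon.seqid, strand=exon.strand))
            if gm.chrom != exon.seqid:
                raise ValueError(
                    f"exon of {tid} on {exon.seqid} but gene {gid} is on {gm.chrom}"
                )
            # GFF/GTF 1-based inclusive -> 0-based half-open
            gm.transcripts.setdefault(tid, []).append((exon.start - 1, exon.end))

    for gm in genes.values():
        for exons in gm.transcripts.values():
            exons.sort()
    model = TranscriptomeModel(genes=genes)
    model.validate()
    return model


def _has_features(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return True
    return False


def _first_attr(feature, *keys):
    for key in keys:
        vals = feature.attributes.get(key)
        if vals:
            return vals[0]
    return None


# ---------------------------------------------------------------------------
# Flattening and classification
# ---------------------------------------------------------------------------


def _transcript_status(exons: list[Interval], start: int, end: int) -> str | None:
    """Status of atomic interval [start, end) within one transcript.

    Returns 'exon', 'intron', or None (outside the transcript span).  Because
    bin boundaries include every exon edge, the interval is never split by an
    exon edge and status is all-or-none.
    """
    if start < exons[0][0] or end > exons[-1][1]:
        return None
    for s, e in exons:
        if s <= start and end <= e:
            return "exon"
        if s >= end:
            break
    return "intron"


def flatten_gene(gene_id: str, gene: GeneModel) -> list[Bin]:
    """Partition one gene into disjoint bins at every exon boundary.

    Bin kinds: ``exon`` (exonic in every covering isoform), ``intron``
    (intronic in every covering isoform), ``as`` (exonic in at least one and
    intronic in at least one).  Gaps between disjoint transcript spans are
    not part of any bin.  Bin ids are ``<gene>:<kind><ordinal>`` with the
    ordinal assigned per kind in 5'->3' gene order.
    """
    boundaries = sorted(
        {p for exons in gene.transcripts.values() for ex in exons for p in ex}
    )
    tx_list = list(gene.transcripts.values())
    raw: list[tuple[int, int, str]] = []
    for start, end in zip(boundaries[:-1], boundaries[1:]):
        statuses = [_transcript_status(exons, start, end) for exons in tx_list]
        n_exon = sum(s == "exon" for s in statuses)
        n_intron = sum(s == "intron" for s in statuses)
        if n_exon == 0 and n_intron == 0:
            continue  # hole between disjoint transcript spans
        if n_exon and n_intron:
            kind = "as"
        elif n_exon:
            kind = "exon"
        else:
            kind = "intron"
        raw.append((start, end, kind))

    bins = [
        Bin(
            bin_id="",
            gene_id=gene_id,
            chrom=gene.chrom,
            strand=gene.strand,
            start=start,
            end=end,
            kind=kind,
        )
        for start, end, kind in raw
    ]
    # ordinals in 5'->3' gene order, numbered per kind
    ordered = bins if gene.strand == "+" else list(reversed(bins))
    counters = {k: 0 for k in BIN_KINDS}
    for b in ordered:
        counters[b.kind] += 1
        b.bin_id = f"{b.gene_id}:{b.kind}{counters[b.kind]}"
    return bins


def classify_bins(bins: list[Bin], gene: GeneModel) -> list[Bin]:
    """Assign event classes to AS bins in place (and return the list).

    Classification is by the kinds of the immediately flanking bins,
    strand-aware for donor/acceptor polarity:

    - exon on both sides        -> IR      (retained intron)
    - intron on both sides      -> ES      (skipped exon)
    - exon one side, intron the other -> Alt5SS when the bin extends the
      shared exon's donor (transcript-5') edge, Alt3SS for the acceptor edge
    - anything else (gene-terminal bins, AS-bin neighbours, composites)
      -> undefined
    """
    for i, b in enumerate(bins):
        if b.kind != "as":
            continue
        left = bins[i - 1] if i > 0 and bins[i - 1].end == b.start else None
        right = bins[i + 1] if i + 1 < len(bins) and bins[i + 1].start == b.end else None
        lk = left.kind if left else None
        rk = right.kind if right else None
        if lk == "exon" and rk == "exon":
            b.event_class = "IR"
        elif lk == "intron" and rk == "intron":
            b.event_class = "ES"
        elif {lk, rk} == {"exon", "intron"}:
            # the bin extends the adjacent shared exon; which edge it extends
            # decides donor (5') vs acceptor (3') in transcript orientation
            exon_on_left = lk == "exon"
            if gene.strand == "+":
                b.event_class = "Alt5SS" if exon_on_left else "Alt3SS"
            else:
                b.event_class = "Alt3SS" if exon_on_left else "Alt5SS"
        else:
            b.event_class = "undefined"
    return bins


def flatten_model(model: TranscriptomeModel) -> list[Bin]:
    """Flatten and classify every gene of a model.

    Sets ``annotated_as`` on each bin: True for AS bins, and for intron
    bins lying inside an intron that is annotated as alternatively spliced
    (its span overlaps a sibling isoform's exon).
    """
    out: list[Bin] = []
    for gid, gm in model.genes.items():
        bins = classify_bins(flatten_gene(gid, gm), gm)
        as_introns = [
            (iv.start, iv.end)
            for iv in enumerate_introns(TranscriptomeModel(genes={gid: gm}))
            if iv.annotated_as
        ]
        for b in bins:
            b.annotated_as = b.kind == "as" or any(
                s < b.end and e > b.start for s, e in as_introns
            )
        out.extend(bins)
    return out


def enumerate_introns(model: TranscriptomeModel) -> list[IntronRecord]:
    """One record per distinct (gene, interval) intron across isoforms.

    An intron is flagged ``annotated_as`` when its span overlaps sequence
    exonic in a sibling isoform of the same gene.
    """
    records: list[IntronRecord] = []
    for gid, gm in model.genes.items():
        seen: set[Interval] = set()
        for tid, exons in gm.transcripts.items():
            for (s1, e1), (s2, e2) in zip(exons[:-1], exons[1:]):
                iv = (e1, s2)
                if iv in seen:
                    continue
                seen.add(iv)
                annotated_as = any(
                    ex[0] < iv[1] and ex[1] > iv[0]
                    for otid, oexons in gm.transcripts.items()
                    if otid != tid
                    for ex in oexons
                )
                if gm.strand == "+":
                    donor, acceptor = iv[0], iv[1] - 1
                else:
                    donor, acceptor = iv[1] - 1, iv[0]
                records.append(
                    IntronRecord(
                        gene_id=gid,
                        chrom=gm.chrom,
                        strand=gm.strand,
                        start=iv[0],
                        end=iv[1],
                        annotated_as=annotated_as,
                        donor=donor,
                        acceptor=acceptor,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def bins_to_frame(bins: Iterable[Bin]):
    """Bins as a DataFrame indexed by bin_id."""
    import pandas as pd

    rows = [
        {
            "bin_id": b.bin_id,
            "gene_id": b.gene_id,
            "chrom": b.chrom,
            "strand": b.strand,
            "start": b.start,
            "end": b.end,
            "length": b.length,
            "kind": b.kind,
            "event_class": b.event_class,
            "annotated_as": b.annotated_as,
        }
        for b in bins
    ]
    return pd.DataFrame(rows).set_index("bin_id")


def write_bins_bed(bins: Iterable[Bin], path: str | Path) -> None:
    """Write bins as BED6+3 (extra columns: kind, event_class, annotated_as)."""
    with open(path, "w") as fh:
        for b in bins:
            fh.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t{b.bin_id}\t0\t{b.strand}"
                f"\t{b.kind}\t{b.event_class}\t{int(b.annotated_as)}\n"
            )


def write_bins_tsv(bins: Iterable[Bin], path: str | Path) -> None:
    bins_to_frame(bins).to_csv(path, sep="\t")
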