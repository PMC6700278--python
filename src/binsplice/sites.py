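"""Splice-site sequence windows, position frequency matrices, enrichment.

Donor and acceptor windows are extracted in transcript orientation
(minus-strand windows are reverse-complemented), so a canonical intron
always reads exon|GT...  at the donor and  ...AG|exon at the acceptor.
Per-position nucleotide frequencies of an intron subset are compared to an
intron universe with hypergeometric tail tests, one per (position, base).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .annotation import IntronRecord

BASES = ("A", "C", "G", "T")


def load_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA genome into a dict of upper-case sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _revcomp(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq).reverse_complement())


def extract_splice_sites(
    genome: dict[str, str],
    introns: list[IntronRecord],
    donor_window: tuple[int, int] = (3, 6),
    acceptor_window: tuple[int, int] = (6, 3),
) -> tuple[list[str], list[str]]:
    """Donor and acceptor windows for each intron, in transcript orientation.

    ``donor_window = (n_exonic, n_intronic)`` takes the last ``n_exonic``
    exon bases and the first ``n_intronic`` intron bases around the donor
    junction; ``acceptor_window = (n_intronic, n_exonic)`` mirrors this at
    the acceptor.  Introns whose windows run off the contig are skipped with
    a warning; ambiguous bases are kept as N.
    """
    d_ex, d_in = donor_window
    a_in, a_ex = acceptor_window
    donors: list[str] = []
    acceptors: list[str] = []
    for iv in introns:
        seq = genome.get(iv.chrom)
        if seq is None:
            warnings.warn(f"chromosome {iv.chrom} not in genome; intron skipped")
            continue
        if iv.strand == "+":
            d_lo, d_hi = iv.start - d_ex, iv.start + d_in
            a_lo, a_hi = iv.end - a_in, iv.end + a_ex
        else:
            d_lo, d_hi = iv.end - d_in, iv.end + d_ex
            a_lo, a_hi = iv.start - a_ex, iv.start + a_in
        if min(d_lo, a_lo) < 0 or max(d_hi, a_hi) > len(seq):
            warnings.warn(f"window outside contig for intron {iv.intron_id}; skipped")
            continue
        donor = seq[d_lo:d_hi]
        acceptor = seq[a_lo:a_hi]
        if iv.strand == "-":
            donor, acceptor = _revcomp(donor), _revcomp(acceptor)
        donors.append(donor)
        acceptors.append(acceptor)
    return donors, acceptors


@dataclass
class PositionFrequencyMatrix:
    """Per-position nucleotide counts and frequencies of aligned windows.

    ``counts`` is positions x {A,C,G,T}; Ns are excluded from a position's
    denominator, so frequencies sum to 1 wherever all bases are called.
    """

    counts: pd.DataFrame
    n_sequences: int

    @property
    def freqs(self) -> pd.DataFrame:
        denom = self.counts.sum(axis=1)
        return self.counts.div(denom.replace(0, np.nan), axis=0)

    @property
    def width(self) -> int:
        return len(self.counts)

    def consensus(self) -> str:
        return "".join(self.counts.idxmax(axis=1))

    def to_tsv(self, path: str | Path, frequencies: bool = False) -> None:
        (self.freqs if frequencies else self.counts).to_csv(path, sep="\t")


def build_pfm(sequences: list[str]) -> PositionFrequencyMatrix:
    """Count nucleotides per position over equal-length sequences."""
    if not sequences:
        raise ValueError("no sequences")
    width = len(sequences[0])
    if any(len(s) != width for s in sequences):
        raise ValueError("sequences must have equal length")
    counts = np.zeros((width, 4), dtype=np.int64)
    idx = {b: j for j, b in enumerate(BASES)}
    for s in sequences:
        for i, ch in enumerate(s.upper()):
            j = idx.get(ch)
            if j is not None:  # N and other ambiguity codes excluded
                counts[i, j] += 1
    return PositionFrequencyMatrix(
        counts=pd.DataFrame(counts, columns=list(BASES)),
        n_sequences=len(sequences),
    )


def positional_enrichment(
    subset: PositionFrequencyMatrix,
    universe: PositionFrequencyMatrix,
    bh: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over/under-representation per (position, base).

    Draws are the ``n`` subset introns from the ``N`` universe introns;
    successes are the ``K`` universe introns carrying the base at the
    position, ``k`` of which fall in the subset.  The over tail is
    P(X >= k), the under tail P(X <= k); the smaller tail and its direction
    are reported.  Optionally BH-adjust across all (position, base) pairs.
    """
    if subset.width != universe.width:
        raise ValueError("subset and universe windows differ in width")
    if subset.n_sequences > universe.n_sequences:
        raise ValueError("subset larger than universe")
    rows = []
    for pos in range(universe.width):
        # per-position denominators (N handling can shrink them)
        n_sub = int(subset.counts.iloc[pos].sum())
        n_uni = int(universe.counts.iloc[pos].sum())
        for base in BASES:
            k = int(subset.counts.iloc[pos][base])
            big_k = int(universe.counts.iloc[pos][base])
            p_over = float(hypergeom.sf(k - 1, n_uni, big_k, n_sub))
            p_under = float(hypergeom.cdf(k, n_uni, big_k, n_sub))
            direction = "over" if p_over <= p_under else "under"
            rows.append(
                {
                    "position": pos,
                    "base": base,
                    "k_subset": k,
                    "n_subset": n_sub,
                    "K_universe": big_k,
                    "N_universe": n_uni,
                    "direction": direction,
                    "pvalue": min(p_over, p_under),
                }
            )
    out = pd.DataFrame(rows)
    if bh:
        from .de import bh_adjust

        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    return out
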