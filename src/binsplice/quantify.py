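"""Counting reads into features and computing read densities.

Reads are simplified genomic intervals (BED); a read increments every
feature it overlaps by at least one base (no fractional assignment).
Densities are reads per base, computed per condition on library-normalized
mean counts, and are the quantity whose mutant/wild-type ratio defines the
splicing fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Integer counts, features x samples, with condition labels.

    ``lib_size`` defaults to column sums but may be supplied (e.g. total
    mapped reads, which can exceed the column sum).
    """

    counts: pd.DataFrame  # features x samples, int
    condition_of: dict[str, str]
    lib_size: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        for s in self.counts.columns:
            if s not in self.condition_of:
                raise ValueError(f"sample {s} has no condition label")
        if not self.lib_size:
            self.lib_size = {s: float(self.counts[s].sum()) for s in self.counts.columns}
        for s, n in self.lib_size.items():
            if n <= 0:
                raise ValueError(f"sample {s} has non-positive library size")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def conditions(self) -> list[str]:
        seen = []
        for s in self.samples:
            c = self.condition_of[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition_of[s] == condition]

    def condition_means(self) -> pd.DataFrame:
        """Mean raw count per feature and condition."""
        return pd.DataFrame(
            {c: self.counts[self.samples_of(c)].mean(axis=1) for c in self.conditions}
        )

    def subset(self, feature_ids) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[feature_ids],
            condition_of=dict(self.condition_of),
            lib_size=dict(self.lib_size),
        )

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        pd.DataFrame(
            {
                "sample": self.samples,
                "condition": [self.condition_of[s] for s in self.samples],
                "lib_size": [self.lib_size[s] for s in self.samples],
            }
        ).to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t")
        return cls(
            counts=counts.astype(np.int64),
            condition_of=dict(zip(sheet["sample"], sheet["condition"])),
            lib_size=dict(zip(sheet["sample"], sheet["lib_size"].astype(float))),
        )


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


def count_intervals(
    features: pd.DataFrame, reads: pd.DataFrame, warn_missing_chrom: bool = True
) -> pd.Series:
    """Count reads overlapping each feature by >= 1 base.

    ``features``: DataFrame with chrom/start/end, indexed by feature id.
    ``reads``: DataFrame with chrom/start/end (one row per read).
    A read overlapping several features increments each of them.
    """
    out = pd.Series(0, index=features.index, dtype=np.int64)
    read_chroms = {}
    for chrom, grp in reads.groupby("chrom", sort=False):
        read_chroms[chrom] = (
            np.sort(grp["start"].to_numpy()),
            np.sort(grp["end"].to_numpy()),
        )
    warned: set[str] = set()
    for chrom, fgrp in features.groupby("chrom", sort=False):
        if chrom not in read_chroms:
            if warn_missing_chrom and chrom not in warned and len(reads):
                warnings.warn(f"no reads on chromosome {chrom}; features get 0")
                warned.add(chrom)
            continue
        starts, ends = read_chroms[chrom]
        n = len(starts)
        fs = fgrp["start"].to_numpy()
        fe = fgrp["end"].to_numpy()
        # overlap iff read.start < f.end and read.end > f.start; the two
        # excluded sets (start >= f.end, end <= f.start) are disjoint
        n_right = n - np.searchsorted(starts, fe, side="left")
        n_left = np.searchsorted(ends, fs, side="right")
        out.loc[fgrp.index] = n - n_right - n_left
    return out


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 intervals (0-based half-open, as BED specifies)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def count_features(
    features: pd.DataFrame,
    sample_reads: dict[str, pd.DataFrame],
    condition_of: dict[str, str],
    lib_size: dict[str, float] | None = None,
) -> CountMatrix:
    """Build a CountMatrix by counting per-sample read intervals into features."""
    cols = {s: count_intervals(features, reads) for s, reads in sample_reads.items()}
    counts = pd.DataFrame(cols)
    return CountMatrix(
        counts=counts,
        condition_of=dict(condition_of),
        lib_size=dict(lib_size) if lib_size else {s: float(len(r)) for s, r in sample_reads.items()},
    )


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------


def normalized_counts(
    cm: CountMatrix, norm_factors: dict[str, float] | None = None
) -> pd.DataFrame:
    """Counts scaled to a common (geometric-mean) effective library size."""
    factors = norm_factors or {s: 1.0 for s in cm.samples}
    eff = np.array([cm.lib_size[s] * factors[s] for s in cm.samples], dtype=float)
    if (eff <= 0).any():
        raise ValueError("non-positive effective library size")
    common = float(np.exp(np.mean(np.log(eff))))
    scale = common / eff
    return cm.counts * scale


def read_density(
    cm: CountMatrix,
    lengths: pd.Series,
    norm_factors: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-feature, per-condition read density (reads per base).

    density(f, c) = mean over samples of condition c of the normalized count
    of f, divided by length(f).
    """
    lengths = lengths.reindex(cm.features)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValueError(f"missing lengths for features, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be >= 1")
    norm = normalized_counts(cm, norm_factors)
    dens = pd.DataFrame(
        {c: norm[cm.samples_of(c)].mean(axis=1) for c in cm.conditions}
    )
    return dens.div(lengths.astype(float), axis=0)
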