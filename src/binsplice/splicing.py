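"""Bin-level differential splicing from read-density fold changes.

Bins (or whole introns treated as features) are filtered — monoexonic genes
out, mean count >= 5 per condition, parent-gene read density > 0.05 in all
genotypes — then tested with the same NB conditional exact test used for
genes.  The effect size is the log2 ratio of bin read densities
(mutant over wild type); a bin is differentially spliced when
|log2FC| > 0.58 and BH FDR < 0.15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import (
    bh_adjust,
    estimate_common_dispersion,
    nb_exact_test,
    tmm_norm_factors,
)
from .quantify import CountMatrix, read_density

__all__ = [
    "filter_bins",
    "summarize_event_frequencies",
    "intron_class_comparison",
    "BinSplicingTest",
    "SplicingResults",
]

CANONICAL_EVENTS = ("IR", "ES", "Alt5SS", "Alt3SS")


def filter_bins(
    bins: pd.DataFrame,
    bin_cm: CountMatrix,
    gene_density: pd.DataFrame,
    monoexonic: set[str],
    min_mean: float = 5.0,
    min_gene_density: float = 0.05,
) -> pd.Index:
    """Eligible bin ids after the three splicing filters.

    Drops (1) every bin of a monoexonic gene, (2) bins whose mean raw count
    is below ``min_mean`` in any condition, (3) every bin of a gene whose
    read density is <= ``min_gene_density`` in any condition.  Filtering is
    order-independent and idempotent.
    """
    bins = bins.loc[bins.index.intersection(bin_cm.features)]
    keep = ~bins["gene_id"].isin(monoexonic)
    means = bin_cm.condition_means().loc[bins.index]
    keep &= (means >= min_mean).all(axis=1)
    dense_genes = gene_density.index[(gene_density > min_gene_density).all(axis=1)]
    keep &= bins["gene_id"].isin(set(dense_genes))
    return bins.index[keep]


def summarize_event_frequencies(
    table: pd.DataFrame, scope: str = "all_detected"
) -> pd.DataFrame:
    """Percentage of each canonical AS event class among records.

    ``scope`` is ``all_detected`` (every tested record) or ``significant``.
    Percentages are reported to one decimal and sum to 100 up to rounding.
    """
    if scope == "significant":
        table = table[table["significant"]]
    elif scope != "all_detected":
        raise ValueError(f"unknown scope {scope!r}")
    sub = table[table["event_class"].isin(CANONICAL_EVENTS)]
    if sub.empty:
        return pd.DataFrame(columns=["n", "percent"])
    counts = sub["event_class"].value_counts()
    out = pd.DataFrame({"n": counts})
    out["percent"] = (100.0 * out["n"] / out["n"].sum()).round(1)
    return out.sort_values("n", ascending=False)


def intron_class_comparison(table: pd.DataFrame) -> dict[str, dict]:
    """Retention increase rate among AS vs constitutively spliced introns.

    Within each ``annotated_as`` label, the percentage of tested introns
    that are significant with a positive density log2FC (more retained in
    the mutant).  A label with no tested introns is reported with
    ``percent_up=None``.
    """
    out: dict[str, dict] = {}
    for label, name in ((True, "AS"), (False, "CS")):
        sub = table[table["annotated_as"] == label]
        n = len(sub)
        n_up = int((sub["significant"] & (sub["log2fc_density"] > 0)).sum())
        out[name] = {
            "n_tested": n,
            "n_retained_up": n_up,
            "percent_up": round(100.0 * n_up / n, 3) if n else None,
        }
    return out


class BinSplicingTest:
    """Bin-level differential splicing model for two genotypes.

    Parameters
    ----------
    bins : DataFrame
        One row per feature (bin or intron), indexed by feature id, with
        columns gene_id, length, kind, event_class, annotated_as.
    bin_cm : CountMatrix
        Raw counts for those features.
    gene_cm : CountMatrix
        Gene-level raw counts (same samples), used for the gene-density
        filter.
    gene_lengths : Series
        Exonic length per gene (bases), for gene read densities.
    monoexonic : set of gene ids
        Genes whose every transcript is single-exon.
    """

    def __init__(
        self,
        bins: pd.DataFrame,
        bin_cm: CountMatrix,
        gene_cm: CountMatrix,
        gene_lengths: pd.Series,
        monoexonic: set[str] | None = None,
        reference: str | None = None,
        alternative: str | None = None,
    ):
        conds = bin_cm.conditions
        if len(conds) != 2:
            raise ValueError(f"need exactly 2 conditions, got {conds}")
        self.bins = bins
        self.bin_cm = bin_cm
        self.gene_cm = gene_cm
        self.gene_lengths = gene_lengths
        self.monoexonic = monoexonic or set()
        self.reference = reference or conds[0]
        self.alternative = alternative or [c for c in conds if c != self.reference][0]

    def fit(
        self,
        min_mean: float = 5.0,
        min_gene_density: float = 0.05,
        fdr_max: float = 0.15,
        lfc_min: float = 0.58,
        dispersion: float | None = None,
    ) -> "SplicingResults":
        gene_factors = tmm_norm_factors(self.gene_cm)
        gene_density = read_density(
            self.gene_cm, self.gene_lengths.astype(float), gene_factors
        )
        eligible = filter_bins(
            self.bins, self.bin_cm, gene_density, self.monoexonic,
            min_mean=min_mean, min_gene_density=min_gene_density,
        )
        cm = self.bin_cm.subset(eligible)
        bins = self.bins.loc[eligible]
        factors = tmm_norm_factors(cm) if len(eligible) >= 2 else {s: 1.0 for s in cm.samples}
        phi = (
            dispersion
            if dispersion is not None
            else estimate_common_dispersion(cm, norm_factors=factors)
        )
        from .quantify import normalized_counts

        pseudo = normalized_counts(cm, factors)
        a_mat = pseudo[cm.samples_of(self.reference)].to_numpy(dtype=float)
        b_mat = pseudo[cm.samples_of(self.alternative)].to_numpy(dtype=float)
        pvals = np.empty(len(eligible))
        for i in range(len(eligible)):
            pvals[i], _ = nb_exact_test(a_mat[i], b_mat[i], phi)

        dens = read_density(cm, bins["length"].astype(float), factors)
        d_ref = dens[self.reference].to_numpy()
        d_alt = dens[self.alternative].to_numpy()
        # zero density in exactly one condition -> +/-inf sentinel, still reported
        lfc = np.zeros(len(eligible))
        both = (d_ref > 0) & (d_alt > 0)
        lfc[both] = np.log2(d_alt[both] / d_ref[both])
        lfc[(d_alt > 0) & ~both] = np.inf
        lfc[(d_ref > 0) & ~both] = -np.inf
        means = cm.condition_means()
        table = pd.DataFrame(
            {
                "gene_id": bins["gene_id"],
                "kind": bins["kind"],
                "event_class": bins["event_class"],
                "annotated_as": bins["annotated_as"],
                f"mean_{self.reference}": means[self.reference],
                f"mean_{self.alternative}": means[self.alternative],
                f"density_{self.reference}": d_ref,
                f"density_{self.alternative}": d_alt,
                "log2fc_density": lfc,
                "density_zero": ~(np.isfinite(lfc)),
                "pvalue": pvals,
                "fdr": bh_adjust(pvals),
            },
            index=eligible,
        )
        table["significant"] = (table["fdr"] < fdr_max) & (
            table["log2fc_density"].abs() > lfc_min
        )
        return SplicingResults(
            model=self,
            table=table,
            dispersion=phi,
            norm_factors=factors,
            n_input=len(self.bins),
            fdr_max=fdr_max,
            lfc_min=lfc_min,
        )


@dataclass
class SplicingResults:
    """Fitted differential-splicing results (one row per tested feature)."""

    model: BinSplicingTest
    table: pd.DataFrame
    dispersion: float
    norm_factors: dict[str, float]
    n_input: int
    fdr_max: float
    lfc_min: float

    @property
    def significant_bins(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    @property
    def affected_genes(self) -> list[str]:
        """Distinct genes carrying at least one significant feature."""
        return sorted(self.table.loc[self.table["significant"], "gene_id"].unique())

    def event_frequencies(self, scope: str = "all_detected") -> pd.DataFrame:
        return summarize_event_frequencies(self.table, scope)

    def intron_class_comparison(self) -> dict[str, dict]:
        return intron_class_comparison(self.table)

    def summary(self) -> str:
        n_sig = int(self.table["significant"].sum())
        lines = [
            "Bin-level differential splicing (NB exact test on bins)",
            "=" * 56,
            f"contrast:          {self.model.alternative} vs {self.model.reference}",
            f"features in:       {self.n_input}",
            f"features tested:   {len(self.table)} (after monoexonic/count/density filters)",
            f"common phi:        {self.dispersion:.4g}",
            f"thresholds:        FDR < {self.fdr_max}, |log2FC density| > {self.lfc_min}",
            f"differentially spliced: {n_sig} in {len(self.affected_genes)} genes",
        ]
        freq = self.event_frequencies("significant")
        if len(freq):
            lines.append("event classes among significant:")
            for cls, row in freq.iterrows():
                lines.append(f"  {cls:8s} {int(row['n']):5d}  {row['percent']}%")
        return "\n".join(lines)
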