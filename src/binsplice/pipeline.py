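"""End-to-end orchestration: annotation -> bins -> DE -> DS -> sites -> enrichment.

`run_pipeline` drives the whole analysis from one YAML config, writes
per-stage TSVs plus a JSON run report (feature counts at every filter step,
event-class frequency tables, DEG/DST overlap), and is deterministic for a
fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import (
    bins_to_frame,
    enumerate_introns,
    flatten_model,
    parse_annotation,
    write_bins_bed,
)
from .de import NBExactTest
from .enrichment import enrich_categories, read_gmt
from .quantify import CountMatrix
from .sites import build_pfm, extract_splice_sites, load_genome, positional_enrichment
from .splicing import BinSplicingTest

@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run."""

    annotation: str
    gene_counts: str
    bin_counts: str
    samples: str
    out_dir: str
    genome: str | None = None
    gene_sets: str | None = None
    deg_fdr: float = 0.05
    ds_fdr: float = 0.15
    lfc: float = 0.58
    min_gene_mean: float = 10.0
    min_bin_mean: float = 5.0
    min_gene_density: float = 0.05
    donor_window: tuple[int, int] = (3, 6)
    acceptor_window: tuple[int, int] = (6, 3)
    seed: int = 1

    def __post_init__(self):
        for name in ("deg_fdr", "ds_fdr", "lfc", "min_gene_mean", "min_bin_mean", "min_gene_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = raw.pop("thresholds", {})
        win = raw.pop("windows", {})
        kw = dict(raw)
        kw.update(thr)
        if "donor" in win:
            kw["donor_window"] = tuple(win["donor"])
        if "acceptor" in win:
            kw["acceptor_window"] = tuple(win["acceptor"])
        return cls(**kw)


def summarize_overlap(deg_ids, dst_ids) -> dict[str, int]:
    """Venn-style counts of DEG-only, DST-only and shared genes."""
    deg, dst = set(deg_ids), set(dst_ids)
    return {
        "deg_only": len(deg - dst),
        "dst_only": len(dst - deg),
        "both": len(deg & dst),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stages": {},
    }
    stage = "annotation"
    try:
        model = parse_annotation(config.annotation)
        bins = flatten_model(model)
        bdf = bins_to_frame(bins)
        write_bins_bed(bins, out / "bins.bed")
        bdf.to_csv(out / "bins.tsv", sep="\t")
        kind_counts = bdf["kind"].value_counts().to_dict()
        report["stages"]["annotation"] = {
            "n_genes": len(model),
            "n_transcripts": sum(len(g.transcripts) for g in model.genes.values()),
            "n_bins": {
                "exon": int(kind_counts.get("exon", 0)),
                "intron": int(kind_counts.get("intron", 0)),
                "as": int(kind_counts.get("as", 0)),
                "total": int(len(bdf)),
            },
        }

        stage = "counts"
        gene_cm = CountMatrix.from_tsv(config.gene_counts, config.samples)
        bin_cm = CountMatrix.from_tsv(config.bin_counts, config.samples)

        stage = "differential_expression"
        de_res = NBExactTest(gene_cm, min_mean=config.min_gene_mean).fit(
            fdr_max=config.deg_fdr, lfc_min=config.lfc
        )
        de_res.table.to_csv(out / "de.tsv", sep="\t")
        s = de_res.deg_summary
        report["stages"]["differential_expression"] = {
            "n_input": de_res.n_input,
            "n_tested": s["n_tested"],
            "n_filtered": de_res.n_input - s["n_tested"],
            "dispersion": de_res.dispersion,
            **{k: s[k] for k in ("n_significant", "n_up", "n_down", "pct_up", "pct_down")},
        }

        stage = "differential_splicing"
        gene_lengths = pd.Series(
            {g: gm.exonic_length() for g, gm in model.genes.items()}
        )
        ds_model = BinSplicingTest(
            bdf, bin_cm, gene_cm, gene_lengths, monoexonic=model.monoexonic_genes
        )
        ds_res = ds_model.fit(
            min_mean=config.min_bin_mean,
            min_gene_density=config.min_gene_density,
            fdr_max=config.ds_fdr,
            lfc_min=config.lfc,
        )
        ds_res.table.to_csv(out / "ds.tsv", sep="\t")
        freq_all = ds_res.event_frequencies("all_detected")
        freq_sig = ds_res.event_frequencies("significant")
        freq_all.to_csv(out / "event_frequencies_all.tsv", sep="\t")
        freq_sig.to_csv(out / "event_frequencies_significant.tsv", sep="\t")
        intron_cls = ds_res.intron_class_comparison()
        report["stages"]["differential_splicing"] = {
            "n_input": ds_res.n_input,
            "n_tested": int(len(ds_res.table)),
            "n_filtered": ds_res.n_input - int(len(ds_res.table)),
            "dispersion": ds_res.dispersion,
            "n_significant": int(ds_res.table["significant"].sum()),
            "n_genes_affected": len(ds_res.affected_genes),
            "event_frequencies_all": freq_all["percent"].to_dict(),
            "event_frequencies_significant": freq_sig["percent"].to_dict(),
            "intron_class_comparison": intron_cls,
        }

        stage = "overlap"
        overlap = summarize_overlap(de_res.significant_genes, ds_res.affected_genes)
        report["stages"]["overlap"] = overlap

        if config.genome:
            stage = "splice_sites"
            genome = load_genome(config.genome)
            introns = enumerate_introns(model)
            sig_up = ds_res.table[
                ds_res.table["significant"] & (ds_res.table["log2fc_density"] > 0)
            ]
            sig_ivs = [
                (bdf.at[b, "gene_id"], bdf.at[b, "start"], bdf.at[b, "end"])
                for b in sig_up.index
                if bdf.at[b, "kind"] in ("as", "intron")
            ]
            subset = [
                iv
                for iv in introns
                if any(
                    iv.gene_id == g and iv.start < e and iv.end > s
                    for g, s, e in sig_ivs
                )
            ]
            d_uni, a_uni = extract_splice_sites(
                genome, introns, config.donor_window, config.acceptor_window
            )
            pfm_d_uni, pfm_a_uni = build_pfm(d_uni), build_pfm(a_uni)
            pfm_d_uni.to_tsv(out / "donor_pfm_universe.tsv")
            pfm_a_uni.to_tsv(out / "acceptor_pfm_universe.tsv")
            sites_report = {
                "n_universe_introns": len(introns),
                "donor_gt_fraction": float(
                    sum(s[config.donor_window[0] : config.donor_window[0] + 2] == "GT" for s in d_uni)
                    / len(d_uni)
                )
                if d_uni
                else None,
                "n_subset_introns": len(subset),
            }
            if subset:
                d_sub, a_sub = extract_splice_sites(
                    genome, subset, config.donor_window, config.acceptor_window
                )
                pfm_d_sub, pfm_a_sub = build_pfm(d_sub), build_pfm(a_sub)
                pfm_d_sub.to_tsv(out / "donor_pfm_subset.tsv")
                pfm_a_sub.to_tsv(out / "acceptor_pfm_subset.tsv")
                enr = pd.concat(
                    [
                        positional_enrichment(pfm_d_sub, pfm_d_uni).assign(site="donor"),
                        positional_enrichment(pfm_a_sub, pfm_a_uni).assign(site="acceptor"),
                    ]
                )
                enr.to_csv(out / "site_enrichment.tsv", sep="\t", index=False)
                sites_report["min_enrichment_p"] = float(enr["pvalue"].min())
            report["stages"]["splice_sites"] = sites_report

        if config.gene_sets:
            stage = "enrichment"
            sets = read_gmt(config.gene_sets)
            universe = [str(g) for g in gene_cm.features]
            enr = enrich_categories(de_res.significant_genes, sets, universe)
            enr.to_csv(out / "enrichment_deg.tsv", sep="\t", index=False)
            report["stages"]["enrichment"] = {
                "n_categories": int(len(enr)),
                "n_enriched_p05": int((enr["pvalue"] < 0.05).sum()) if len(enr) else 0,
            }
    except Exception as exc:
        with open(out / "report.partial.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
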