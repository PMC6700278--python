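"""Gene-level differential expression by the negative-binomial exact test.

The workflow mirrors the classic two-group RNA-seq exact-test analysis:
discard weakly expressed genes, compute TMM (trimmed mean of M-values)
normalization factors, scale counts to a common library, estimate a single
common NB dispersion by conditional maximum likelihood, test each gene with
a two-sided conditional exact test on the group sums, and adjust p-values
by Benjamini-Hochberg.  A gene is called differentially expressed when
FDR < 0.05 and |log2 fold change| > 0.58 (about 1.5-fold).

The NB parameterization throughout is variance = mean + phi * mean^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix, normalized_counts

__all__ = [
    "filter_low_expression",
    "tmm_norm_factors",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "call_deg",
    "NBExactTest",
    "DEResults",
]


def filter_low_expression(cm: CountMatrix, min_mean: float = 10.0) -> CountMatrix:
    """Keep features whose mean raw count is >= ``min_mean`` in every condition.

    The boundary is inclusive: a mean of exactly ``min_mean`` is kept.
    """
    if len(cm.conditions) < 2:
        raise ValueError("need >= 2 conditions to filter per condition")
    means = cm.condition_means()
    keep = (means >= min_mean).all(axis=1)
    return cm.subset(cm.features[keep])


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim=0.30, abs_trim=0.05):
    """TMM factor of one sample against the reference sample."""
    mask = (obs > 0) & (ref > 0)
    obs, ref = obs[mask].astype(float), ref[mask].astype(float)
    if obs.size == 0:
        return 1.0
    p_o, p_r = obs / n_obs, ref / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    # inverse-variance weighting of the kept M-values
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def tmm_norm_factors(
    cm: CountMatrix,
    ref_sample: str | None = None,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> dict[str, float]:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    30% of genes are trimmed from each tail by log-ratio and 5% by absolute
    expression before the weighted mean of M-values is taken.  The reference
    sample is the one whose upper-quartile count fraction is closest to the
    across-sample mean, unless supplied.
    """
    counts = cm.counts
    if len(cm.samples) < 2:
        raise ValueError("TMM needs >= 2 samples")
    for s in cm.samples:
        if counts[s].sum() == 0:
            raise ValueError(f"sample {s} has all-zero counts")
    lib = np.array([cm.lib_size[s] for s in cm.samples])
    if ref_sample is None:
        uq = np.array(
            [np.quantile(counts[s].to_numpy() / cm.lib_size[s], 0.75) for s in cm.samples]
        )
        ref_sample = cm.samples[int(np.argmin(np.abs(uq - uq.mean())))]
    ref = counts[ref_sample].to_numpy()
    n_ref = cm.lib_size[ref_sample]
    raw = np.array(
        [
            _tmm_pair(counts[s].to_numpy(), ref, cm.lib_size[s], n_ref,
                      logratio_trim, abs_trim)
            for s in cm.samples
        ]
    )
    factors = raw / np.exp(np.mean(np.log(raw)))
    return dict(zip(cm.samples, factors.astype(float)))


# ---------------------------------------------------------------------------
# Common dispersion (conditional maximum likelihood)
# ---------------------------------------------------------------------------


def _cond_loglik(phi: float, group_mats: list[np.ndarray]) -> float:
    """Conditional NB log-likelihood given per-group totals, summed over genes.

    For a group of n samples with counts y_i and total z, conditioning on z
    removes the mean and leaves (r = 1/phi):

        sum_i lgamma(y_i + r) + lgamma(n r) - lgamma(z + n r) - n lgamma(r)
    """
    r = 1.0 / phi
    total = 0.0
    for y in group_mats:  # genes x samples, n >= 2
        n = y.shape[1]
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r)) + len(z) * gammaln(n * r)
            - np.sum(gammaln(z + n * r)) - len(z) * n * gammaln(r)
        )
    return total


def estimate_common_dispersion(
    cm: CountMatrix,
    groups: dict[str, str] | None = None,
    norm_factors: dict[str, float] | None = None,
    tol: float = 1e-6,
) -> float:
    """Common NB dispersion phi by conditional ML on equal-sized libraries.

    Counts are first scaled to the geometric-mean effective library
    (continuous pseudo-counts), then the conditional log-likelihood is
    maximized by bounded search on log10(phi).  phi = 0 recovers Poisson.
    """
    groups = groups or cm.condition_of
    pseudo = normalized_counts(cm, norm_factors)
    labels = sorted(set(groups.values()))
    group_mats = []
    for g in labels:
        samples = [s for s in cm.samples if groups[s] == g]
        if len(samples) >= 2:
            group_mats.append(pseudo[samples].to_numpy(dtype=float))
    if not group_mats:
        warnings.warn("no replicated group; dispersion not estimable, using phi=0")
        return 0.0

    lo, hi = -8.0, 1.0
    res = minimize_scalar(
        lambda x: -_cond_loglik(10.0**x, group_mats),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol},
    )
    phi = float(10.0**res.x)
    # optimum pinned at the lower boundary means no detectable overdispersion
    if phi < 1e-6:
        return 0.0
    return phi


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------


def _group_sum_logpmf(s: np.ndarray, n: int, mu: float, phi: float) -> np.ndarray:
    """log pmf of the sum of n iid NB(mu, phi) at integer points s.

    The sum is NB with mean n*mu and dispersion phi/n (size r = n/phi);
    phi = 0 degenerates to Poisson(n*mu).
    """
    m = n * mu
    if phi == 0.0:
        return s * np.log(m) - m - gammaln(s + 1.0)
    r = n / phi
    return (
        gammaln(s + r) - gammaln(r) - gammaln(s + 1.0)
        + r * np.log(r / (r + m)) + s * np.log(m / (r + m))
    )


def nb_exact_test(
    counts_a, counts_b, phi: float, max_total: int = 2_000_000
) -> tuple[float, float]:
    """Two-sided conditional NB exact test on two groups of equalized counts.

    Conditions on the total S = sum(A) + sum(B); the group sums are NB with
    the common per-sample null mean and dispersion phi / n_group.  The
    two-sided p-value sums the conditional probabilities of every outcome at
    most as probable as the observed split (ties included).

    Returns ``(pvalue, log2fc)`` where log2fc is the log2 ratio of the B
    group mean over the A group mean, with a 0.125-per-sample prior offset
    so zero counts stay finite.  Counts must already be on equalized
    (common) library sizes.
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    n_a, n_b = a.size, b.size
    s_a, s_b = float(a.sum()), float(b.sum())
    log2fc = float(np.log2((s_b / n_b + 0.125) / (s_a / n_a + 0.125)))
    total = int(round(s_a + s_b))
    if total <= 0:
        return 1.0, 0.0
    if total > max_total:
        raise ValueError(f"total count {total} too large for exact enumeration")
    obs = int(round(s_a))
    mu = total / (n_a + n_b)
    s = np.arange(total + 1)
    logp = _group_sum_logpmf(s, n_a, mu, phi) + _group_sum_logpmf(
        (total - s).astype(float), n_b, mu, phi
    )
    logp -= logsumexp(logp)
    p = float(np.exp(logsumexp(logp[logp <= logp[obs] + 1e-10])))
    return min(p, 1.0), log2fc


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_deg(
    table: pd.DataFrame, fdr_max: float = 0.05, lfc_min: float = 0.58
) -> tuple[pd.DataFrame, dict]:
    """Flag significant features and summarize the up/down split.

    A feature is significant iff fdr < ``fdr_max`` and |log2fc| > ``lfc_min``
    (both strict).  The summary reports n_up, n_down and the percentage of
    each among the significant set, to one decimal.
    """
    table = table.copy()
    table["significant"] = (table["fdr"] < fdr_max) & (table["log2fc"].abs() > lfc_min)
    table["direction"] = np.where(
        ~table["significant"], "ns", np.where(table["log2fc"] > 0, "up", "down")
    )
    n_up = int((table["direction"] == "up").sum())
    n_down = int((table["direction"] == "down").sum())
    n = n_up + n_down
    summary = {
        "n_tested": int(len(table)),
        "n_significant": n,
        "n_up": n_up,
        "n_down": n_down,
        "pct_up": round(100.0 * n_up / n, 1) if n else float("nan"),
        "pct_down": round(100.0 * n_down / n, 1) if n else float("nan"),
    }
    return table, summary


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class NBExactTest:
    """Two-group NB exact-test differential expression model.

    Parameters
    ----------
    cm : CountMatrix
        Raw integer counts with exactly two conditions.
    reference, alternative : str, optional
        Condition labels; fold changes are alternative over reference.
        Default: first condition encountered is the reference (e.g. wild
        type), the second the alternative (e.g. mutant).
    min_mean : float
        Low-expression filter: minimum mean raw count per condition.
    """

    def __init__(
        self,
        cm: CountMatrix,
        reference: str | None = None,
        alternative: str | None = None,
        min_mean: float = 10.0,
    ):
        conds = cm.conditions
        if len(conds) != 2:
            raise ValueError(f"need exactly 2 conditions, got {conds}")
        self.cm = cm
        self.reference = reference or conds[0]
        self.alternative = alternative or [c for c in conds if c != self.reference][0]
        self.min_mean = min_mean

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, condition_of: dict[str, str], **kw
    ) -> "NBExactTest":
        return cls(CountMatrix(counts=counts, condition_of=condition_of), **kw)

    def fit(
        self,
        fdr_max: float = 0.05,
        lfc_min: float = 0.58,
        dispersion: float | None = None,
    ) -> "DEResults":
        cm_all = self.cm
        cm = filter_low_expression(cm_all, self.min_mean) if self.min_mean > 0 else cm_all
        factors = tmm_norm_factors(cm)
        phi = (
            dispersion
            if dispersion is not None
            else estimate_common_dispersion(cm, norm_factors=factors)
        )
        pseudo = normalized_counts(cm, factors)
        a_cols = cm.samples_of(self.reference)
        b_cols = cm.samples_of(self.alternative)
        a_mat = pseudo[a_cols].to_numpy(dtype=float)
        b_mat = pseudo[b_cols].to_numpy(dtype=float)
        pvals = np.empty(len(cm.features))
        lfcs = np.empty(len(cm.features))
        for i in range(len(cm.features)):
            pvals[i], lfcs[i] = nb_exact_test(a_mat[i], b_mat[i], phi)
        means = cm.condition_means()
        table = pd.DataFrame(
            {
                f"mean_{self.reference}": means[self.reference],
                f"mean_{self.alternative}": means[self.alternative],
                "log2fc": lfcs,
                "pvalue": pvals,
                "fdr": bh_adjust(pvals),
            },
            index=cm.features,
        )
        table, summary = call_deg(table, fdr_max=fdr_max, lfc_min=lfc_min)
        return DEResults(
            model=self,
            table=table,
            dispersion=phi,
            norm_factors=factors,
            n_input=len(cm_all.features),
            deg_summary=summary,
            fdr_max=fdr_max,
            lfc_min=lfc_min,
        )


@dataclass
class DEResults:
    """Fitted differential-expression results.

    ``table`` has one row per tested gene: condition means, log2fc
    (alternative over reference), pvalue, BH fdr, significance call.
    """

    model: NBExactTest
    table: pd.DataFrame
    dispersion: float
    norm_factors: dict[str, float]
    n_input: int
    deg_summary: dict
    fdr_max: float
    lfc_min: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def summary(self) -> str:
        s = self.deg_summary
        lines = [
            "NB exact-test differential expression",
            "=" * 46,
            f"contrast:        {self.model.alternative} vs {self.model.reference}",
            f"genes in:        {self.n_input}",
            f"genes tested:    {s['n_tested']} (mean >= {self.model.min_mean} per condition)",
            f"common phi:      {self.dispersion:.4g}",
            f"thresholds:      FDR < {self.fdr_max}, |log2FC| > {self.lfc_min}",
            f"DEG:             {s['n_significant']}",
        ]
        if s["n_significant"]:
            lines.append(
                f"  up:            {s['n_up']} ({s['pct_up']}%)"
            )
            lines.append(
                f"  down:          {s['n_down']} ({s['pct_down']}%)"
            )
        return "\n".join(lines)
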