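"""Inference on SRD annotations against graph-wide null distributions.

The null distribution is the SRD of *every* gene-metabolite combination in
the graph.  Observed pair sets are compared to it three ways:

* a quartile threshold — the first quartile of the finite null values defines
  "small" SRD (on the human overview map this lands at 8);
* a permutation test on the median — reassigning metabolites to genes within
  the observed entity sets and asking how often a random assignment attains a
  median SRD as small as the observed one;
* a Welch two-sample t test of observed finite SRDs against the null;
* the SRD vs significance correlation — Pearson r between SRD and
  -log10(min p), with a graph-aware empirical p from the same permutation
  scheme (the graph's topology makes parametric p values optimistic).

Empirical p values always use the (1 + k) / (1 + n) estimator, so they are
never exactly zero, and every stochastic routine is reproducible from
(seed, n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .graph import MetabolicGraph
from .srd import all_pairs_srd_matrix, srd_batch

__all__ = [
    "null_distribution",
    "quartile_threshold",
    "permutation_test_median",
    "welch_vs_null",
    "srd_pvalue_correlation",
    "categorize_small_srd",
    "PermutationMedianResult",
    "CorrelationResult",
    "SRDStatsReport",
    "compile_report",
]

RESAMPLE = "resample"
SHUFFLE = "shuffle"


def null_distribution(g: MetabolicGraph) -> tuple[np.ndarray, int]:
    """All-pairs SRD values: (sorted finite values, count of infinite).

    NA cannot occur — every gene and metabolite is in-graph by construction.
    """
    _, _, D = all_pairs_srd_matrix(g)
    flat = D.ravel()
    finite = flat[np.isfinite(flat)]
    return np.sort(finite), int(np.isinf(flat).sum())


def quartile_threshold(null_values: np.ndarray) -> int:
    """First quartile of the finite null SRDs, floored to an integer.

    Uses the type-7 (linear interpolation) quantile, numpy's default; the
    floor keeps the threshold a whole number of reaction steps.  Infinite
    values must be excluded by the caller (``null_distribution`` already
    separates them).
    """
    values = np.asarray(null_values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 4:
        raise ValueError(f"quartile_threshold needs >=4 finite values, got {len(values)}")
    return int(np.floor(np.percentile(values, 25)))


def _observed_srd_matrix(
    g: MetabolicGraph, genes: list[str], mets: list[str]
) -> np.ndarray:
    """Dense SRD lookup for the observed entity sets (inf = no path/absent)."""
    results = srd_batch(g, [(gn, m) for gn in genes for m in mets])
    D = np.array([r.srd.as_float() for r in results]).reshape(len(genes), len(mets))
    return np.where(np.isnan(D), np.inf, D)  # absent entities: never finite


def _finite_median(values: np.ndarray) -> float:
    finite = values[np.isfinite(values)]
    return float(np.median(finite)) if len(finite) else np.inf


@dataclass
class PermutationMedianResult:
    observed_median: float
    perm_medians: np.ndarray
    empirical_p: float
    n_perm: int
    seed: int
    scheme: str
    n_infinite_observed: int = 0


def permutation_test_median(
    g: MetabolicGraph,
    observed_pairs: list[tuple[str, str]],
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = RESAMPLE,
) -> PermutationMedianResult:
    """Is the observed median SRD smaller than random gene-metabolite pairing?

    Each permutation keeps every pair's gene and reassigns its metabolite
    from the observed metabolite set: scheme ``resample`` draws uniformly
    with replacement from the distinct observed metabolites; ``shuffle``
    permutes the observed metabolite column (exchangeable variant).  Medians
    are taken over finite SRDs only (infinite values are excluded before the
    median, as when annotating real pair sets).  The one-sided empirical p is
    ``(1 + #{perm median <= observed median}) / (n_perm + 1)``.
    """
    if scheme not in (RESAMPLE, SHUFFLE):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = [gn for gn, _ in observed_pairs]
    met_col = [m for _, m in observed_pairs]
    gene_set = sorted(set(genes))
    met_set = sorted(set(met_col))
    D = _observed_srd_matrix(g, gene_set, met_set)
    gi = np.array([gene_set.index(gn) for gn in genes])
    mi = np.array([met_set.index(m) for m in met_col])

    observed = D[gi, mi]
    n_inf = int(np.isinf(observed).sum())
    if n_inf == len(observed):
        raise ValueError("all observed SRDs are infinite; no finite median exists")
    observed_median = _finite_median(observed)

    rng = np.random.default_rng(seed)
    perm_medians = np.empty(n_perm)
    for b in range(n_perm):
        if scheme == RESAMPLE:
            mj = rng.integers(0, len(met_set), size=len(observed_pairs))
        else:
            mj = mi[rng.permutation(len(mi))]
        perm_medians[b] = _finite_median(D[gi, mj])
    empirical_p = (1 + int((perm_medians <= observed_median).sum())) / (n_perm + 1)
    return PermutationMedianResult(
        observed_median=observed_median,
        perm_medians=perm_medians,
        empirical_p=empirical_p,
        n_perm=n_perm,
        seed=seed,
        scheme=scheme,
        n_infinite_observed=n_inf,
    )


def welch_vs_null(observed_finite, null_finite) -> tuple[float, float]:
    """Welch two-sample t test (Satterthwaite df), two-sided.

    Compares the observed finite SRDs with the graph-wide null values without
    assuming equal variances.
    """
    a = np.asarray(observed_finite, dtype=float)
    b = np.asarray(null_finite, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_vs_null needs >=2 values per sample")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() != b.mean():
        raise ValueError("both samples are degenerate (zero variance)")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationResult:
    r: float | None
    parametric_p: float | None
    empirical_p: float | None
    n_pairs: int
    n_perm: int
    seed: int
    method: str
    message: str = ""
    perm_r: np.ndarray = field(default_factory=lambda: np.empty(0))


def srd_pvalue_correlation(
    g: MetabolicGraph,
    pairs: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "pearson",
    pairlevel_p: float | None = None,
    scheme: str = RESAMPLE,
) -> CorrelationResult:
    """Correlation between SRD and association significance (-log10 min p).

    Restricted to pairs with finite SRD and, when ``pairlevel_p`` is given,
    min p below it.  The parametric p assumes independent observations, which
    the shared graph structure violates; the empirical p therefore permutes
    the metabolite assignment (same schemes as the median test), recomputes
    SRD from the graph and r against the unchanged -log10 p, and reports
    ``(1 + #{r_perm <= r_obs}) / (n_perm + 1)`` for the negative-correlation
    alternative.
    """
    df = pairs.copy()
    if pairlevel_p is not None:
        df = df[df["min_p"] <= pairlevel_p]
    genes = df["kegg_gene_id"].astype(str).tolist()
    mets = df["metabolite_key"].astype(str).tolist()
    gene_set = sorted(set(genes))
    met_set = sorted(set(mets))
    D = _observed_srd_matrix(g, gene_set, met_set)
    gi = np.array([gene_set.index(gn) for gn in genes], dtype=int)
    mi = np.array([met_set.index(m) for m in mets], dtype=int)
    srd_obs = D[gi, mi] if len(df) else np.empty(0)
    finite = np.isfinite(srd_obs)
    if finite.sum() < 10:
        raise ValueError(
            f"srd_pvalue_correlation needs >=10 finite-SRD pairs, got {int(finite.sum())}"
        )
    logp = -np.log10(df["min_p"].to_numpy(dtype=float))

    x, y = srd_obs[finite], logp[finite]
    if np.all(x == x[0]):
        return CorrelationResult(
            r=None,
            parametric_p=None,
            empirical_p=None,
            n_pairs=int(finite.sum()),
            n_perm=n_perm,
            seed=seed,
            method=method,
            message="SRD is constant across pairs; correlation is undefined",
        )
    corr = sps.pearsonr if method == "pearson" else sps.spearmanr
    r_obs, parametric_p = map(float, corr(x, y))

    rng = np.random.default_rng(seed)
    perm_r = np.full(n_perm, np.nan)
    n = len(srd_obs)
    for b in range(n_perm):
        if scheme == RESAMPLE:
            mj = rng.integers(0, len(met_set), size=n)
        else:
            mj = mi[rng.permutation(n)]
        srd_b = D[gi, mj]
        ok = np.isfinite(srd_b)
        xb = srd_b[ok]
        if ok.sum() >= 3 and not np.all(xb == xb[0]):
            perm_r[b] = corr(xb, logp[ok])[0]
    k = int(np.nansum(perm_r <= r_obs))
    empirical_p = (1 + k) / (n_perm + 1)
    return CorrelationResult(
        r=r_obs,
        parametric_p=parametric_p,
        empirical_p=empirical_p,
        n_pairs=int(finite.sum()),
        n_perm=n_perm,
        seed=seed,
        method=method,
        perm_r=perm_r,
    )


def categorize_small_srd(pairs: pd.DataFrame, threshold: int = 8) -> pd.DataFrame:
    """Per significance category: how many pairs have small (<= threshold) SRD.

    Percentages are computed among finite-SRD pairs only; infinite and NA
    outcomes are tallied separately as their own classes (they say "no
    relationship measurable", not "far").  Expects columns ``category`` and
    ``srd`` (float, with ``inf`` for disconnected and ``nan`` for NA).
    """
    rows = []
    for cat, sub in pairs.groupby("category", observed=False):
        vals = sub["srd"].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        n_fin = len(finite)
        n_le = int((finite <= threshold).sum())
        rows.append(
            {
                "category": cat,
                "n_finite": n_fin,
                "n_small": n_le,
                "n_large": n_fin - n_le,
                "pct_small": round(100 * n_le / n_fin, 2) if n_fin else np.nan,
                "pct_large": round(100 * (n_fin - n_le) / n_fin, 2) if n_fin else np.nan,
                "n_infinite": int(np.isinf(vals).sum()),
                "n_na": int(np.isnan(vals).sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SRDStatsReport:
    """Bundle of the inferential results for one observed pair set."""

    null_values: np.ndarray
    n_null_infinite: int
    q1_threshold: int
    observed_median: float
    perm_medians: np.ndarray
    empirical_p: float
    welch_t: float
    welch_p: float
    corr_r: float | None
    corr_parametric_p: float | None
    corr_empirical_p: float | None
    n_perm: int
    seed: int

    def summary_text(self) -> str:
        lines = [
            f"null SRD values: {len(self.null_values)} finite, "
            f"{self.n_null_infinite} infinite",
            f"first-quartile (small SRD) threshold: {self.q1_threshold}",
            f"observed median SRD: {self.observed_median}",
            f"permutation empirical p (n_perm={self.n_perm}, seed={self.seed}): "
            f"{self.empirical_p:.4g}",
            f"Welch vs null: t={self.welch_t:.4g}, p={self.welch_p:.4g}",
        ]
        if self.corr_r is None:
            lines.append("SRD vs -log10(p) correlation: not computable")
        else:
            lines.append(
                f"SRD vs -log10(p) correlation: r={self.corr_r:.3f}, "
                f"parametric p={self.corr_parametric_p:.3g}, "
                f"empirical p={self.corr_empirical_p:.4g}"
            )
        return "\n".join(lines)


def compile_report(
    g: MetabolicGraph,
    pairs: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = RESAMPLE,
) -> SRDStatsReport:
    """Run the full inferential layer for an annotated pair table.

    ``pairs`` must carry kegg_gene_id, metabolite_key, min_p and srd columns
    (as produced by the annotation pipeline).
    """
    null_values, n_inf = null_distribution(g)
    q1 = quartile_threshold(null_values)
    observed_pairs = list(zip(pairs["kegg_gene_id"], pairs["metabolite_key"]))
    perm = permutation_test_median(g, observed_pairs, n_perm=n_perm, seed=seed, scheme=scheme)
    srd_vals = pairs["srd"].to_numpy(dtype=float)
    welch_t, welch_p = welch_vs_null(srd_vals[np.isfinite(srd_vals)], null_values)
    try:
        corr = srd_pvalue_correlation(
            g, pairs, n_perm=n_perm, seed=seed + 1, scheme=scheme
        )
        corr_r, corr_pp, corr_ep = corr.r, corr.parametric_p, corr.empirical_p
    except ValueError:
        corr_r = corr_pp = corr_ep = None
    return SRDStatsReport(
        null_values=null_values,
        n_null_infinite=n_inf,
        q1_threshold=q1,
        observed_median=perm.observed_median,
        perm_medians=perm.perm_medians,
        empirical_p=perm.empirical_p,
        welch_t=welch_t,
        welch_p=welch_p,
        corr_r=corr_r,
        corr_parametric_p=corr_pp,
        corr_empirical_p=corr_ep,
        n_perm=n_perm,
        seed=seed,
    )
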