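"""Expression statistics stratified by m6A category.

RPKM and nuclear indexes, two-tailed Wilcoxon rank-sum comparisons across
m6A-level strata with ECDF tables for cumulative-fraction plots, and
pseudogene-cognate expression correlations across samples with
Benjamini-Hochberg FDR control.  The expected patterns under m6A-dependent
cytosolic decay are lower cytosolic expression and higher nuclear index for
the high-m6A stratum, and weaker pair correlation (ceRNA coupling) the more
methylated the pseudogene is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: default pseudocount (RPKM) in nuclear-index ratios
NUCLEAR_INDEX_PSEUDOCOUNT = 0.01

STRATUM_PAIRS = [("high", "low"), ("high", "medium"), ("medium", "low")]


@dataclass
class PairCorrelation:
    pair_id: str
    r: float
    p: float
    q: float
    n_samples: int

    @property
    def sign(self) -> str:
        return "positive" if self.r >= 0 else "negative"


def rpkm(count: float, length: int, library_size: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return count / (length / 1_000.0) / (library_size / 1_000_000.0)


def nuclear_index(
    nucleus_rpkm: float,
    cytosol_rpkm: float,
    pseudocount: float = NUCLEAR_INDEX_PSEUDOCOUNT,
) -> float:
    """Nucleus-to-cytosol expression ratio, pseudocount-stabilized.

    With ``pseudocount=0`` a zero cytosolic RPKM raises instead of returning
    infinity.
    """
    if nucleus_rpkm < 0 or cytosol_rpkm < 0:
        raise ValueError("RPKMs must be >= 0")
    if pseudocount == 0 and cytosol_rpkm == 0:
        raise ValueError("cytosol RPKM is 0 and pseudocount is 0")
    return (nucleus_rpkm + pseudocount) / (cytosol_rpkm + pseudocount)


def ecdf_table(values: Sequence[float]) -> pd.DataFrame:
    """Right-continuous empirical CDF as a step-function table."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        return pd.DataFrame(columns=["value", "cumulative_fraction"])
    ux, counts = np.unique(x, return_counts=True)
    return pd.DataFrame(
        {"value": ux, "cumulative_fraction": np.cumsum(counts) / x.size}
    )


def _rank_sum_p(a: np.ndarray, b: np.ndarray, exact_threshold: int = 20) -> float:
    """Two-tailed rank-sum p: normal approximation with tie correction for
    the sample sizes the cohort analyses use; exact Mann-Whitney enumeration
    when both groups are smaller than ``exact_threshold``."""
    if max(a.size, b.size) < exact_threshold:
        try:
            return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
        except ValueError:  # ties: exact enumeration unavailable
            pass
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)


def stratified_wilcoxon(
    values: Mapping[str, float],
    categories: Mapping[str, str],
    min_per_stratum: int = 3,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Pairwise two-tailed Wilcoxon rank-sum across m6A strata plus per-stratum
    ECDF tables.

    ``values`` maps gene -> outcome, ``categories`` maps gene -> stratum in
    {high, medium, low}.  Comparisons with an undersized stratum are reported
    with NaN p and skipped=True rather than dropped silently.
    """
    groups: dict[str, list[float]] = {"high": [], "medium": [], "low": []}
    for gene, v in values.items():
        cat = categories.get(gene)
        if cat in groups and np.isfinite(v):
            groups[cat].append(float(v))
    arrays = {k: np.asarray(v) for k, v in groups.items()}
    rows = []
    for ga, gb in STRATUM_PAIRS:
        a, b = arrays[ga], arrays[gb]
        if a.size < min_per_stratum or b.size < min_per_stratum:
            rows.append((ga, gb, a.size, b.size, float("nan"), float("nan"), True))
            continue
        p = _rank_sum_p(a, b)
        shift = float(np.median(a) - np.median(b))
        rows.append((ga, gb, a.size, b.size, p, shift, False))
    tests = pd.DataFrame(
        rows,
        columns=["stratum_a", "stratum_b", "n_a", "n_b", "p", "median_shift", "skipped"],
    )
    ecdfs = {k: ecdf_table(v) for k, v in arrays.items() if len(v)}
    return tests, ecdfs


def pair_correlations(
    expr_matrix: pd.DataFrame,
    pairs: Sequence[tuple[str, str, str]],
    log_transform: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-pair Pearson correlation of pseudogene vs cognate expression
    across samples, BH-adjusted across all testable pairs.

    ``pairs`` yields (pair_id, pseudogene_id, cognate_id).  Expression is
    log2(x + 1)-transformed by default.  Zero-variance pairs are flagged
    untestable and excluded from the BH family.  ``significant`` marks
    q < alpha.
    """
    if expr_matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    mat = np.log2(expr_matrix + 1.0) if log_transform else expr_matrix
    rows = []
    for pair_id, pg, cg in pairs:
        if pg not in mat.index or cg not in mat.index:
            rows.append((pair_id, pg, cg, np.nan, np.nan, False))
            continue
        x = mat.loc[pg].to_numpy(dtype=float)
        y = mat.loc[cg].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((pair_id, pg, cg, np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((pair_id, pg, cg, float(r), float(p), True))
    df = pd.DataFrame(
        rows, columns=["pair_id", "pseudogene_id", "cognate_id", "r", "p", "testable"]
    )
    df["q"] = np.nan
    testable = df["testable"].to_numpy()
    if testable.any():
        df.loc[testable, "q"] = bh_adjust(df.loc[testable, "p"].to_numpy())
    df["significant"] = df["q"] < alpha
    df["sign"] = np.where(df["r"] >= 0, "positive", "negative")
    df["n_samples"] = expr_matrix.shape[1]
    return df


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, q >= p)."""
    return multipletests(pvalues, method="fdr_bh")[1]


def correlation_by_stratum(
    correlations: pd.DataFrame,
    categories: Mapping[str, str],
    classes: Mapping[str, str] | None = None,
) -> dict[str, tuple[pd.DataFrame, dict[str, pd.DataFrame]]]:
    """Stratified Wilcoxon on pair correlation coefficients, run separately
    per pseudogene class when ``classes`` (pseudogene -> class) is given.

    ``categories`` maps pseudogene -> m6A stratum of the pseudogene.  Returns
    {class: (tests table, ECDFs)}; with no classes, a single "all" entry.
    """
    out = {}
    by_class: dict[str, list[tuple[str, float]]] = {}
    for row in correlations.itertuples(index=False):
        if not row.testable or not np.isfinite(row.r):
            continue
        klass = (classes or {}).get(row.pseudogene_id, "all")
        by_class.setdefault(klass, []).append((row.pseudogene_id, row.r))
    for klass, entries in sorted(by_class.items()):
        values = {pg: r for pg, r in entries}
        out[klass] = stratified_wilcoxon(values, categories)
    return out
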