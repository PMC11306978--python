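"""Selection classing from Ka/Ks, expression and DE calling, TE-proximity effects.

Selection classes follow the banded Ka/Ks convention: purifying when
omega <= 1 - SD, neutral within 1 +/- SD, positive above 1 + SD, with SD
defaulting to 0.213 (bands at 0.787 and 1.213).

Differential expression is a defined two-part rule on TPM: a gene is DE for a
treatment when |log2 fold change| (on pseudo-counted condition means) exceeds
a threshold AND a Welch t-test on log2(TPM+1) replicates, BH-adjusted across
genes within the treatment, is significant AND the gene is expressed
(mean TPM > 1 in at least one condition).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, rank_test

__all__ = [
    "SD_WIDTH_DEFAULT",
    "TE_BINS",
    "classify_selection",
    "call_de",
    "call_de_counts",
    "de_table",
    "max_expression",
    "expressed_flags",
    "assign_te_bins",
    "te_proximity_effect",
    "expression_selection_regression",
]

SD_WIDTH_DEFAULT = 0.213

#: distance bins (label, lower, upper), upper bounds inclusive, bp
TE_BINS = (
    ("overlapping", 0, 0),
    ("near", 1, 200),
    ("mid", 201, 2000),
    ("far", 2001, np.inf),
)


def classify_selection(omega, sd_width: float = SD_WIDTH_DEFAULT):
    """Class a Ka/Ks ratio as purifying / neutral / positive / undefined.

    purifying: omega <= 1 - sd_width (boundary inclusive);
    neutral:   1 - sd_width < omega <= 1 + sd_width;
    positive:  omega > 1 + sd_width;
    undefined: omega is None/NaN (e.g. Ks = 0).

    Accepts a scalar or an array; negative omega raises.
    """
    scalar = np.isscalar(omega) or omega is None
    arr = np.asarray([omega] if scalar else omega, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("omega must be nonnegative")
    out = np.full(arr.shape, "undefined", dtype=object)
    finite = np.isfinite(arr)
    out[finite & (arr <= 1 - sd_width)] = "purifying"
    out[finite & (arr > 1 - sd_width) & (arr <= 1 + sd_width)] = "neutral"
    out[finite & (arr > 1 + sd_width)] = "positive"
    return out[0] if scalar else out


def _condition_means(tpm: pd.DataFrame, condition: str) -> pd.Series:
    cols = [c for c in tpm.columns if c.rsplit("_", 1)[0] == condition]
    if not cols:
        raise ValueError(f"no replicate columns found for condition {condition!r}")
    return tpm[cols].mean(axis=1)


def expressed_flags(tpm: pd.DataFrame, threshold: float = 1.0) -> pd.Series:
    """Expressed = mean TPM > threshold in at least one condition."""
    conditions = sorted({c.rsplit("_", 1)[0] for c in tpm.columns})
    means = pd.DataFrame({cond: _condition_means(tpm, cond) for cond in conditions})
    return means.max(axis=1) > threshold


def max_expression(tpm: pd.DataFrame) -> pd.Series:
    """Per-gene max over conditions of log2(mean TPM + 1)."""
    if tpm.shape[0] == 0 or tpm.shape[1] == 0:
        raise ValueError("empty TPM matrix")
    conditions = sorted({c.rsplit("_", 1)[0] for c in tpm.columns})
    means = pd.DataFrame({cond: _condition_means(tpm, cond) for cond in conditions})
    return np.log2(means.max(axis=1) + 1.0)


def call_de(
    tpm: pd.DataFrame,
    treatment: str,
    control: str = "control",
    min_log2fc: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    fold_change_only: bool = False,
) -> pd.DataFrame:
    """Call differential expression for one treatment against control.

    ``tpm`` is genes x ``condition_replicate`` columns (e.g. ``cold_1``).
    Returns a DataFrame indexed by gene with columns log2fc, p, q, de_flag.
    log2fc = log2((mean_treat + c) / (mean_ctrl + c)); significance by
    two-sided Welch t on log2(TPM+1) replicates, BH across genes;
    de_flag requires |log2fc| > min_log2fc, q <= alpha and the gene expressed.
    With ``fold_change_only`` (for unreplicated designs) the test is skipped
    and the flag is |log2fc| > min_log2fc AND expressed.
    """
    if np.any(tpm.to_numpy() < 0):
        raise ValueError("TPM values must be nonnegative")
    t_cols = [c for c in tpm.columns if c.rsplit("_", 1)[0] == treatment]
    c_cols = [c for c in tpm.columns if c.rsplit("_", 1)[0] == control]
    if not t_cols or not c_cols:
        raise ValueError(f"missing columns for {treatment!r} or {control!r}")
    if (len(t_cols) < 2 or len(c_cols) < 2) and not fold_change_only:
        raise ValueError(
            "need >= 2 replicates per condition for the Welch test; "
            "pass fold_change_only=True to flag on fold change alone"
        )
    mean_t = tpm[t_cols].mean(axis=1)
    mean_c = tpm[c_cols].mean(axis=1)
    log2fc = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))
    expressed = expressed_flags(tpm)
    out = pd.DataFrame({"log2fc": log2fc}, index=tpm.index)
    if fold_change_only:
        out["p"] = np.nan
        out["q"] = np.nan
        out["de_flag"] = (log2fc.abs() > min_log2fc) & expressed
        return out
    lt = np.log2(tpm[t_cols].to_numpy() + 1.0)
    lc = np.log2(tpm[c_cols].to_numpy() + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, p = sps.ttest_ind(lt, lc, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance genes: no evidence
    q = bh_adjust(p)
    out["p"] = p
    out["q"] = q
    out["de_flag"] = (log2fc.abs() > min_log2fc) & (out["q"] <= alpha) & expressed
    return out


def call_de_counts(
    counts: pd.DataFrame,
    treatment: str,
    control: str = "control",
    min_log2fc: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Exact-test DE on raw counts (Poisson conditional binomial).

    Replicate counts are summed per condition; under an equal-dispersion-zero
    (Poisson) null with library-size offset, the treatment sum conditioned on
    the total is Binomial(k_t + k_c, L_t / (L_t + L_c)). The two-sided exact
    binomial p is BH-adjusted across genes. Overdispersion is ignored, so
    p-values are anti-conservative for noisy biological replicates; the
    TPM-based :func:`call_de` is the default route.
    """
    if np.any(counts.to_numpy() < 0):
        raise ValueError("counts must be nonnegative")
    t_cols = [c for c in counts.columns if c.rsplit("_", 1)[0] == treatment]
    c_cols = [c for c in counts.columns if c.rsplit("_", 1)[0] == control]
    if not t_cols or not c_cols:
        raise ValueError(f"missing columns for {treatment!r} or {control!r}")
    kt = counts[t_cols].sum(axis=1).round().astype(int)
    kc = counts[c_cols].sum(axis=1).round().astype(int)
    lib_t, lib_c = float(kt.sum()), float(kc.sum())
    if lib_t == 0 or lib_c == 0:
        raise ValueError("a condition has zero total counts")
    p0 = lib_t / (lib_t + lib_c)
    pvals = np.array(
        [
            sps.binomtest(int(a), int(a + b), p0).pvalue if a + b > 0 else 1.0
            for a, b in zip(kt, kc)
        ]
    )
    # fold change on library-size-normalised means
    rate_t = (kt + pseudocount) / lib_t
    rate_c = (kc + pseudocount) / lib_c
    log2fc = np.log2(rate_t / rate_c)
    q = bh_adjust(pvals)
    out = pd.DataFrame(
        {"log2fc": log2fc, "p": pvals, "q": q}, index=counts.index
    )
    out["de_flag"] = (out["log2fc"].abs() > min_log2fc) & (out["q"] <= alpha)
    return out


def de_table(
    tpm: pd.DataFrame,
    treatments: list[str],
    control: str = "control",
    **kwargs,
) -> pd.DataFrame:
    """Per-gene DE flags and log2fc across several treatments.

    Columns: ``de_<t>`` (bool) and ``log2fc_<t>`` per treatment, plus
    ``expressed``.
    """
    out = pd.DataFrame(index=tpm.index)
    out["expressed"] = expressed_flags(tpm)
    for t in treatments:
        res = call_de(tpm, t, control=control, **kwargs)
        out[f"de_{t}"] = res["de_flag"]
        out[f"log2fc_{t}"] = res["log2fc"]
    return out


def trigger_sets(de_flags: pd.DataFrame, treatments: list[str]) -> pd.Series:
    """Collapse per-treatment DE flags into per-gene frozensets of triggers."""
    cols = [f"de_{t}" for t in treatments]
    flags = de_flags[cols].to_numpy(dtype=bool)
    return pd.Series(
        [frozenset(t for t, f in zip(treatments, row) if f) for row in flags],
        index=de_flags.index,
    )


def _min_te_distance(genes: pd.DataFrame, tes: pd.DataFrame) -> pd.Series:
    """Minimum distance (bp) from each gene to any TE, both flanks, 0 if overlapping.

    Coordinates are 0-based half-open. Vectorised per chromosome via sorted
    TE endpoint arrays; strand-agnostic.
    """
    dist = pd.Series(np.inf, index=genes.index, dtype=float)
    for chrom, g in genes.groupby("chrom", sort=False):
        t = tes[tes["chrom"] == chrom]
        if t.empty:
            continue
        ts = t["start"].to_numpy()
        te = t["end"].to_numpy()
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        d = np.empty(gs.size)
        for i in range(gs.size):
            # gap to each TE: start_te - gene_end if TE right of the gene,
            # gene_start - end_te if left of it, 0 if overlapping
            gaps = np.maximum(np.maximum(gs[i] - te, ts - ge[i]), 0)
            d[i] = float(gaps.min())
        dist.loc[g.index] = d
    return dist


def assign_te_bins(genes: pd.DataFrame, tes: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene to a TE-distance bin by minimum distance over all TEs.

    ``genes`` and ``tes`` need columns chrom/start/end (0-based half-open).
    Returns a DataFrame (index = gene index) with columns ``distance`` and
    ``bin`` in {overlapping, near, mid, far}; genes on chromosomes without any
    TE are ``far`` with infinite distance.
    """
    dist = _min_te_distance(genes, tes)
    labels = np.full(dist.size, "far", dtype=object)
    d = dist.to_numpy()
    for label, lo, hi in TE_BINS:
        mask = (d >= lo) & (d <= hi)
        labels[mask] = label
    return pd.DataFrame({"distance": dist, "bin": labels}, index=genes.index)


def te_proximity_effect(
    genes: pd.DataFrame,
    tes: pd.DataFrame,
    expression: pd.Series,
) -> pd.DataFrame:
    """Quantify expression suppression by TE proximity.

    ``expression`` is a per-gene summary TPM (indexed like ``genes``). For
    each distance bin the table reports the gene count, median expression,
    percent reduction relative to the far bin
    ((1 - median_bin/median_far) * 100), the log2 ratio of medians, and a
    two-sided rank-sum p-value of bin vs far. When the far bin is empty or
    has zero median, reductions are NaN (reported as undefined).
    """
    bins = assign_te_bins(genes, tes)
    expr = expression.reindex(bins.index)
    far_vals = expr[bins["bin"] == "far"].dropna()
    med_far = float(np.median(far_vals)) if len(far_vals) else np.nan
    rows = []
    for label, _, _ in TE_BINS:
        vals = expr[bins["bin"] == label].dropna()
        med = float(np.median(vals)) if len(vals) else np.nan
        if label != "far" and len(vals) and len(far_vals):
            _, p = rank_test(vals.to_numpy(), far_vals.to_numpy())
        else:
            p = np.nan
        if np.isfinite(med) and np.isfinite(med_far) and med_far > 0:
            pct = (1 - med / med_far) * 100
            log2_reduction = np.log2(med_far / med) if med > 0 else np.inf
        else:
            pct, log2_reduction = np.nan, np.nan
        rows.append(
            {
                "bin": label,
                "n_genes": int(len(vals)),
                "median_expression": med,
                "pct_reduction_vs_far": pct,
                "log2_reduction_vs_far": log2_reduction,
                "p_vs_far": p,
            }
        )
    return pd.DataFrame(rows).set_index("bin")


def expression_selection_regression(max_expr, omega) -> tuple[float, float]:
    """OLS of Ka/Ks on maximum expression; returns (slope, two-sided p).

    Tests the linear association between how highly a gene can be expressed
    and the strength of purifying selection on it.
    """
    x = np.asarray(max_expr, dtype=float)
    y = np.asarray(omega, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.pvalue)
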