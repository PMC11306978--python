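"""End-to-end analysis of a dataset bundle.

Runs the full post-WGD fractionation analysis in order: Ks-mixture WGD
detection and calibration dating, TE-burst dating, syntenic-window
construction, gene-tree subgenome assignment, bias partitioning, Ka/Ks
selection classing, expression/DE calling, TE-proximity quantification,
duplicate-fate classification against progenitor singletons, and enrichment
of DE gene sets in high-bias LF regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dating, expression as expr, fate as fate_mod, stats as fstats, windows as win
from .simulate import SyntheticBundle

__all__ = ["PipelineResult", "analyze_bundle"]


@dataclass
class PipelineResult:
    """All stage outputs plus a flat summary dict for reporting."""

    ks_fit: dating.KsMixtureFit
    wgd_age_ma: float
    te_burst_peaks: list[tuple[float, float]]
    windows: list[win.SyntenicWindow]
    assignment: win.SubgenomeAssignment
    selection: pd.Series
    de_flags: pd.DataFrame
    te_effect: pd.DataFrame
    fate_records: list[fate_mod.FateRecord]
    fate_summary: dict
    progenitor_summary: fate_mod.ProgenitorSummary | None
    enrichment: list[fstats.EnrichmentResult]
    summary: dict = field(default_factory=dict)


def _gene_window_map(windows: list[win.SyntenicWindow]) -> dict[str, tuple[str, str]]:
    out: dict[str, tuple[str, str]] = {}
    for w in windows:
        for g in w.genes_a:
            out[g] = (w.window_id, "a")
        for g in w.genes_b:
            out[g] = (w.window_id, "b")
    return out


def analyze_bundle(
    bundle: SyntheticBundle,
    use_truth_de: bool = False,
    truth=None,
    alpha: float = 0.05,
    seed: int = 0,
) -> PipelineResult:
    """Run the whole pipeline on a bundle and summarise the outcome.

    ``use_truth_de=True`` replaces the data-driven DE flags by the planted
    trigger sets from ``truth`` (a :class:`~fractiomics.simulate.GroundTruth`),
    which isolates the fate classifier from DE-calling noise.
    """
    cfg = bundle.config
    treatments = list(cfg.treatments)

    # --- WGD dating from the paralog Ks distribution
    ks_fit = dating.fit_ks_mixture(bundle.pairs["ks"].to_numpy(), k_components=2, seed=seed)
    young_peak = float(ks_fit.means[0])
    wgd_age = dating.date_by_calibration(young_peak)

    # --- TE amplification bursts
    te_peaks = dating.detect_burst_peaks(bundle.tes["divergence"].to_numpy())

    # --- syntenic windows, subgenome assignment, bias partition
    windows = win.build_windows(bundle.anchors)
    gw = _gene_window_map(windows)
    pair_copies = {
        r.pair_id: (r.copy_a_gene, r.copy_b_gene) for r in bundle.pairs.itertuples()
    }
    pair_window = {
        pid: gw[a][0]
        for pid, (a, b) in pair_copies.items()
        if a in gw and b in gw and gw[a][0] == gw[b][0]
    }
    assignment = win.assign_subgenomes(windows, bundle.trees, pair_copies, pair_window)
    win.partition_bias(windows, alpha=alpha)

    # --- selection classes
    omega = bundle.kaks["omega"]
    selection = pd.Series(expr.classify_selection(omega.to_numpy()), index=omega.index)

    # --- expression, DE and triggers
    de_flags = expr.de_table(bundle.tpm, treatments)
    expressed = de_flags["expressed"]
    if use_truth_de:
        if truth is None:
            raise ValueError("use_truth_de requires the ground truth")
        tg = truth.genes
        triggers = tg["triggers_true"].apply(
            lambda s: frozenset(s.split(",")) if s else frozenset()
        )
        expressed = tg["expressed_true"].astype(bool)
    else:
        triggers = expr.trigger_sets(de_flags, treatments)

    # --- TE proximity effect on expression (control-condition TPM)
    ctrl_cols = [c for c in bundle.tpm.columns if c.startswith("control_")]
    ctrl_mean = bundle.tpm[ctrl_cols].mean(axis=1)
    te_effect = expr.te_proximity_effect(bundle.genes, bundle.tes, ctrl_mean)

    # --- expression level vs Ka/Ks
    max_expr = expr.max_expression(bundle.tpm)
    shared = max_expr.index.intersection(omega.index)
    slope, slope_p = expr.expression_selection_regression(
        max_expr.loc[shared], omega.loc[shared]
    )

    # --- duplicate fates against progenitor singletons
    fate_records: list[fate_mod.FateRecord] = []
    win_by_id = {w.window_id: w for w in windows}
    for r in bundle.pairs.itertuples():
        wid = pair_window.get(r.pair_id)
        w = win_by_id.get(wid) if wid else None
        if w is None or w.track_lf is None:
            continue
        lf_gene, mf_gene = (
            (r.copy_a_gene, r.copy_b_gene)
            if w.track_lf == "a"
            else (r.copy_b_gene, r.copy_a_gene)
        )
        if not (
            lf_gene in expressed.index
            and mf_gene in expressed.index
            and bool(expressed[lf_gene])
            and bool(expressed[mf_gene])
        ):
            continue
        prog_row = bundle.prog_flags.loc[r.ref_gene]
        trig_prog = frozenset(t for t in treatments if bool(prog_row[t]))
        rec = fate_mod.FateRecord(
            pair_id=r.pair_id,
            lf_gene=lf_gene,
            mf_gene=mf_gene,
            selection_lf=selection.get(lf_gene, "undefined"),
            selection_mf=selection.get(mf_gene, "undefined"),
            triggers_lf=triggers.get(lf_gene, frozenset()),
            triggers_mf=triggers.get(mf_gene, frozenset()),
            triggers_prog=trig_prog,
        )
        rec.classify()
        fate_records.append(rec)
    fate_summary = fate_mod.summarize_fates(fate_records) if fate_records else {}

    # --- progenitor singleton outcomes
    prog_de_ids = [
        str(i)
        for i, row in bundle.prog_flags.iterrows()
        if any(bool(row[t]) for t in treatments)
    ]
    responsive = triggers.apply(bool) & expressed
    status_rows = {}
    for a in bundle.anchors.itertuples():
        copies = [g for g in (a.copy_a_gene, a.copy_b_gene) if pd.notna(g)]
        if len(copies) == 2:
            status = "duplicate"
        elif len(copies) == 1:
            status = "singleton"
        else:
            status = "lost"
        r_flags = [bool(responsive.get(g, False)) for g in copies]
        status_rows[a.ref_gene] = {
            "status": status,
            "responsive_lf": r_flags[0] if r_flags else False,
            "responsive_mf": r_flags[1] if len(r_flags) > 1 else False,
        }
    gene_table = pd.DataFrame.from_dict(status_rows, orient="index")
    prog_summary = (
        fate_mod.summarize_progenitor_outcomes(prog_de_ids, gene_table)
        if prog_de_ids
        else None
    )

    # --- enrichment of DE gene sets in high-bias LF regions
    background = [g for w in windows for g in (*w.genes_a, *w.genes_b)]
    region = [
        g
        for w in windows
        if w.bias_class == "high-bias"
        for g in w.genes_lf
    ]
    anno_sets = {
        f"de_{t}": set(triggers.index[triggers.apply(lambda s: t in s)]) & set(background)
        for t in treatments
    }
    enrichment = (
        fstats.hypergeom_enrichment(region, anno_sets, background) if region else []
    )

    # --- aggregate counts
    assigned = [w for w in windows if w.track_lf is not None]
    retained_lf = sum(w.retained_lf for w in assigned)
    retained_mf = sum(w.retained_mf for w in assigned)
    n_syntenic = sum(w.retained_a + w.retained_b for w in windows)
    n_dup_genes = 2 * len(pair_window)
    bias_counts = {
        c: sum(1 for w in windows if w.bias_class == c)
        for c in ("low-bias", "high-bias", "inverse-bias", "untested")
    }
    og = bundle.orthogroups
    og_presence_pct = 100 * og["present"].mean() if len(og) else np.nan

    mid = te_effect.loc["mid"]
    summary = {
        "n_windows_detected": len(windows),
        "n_syntenic_genes": int(n_syntenic),
        "n_duplicate_genes": int(n_dup_genes),
        "n_pairs": int(len(pair_window)),
        "duplicate_fraction_pct": 100 * n_dup_genes / n_syntenic if n_syntenic else np.nan,
        "retained_lf_total": int(retained_lf),
        "retained_mf_total": int(retained_mf),
        "lf_retention_share_pct": 100 * retained_lf / max(retained_lf + retained_mf, 1),
        "n_low_bias": bias_counts["low-bias"],
        "n_high_bias": bias_counts["high-bias"],
        "n_inverse_bias": bias_counts["inverse-bias"],
        "ks_peak_young": young_peak,
        "ks_peak_old": float(ks_fit.means[-1]),
        "wgd_age_ma": wgd_age,
        "te_burst_peak_divergence": te_peaks[0][0] if te_peaks else np.nan,
        "te_mid_bin_log2_reduction": float(mid["log2_reduction_vs_far"]),
        "te_mid_bin_pct_reduction": float(mid["pct_reduction_vs_far"]),
        "expression_omega_slope": slope,
        "expression_omega_slope_p": slope_p,
        "orthogroup_presence_pct": float(og_presence_pct),
    }
    if fate_summary:
        summary.update(
            {
                "n_expressed_pairs": fate_summary["n_pairs"],
                "dosage_balance_share_pct": fate_summary["dosage_balance_share_pct"],
                "trigger_change_share_pct": fate_summary["trigger_change_share_pct"],
                "neutral_share_pct": fate_summary["neutral_share_pct"],
                "neofunctionalization_share_pct": fate_summary[
                    "neofunctionalization_share_pct"
                ],
            }
        )
    if enrichment:
        summary["top_enriched_set"] = enrichment[0].set_id
        summary["top_enriched_q"] = enrichment[0].q

    return PipelineResult(
        ks_fit=ks_fit,
        wgd_age_ma=wgd_age,
        te_burst_peaks=te_peaks,
        windows=windows,
        assignment=assignment,
        selection=selection,
        de_flags=de_flags,
        te_effect=te_effect,
        fate_records=fate_records,
        fate_summary=fate_summary,
        progenitor_summary=prog_summary,
        enrichment=enrichment,
        summary=summary,
    )
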