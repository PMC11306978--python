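"""Synthetic mesopolyploid genome generator with full ground truth.

Builds a labelled dataset with the statistical structure the downstream
analysis assumes: two subgenomes with asymmetric gene retention inside
syntenic windows, a TE load difference between subgenomes, TE-proximity
expression suppression, a bimodal paralog Ks distribution (two WGD peaks),
banded Ka/Ks selection classes, per-treatment differential-expression
structure with trigger conservation/loss/gain relative to progenitor flags,
and gene trees carrying the subgenome signal. Identical seed and config give
a byte-identical bundle.

Gene coordinates are synthesised on artificial chromosomes with uniform gene
spacing (window logic depends on gene order, not physical distance); TE
distances to genes are explicit in bp so the proximity bins are all
populated. Subgenome-1 is the planted least-fractionated lineage: its copies
are sister to the ``progenitor_1`` taxon in concordant gene trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from .fate import classify_pair_fate
from .io import write_gff3, write_trees_tsv

__all__ = ["SyntheticBundle", "GroundTruth", "simulate_dataset", "simulate_expression", "write_bundle"]

_TE_NEAR_MAX_BP = 2000  # suppression applies to genes with a TE within this distance


@dataclass
class GroundTruth:
    """Planted labels for every simulated entity."""

    genes: pd.DataFrame  # per retained gene: subgenome, window, te flags, expression truth
    pairs: pd.DataFrame  # per both-retained pair: fate category, trigger sets, ks
    windows: pd.DataFrame  # per window: bias class, which track is subgenome-1


@dataclass
class SyntheticBundle:
    """All generated tables, cross-referenced by stable identifiers."""

    config: SimulationConfig
    genes: pd.DataFrame
    tes: pd.DataFrame
    anchors: pd.DataFrame
    pairs: pd.DataFrame
    kaks: pd.DataFrame
    tpm: pd.DataFrame
    trees: dict[str, str]
    prog_flags: pd.DataFrame
    orthogroups: pd.DataFrame


def _draw_mixture(rng, components, size, lower=0.0, upper=np.inf):
    """Draw from a Gaussian mixture, resampling outside [lower, upper]."""
    comps = np.asarray(components, dtype=float)
    out = np.empty(size)
    idx = rng.choice(len(comps), size=size, p=comps[:, 2] / comps[:, 2].sum())
    for j in range(len(comps)):
        sel = idx == j
        n = int(sel.sum())
        if not n:
            continue
        draws = rng.normal(comps[j, 0], comps[j, 1], size=n)
        bad = (draws < lower) | (draws > upper)
        while bad.any():
            draws[bad] = rng.normal(comps[j, 0], comps[j, 1], size=int(bad.sum()))
            bad = (draws < lower) | (draws > upper)
        out[sel] = draws
    return out


def _adjusted_retention(p: float, n_ref: int, seed_len: int) -> float:
    """Retention prob for non-seed genes so the window expectation stays p."""
    if n_ref == seed_len:
        return 1.0
    return float(np.clip((p * n_ref - seed_len) / (n_ref - seed_len), 0.0, 1.0))


def _draw_trigger_set(rng, treatments, enriched=None, boost=0.0) -> frozenset[str]:
    k = 1 if rng.random() < 0.7 else 2
    if enriched is not None and rng.random() < boost:
        first = enriched
        rest = [t for t in treatments if t != enriched]
        picks = {first} | set(rng.choice(rest, size=k - 1, replace=False)) if k > 1 else {first}
    else:
        picks = set(rng.choice(list(treatments), size=k, replace=False))
    return frozenset(picks)


def simulate_expression(
    genes: pd.DataFrame,
    te_near_flags: pd.Series,
    config: SimulationConfig,
    trigger_sets: pd.Series | None = None,
    baseline_log2: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a TPM matrix (genes x condition_replicate columns).

    Baseline log2 TPM is log-normal (drawn here unless ``baseline_log2`` is
    supplied); genes flagged TE-near have their baseline shifted down by
    ``te_expr_log2_reduction``; genes with a trigger set get
    ``de_effect_log2`` added in the triggering condition(s); replicate noise
    is i.i.d. normal on the log2 scale.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gene_ids = genes.index if isinstance(genes, pd.DataFrame) else pd.Index(genes)
    missing = gene_ids.difference(te_near_flags.index)
    if len(missing):
        raise ValueError(
            f"data consistency: te_near_flags missing for {len(missing)} gene(s), "
            f"e.g. {list(missing[:3])}"
        )
    n = len(gene_ids)
    if baseline_log2 is None:
        silent = rng.random(n) < config.silent_fraction
        mu = np.where(
            silent,
            rng.normal(config.silent_log2_mean, 1.0, size=n),
            rng.normal(config.expr_log2_mean, config.expr_log2_sd, size=n),
        )
        baseline_log2 = pd.Series(mu, index=gene_ids)
    base = baseline_log2.reindex(gene_ids).to_numpy(dtype=float).copy()
    base = base - config.te_expr_log2_reduction * te_near_flags.reindex(gene_ids).to_numpy(dtype=float)

    conditions = ("control",) + tuple(config.treatments)
    cols, data = [], []
    trig = (
        trigger_sets.reindex(gene_ids)
        if trigger_sets is not None
        else pd.Series([frozenset()] * n, index=gene_ids)
    )
    trig = trig.apply(lambda s: s if isinstance(s, (set, frozenset)) else frozenset())
    for cond in conditions:
        boost = np.array(
            [config.de_effect_log2 if cond in s else 0.0 for s in trig], dtype=float
        )
        for rep in range(1, config.n_replicates + 1):
            noise = rng.normal(0.0, config.replicate_noise_sd, size=n)
            cols.append(f"{cond}_{rep}")
            data.append(np.power(2.0, base + boost + noise))
    tpm = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
    tpm.index.name = "gene_id"
    return tpm


def simulate_dataset(config: SimulationConfig | None = None) -> tuple[SyntheticBundle, GroundTruth]:
    """Generate the full labelled bundle; identical seed -> identical output."""
    cfg = config or SimulationConfig()
    if not isinstance(cfg, SimulationConfig):
        raise ConfigError("config must be a SimulationConfig")
    rng = np.random.default_rng(cfg.seed)

    n_low = int(round(cfg.frac_low_bias_windows * cfg.n_windows))
    low_bias_ids = set(rng.choice(cfg.n_windows, size=n_low, replace=False).tolist())
    n_ref = cfg.genes_per_window_ref
    seed_len = min(cfg.seed_run_length, n_ref)
    p_eq = (cfg.retention_prob_lf + cfg.retention_prob_mf) / 2

    anchor_rows = []
    gene_rows = []
    te_rows = []
    pair_rows = []
    kaks_rows = []
    tree_map: dict[str, str] = {}
    prog_rows = []
    og_rows = []
    truth_gene_rows = []
    truth_pair_rows = []
    truth_window_rows = []

    te_bin_edges = {
        "overlapping": None,
        "near": (1, 200),
        "mid": (201, _TE_NEAR_MAX_BP),
        "far": (2500, 8000),  # explicit distal TE, still > the 2 kb near zone
    }
    bin_labels = ("overlapping", "near", "mid", "far")
    fam_names = [f for f, _ in cfg.te_families]
    fam_w = np.array([w for _, w in cfg.te_families], dtype=float)
    fam_w = fam_w / fam_w.sum()

    ref_counter = {c: 0 for c in range(cfg.n_ref_chroms)}
    te_counter = 0
    chrom_te_bp: dict[str, int] = {}

    def _add_te(chrom: str, start: int, te_len: int) -> None:
        # family and divergence are drawn in one vectorised pass afterwards
        nonlocal te_counter
        te_counter += 1
        te_rows.append(
            {
                "te_id": f"TE{te_counter:06d}",
                "chrom": chrom,
                "start": start,
                "end": start + te_len,
            }
        )
        chrom_te_bp[chrom] = chrom_te_bp.get(chrom, 0) + te_len

    # per-gene expression bookkeeping, assembled across windows
    all_gene_ids: list[str] = []
    all_baseline: list[float] = []
    all_te_near: list[bool] = []
    all_triggers: list[frozenset] = []

    for w in range(cfg.n_windows):
        wid = f"w{w + 1:04d}"
        chrom_i = w % cfg.n_ref_chroms
        ref_chrom = f"RefChr{chrom_i + 1}"
        low_bias = w in low_bias_ids
        track_s1 = "a" if rng.random() < 0.5 else "b"
        if low_bias:
            p1 = p2 = p_eq
        else:
            p1, p2 = cfg.retention_prob_lf, cfg.retention_prob_mf
        p1_adj = _adjusted_retention(p1, n_ref, seed_len)
        p2_adj = _adjusted_retention(p2, n_ref, seed_len)
        p_a = p1_adj if track_s1 == "a" else p2_adj
        p_b = p2_adj if track_s1 == "a" else p1_adj

        keep_a = rng.random(n_ref) < p_a
        keep_b = rng.random(n_ref) < p_b
        keep_a[:seed_len] = True
        keep_b[:seed_len] = True

        # pair Ks drawn from the planted WGD mixture
        ks_pair = _draw_mixture(rng, cfg.ks_components, n_ref, lower=0.0)

        chrom_a, chrom_b = f"Bla_{wid}_a", f"Bla_{wid}_b"
        pos_a = pos_b = 0
        truth_window_rows.append(
            {
                "window_id": wid,
                "ref_chrom": ref_chrom,
                "bias_class": "low-bias" if low_bias else "high-bias",
                "track_s1": track_s1,
                "p_retention_s1": p1,
                "p_retention_s2": p2,
            }
        )

        for g in range(n_ref):
            ref_counter[chrom_i] += 1
            ref_idx = ref_counter[chrom_i]
            ref_gene = f"At_{chrom_i + 1}_{ref_idx:05d}"
            ka, kb = bool(keep_a[g]), bool(keep_b[g])
            gene_a = f"Bl_{wid}_{g:03d}a" if ka else None
            gene_b = f"Bl_{wid}_{g:03d}b" if kb else None
            anchor_rows.append(
                {
                    "ref_gene": ref_gene,
                    "ref_chrom": ref_chrom,
                    "ref_index": ref_idx,
                    "copy_a_gene": gene_a,
                    "copy_b_gene": gene_b,
                }
            )

            # progenitor trigger set
            if rng.random() < cfg.prog_de_rate:
                prog_set = _draw_trigger_set(rng, cfg.treatments)
            else:
                prog_set = frozenset()
            prog_rows.append(
                {"ref_gene": ref_gene, **{t: t in prog_set for t in cfg.treatments}}
            )
            # conserved-orthogroup presence anywhere in the assembly is a
            # planted rate, independent of retention inside syntenic windows
            og_rows.append(
                {
                    "orthogroup_id": f"OG_{ref_gene}",
                    "ref_gene": ref_gene,
                    "present": int(rng.random() < cfg.og_presence_rate),
                }
            )

            copies = []
            if ka:
                copies.append(("a", gene_a, chrom_a))
            if kb:
                copies.append(("b", gene_b, chrom_b))
            copy_info = {}
            for track, gid, chrom in copies:
                if track == "a":
                    start = pos_a
                    pos_a += cfg.gene_spacing
                else:
                    start = pos_b
                    pos_b += cfg.gene_spacing
                end = start + cfg.gene_length
                subg = "S1" if track == track_s1 else "S2"
                gene_rows.append(
                    {
                        "gene_id": gid,
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "strand": "+",
                        "track": track,
                        "subgenome_true": subg,
                        "window_id": wid,
                        "ref_gene": ref_gene,
                    }
                )

                # planted TE proximity
                bin_lab = bin_labels[rng.choice(4, p=cfg.te_bin_probs)]
                te_dist = np.nan
                if bin_lab == "overlapping":
                    te_len = int(np.clip(rng.normal(cfg.te_mean_length, 150), 100, cfg.gene_length - 200))
                    _add_te(chrom, start + 100, te_len)
                    te_dist = 0.0
                elif bin_lab in ("near", "mid"):
                    lo_d, hi_d = te_bin_edges[bin_lab]
                    d = int(rng.integers(lo_d, hi_d + 1))
                    te_len = int(np.clip(rng.normal(cfg.te_mean_length, 150), 100, 2000))
                    _add_te(chrom, end + d, te_len)
                    te_dist = float(d)
                else:  # far: half the genes get an explicit distal TE
                    if rng.random() < 0.5:
                        lo_d, hi_d = te_bin_edges["far"]
                        d = int(rng.integers(lo_d, hi_d + 1))
                        te_len = int(np.clip(rng.normal(cfg.te_mean_length, 150), 100, 2000))
                        _add_te(chrom, end + d, te_len)
                        te_dist = float(d)
                te_near = bin_lab in ("overlapping", "near", "mid")

                # trigger evolution relative to the progenitor
                if prog_set:
                    conserve, lose, gain = cfg.trigger_transition_probs
                    u = rng.random()
                    if u < conserve:
                        trig = prog_set
                    elif u < conserve + lose:
                        trig = frozenset()
                    else:
                        extra = _draw_trigger_set(
                            rng,
                            cfg.treatments,
                            enriched=cfg.enriched_trigger if (not low_bias and subg == "S1") else None,
                            boost=cfg.enriched_trigger_boost,
                        )
                        trig = prog_set | extra
                else:
                    if rng.random() < cfg.background_gain_prob:
                        trig = _draw_trigger_set(
                            rng,
                            cfg.treatments,
                            enriched=cfg.enriched_trigger if (not low_bias and subg == "S1") else None,
                            boost=cfg.enriched_trigger_boost,
                        )
                    else:
                        trig = frozenset()

                # baseline expression
                if rng.random() < cfg.silent_fraction:
                    mu = float(rng.normal(cfg.silent_log2_mean, 1.0))
                else:
                    mu = float(rng.normal(cfg.expr_log2_mean, cfg.expr_log2_sd))
                mu_eff = mu - (cfg.te_expr_log2_reduction if te_near else 0.0)

                # selection class; purifying omega is coupled to expression
                cls_i = rng.choice(3, p=cfg.selection_class_probs)
                cls, lo, hi = cfg.kaks_by_class[cls_i]
                if cls == "purifying":
                    omega = float(
                        np.clip(
                            cfg.omega_expression_intercept
                            + cfg.omega_expression_slope * mu_eff
                            + rng.normal(0.0, cfg.omega_noise_sd),
                            lo,
                            hi,
                        )
                    )
                else:
                    omega = float(rng.uniform(lo, hi))
                ks_ref = float(max(rng.normal(cfg.ref_ks_mean, cfg.ref_ks_sd), 1e-3))
                kaks_rows.append(
                    {"gene_id": gid, "ka": omega * ks_ref, "ks": ks_ref, "omega": omega}
                )

                copy_info[track] = {
                    "gene_id": gid,
                    "class": cls,
                    "omega": omega,
                    "triggers": trig,
                    "mu": mu,
                    "te_near": te_near,
                    "subgenome": subg,
                }
                all_gene_ids.append(gid)
                all_baseline.append(mu)
                all_te_near.append(te_near)
                all_triggers.append(trig)
                truth_gene_rows.append(
                    {
                        "gene_id": gid,
                        "window_id": wid,
                        "track": track,
                        "subgenome_true": subg,
                        "selection_class_true": cls,
                        "omega_true": omega,
                        "te_bin_true": bin_lab,
                        "te_distance_true": te_dist,
                        "te_near_true": te_near,
                        "baseline_log2": mu,
                        "expressed_true": mu
                        - (cfg.te_expr_log2_reduction if te_near else 0.0)
                        > 0,
                        "triggers_true": ",".join(sorted(trig)),
                    }
                )

            if ka and kb:
                pair_id = f"pair_{ref_gene}"
                pair_rows.append(
                    {
                        "pair_id": pair_id,
                        "ref_gene": ref_gene,
                        "copy_a_gene": gene_a,
                        "copy_b_gene": gene_b,
                        "window_id": wid,
                        "ks": float(ks_pair[g]),
                    }
                )
                # gene tree: subgenome-1 copy sister to progenitor_1
                g_s1, g_s2 = (gene_a, gene_b) if track_s1 == "a" else (gene_b, gene_a)
                flipped = rng.random() < cfg.tree_flip_prob
                if flipped:
                    g_s1, g_s2 = g_s2, g_s1
                tree_map[pair_id] = (
                    f"(({g_s1}:0.05,progenitor_1:0.05):0.05,"
                    f"({g_s2}:0.05,progenitor_2:0.05):0.05,outgroup:0.20);"
                )

                info_a, info_b = copy_info["a"], copy_info["b"]
                info_lf = info_a if info_a["subgenome"] == "S1" else info_b
                info_mf = info_b if info_a["subgenome"] == "S1" else info_a
                expr_lf = info_lf["mu"] - (cfg.te_expr_log2_reduction if info_lf["te_near"] else 0) > 0
                expr_mf = info_mf["mu"] - (cfg.te_expr_log2_reduction if info_mf["te_near"] else 0) > 0
                if expr_lf and expr_mf:
                    fate = classify_pair_fate(
                        info_lf["class"],
                        info_mf["class"],
                        info_lf["triggers"],
                        info_mf["triggers"],
                        prog_set,
                    )
                else:
                    fate = ""
                truth_pair_rows.append(
                    {
                        "pair_id": pair_id,
                        "window_id": wid,
                        "lf_gene": info_lf["gene_id"],
                        "mf_gene": info_mf["gene_id"],
                        "ks_true": float(ks_pair[g]),
                        "expressed_pair_true": bool(expr_lf and expr_mf),
                        "fate_true": fate,
                        "triggers_prog_true": ",".join(sorted(prog_set)),
                        "triggers_lf_true": ",".join(sorted(info_lf["triggers"])),
                        "triggers_mf_true": ",".join(sorted(info_mf["triggers"])),
                    }
                )

        # spacer (nonsyntenic) reference genes after each window
        for _s in range(cfg.spacer_genes):
            ref_counter[chrom_i] += 1
            ref_idx = ref_counter[chrom_i]
            ref_gene = f"At_{chrom_i + 1}_{ref_idx:05d}"
            anchor_rows.append(
                {
                    "ref_gene": ref_gene,
                    "ref_chrom": ref_chrom,
                    "ref_index": ref_idx,
                    "copy_a_gene": None,
                    "copy_b_gene": None,
                }
            )
            prog_rows.append(
                {"ref_gene": ref_gene, **{t: False for t in cfg.treatments}}
            )
            og_rows.append(
                {
                    "orthogroup_id": f"OG_{ref_gene}",
                    "ref_gene": ref_gene,
                    "present": int(rng.random() < cfg.og_presence_rate),
                }
            )

        # distal filler TEs realising the per-subgenome TE density
        for track, chrom, span_end in (("a", chrom_a, pos_a), ("b", chrom_b, pos_b)):
            subg = "S1" if track == track_s1 else "S2"
            density = cfg.te_density_lf if subg == "S1" else cfg.te_density_mf
            span_mb = max(span_end, cfg.gene_spacing) / 1e6
            target_bp = density * span_mb
            placed_bp = chrom_te_bp.get(chrom, 0)
            n_fill = max(0, int(round((target_bp - placed_bp) / cfg.te_mean_length)))
            n_genes_track = max(1, span_end // cfg.gene_spacing)
            for _f in range(n_fill):
                gslot = int(rng.integers(0, n_genes_track))
                gene_end = gslot * cfg.gene_spacing + cfg.gene_length
                d = int(rng.integers(2500, 8001))
                te_len = int(np.clip(rng.normal(cfg.te_mean_length, 150), 100, 2000))
                _add_te(chrom, gene_end + d, te_len)

    genes = pd.DataFrame(gene_rows).set_index("gene_id")
    tes = pd.DataFrame(te_rows)
    if len(tes):
        fam_idx = rng.choice(len(fam_names), size=len(tes), p=fam_w)
        tes["family"] = [fam_names[i] for i in fam_idx]
        tes["divergence"] = _draw_mixture(
            rng, cfg.te_divergence_modes, len(tes), 0.0, 0.749
        )
    else:
        tes["family"] = pd.Series(dtype=str)
        tes["divergence"] = pd.Series(dtype=float)
    anchors = pd.DataFrame(anchor_rows)
    pairs = pd.DataFrame(pair_rows)
    kaks = pd.DataFrame(kaks_rows).set_index("gene_id")
    prog_flags = pd.DataFrame(prog_rows).set_index("ref_gene")
    orthogroups = pd.DataFrame(og_rows)

    tpm = simulate_expression(
        genes,
        te_near_flags=pd.Series(all_te_near, index=all_gene_ids),
        config=cfg,
        trigger_sets=pd.Series(all_triggers, index=all_gene_ids),
        baseline_log2=pd.Series(all_baseline, index=all_gene_ids),
        rng=rng,
    )

    truth = GroundTruth(
        genes=pd.DataFrame(truth_gene_rows).set_index("gene_id"),
        pairs=pd.DataFrame(truth_pair_rows).set_index("pair_id"),
        windows=pd.DataFrame(truth_window_rows).set_index("window_id"),
    )
    bundle = SyntheticBundle(
        config=cfg,
        genes=genes,
        tes=tes,
        anchors=anchors,
        pairs=pairs,
        kaks=kaks,
        tpm=tpm,
        trees=tree_map,
        prog_flags=prog_flags,
        orthogroups=orthogroups,
    )
    return bundle, truth


def write_bundle(bundle: SyntheticBundle, truth: GroundTruth, outdir: str | Path) -> None:
    """Write the bundle to ``outdir`` (GFF3 + TSVs + trees + truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes = bundle.genes.reset_index()
    gene_feats = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "source": "fractiomics-sim",
            "feature": "gene",
            "start": genes["start"],
            "end": genes["end"],
            "score": ".",
            "strand": genes["strand"],
            "frame": ".",
            "attributes": [
                {"ID": gid, "window": w, "ref_gene": r}
                for gid, w, r in zip(genes["gene_id"], genes["window_id"], genes["ref_gene"])
            ],
        }
    )
    write_gff3(gene_feats, outdir / "genes.gff3")

    te_feats = pd.DataFrame(
        {
            "chrom": bundle.tes["chrom"],
            "source": "fractiomics-sim",
            "feature": "transposable_element",
            "start": bundle.tes["start"],
            "end": bundle.tes["end"],
            "score": ".",
            "strand": "+",
            "frame": ".",
            "attributes": [
                {"ID": tid, "family": fam, "divergence": f"{div:.4f}"}
                for tid, fam, div in zip(
                    bundle.tes["te_id"], bundle.tes["family"], bundle.tes["divergence"]
                )
            ],
        }
    )
    write_gff3(te_feats, outdir / "tes.gff3")

    def _tsv(df: pd.DataFrame, name: str, index: bool) -> None:
        df.to_csv(outdir / name, sep="\t", index=index, float_format="%.6g")

    _tsv(bundle.anchors, "anchors.tsv", index=False)
    _tsv(bundle.pairs, "pairs.tsv", index=False)
    _tsv(bundle.kaks, "kaks.tsv", index=True)
    _tsv(bundle.tpm, "tpm.tsv", index=True)
    _tsv(bundle.prog_flags, "progenitor_flags.tsv", index=True)
    _tsv(bundle.orthogroups, "orthogroups.tsv", index=False)
    write_trees_tsv(bundle.trees, outdir / "gene_trees.tsv")

    truth_obj = {
        "genes": truth.genes.reset_index().to_dict(orient="list"),
        "pairs": truth.pairs.reset_index().to_dict(orient="list"),
        "windows": truth.windows.reset_index().to_dict(orient="list"),
    }
    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_obj, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
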