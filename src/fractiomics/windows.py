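"""Syntenic-window construction, subgenome assignment and bias partitioning.

A mesopolyploid genome carries two homoeologous copies of each ancestral
region. Against a diploid reference gene order, collinearity anchors link
each reference gene to 0, 1 or 2 retained copies on two "copy tracks".
Windows of syntenic duplicates are seeded by runs of anchors with both copies
present, extended along the reference order, and then assigned to the
least-fractionated (LF) and most-fractionated (MF) subgenomes using gene-tree
sister relationships to progenitor-side taxa. A per-window chi-square test on
retained/lost counts partitions windows into low-bias and high-bias
fractionation classes.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Phylo
from scipy.stats import chi2_contingency

logger = logging.getLogger(__name__)

__all__ = [
    "SyntenicWindow",
    "SubgenomeAssignment",
    "build_windows",
    "assign_subgenomes",
    "chi2_2x2",
    "partition_bias",
    "windows_table",
]


def chi2_2x2(a: int, b: int, c: int, d: int, correction: bool = False) -> tuple[float, float]:
    """Chi-square test of independence on a 2x2 table [[a, b], [c, d]].

    Returns ``(statistic, p)``; a zero row or column margin gives (0, 1)
    (degenerate proportions carry no evidence of a difference).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("negative cell count")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 0.0, 1.0
    stat, p, _, _ = chi2_contingency(table, correction=correction)
    return float(stat), float(p)

ANCHOR_COLUMNS = ("ref_gene", "ref_chrom", "ref_index", "copy_a_gene", "copy_b_gene")


@dataclass
class SyntenicWindow:
    """A duplicated chromosomal segment along the reference gene order.

    Retention counts are kept per copy track (a/b) until subgenome assignment
    maps tracks to LF/MF; ``capacity`` is the number of reference genes
    spanned (retained + lost per track equals capacity).
    """

    window_id: str
    ref_chrom: str
    start_index: int  # ref_index of first anchor, inclusive
    end_index: int  # ref_index of last anchor, inclusive
    retained_a: int
    retained_b: int
    genes_a: list[str] = field(default_factory=list, repr=False)
    genes_b: list[str] = field(default_factory=list, repr=False)
    pair_ids: list[str] = field(default_factory=list, repr=False)
    # filled by assign_subgenomes / partition_bias
    track_lf: str | None = None  # "a" or "b"
    support: float = np.nan
    low_confidence: bool = False
    bias_class: str = "untested"
    chi2_stat: float = np.nan
    p_value: float = np.nan

    @property
    def capacity(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def lost_a(self) -> int:
        return self.capacity - self.retained_a

    @property
    def lost_b(self) -> int:
        return self.capacity - self.retained_b

    def _lf_is_a(self) -> bool:
        if self.track_lf is None:
            raise ValueError(f"window {self.window_id}: subgenomes not assigned yet")
        return self.track_lf == "a"

    @property
    def retained_lf(self) -> int:
        return self.retained_a if self._lf_is_a() else self.retained_b

    @property
    def retained_mf(self) -> int:
        return self.retained_b if self._lf_is_a() else self.retained_a

    @property
    def lost_lf(self) -> int:
        return self.capacity - self.retained_lf

    @property
    def lost_mf(self) -> int:
        return self.capacity - self.retained_mf

    @property
    def genes_lf(self) -> list[str]:
        return self.genes_a if self._lf_is_a() else self.genes_b

    @property
    def genes_mf(self) -> list[str]:
        return self.genes_b if self._lf_is_a() else self.genes_a


def _validate_anchors(anchors: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANCHOR_COLUMNS if c not in anchors.columns]
    if missing:
        raise ValueError(f"anchor table missing columns: {missing}")
    for chrom, grp in anchors.groupby("ref_chrom", sort=False):
        idx = grp["ref_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            raise ValueError(f"anchors not sorted by ref_index on {chrom!r}")
    return anchors


def build_windows(
    anchors: pd.DataFrame,
    seed_size: int = 10,
    window_ref_genes: int = 100,
    max_nonsyntenic: int = 20,
) -> list[SyntenicWindow]:
    """Scan ordered anchors and emit nonoverlapping syntenic windows.

    ``anchors`` has columns ref_gene, ref_chrom, ref_index (sorted ascending
    within each chromosome), copy_a_gene, copy_b_gene (null/NaN = copy absent).

    A window opens at a run of >= ``seed_size`` consecutive anchors with both
    copies present and extends rightward up to ``window_ref_genes`` reference
    genes. Extension stops early when either copy track accumulates a run of
    more than ``max_nonsyntenic`` consecutive anchors without that copy (a
    stretch with no syntenic support); the window is then truncated before
    the offending gap. Placement is greedy left-to-right and windows never
    overlap or cross chromosome boundaries.
    """
    _validate_anchors(anchors)
    windows: list[SyntenicWindow] = []
    wid = 0
    for chrom, grp in anchors.groupby("ref_chrom", sort=False):
        grp = grp.reset_index(drop=True)
        has_a = grp["copy_a_gene"].notna().to_numpy()
        has_b = grp["copy_b_gene"].notna().to_numpy()
        both = has_a & has_b
        n = len(grp)
        i = 0
        while i < n:
            # find the next seed: seed_size consecutive anchors with both copies
            if not both[i]:
                i += 1
                continue
            run_end = i
            while run_end < n and both[run_end]:
                run_end += 1
            if run_end - i < seed_size:
                i = run_end
                continue
            # extend from the seed start up to window_ref_genes anchors
            start = i
            end = start  # last included position
            gap_a = gap_b = 0
            for j in range(start, min(start + window_ref_genes, n)):
                gap_a = 0 if has_a[j] else gap_a + 1
                gap_b = 0 if has_b[j] else gap_b + 1
                if gap_a > max_nonsyntenic or gap_b > max_nonsyntenic:
                    break
                end = j
            # trim trailing anchors with no syntenic support at all
            while end > start and not (has_a[end] or has_b[end]):
                end -= 1
            wid += 1
            sl = slice(start, end + 1)
            genes_a = [g for g in grp["copy_a_gene"].iloc[sl] if pd.notna(g)]
            genes_b = [g for g in grp["copy_b_gene"].iloc[sl] if pd.notna(g)]
            pairs = [
                str(r.ref_gene)
                for r in grp.iloc[sl].itertuples()
                if pd.notna(r.copy_a_gene) and pd.notna(r.copy_b_gene)
            ]
            windows.append(
                SyntenicWindow(
                    window_id=f"w{wid:04d}",
                    ref_chrom=str(chrom),
                    start_index=int(grp["ref_index"].iloc[start]),
                    end_index=int(grp["ref_index"].iloc[end]),
                    retained_a=len(genes_a),
                    retained_b=len(genes_b),
                    genes_a=genes_a,
                    genes_b=genes_b,
                    pair_ids=pairs,
                )
            )
            i = end + 1
    return windows


@dataclass
class SubgenomeAssignment:
    """Per-window mapping of copy tracks to the LF/MF subgenomes."""

    track_lf: dict[str, str]  # window_id -> "a" | "b"
    support: dict[str, float]  # fraction of concordant trees per window
    low_confidence: set[str]
    unassigned: set[str]
    n_trees_used: int
    n_trees_skipped: int


def _sister_anchor(tree, copy_label: str, anchor_taxa: tuple[str, str]) -> str | None:
    """Which anchor taxon is the immediate sister of ``copy_label`` in the tree."""
    terminals = {t.name for t in tree.get_terminals()}
    if copy_label not in terminals:
        return None
    clade = next(t for t in tree.get_terminals() if t.name == copy_label)
    path = tree.get_path(clade)
    # walk outward from the tip until a clade containing an anchor taxon appears
    for node in reversed([tree.root] + path[:-1]):
        names = {t.name for t in node.get_terminals()}
        anchors_here = [a for a in anchor_taxa if a in names]
        if anchors_here:
            if len(anchors_here) == 1 and len(names) <= 3:
                return anchors_here[0]
            return None  # both anchors join at once: uninformative
    return None


def assign_subgenomes(
    windows: list[SyntenicWindow],
    trees: dict[str, str],
    pair_copies: dict[str, tuple[str, str]],
    pair_window: dict[str, str],
    anchor_taxa: tuple[str, str] = ("progenitor_1", "progenitor_2"),
    support_threshold: float = 0.6,
) -> SubgenomeAssignment:
    """Assign copy tracks to LF/MF subgenomes from gene-tree sister signals.

    ``trees`` maps pair_id to a Newick string containing both copy gene
    labels and progenitor-side anchor taxa; ``pair_copies`` maps pair_id to
    (copy_a_gene, copy_b_gene); ``pair_window`` maps pair_id to window_id.

    Per window, each usable tree votes on the orientation: a tree in which
    copy a is sister to ``anchor_taxa[0]`` (and/or copy b to
    ``anchor_taxa[1]``) supports one orientation, the reverse tree the other.
    The majority orientation wins; support is the winning vote fraction.
    Ties break deterministically (track a to the first anchor's side) and are
    flagged low-confidence, as are windows below ``support_threshold``.
    Genome-wide, the side with more retained genes is labelled LF. Trees
    missing a copy label are skipped with a logged warning; windows with no
    usable tree are left unassigned.
    """
    votes: dict[str, list[int]] = {w.window_id: [0, 0] for w in windows}
    n_used = n_skipped = 0
    for pair_id, nwk in trees.items():
        if pair_id not in pair_copies or pair_id not in pair_window:
            n_skipped += 1
            continue
        copy_a, copy_b = pair_copies[pair_id]
        wid = pair_window[pair_id]
        if wid not in votes:
            n_skipped += 1
            continue
        try:
            tree = Phylo.read(_io.StringIO(nwk), "newick")
        except Exception:
            logger.warning("unparseable tree for pair %s; skipped", pair_id)
            n_skipped += 1
            continue
        terminals = {t.name for t in tree.get_terminals()}
        if copy_a not in terminals or copy_b not in terminals:
            logger.warning("tree for pair %s missing a copy label; skipped", pair_id)
            n_skipped += 1
            continue
        vote = 0
        sa = _sister_anchor(tree, copy_a, anchor_taxa)
        sb = _sister_anchor(tree, copy_b, anchor_taxa)
        if sa == anchor_taxa[0] or sb == anchor_taxa[1]:
            vote += 1
        if sa == anchor_taxa[1] or sb == anchor_taxa[0]:
            vote -= 1
        if vote == 0:
            n_skipped += 1
            continue
        votes[wid][0 if vote > 0 else 1] += 1
        n_used += 1

    # orientation "side" per track: side 0 = anchor_taxa[0] lineage
    track_side: dict[str, str | None] = {}
    support: dict[str, float] = {}
    low_conf: set[str] = set()
    unassigned: set[str] = set()
    for w in windows:
        fwd, rev = votes[w.window_id]
        total = fwd + rev
        if total == 0:
            track_side[w.window_id] = None
            unassigned.add(w.window_id)
            continue
        if fwd == rev:
            # deterministic tie-break: copy track a joins the first anchor's side
            track_side[w.window_id] = "a"
            support[w.window_id] = 0.5
            low_conf.add(w.window_id)
            continue
        track_side[w.window_id] = "a" if fwd > rev else "b"
        s = max(fwd, rev) / total
        support[w.window_id] = s
        if s < support_threshold:
            low_conf.add(w.window_id)

    # label the side with more retained genes genome-wide as LF
    side0_retained = side1_retained = 0
    for w in windows:
        side_a = track_side.get(w.window_id)
        if side_a is None:
            continue
        if side_a == "a":
            side0_retained += w.retained_a
            side1_retained += w.retained_b
        else:
            side0_retained += w.retained_b
            side1_retained += w.retained_a
    lf_side_is_0 = side0_retained >= side1_retained

    track_lf: dict[str, str] = {}
    for w in windows:
        side_a = track_side.get(w.window_id)
        if side_a is None:
            continue
        a_on_side0 = side_a == "a"
        track_lf[w.window_id] = ("a" if a_on_side0 else "b") if lf_side_is_0 else ("b" if a_on_side0 else "a")
        w.track_lf = track_lf[w.window_id]
        w.support = support[w.window_id]
        w.low_confidence = w.window_id in low_conf
    return SubgenomeAssignment(
        track_lf=track_lf,
        support=support,
        low_confidence=low_conf,
        unassigned=unassigned,
        n_trees_used=n_used,
        n_trees_skipped=n_skipped,
    )


def partition_bias(
    windows: list[SyntenicWindow],
    alpha: float = 0.05,
    continuity_correction: bool = False,
    bh_adjust_pvalues: bool = False,
) -> list[SyntenicWindow]:
    """Partition windows into low-bias / high-bias fractionation classes.

    Per window, a 2x2 chi-square test (no continuity correction by default)
    on (retained, lost) x (LF, MF). p > alpha -> low-bias; p <= alpha with a
    retention deficit on MF -> high-bias; p <= alpha with the deficit on LF
    -> inverse-bias (reported separately). Windows with zero capacity or an
    all-zero margin are untested. Requires subgenome assignment first.
    Optionally BH-adjusts the p-values across windows before thresholding.
    """
    testable = []
    for w in windows:
        if w.track_lf is None or w.capacity == 0:
            w.bias_class = "untested"
            continue
        w.chi2_stat, w.p_value = chi2_2x2(
            w.retained_lf, w.lost_lf, w.retained_mf, w.lost_mf,
            correction=continuity_correction,
        )
        testable.append(w)
    pvals = np.array([w.p_value for w in testable])
    if bh_adjust_pvalues and len(testable):
        from .stats import bh_adjust

        pvals = bh_adjust(pvals)
    for w, p in zip(testable, pvals):
        if p > alpha:
            w.bias_class = "low-bias"
        else:
            prop_lf = w.retained_lf / w.capacity
            prop_mf = w.retained_mf / w.capacity
            w.bias_class = "high-bias" if prop_mf < prop_lf else "inverse-bias"
    return windows


def windows_table(windows: list[SyntenicWindow]) -> pd.DataFrame:
    """Tabulate windows (one row each) for reporting and TSV output."""
    rows = []
    for w in windows:
        assigned = w.track_lf is not None
        rows.append(
            {
                "window_id": w.window_id,
                "ref_chrom": w.ref_chrom,
                "start_index": w.start_index,
                "end_index": w.end_index,
                "capacity": w.capacity,
                "retained_a": w.retained_a,
                "retained_b": w.retained_b,
                "track_lf": w.track_lf if assigned else "",
                "retained_lf": w.retained_lf if assigned else np.nan,
                "retained_mf": w.retained_mf if assigned else np.nan,
                "support": w.support,
                "low_confidence": w.low_confidence,
                "bias_class": w.bias_class,
                "chi2_stat": w.chi2_stat,
                "p_value": w.p_value,
            }
        )
    return pd.DataFrame(rows)
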