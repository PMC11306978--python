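"""Fate classification of retained duplicate pairs against progenitor singletons.

After a WGD, each retained pair of duplicates can be read against the
single-copy ortholog of a diploid relative (the "progenitor singleton") that
stands in for the pre-duplication state. Comparing the selection signal on
both copies and the sets of environmental conditions (cold, heat, drought,
herbivory) that trigger differential expression in each copy versus the
progenitor yields a small taxonomy of duplicate fates: retention under dosage
balance (no trigger anywhere, or both copies keeping the ancestral triggers),
loss of responsiveness, single-copy conservation of the trigger with the
other copy turned constitutive ("turn a hobby into a job"), trigger gain, and
the rare neutral or neofunctionalization cases.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "FATE_CATEGORIES",
    "FateRecord",
    "ProgenitorSummary",
    "classify_pair_fate",
    "summarize_fates",
    "summarize_progenitor_outcomes",
]

FATE_CATEGORIES = (
    "neutral_divergence",
    "neofunctionalization_candidate",
    "dosage_conserved_no_trigger",
    "dosage_conserved_same_trigger",
    "trigger_lost_both",
    "trigger_conserved_lf_other_constitutive",
    "trigger_conserved_mf_other_constitutive",
    "trigger_gain",
    "other_change",
)

#: categories counted as retention under dosage-balance constraint
DOSAGE_CATEGORIES = ("dosage_conserved_no_trigger", "dosage_conserved_same_trigger")


@dataclass
class FateRecord:
    """One expressed duplicate pair with its classification inputs and fate."""

    pair_id: str
    lf_gene: str
    mf_gene: str
    selection_lf: str
    selection_mf: str
    triggers_lf: frozenset[str]
    triggers_mf: frozenset[str]
    triggers_prog: frozenset[str]
    expressed_pair: bool = True
    category: str | None = field(default=None)

    def classify(self) -> str:
        self.category = classify_pair_fate(
            self.selection_lf,
            self.selection_mf,
            self.triggers_lf,
            self.triggers_mf,
            self.triggers_prog,
            expressed_lf=self.expressed_pair,
            expressed_mf=self.expressed_pair,
        )
        return self.category


def classify_pair_fate(
    selection_lf: str,
    selection_mf: str,
    triggers_lf: frozenset[str] | set[str],
    triggers_mf: frozenset[str] | set[str],
    triggers_prog: frozenset[str] | set[str],
    expressed_lf: bool = True,
    expressed_mf: bool = True,
    relaxed_same_trigger: bool = False,
) -> str:
    """Classify one expressed duplicate pair into a fate category.

    The decision cascade, evaluated in order:

    1. any member neutral -> ``neutral_divergence``
    2. exactly one member positive, the other purifying ->
       ``neofunctionalization_candidate``
    3. both purifying:
       a. progenitor and both members triggerless -> ``dosage_conserved_no_trigger``
       b. both members' triggers equal the (nonempty) progenitor's ->
          ``dosage_conserved_same_trigger``
       c. progenitor responsive, both members triggerless -> ``trigger_lost_both``
       d. one member's triggers equal the progenitor's, the other triggerless ->
          ``trigger_conserved_{lf|mf}_other_constitutive``
       e. any member carries a trigger absent from the progenitor -> ``trigger_gain``
       f. anything else -> ``other_change``

    A pair with both a lost ancestral trigger and a gained novel one is
    ``trigger_gain`` (rule e precedes f). ``relaxed_same_trigger`` accepts
    nonempty intersection with the progenitor instead of set equality in
    rule b/d. Unexpressed members are a caller error: filter first.
    """
    if not (expressed_lf and expressed_mf):
        raise ValueError("fate is defined only for pairs with both members expressed")
    t_lf, t_mf, t_prog = frozenset(triggers_lf), frozenset(triggers_mf), frozenset(triggers_prog)

    if "neutral" in (selection_lf, selection_mf):
        return "neutral_divergence"
    sel = {selection_lf, selection_mf}
    if sel == {"positive", "purifying"}:
        return "neofunctionalization_candidate"
    if sel != {"purifying"}:
        return "other_change"  # e.g. both positive, or undefined omega

    def matches_prog(t: frozenset[str]) -> bool:
        if relaxed_same_trigger:
            return bool(t & t_prog)
        return t == t_prog

    if not t_prog and not t_lf and not t_mf:
        return "dosage_conserved_no_trigger"
    if t_prog and matches_prog(t_lf) and matches_prog(t_mf):
        return "dosage_conserved_same_trigger"
    if t_prog and not t_lf and not t_mf:
        return "trigger_lost_both"
    if t_prog and matches_prog(t_lf) and not t_mf:
        return "trigger_conserved_lf_other_constitutive"
    if t_prog and matches_prog(t_mf) and not t_lf:
        return "trigger_conserved_mf_other_constitutive"
    if (t_lf - t_prog) or (t_mf - t_prog):
        return "trigger_gain"
    return "other_change"


def summarize_fates(records: list[FateRecord] | pd.DataFrame) -> dict:
    """Counts, per-category proportions and aggregate fate shares.

    Returns a dict with ``n_pairs``, ``counts`` and ``proportions`` (over the
    explicit category partition; proportions sum to 1), plus the headline
    aggregate shares in percent:

    - ``dosage_balance_share_pct``: pairs retained with conserved function
      under dosage balance (no trigger anywhere, or same triggers as the
      progenitor);
    - ``trigger_change_share_pct``: its complement, pairs whose environmental
      response changed (this is the convention under which the two headline
      shares sum to 100);
    - ``neutral_share_pct`` and ``neofunctionalization_share_pct``.
    """
    if isinstance(records, pd.DataFrame):
        cats = list(records["category"])
    else:
        cats = [r.category if r.category is not None else r.classify() for r in records]
    if not cats:
        raise ValueError("no fate records to summarise")
    unknown = set(cats) - set(FATE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown fate categories: {sorted(unknown)}")
    n = len(cats)
    counts = Counter(cats)
    full_counts = {c: counts.get(c, 0) for c in FATE_CATEGORIES}
    dosage = sum(full_counts[c] for c in DOSAGE_CATEGORIES)
    return {
        "n_pairs": n,
        "counts": full_counts,
        "proportions": {c: full_counts[c] / n for c in FATE_CATEGORIES},
        "dosage_balance_share_pct": 100 * dosage / n,
        "trigger_change_share_pct": 100 * (n - dosage) / n,
        "neutral_share_pct": 100 * full_counts["neutral_divergence"] / n,
        "neofunctionalization_share_pct": 100 * full_counts["neofunctionalization_candidate"] / n,
    }


@dataclass
class ProgenitorSummary:
    """Outcomes of ancestrally environment-responsive progenitor orthologs."""

    counts: dict[str, int]
    n_input: int

    OUTCOMES = (
        "singleton_constitutive",
        "singleton_responsive",
        "duplicate_constitutive",
        "duplicate_one_responsive_one_constitutive",
        "duplicate_both_responsive",
        "lost",
        "unmapped",
    )

    def percentages(self) -> dict[str, float]:
        return {k: round(100 * v / self.n_input, 1) for k, v in self.counts.items()}


def summarize_progenitor_outcomes(
    prog_de_ids: list[str] | set[str],
    gene_table: pd.DataFrame,
    fate_records: list[FateRecord] | None = None,
) -> ProgenitorSummary:
    """Partition environment-responsive progenitor orthologs by their outcome.

    ``prog_de_ids`` are progenitor (reference-species) gene ids flagged DE in
    the progenitor. ``gene_table`` maps each progenitor id to its outcome in
    the polyploid, one row per progenitor id with columns:

    - ``status``: {"duplicate", "singleton", "lost"}
    - ``responsive_lf``, ``responsive_mf``: bool, whether the retained LF/MF
      copy is DE under any treatment (for singletons only one is meaningful;
      a singleton is responsive when either flag is set).

    Progenitor ids missing from the table are counted in an explicit
    ``unmapped`` bucket, never dropped. Outcomes partition the input set.
    """
    ids = sorted(set(prog_de_ids))
    if not ids:
        raise ValueError("empty progenitor DE set")
    table = gene_table
    if table.index.has_duplicates:
        raise ValueError("gene_table index (progenitor ids) contains duplicates")
    counts = {k: 0 for k in ProgenitorSummary.OUTCOMES}
    for pid in ids:
        if pid not in table.index:
            counts["unmapped"] += 1
            continue
        row = table.loc[pid]
        status = row["status"]
        resp_lf = bool(row.get("responsive_lf", False))
        resp_mf = bool(row.get("responsive_mf", False))
        if status == "lost":
            counts["lost"] += 1
        elif status == "singleton":
            if resp_lf or resp_mf:
                counts["singleton_responsive"] += 1
            else:
                counts["singleton_constitutive"] += 1
        elif status == "duplicate":
            n_resp = int(resp_lf) + int(resp_mf)
            if n_resp == 2:
                counts["duplicate_both_responsive"] += 1
            elif n_resp == 1:
                counts["duplicate_one_responsive_one_constitutive"] += 1
            else:
                counts["duplicate_constitutive"] += 1
        else:
            raise ValueError(f"unknown retention status {status!r} for {pid!r}")
    _ = fate_records  # accepted for API symmetry; outcomes come from the table
    return ProgenitorSummary(counts=counts, n_input=len(ids))
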