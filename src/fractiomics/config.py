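"""Configuration for the synthetic mesopolyploid genome generator.

Defaults mirror the magnitudes of a fractionating Brassicaceae mesopolyploid:
122 syntenic windows of 100 reference genes, ~0.57 vs ~0.43 gene retention on
the least- vs most-fractionated subgenome, a bimodal paralog Ks distribution
with modes 0.34 (sd 0.15) and 0.96 (sd 0.42), TE-proximity expression
suppression of 1.83 log2 units, and treatment panels of cold, heat, drought
and herbivory with replicated controls. All of it is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

__all__ = ["SimulationConfig", "ConfigError"]


class ConfigError(ValueError):
    """An invalid configuration field (the message names it)."""


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"invalid config field {name!r}: {msg}")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic dataset, with genome-realistic defaults."""

    # genome layout
    n_windows: int = 122
    genes_per_window_ref: int = 100
    n_ref_chroms: int = 9
    spacer_genes: int = 30  # nonsyntenic reference genes between windows
    gene_length: int = 2_000  # bp
    gene_spacing: int = 20_000  # bp between gene starts

    # fractionation
    retention_prob_lf: float = 0.57
    retention_prob_mf: float = 0.43
    frac_low_bias_windows: float = 36 / 122
    seed_run_length: int = 12  # intact both-retained run opening each window

    # transposable elements
    te_density_lf: float = 150_000.0  # expected TE bp per Mb
    te_density_mf: float = 250_000.0
    te_expr_log2_reduction: float = 1.83  # suppression for genes with a TE <= 2000 bp
    te_bin_probs: tuple[float, float, float, float] = (0.05, 0.15, 0.30, 0.50)
    te_mean_length: int = 500  # bp
    te_divergence_modes: tuple[tuple[float, float, float], ...] = (
        (0.06, 0.01, 0.5),
        (0.10, 0.01, 0.5),
    )
    te_families: tuple[tuple[str, float], ...] = (
        ("LTR/Copia", 0.30),
        ("LTR/Gypsy", 0.30),
        ("DTA", 0.10),
        ("DTM", 0.10),
        ("DTH", 0.10),
        ("LINE", 0.10),
    )

    # substitution rates
    ks_components: tuple[tuple[float, float, float], ...] = (
        (0.34, 0.15, 0.5),
        (0.96, 0.42, 0.5),
    )
    ref_ks_mean: float = 0.50  # per-gene Ks vs the reference ortholog
    ref_ks_sd: float = 0.10
    selection_class_probs: tuple[float, float, float] = (0.9965, 0.002, 0.0015)
    kaks_by_class: tuple[tuple[str, float, float], ...] = (
        ("purifying", 0.02, 0.787),
        ("neutral", 0.7875, 1.213),
        ("positive", 1.2135, 2.0),
    )
    # linear coupling of purifying-class omega to baseline log2 expression:
    # highly expressed genes sit under stronger purifying selection
    omega_expression_slope: float = -0.10
    omega_expression_intercept: float = 0.45
    omega_noise_sd: float = 0.08

    # expression
    treatments: tuple[str, ...] = ("cold", "heat", "drought", "herbivory")
    n_replicates: int = 3
    expr_log2_mean: float = 3.0
    expr_log2_sd: float = 2.0
    silent_fraction: float = 0.10
    silent_log2_mean: float = -3.0
    replicate_noise_sd: float = 0.15
    de_effect_log2: float = 2.0

    # progenitor triggers and their evolution per copy
    prog_de_rate: float = 0.20
    trigger_transition_probs: tuple[float, float, float] = (0.20, 0.70, 0.10)
    background_gain_prob: float = 0.10
    enriched_trigger: str = "cold"
    enriched_trigger_boost: float = 0.60  # prob a gain in a high-bias window picks it

    # gene trees
    tree_flip_prob: float = 0.10

    # fraction of conserved orthogroups present anywhere in the assembly
    og_presence_rate: float = 0.938

    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_windows >= 1, "n_windows", "must be >= 1")
        _check(self.genes_per_window_ref >= 1, "genes_per_window_ref", "must be >= 1")
        _check(self.n_ref_chroms >= 1, "n_ref_chroms", "must be >= 1")
        _check(self.spacer_genes >= 0, "spacer_genes", "must be >= 0")
        _check(self.gene_length > 0, "gene_length", "must be positive")
        _check(
            self.gene_spacing > self.gene_length,
            "gene_spacing",
            "must exceed gene_length",
        )
        for name in (
            "retention_prob_lf",
            "retention_prob_mf",
            "frac_low_bias_windows",
            "silent_fraction",
            "prog_de_rate",
            "background_gain_prob",
            "enriched_trigger_boost",
            "tree_flip_prob",
            "og_presence_rate",
        ):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, name, f"probability must lie in [0, 1], got {v}")
        _check(
            self.retention_prob_lf >= self.retention_prob_mf,
            "retention_prob_mf",
            "must not exceed retention_prob_lf",
        )
        _check(
            0 <= self.seed_run_length <= self.genes_per_window_ref,
            "seed_run_length",
            "must lie in [0, genes_per_window_ref]",
        )
        _check(self.te_density_lf >= 0, "te_density_lf", "must be nonnegative")
        _check(self.te_density_mf >= 0, "te_density_mf", "must be nonnegative")
        _check(self.te_mean_length > 0, "te_mean_length", "must be positive")
        _check(
            len(self.te_bin_probs) == 4
            and all(0 <= p <= 1 for p in self.te_bin_probs)
            and abs(sum(self.te_bin_probs) - 1) < 1e-9,
            "te_bin_probs",
            "must be 4 probabilities summing to 1",
        )
        for comps, name in (
            (self.ks_components, "ks_components"),
            (self.te_divergence_modes, "te_divergence_modes"),
        ):
            _check(len(comps) >= 1, name, "needs at least one component")
            _check(
                abs(sum(c[2] for c in comps) - 1) < 1e-9,
                name,
                "component weights must sum to 1",
            )
            _check(all(c[1] > 0 for c in comps), name, "component sd must be positive")
        _check(
            abs(sum(self.selection_class_probs) - 1) < 1e-9
            and all(0 <= p <= 1 for p in self.selection_class_probs),
            "selection_class_probs",
            "must be 3 probabilities summing to 1",
        )
        _check(
            [c[0] for c in self.kaks_by_class] == ["purifying", "neutral", "positive"]
            and all(0 <= lo < hi for _, lo, hi in self.kaks_by_class),
            "kaks_by_class",
            "must give (low, high) omega ranges for purifying/neutral/positive",
        )
        _check(self.omega_noise_sd >= 0, "omega_noise_sd", "must be nonnegative")
        _check(len(self.treatments) >= 1, "treatments", "needs at least one treatment")
        _check("control" not in self.treatments, "treatments", "'control' is implicit")
        _check(self.n_replicates >= 2, "n_replicates", "must be >= 2")
        _check(self.replicate_noise_sd >= 0, "replicate_noise_sd", "must be nonnegative")
        _check(
            abs(sum(self.trigger_transition_probs) - 1) < 1e-9
            and all(0 <= p <= 1 for p in self.trigger_transition_probs),
            "trigger_transition_probs",
            "must be (conserve, lose, gain) probabilities summing to 1",
        )
        _check(
            self.enriched_trigger in self.treatments,
            "enriched_trigger",
            "must be one of the treatments",
        )
        fam_w = sum(w for _, w in self.te_families)
        _check(fam_w > 0, "te_families", "weights must have positive sum")

    def replace(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return SimulationConfig(**current)
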