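"""Configuration and planted ground truth for the synthetic dataset
generator."""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


DEFAULT_CISLOGIC_MIX = {
    "sync": 0.25,
    "repression": 0.15,
    "enh_switch": 0.15,
    "early_open": 0.15,
    "null": 0.30,
}


@dataclass
class SyntheticConfig:
    """Shapes and rates of the planted dataset.

    Defaults emulate the study conditions: 10 embryonic stages profiled by
    RNA (the first 9 also by ATAC), 30 expression archetypes, roughly a
    third of genes multi-isoform with 35% of those switching their
    predominant isoform, a 51% vs 18% conserved-element foreground/
    background split, and a single planted pioneer TF.
    """

    n_genes: int = 600
    n_stages: int = 10
    n_clusters: int = 30
    isoform_rate: float = 0.3
    switch_rate: float = 0.35
    cislogic_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CISLOGIC_MIX)
    )
    noise_sd: float = 0.1
    conserved_fraction_fg: float = 0.51
    conserved_fraction_bg: float = 0.18
    n_motifs: int = 6
    pioneer_ids: tuple[str, ...] = ("M0",)
    seed: int = 0

    # secondary knobs (fixed study-condition choices, see docs/methods.md)
    zscale: float = 1.0  # z -> log-TPM scale factor
    early_shift: int = 2  # stages an early-opening element leads its gene
    motif_length: int = 12
    cut_baseline: float = 5.0  # Tn5 cuts per base inside elements
    pioneer_flank_boost: float = 16.0
    pioneer_core_factor: float = 0.15
    pioneer_acc_boost: float = 20.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.n_stages < 3:
            raise ConfigError("n_stages must be >= 3")
        if not 2 <= self.n_clusters < 10 * self.n_stages:
            raise ConfigError("n_clusters out of range")
        for name in ("isoform_rate", "switch_rate", "noise_sd",
                     "conserved_fraction_fg", "conserved_fraction_bg"):
            v = getattr(self, name)
            if name == "noise_sd":
                if v < 0:
                    raise ConfigError("noise_sd must be non-negative")
                continue
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0,1]")
        mix_keys = set(DEFAULT_CISLOGIC_MIX)
        if set(self.cislogic_mix) - mix_keys:
            raise ConfigError(
                f"cislogic_mix has unknown keys {sorted(set(self.cislogic_mix) - mix_keys)}"
            )
        if any(v < 0 for v in self.cislogic_mix.values()):
            raise ConfigError("cislogic_mix fractions must be non-negative")
        if sum(self.cislogic_mix.values()) > 1.0 + 1e-9:
            raise ConfigError("cislogic_mix must sum to <= 1")
        if self.n_motifs < 1:
            raise ConfigError("n_motifs must be positive")
        if self.n_motifs < len(self.pioneer_ids):
            raise ConfigError("pioneer_ids exceed n_motifs")
        if self.early_shift < 2:
            raise ConfigError("early_shift must be >= 2 stages")

    @property
    def rna_stages(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_stages)]

    @property
    def atac_stages(self) -> list[str]:
        # one fewer stage profiled by ATAC than by RNA, as in the study design
        return self.rna_stages[:-1]

    @property
    def stage_map(self) -> dict[str, str]:
        """Injective map from ATAC stage labels into RNA stage labels."""
        return {s: s for s in self.atac_stages}


GENE_TYPES = ("sync", "repression", "enh_switch", "early_open", "null")


@dataclass
class TruthLabels:
    """Planted ground truth; the oracle for every downstream stage.

    ``gene_cluster`` is -1 for genes whose expression profile is not one of
    the archetypes (enhancer-switching and early-opening genes have bespoke
    bimodal / ramp profiles).
    """

    gene_cluster: dict[str, int] = field(default_factory=dict)
    gene_type: dict[str, str] = field(default_factory=dict)
    multi_isoform_genes: list[str] = field(default_factory=list)
    gene_switch: dict[str, bool] = field(default_factory=dict)
    switch_detail: dict[str, dict] = field(default_factory=dict)
    element_type: dict[str, str] = field(default_factory=dict)
    element_gene: dict[str, str] = field(default_factory=dict)
    element_conserved: dict[str, bool] = field(default_factory=dict)
    enh_switch_pairs: dict[str, list[str]] = field(default_factory=dict)
    early_shift: int = 2
    motif_pioneer: dict[str, bool] = field(default_factory=dict)
    pioneer_stage: dict[str, str] = field(default_factory=dict)
    motif_tf: dict[str, str] = field(default_factory=dict)
    cluster_peak_stage: dict[str, int] = field(default_factory=dict)
    motif_elements: dict[str, list[str]] = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "TruthLabels":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)
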