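"""Core domain types shared across the pipeline.

Expression data travels as a plain pandas DataFrame (genes x samples,
log2 scale) and sample metadata as a DataFrame with one row per sample;
the light dataclasses below carry everything that is not naturally
tabular: configuration, contrast definitions, gene-set collections,
annotation maps, module partitions and planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

GROUPS = ("AC", "BET", "BER")
STIMULATIONS = ("EW", "M")
GENDERS = ("F", "M")

#: metadata columns every sample table must provide
SAMPLE_COLUMNS = ("sample_id", "subject_id", "group", "stimulation", "gender", "batch")


class ConfigError(ValueError):
    """Invalid simulation or pipeline configuration."""


def _default_group_sizes() -> dict:
    # cohort structure: 34 baked-egg-reactive, 20 baked-egg-tolerant,
    # 14 atopic egg-tolerant controls
    return {"AC": 14, "BET": 20, "BER": 34}


def _default_cytokine_effects() -> dict:
    # log10 pg/ml EW-vs-media shifts by clinical group; magnitudes mirror a
    # Th2-skewed allergic response (IL-9/TNFa strongest in reactive subjects)
    return {
        "IL-9": {"BER": 2.0, "BET": 1.9},
        "TNFa": {"BER": 1.8, "BET": 1.5},
        "IL-5": {"BER": 2.0, "BET": 1.8},
        "GM-CSF": {"BER": 1.2, "BET": 1.0},
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study generator.

    Defaults emulate the study design: three clinical groups with paired
    egg-white (EW) and media (M) cultures per subject, five array batches,
    planted stimulation-response genes in the allergic groups, three
    latent-factor co-expression modules, a gene-set collection with one
    category enriched for the planted response, and floor-censored
    cytokine panels.
    """

    n_subjects_per_group: Mapping[str, int] = field(default_factory=_default_group_sizes)
    n_genes: int = 2000
    n_de_genes: int = 100
    de_log2fc: float = 1.0
    de_groups: Sequence[str] = ("BER", "BET")
    n_modules: int = 3
    module_sizes: Sequence[int] = (100, 100, 100)
    module_cor: float = 0.8
    noise_sd: float = 0.5
    n_signatures: int = 200
    n_categories: int = 20
    n_planted_signatures: int = 10
    planted_overlap: float = 0.5
    signature_size: int = 40
    planted_category: str = "CAT00"
    cytokine_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_cytokine_effects
    )
    null_cytokines: Sequence[str] = ("IFNg", "IL-6", "IL-10", "IL-17A", "IL-27")
    cytokine_noise_sd: float = 0.5
    detection_floor: float = 0.5
    gender_effect: float = 0.1
    batch_effect: float = 0.05
    n_batches: int = 5
    subject_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_modules", "n_signatures",
                     "n_categories", "signature_size", "n_batches"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("n_de_genes", "n_planted_signatures"):  # 0 = null case
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.n_subjects_per_group:
            raise ConfigError("n_subjects_per_group must be non-empty")
        for g, n in self.n_subjects_per_group.items():
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r}")
            if n < 1:
                raise ConfigError(f"group {g} needs >= 1 subject")
        if len(self.module_sizes) != self.n_modules:
            raise ConfigError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) + self.n_de_genes > self.n_genes:
            raise ConfigError("module sizes plus DE genes exceed n_genes")
        if not 0.0 < self.module_cor < 1.0:
            raise ConfigError("module_cor must lie in (0, 1)")
        if not 0.0 < self.planted_overlap <= 1.0:
            raise ConfigError("planted_overlap must lie in (0, 1]")
        if self.n_planted_signatures > 0:
            n_overlap = int(round(self.planted_overlap * self.signature_size))
            if n_overlap > self.n_de_genes:
                raise ConfigError(
                    f"planted overlap of {n_overlap} genes exceeds the "
                    f"{self.n_de_genes} planted DE genes"
                )
        for g in self.de_groups:
            if g not in GROUPS:
                raise ConfigError(f"unknown DE group {g!r}")


@dataclass
class GroundTruth:
    """What the generator planted, keyed so tests can score recovery."""

    gene_ids: Sequence[str]
    de_gene_ids: Mapping[str, Sequence[str]]  # contrast_id -> planted genes
    module_assignment: pd.Series  # gene_id -> module label (0 = none)
    module_latents: Optional[pd.DataFrame] = None  # module x sample factors
    enriched_signature_ids: Sequence[str] = ()
    enriched_category_id: str = ""
    cytokine_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class ContrastSpec:
    """One differential-expression comparison.

    family:
      * ``between_group_within_condition`` -- group_a vs group_b using only
        samples of ``condition``;
      * ``within_group_EW_vs_M`` -- per-subject EW-M response inside
        ``group_a``;
      * ``difference_of_differences`` -- EW-M response of group_a vs that
        of group_b (the interaction contrast).
    """

    family: str
    group_a: str
    group_b: Optional[str] = None
    condition: Optional[str] = None

    FAMILIES = (
        "between_group_within_condition",
        "within_group_EW_vs_M",
        "difference_of_differences",
    )

    def __post_init__(self) -> None:
        if self.family not in self.FAMILIES:
            raise ConfigError(f"unknown contrast family {self.family!r}")
        if self.family == "between_group_within_condition":
            if self.group_b is None or self.condition is None:
                raise ConfigError("family 1 needs group_b and condition")
        elif self.family == "difference_of_differences":
            if self.group_b is None:
                raise ConfigError("family 3 needs group_b")
        if self.group_b is not None and self.group_a == self.group_b:
            raise ConfigError("contrast groups must be distinct")

    @property
    def contrast_id(self) -> str:
        if self.family == "between_group_within_condition":
            return f"{self.group_a}_vs_{self.group_b}@{self.condition}"
        if self.family == "within_group_EW_vs_M":
            return f"EWvsM@{self.group_a}"
        return f"{self.group_a}_vs_{self.group_b}@EWvsM"


@dataclass
class DEGSignature:
    """Direction-tagged, size-standardized differential-expression gene list."""

    contrast_id: str
    direction: str  # "up" | "down"
    gene_ids: list

    @property
    def signature_id(self) -> str:
        return f"{self.contrast_id}:{self.direction}"


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) over a common identifier space."""

    name: str
    sets: dict  # set_name -> list of unique gene ids
    source: str = ""

    def __post_init__(self) -> None:
        for set_name, members in self.sets.items():
            if not members:
                raise ConfigError(f"gene set {set_name!r} is empty")
            if len(set(members)) != len(members):
                self.sets[set_name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, names) -> "GeneSetCollection":
        keep = {n: list(self.sets[n]) for n in names if n in self.sets}
        return GeneSetCollection(name=self.name, sets=keep, source=self.source)


@dataclass
class AnnotationMap:
    """signature -> category assignment at one annotation level."""

    level: int
    assignments: dict  # signature_name -> category_name

    def categories(self) -> dict:
        out: dict = {}
        for sig, cat in self.assignments.items():
            out.setdefault(cat, []).append(sig)
        return out

    def category_sizes(self) -> dict:
        return {cat: len(sigs) for cat, sigs in self.categories().items()}


@dataclass
class ModulePartition:
    """gene -> numeric module label; 0 means unassigned.

    Labels are assigned in order of module size (1 = largest), matching
    the convention of naming co-expression modules numerically by size.
    """

    assignment: pd.Series

    def module_labels(self) -> list:
        labels = sorted(set(self.assignment.values) - {0})
        return labels

    def sizes(self) -> dict:
        vc = self.assignment[self.assignment != 0].value_counts()
        return {int(k): int(v) for k, v in vc.items()}

    def genes_in(self, label: int) -> list:
        return list(self.assignment.index[self.assignment == label])


@dataclass
class RobustFitResult:
    """Per-cytokine robust regression of transformed EW-M deltas on group."""

    cytokine: str
    coefficients: pd.DataFrame  # index: group level; columns coef, se, p_value
    converged: bool
    n_obs: int
    scale: float
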