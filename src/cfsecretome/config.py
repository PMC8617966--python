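"""Simulation configuration for the synthetic secretome/transcriptome study.

The defaults encode the emulated study design: 4 patients, three conditions
(control, TNFA = TNF-alpha stimulation, TGFB = TGF-beta stimulation) in a
fully paired layout, with a planted cytokine response to TNF-alpha
(log2FC = 1.5) and a planted collagen response to TGF-beta (log2FC = 1.0).
Random-effect and residual standard deviations are on the log2 scale and
apply to both the protein and the transcript layer (MS intensities convert
internally to log10).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

CONTROL = "control"
TNFA = "TNFA"
TGFB = "TGFB"
DEFAULT_CONDITIONS = (CONTROL, TNFA, TGFB)

# protein/gene categories planted by the generator
ECM_SCAFFOLD = "ecm_scaffold"
COLLAGEN = "collagen"
CYTOKINE = "cytokine"
MMP_TIMP = "mmp_timp"
OTHER_SECRETED = "other_secreted"
MEMBRANE = "membrane"
ER = "er"
INTRACELLULAR = "intracellular"

CATEGORIES = (
    ECM_SCAFFOLD,
    COLLAGEN,
    CYTOKINE,
    MMP_TIMP,
    OTHER_SECRETED,
    MEMBRANE,
    ER,
    INTRACELLULAR,
)
SECRETED_CATEGORIES = (ECM_SCAFFOLD, COLLAGEN, CYTOKINE, MMP_TIMP, OTHER_SECRETED)

HOUSEKEEPING_GENE = "CDKN1B"


@dataclass(frozen=True)
class DropoutConfig:
    """Abundance-dependent MS detection model.

    Detection probability is logistic in log10 peptide intensity:
    ``p_detect = 1 / (1 + exp(-(log10_intensity - midpoint) / scale))``,
    so low-abundance peptides drop out preferentially — the mechanism by
    which array-level detection exceeds MS-level detection.
    """

    enabled: bool = True
    midpoint_log10: float = 5.0
    scale: float = 0.5

    def detect_probability(self, log10_intensity):
        import numpy as np

        if not self.enabled:
            return np.ones_like(np.asarray(log10_intensity, dtype=float))
        z = (np.asarray(log10_intensity, dtype=float) - self.midpoint_log10) / self.scale
        return 1.0 / (1.0 + np.exp(-z))


def _default_n_proteins() -> dict[str, int]:
    return {
        ECM_SCAFFOLD: 10,
        COLLAGEN: 8,
        CYTOKINE: 8,
        MMP_TIMP: 6,
        OTHER_SECRETED: 20,
        MEMBRANE: 6,
        ER: 4,
        INTRACELLULAR: 8,
    }


def _default_effects() -> dict[tuple[str, str], float]:
    return {(TNFA, CYTOKINE): 1.5, (TGFB, COLLAGEN): 1.0}


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 4
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_proteins: dict[str, int] = field(default_factory=_default_n_proteins)
    effect_log2fc: dict[tuple[str, str], float] = field(default_factory=_default_effects)
    patient_sd: float = 0.3  # log2-scale patient random effect SD
    noise_sd: float = 0.3  # log2-scale residual SD
    ms_dropout: DropoutConfig = field(default_factory=DropoutConfig)
    probes_per_gene: tuple[int, int] = (1, 5)
    ms_replicates: int = 1  # MS injections per patient x condition
    shared_fraction: float = 0.3  # fraction of cell proteins with a serum near-homolog
    n_serum_only: int = 4  # serum proteins with no cell counterpart
    n_below_threshold_genes: int = 10  # extra genes planted below array detection
    n_background_genes: int = 300  # null non-secreted transcriptome background
    peptide_sd: float = 0.2  # log10-scale fixed per-peptide ionization offset SD
    probe_offset_sd: float = 0.5  # log2-scale fixed per-probe affinity offset SD
    base_log10_range: tuple[float, float] = (5.5, 8.0)  # MS protein abundance
    base_log2_range: tuple[float, float] = (6.0, 12.0)  # array gene expression

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("a paired design needs at least 2 patients")
        if CONTROL not in self.conditions:
            raise ValueError("conditions must include 'control'")
        for name in ("patient_sd", "noise_sd", "peptide_sd", "probe_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.probes_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("probes_per_gene must satisfy 1 <= lo <= hi")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must lie in [0, 1]")
        unknown = set(self.n_proteins) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown protein categories: {sorted(unknown)}")
        for (cond, cat), fc in self.effect_log2fc.items():
            if cond not in self.conditions:
                raise ValueError(f"effect references unknown condition {cond!r}")
            if cat not in CATEGORIES:
                raise ValueError(f"effect references unknown category {cat!r}")
            if self.n_proteins.get(cat, 0) < 1:
                raise ValueError(
                    f"effect planted on category {cat!r} but n_proteins[{cat!r}] is 0"
                )

    def true_log2fc(self, condition: str, category: str) -> float:
        if condition == CONTROL:
            return 0.0
        return self.effect_log2fc.get((condition, category), 0.0)


def load_config(path: str | Path) -> SimConfig:
    """Build a SimConfig from a YAML file; absent keys keep their defaults.

    ``effect_log2fc`` is given in YAML as a nested mapping
    ``{condition: {category: log2fc}}``; ``ms_dropout`` as a mapping of the
    DropoutConfig fields.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    for key, value in raw.items():
        if key == "effect_log2fc":
            kwargs[key] = {
                (cond, cat): float(fc)
                for cond, per_cat in value.items()
                for cat, fc in per_cat.items()
            }
        elif key == "ms_dropout":
            kwargs[key] = DropoutConfig(**value)
        elif key in ("conditions",):
            kwargs[key] = tuple(value)
        elif key in ("probes_per_gene", "base_log10_range", "base_log2_range"):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return SimConfig(**kwargs)


def config_to_dict(config: SimConfig) -> dict:
    """JSON/YAML-serializable view of a SimConfig (inverse of load_config)."""
    d = asdict(config)
    effects: dict[str, dict[str, float]] = {}
    for (cond, cat), fc in config.effect_log2fc.items():
        effects.setdefault(cond, {})[cat] = fc
    d["effect_log2fc"] = effects
    d["conditions"] = list(config.conditions)
    d["probes_per_gene"] = list(config.probes_per_gene)
    d["base_log10_range"] = list(config.base_log10_range)
    d["base_log2_range"] = list(config.base_log2_range)
    return d
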