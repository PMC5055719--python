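"""Pipeline configuration.

All stage thresholds live in a single :class:`PipelineConfig` so that a run
is fully described by one YAML file plus a seed.  Defaults are the working
thresholds of the shrimp-transcriptome HTT screen this package implements:
E < 1e-5 for TE candidacy and nucleotide top-hit screening, E < 1e-20 for
family assignment and protein homologue searches, E < 1e-10 for genome-level
homologue presence, and a 60 % query-coverage floor for protein hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and knobs shared across pipeline stages.

    Parameters
    ----------
    e_te_candidate:
        E-value ceiling (strict) a repeat-library top hit must beat for a
        transcript to be called TE-derived.
    e_family:
        E-value ceiling (strict) for assigning a named TE family from the
        best same-species repeat-library nucleotide hit.
    e_nt_hit:
        Significance ceiling for nucleotide-database hits screened for
        top-hit taxon / HTT calling.
    e_genome_hit:
        Significance ceiling for genome (chromosome/HTGS) homologue hits.
    e_protein_hit:
        Significance ceiling for protein homologue hits feeding trees.
    min_protein_coverage:
        Minimum query coverage (fraction) for protein hits; lower-coverage
        hits are discarded before per-organism deduplication.
    mfc_thresholds:
        Max-fold-change thresholds swept when profiling differential
        expression.
    novelty_training_mfc:
        Strict lower bound on max fold change for HTT transcripts admitted
        to the one-class training set.
    random_seed:
        Seed for every stochastic stage (synthetic worlds, novelty fits).
    """

    e_te_candidate: float = 1e-5
    e_family: float = 1e-20
    e_nt_hit: float = 1e-5
    e_genome_hit: float = 1e-10
    e_protein_hit: float = 1e-20
    min_protein_coverage: float = 0.60
    mfc_thresholds: tuple[int, ...] = tuple(range(1, 41))
    novelty_training_mfc: float = 4.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("e_te_candidate", "e_family", "e_nt_hit",
                     "e_genome_hit", "e_protein_hit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.min_protein_coverage <= 1:
            raise ValueError("min_protein_coverage must be in (0, 1]")
        thresholds = tuple(self.mfc_thresholds)
        object.__setattr__(self, "mfc_thresholds", thresholds)
        if not thresholds or thresholds[0] < 1:
            raise ValueError("mfc_thresholds must start at >= 1")
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError("mfc_thresholds must be strictly increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["mfc_thresholds"] = list(self.mfc_thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


DEFAULT_CONFIG = PipelineConfig()
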