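"""Pipeline thresholds and length sets.

All inequalities in the filter cascade are strict: an epitope passes the
class-I gate only with IC50 < 500 nM, an expressed source only with
TPM > 1, a mutation only with RNA-VAF > 0.6.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    ic50_max_class_i: float = 500.0  # nM, strict <
    ic50_max_class_ii: float = 1000.0  # nM, strict <
    rna_vaf_min: float = 0.6  # strict >, mutations only
    tpm_min: float = 1.0  # strict >, supporting expression
    normal_max_lt: float = 1.0  # strict <, normal-panel mu+2*sigma ceiling
    mutation_lengths_class_i: tuple[int, ...] = (8, 9, 10, 11, 12)
    tag_lengths_class_i: tuple[int, ...] = (9, 10, 11, 12)
    lengths_class_ii: tuple[int, ...] = (15,)
    ms_probability_min: float = 0.7  # strict >, MS identification probability
    surrogate_salt: str = "oran"
    rng_seed: int = 0

    def __post_init__(self):
        for name in (
            "ic50_max_class_i",
            "ic50_max_class_ii",
            "rna_vaf_min",
            "tpm_min",
            "normal_max_lt",
            "ms_probability_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "mutation_lengths_class_i",
            "tag_lengths_class_i",
            "lengths_class_ii",
        ):
            lengths = tuple(sorted(set(getattr(self, name))))
            if not lengths:
                raise ValueError(f"{name} must be non-empty")
            setattr(self, name, lengths)

    def lengths_for(self, mhc_class: str, category: str) -> tuple[int, ...]:
        if mhc_class == "II":
            return self.lengths_class_ii
        if category == "TAA":
            return self.tag_lengths_class_i
        return self.mutation_lengths_class_i

    def ic50_max(self, mhc_class: str) -> float:
        return self.ic50_max_class_i if mhc_class == "I" else self.ic50_max_class_ii

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("mutation_lengths_class_i", "tag_lengths_class_i", "lengths_class_ii"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key in ("mutation_lengths_class_i", "tag_lengths_class_i", "lengths_class_ii"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
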