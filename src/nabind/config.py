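"""Run configuration: the method's printed constants plus run parameters.

The defaults are the published ones: 5.0 A contact cutoff, minimum chain
length 30, redundancy clustering at 30% identity / 50% coverage, 3 CV
folds and 1,000 trees.  A stricter validation-style clustering (e.g. 90%
coverage) is obtained by overriding ``coverage_thr``.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

DEFAULT_NEGATIVE_KEYWORDS = (
    "DNA binding", "RNA binding", "GO:0003677", "GO:0003723",
    "transcription", "replication", "recombination", "repair",
    "nucleic acid",
)


@dataclass
class RunConfig:
    contact_cutoff: float = 5.0
    min_length: int = 30
    identity_thr: float = 0.30
    coverage_thr: float = 0.50
    k_folds: int = 3
    n_trees: int = 1000
    seed: int = 0
    na_kind: str = "DNA"
    z3_two_sided: bool = False
    schema_path: Optional[str] = None
    keywords: tuple[str, ...] = DEFAULT_NEGATIVE_KEYWORDS
    # planted-simulation block (used by the `simulate` and `run` commands)
    sim_n_proteins: int = 200
    sim_fraction_binders: float = 0.5
    sim_effect_size: float = 2.0

    def __post_init__(self):
        self.keywords = tuple(self.keywords)
        positives = {
            "contact_cutoff": self.contact_cutoff,
            "min_length": self.min_length,
            "identity_thr": self.identity_thr,
            "coverage_thr": self.coverage_thr,
            "k_folds": self.k_folds,
            "n_trees": self.n_trees,
        }
        for name, v in positives.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["keywords"] = list(self.keywords)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @property
    def config_hash(self) -> str:
        data = asdict(self)
        data["keywords"] = list(self.keywords)
        canonical = yaml.safe_dump(data, sort_keys=True)
        return hashlib.sha1(canonical.encode()).hexdigest()[:12]
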