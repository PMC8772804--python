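"""Configuration objects and deterministic seed management.

Every randomized stage of the pipeline (rarefaction, permutation tests, EM
restarts, the cohort generator) draws its generator from a single master seed
through :func:`stage_rng`, so a rerun with the same configuration is
bit-identical while the stages remain statistically independent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

# Fixed stage indices: stage name -> offset mixed into the SeedSequence.
# Appending new stages is safe; renumbering existing ones breaks reproducibility.
_STAGE_KEYS = {
    "generator": 0,
    "rarefaction": 1,
    "enterotype": 2,
    "dbrda": 3,
    "permanova": 4,
    "reads": 5,
    "pangenome": 6,
    "matching": 7,
    "misc": 8,
}


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for a named pipeline stage, derived from the master seed."""
    try:
        key = _STAGE_KEYS[stage]
    except KeyError:
        raise ValueError(f"unknown pipeline stage {stage!r}; known: {sorted(_STAGE_KEYS)}")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


def stage_seed(master_seed: int, stage: str) -> int:
    """A plain integer seed (< 2**31) for APIs that do not take a Generator."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_KEYS[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class AnalysisConfig:
    """Tunable parameters of the baseline / longitudinal analyses.

    Defaults follow the analysis protocol: rarefaction to 10,000 reads per
    sample, feature retention at >= 5e-4 relative abundance in >= 20% of
    samples, 999 permutations for distance-based tests, and enterotype model
    orders 1..6.
    """

    rarefaction_depth: int = 10_000
    feature_min_abundance: float = 5e-4
    feature_min_prevalence: float = 0.20
    n_permutations: int = 999
    k_range: tuple = (1, 2, 3, 4, 5, 6)
    alpha: float = 0.05
    seed: int = 0
    min_identity: float = 0.80
    min_aligned_fraction: float = 0.50
    dmm_restarts: int = 5
    dmm_tol: float = 1e-6
    dmm_max_iter: int = 500

    def __post_init__(self):
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be > 0")
        if not (0.0 < self.feature_min_prevalence <= 1.0):
            raise ValueError("feature_min_prevalence must be in (0, 1]")
        if len(self.k_range) == 0:
            raise ValueError("k_range must be non-empty")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    def config_hash(self) -> str:
        """Short stable hash of the configuration, embedded in every artifact."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def rng(self, stage: str) -> np.random.Generator:
        return stage_rng(self.seed, stage)
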