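"""Functional aggregation: species abundances -> KO abundances -> module scores.

KO (KEGG Ortholog group) abundance in a sample is the sum of the relative
abundances of the species whose pan-genome contains that KO:
KO[s, k] = sum_j A[s, j] * P[j, k] with P a binary species x KO presence
matrix. Metabolic modules are scored from KO abundances by the
median-of-steps convention: a module is an ordered list of steps, each step a
set of alternative KOs; the step abundance is the sum over its (deduplicated)
alternatives, module coverage is the fraction of steps with positive
abundance, and the module abundance is the median step abundance when the
coverage reaches the cutoff (default 2/3), else zero. Both the cutoff and the
aggregation are configurable; curated module databases are user-supplied in
the plain-text format parsed by :func:`parse_modules`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceTable

log = logging.getLogger("gutpipe")

__all__ = ["ModuleDefinition", "parse_modules", "ko_abundance", "module_abundance"]


@dataclass
class ModuleDefinition:
    module_id: str
    name: str
    steps: list  # list of sets of KO ids

    def __post_init__(self):
        if len(self.steps) == 0:
            raise ValueError(f"module {self.module_id} has no steps")
        self.steps = [set(s) for s in self.steps]
        if any(len(s) == 0 for s in self.steps):
            raise ValueError(f"module {self.module_id} has an empty step")


def parse_modules(source) -> list[ModuleDefinition]:
    """Parse plain-text module definitions.

    Format: blank-line-separated records; each record starts with a header
    line ``MODULE<tab>id<tab>name`` followed by one line per step listing
    comma-separated alternative KO ids.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    else:
        text = str(source)
    modules = []
    for block in text.strip().split("\n\n"):
        lines = [ln.strip() for ln in block.strip().splitlines() if ln.strip()]
        if not lines:
            continue
        header = lines[0].split("\t")
        if header[0] != "MODULE" or len(header) < 3:
            raise ValueError(f"malformed module header: {lines[0]!r}")
        steps = [set(k.strip() for k in ln.split(",") if k.strip()) for ln in lines[1:]]
        modules.append(ModuleDefinition(module_id=header[1], name=header[2], steps=steps))
    return modules


def ko_abundance(abundance: AbundanceTable, presence: pd.DataFrame) -> pd.DataFrame:
    """Samples x KO abundance: KO[s, k] = sum_j A[s, j] * P[j, k].

    Species absent from the presence matrix are logged and excluded.
    """
    vals = presence.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    species = [s for s in abundance.taxon_ids if s in presence.index]
    unmapped = [s for s in abundance.taxon_ids if s not in presence.index]
    if unmapped:
        log.info("ko_abundance: %d species without pan-genome entry excluded: %s",
                 len(unmapped), unmapped[:5])
    if not species:
        raise ValueError("no species of the abundance table appear in the presence matrix")
    a = abundance.counts[species].to_numpy(dtype=float)
    p = presence.loc[species].to_numpy(dtype=float)
    return pd.DataFrame(a @ p, index=abundance.counts.index, columns=presence.columns)


def module_abundance(
    ko_table: pd.DataFrame,
    modules: list[ModuleDefinition],
    coverage_cutoff: float = 2 / 3,
    aggregate: str = "median",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score modules from KO abundances.

    Returns (abundance, coverage), both samples x modules. KOs referenced by
    a module but absent from the KO table count as zero (logged).
    """
    if aggregate not in ("median", "sum"):
        raise ValueError("aggregate must be 'median' or 'sum'")
    agg = np.median if aggregate == "median" else np.sum
    known = set(ko_table.columns)
    ab = {}
    cov = {}
    for mod in modules:
        missing = sorted(set().union(*mod.steps) - known)
        if missing:
            log.info("module %s: %d KOs absent from table: %s",
                     mod.module_id, len(missing), missing[:5])
        step_values = np.vstack([
            ko_table[[k for k in step if k in known]].sum(axis=1).to_numpy()
            if (step & known) else np.zeros(len(ko_table))
            for step in mod.steps
        ])  # n_steps x n_samples
        coverage = (step_values > 0).mean(axis=0)
        value = agg(step_values, axis=0)
        ab[mod.module_id] = np.where(coverage >= coverage_cutoff, value, 0.0)
        cov[mod.module_id] = coverage
    idx = ko_table.index
    return pd.DataFrame(ab, index=idx), pd.DataFrame(cov, index=idx)
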