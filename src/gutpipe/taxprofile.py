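"""From per-read taxonomic assignments to rarefied, filtered abundance tables.

The upstream classifier assigns each long read a candidate taxon; a second
alignment step against the candidate's reference genome yields a confirmation
identity and an aligned fraction. This module implements the downstream
consolidation only: the two-step false-positive filter (human-read removal +
identity/coverage thresholds), read tabulation into species counts,
rarefaction without replacement to a common depth, genus-level collapse, and
the abundance/prevalence feature filter. The classifier and aligner themselves
are out of scope — their tabular output (or a synthetic equivalent) is the
input here.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import AbundanceTable

log = logging.getLogger("gutpipe")

__all__ = ["confirm_assignments", "tabulate", "rarefy", "collapse_rank", "filter_features",
           "collapse_candidates"]

_READ_COLUMNS = ["read_id", "sample_id", "candidate_taxon", "classifier_score",
                 "confirmed_identity", "aligned_fraction", "human_flag"]


def collapse_candidates(reads: pd.DataFrame) -> pd.DataFrame:
    """Keep one best candidate row per read: highest classifier score, ties
    broken by lowest candidate taxon id (deterministic)."""
    ordered = reads.sort_values(
        ["read_id", "classifier_score", "candidate_taxon"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(subset="read_id", keep="first").reset_index(drop=True)


def confirm_assignments(
    reads: pd.DataFrame,
    min_identity: float = 0.80,
    min_aligned_fraction: float = 0.50,
) -> pd.DataFrame:
    """Two-step confirmation filter on candidate assignments.

    Removes human-flagged reads unconditionally, then reads whose alignment
    confirmation fails either the identity or the aligned-fraction threshold.
    Retained rows are returned unchanged, so the operation is idempotent.
    """
    for thr, name in ((min_identity, "min_identity"), (min_aligned_fraction, "min_aligned_fraction")):
        if not (0.0 <= thr <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    if reads.empty:
        log.warning("confirm_assignments: empty read table")
        return reads.copy()
    keep = (
        (~reads["human_flag"].astype(bool))
        & (reads["confirmed_identity"] >= min_identity)
        & (reads["aligned_fraction"] >= min_aligned_fraction)
    )
    removed = int((~keep).sum())
    log.info("confirm_assignments: removed %d / %d reads", removed, len(reads))
    return reads.loc[keep].reset_index(drop=True)


def tabulate(reads: pd.DataFrame, taxonomy: dict | None = None) -> AbundanceTable:
    """Count confirmed reads into a samples x species table.

    The species universe is the union of observed candidate taxa.
    """
    if reads.empty:
        return AbundanceTable(pd.DataFrame(dtype=int), taxonomy=taxonomy or {})
    counts = (
        reads.groupby(["sample_id", "candidate_taxon"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    counts.index.name = None
    counts.columns.name = None
    return AbundanceTable(counts.astype(int), taxonomy=taxonomy or {})


def rarefy(table: AbundanceTable, depth: int = 10_000, seed: int = 0) -> AbundanceTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    One multivariate-hypergeometric draw per sample. Samples with fewer than
    ``depth`` reads are excluded and listed in the log; if no sample reaches
    the depth, an error reports the per-sample read census.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.counts.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        census = totals.to_dict()
        raise ValueError(f"no sample reaches rarefaction depth {depth}; read census: {census}")
    excluded = list(totals.index[~keep])
    if excluded:
        log.info("rarefy: excluded %d samples below depth %d: %s",
                 len(excluded), depth, excluded[:10])
    rng = np.random.default_rng(seed)
    sub = table.counts.loc[keep]
    out = np.vstack([
        rng.multivariate_hypergeometric(row.astype(np.int64), depth)
        for row in sub.to_numpy()
    ])
    rarefied = pd.DataFrame(out, index=sub.index, columns=sub.columns, dtype=int)
    return AbundanceTable(rarefied, taxonomy=dict(table.taxonomy), rarefaction_depth=depth)


def collapse_rank(table: AbundanceTable, rank: str = "genus") -> AbundanceTable:
    """Sum species counts within each genus; per-sample totals are conserved.

    A table whose columns are already genus ids (all map onto themselves or
    taxonomy is empty and columns equal the genus universe) passes through
    unchanged.
    """
    if rank != "genus":
        raise ValueError("only genus-level collapse is supported")
    taxonomy = table.taxonomy
    cols = table.taxon_ids
    if taxonomy and set(cols) <= set(taxonomy.values()):
        return table  # already at genus level
    orphans = [c for c in cols if c not in taxonomy]
    if orphans:
        raise ValueError(f"species without genus mapping: {orphans[:10]}")
    genus = pd.Series({c: taxonomy[c] for c in cols})
    collapsed = table.counts.T.groupby(genus).sum().T
    collapsed.columns.name = None
    return AbundanceTable(
        collapsed,
        taxonomy={},
        relative=table.relative,
        rarefaction_depth=table.rarefaction_depth,
        filtered=table.filtered,
    )


def filter_features(
    table: AbundanceTable,
    min_abundance: float = 5e-4,
    min_prevalence: float = 0.20,
) -> AbundanceTable:
    """Keep feature j iff it reaches ``min_abundance`` relative abundance in at
    least ``min_prevalence`` of the samples (both bounds inclusive)."""
    if not table.relative:
        raise ValueError("feature filter expects a relative-abundance table")
    x = table.counts.to_numpy()
    prevalence = (x >= min_abundance).mean(axis=0)
    keep = prevalence >= min_prevalence
    dropped = list(table.counts.columns[~keep])
    if dropped:
        log.info("filter_features: dropped %d features: %s", len(dropped), dropped[:10])
    kept = table.counts.loc[:, keep]
    return AbundanceTable(kept, taxonomy=dict(table.taxonomy), relative=True, filtered=True)
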