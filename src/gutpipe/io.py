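"""Reading and writing the pipeline's tabular formats.

Abundance tables travel as TSV (taxa x samples or transposed, declared by an
orientation flag), clinical tables as CSV, taxonomy as a three-column TSV
(species_id, species_name, genus). Written artifacts carry a leading comment
line embedding the configuration hash and seed so any file can be traced back
to the run that produced it.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceTable, validate_clinical

log = logging.getLogger("gutpipe")

__all__ = ["read_tables", "read_abundance", "read_clinical", "read_taxonomy", "write_artifact"]


def read_taxonomy(path) -> dict:
    """Read a species -> genus map from TSV with columns species_id, species_name, genus."""
    tax = pd.read_csv(path, sep="\t", comment="#")
    for col in ("species_id", "genus"):
        if col not in tax.columns:
            raise ValueError(f"taxonomy file missing required column '{col}'")
    return dict(zip(tax["species_id"], tax["genus"]))


def read_abundance(path, orientation: str = "taxa_rows", taxonomy: dict | None = None) -> AbundanceTable:
    """Read an abundance TSV.

    orientation='taxa_rows' means taxa as rows / samples as columns on disk
    (the common export layout); 'samples_rows' is the transposed layout.
    The returned table always has samples as rows.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError("orientation must be 'taxa_rows' or 'samples_rows'")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if orientation == "taxa_rows":
        df = df.T
    arr = df.to_numpy()
    if (arr < 0).any():
        raise ValueError(f"negative counts in {path}")
    is_relative = bool(arr.size) and not np.allclose(arr, np.round(arr))
    return AbundanceTable(df, taxonomy=taxonomy or {}, relative=is_relative)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    return validate_clinical(df)


def read_tables(
    abundance_path,
    clinical_path,
    taxonomy_path=None,
    orientation: str = "taxa_rows",
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Read and cross-validate the abundance + clinical input pair.

    Sample ids present in only one of the two tables are reported via the
    logger; the intersection is what downstream stages will consume.
    """
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else None
    abundance = read_abundance(abundance_path, orientation=orientation, taxonomy=taxonomy)
    clinical = read_clinical(clinical_path)
    ab_samples = set(abundance.sample_ids)
    cl_samples = set(clinical["subject_id"].astype(str) + "_" + clinical["visit"].astype(str))
    only_ab = sorted(ab_samples - cl_samples)
    only_cl = sorted(cl_samples - ab_samples)
    if only_ab:
        log.warning("%d abundance samples without clinical rows (e.g. %s)", len(only_ab), only_ab[:3])
    if only_cl:
        log.warning("%d clinical rows without abundance samples (e.g. %s)", len(only_cl), only_cl[:3])
    return abundance, clinical


def write_artifact(df: pd.DataFrame, path, config_hash: str, seed: int, index: bool = True) -> None:
    """Write a DataFrame as CSV with a provenance comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=index)
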