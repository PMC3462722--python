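"""Access to the small data files shipped with the package.

* ``species_meta`` — kingdom/clade annotation for the species codes used
  in examples and simulations.
* ``mir168_catalog`` — the two clade-diagnostic miR168 mature sequence
  variants under their monocot and dicot carrier species.
* ``public_library_table`` — published summary statistics for 19 public
  animal small-RNA libraries with significant plant miRNA content; the
  count columns serve as inputs for regression-testing the profiler
  arithmetic against the published percent columns.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .catalog import Catalog, load_species_meta, parse_mature_fasta


def _data_path(name: str) -> Path:
    return Path(resources.files("xenomir").joinpath("data", name))


def species_meta_path() -> Path:
    return _data_path("species_meta.tsv")


def species_meta() -> dict[str, tuple[str, str]]:
    return load_species_meta(species_meta_path())


def mir168_catalog() -> Catalog:
    """Catalog of the monocot and dicot miR168 variants (8 records)."""
    return parse_mature_fasta(_data_path("mir168_variants.fasta"), species_meta())


def public_library_table() -> pd.DataFrame:
    """The 19-library published summary table (counts and percent columns)."""
    return pd.read_csv(_data_path("public_srna_libraries.tsv"), sep="\t", comment="#")
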