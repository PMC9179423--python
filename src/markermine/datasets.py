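"""Packaged reference data: seed marker sets and the published qPCR table.

``table3()`` returns the transcribed per-patient qPCR outcome table for
the 42 experimentally tested candidate colorectal-cancer markers (gene,
patient, expression ratio, p-value) together with the printed
direction/arrow annotation, so the classifier can be checked cell by cell
against the published calls.  ``seed_sets()`` returns the two
independent sets of 10 validated CRC markers used to train and validate
the expansion procedure.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from markermine.expansion import SeedSet
from markermine.io import read_alias_table, read_gene_list

_DATA = resources.files("markermine") / "data"


def _path(name: str):
    return _DATA / name


def default_aliases() -> dict[str, str]:
    """Alias table resolving the non-standard seed spellings."""
    with resources.as_file(_path("aliases.tsv")) as p:
        return read_alias_table(p)


def seed_sets() -> tuple[SeedSet, SeedSet]:
    """The packaged (training, validation) seed sets of 10 CRC markers each."""
    aliases = default_aliases()
    with resources.as_file(_path("seeds_training.txt")) as p:
        training = SeedSet("training", read_gene_list(p, aliases))
    with resources.as_file(_path("seeds_validation.txt")) as p:
        validation = SeedSet("validation", read_gene_list(p, aliases))
    return training, validation


def table3() -> pd.DataFrame:
    """Published qPCR outcomes: 42 genes x 3 patients.

    Columns: gene, patient (str), ratio (2^-ddCt, tumor vs matched
    mucosa), p_value, printed_direction ({up, down, none}) and
    printed_arrows (0-4) as annotated in the publication.
    """
    with resources.as_file(_path("table3.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"patient": str})
    assert set(df.columns) == {
        "gene",
        "patient",
        "ratio",
        "p_value",
        "printed_direction",
        "printed_arrows",
    }
    return df
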