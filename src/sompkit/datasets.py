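"""Packaged reference tables for the *Stylophora pistillata* skeletal proteome.

Two small published tables ship with the package: the curated list of 60
skeletal proteins detected across all purification treatments and solubility
fractions (accession, annotation, best identification score, GO-categorized
flag, per-solubility detection), and the ortholog-pair table linking curated
proteins to the three previously published coral skeletal proteomes.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .io_tables import OrthologPair, read_ortholog_table

#: Labels of the previously published skeletal proteomes used for comparison.
PUBLISHED_PROTEOMES: tuple[str, ...] = (
    "A_digitifera_2016",
    "A_millepora_2013",
    "S_pistillata_2013",
)


def _data_path(name: str):
    return files("sompkit").joinpath(f"data/{name}")


def published_skeletal_proteins() -> pd.DataFrame:
    """The published curated skeletal proteome, indexed by accession.

    Columns: annotation, best_score, go_categorized (bool), ssom (bool),
    isom (bool). The ssom/isom flags reproduce the printed per-solubility
    detection marks as published.
    """
    with _data_path("spis_skeletal_proteins.tsv").open() as handle:
        frame = pd.read_csv(handle, sep="\t", dtype=str)
    frame["best_score"] = frame["best_score"].astype(float)
    for col in ("go_categorized", "ssom", "isom"):
        frame[col] = frame[col].map({"true": True, "false": False})
    return frame.set_index("accession")


def published_ortholog_pairs() -> list[OrthologPair]:
    """Ortholog pairs linking curated proteins to published skeletal proteomes."""
    return read_ortholog_table(
        _data_path("spis_skeletal_orthologs.tsv"), PUBLISHED_PROTEOMES
    )
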