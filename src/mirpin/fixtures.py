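"""Packaged supplementary-table fixtures from the source study.

The study's headline lists (differentially expressed miRNAs/genes, network
sizes, enrichment results, marker AUCs) were derived from external database
releases that cannot be recomputed here; the printed tables are shipped as
TSV resources and re-counted instead. Row counts are frozen by the test
suite: S1=90, S2=726, S3=437, S4=18, S5=18.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io import UsageError

_FILES = {
    "S1": "table_s1_mirnas.tsv",
    "S2": "table_s2_down_genes.tsv",
    "S3": "table_s3_up_genes.tsv",
    "S4": "table_s4_roc.tsv",
    "S5": "table_s5_networks.tsv",
    "S6": "table_s6_enriched_terms.tsv",
}

EXPECTED_ROW_COUNTS = {"S1": 90, "S2": 726, "S3": 437, "S4": 18, "S5": 18}


@dataclass
class FixtureTable:
    name: str
    rows: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)


def load_fixture(name: str) -> FixtureTable:
    """Load one of the packaged supplementary tables (S1..S6)."""
    if name not in _FILES:
        raise UsageError(f"unknown fixture {name!r}; choose from {sorted(_FILES)}")
    ref = resources.files("mirpin.data") / _FILES[name]
    with resources.as_file(ref) as path:
        rows = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return FixtureTable(name=name, rows=rows)
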