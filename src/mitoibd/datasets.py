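"""Bundled sample-locality tables for the two focal salamander datasets.

The package ships the published voucher/locality tables for the
*Batrachoseps major* and *B. nigriventris* mitochondrial datasets
(population number, clade assignment, decimal-degree coordinates, and
introduced-candidate flags).  The corresponding cytb alignments are not
redistributable here and must be supplied by the user; loaders accept an
optional drop-list of excluded populations.
"""

from __future__ import annotations

from importlib import resources

from .alignio import SampleTable, read_sample_table

__all__ = [
    "load_bmajor_table",
    "load_bnigriventris_table",
    "BMAJOR_EXCLUDED_POPULATIONS",
    "BMAJOR_NORTHERN_CLADES",
]

#: Populations excluded from the B. major analyses (low-quality data).
BMAJOR_EXCLUDED_POPULATIONS = ("17",)

#: Clade labels of the eight northern B. major subclades.
BMAJOR_NORTHERN_CLADES = tuple(str(k) for k in range(1, 9))


def _bundled(name: str) -> SampleTable:
    with resources.as_file(resources.files("mitoibd.data") / name) as path:
        return read_sample_table(path)


def load_bmajor_table(apply_drop_list: bool = True) -> SampleTable:
    """The B. major sample table (97 rows; 96 after the default drop-list)."""
    table = _bundled("bmajor_samples.tsv")
    if apply_drop_list:
        table = table.drop_populations(BMAJOR_EXCLUDED_POPULATIONS)
    return table


def load_bnigriventris_table() -> SampleTable:
    """The B. nigriventris sample table (63 rows)."""
    return _bundled("bnigriventris_samples.tsv")
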