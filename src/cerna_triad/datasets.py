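"""Packaged reference tables.

Two small differential-expression tables from a published two-phase goat
lactation study (early, day 5, as control vs mature, day 30) ship with the
package: the 24 differentially expressed known miRNAs (with fold change,
log2 fold change, raw and BH-adjusted p-values and mature sequence) and the
33 differentially expressed lncRNAs (fold change, log2 fold change, raw
p-value, assembler gene id and class code). Values are as printed in the
source tables: miRNA columns are rounded to two decimals, lncRNA columns
carry full precision, zero-control-baseline lncRNAs appear as ``Inf``, and
the two zero-treatment rows print a placeholder ``0`` for their log2 fold
change (this package's own :func:`~cerna_triad.quant.fold_change` reports
``-inf`` there instead).

These tables serve as parsing/classification fixtures and as worked
examples for the direction rule.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_mirna_table", "load_lncrna_table"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("cerna_triad.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t").rename(columns={"up_down": "direction"})


def load_mirna_table() -> pd.DataFrame:
    """Differentially expressed known miRNAs (24 rows) between lactation
    phases; columns ``feature_id foldChange log2FoldChange pval padj
    direction sequence``."""
    return _load("goat_lactation_mirna_de.tsv")


def load_lncrna_table() -> pd.DataFrame:
    """Differentially expressed lncRNAs (33 rows) between lactation phases;
    columns ``feature_id foldChange log2FoldChange pval direction gene_id
    class_code``. ``foldChange`` is ``inf`` for zero-control features."""
    return _load("goat_lactation_lncrna_de.tsv")
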