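"""GFF3 annotation access.

Thin wrappers around :mod:`gffutils`: load a GFF3 into an in-memory
database and pull out the two views the pipeline needs — structural-RNA
intervals (rRNA/tRNA/tmRNA, for masking) and stranded gene records (for
orientation calls and regulator-target resolution). GFF3 coordinates are
1-based closed; everything returned here is 0-based half-open.
"""

from __future__ import annotations

import warnings

import gffutils
import pandas as pd

STRUCTURAL_RNA_TYPES = ("rRNA", "tRNA", "tmRNA")

__all__ = ["load_gff", "structural_rna_intervals", "gene_table", "STRUCTURAL_RNA_TYPES"]


def load_gff(path) -> gffutils.FeatureDB:
    return gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def structural_rna_intervals(db: gffutils.FeatureDB) -> list[tuple[int, int]]:
    """0-based half-open intervals of every rRNA/tRNA/tmRNA feature."""
    out: list[tuple[int, int]] = []
    for ftype in STRUCTURAL_RNA_TYPES:
        for feat in db.features_of_type(ftype):
            out.append((feat.start - 1, feat.end))
    if not out:
        warnings.warn("no rRNA/tRNA/tmRNA features found; structural-RNA mask is empty")
    return sorted(out)


def gene_table(db: gffutils.FeatureDB, featuretypes=("gene",)) -> pd.DataFrame:
    """Stranded gene records as a DataFrame (gene_id, name, start, end, strand).

    Records without a usable strand are dropped with a warning. ``start``/
    ``end`` are 0-based half-open.
    """
    rows = []
    n_unstranded = 0
    for ftype in featuretypes:
        for feat in db.features_of_type(ftype):
            if feat.strand not in ("+", "-"):
                n_unstranded += 1
                continue
            name = feat.attributes.get("Name", [feat.id])[0]
            rows.append(
                {
                    "gene_id": feat.id,
                    "name": name,
                    "start": feat.start - 1,
                    "end": feat.end,
                    "strand": feat.strand,
                }
            )
    if n_unstranded:
        warnings.warn(f"dropped {n_unstranded} unstranded records from orientation input")
    return pd.DataFrame(rows, columns=["gene_id", "name", "start", "end", "strand"])
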