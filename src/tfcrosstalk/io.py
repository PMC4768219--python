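"""Readers for the annotation, expression and term input formats."""

from __future__ import annotations

import pandas as pd

from .errors import InputError

ANNOTATION_COLUMNS = ["gene_id", "chrom", "tss", "strand"]


def read_annotation_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise InputError(f"annotation TSV missing columns: {sorted(missing)}")
    return ann[ANNOTATION_COLUMNS]


def read_annotation_gff3(path) -> pd.DataFrame:
    """Gene anchors from GFF3 ``gene`` features (1-based closed converted to a
    0-based TSS; the TSS is the 5' end per strand)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if feat.strand == "+":
            tss = feat.start - 1
        elif feat.strand == "-":
            tss = feat.end - 1
        else:
            raise InputError(f"gene {gene_id}: strand must be + or -")
        rows.append((gene_id, feat.seqid, tss, feat.strand))
    if not rows:
        raise InputError("no gene features found in GFF3 input")
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def read_annotation(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        return read_annotation_gff3(path)
    return read_annotation_tsv(path)


def read_terms(path) -> pd.DataFrame:
    terms = pd.read_csv(path, sep="\t")
    if not {"gene_id", "term_id"}.issubset(terms.columns):
        raise InputError("term table needs gene_id and term_id columns")
    return terms
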