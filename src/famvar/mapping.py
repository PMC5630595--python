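"""Mapping protein changes onto family alignment columns.

A variant hits an alignment column when some domain instance of its protein
covers the residue and maps it to a column; residues falling inside
insertions (present in the protein, absent from the family model) map to
nothing. Consensus calling is per column over the members aligned there:
the modal residue wins (ties broken alphabetically) and the column is
conserved when the modal frequency reaches the threshold — the uppercase
letters of a "dRy"-style motif rendering.
"""

from __future__ import annotations

import pandas as pd

from famvar.containers import (
    DomainInstance,
    FamilyAlignment,
    Proteome,
    VariantRecord,
    VariantTable,
)
from famvar.io import read_variants  # noqa: F401  (re-exported module surface)

#: default modal-frequency threshold for calling a column conserved
CONSERVATION_THRESHOLD = 0.5

CANONICAL = "canonical"
NON_CANONICAL = "non_canonical"
UNKNOWN = "unknown"


def map_variant_to_column(
    variant: VariantRecord,
    instances_by_protein: dict[str, list[DomainInstance]],
) -> list[tuple[str, int]]:
    """All (family, column) coordinates a variant's residue aligns to.

    A protein with two instances of the same family yields one hit per
    instance; an unmapped (insertion) residue yields none. Stop-gain and
    frameshift variants map like any other — their consequence class is
    carried on the record, not here.
    """
    hits: list[tuple[str, int]] = []
    for inst in instances_by_protein.get(variant.protein, []):
        if inst.start <= variant.position <= inst.end:
            col = inst.column_of(variant.position)
            if col is not None:
                hits.append((inst.family, col))
    return hits


def map_table_to_columns(
    table: VariantTable, proteome: Proteome
) -> pd.DataFrame:
    """Long-form hit table: one row per (variant, family, column) hit."""
    idx = proteome.instances_by_protein()
    rows = []
    for i, v in enumerate(table.variants):
        for fam, col in map_variant_to_column(v, idx):
            rows.append((i, v.protein, v.position, v.consequence,
                         v.pooled_count, fam, col))
    return pd.DataFrame(
        rows,
        columns=["variant_index", "protein", "position", "consequence",
                 "pooled_count", "family", "column"],
    )


def compute_consensus(
    fa: FamilyAlignment,
    sequences: dict[str, str],
    threshold: float = CONSERVATION_THRESHOLD,
) -> pd.DataFrame:
    """Per-column modal residue, its frequency, and the conserved flag.

    Frequencies are over members with a residue aligned at the column; a
    column with no aligned member gets residue None and conserved False.
    Ties on the modal count break alphabetically by residue letter.
    """
    if not fa.members:
        raise ValueError(f"family {fa.family} has no members")
    residues = fa.column_residues(sequences)
    rows = []
    for col in range(1, fa.model_length + 1):
        letters = residues[col]
        if not letters:
            rows.append((col, None, float("nan"), 0, False))
            continue
        counts = pd.Series(letters).value_counts()
        top = counts[counts == counts.max()].index.min()  # alphabetical tie
        freq = counts.max() / len(letters)
        rows.append((col, top, freq, len(letters), freq >= threshold))
    return pd.DataFrame(
        rows, columns=["column", "residue", "frequency", "n_aligned",
                       "conserved"]
    ).set_index("column")


def motif_string(consensus: pd.DataFrame, columns: list[int]) -> str:
    """Render consensus residues with conservation as case, e.g. ``dRy``."""
    out = []
    for col in columns:
        row = consensus.loc[col]
        if row["residue"] is None:
            out.append(".")
        else:
            out.append(row["residue"].upper() if row["conserved"]
                       else row["residue"].lower())
    return "".join(out)


def canonical_check(
    protein: str,
    fa: FamilyAlignment,
    sequences: dict[str, str],
    columns: list[int],
    consensus: pd.DataFrame | None = None,
) -> dict[int, str]:
    """Canonical / non-canonical residue status at chosen columns.

    A receptor is canonical at a column when its aligned residue equals the
    family consensus residue there; columns unmapped in this receptor (or
    with undefined consensus) report "unknown".
    """
    if consensus is None:
        consensus = compute_consensus(fa, sequences)
    instances = [m for m in fa.members if m.protein == protein]
    if not instances:
        raise ValueError(f"{protein} has no domain instance in {fa.family}")
    seq = sequences[protein]
    out: dict[int, str] = {}
    for col in columns:
        cons = consensus.loc[col, "residue"]
        residue = None
        for inst in instances:
            pos = inst.residue_of(col)
            if pos is not None:
                residue = seq[pos - 1]
                break
        if residue is None or cons is None:
            out[col] = UNKNOWN
        elif residue == cons:
            out[col] = CANONICAL
        else:
            out[col] = NON_CANONICAL
    return out


def canonical_status_table(
    fa: FamilyAlignment,
    sequences: dict[str, str],
    columns: list[int],
    threshold: float = CONSERVATION_THRESHOLD,
) -> pd.DataFrame:
    """Receptor x column status matrix for every member of the family."""
    consensus = compute_consensus(fa, sequences, threshold)
    proteins = sorted({m.protein for m in fa.members})
    data = {
        p: canonical_check(p, fa, sequences, columns, consensus)
        for p in proteins
    }
    return pd.DataFrame.from_dict(data, orient="index")[columns]
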