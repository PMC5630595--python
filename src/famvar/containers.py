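"""Core data containers shared across the analysis modules.

All residue positions are 1-based; alignment columns are 1-based over the
family model length. Domain instances map protein residues to alignment
columns partially: residues falling in deleted columns are absent from the
map, and insertion residues (present in the protein but not in the family
model) are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Consequence classes carried by a variant record.
MISSENSE = "missense"
STOP_GAIN = "stop_gain"
FRAMESHIFT = "frameshift"
LOF_CONSEQUENCES = frozenset({STOP_GAIN, FRAMESHIFT})
CONSEQUENCES = frozenset({MISSENSE, STOP_GAIN, FRAMESHIFT})


@dataclass
class VariantRecord:
    """A unique protein change with per-individual diploid allele counts.

    Parameters
    ----------
    protein : str
        Protein identifier.
    position : int
        1-based residue index of the change.
    ref_residue : str
        Reference amino-acid letter (must match the protein sequence).
    alt_residue : str
        Alternate amino-acid letter for missense records; ``"*"`` for
        stop-gains and ``"fs"`` for frameshifts.
    consequence : str
        One of ``missense``, ``stop_gain``, ``frameshift``.
    allele_counts : numpy.ndarray
        Integer alternate-allele count per individual, each in {0, 1, 2}.
    """

    protein: str
    position: int
    ref_residue: str
    alt_residue: str
    consequence: str
    allele_counts: np.ndarray

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        self.allele_counts = np.asarray(self.allele_counts, dtype=np.int8)
        if self.allele_counts.size and (
            self.allele_counts.min() < 0 or self.allele_counts.max() > 2
        ):
            raise ValueError("allele counts must be in {0, 1, 2}")
        if self.consequence == MISSENSE and self.ref_residue == self.alt_residue:
            raise ValueError("missense ref and alt residues must differ")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.protein, self.position, self.alt_residue)

    @property
    def pooled_count(self) -> int:
        """Total alternate-allele count over the cohort."""
        return int(self.allele_counts.sum())


class VariantTable:
    """An ordered collection of variant records over a fixed cohort.

    Records are kept sorted by (protein, position, alt) so that genotype
    matrices and fingerprints have a deterministic column order.
    """

    def __init__(self, variants: list[VariantRecord], individuals: list[str]):
        n = len(individuals)
        for v in variants:
            if v.allele_counts.shape != (n,):
                raise ValueError(
                    f"variant {v.key} has {v.allele_counts.shape[0]} genotype "
                    f"entries for a cohort of {n}"
                )
        self.variants = sorted(variants, key=lambda v: v.key)
        self.individuals = list(individuals)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def genotypes(self) -> np.ndarray:
        """(n_variants, n_individuals) matrix of allele counts."""
        if not self.variants:
            return np.zeros((0, self.n_individuals), dtype=np.int8)
        return np.vstack([v.allele_counts for v in self.variants])

    def subset(self, predicate) -> "VariantTable":
        """New table with the records for which ``predicate(record)`` holds."""
        return VariantTable(
            [v for v in self.variants if predicate(v)], self.individuals
        )

    def missense(self) -> "VariantTable":
        return self.subset(lambda v: v.consequence == MISSENSE)

    def loss_of_function(self) -> "VariantTable":
        return self.subset(lambda v: v.consequence in LOF_CONSEQUENCES)

    def pooled_counts(self) -> np.ndarray:
        return np.array([v.pooled_count for v in self.variants], dtype=np.int64)

    def to_dataframe(self, genotypes: bool = True) -> pd.DataFrame:
        rows = {
            "protein": [v.protein for v in self.variants],
            "position": [v.position for v in self.variants],
            "ref": [v.ref_residue for v in self.variants],
            "alt": [v.alt_residue for v in self.variants],
            "consequence": [v.consequence for v in self.variants],
        }
        df = pd.DataFrame(rows)
        if genotypes:
            gt = self.genotypes()
            df = pd.concat(
                [df, pd.DataFrame(gt, columns=self.individuals)], axis=1
            )
        return df


@dataclass
class DomainInstance:
    """One occurrence of a family model within a protein.

    ``column_map`` maps 1-based residue indices (within [start, end]) to
    1-based alignment columns; it is partial (deleted columns are missing)
    and strictly increasing (insertions are skipped, never reordered).
    """

    family: str
    protein: str
    start: int
    end: int
    column_map: dict[int, int]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("domain start must be <= end")
        prev_col = 0
        for pos in sorted(self.column_map):
            if not (self.start <= pos <= self.end):
                raise ValueError(
                    f"mapped residue {pos} outside domain bounds "
                    f"[{self.start}, {self.end}]"
                )
            col = self.column_map[pos]
            if col <= prev_col:
                raise ValueError("column map must be strictly increasing")
            prev_col = col

    def column_of(self, position: int) -> int | None:
        """Alignment column for a residue, or None if unmapped."""
        return self.column_map.get(position)

    def residue_of(self, column: int) -> int | None:
        """Residue index aligned to a column in this instance, or None."""
        for pos, col in self.column_map.items():
            if col == column:
                return pos
        return None


@dataclass
class FamilyAlignment:
    """A protein family: model length plus member domain instances."""

    family: str
    model_length: int
    members: list[DomainInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.members:
            if m.column_map and max(m.column_map.values()) > self.model_length:
                raise ValueError(
                    f"instance {m.protein} maps beyond model length "
                    f"{self.model_length}"
                )

    @property
    def n_instances(self) -> int:
        return len(self.members)

    def instances_with_column(self, column: int) -> list[DomainInstance]:
        return [m for m in self.members if column in m.column_map.values()]

    def column_residues(self, sequences: dict[str, str]) -> dict[int, list[str]]:
        """Residue letters observed at each column, over aligned members."""
        out: dict[int, list[str]] = {c: [] for c in range(1, self.model_length + 1)}
        for inst in self.members:
            seq = sequences[inst.protein]
            for pos, col in inst.column_map.items():
                out[col].append(seq[pos - 1])
        return out


@dataclass
class Proteome:
    """Protein sequences, optional coding sequences, and family alignments."""

    sequences: dict[str, str]
    families: list[FamilyAlignment]
    coding: dict[str, str] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def family(self, name: str) -> FamilyAlignment:
        for fa in self.families:
            if fa.family == name:
                return fa
        raise KeyError(name)

    def instances_by_protein(self) -> dict[str, list[DomainInstance]]:
        idx: dict[str, list[DomainInstance]] = {}
        for fa in self.families:
            for inst in fa.members:
                idx.setdefault(inst.protein, []).append(inst)
        return idx
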