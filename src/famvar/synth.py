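"""Synthetic cohorts, proteomes, variant tables and receptor screens.

The generators emulate the inputs of a population-scale protein-family
variant analysis: a diploid cohort with super-population structure, a
proteome organised into family alignments with residue-to-column maps,
per-individual missense and loss-of-function variants, and a
receptor/odorant activity screen. Every generator is deterministic for a
fixed seed and supports planted ground truth (enriched alignment columns,
sub-population-specific loss-of-function fingerprints, canonical vs.
non-canonical receptor activity rates) so downstream statistics can be
tested against known structure.

Scale defaults mirror the per-site allele rate of a large human cohort
(roughly 23M alleles over an 11M-residue proteome across ~5000 haplotypes,
i.e. ~4e-4 alternate alleles per residue per haplotype) on a desk-scale
proteome of a few dozen families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from famvar.containers import (
    AMINO_ACIDS,
    FRAMESHIFT,
    MISSENSE,
    STOP_GAIN,
    DomainInstance,
    FamilyAlignment,
    Proteome,
    VariantRecord,
    VariantTable,
)


class ConfigError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


#: 1000 Genomes Phase III super-population proportions (approximate).
DEFAULT_SUBPOP_WEIGHTS = {
    "AFR": 0.26,
    "EUR": 0.20,
    "EAS": 0.20,
    "SAS": 0.20,
    "AMR": 0.14,
}


@dataclass
class ScreenConfig:
    """Receptor/odorant screen layout and positive rates.

    ``canonical_rate`` / ``noncanonical_rate`` are the probabilities that a
    single receptor-odorant screen is positive for receptors carrying the
    consensus (canonical) or a non-consensus residue at the scored column.
    Positive screens receive a log10 molar EC50 uniform in
    ``log10_ec50_range``; -9 (1 nM) is the strongest potency represented.
    """

    n_receptors: int = 200
    n_odorants: int = 45
    n_noncanonical: int = 24
    canonical_rate: float = 102 / 8815
    noncanonical_rate: float = 1 / 1089
    log10_ec50_range: tuple[float, float] = (-9.0, 0.0)
    exact_counts: bool = False

    def validate(self) -> None:
        if self.n_receptors < 1 or self.n_odorants < 1:
            raise ConfigError("screen sizes must be >= 1")
        if not (0 <= self.n_noncanonical <= self.n_receptors):
            raise ConfigError("n_noncanonical out of range")
        for r in (self.canonical_rate, self.noncanonical_rate):
            if not (0.0 <= r <= 1.0):
                raise ConfigError("positive rates must be in [0, 1]")
        lo, hi = self.log10_ec50_range
        if not (-9.0 <= lo <= hi <= 0.0):
            raise ConfigError("log10 EC50 range must lie within [-9, 0]")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Notes
    -----
    ``base_variant_rate`` is the per-residue, per-haplotype probability of
    carrying an alternate allele; ``planted_positions`` multiplies that rate
    at chosen (family, column) coordinates. ``lof_rates`` are per-gene,
    per-haplotype probabilities of a stop-gain and a frameshift allele.
    ``marker_genes_per_subpop`` plants stop-gain variants whose carrier
    frequency is high inside one sub-population and low outside, giving each
    sub-population a recoverable loss-of-function fingerprint.
    """

    n_individuals: int = 500
    subpop_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBPOP_WEIGHTS)
    )
    n_families: int = 20
    members_per_family: tuple[int, int] = (8, 12)
    model_length: tuple[int, int] = (40, 60)
    flank_length: tuple[int, int] = (5, 15)
    base_variant_rate: float = 4.2e-4
    planted_positions: list[tuple[str, int, float]] = field(default_factory=list)
    lof_rates: tuple[float, float] = (0.02, 0.02)
    conserved_fraction: float = 0.25
    conserved_identity: float = 0.95
    background_identity: float = 0.4
    gap_rate: float = 0.02
    insertion_rate: float = 0.02
    marker_genes_per_subpop: int = 0
    marker_in_freq: float = 0.8
    marker_out_freq: float = 0.01
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_families < 1:
            raise ConfigError("counts must be >= 1")
        total = sum(self.subpop_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"sub-population weights sum to {total}, not 1")
        if any(w < 0 for w in self.subpop_weights.values()):
            raise ConfigError("sub-population weights must be non-negative")
        for lo, hi in (self.members_per_family, self.model_length, self.flank_length):
            if not (1 <= lo <= hi):
                raise ConfigError("count ranges must satisfy 1 <= lo <= hi")
        if self.base_variant_rate < 0:
            raise ConfigError("base_variant_rate must be non-negative")
        for fam, col, mult in self.planted_positions:
            if mult < 1:
                raise ConfigError(f"rate multiplier {mult} at {fam}:{col} is < 1")
            if col < 1:
                raise ConfigError("planted columns are 1-based")
        if any(r < 0 or r > 1 for r in self.lof_rates):
            raise ConfigError("lof rates must be probabilities")
        self.screen.validate()

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one pipeline stage."""
        return np.random.default_rng([self.seed, stream])


# stream offsets so each generator draws from an independent stream
_COHORT, _PROTEOME, _VARIANTS, _SCREEN = 1, 2, 3, 4


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Cohort table with columns ``individual``, ``subpop``, ``sex``."""
    config.validate()
    rng = config.rng(_COHORT)
    labels = sorted(config.subpop_weights)
    weights = np.array([config.subpop_weights[k] for k in labels])
    subpops = rng.choice(labels, size=config.n_individuals, p=weights)
    sexes = rng.choice(["F", "M"], size=config.n_individuals)
    ids = [f"ind{i:05d}" for i in range(config.n_individuals)]
    return pd.DataFrame({"individual": ids, "subpop": subpops, "sex": sexes})


def _back_translate(protein: str, rng: np.random.Generator,
                    codons_by_aa: dict[str, list[str]]) -> str:
    return "".join(
        codons_by_aa[aa][rng.integers(len(codons_by_aa[aa]))] for aa in protein
    )


def _codons_by_amino_acid() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    out: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        out.setdefault(aa, []).append(codon)
    for aa in out:
        out[aa].sort()
    return out


def generate_proteome(config: SyntheticConfig) -> Proteome:
    """Build family alignments, member proteins and coding sequences.

    Each member protein is flank + one domain instance + flank. Within the
    domain, each model column is deleted with probability ``gap_rate``
    (residue absent, column unmapped in that member) and followed by a short
    unmapped insertion with probability ``insertion_rate``. A configured
    fraction of columns is built conserved: members carry the consensus
    residue there with probability ``conserved_identity``.
    """
    config.validate()
    rng = config.rng(_PROTEOME)
    aas = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    codons = _codons_by_amino_acid()

    sequences: dict[str, str] = {}
    coding: dict[str, str] = {}
    families: list[FamilyAlignment] = []
    for f in range(config.n_families):
        fam = f"FAM{f:03d}"
        model_len = int(rng.integers(config.model_length[0],
                                     config.model_length[1] + 1))
        n_members = int(rng.integers(config.members_per_family[0],
                                     config.members_per_family[1] + 1))
        consensus = rng.choice(aas, size=model_len)
        n_cons = int(round(config.conserved_fraction * model_len))
        conserved_cols = set(
            rng.choice(model_len, size=n_cons, replace=False) + 1
        )
        members: list[DomainInstance] = []
        for m in range(n_members):
            pid = f"{fam}_p{m:02d}"
            seq: list[str] = []
            column_map: dict[int, int] = {}
            f1 = int(rng.integers(config.flank_length[0],
                                  config.flank_length[1] + 1))
            seq.extend(rng.choice(aas, size=f1))
            start = f1 + 1
            pos = start
            for col in range(1, model_len + 1):
                if rng.random() < config.gap_rate:
                    continue  # deletion: column unmapped in this member
                ident = (config.conserved_identity if col in conserved_cols
                         else config.background_identity)
                if rng.random() < ident:
                    res = consensus[col - 1]
                else:
                    res = aas[rng.integers(len(aas))]
                seq.append(res)
                column_map[pos] = col
                pos += 1
                if rng.random() < config.insertion_rate:
                    k = int(rng.integers(1, 4))
                    seq.extend(rng.choice(aas, size=k))
                    pos += k
            end = pos - 1
            f2 = int(rng.integers(config.flank_length[0],
                                  config.flank_length[1] + 1))
            seq.extend(rng.choice(aas, size=f2))
            protein = "".join(seq)
            sequences[pid] = protein
            coding[pid] = _back_translate(protein, rng, codons)
            members.append(DomainInstance(fam, pid, start, end, column_map))
        families.append(FamilyAlignment(fam, model_len, members))
    return Proteome(sequences=sequences, families=families, coding=coding)


def _per_residue_rates(proteome: Proteome,
                       config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Per-haplotype missense rate for every residue of every protein."""
    rates = {
        pid: np.full(len(seq), config.base_variant_rate)
        for pid, seq in proteome.sequences.items()
    }
    for fam_name, col, mult in config.planted_positions:
        fa = proteome.family(fam_name)
        if col > fa.model_length:
            raise ConfigError(
                f"planted column {col} exceeds model length {fa.model_length} "
                f"of {fam_name}"
            )
        for inst in fa.members:
            pos = inst.residue_of(col)
            if pos is not None:
                rates[inst.protein][pos - 1] *= mult
    return rates


def _sample_genotypes(n_individuals: int, k_alleles: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Place k alternate alleles on distinct haplotypes of a diploid cohort."""
    haps = rng.choice(2 * n_individuals, size=k_alleles, replace=False)
    return np.bincount(haps // 2, minlength=n_individuals).astype(np.int8)


def generate_variants(proteome: Proteome, cohort: pd.DataFrame,
                      config: SyntheticConfig) -> VariantTable:
    """Draw per-individual diploid variants over the proteome.

    Missense alleles are Bernoulli per residue per haplotype at the
    (possibly planted-multiplied) rate; each polymorphic residue becomes one
    variant record with a single alternate residue. Stop-gain and frameshift
    alleles are drawn per gene per haplotype at ``lof_rates`` and carry a
    class marker instead of an alternate residue. Sub-population marker
    genes, when configured, receive an extra stop-gain whose per-haplotype
    frequency is ``marker_in_freq`` inside the target sub-population and
    ``marker_out_freq`` outside.
    """
    config.validate()
    rng = config.rng(_VARIANTS)
    n = len(cohort)
    n_hap = 2 * n
    rates = _per_residue_rates(proteome, config)
    aas = list(AMINO_ACIDS)

    variants: list[VariantRecord] = []
    for pid, seq in proteome.sequences.items():
        ks = rng.binomial(n_hap, np.minimum(rates[pid], 1.0))
        for i in np.flatnonzero(ks):
            ref = seq[i]
            alt = aas[rng.integers(len(aas))]
            while alt == ref:
                alt = aas[rng.integers(len(aas))]
            counts = _sample_genotypes(n, int(ks[i]), rng)
            variants.append(
                VariantRecord(pid, int(i) + 1, ref, alt, MISSENSE, counts)
            )
        for rate, consequence, marker in (
            (config.lof_rates[0], STOP_GAIN, "*"),
            (config.lof_rates[1], FRAMESHIFT, "fs"),
        ):
            if rate <= 0:
                continue
            k = int(rng.binomial(n_hap, rate))
            if k == 0:
                continue
            pos = int(rng.integers(len(seq))) + 1
            counts = _sample_genotypes(n, k, rng)
            variants.append(
                VariantRecord(pid, pos, seq[pos - 1], marker, consequence, counts)
            )

    variants.extend(_marker_variants(proteome, cohort, config, rng))
    return VariantTable(variants, list(cohort["individual"]))


def _marker_variants(proteome: Proteome, cohort: pd.DataFrame,
                     config: SyntheticConfig,
                     rng: np.random.Generator) -> list[VariantRecord]:
    if config.marker_genes_per_subpop <= 0:
        return []
    subpops = sorted(cohort["subpop"].unique())
    proteins = list(proteome.sequences)
    needed = config.marker_genes_per_subpop * len(subpops)
    if needed > len(proteins):
        raise ConfigError("not enough proteins for the requested marker genes")
    membership = cohort["subpop"].to_numpy()
    out: list[VariantRecord] = []
    gene_iter = iter(proteins)
    for sp in subpops:
        in_group = membership == sp
        for _ in range(config.marker_genes_per_subpop):
            pid = next(gene_iter)
            seq = proteome.sequences[pid]
            freqs = np.where(in_group, config.marker_in_freq,
                             config.marker_out_freq)
            counts = rng.binomial(2, freqs).astype(np.int8)
            if counts.sum() == 0:
                continue
            # fixed marker position 1 residue in from the C-terminus
            pos = max(1, len(seq) - 1)
            out.append(
                VariantRecord(pid, pos, seq[pos - 1], "*", STOP_GAIN, counts)
            )
    return out


def generate_screen(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Receptor x odorant screen table plus ground-truth canonical flags.

    Returns a DataFrame with columns ``receptor``, ``odorant``,
    ``log10_ec50`` (NaN for negative screens) and a dict mapping receptor id
    to True (canonical) / False (non-canonical). With ``exact_counts`` the
    number of positives per group is ``round(rate * n_screens)`` placed
    uniformly at random rather than Bernoulli per screen.
    """
    config.validate()
    sc = config.screen
    rng = config.rng(_SCREEN)
    receptors = [f"OR{i:04d}" for i in range(sc.n_receptors)]
    odorants = [f"odor{j:03d}" for j in range(sc.n_odorants)]
    noncanon = set(
        rng.choice(sc.n_receptors, size=sc.n_noncanonical, replace=False)
    )
    status = {r: (i not in noncanon) for i, r in enumerate(receptors)}

    rec_col = np.repeat(receptors, sc.n_odorants)
    odo_col = np.tile(odorants, sc.n_receptors)
    canonical = np.repeat([status[r] for r in receptors], sc.n_odorants)

    if sc.exact_counts:
        positive = np.zeros(rec_col.size, dtype=bool)
        for mask, rate in ((canonical, sc.canonical_rate),
                           (~canonical, sc.noncanonical_rate)):
            idx = np.flatnonzero(mask)
            k = int(round(rate * idx.size))
            if k:
                positive[rng.choice(idx, size=k, replace=False)] = True
    else:
        p = np.where(canonical, sc.canonical_rate, sc.noncanonical_rate)
        positive = rng.random(rec_col.size) < p

    lo, hi = sc.log10_ec50_range
    ec50 = np.full(rec_col.size, np.nan)
    ec50[positive] = rng.uniform(lo, hi, size=int(positive.sum()))
    screen = pd.DataFrame(
        {"receptor": rec_col, "odorant": odo_col, "log10_ec50": ec50}
    )
    return screen, status


def screen_from_contingency(
    n_canonical: int,
    k_canonical: int,
    n_noncanonical: int,
    k_noncanonical: int,
    log10_ec50: float = -9.0,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Deterministic one-odorant screen with exact per-group positive counts.

    Useful for reproducing published contingency tables: each screen is one
    receptor tested against a single odorant, with the first ``k`` screens of
    each group positive at the given potency.
    """
    if not (0 <= k_canonical <= n_canonical and 0 <= k_noncanonical <= n_noncanonical):
        raise ConfigError("positives cannot exceed screens")
    rows = []
    status: dict[str, bool] = {}
    for group, n_scr, k_pos, canon in (
        ("can", n_canonical, k_canonical, True),
        ("non", n_noncanonical, k_noncanonical, False),
    ):
        for i in range(n_scr):
            rid = f"{group}{i:05d}"
            status[rid] = canon
            rows.append(
                (rid, "odor000", log10_ec50 if i < k_pos else np.nan)
            )
    screen = pd.DataFrame(rows, columns=["receptor", "odorant", "log10_ec50"])
    return screen, status
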