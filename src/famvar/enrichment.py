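"""Variant enrichment at family alignment positions.

The model: alternate alleles pooled over a diploid cohort are compared,
per alignment column, against the count expected if alleles fell uniformly
over the proteome. With A total alleles over a proteome of P residues, a
column mapped in I domain instances expects ``A / P * I`` alleles (a whole
family of model length L expects ``A / P * I * L``). Enrichment is the
base-2 log-odds of observed over expected. Significance comes from an
upper-tail binomial test whose per-allele success probability (the prior)
is estimated by shuffling every individual's missense variants uniformly
within their own protein, so the prior inherits the proteome's domain
composition rather than assuming exact uniformity. P-values are corrected
by Benjamini-Hochberg over the tested set — positions with at least 50
observed or 5 expected alleles.

The entry point is :class:`PositionEnrichment`; ``fit()`` returns a
:class:`PositionEnrichmentResults` carrying the per-column table,
descriptive statistics (population fraction, identical-pair counts), and
the enrichment filter.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from famvar.containers import Proteome, VariantTable
from famvar.mapping import compute_consensus, map_table_to_columns

__all__ = [
    "PositionEnrichment",
    "PositionEnrichmentResults",
    "expected_count",
    "log_odds",
    "shuffle_prior",
    "analytic_shuffle_prior",
    "binomial_pvalue",
    "bh_fdr",
    "enriched_positions",
    "population_fraction",
    "identical_spectrum_pairs",
    "gene_fraction_by_subgroup",
    "position_zscores",
    "codon_cg_fraction",
]


def expected_count(total_alleles: float, proteome_length: int,
                   n_instances: int, span: int) -> float:
    """Expected alleles under uniform placement over the proteome.

    ``span`` is the family model length for a whole-family expectation and
    1 for a single column.
    """
    if proteome_length <= 0:
        raise ValueError("proteome length must be positive")
    return total_alleles / proteome_length * n_instances * span


def log_odds(observed: float, expected: float) -> float:
    """Base-2 log of observed over expected; -inf when nothing observed."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if observed == 0:
        return -math.inf
    return math.log2(observed / expected)


def binomial_pvalue(k_observed: int, n_trials: int, prior: float) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(n, prior)."""
    if not (0 <= k_observed <= n_trials):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 <= prior <= 1.0):
        raise ValueError("prior must be in [0, 1]")
    if k_observed == 0:
        return 1.0
    return float(stats.binom.sf(k_observed - 1, n_trials, prior))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up Q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _target_residues(proteome: Proteome, target) -> dict[str, list[int]]:
    """Residues of each protein mapping into the target family or column."""
    out: dict[str, list[int]] = {}
    if isinstance(target, str):
        fa = proteome.family(target)
        for inst in fa.members:
            out.setdefault(inst.protein, []).extend(inst.column_map.keys())
    else:
        family, column = target
        fa = proteome.family(family)
        for inst in fa.members:
            pos = inst.residue_of(column)
            if pos is not None:
                out.setdefault(inst.protein, []).append(pos)
    return out


def analytic_shuffle_prior(variants: VariantTable, proteome: Proteome,
                           target) -> float:
    """Closed-form limit of the shuffle prior.

    Equals sum over proteins of (alleles_in_protein * mapped_residues /
    protein_length) divided by the total allele count.
    """
    missense = variants.missense()
    per_protein: dict[str, int] = {}
    for v in missense:
        per_protein[v.protein] = per_protein.get(v.protein, 0) + v.pooled_count
    total = sum(per_protein.values())
    if total == 0:
        return 0.0
    mapped = _target_residues(proteome, target)
    hit = sum(
        alleles * len(mapped.get(pid, [])) / len(proteome.sequences[pid])
        for pid, alleles in per_protein.items()
    )
    return hit / total


def shuffle_prior(variants: VariantTable, proteome: Proteome, target,
                  n_shuffles: int = 100, seed: int | None = None) -> float:
    """Per-allele success probability from within-protein shuffling.

    Every individual's missense alleles are relocated uniformly at random
    within their own protein (collisions allowed); the returned prior is
    the mean fraction of alleles landing on the target — a (family, column)
    pair or a whole family name — over ``n_shuffles`` shuffles.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    rng = np.random.default_rng(seed)
    missense = variants.missense()
    per_protein: dict[str, int] = {}
    for v in missense:
        per_protein[v.protein] = per_protein.get(v.protein, 0) + v.pooled_count
    total = sum(per_protein.values())
    if total == 0:
        return 0.0
    mapped = _target_residues(proteome, target)
    hits = np.zeros(n_shuffles, dtype=np.int64)
    for pid, alleles in per_protein.items():
        m = len(mapped.get(pid, []))
        if m == 0:
            continue
        length = len(proteome.sequences[pid])
        hits += rng.binomial(alleles, m / length, size=n_shuffles)
    return float(hits.mean() / total)


def enriched_positions(results: pd.DataFrame, min_observed: int = 50,
                       min_expected: float = 5.0, min_log_odds: float = 1.0,
                       max_q: float = 0.01,
                       min_genes: int | None = 10) -> pd.DataFrame:
    """Apply the enrichment filters (all thresholds inclusive).

    Keeps rows with (observed >= min_observed OR expected >= min_expected)
    AND log_odds >= min_log_odds AND q <= max_q, optionally requiring at
    least ``min_genes`` member genes with variants at the position.
    """
    keep = (
        ((results["observed_alleles"] >= min_observed)
         | (results["expected_alleles"] >= min_expected))
        & (results["log_odds"] >= min_log_odds)
        & (results["q_value"] <= max_q)
    )
    if min_genes is not None:
        keep &= results["n_genes_with_variants"] >= min_genes
    return results[keep.fillna(False)]


def population_fraction(genotype_block: np.ndarray) -> float:
    """Fraction of individuals carrying >= 1 alternate allele at a position.

    ``genotype_block`` is the (n_variants_at_position, n_individuals)
    allele-count matrix of all variants mapping to one column.
    """
    if genotype_block.size == 0:
        return 0.0
    return float((genotype_block > 0).any(axis=0).mean())


def identical_spectrum_pairs(genotype_block: np.ndarray) -> int:
    """Unordered pairs of individuals with identical variant spectra.

    Individuals are compared on their full allele-count vector over the
    variants mapping to one column; with no variants everyone matches,
    giving C(n, 2).
    """
    if genotype_block.ndim != 2:
        raise ValueError("expected a (variants, individuals) matrix")
    n = genotype_block.shape[1]
    if genotype_block.shape[0] == 0:
        return n * (n - 1) // 2
    _, counts = np.unique(genotype_block, axis=1, return_counts=True)
    return int(np.sum(counts * (counts - 1) // 2))


def gene_fraction_by_subgroup(hit_genes: set[str],
                              mapped_genes_by_group: dict[str, set[str]],
                              ) -> dict[str, float]:
    """Per group: fraction of its column-mapped genes carrying a variant.

    Groups with no mapped gene report NaN.
    """
    out = {}
    for group, genes in mapped_genes_by_group.items():
        if not genes:
            out[group] = float("nan")
        else:
            out[group] = len(hit_genes & genes) / len(genes)
    return out


def position_zscores(counts) -> np.ndarray:
    """Standard scores of per-column counts (population standard deviation)."""
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ValueError("need counts for at least two columns")
    sd = c.std(ddof=0)
    if sd == 0:
        return np.zeros_like(c)
    return (c - c.mean()) / sd


def codon_cg_fraction(residues, coding: dict[str, str]) -> float:
    """Percent of residues whose codon contains the CG dinucleotide.

    Within-codon only: the four CGN arginine codons qualify, AGA/AGG do
    not. ``residues`` is an iterable of (protein, 1-based position).
    """
    residues = list(residues)
    if not residues:
        raise ValueError("empty residue set")
    n_cg = 0
    for pid, pos in residues:
        cds = coding[pid]
        codon = cds[3 * (pos - 1): 3 * pos]
        if len(codon) != 3:
            raise ValueError(f"{pid}:{pos} has no codon in the coding sequence")
        n_cg += "CG" in codon.upper()
    return 100.0 * n_cg / len(residues)


class PositionEnrichment:
    """Per-column variant enrichment model over a proteome and cohort.

    Parameters
    ----------
    variants : VariantTable
        Diploid variant table; only missense records enter the counting
        (loss-of-function classes are retained for fingerprints elsewhere).
    proteome : Proteome
        Sequences plus family alignments with residue-to-column maps.
    conservation_threshold : float
        Modal-frequency threshold for flagging a column conserved.
    """

    def __init__(self, variants: VariantTable, proteome: Proteome,
                 conservation_threshold: float = 0.5):
        self.variants = variants
        self.proteome = proteome
        self.conservation_threshold = conservation_threshold

    def fit(self, n_shuffles: int = 100, seed: int | None = None,
            min_observed: int = 50,
            min_expected: float = 5.0) -> "PositionEnrichmentResults":
        """Compute per-column and per-family enrichment statistics.

        The shuffle-prior is estimated once for the whole proteome: each
        shuffle relocates every protein's pooled missense alleles uniformly
        within that protein, and landed counts are accumulated per column.
        ``min_observed`` / ``min_expected`` define the tested set over
        which Benjamini-Hochberg correction runs (one global family).
        """
        rng = np.random.default_rng(seed)
        proteome = self.proteome
        missense = self.variants.missense()
        proteome_length = proteome.total_length

        per_protein: dict[str, int] = {}
        for v in missense:
            per_protein[v.protein] = per_protein.get(v.protein, 0) + v.pooled_count
        total_alleles = sum(per_protein.values())

        hits = map_table_to_columns(missense, proteome)
        genotypes = missense.genotypes()

        # one set of shuffles shared by every column and family
        col_index: dict[tuple[str, int], int] = {}
        fam_index: dict[str, int] = {}
        col_residues: dict[str, list[tuple[int, int]]] = {}
        for fa in proteome.families:
            fam_index[fa.family] = len(fam_index)
            for inst in fa.members:
                lst = col_residues.setdefault(inst.protein, [])
                for pos, col in inst.column_map.items():
                    key = (fa.family, col)
                    if key not in col_index:
                        col_index[key] = len(col_index)
                    lst.append((pos, col_index[key]))
        n_cols = len(col_index)
        col_hits = np.zeros((n_cols, n_shuffles), dtype=np.int64)
        col_analytic = np.zeros(n_cols)
        if total_alleles > 0:
            for pid, alleles in per_protein.items():
                residues = col_residues.get(pid)
                if not residues:
                    continue
                length = len(proteome.sequences[pid])
                placed = rng.multinomial(
                    alleles, np.full(length, 1.0 / length), size=n_shuffles
                )  # (n_shuffles, length)
                for pos, ci in residues:
                    col_hits[ci] += placed[:, pos - 1]
                    col_analytic[ci] += alleles / length
        col_prior = col_hits.mean(axis=1) / max(total_alleles, 1)
        # a zero shuffle estimate on a column with observed alleles would give
        # p = 0; fall back to the closed-form limit of the shuffle prior there
        zero = col_prior == 0
        col_prior[zero] = col_analytic[zero] / max(total_alleles, 1)

        rows = []
        gt_blocks: dict[tuple[str, int], np.ndarray] = {}
        for fa in proteome.families:
            consensus = compute_consensus(
                fa, proteome.sequences, self.conservation_threshold
            )
            fam_hits = hits[hits["family"] == fa.family]
            for col in range(1, fa.model_length + 1):
                n_inst = len(fa.instances_with_column(col))
                if n_inst == 0:
                    continue
                at_col = fam_hits[fam_hits["column"] == col]
                observed = int(at_col["pooled_count"].sum())
                expected = expected_count(
                    total_alleles, proteome_length, n_inst, 1
                )
                block = genotypes[at_col["variant_index"].to_numpy()]
                gt_blocks[(fa.family, col)] = block
                prior = float(col_prior[col_index[(fa.family, col)]])
                p = (binomial_pvalue(observed, total_alleles, prior)
                     if total_alleles > 0 else 1.0)
                rows.append({
                    "family": fa.family,
                    "column": col,
                    "observed_alleles": observed,
                    "expected_alleles": expected,
                    "log_odds": log_odds(observed, expected),
                    "prior": prior,
                    "p_value": p,
                    "n_genes_with_variants": at_col["protein"].nunique(),
                    "n_instances": n_inst,
                    "conserved": bool(consensus.loc[col, "conserved"]),
                    "consensus_residue": consensus.loc[col, "residue"],
                    "population_fraction": population_fraction(block),
                    "identical_pairs": identical_spectrum_pairs(block),
                })
        table = pd.DataFrame(rows)
        if len(table):
            tested = ((table["observed_alleles"] >= min_observed)
                      | (table["expected_alleles"] >= min_expected))
            table["tested"] = tested
            table["q_value"] = np.nan
            if tested.any():
                table.loc[tested, "q_value"] = bh_fdr(
                    table.loc[tested, "p_value"].to_numpy()
                )

        family_table = self._fit_families(per_protein, total_alleles,
                                          proteome_length, hits, n_shuffles,
                                          rng)
        return PositionEnrichmentResults(self, table, family_table,
                                         total_alleles, proteome_length,
                                         gt_blocks)

    def _fit_families(self, per_protein, total_alleles, proteome_length,
                      hits, n_shuffles, rng) -> pd.DataFrame:
        rows = []
        for fa in self.proteome.families:
            observed = int(
                hits.loc[hits["family"] == fa.family, "pooled_count"].sum()
            )
            expected = expected_count(total_alleles, proteome_length,
                                      fa.n_instances, fa.model_length)
            if total_alleles > 0:
                shuffles = np.zeros(n_shuffles, dtype=np.int64)
                mapped = _target_residues(self.proteome, fa.family)
                for pid, alleles in per_protein.items():
                    m = len(mapped.get(pid, []))
                    if m:
                        shuffles += rng.binomial(
                            alleles, m / len(self.proteome.sequences[pid]),
                            size=n_shuffles,
                        )
                prior = float(shuffles.mean() / total_alleles)
                if prior == 0:
                    prior = analytic_shuffle_prior(
                        self.variants, self.proteome, fa.family
                    )
                p = binomial_pvalue(observed, total_alleles, prior)
            else:
                prior, p = 0.0, 1.0
            rows.append({
                "family": fa.family,
                "observed_alleles": observed,
                "expected_alleles": expected,
                "log_odds": log_odds(observed, expected),
                "prior": prior,
                "p_value": p,
            })
        table = pd.DataFrame(rows)
        if len(table):
            table["q_value"] = bh_fdr(table["p_value"].to_numpy())
        return table


class PositionEnrichmentResults:
    """Fitted per-column enrichment statistics.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per (family, column) with observed/expected counts,
        log-odds, shuffle prior, p and Q values, conservation flag,
        population fraction and identical-pair count.
    family_table : pandas.DataFrame
        Whole-family equivalents.
    """

    def __init__(self, model: PositionEnrichment, table: pd.DataFrame,
                 family_table: pd.DataFrame, total_alleles: int,
                 proteome_length: int,
                 genotype_blocks: dict[tuple[str, int], np.ndarray]):
        self.model = model
        self.table = table
        self.family_table = family_table
        self.total_alleles = total_alleles
        self.proteome_length = proteome_length
        self._genotype_blocks = genotype_blocks

    def enriched(self, min_observed: int = 50, min_expected: float = 5.0,
                 min_log_odds: float = 1.0, max_q: float = 0.01,
                 min_genes: int | None = 10) -> pd.DataFrame:
        """Positions passing the enrichment filters, sorted by log-odds."""
        out = enriched_positions(self.table, min_observed, min_expected,
                                 min_log_odds, max_q, min_genes)
        return out.sort_values("log_odds", ascending=False)

    def genotype_block(self, family: str, column: int) -> np.ndarray:
        """Allele-count matrix of the variants mapping to one column."""
        return self._genotype_blocks[(family, column)]

    def summary(self, top: int = 10) -> str:
        lines = [
            "Position enrichment results",
            "=" * 60,
            f"proteome length:      {self.proteome_length} aa",
            f"total pooled alleles: {self.total_alleles}",
            f"columns evaluated:    {len(self.table)}",
        ]
        if len(self.table):
            n_tested = int(self.table["tested"].sum())
            enr = self.enriched(min_genes=None)
            lines.append(f"columns tested (count floor): {n_tested}")
            lines.append(f"enriched (log-odds>=1, Q<=0.01): {len(enr)}")
            cols = ["family", "column", "observed_alleles",
                    "expected_alleles", "log_odds", "q_value", "conserved"]
            lines.append("")
            lines.append(enr[cols].head(top).to_string(index=False))
        return "\n".join(lines)
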