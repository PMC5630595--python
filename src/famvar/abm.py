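"""Odorant-driven agent-based model of movement, mating and mutation.

Genotyped animals live on a discrete grid (default 200 x 200, one animal
per cell) scattered with point odorant sources. Each animal carries a
diploid genotype over ``n_genes`` receptor loci; every allele is a receptor
profile responding to 1-14 odorants with attraction (+1) or repulsion (-1),
drawn with equal probability. The net drive on animal ``a`` is

    m_a = sum_i sum_j AR_ij / d_ia * (o_i - p_a) / ||o_i - p_a||

over odorants ``i`` and the animal's receptors ``j``, where ``d_ia`` is the
animal-odorant distance. Each step every animal moves one grid point —
with probability ``fraction_odor_driven`` along the unit vector of
``m_a`` (components rounded to {-1, 0, 1}), otherwise to a uniformly
random neighbour; moves into occupied or out-of-bounds cells are
cancelled. After moving, adjacent opposite-sex pairs mate with probability
``mating_probability`` when at least ``min_empty_cells`` neighbouring
cells of one parent are free; the offspring inherits one allele per locus
from each parent, each allele mutating to a random pool allele with
probability ``mutation_rate``, and is placed next to that parent.

Diploidy is resolved per locus as the sign of the two alleles' summed
responses (conflicting attraction/repulsion cancels). The grid has hard
walls; animals never die, so population changes only through births.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = ["ABMConfig", "World", "spawn_offspring", "diversity_metric",
           "run"]

_NEIGHBOURS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


@dataclass
class ABMConfig:
    """Simulation parameters; defaults are the reference scenario."""

    grid: tuple[int, int] = (200, 200)
    n_odorants: int = 50
    n_founders: int = 40
    n_genes: int = 100
    max_ligands: int = 14
    alleles_per_locus: int = 8
    fraction_odor_driven: float = 0.5
    mating_probability: float = 0.3
    mutation_rate: float = 0.05
    min_empty_cells: int = 5
    seed: int = 0

    def validate(self) -> None:
        gx, gy = self.grid
        if gx < 2 or gy < 2:
            raise ValueError("grid too small")
        if self.n_founders > gx * gy:
            raise ValueError("more founders than grid cells")
        if not (0.0 <= self.fraction_odor_driven <= 1.0):
            raise ValueError("fraction_odor_driven must be in [0, 1]")
        for p in (self.mating_probability, self.mutation_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        if self.max_ligands < 1:
            raise ValueError("alleles need at least one ligand")


def _random_allele_pool(config: ABMConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """(n_genes, alleles_per_locus, n_odorants) response array in {-1,0,1}."""
    pool = np.zeros(
        (config.n_genes, config.alleles_per_locus, config.n_odorants),
        dtype=np.int8,
    )
    max_lig = min(config.max_ligands, config.n_odorants)
    if max_lig == 0:
        return pool
    for g in range(config.n_genes):
        for a in range(config.alleles_per_locus):
            k = int(rng.integers(1, max_lig + 1))
            ligands = rng.choice(config.n_odorants, size=k, replace=False)
            pool[g, a, ligands] = rng.choice([-1, 1], size=k)
    return pool


def spawn_offspring(g1: np.ndarray, g2: np.ndarray,
                    alleles_per_locus: int, mutation_rate: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Offspring genotype from two parents; returns (genotype, n_mutations).

    One allele per locus is drawn uniformly from each parent's pair; each
    inherited allele is then independently replaced by a uniformly random
    pool allele with probability ``mutation_rate``.
    """
    n_genes = g1.shape[0]
    loci = np.arange(n_genes)
    child = np.stack(
        [g1[loci, rng.integers(2, size=n_genes)],
         g2[loci, rng.integers(2, size=n_genes)]],
        axis=1,
    )
    mutated = rng.random((n_genes, 2)) < mutation_rate
    n_mut = int(mutated.sum())
    if n_mut:
        child[mutated] = rng.integers(alleles_per_locus, size=n_mut)
    return child, n_mut


def diversity_metric(genotypes: list[np.ndarray],
                     max_individuals: int = 200,
                     rng: np.random.Generator | None = None) -> float:
    """Mean pairwise genotype mismatch fraction.

    Allele pairs at each locus are order-normalised, then two animals are
    compared slot by slot over all 2 x n_genes allele slots; the metric is
    the mismatch fraction averaged over all animal pairs. Populations
    larger than ``max_individuals`` are subsampled.
    """
    if len(genotypes) < 2:
        raise ValueError("need at least two animals")
    g = np.sort(np.stack(genotypes), axis=2)  # (n, genes, 2)
    n = g.shape[0]
    if n > max_individuals:
        if rng is None:
            rng = np.random.default_rng(0)
        g = g[rng.choice(n, size=max_individuals, replace=False)]
        n = max_individuals
    flat = g.reshape(n, -1)
    total = 0.0
    n_pairs = 0
    for i in range(n - 1):
        total += (flat[i + 1:] != flat[i]).mean(axis=1).sum()
        n_pairs += n - 1 - i
    return total / n_pairs


class World:
    """Grid world state: odorants, animals, occupancy, counters."""

    def __init__(self, config: ABMConfig,
                 odorants: np.ndarray | None = None,
                 positions: np.ndarray | None = None,
                 sexes: list[str] | None = None,
                 genotypes: list[np.ndarray] | None = None,
                 allele_pool: np.ndarray | None = None):
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self._metric_rng = np.random.default_rng([config.seed, 9999])
        gx, gy = config.grid

        if odorants is None:
            cells = self.rng.choice(gx * gy, size=config.n_odorants,
                                    replace=False)
            odorants = np.column_stack([cells // gy, cells % gy])
        self.odorants = np.asarray(odorants, dtype=np.int64)
        if self.odorants.size and (
            self.odorants.min() < 0
            or self.odorants[:, 0].max() >= gx
            or self.odorants[:, 1].max() >= gy
        ):
            raise ValueError("odorant outside grid bounds")

        self.allele_pool = (
            _random_allele_pool(config, self.rng)
            if allele_pool is None else np.asarray(allele_pool, dtype=np.int8)
        )

        if positions is None:
            positions = self._founder_block(config.n_founders)
        self.positions: list[np.ndarray] = [
            np.asarray(p, dtype=np.int64) for p in positions
        ]
        n = len(self.positions)
        if sexes is None:
            sexes = list(self.rng.choice(["F", "M"], size=n))
        self.sexes = list(sexes)
        if genotypes is None:
            genotypes = [
                self.rng.integers(self.allele_pool.shape[1],
                                  size=(config.n_genes, 2))
                for _ in range(n)
            ]
        self.genotypes = [np.asarray(g) for g in genotypes]
        self.net_ar = [self._effective_response(g) for g in self.genotypes]

        self.occupancy: dict[tuple[int, int], int] = {}
        for i, p in enumerate(self.positions):
            key = (int(p[0]), int(p[1]))
            if key in self.occupancy:
                raise ValueError(f"two animals share cell {key}")
            self.occupancy[key] = i

        self.step_count = 0
        self.n_matings = 0
        self.n_offspring_alleles = 0
        self.n_mutation_events = 0

    # -- construction helpers ------------------------------------------------

    def _founder_block(self, n: int) -> list[np.ndarray]:
        """Founders fill a centred square block, row-major."""
        gx, gy = self.config.grid
        side = int(np.ceil(np.sqrt(n)))
        x0, y0 = (gx - side) // 2, (gy - side) // 2
        cells = [(x0 + i // side, y0 + i % side) for i in range(n)]
        return [np.array(c, dtype=np.int64) for c in cells]

    def _effective_response(self, genotype: np.ndarray) -> np.ndarray:
        """Per-odorant net response: sign of summed allele responses per locus."""
        a1 = self.allele_pool[np.arange(self.config.n_genes), genotype[:, 0]]
        a2 = self.allele_pool[np.arange(self.config.n_genes), genotype[:, 1]]
        return np.sign(a1 + a2).sum(axis=0).astype(np.float64)

    # -- dynamics ------------------------------------------------------------

    @property
    def population(self) -> int:
        return len(self.positions)

    def attraction_vector(self, index: int) -> np.ndarray:
        """Net attraction/repulsion drive m_a for one animal.

        Each odorant contributes its net receptor response divided by the
        distance, along the unit vector toward the odorant; an odorant on
        the animal's own cell (distance zero) contributes nothing.
        """
        pos = self.positions[index]
        diffs = self.odorants - pos
        d2 = (diffs ** 2).sum(axis=1).astype(np.float64)
        ok = d2 > 0
        if not ok.any():
            return np.zeros(2)
        # AR/d * diff/||diff|| = AR * diff / d^2
        weights = self.net_ar[index][ok] / d2[ok]
        return (weights[:, None] * diffs[ok]).sum(axis=0)

    def _step_delta(self, index: int) -> np.ndarray:
        if self.rng.random() < self.config.fraction_odor_driven:
            m = self.attraction_vector(index)
            norm = np.hypot(m[0], m[1])
            if norm > 0:
                return np.rint(m / norm).astype(np.int64)
        return _NEIGHBOURS[self.rng.integers(8)]

    def _try_move(self, index: int) -> None:
        delta = self._step_delta(index)
        if delta[0] == 0 and delta[1] == 0:
            return
        pos = self.positions[index]
        target = (int(pos[0] + delta[0]), int(pos[1] + delta[1]))
        gx, gy = self.config.grid
        if not (0 <= target[0] < gx and 0 <= target[1] < gy):
            return
        if target in self.occupancy:
            return
        del self.occupancy[(int(pos[0]), int(pos[1]))]
        self.occupancy[target] = index
        self.positions[index] = np.array(target, dtype=np.int64)

    def _empty_neighbours(self, pos: np.ndarray) -> list[tuple[int, int]]:
        gx, gy = self.config.grid
        out = []
        for dx, dy in _NEIGHBOURS:
            cell = (int(pos[0] + dx), int(pos[1] + dy))
            if (0 <= cell[0] < gx and 0 <= cell[1] < gy
                    and cell not in self.occupancy):
                out.append(cell)
        return out

    def _adjacent_mates(self, index: int, mated: set[int]) -> list[int]:
        pos = self.positions[index]
        partners = []
        for dx, dy in _NEIGHBOURS:
            cell = (int(pos[0] + dx), int(pos[1] + dy))
            j = self.occupancy.get(cell)
            if (j is not None and j not in mated
                    and self.sexes[j] != self.sexes[index]):
                partners.append(j)
        return partners

    def _spawn(self, i: int, j: int) -> None:
        cfg = self.config
        # offspring placement requires breathing room around one parent
        for parent in (i, j):
            empty = self._empty_neighbours(self.positions[parent])
            if len(empty) >= cfg.min_empty_cells:
                child, n_mut = spawn_offspring(
                    self.genotypes[i], self.genotypes[j],
                    self.allele_pool.shape[1], cfg.mutation_rate, self.rng,
                )
                cell = empty[self.rng.integers(len(empty))]
                idx = len(self.positions)
                self.positions.append(np.array(cell, dtype=np.int64))
                self.sexes.append(str(self.rng.choice(["F", "M"])))
                self.genotypes.append(child)
                self.net_ar.append(self._effective_response(child))
                self.occupancy[cell] = idx
                self.n_matings += 1
                self.n_offspring_alleles += 2 * cfg.n_genes
                self.n_mutation_events += n_mut
                return

    def step(self) -> None:
        """One cycle: move every animal, then resolve matings."""
        order = self.rng.permutation(self.population)
        for i in order:
            self._try_move(int(i))
        mated: set[int] = set()
        order = self.rng.permutation(self.population)
        for i in order:
            i = int(i)
            if i in mated:
                continue
            partners = self._adjacent_mates(i, mated)
            if not partners:
                continue
            j = int(partners[self.rng.integers(len(partners))])
            if self.rng.random() < self.config.mating_probability:
                mated.add(i)
                mated.add(j)
                self._spawn(i, j)
        self.step_count += 1

    # -- metrics -------------------------------------------------------------

    def community_count(self, radius: int = 2) -> int:
        """Connected components of animals within Chebyshev distance 2."""
        n = self.population
        if n == 0:
            return 0
        pts = np.stack(self.positions)
        pairs = cKDTree(pts).query_pairs(r=radius, p=np.inf,
                                         output_type="ndarray")
        if len(pairs) == 0:
            return n
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        return int(connected_components(adj, directed=False)[0])

    def diversity(self) -> float:
        return diversity_metric(self.genotypes, rng=self._metric_rng)

    def mean_odorant_distance(self) -> float:
        """Mean Euclidean distance from each animal to its nearest odorant."""
        pts = np.stack(self.positions).astype(float)
        d = np.linalg.norm(
            pts[:, None, :] - self.odorants[None, :, :], axis=2
        )
        return float(d.min(axis=1).mean())


def run(world: World, n_steps: int, record_every: int = 10) -> pd.DataFrame:
    """Advance the world and record metrics every ``record_every`` steps.

    Returns a time series of population size, spatial community count,
    genetic diversity and cumulative mating/mutation counters; the initial
    state is always the first row and the final state the last.
    """
    records = []

    def snapshot():
        records.append({
            "step": world.step_count,
            "population": world.population,
            "n_communities": world.community_count(),
            "diversity": (world.diversity() if world.population >= 2
                          else float("nan")),
            "n_matings": world.n_matings,
            "n_mutation_events": world.n_mutation_events,
        })

    snapshot()
    for t in range(1, n_steps + 1):
        world.step()
        if t % record_every == 0 or t == n_steps:
            snapshot()
    return pd.DataFrame(records)
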