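"""Genetic map, meiosis, crossing and single-seed-descent advancement.

Meiosis follows the classical count-location model without interference: the
number of crossovers per chromosome is Poisson with mean equal to the map
length in Morgans, crossover locations are uniform along the chromosome, and
the starting phase of the transmitted mosaic is a fair coin flip.  Gametes are
built marker-wise as a mosaic of the parent's two haplotypes, which keeps
identity-by-descent bookkeeping exact: an allele can only come from one of the
two parental haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Safflower is n = 12; used when no map is supplied.
DEFAULT_N_CHROMOSOMES = 12
DEFAULT_CHROM_LENGTH_M = 1.0

__all__ = [
    "GeneticMap",
    "Individual",
    "make_gamete",
    "cross",
    "self_pollinate",
    "advance_ssd",
]


@dataclass
class GeneticMap:
    """Marker positions on a multi-chromosome map, lengths in Morgans."""

    lengths: np.ndarray  # (n_chromosomes,) chromosome lengths in Morgans
    marker_chrom: np.ndarray  # (n_markers,) chromosome index per marker
    marker_pos: np.ndarray  # (n_markers,) position in Morgans within chromosome

    # global coordinates with a 1-Morgan guard gap between chromosomes, so a
    # single sorted search can count crossovers without mixing chromosomes
    _offsets: np.ndarray = field(init=False, repr=False)
    _marker_global: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.marker_chrom = np.asarray(self.marker_chrom, dtype=np.int64)
        self.marker_pos = np.asarray(self.marker_pos, dtype=float)
        if self.marker_chrom.shape != self.marker_pos.shape:
            raise ValueError("marker_chrom and marker_pos must have equal length")
        if np.any(self.lengths < 0):
            raise ValueError("chromosome lengths must be non-negative")
        if np.any((self.marker_chrom < 0) | (self.marker_chrom >= len(self.lengths))):
            raise ValueError("marker chromosome index out of range")
        if np.any(self.marker_pos < 0) or np.any(
            self.marker_pos > self.lengths[self.marker_chrom]
        ):
            raise ValueError("marker positions must lie within their chromosome")
        for c in range(len(self.lengths)):
            pos_c = self.marker_pos[self.marker_chrom == c]
            if np.any(np.diff(pos_c) < 0):
                raise ValueError("marker positions must be non-decreasing per chromosome")
        self._offsets = np.concatenate([[0.0], np.cumsum(self.lengths + 1.0)[:-1]])
        self._marker_global = self._offsets[self.marker_chrom] + self.marker_pos

    @property
    def n_chromosomes(self) -> int:
        return len(self.lengths)

    @property
    def n_markers(self) -> int:
        return len(self.marker_pos)

    @classmethod
    def default(
        cls,
        n_markers: int,
        n_chromosomes: int = DEFAULT_N_CHROMOSOMES,
        chrom_length: float = DEFAULT_CHROM_LENGTH_M,
    ) -> "GeneticMap":
        """Evenly spaced markers split as equally as possible over chromosomes."""
        if n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        base, extra = divmod(n_markers, n_chromosomes)
        counts = np.array([base + (1 if c < extra else 0) for c in range(n_chromosomes)])
        chrom = np.repeat(np.arange(n_chromosomes), counts)
        pos = np.concatenate(
            [
                np.linspace(0.0, chrom_length, k + 2)[1:-1] if k else np.empty(0)
                for k in counts
            ]
        )
        return cls(np.full(n_chromosomes, chrom_length), chrom, pos)

    def to_tsv(self, path, marker_ids=None) -> None:
        ids = marker_ids if marker_ids is not None else [f"m{i}" for i in range(self.n_markers)]
        pd.DataFrame(
            {
                "marker": ids,
                "chromosome": self.marker_chrom,
                "position_Morgans": self.marker_pos,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t")
        chrom = df["chromosome"].to_numpy()
        lengths = np.zeros(int(chrom.max()) + 1)
        for c in range(len(lengths)):
            pos_c = df.loc[df["chromosome"] == c, "position_Morgans"]
            lengths[c] = float(pos_c.max()) if len(pos_c) else 0.0
        return cls(lengths, chrom, df["position_Morgans"].to_numpy())


@dataclass
class Individual:
    """Phased diploid: two haplotypes over the shared marker set."""

    id: str
    haplotypes: np.ndarray  # (2, n_markers) uint8 in {0, 1}
    parents: tuple = (None, None)
    generation: str = "founder"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != 2:
            raise ValueError("haplotypes must have shape (2, n_markers)")

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def dosage(self) -> np.ndarray:
        """Minor/alt allele count per marker, in {0, 1, 2}."""
        return self.haplotypes.sum(axis=0)


def _recombination_phase(gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """Which parental haplotype (0/1) each marker is copied from in one gamete."""
    n_xo = rng.poisson(gmap.lengths)
    start = rng.integers(0, 2, size=gmap.n_chromosomes)
    if n_xo.sum() == 0:
        return start[gmap.marker_chrom]
    xo_chrom = np.repeat(np.arange(gmap.n_chromosomes), n_xo)
    xo_pos = rng.uniform(0.0, np.repeat(gmap.lengths, n_xo))
    xo_global = np.sort(gmap._offsets[xo_chrom] + xo_pos)
    # crossovers strictly before each marker, counted within its own chromosome
    cum_before = np.concatenate([[0], np.cumsum(n_xo)[:-1]])
    n_before = np.searchsorted(xo_global, gmap._marker_global) - cum_before[gmap.marker_chrom]
    return (start[gmap.marker_chrom] + n_before) % 2


def make_gamete(
    parent: Individual, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant haplotype sampled from a parent.

    Crossover counts are Poisson(length in Morgans) per chromosome, positions
    uniform, no interference; the starting haplotype is chosen with
    probability 1/2 independently per chromosome.
    """
    if parent.n_markers != gmap.n_markers:
        raise ValueError(
            f"genotype has {parent.n_markers} markers but map has {gmap.n_markers}"
        )
    phase = _recombination_phase(gmap, rng)
    return np.where(phase == 0, parent.haplotypes[0], parent.haplotypes[1]).astype(np.uint8)


def cross(
    p1: Individual,
    p2: Individual,
    n_progeny: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    generation: str = "F1",
    id_prefix: str = "x",
) -> list[Individual]:
    """Biparental cross: each progeny receives one independent gamete per parent."""
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    return [
        Individual(
            id=f"{id_prefix}_{i}",
            haplotypes=np.stack([make_gamete(p1, gmap, rng), make_gamete(p2, gmap, rng)]),
            parents=(p1.id, p2.id),
            generation=generation,
        )
        for i in range(n_progeny)
    ]


def self_pollinate(
    ind: Individual,
    gmap: GeneticMap,
    rng: np.random.Generator,
    generation: str,
    new_id: str,
) -> Individual:
    """One selfed seed (two independent gametes from the same plant)."""
    return Individual(
        id=new_id,
        haplotypes=np.stack([make_gamete(ind, gmap, rng), make_gamete(ind, gmap, rng)]),
        parents=(ind.id, ind.id),
        generation=generation,
    )


def advance_ssd(
    f1s_per_cross: list[list[Individual]],
    gmap: GeneticMap,
    rng: np.random.Generator,
    n_f2_bulk: int = 200,
    n_f4_per_cross: int = 100,
    id_prefix: str = "ssd",
) -> list[Individual]:
    """Advance F1 families to F4 by single-seed descent.

    Per cross the kept F1s are selfed round-robin to a bulk of ``n_f2_bulk``
    F2 plants; ``n_f4_per_cross`` F2s are drawn from the bulk without
    replacement as lineage founders, and each lineage is selfed F2->F3->F4
    keeping one seed per generation.  Returns the F4s, n_f4_per_cross per
    cross.
    """
    if n_f4_per_cross > n_f2_bulk:
        raise ValueError("cannot sample more SSD lineages than the F2 bulk size")
    f4s: list[Individual] = []
    for ci, f1s in enumerate(f1s_per_cross):
        if not f1s:
            raise ValueError(f"cross {ci} contributed no F1 individuals")
        f2s = [
            self_pollinate(
                f1s[i % len(f1s)], gmap, rng, "F2", f"{id_prefix}_{ci}_F2_{i}"
            )
            for i in range(n_f2_bulk)
        ]
        starts = rng.choice(n_f2_bulk, size=n_f4_per_cross, replace=False)
        for li, si in enumerate(starts):
            f3 = self_pollinate(f2s[si], gmap, rng, "F3", f"{id_prefix}_{ci}_F3_{li}")
            f4s.append(
                self_pollinate(f3, gmap, rng, "F4", f"{id_prefix}_{ci}_F4_{li}")
            )
    return f4s


def dosage_matrix(individuals: list[Individual]) -> np.ndarray:
    """Stack individuals' dosages into an (n, m) int matrix."""
    return np.stack([ind.dosage for ind in individuals]).astype(np.int64)


def pedigree_frame(individuals: list[Individual]) -> pd.DataFrame:
    """Pedigree export: id, parent1, parent2, generation."""
    return pd.DataFrame(
        {
            "id": [i.id for i in individuals],
            "parent1": [i.parents[0] for i in individuals],
            "parent2": [i.parents[1] for i in individuals],
            "generation": [i.generation for i in individuals],
        }
    )
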