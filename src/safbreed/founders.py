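"""Synthetic founder panels with subpopulation structure and two-trait genetics.

The generator emulates the statistical shape of a diverse crop panel: a set of
phased diploid founders genotyped at biallelic SNPs, all with minor allele
frequency above a floor, mild subpopulation structure, and two polygenic
traits with chosen narrow-sense heritabilities and genetic correlation.

Allele frequencies follow a Balding-Nichols construction: each marker has an
ancestral frequency p0 ~ Uniform, and each subpopulation draws its own
frequency from Beta(p0 (1-d)/d, (1-p0)(1-d)/d) where d is the Fst-like
divergence, so that E[Var_subpop(p)] = d * p0 * (1 - p0).  Haplotype alleles
are then independent Bernoulli draws per marker — relationship structure and
trait architecture are realistic targets here, linkage disequilibrium among
founders is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneticMap, Individual

TRAITS = ("GY", "OL")

__all__ = [
    "FounderConfig",
    "TraitArchitecture",
    "Population",
    "simulate_founders",
    "simulate_trait_architecture",
    "simulate_phenotypes",
    "true_breeding_values",
]


@dataclass
class FounderConfig:
    """Founder-panel shape; defaults follow the safflower diversity panel
    (349 accessions, 6911 MAF-filtered SNPs) with mild structure."""

    n_individuals: int = 349
    n_markers: int = 6911
    n_subpops: int = 3
    maf_min: float = 0.01
    fst_like_divergence: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_markers < 10:
            raise ValueError("n_markers must be >= 10")
        if not (0.0 < self.maf_min < 0.5):
            raise ValueError("maf_min must lie in (0, 0.5)")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not (0.0 <= self.fst_like_divergence < 1.0):
            raise ValueError("fst_like_divergence must lie in [0, 1)")


@dataclass
class TraitArchitecture:
    """QTL positions and per-trait additive effects.

    ``effects`` has one row per QTL and one column per trait; effects are
    rescaled after construction so that the realized genetic variance of each
    trait equals ``var_g`` and the realized correlation of true breeding
    values in the generating population equals ``rg`` (exactly, by a
    Gram-Schmidt rotation in breeding-value space, whenever the drawn effects
    span two dimensions).
    """

    qtl_indices: np.ndarray  # (n_qtl,) marker indices
    effects: np.ndarray  # (n_qtl, 2) additive effect per trait
    h2: tuple[float, float]  # narrow-sense heritability targets per trait
    rg: float  # target genetic correlation
    var_g: tuple[float, float] = (1.0, 1.0)  # realized genetic variances

    def __post_init__(self) -> None:
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=np.int64)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (len(self.qtl_indices), 2):
            raise ValueError("effects must be (n_qtl, 2)")
        for h in self.h2:
            if not (0.0 < h <= 1.0):
                raise ValueError("h2 must lie in (0, 1]")
        if not (-1.0 <= self.rg <= 1.0):
            raise ValueError("rg must lie in [-1, 1]")


@dataclass
class Population:
    """Founder panel: individuals over a shared marker set and genetic map."""

    individuals: list[Individual]
    marker_ids: list[str]
    gmap: GeneticMap
    subpop: np.ndarray | None = None  # (n,) subpopulation label per individual
    ancestral_freqs: np.ndarray | None = None  # (m,) p0 per marker
    subpop_freqs: np.ndarray | None = None  # (n_subpops, m)

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("individual ids must be unique")
        m = len(self.marker_ids)
        if any(ind.n_markers != m for ind in self.individuals):
            raise ValueError("all individuals must share the marker set")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def dosages(self) -> np.ndarray:
        return np.stack([ind.dosage for ind in self.individuals]).astype(np.int64)

    def to_csv(self, path) -> None:
        """Dosage matrix, individuals x markers, marker-id header."""
        pd.DataFrame(
            self.dosages(),
            index=[i.id for i in self.individuals],
            columns=self.marker_ids,
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path, gmap: GeneticMap | None = None, seed: int | None = None):
        """Read an unphased dosage matrix; heterozygotes are phased uniformly
        at random (meiosis needs phase; real panels rarely record it)."""
        df = pd.read_csv(path, index_col=0)
        dos = df.to_numpy(dtype=np.int64)
        if not np.isin(dos, (0, 1, 2)).all():
            raise ValueError("dosages must be coded 0/1/2")
        rng = np.random.default_rng(seed)
        het_first = rng.integers(0, 2, size=dos.shape)
        hap0 = (dos == 2).astype(np.uint8) | ((dos == 1) & (het_first == 0)).astype(np.uint8)
        hap1 = (dos - hap0).astype(np.uint8)
        inds = [
            Individual(str(df.index[i]), np.stack([hap0[i], hap1[i]]), generation="founder")
            for i in range(dos.shape[0])
        ]
        gmap = gmap if gmap is not None else GeneticMap.default(dos.shape[1])
        return cls(inds, [str(c) for c in df.columns], gmap)


def _draw_marker_columns(
    m: int, n: int, subpop: np.ndarray, n_subpops: int, divergence: float,
    rng: np.random.Generator,
):
    """Haplotype columns for m markers: (p0, subpop freqs, (n,2,m) alleles)."""
    p0 = rng.uniform(0.05, 0.95, size=m)
    if n_subpops > 1 and divergence > 0.0:
        a = p0 * (1.0 - divergence) / divergence
        b = (1.0 - p0) * (1.0 - divergence) / divergence
        ps = rng.beta(a, b, size=(n_subpops, m))
        ps = np.clip(ps, 1e-6, 1.0 - 1e-6)
    else:
        ps = np.tile(p0, (n_subpops, 1))
    freq_per_ind = ps[subpop]  # (n, m)
    alleles = (rng.random((n, 2, m)) < freq_per_ind[:, None, :]).astype(np.uint8)
    return p0, ps, alleles


def simulate_founders(config: FounderConfig, gmap: GeneticMap | None = None) -> Population:
    """Generate a founder panel whose every marker has realized MAF >= maf_min.

    Markers failing the MAF floor are redrawn (new ancestral frequency, new
    subpopulation frequencies, new genotype column) until the panel is clean,
    emulating the endpoint of a MAF-filtered real panel.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_markers
    subpop = np.arange(n) % config.n_subpops
    p0, ps, alleles = _draw_marker_columns(
        m, n, subpop, config.n_subpops, config.fst_like_divergence, rng
    )
    for _ in range(1000):
        freq = alleles.sum(axis=(0, 1)) / (2.0 * n)
        maf = np.minimum(freq, 1.0 - freq)
        bad = np.flatnonzero(maf < config.maf_min)
        if bad.size == 0:
            break
        p0b, psb, ab = _draw_marker_columns(
            bad.size, n, subpop, config.n_subpops, config.fst_like_divergence, rng
        )
        p0[bad], ps[:, bad], alleles[:, :, bad] = p0b, psb, ab
    else:  # pragma: no cover - would need a pathological configuration
        raise RuntimeError("could not satisfy the MAF floor after 1000 redraw rounds")

    gmap = gmap if gmap is not None else GeneticMap.default(m)
    individuals = [
        Individual(f"G{i}", alleles[i], generation="founder") for i in range(n)
    ]
    return Population(
        individuals,
        [f"m{j}" for j in range(m)],
        gmap,
        subpop=subpop,
        ancestral_freqs=p0,
        subpop_freqs=ps,
    )


def true_breeding_values(dosages: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """(n, 2) additive genetic values from QTL dosages and effects."""
    X = np.asarray(dosages)[:, arch.qtl_indices].astype(float)
    return X @ arch.effects


def simulate_trait_architecture(
    pop: Population,
    n_qtl: int,
    h2: tuple[float, float] = (0.54, 0.80),
    rg: float = 0.19,
    seed: int | None = None,
    var_g: tuple[float, float] = (1.0, 1.0),
) -> TraitArchitecture:
    """Draw a two-trait QTL architecture hitting the target moments exactly.

    Effects start as iid standard normals per trait; the second trait's
    effect vector is then rotated in breeding-value space so that the
    realized TBV correlation in ``pop`` equals ``rg``, and both are rescaled
    so realized genetic variances equal ``var_g``.  With a single QTL (or
    |rg| = 1) the two traits collapse onto proportional effects.
    """
    if n_qtl > pop.n_markers:
        raise ValueError("n_qtl cannot exceed the number of markers")
    if n_qtl < 1:
        raise ValueError("n_qtl must be >= 1")
    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(pop.n_markers, size=n_qtl, replace=False))
    a = rng.standard_normal((n_qtl, 2))
    X = pop.dosages()[:, qtl].astype(float)
    Xc = X - X.mean(axis=0)

    g1 = Xc @ a[:, 0]
    v1 = g1.var()
    if v1 <= 0:
        raise ValueError("degenerate architecture: trait-1 TBV has zero variance")
    # orthogonalize trait 2 against trait 1 in breeding-value space
    g2 = Xc @ a[:, 1]
    b_perp = a[:, 1] - (np.dot(g1, g2) / np.dot(g1, g1)) * a[:, 0]
    g_perp = Xc @ b_perp
    v_perp = g_perp.var()

    s1, s2 = np.sqrt(var_g)
    a1 = a[:, 0] * (s1 / np.sqrt(v1))
    if v_perp <= 1e-12 * max(v1, 1.0) or abs(rg) >= 1.0:
        # one-dimensional genetic space: proportional effects, correlation +-1
        a2 = np.sign(rg if rg != 0 else 1.0) * a[:, 0] * (s2 / np.sqrt(v1))
    else:
        a2 = s2 * (
            rg * a[:, 0] / np.sqrt(v1)
            + np.sqrt(1.0 - rg**2) * b_perp / np.sqrt(v_perp)
        )
    return TraitArchitecture(qtl, np.column_stack([a1, a2]), tuple(h2), rg, tuple(var_g))


def simulate_phenotypes(
    pop: Population, arch: TraitArchitecture, seed: int | None = None
) -> pd.DataFrame:
    """One BLUE-like phenotype per individual per trait: TBV plus independent
    normal noise with variance var_g * (1 - h2) / h2 so the generating h2 is
    the stated one."""
    tbv = true_breeding_values(pop.dosages(), arch)
    rng = np.random.default_rng(seed)
    out = {"id": [ind.id for ind in pop.individuals]}
    for t, trait in enumerate(TRAITS):
        vg = tbv[:, t].var()
        ve = vg * (1.0 - arch.h2[t]) / arch.h2[t]
        noise = rng.normal(0.0, np.sqrt(ve), size=pop.n_individuals) if ve > 0 else 0.0
        out[trait] = tbv[:, t] + noise
    return pd.DataFrame(out).set_index("id")
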