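"""VanRaden genomic relationship matrix, inbreeding coefficient and rate.

The GRM follows VanRaden's first method: with dosage matrix M (n x m) and
base allele frequencies p, Z = M - 2p and G = Z Z' / (2 * sum_j p_j (1 - p_j)).
Markers monomorphic under the base frequencies carry no information and are
excluded from numerator and denominator alike.

The population inbreeding coefficient is F = mean(diag(G)) - 1, and the rate
of inbreeding between consecutive cycles i and j = i + 1 is dF = F_j - F_i.
Because F is measured against the base frequencies, tracking loss of the
initial diversity over breeding cycles requires holding the base frequencies
fixed at their founder values (the default in the breeding-program driver).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GRMatrix", "compute_grm", "inbreeding_coefficient", "delta_F"]


@dataclass
class GRMatrix:
    values: np.ndarray  # (n, n) symmetric
    base_freqs: np.ndarray  # (m,) allele frequencies used for centering
    individual_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match the id list")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GRM contains non-finite entries")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.individual_ids
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path, base_freqs=None) -> "GRMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            df.to_numpy(),
            np.asarray(base_freqs) if base_freqs is not None else np.empty(0),
            list(df.index),
        )


def compute_grm(dosages, base_freqs="from-data", individual_ids=None) -> GRMatrix:
    """VanRaden method-1 GRM from a 0/1/2 dosage matrix.

    Parameters
    ----------
    dosages : (n, m) array of allele counts in {0, 1, 2}.
    base_freqs : per-marker allele frequency used for centering, or
        ``"from-data"`` to use the in-sample frequencies ``mean(dosage)/2``.
    """
    M = np.asarray(dosages, dtype=float)
    if M.ndim != 2:
        raise ValueError("dosages must be a 2-D matrix")
    n, m = M.shape
    if isinstance(base_freqs, str):
        if base_freqs != "from-data":
            raise ValueError("base_freqs must be an array or 'from-data'")
        p = M.mean(axis=0) / 2.0
    else:
        p = np.asarray(base_freqs, dtype=float)
        if p.shape != (m,):
            raise ValueError("base_freqs length does not match marker count")
    usable = (p > 0.0) & (p < 1.0)
    if not usable.any():
        raise ValueError("all markers are monomorphic under the base frequencies")
    pu = p[usable]
    Z = M[:, usable] - 2.0 * pu
    denom = 2.0 * np.sum(pu * (1.0 - pu))
    G = (Z @ Z.T) / denom
    ids = individual_ids if individual_ids is not None else list(range(n))
    return GRMatrix(G, p, list(ids))


def inbreeding_coefficient(grm: GRMatrix) -> float:
    """F = mean of GRM diagonal minus 1 (0 at Hardy-Weinberg under base freqs)."""
    diag = np.diag(grm.values)
    if diag.size == 0:
        raise ValueError("empty GRM")
    return float(diag.mean() - 1.0)


def delta_F(f_i: float, f_j: float) -> float:
    """Rate of inbreeding between consecutive cycles: F_j - F_i."""
    return f_j - f_i
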