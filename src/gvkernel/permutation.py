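"""Permutation-based p-values for the aggregate kernel statistic.

The null distribution of S is approximated by resampling the observed
phenotype without replacement: for each of B uniform random permutations
of y the aggregate statistic is recomputed through the O(n) path, so one
test costs O(n·l·B).  Genotype vectors are never permuted — relabelling
y is equivalent and touches one vector instead of 3l.

The p-value is the add-one estimator (count_ge + 1)/(B + 1) with ties
counted as exceedances, which is a valid permutation p-value and can
never be exactly zero.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Optional, Sequence

import numpy as np

from .core import GenotypeSite, InputError, PhenotypeVector
from .kernels import GRM, IBS, KernelTestResult, WeightScheme, kernel_statistic

__all__ = [
    "PermutationResult",
    "permutation_test",
    "reject_null",
    "iter_permutation_chunks",
]

#: Permutations are drawn and evaluated in batches of this many.
CHUNK_SIZE = 512


@dataclasses.dataclass(frozen=True)
class PermutationResult:
    """Outcome of a permutation test on one kernel statistic."""

    observed_S: float
    B: int
    count_ge: int
    p_value: float
    seed: int
    kernel: str
    n: int
    n_sites: int
    null_statistics: Optional[np.ndarray] = dataclasses.field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.count_ge <= self.B):
            raise InputError("tie-inclusive exceedance count outside [0, B]")
        expected = (self.count_ge + 1) / (self.B + 1)
        if abs(self.p_value - expected) > 1e-15:
            raise InputError("p-value inconsistent with exceedance count")


def iter_permutation_chunks(
    rng: np.random.Generator, n: int, B: int, chunk_size: int = CHUNK_SIZE
) -> Iterator[np.ndarray]:
    """Yield (m, n) index arrays covering B uniform random permutations.

    Deterministic given the generator state; exposed so an independent
    (e.g. brute-force matrix) evaluation can replay the exact permutations
    of a seeded test.
    """
    base = np.arange(n)
    produced = 0
    while produced < B:
        m = min(chunk_size, B - produced)
        idx = np.tile(base, (m, 1))
        rng.permuted(idx, axis=1, out=idx)
        yield idx
        produced += m


def _batch_statistics(
    Bm: np.ndarray, Cm: np.ndarray, w: np.ndarray, Y: np.ndarray, kernel: str
) -> np.ndarray:
    """Aggregate statistics for the phenotype columns of Y (shape n×m)."""
    yb = Bm @ Y
    yc = Cm @ Y
    if kernel == GRM:
        per_site = (yb + 2.0 * yc) ** 2
    else:
        ya = -yb - yc
        per_site = 2.0 * ya**2 + 2.0 * yc**2
    return w @ per_site


def permutation_test(
    y: PhenotypeVector,
    sites: Sequence[GenotypeSite],
    scheme: Optional[WeightScheme] = None,
    kernel: str = GRM,
    B: int = 999,
    seed: Optional[int] = None,
    keep_null: bool = False,
) -> PermutationResult:
    """Estimate P(S_perm ≥ S_obs) over B phenotype permutations.

    Parameters
    ----------
    B
        Number of permutations (≥ 1).
    seed
        Seed for the permutation stream.  ``None`` draws one from entropy;
        the seed actually used is always recorded in the result.
    keep_null
        If true, the B permuted statistics are kept on the result (for
        plotting or diagnostics); off by default to bound memory at large B.
    """
    if B < 1:
        raise InputError(f"need at least 1 permutation, got {B}")
    observed = kernel_statistic(y, sites, scheme, kernel)
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    seed = int(seed)
    rng = np.random.default_rng(seed)

    Bm = np.stack([s.b for s in sites]).astype(np.float64)
    Cm = np.stack([s.c for s in sites]).astype(np.float64)
    w = observed.weights
    yv = y.values

    count_ge = 0
    null_parts: list[np.ndarray] = []
    for idx in iter_permutation_chunks(rng, y.n, B):
        Y = yv[idx].T
        stats = _batch_statistics(Bm, Cm, w, Y, observed.kernel)
        count_ge += int(np.count_nonzero(stats >= observed.S))
        if keep_null:
            null_parts.append(stats)

    return PermutationResult(
        observed_S=observed.S,
        B=B,
        count_ge=count_ge,
        p_value=(count_ge + 1) / (B + 1),
        seed=seed,
        kernel=observed.kernel,
        n=y.n,
        n_sites=len(sites),
        null_statistics=np.concatenate(null_parts) if keep_null else None,
    )


def reject_null(result: PermutationResult, alpha: float) -> bool:
    """True iff the permutation p-value is ≤ alpha.

    ``alpha`` must lie in (0, 1]; the degenerate alpha = 1 always rejects
    (every valid p-value is ≤ 1) and exists for calibration experiments.
    """
    if not (0 < alpha <= 1):
        raise InputError(f"significance level must be in (0, 1], got {alpha}")
    return result.p_value <= alpha
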