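"""Brute-force kernel matrices and quadratic forms.

This module is the ground truth the fast path is tested against.  It
builds the explicit n×n per-site GRM and IBS matrices with naive double
loops and evaluates ``yᵀKy`` entry by entry — deliberately O(n²) with no
algebraic shortcuts, so it shares no code with the O(n) implementation in
:mod:`gvkernel.kernels`.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .core import GenotypeSite, InputError, PhenotypeVector, SiteId, genotype_value

__all__ = [
    "KernelMatrix",
    "grm_matrix",
    "g_matrix",
    "ibs_pair",
    "ibs_matrix",
    "ibs_matrix_rank_structured",
    "quadratic_form",
]

# Shared-allele counts for every ordered pair of genotype values (0, 1, 2):
# hom-ref/hom-ref and hom-alt/hom-alt share both alleles, a heterozygote
# shares exactly one allele with anything, opposite homozygotes share none.
_IBS_TABLE = {
    (0, 0): 2, (0, 1): 1, (0, 2): 0,
    (1, 0): 1, (1, 1): 2, (1, 2): 1,
    (2, 0): 0, (2, 1): 1, (2, 2): 2,
}


@dataclasses.dataclass(frozen=True)
class KernelMatrix:
    """An explicit per-site kernel matrix (GRM, IBS, or the raw ggᵀ form)."""

    kind: str
    entries: np.ndarray
    site_id: SiteId

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InputError("kernel matrix must be square")
        object.__setattr__(self, "entries", m)

    @property
    def n(self) -> int:
        return int(self.entries.shape[0])

    def to_tsv(self, path, individual_ids: Sequence[str] | None = None) -> None:
        """Export row-major with a header of individual IDs, for inspection."""
        ids = list(individual_ids) if individual_ids is not None else [
            f"I{i}" for i in range(self.n)
        ]
        if len(ids) != self.n:
            raise InputError("individual ID count does not match matrix size")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(ids) + "\n")
            for row in self.entries:
                fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def grm_matrix(site: GenotypeSite) -> KernelMatrix:
    """Per-site GRM: entries (g(i) − μ)(g(j) − μ); every row sums to 0."""
    n = site.n
    mu = site.mu
    m = np.empty((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(n):
            m[i, j] = (float(site.g[i]) - mu) * (float(site.g[j]) - mu)
    return KernelMatrix(kind="GRM", entries=m, site_id=site.site_id)


def g_matrix(site: GenotypeSite) -> KernelMatrix:
    """The uncentered outer-product matrix with entries g(i)·g(j)."""
    n = site.n
    m = np.empty((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(n):
            m[i, j] = float(site.g[i]) * float(site.g[j])
    return KernelMatrix(kind="G", entries=m, site_id=site.site_id)


def ibs_pair(call_i: str, call_j: str) -> int:
    """Number of alleles (0, 1 or 2) two individuals share at a site."""
    return _IBS_TABLE[(genotype_value(call_i), genotype_value(call_j))]


def ibs_matrix(site: GenotypeSite) -> KernelMatrix:
    """Per-site IBS matrix via pairwise shared-allele lookup."""
    n = site.n
    m = np.empty((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(n):
            m[i, j] = _IBS_TABLE[(int(site.g[i]), int(site.g[j]))]
    return KernelMatrix(kind="IBS", entries=m, site_id=site.site_id)


def ibs_matrix_rank_structured(site: GenotypeSite) -> KernelMatrix:
    """IBS matrix via its rank-structured form 2aaᵀ + 1bᵀ + b1ᵀ + 2ccᵀ.

    An independent construction route from :func:`ibs_matrix`; the two must
    agree entrywise.
    """
    a = site.a.astype(np.float64)
    b = site.b.astype(np.float64)
    c = site.c.astype(np.float64)
    ones = np.ones(site.n, dtype=np.float64)
    m = 2.0 * np.outer(a, a) + np.outer(ones, b) + np.outer(b, ones) + 2.0 * np.outer(c, c)
    return KernelMatrix(kind="IBS", entries=m, site_id=site.site_id)


def quadratic_form(y: PhenotypeVector, K: KernelMatrix) -> float:
    """Direct Σᵢ Σⱼ y(i)·K(i,j)·y(j) with an O(n²) double loop."""
    if K.n != y.n:
        raise InputError(f"kernel matrix is {K.n}×{K.n} but phenotype has {y.n} entries")
    yv = y.values
    terms = []
    for i in range(K.n):
        for j in range(K.n):
            terms.append(yv[i] * K.entries[i, j] * yv[j])
    return math.fsum(terms)
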