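"""Phenotype and per-site genotype primitives.

Every biallelic site *k* is decomposed into three binary indicator vectors
over the ``n`` individuals of the cohort:

* ``a`` — 1 where the individual is homozygous for the reference allele,
* ``b`` — 1 where the individual is heterozygous,
* ``c`` — 1 where the individual is homozygous for the alternative allele.

These satisfy ``a + b + c = 1`` elementwise, and the alternative-allele
count is ``g = b + 2c``.  All kernel statistics downstream are inner
products of these vectors with a mean-centered phenotype vector ``y``,
which is what makes evaluating the quadratic forms ``yᵀKy`` possible in
O(n) time per site without ever forming an n×n kernel matrix.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "InputError",
    "GenotypeCallError",
    "MissingGenotypeError",
    "SiteId",
    "PhenotypeVector",
    "GenotypeSite",
    "SiteStatistics",
    "center_phenotype",
    "build_genotype_site",
    "genotype_value",
    "is_monomorphic",
]

logger = logging.getLogger("gvkernel.core")

#: Missing-genotype policies accepted by :func:`build_genotype_site`.
MISSING_POLICIES = ("error", "drop-site", "ref-impute")


class InputError(ValueError):
    """Invalid user input (bad call, malformed phenotype, shape mismatch)."""


class GenotypeCallError(InputError):
    """A genotype call string that is not a valid diploid biallelic call."""


class MissingGenotypeError(GenotypeCallError):
    """A call containing a missing allele (``./.`` or a half-call)."""


class SiteId(NamedTuple):
    """Identity of a variant site: 1-based VCF coordinates plus optional rsID."""

    chrom: str
    pos: int
    rsid: Optional[str] = None

    def __str__(self) -> str:
        label = f"{self.chrom}:{self.pos}"
        return f"{label} ({self.rsid})" if self.rsid else label

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}"


_UNKNOWN_SITE = SiteId(".", 0)


def _parse_alleles(call: str) -> tuple[int, int]:
    """Split a diploid GT string into its two allele indices.

    Both ``/`` (unphased) and ``|`` (phased) separators are accepted; the
    statistics depend only on allele counts, so phase is discarded.
    """
    text = str(call).strip().replace("|", "/")
    parts = text.split("/")
    if len(parts) != 2:
        raise GenotypeCallError(f"genotype call {call!r} is not diploid")
    alleles = []
    for token in parts:
        if token == ".":
            raise MissingGenotypeError(f"missing allele in genotype call {call!r}")
        try:
            index = int(token)
        except ValueError:
            raise GenotypeCallError(f"unrecognized allele {token!r} in call {call!r}") from None
        if index < 0:
            raise GenotypeCallError(f"negative allele index in call {call!r}")
        if index > 1:
            raise GenotypeCallError(
                f"allele index {index} in call {call!r}: only biallelic sites are supported"
            )
        alleles.append(index)
    return alleles[0], alleles[1]


def genotype_value(call: str) -> int:
    """Number of alternative alleles in a diploid biallelic call.

    Returns 0 for ``0/0``, 1 for a heterozygote (``0/1`` or ``1/0``, phased
    or not), and 2 for ``1/1``.
    """
    first, second = _parse_alleles(call)
    return first + second


@dataclasses.dataclass(frozen=True)
class PhenotypeVector:
    """A quantitative phenotype, mean-centered so that ``yᵀ1 = 0``.

    The centering constraint is what collapses the GRM quadratic form
    ``yᵀX_k y`` onto ``yᵀG_k y`` and lets ``yᵀa`` be recovered as
    ``−yᵀb − yᵀc``; it is therefore validated at construction.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.array(self.values, dtype=np.float64, copy=True)
        if v.ndim != 1:
            raise InputError("phenotype must be one-dimensional")
        if v.size < 2:
            raise InputError(f"need at least 2 individuals, got {v.size}")
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise InputError(f"non-finite phenotype value at index {bad}")
        scale = max(1.0, float(np.max(np.abs(v))))
        if abs(float(v.mean())) > 1e-12 * scale:
            raise InputError(
                "phenotype is not centered; use center_phenotype() on raw values"
            )
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n


def center_phenotype(raw_values: Sequence[float]) -> PhenotypeVector:
    """Center raw trait values to mean zero.

    Two-pass subtraction keeps the residual mean at the rounding floor even
    for large-magnitude traits.
    """
    v = np.array(raw_values, dtype=np.float64, copy=True)
    if v.ndim != 1:
        raise InputError("phenotype must be one-dimensional")
    if v.size < 2:
        raise InputError(f"need at least 2 individuals, got {v.size}")
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise InputError(f"non-finite phenotype value at index {bad}")
    v -= v.mean()
    v -= v.mean()
    return PhenotypeVector(v)


@dataclasses.dataclass(frozen=True)
class GenotypeSite:
    """One biallelic site, stored as the indicator decomposition (a, b, c).

    ``g`` is the derived alternative-allele count vector, ``p`` the
    alternative allele frequency and ``mu = 2p`` the mean genotype value.
    """

    site_id: SiteId
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    g: np.ndarray
    p: float
    mu: float

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=np.uint8)
        b = np.asarray(self.b, dtype=np.uint8)
        c = np.asarray(self.c, dtype=np.uint8)
        g = np.asarray(self.g, dtype=np.int64)
        n = a.size
        if not (b.size == c.size == g.size == n) or n < 1:
            raise InputError(f"inconsistent vector lengths at site {self.site_id}")
        if not np.all(a + b + c == 1):
            raise InputError(f"a+b+c != 1 at site {self.site_id}")
        if not np.all(g == b.astype(np.int64) + 2 * c.astype(np.int64)):
            raise InputError(f"g != b + 2c at site {self.site_id}")
        alt = int(b.sum()) + 2 * int(c.sum())
        if abs(self.p - alt / (2 * n)) > 1e-12:
            raise InputError(f"allele frequency inconsistent at site {self.site_id}")
        if abs(self.mu - alt / n) > 1e-12:
            raise InputError(f"mean genotype value inconsistent at site {self.site_id}")
        for arr, name in ((a, "a"), (b, "b"), (c, "c"), (g, "g")):
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    @property
    def n(self) -> int:
        return int(self.a.size)

    @classmethod
    def from_genotype_values(
        cls, values: Sequence[int], site_id: SiteId = _UNKNOWN_SITE
    ) -> "GenotypeSite":
        """Build a site from per-individual alternative-allele counts (0/1/2)."""
        g = np.asarray(values, dtype=np.int64)
        if g.ndim != 1 or g.size < 1:
            raise InputError(f"empty genotype vector at site {site_id}")
        if not np.all((g >= 0) & (g <= 2)):
            raise InputError(f"genotype values must be 0, 1 or 2 at site {site_id}")
        n = g.size
        a = (g == 0).astype(np.uint8)
        b = (g == 1).astype(np.uint8)
        c = (g == 2).astype(np.uint8)
        alt = int(g.sum())
        return cls(site_id=site_id, a=a, b=b, c=c, g=g, p=alt / (2 * n), mu=alt / n)

    def calls(self) -> list[str]:
        """Reconstruct canonical unphased GT strings, inverse of from-calls."""
        table = ("0/0", "0/1", "1/1")
        return [table[v] for v in self.g]


def build_genotype_site(
    calls: Sequence[str],
    site_id: SiteId = _UNKNOWN_SITE,
    missing: str = "error",
) -> Optional[GenotypeSite]:
    """Build a :class:`GenotypeSite` from diploid GT strings.

    ``missing`` selects the policy for ``./.`` and half-calls: ``"error"``
    (default) raises an :class:`InputError` naming the site and individual,
    ``"drop-site"`` returns ``None`` with a logged warning, and
    ``"ref-impute"`` counts the individual as ``0/0``.  Imputation changes
    the statistics, so it is never done silently.
    """
    if missing not in MISSING_POLICIES:
        raise InputError(f"unknown missing-data policy {missing!r}; choose from {MISSING_POLICIES}")
    if len(calls) < 1:
        raise InputError(f"no genotype calls at site {site_id}")
    values = np.empty(len(calls), dtype=np.int64)
    for i, call in enumerate(calls):
        try:
            values[i] = genotype_value(call)
        except MissingGenotypeError:
            if missing == "error":
                raise InputError(
                    f"missing genotype for individual {i} at site {site_id}"
                ) from None
            if missing == "drop-site":
                logger.warning("dropping site %s: missing genotype for individual %d", site_id, i)
                return None
            values[i] = 0
    return GenotypeSite.from_genotype_values(values, site_id)


def is_monomorphic(site: GenotypeSite) -> bool:
    """True iff every individual carries the same allele (p = 0 or p = 1)."""
    alt = int(site.g.sum())
    return alt == 0 or alt == 2 * site.n


@dataclasses.dataclass(frozen=True)
class SiteStatistics:
    """Per-site scalar quadratic forms: Q (GRM kernel) and R (IBS kernel).

    Both are sums of squares, hence nonnegative.
    """

    site_id: SiteId
    Q: float
    R: float

    def __post_init__(self) -> None:
        if self.Q < 0 or self.R < 0:
            raise InputError(f"negative kernel statistic at site {self.site_id}")
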