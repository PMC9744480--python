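"""Model/results interface for kernel association testing.

`KernelAssociationTest` is constructed from a phenotype and a set of
biallelic sites (directly, from a VCF + phenotype table, or from a
DataFrame of genotype calls); ``fit()`` runs the O(n) statistic and its
permutation test and returns a `KernelAssociationResults` carrying the
statistic, the permutation p-value, the per-site decomposition and a
``summary()`` table.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    GenotypeSite,
    InputError,
    PhenotypeVector,
    SiteId,
    build_genotype_site,
    center_phenotype,
)
from .kernels import GRM, WeightScheme, kernel_statistic
from .permutation import PermutationResult, permutation_test

__all__ = ["KernelAssociationTest", "KernelAssociationResults"]


def _site_id_from_label(label, ordinal: int) -> SiteId:
    text = str(label)
    chrom, _, pos = text.partition(":")
    if pos.isdigit() and chrom:
        return SiteId(chrom=chrom, pos=int(pos), rsid=None)
    return SiteId(chrom=".", pos=ordinal + 1, rsid=text)


class KernelAssociationTest:
    """Variance-component association test between a variant set and a trait.

    The statistic is the SKAT quadratic form S = yᵀKy for a centered
    phenotype y and a kernel K that is either the weighted per-site sum of
    genetic-relationship matrices (GRM) or of identity-by-state matrices
    (IBS); both are evaluated in O(n) per site without forming K.

    Parameters
    ----------
    endog
        Raw trait values, one per individual (centered internally), or an
        already-centered :class:`PhenotypeVector`.
    sites
        The variant set, as :class:`GenotypeSite` objects sharing the
        phenotype's sample order.
    kernel
        "GRM" (default) or "IBS"; case-insensitive.
    weights
        A :class:`WeightScheme`; uniform if omitted.

    Examples
    --------
    >>> calls = pd.DataFrame({"1:101": ["0/1", "0/0", "0/0", "0/0"],
    ...                       "1:102": ["0/0", "1/1", "0/0", "0/1"]})
    >>> model = KernelAssociationTest.from_dataframe(calls, [4.9, 3.2, 5.5, 4.1])
    >>> res = model.fit(permutations=999, seed=1)
    >>> 0 < res.pvalue <= 1
    True
    """

    def __init__(
        self,
        endog,
        sites: Sequence[GenotypeSite],
        kernel: str = GRM,
        weights: Optional[WeightScheme] = None,
        individual_ids: Optional[Sequence[str]] = None,
    ):
        if isinstance(endog, PhenotypeVector):
            self.phenotype = endog
        else:
            self.phenotype = center_phenotype(np.asarray(endog, dtype=np.float64))
        self.sites = tuple(sites)
        if not self.sites:
            raise InputError("the variant set is empty")
        for s in self.sites:
            if s.n != self.phenotype.n:
                raise InputError(
                    f"site {s.site_id} has {s.n} individuals, phenotype has "
                    f"{self.phenotype.n}"
                )
        self.kernel = str(kernel).upper()
        self.weights = weights if weights is not None else WeightScheme.uniform()
        self.individual_ids = (
            tuple(individual_ids)
            if individual_ids is not None
            else tuple(f"I{i}" for i in range(self.phenotype.n))
        )
        if len(self.individual_ids) != self.phenotype.n:
            raise InputError("individual_ids length does not match phenotype")

    @classmethod
    def from_vcf(
        cls,
        vcf_path,
        phenotype_path,
        kernel: str = GRM,
        weights: Optional[WeightScheme] = None,
        region: Optional[str] = None,
        missing: str = "error",
    ) -> "KernelAssociationTest":
        """Build the model from a VCF and a phenotype TSV."""
        from .io import load_cohort  # deferred: keeps cyvcf2 out of array-only use

        cohort = load_cohort(vcf_path, phenotype_path, region=region, missing=missing)
        return cls(
            cohort.phenotype,
            cohort.sites,
            kernel=kernel,
            weights=weights,
            individual_ids=cohort.individual_ids,
        )

    @classmethod
    def from_dataframe(
        cls,
        genotypes: pd.DataFrame,
        endog,
        kernel: str = GRM,
        weights: Optional[WeightScheme] = None,
        missing: str = "error",
    ) -> "KernelAssociationTest":
        """Build the model from a DataFrame of GT strings.

        Rows are individuals, columns are sites; column labels of the form
        "chrom:pos" become coordinates, anything else is kept as a site
        name.  The DataFrame index supplies individual IDs.
        """
        sites = []
        for ordinal, col in enumerate(genotypes.columns):
            site = build_genotype_site(
                genotypes[col].tolist(),
                _site_id_from_label(col, ordinal),
                missing=missing,
            )
            if site is not None:
                sites.append(site)
        return cls(
            endog,
            sites,
            kernel=kernel,
            weights=weights,
            individual_ids=[str(i) for i in genotypes.index],
        )

    @property
    def nobs(self) -> int:
        return self.phenotype.n

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def statistic(self):
        """The observed aggregate statistic, without a permutation test."""
        return kernel_statistic(self.phenotype, self.sites, self.weights, self.kernel)

    def fit(
        self,
        permutations: int = 9999,
        seed: Optional[int] = None,
        keep_null: bool = False,
    ) -> "KernelAssociationResults":
        """Run the permutation test and return a results object.

        Parameters
        ----------
        permutations
            Number of phenotype permutations B; the smallest attainable
            p-value is 1/(B+1).
        seed
            Seed for the permutation stream (drawn from entropy if omitted;
            always recorded on the results).
        keep_null
            Keep the B permuted statistics for plotting.
        """
        observed = self.statistic()
        perm = permutation_test(
            self.phenotype,
            self.sites,
            scheme=self.weights,
            kernel=self.kernel,
            B=permutations,
            seed=seed,
            keep_null=keep_null,
        )
        return KernelAssociationResults(self, observed, perm)


class KernelAssociationResults:
    """Fitted kernel association test: statistic, p-value, diagnostics."""

    def __init__(self, model: KernelAssociationTest, kernel_result, permutation: PermutationResult):
        self.model = model
        self.kernel_result = kernel_result
        self.permutation = permutation

    @property
    def statistic(self) -> float:
        """The observed aggregate statistic S."""
        return self.kernel_result.S

    @property
    def pvalue(self) -> float:
        """Add-one permutation p-value, (count_ge + 1)/(B + 1)."""
        return self.permutation.p_value

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def n_sites(self) -> int:
        return self.model.n_sites

    @property
    def per_site(self) -> pd.DataFrame:
        """Per-site decomposition: coordinates, MAF, weight, Q and R."""
        rows = []
        for site, st, w in zip(
            self.model.sites, self.kernel_result.per_site, self.kernel_result.weights
        ):
            rows.append(
                {
                    "chrom": site.site_id.chrom,
                    "pos": site.site_id.pos,
                    "rsid": site.site_id.rsid,
                    "af": site.p,
                    "maf": min(site.p, 1 - site.p),
                    "weight": float(w),
                    "Q": st.Q,
                    "R": st.R,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary table."""
        p = self.permutation
        lines = [
            "Kernel Association Test",
            "=" * 56,
            f"{'Kernel:':<28}{p.kernel}",
            f"{'No. individuals:':<28}{p.n}",
            f"{'No. sites:':<28}{p.n_sites}",
            f"{'Statistic S:':<28}{self.statistic:.6g}",
            f"{'Permutations (B):':<28}{p.B}",
            f"{'Permuted >= observed:':<28}{p.count_ge}",
            f"{'Permutation p-value:':<28}{self.pvalue:.6g}",
            f"{'Seed:':<28}{p.seed}",
            "-" * 56,
        ]
        table = self.per_site
        lines.append(f"{'site':<20}{'maf':>9}{'weight':>9}{'Q':>9}{'R':>9}")
        for _, row in table.iterrows():
            label = row["rsid"] or f"{row['chrom']}:{row['pos']}"
            lines.append(
                f"{str(label):<20}{row['maf']:>9.4g}{row['weight']:>9.4g}"
                f"{row['Q']:>9.4g}{row['R']:>9.4g}"
            )
        lines.append("=" * 56)
        return "\n".join(lines)

    def plot_null(self, ax=None, bins: int = 50):
        """Histogram of the permutation null with the observed S marked.

        Requires ``fit(keep_null=True)``.
        """
        if self.permutation.null_statistics is None:
            raise InputError("refit with keep_null=True to plot the null distribution")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.permutation.null_statistics, bins=bins, color="0.7")
        ax.axvline(self.statistic, color="C3", label=f"observed S = {self.statistic:.4g}")
        ax.set_xlabel(f"permuted {self.permutation.kernel} statistic")
        ax.set_ylabel("count")
        ax.legend()
        return ax

    def __repr__(self) -> str:
        return (
            f"<KernelAssociationResults kernel={self.permutation.kernel} "
            f"S={self.statistic:.6g} p={self.pvalue:.4g} n={self.nobs} "
            f"sites={self.n_sites}>"
        )
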