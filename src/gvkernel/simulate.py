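"""Synthetic genotype and phenotype generation.

Genotypes are drawn independently per site under Hardy–Weinberg
equilibrium at a specified alternative-allele frequency p: an individual
is homozygous alternative with probability p², heterozygous with
2p(1−p) and homozygous reference otherwise.  Monomorphic realizations —
inevitable at rare frequencies in finite cohorts — are excluded, either
by dropping the site (default) or redrawing it.

Phenotypes follow a carrier model: individuals carrying at least one
alternative allele at any causal site are shifted by ``carrier_effect``
trait units (default −1.0 µg/dL, a realistic rare-variant effect on a
serum metabolite such as uric acid), and independent Normal(0, noise_sd)
environmental noise (default SD 1.0 µg/dL) is added to everyone.  An
additive per-site mode (one shift per causal site carried) is available
behind the ``effect_mode`` switch.

Sites are drawn independently, so the panel carries no linkage
disequilibrium; see the methods note for what that implies.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .core import GenotypeSite, InputError, SiteId, center_phenotype
from .kernels import GRM, WeightScheme
from .permutation import permutation_test, reject_null

__all__ = [
    "DEFAULT_SITE_FREQS",
    "SimulationConfig",
    "PowerResult",
    "simulate_genotypes",
    "simulate_phenotype",
    "power_experiment",
]

#: Default 7-site rare-variant panel: alternative-allele counts of
#: 1, 2, 3, 4, 5, 8 and 10 out of the 5008 haplotypes of a 2504-individual
#: cohort, mimicking the frequency spectrum of rare functional variants in
#: a single gene.
DEFAULT_SITE_FREQS: tuple[float, ...] = tuple(
    ac / 5008 for ac in (1, 2, 3, 4, 5, 8, 10)
)

_REDRAW_LIMIT = 10_000


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated cohort.

    Genotype and phenotype seeds are independent so the genotype panel can
    be held fixed while phenotype noise is redrawn across replicates.
    """

    n: int = 2504
    site_freqs: tuple[float, ...] = DEFAULT_SITE_FREQS
    carrier_effect: float = -1.0
    noise_sd: float = 1.0
    genotype_seed: int = 0
    phenotype_seed: int = 1
    monomorphic: str = "drop"  # or "redraw"
    effect_mode: str = "carrier"  # or "additive"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InputError(f"sample size must be at least 2, got {self.n}")
        freqs = tuple(float(p) for p in self.site_freqs)
        if len(freqs) == 0:
            raise InputError("at least one site frequency is required")
        for p in freqs:
            if not (0.0 < p < 1.0):
                raise InputError(f"allele frequency {p} outside the open interval (0, 1)")
        if not self.noise_sd > 0:
            raise InputError(f"noise SD must be positive, got {self.noise_sd}")
        if self.monomorphic not in ("drop", "redraw"):
            raise InputError(f"unknown monomorphic policy {self.monomorphic!r}")
        if self.effect_mode not in ("carrier", "additive"):
            raise InputError(f"unknown effect mode {self.effect_mode!r}")
        object.__setattr__(self, "site_freqs", freqs)


def _draw_site_values(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Draw n genotype values under HWE at alternative frequency p."""
    u = rng.random(n)
    values = np.zeros(n, dtype=np.int64)
    hom_alt = p * p
    het = 2.0 * p * (1.0 - p)
    values[u < hom_alt] = 2
    values[(u >= hom_alt) & (u < hom_alt + het)] = 1
    return values


def simulate_genotypes(config: SimulationConfig) -> list[GenotypeSite]:
    """Draw the genotype panel; monomorphic realizations dropped or redrawn.

    Deterministic given ``config.genotype_seed``.  Under the drop policy the
    returned list may be shorter than ``site_freqs`` (possibly empty at
    extreme rarity); under redraw each site is resampled until polymorphic.
    """
    rng = np.random.default_rng(config.genotype_seed)
    sites: list[GenotypeSite] = []
    for k, p in enumerate(config.site_freqs):
        values = _draw_site_values(rng, config.n, p)
        if config.monomorphic == "redraw":
            tries = 0
            while values.sum() in (0, 2 * config.n):
                tries += 1
                if tries > _REDRAW_LIMIT:
                    raise InputError(
                        f"site {k} at frequency {p} stayed monomorphic after "
                        f"{_REDRAW_LIMIT} redraws"
                    )
                values = _draw_site_values(rng, config.n, p)
        elif values.sum() in (0, 2 * config.n):
            continue
        site_id = SiteId(chrom="1", pos=1000 + k, rsid=f"sim{k}")
        sites.append(GenotypeSite.from_genotype_values(values, site_id))
    return sites


def simulate_phenotype(
    sites: Sequence[GenotypeSite], config: SimulationConfig
) -> np.ndarray:
    """Raw (uncentered) phenotype values for the cohort.

    Under the default carrier mode an individual is shifted by
    ``carrier_effect`` once if they carry ≥ 1 alternative allele at ≥ 1
    causal site; under additive mode, once per causal site carried.
    Deterministic given ``config.phenotype_seed``.  Centering is left to
    the caller (it is always applied before any statistic is computed).
    """
    if len(sites) == 0 and config.carrier_effect != 0.0:
        raise InputError("carrier effect requested but the causal site list is empty")
    for s in sites:
        if s.n != config.n:
            raise InputError(
                f"site {s.site_id} has {s.n} individuals, config says {config.n}"
            )
    rng = np.random.default_rng(config.phenotype_seed)
    shift = np.zeros(config.n, dtype=np.float64)
    if sites and config.carrier_effect != 0.0:
        G = np.stack([s.g for s in sites])
        if config.effect_mode == "carrier":
            shift = config.carrier_effect * (G > 0).any(axis=0).astype(np.float64)
        else:
            shift = config.carrier_effect * (G > 0).sum(axis=0).astype(np.float64)
    return shift + rng.normal(0.0, config.noise_sd, config.n)


@dataclasses.dataclass(frozen=True)
class PowerResult:
    """Rejection tally of a repeated simulate-and-test experiment."""

    kernel: str
    replicates: int
    rejections: int
    alpha: float
    B: int
    master_seed: int
    p_values: tuple[float, ...]


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def power_experiment(
    config: SimulationConfig,
    kernel: str = GRM,
    B: int = 999,
    alpha: float = 0.01,
    replicates: int = 10,
    master_seed: int = 0,
    redraw_genotypes: bool = False,
    scheme: Optional[WeightScheme] = None,
) -> PowerResult:
    """Repeat simulate → permutation-test → reject and count rejections.

    By default the genotype panel is drawn once from the master seed and
    held fixed across replicates, with fresh phenotype noise and a fresh
    permutation stream per replicate (a fixed cohort retested under new
    environmental noise).  ``redraw_genotypes=True`` resamples the panel
    each replicate instead.  Fully reproducible from ``master_seed``.
    """
    if replicates < 1:
        raise InputError(f"need at least 1 replicate, got {replicates}")
    root = np.random.SeedSequence(master_seed)
    geno_ss, pheno_ss, perm_ss = root.spawn(3)
    pheno_children = pheno_ss.spawn(replicates)
    perm_children = perm_ss.spawn(replicates)
    geno_children = geno_ss.spawn(replicates) if redraw_genotypes else None

    sites = None
    if not redraw_genotypes:
        cfg = dataclasses.replace(config, genotype_seed=_child_seed(geno_ss))
        sites = simulate_genotypes(cfg)
        if not sites:
            raise InputError("genotype panel is empty after monomorphic exclusion")

    rejections = 0
    p_values = []
    for r in range(replicates):
        if redraw_genotypes:
            cfg = dataclasses.replace(config, genotype_seed=_child_seed(geno_children[r]))
            sites = simulate_genotypes(cfg)
            if not sites:
                raise InputError(
                    f"replicate {r}: genotype panel empty after monomorphic exclusion"
                )
        else:
            cfg = config
        cfg = dataclasses.replace(cfg, phenotype_seed=_child_seed(pheno_children[r]))
        y = center_phenotype(simulate_phenotype(sites, cfg))
        result = permutation_test(
            y, sites, scheme=scheme, kernel=kernel, B=B, seed=_child_seed(perm_children[r])
        )
        p_values.append(result.p_value)
        if reject_null(result, alpha):
            rejections += 1

    return PowerResult(
        kernel=kernel,
        replicates=replicates,
        rejections=rejections,
        alpha=alpha,
        B=B,
        master_seed=int(master_seed),
        p_values=tuple(p_values),
    )
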