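"""Readers and writers for the formats the tool touches.

VCF genotypes are read through cyvcf2 (plain or bgzipped, GT field only);
phenotypes and per-site weights are plain TSV; results serialize to TSV
or JSON.  A minimal GT-only VCF writer lets the simulator exercise the
same file path as real data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    GenotypeSite,
    InputError,
    PhenotypeVector,
    SiteId,
    center_phenotype,
    is_monomorphic,
)
from .kernels import KernelTestResult, WeightScheme
from .permutation import PermutationResult

__all__ = [
    "CohortData",
    "read_vcf",
    "write_vcf",
    "read_phenotype",
    "write_phenotype",
    "read_weights",
    "write_result",
    "result_to_dict",
    "load_cohort",
]

logger = logging.getLogger("gvkernel.io")

PathLike = Union[str, Path]


@dataclasses.dataclass(frozen=True)
class CohortData:
    """Genotypes and phenotype aligned on one ordered set of individuals."""

    individual_ids: tuple[str, ...]
    sites: tuple[GenotypeSite, ...]
    phenotype: PhenotypeVector

    def __post_init__(self) -> None:
        n = len(self.individual_ids)
        if self.phenotype.n != n:
            raise InputError("phenotype length does not match individual count")
        for s in self.sites:
            if s.n != n:
                raise InputError(f"site {s.site_id} does not match individual count")

    @property
    def n(self) -> int:
        return len(self.individual_ids)


def _parse_region(region: str) -> tuple[str, Optional[int], Optional[int]]:
    if ":" not in region:
        return region, None, None
    chrom, _, span = region.partition(":")
    start_s, _, end_s = span.partition("-")
    try:
        start = int(start_s.replace(",", ""))
        end = int(end_s.replace(",", "")) if end_s else start
    except ValueError:
        raise InputError(f"malformed region {region!r}; expected chrom or chrom:start-end")
    return chrom, start, end


def read_vcf(
    path: PathLike,
    region: Optional[str] = None,
    missing: str = "error",
) -> tuple[list[str], list[GenotypeSite]]:
    """Read biallelic GT records into genotype sites.

    Multiallelic, non-diploid and monomorphic records are skipped with a
    logged count; missing calls follow ``missing`` ("error", "drop-site"
    or "ref-impute").  Coordinates stay 1-based as in the file.
    """
    if missing not in ("error", "drop-site", "ref-impute"):
        raise InputError(f"unknown missing-data policy {missing!r}")
    try:
        vcf = VCF(str(path))
    except OSError as exc:
        raise OSError(f"cannot open VCF {path}: {exc}") from exc
    ids = list(vcf.samples)
    if not ids:
        raise InputError(f"VCF {path} declares no samples")
    want = _parse_region(region) if region else None

    counts: Counter = Counter()
    sites: list[GenotypeSite] = []
    for v in vcf:
        if want is not None:
            chrom, start, end = want
            if v.CHROM != chrom:
                continue
            if start is not None and not (start <= v.POS <= end):
                continue
        counts["records"] += 1
        if len(v.ALT) != 1:
            counts["skipped_multiallelic"] += 1
            continue
        site_id = SiteId(chrom=str(v.CHROM), pos=int(v.POS), rsid=v.ID or None)
        values = np.empty(len(ids), dtype=np.int64)
        usable = True
        for i, gt in enumerate(v.genotypes):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) != 2:
                counts["skipped_non_diploid"] += 1
                usable = False
                break
            if any(a < 0 for a in alleles):  # ./., half-calls treated alike
                if missing == "error":
                    raise InputError(
                        f"missing genotype for individual {ids[i]} at site {site_id}"
                    )
                if missing == "drop-site":
                    counts["skipped_missing"] += 1
                    usable = False
                    break
                values[i] = 0
                continue
            if any(a > 1 for a in alleles):
                counts["skipped_bad_allele"] += 1
                usable = False
                break
            values[i] = alleles[0] + alleles[1]
        if not usable:
            continue
        site = GenotypeSite.from_genotype_values(values, site_id)
        if is_monomorphic(site):
            counts["skipped_monomorphic"] += 1
            continue
        sites.append(site)
        counts["used"] += 1

    logger.info(
        "read_vcf %s: %d records, %d used, skipped: %d multiallelic, %d monomorphic, "
        "%d missing, %d non-diploid, %d bad-allele",
        path,
        counts["records"],
        counts["used"],
        counts["skipped_multiallelic"],
        counts["skipped_monomorphic"],
        counts["skipped_missing"],
        counts["skipped_non_diploid"],
        counts["skipped_bad_allele"],
    )
    if not sites:
        raise InputError(f"no usable sites in {path}")
    return ids, sites


def write_vcf(
    path: PathLike,
    individual_ids: Sequence[str],
    sites: Sequence[GenotypeSite],
    source: str = "gvkernel",
) -> None:
    """Write sites as a minimal GT-only VCF 4.2 text file."""
    ids = list(individual_ids)
    for s in sites:
        if s.n != len(ids):
            raise InputError(f"site {s.site_id} does not match individual count")
    chroms = []
    for s in sites:
        if s.site_id.chrom not in chroms:
            chroms.append(s.site_id.chrom)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ids)
            + "\n"
        )
        for s in sites:
            row = [
                s.site_id.chrom,
                str(s.site_id.pos),
                s.site_id.rsid or ".",
                "A",
                "T",
                ".",
                "PASS",
                ".",
                "GT",
            ] + s.calls()
            fh.write("\t".join(row) + "\n")


def read_phenotype(path: PathLike, individual_ids: Sequence[str]) -> PhenotypeVector:
    """Read and center a phenotype table aligned to ``individual_ids``.

    Accepts a 2-column TSV (individual id, value) in any row order, or a
    1-column file of values already in sample order.  Every individual
    must appear exactly once; non-numeric values are reported by id.
    """
    ids = list(individual_ids)
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, dtype=str, comment="#", keep_default_na=False
        )
    except OSError as exc:
        raise OSError(f"cannot read phenotype file {path}: {exc}") from exc
    if df.shape[1] == 1:
        values = pd.to_numeric(df[0], errors="coerce")
        if df.shape[0] != len(ids):
            raise InputError(
                f"{path}: {df.shape[0]} values for {len(ids)} individuals "
                "(1-column files must follow VCF sample order)"
            )
        bad = values.index[values.isna()]
        if len(bad):
            raise InputError(f"{path}: non-numeric phenotype value on row {bad[0] + 1}")
        return center_phenotype(values.to_numpy())

    # possible header row: non-numeric value whose id matches no individual
    first_val = pd.to_numeric(pd.Series([df.iloc[0, 1]]), errors="coerce")
    if first_val.isna().iloc[0] and df.iloc[0, 0] not in ids:
        df = df.iloc[1:].reset_index(drop=True)
    keys = df[0].tolist()
    dup = pd.Series(keys)
    if dup.duplicated().any():
        raise InputError(f"{path}: duplicate individual id {dup[dup.duplicated()].iloc[0]!r}")
    values = pd.to_numeric(df[1], errors="coerce")
    bad = values.index[values.isna()]
    if len(bad):
        raise InputError(
            f"{path}: non-numeric phenotype value {df.iloc[bad[0], 1]!r} "
            f"for individual {df.iloc[bad[0], 0]!r}"
        )
    table = dict(zip(keys, values.to_numpy()))
    ordered = []
    for ind in ids:
        if ind not in table:
            raise InputError(f"{path}: no phenotype for individual {ind!r}")
        ordered.append(table[ind])
    return center_phenotype(np.asarray(ordered, dtype=np.float64))


def write_phenotype(path: PathLike, individual_ids: Sequence[str], values) -> None:
    """Write raw phenotype values as a 2-column TSV (id, value)."""
    vals = np.asarray(values, dtype=np.float64)
    if vals.size != len(individual_ids):
        raise InputError("phenotype length does not match individual count")
    with open(path, "w", encoding="utf-8") as fh:
        for ind, v in zip(individual_ids, vals):
            fh.write(f"{ind}\t{v:.12g}\n")


def read_weights(path: PathLike, sites: Sequence[GenotypeSite]) -> WeightScheme:
    """Read a 2-column TSV of per-site weights keyed by "chrom:pos" or rsID.

    Every site must resolve to a weight; silent dropping would corrupt S.
    """
    df = pd.read_csv(
        path, sep=r"\s+", header=None, dtype=str, comment="#", keep_default_na=False
    )
    if df.shape[1] < 2:
        raise InputError(f"{path}: weight files need two columns (site key, weight)")
    table: dict[str, float] = {}
    for _, row in df.iterrows():
        try:
            table[str(row[0])] = float(row[1])
        except ValueError:
            raise InputError(f"{path}: non-numeric weight {row[1]!r} for site {row[0]!r}")
    weights = []
    for s in sites:
        if s.site_id.key in table:
            weights.append(table[s.site_id.key])
        elif s.site_id.rsid and s.site_id.rsid in table:
            weights.append(table[s.site_id.rsid])
        else:
            raise InputError(f"{path}: no weight for site {s.site_id}")
    return WeightScheme.custom_weights(weights)


def result_to_dict(result: Union[KernelTestResult, PermutationResult]) -> dict:
    """Plain-JSON representation of a result object."""
    if isinstance(result, PermutationResult):
        return {
            "type": "permutation",
            "kernel": result.kernel,
            "S": result.observed_S,
            "B": result.B,
            "count_ge": result.count_ge,
            "p_value": result.p_value,
            "seed": result.seed,
            "n": result.n,
            "n_sites": result.n_sites,
        }
    if isinstance(result, KernelTestResult):
        return {
            "type": "kernel_statistic",
            "kernel": result.kernel,
            "S": result.S,
            "n_sites": result.n_sites,
            "per_site": [
                {
                    "chrom": st.site_id.chrom,
                    "pos": st.site_id.pos,
                    "rsid": st.site_id.rsid,
                    "weight": float(w),
                    "Q": st.Q,
                    "R": st.R,
                }
                for st, w in zip(result.per_site, result.weights)
            ],
        }
    raise InputError(f"cannot serialize object of type {type(result).__name__}")


def write_result(
    result: Union[KernelTestResult, PermutationResult],
    path: PathLike,
    format: str = "json",
) -> None:
    """Serialize a result to JSON (nested) or TSV (flat, headered).

    Numeric fields keep at least 12 significant digits in TSV; JSON keeps
    full double precision.
    """
    payload = result_to_dict(result)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
        return
    if format != "tsv":
        raise InputError(f"unknown result format {format!r}")

    def fmt(v) -> str:
        if isinstance(v, float):
            return f"{v:.12g}"
        return "" if v is None else str(v)

    with open(path, "w", encoding="utf-8") as fh:
        if payload["type"] == "permutation":
            cols = ["kernel", "S", "B", "count_ge", "p_value", "seed", "n", "n_sites"]
            fh.write("\t".join(cols) + "\n")
            fh.write("\t".join(fmt(payload[c]) for c in cols) + "\n")
        else:
            cols = ["kernel", "S", "n_sites", "chrom", "pos", "rsid", "weight", "Q", "R"]
            fh.write("\t".join(cols) + "\n")
            for row in payload["per_site"]:
                fh.write(
                    "\t".join(
                        fmt(v)
                        for v in (
                            payload["kernel"],
                            payload["S"],
                            payload["n_sites"],
                            row["chrom"],
                            row["pos"],
                            row["rsid"],
                            row["weight"],
                            row["Q"],
                            row["R"],
                        )
                    )
                    + "\n"
                )


def load_cohort(
    vcf_path: PathLike,
    phenotype_path: PathLike,
    region: Optional[str] = None,
    missing: str = "error",
) -> CohortData:
    """Read a VCF and a phenotype table into one aligned cohort."""
    ids, sites = read_vcf(vcf_path, region=region, missing=missing)
    phenotype = read_phenotype(phenotype_path, ids)
    return CohortData(
        individual_ids=tuple(ids), sites=tuple(sites), phenotype=phenotype
    )
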