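"""Genome-composition accounting, sequencing summary arithmetic, and the
sample- and site-level QC filters.

Composition proportions are taken over the scaffolded portion of the
assembly (assembly length x fraction of the genome placed in scaffolds),
since unscaffolded contigs never enter the whole-genome alignment; a
flag restores the raw assembly length as denominator.  All QC boundaries
are strict "below removes": coverage < 10x, alignment < 75%, carrier
fraction < 10% of samples, summed supporting reads < 20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenomeRegion, GenotypeMatrix, SampleRecord


def region_composition_summary(
    regions: list[GenomeRegion],
    assembly_length: int,
    scaffold_fraction: float = 1.0,
    use_raw_assembly_length: bool = False,
) -> pd.DataFrame:
    """Per-region-type count, mean size +/- sd (Kbp), total (Mbp), proportion.

    Region types may overlap on the genome, so proportions need not sum
    to 1.  The sd is the population standard deviation of region lengths.
    """
    if not (0.0 < scaffold_fraction <= 1.0):
        raise ValueError("scaffold_fraction must be in (0, 1]")
    denom = assembly_length if use_raw_assembly_length else assembly_length * scaffold_fraction
    rows = []
    by_type: dict[str, list[int]] = {}
    for reg in regions:
        by_type.setdefault(reg.region_type.value, []).append(reg.length)
    for rtype, lengths in sorted(by_type.items()):
        arr = np.asarray(lengths, dtype=float)
        total = float(arr.sum())
        rows.append(
            {
                "region_type": rtype,
                "count": arr.size,
                "mean_size_kbp": arr.mean() / 1e3,
                "sd_size_kbp": arr.std(ddof=0) / 1e3,
                "total_mbp": total / 1e6,
                "proportion_pct": 100.0 * total / denom,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["region_type", "count", "mean_size_kbp", "sd_size_kbp",
                 "total_mbp", "proportion_pct"],
    )


def estimate_coverage(total_bases: int, assembly_length: int) -> float:
    """Sequencing depth = total sequenced bases / assembly length (2 dp)."""
    if assembly_length <= 0:
        raise ValueError("assembly_length must be positive")
    return round(total_bases / assembly_length, 2)


def informative_pair_fraction(n_informative_pairs: int, n_total_pairs: int) -> float:
    """Percentage of read pairs carrying linkage information (2 dp)."""
    if n_total_pairs <= 0:
        raise ValueError("n_total_pairs must be positive")
    return round(100.0 * n_informative_pairs / n_total_pairs, 2)


def variable_site_fraction(
    n_variable_sites: int,
    assembly_length: int,
    scaffold_fraction: float = 1.0,
) -> float:
    """Percentage of the (scaffolded) genome that is variable (2 dp)."""
    if not (0.0 < scaffold_fraction <= 1.0):
        raise ValueError("scaffold_fraction must be in (0, 1]")
    return round(100.0 * n_variable_sites / (assembly_length * scaffold_fraction), 2)


@dataclass(frozen=True)
class Exclusion:
    sample_id: str
    reason: str


def qc_filter_samples(
    samples: list[SampleRecord],
    min_coverage: float = 10.0,
    min_alignment: float = 0.75,
) -> tuple[list[SampleRecord], list[Exclusion]]:
    """Drop low-coverage, low-alignment, and PCA-flagged samples.

    Rules are applied in a fixed order — coverage, then alignment, then
    the PCA flag — and each excluded sample is reported once with the
    first failing rule as its reason.  Boundary values are kept (only
    strictly-below values are removed).
    """
    retained = []
    excluded = []
    for s in samples:
        if s.est_coverage < min_coverage:
            excluded.append(Exclusion(s.sample_id, f"coverage<{min_coverage:g}x"))
        elif s.pct_aligned < min_alignment:
            excluded.append(Exclusion(s.sample_id, f"alignment<{100 * min_alignment:g}%"))
        elif s.excluded_by_pca:
            excluded.append(Exclusion(s.sample_id, "pca_outlier"))
        else:
            retained.append(s)
    return retained, excluded


def filter_snp_sites(
    matrix: GenotypeMatrix,
    min_sample_fraction: float = 0.10,
    min_supporting_reads: int = 20,
    biallelic_only: bool = True,
    per_sample_depth: bool = False,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Site-level variant filters: carrier fraction, support depth, biallelic.

    Removes sites carried (genotype >= 1) by fewer than
    ``min_sample_fraction`` of the genotyped samples, sites whose
    alternate-supporting read depth — summed over carrier samples by
    default, or required per carrier sample with ``per_sample_depth`` —
    is below ``min_supporting_reads``, and (when ``biallelic_only``)
    indels and multiallelic records.  The first failing rule wins, and
    the report lists each removed site once with its reason.
    """
    reasons: list[dict] = []
    keep_ids: list[str] = []
    calls = matrix.calls
    meta = matrix.variant_meta
    for j, vid in enumerate(matrix.variant_ids):
        col = calls[:, j]
        genotyped = col != MISSING
        n_geno = int(genotyped.sum())
        carriers = (col >= 1) & genotyped
        reason = None
        if biallelic_only and meta is not None:
            row = meta.iloc[j]
            if bool(row["is_indel"]):
                reason = "indel"
            elif bool(row["is_multiallelic"]):
                reason = "multiallelic"
        if reason is None:
            frac = carriers.sum() / n_geno if n_geno else 0.0
            if frac < min_sample_fraction:
                reason = f"carriers<{100 * min_sample_fraction:g}%_of_samples"
        if reason is None and matrix.depths is not None:
            depths = matrix.depths[:, j]
            carrier_depths = depths[carriers]
            if per_sample_depth:
                low = carrier_depths.size == 0 or carrier_depths.min() < min_supporting_reads
            else:
                low = carrier_depths.sum() < min_supporting_reads
            if low:
                reason = f"supporting_reads<{min_supporting_reads}"
        if reason is None:
            keep_ids.append(vid)
        else:
            reasons.append({"variant_id": vid, "reason": reason})
    report = pd.DataFrame(reasons, columns=["variant_id", "reason"])
    return matrix.subset_variants(keep_ids), report
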