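"""SV linkage from genotype-matrix correlation.

Co-occurrence of structural arrangements across individuals is measured
as the Pearson correlation of 0/1/2 genotype columns over pairwise-
complete samples.  Pairs with R^2 at or above a threshold (0.6 by
default) are called linked, and linked pairs are decomposed by whether
the two SVs share a chromosome and, if so, by their physical separation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_formats import GenomeRegion, GenotypeMatrix


@dataclass(frozen=True)
class LinkagePair:
    """Correlation of one unordered SV pair across shared samples."""

    sv_id_1: str
    sv_id_2: str
    r: float
    n_shared: int
    same_chromosome: bool | None = None
    separation_bp: int | None = None  # undefined when on different chromosomes
    category_1: str = ""
    category_2: str = ""

    @property
    def r2(self) -> float:
        return self.r * self.r


def pool_matrices(
    matrix_a: GenotypeMatrix,
    matrix_b: GenotypeMatrix,
    flip_b: bool = True,
) -> GenotypeMatrix:
    """Stack both populations' calls into one matrix in a single polarity.

    Population B was genotyped against its own reference, where ALT is
    the genome-A arrangement; ``flip_b`` recodes those calls (0<->2) so
    every column counts the genome-B arrangement for all individuals.
    Only SVs genotyped in both populations (symmetric events) are kept.
    """
    shared = [v for v in matrix_a.variant_ids if v in set(matrix_b.variant_ids)]
    sub_a = matrix_a.subset_variants(shared)
    sub_b = matrix_b.subset_variants(shared)
    calls_b = sub_b.calls.copy()
    if flip_b:
        mask = calls_b != -1
        calls_b[mask] = 2 - calls_b[mask]
    return GenotypeMatrix(
        sub_a.sample_ids + sub_b.sample_ids,
        shared,
        np.vstack([sub_a.calls, calls_b]),
        None,
        sub_a.variant_meta,
    )


def genotype_correlation(
    matrix: GenotypeMatrix,
    min_shared: int = 3,
    categories: dict[str, str] | None = None,
) -> list[LinkagePair]:
    """All pairwise genotype correlations over pairwise-complete samples.

    Each unordered pair appears at most once.  A pair is dropped when the
    correlation is undefined — fewer than ``min_shared`` samples are
    genotyped for both SVs, or either column is constant on the shared
    samples — mirroring the removal of undefined correlations from the
    published heatmaps.
    """
    if matrix.n_variants < 2 or matrix.n_samples == 0:
        raise ValueError("need a non-empty matrix with at least 2 SVs")
    frame = matrix.to_frame()
    corr = frame.corr(method="pearson", min_periods=max(min_shared, 2))
    notna = frame.notna().to_numpy(dtype=np.int64)
    shared = notna.T @ notna
    cats = categories or {}
    pairs: list[LinkagePair] = []
    ids = matrix.variant_ids
    cvals = corr.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = cvals[i, j]
            n = int(shared[i, j])
            if n < min_shared or not np.isfinite(r):
                continue
            pairs.append(
                LinkagePair(
                    ids[i], ids[j], float(r), n,
                    category_1=cats.get(ids[i], ""),
                    category_2=cats.get(ids[j], ""),
                )
            )
    return pairs


def genotype_correlation_by_group(
    matrix: GenotypeMatrix,
    groups: dict[str, str],
    min_shared: int = 3,
) -> dict[str, list[LinkagePair]]:
    """Correlations computed within groups (e.g. sv_type x category).

    SVs without a group label are skipped; groups with fewer than two
    SVs yield no pairs.
    """
    out: dict[str, list[LinkagePair]] = {}
    by_group: dict[str, list[str]] = {}
    for sv_id in matrix.variant_ids:
        if sv_id in groups:
            by_group.setdefault(groups[sv_id], []).append(sv_id)
    for label, ids in sorted(by_group.items()):
        if len(ids) < 2:
            out[label] = []
            continue
        sub = matrix.subset_variants(ids)
        out[label] = genotype_correlation(sub, min_shared=min_shared)
    return out


def linked_pairs(pairs: list[LinkagePair], threshold: float = 0.6) -> list[LinkagePair]:
    """Keep pairs with R^2 >= threshold (inclusive)."""
    return [p for p in pairs if p.r2 >= threshold]


def pair_separation(
    pairs: list[LinkagePair],
    sv_regions: dict[str, GenomeRegion],
) -> tuple[list[LinkagePair], dict]:
    """Annotate pairs with chromosome co-location and physical separation.

    Separation is the gap between the two intervals in one reference
    genome: 0 when they overlap or abut, otherwise the distance between
    the nearer ends.  Pairs on different chromosomes have no separation.
    The summary reports the cross-chromosome fraction and the minimum and
    median same-chromosome separation.
    """
    annotated = []
    seps = []
    n_diff = 0
    for p in pairs:
        try:
            reg1, reg2 = sv_regions[p.sv_id_1], sv_regions[p.sv_id_2]
        except KeyError as exc:
            raise ValueError(f"no region for SV {exc.args[0]!r}") from exc
        if reg1.chrom != reg2.chrom:
            n_diff += 1
            annotated.append(replace(p, same_chromosome=False, separation_bp=None))
            continue
        first, second = sorted((reg1, reg2), key=lambda r: r.start)
        sep = max(0, second.start - first.end)
        seps.append(sep)
        annotated.append(replace(p, same_chromosome=True, separation_bp=sep))
    total = len(annotated)
    summary = {
        "n_pairs": total,
        "n_different_chromosome": n_diff,
        "fraction_different_chromosome": n_diff / total if total else float("nan"),
        "min_same_chromosome_separation_bp": int(min(seps)) if seps else None,
        "median_same_chromosome_separation_bp": float(np.median(seps)) if seps else None,
    }
    return annotated, summary


def pairs_to_frame(pairs: list[LinkagePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sv_id_1": p.sv_id_1,
                "sv_id_2": p.sv_id_2,
                "r": p.r,
                "r2": p.r2,
                "n_shared": p.n_shared,
                "same_chromosome": p.same_chromosome,
                "separation_bp": p.separation_bp,
                "category_1": p.category_1,
                "category_2": p.category_2,
            }
            for p in pairs
        ],
        columns=[
            "sv_id_1", "sv_id_2", "r", "r2", "n_shared", "same_chromosome",
            "separation_bp", "category_1", "category_2",
        ],
    )


def r2_matrix(pairs: list[LinkagePair], variant_ids: list[str]) -> pd.DataFrame:
    """Square R^2 matrix (NaN where the correlation was undefined)."""
    mat = pd.DataFrame(np.nan, index=variant_ids, columns=variant_ids)
    for v in variant_ids:
        mat.loc[v, v] = 1.0
    for p in pairs:
        mat.loc[p.sv_id_1, p.sv_id_2] = p.r2
        mat.loc[p.sv_id_2, p.sv_id_1] = p.r2
    return mat
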