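"""Per-SNP Weir & Cockerham fixation index, SNP density, region means of a
windowed recombination track, region selection, and region-type contrasts.

The two-population theta estimator is implemented directly from the 1984
variance-component decomposition (a: among populations, b: among
individuals within populations, c: within individuals), per SNP, with
heterozygote proportions taken from the diploid genotype counts.  Theta
is deliberately not clamped to [0, 1]: slightly negative estimates near
zero differentiation are kept so region averages stay unbiased.

Region-type contrasts use one-way fixed-effects ANOVA followed by the
Tukey-Kramer HSD procedure (studentized-range distribution, df = N - k),
with syntenic regions as the reference level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenomeRegion, GenotypeMatrix, RegionType, WindowTrack
from .sv_classify import Category, SVClassification

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpCounts:
    """Per-SNP genotype summary for the two populations.

    n1/n2 are diploid sample counts genotyped at the site, p1/p2 the
    alternate-allele frequencies, h1/h2 the observed heterozygote
    proportions.
    """

    chrom: str
    pos: int
    n1: int
    n2: int
    p1: float
    p2: float
    h1: float
    h2: float

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError(f"SNP {self.chrom}:{self.pos}: both populations "
                             "must have at least one genotyped sample")


@dataclass(frozen=True)
class FstComponents:
    """Weir-Cockerham intermediates and variance components for one SNP."""

    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    h_bar: float
    a: float
    b: float
    c: float

    @property
    def theta(self) -> float:
        """a / (a + b + c); NaN when the denominator is zero."""
        denom = self.a + self.b + self.c
        if denom == 0:
            return math.nan
        return self.a / denom


def wc_fst(snp: SnpCounts) -> FstComponents:
    """Weir & Cockerham two-population theta components for one SNP."""
    n1, n2 = float(snp.n1), float(snp.n2)
    p1, p2, h1, h2 = snp.p1, snp.p2, snp.h1, snp.h2
    r = 2.0
    n_sum = n1 + n2
    n_bar = n_sum / r
    n_c = (n_sum - (n1 * n1 + n2 * n2) / n_sum) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / n_sum
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / n_sum
    if n_bar <= 1.0:
        raise ValueError("theta is undefined for single-sample populations (n_bar <= 1)")
    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1.0)) * (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return FstComponents(n_bar, n_c, p_bar, s2, h_bar, a, b, c)


def snp_counts_from_matrix(
    matrix: GenotypeMatrix,
    population_of: dict[str, str],
    pop1: str = "A",
    pop2: str = "B",
) -> list[SnpCounts]:
    """Summarize a combined-population SNP genotype matrix per site.

    Sites where either population has no genotyped sample are skipped.
    Positions come from the matrix's VCF-derived site metadata.
    """
    if matrix.variant_meta is None:
        raise ValueError("matrix has no site metadata (chrom/pos); read from VCF")
    idx1 = [i for i, s in enumerate(matrix.sample_ids) if population_of.get(s) == pop1]
    idx2 = [i for i, s in enumerate(matrix.sample_ids) if population_of.get(s) == pop2]
    if not idx1 or not idx2:
        raise ValueError("both populations need at least one sample in the matrix")
    out = []
    calls = matrix.calls
    meta = matrix.variant_meta
    for j in range(matrix.n_variants):
        row = {}
        for key, idx in (("1", idx1), ("2", idx2)):
            sub = calls[idx, j]
            geno = sub[sub != MISSING]
            n = geno.size
            row["n" + key] = n
            row["p" + key] = float(geno.sum()) / (2.0 * n) if n else math.nan
            row["h" + key] = float((geno == 1).sum()) / n if n else math.nan
        if row["n1"] == 0 or row["n2"] == 0:
            continue
        out.append(
            SnpCounts(
                chrom=str(meta.iloc[j]["chrom"]),
                pos=int(meta.iloc[j]["pos"]),
                **row,
            )
        )
    return out


def fst_frame(snps: list[SnpCounts]) -> pd.DataFrame:
    """Per-SNP theta table (chrom, pos, theta, components)."""
    rows = []
    for snp in snps:
        comp = wc_fst(snp)
        rows.append(
            {
                "chrom": snp.chrom,
                "pos": snp.pos,
                "a": comp.a,
                "b": comp.b,
                "c": comp.c,
                "theta": comp.theta,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "a", "b", "c", "theta"])


def mean_fst(frame: pd.DataFrame, weighted: bool = True) -> float:
    """Multi-locus fixation index from a per-SNP component table.

    The weighted (ratio-of-sums) form sum(a) / sum(a+b+c) is the
    conventional multi-locus Weir-Cockerham estimate and is nearly
    unbiased; the unweighted form averages per-SNP theta, dropping
    undefined sites, and is biased toward zero by low-information SNPs.
    """
    if weighted:
        denom = (frame["a"] + frame["b"] + frame["c"]).sum()
        if denom == 0:
            return math.nan
        return float(frame["a"].sum() / denom)
    return float(frame["theta"].mean())


# ---------------------------------------------------------------------------
# Per-region aggregation
# ---------------------------------------------------------------------------


def snp_density(
    regions: list[GenomeRegion],
    snp_positions: dict[str, np.ndarray],
) -> pd.DataFrame:
    """SNP count and SNPs/kb per region (half-open membership).

    A SNP at ``pos`` counts for region [start, end) iff start <= pos < end;
    overlapping regions each count it.  ``snp_positions`` maps chromosome
    to a sorted array of SNP positions.
    """
    rows = []
    sorted_pos = {c: np.sort(np.asarray(p)) for c, p in snp_positions.items()}
    for reg in regions:
        pos = sorted_pos.get(reg.chrom)
        if pos is None:
            n = 0
        else:
            n = int(np.searchsorted(pos, reg.end, "left") - np.searchsorted(pos, reg.start, "left"))
        rows.append(
            {
                "region_id": reg.region_id,
                "region_type": reg.region_type.value,
                "n_snps": n,
                "snps_per_kb": 1000.0 * n / reg.length,
            }
        )
    return pd.DataFrame(rows, columns=["region_id", "region_type", "n_snps", "snps_per_kb"])


def region_mean_track(
    track: WindowTrack,
    regions: list[GenomeRegion],
    overlap_weighted: bool = True,
) -> pd.DataFrame:
    """Mean track value per region.

    Overlap-weighted mode weights each window's value by the number of
    bases it shares with the region; the alternative averages whole
    windows that overlap the region at all.  Regions overlapping no
    window get NaN.
    """
    by_chrom = track.by_chrom()
    rows = []
    for reg in regions:
        mean = math.nan
        n_win = 0
        if reg.chrom in by_chrom:
            starts, ends, values = by_chrom[reg.chrom]
            lo = np.searchsorted(ends, reg.start, "right")
            hi = np.searchsorted(starts, reg.end, "left")
            if hi > lo:
                w_starts, w_ends, w_vals = starts[lo:hi], ends[lo:hi], values[lo:hi]
                overlap = np.minimum(w_ends, reg.end) - np.maximum(w_starts, reg.start)
                keep = overlap > 0
                n_win = int(keep.sum())
                if n_win:
                    if overlap_weighted:
                        mean = float(
                            (w_vals[keep] * overlap[keep]).sum() / overlap[keep].sum()
                        )
                    else:
                        mean = float(w_vals[keep].mean())
        rows.append(
            {
                "region_id": reg.region_id,
                "region_type": reg.region_type.value,
                "n_windows": n_win,
                "mean_value": mean,
            }
        )
    return pd.DataFrame(rows, columns=["region_id", "region_type", "n_windows", "mean_value"])


def region_mean_snp(
    regions: list[GenomeRegion],
    snp_frame: pd.DataFrame,
    value_col: str = "theta",
) -> pd.DataFrame:
    """Unweighted mean of a per-SNP value over SNPs inside each region.

    Sites with an undefined value (NaN theta, e.g. monomorphic across
    both populations) are excluded from the mean rather than counted as
    zero.  Regions with no informative SNP get NaN.
    """
    rows = []
    frame = snp_frame.dropna(subset=[value_col])
    by_chrom = {
        str(chrom): (grp["pos"].to_numpy(), grp[value_col].to_numpy())
        for chrom, grp in frame.groupby("chrom", sort=False)
    }
    for c in by_chrom:
        pos, val = by_chrom[c]
        order = np.argsort(pos, kind="stable")
        by_chrom[c] = (pos[order], val[order])
    for reg in regions:
        mean = math.nan
        n = 0
        if reg.chrom in by_chrom:
            pos, val = by_chrom[reg.chrom]
            lo = np.searchsorted(pos, reg.start, "left")
            hi = np.searchsorted(pos, reg.end, "left")
            n = int(hi - lo)
            if n:
                mean = float(val[lo:hi].mean())
        rows.append(
            {
                "region_id": reg.region_id,
                "region_type": reg.region_type.value,
                "n_snps": n,
                "mean_value": mean,
            }
        )
    return pd.DataFrame(rows, columns=["region_id", "region_type", "n_snps", "mean_value"])


def select_regions(
    regions: list[GenomeRegion],
    classifications: list[SVClassification] | None = None,
    min_length: int = 2000,
    require_fixed: bool = True,
    include_both_fixed: bool = False,
) -> list[GenomeRegion]:
    """Apply the region filters used before the region-type contrasts.

    SV regions are kept when their cross-species classification is a
    fixed difference (SD; optionally also both-fixed private calls) and
    their length is at least ``min_length`` — low-frequency arrangements
    cannot leave a detectable footprint, and events shorter than the
    track window add noise.  Gene/TE/syntenic regions are filtered by
    length only.
    """
    from .io_formats import SV_TYPES

    fixed_ids: set[str] = set()
    if classifications is not None:
        for c in classifications:
            if c.category is Category.SD:
                fixed_ids.add(c.sv_id)
            elif (
                include_both_fixed
                and c.category is Category.PRIVATE_OR_ARTIFACT
                and c.sub_label == "both_fixed"
            ):
                fixed_ids.add(c.sv_id)
    out = []
    for reg in regions:
        if reg.length < min_length:
            continue
        if reg.region_type in SV_TYPES and require_fixed:
            if classifications is not None and reg.region_id not in fixed_ids:
                continue
        out.append(reg)
    return out


# ---------------------------------------------------------------------------
# ANOVA + Tukey-Kramer HSD
# ---------------------------------------------------------------------------


@dataclass
class TukeyResult:
    """One-way ANOVA and all-pairs Tukey-Kramer comparison across groups."""

    f_statistic: float
    p_value: float
    degenerate: bool
    group_stats: pd.DataFrame  # group, n, mean, ci_low, ci_high
    pairwise: pd.DataFrame  # group_1, group_2, diff, p_adj, ci_low, ci_high
    excluded_groups: list[str]

    def significant_vs_reference(
        self, reference: str = RegionType.SYNTENIC.value, alpha: float = 0.05
    ) -> dict[str, bool]:
        """Which groups differ from the reference at adjusted p <= alpha."""
        out = {}
        for _, row in self.pairwise.iterrows():
            if reference in (row["group_1"], row["group_2"]):
                other = row["group_2"] if row["group_1"] == reference else row["group_1"]
                out[other] = bool(row["p_adj"] <= alpha)
        return out


def anova_tukey(
    values_by_group: dict[str, list[float] | np.ndarray],
    alpha: float = 0.05,
    compute_pairwise: bool = True,
) -> TukeyResult:
    """One-way fixed-effects ANOVA plus Tukey-Kramer HSD across groups.

    Groups with fewer than two finite values are excluded with a logged
    notice; NaNs are dropped beforehand.  Adjusted p-values and
    simultaneous CIs come from the studentized-range distribution with
    df = N - k (Tukey-Kramer for unequal group sizes).  A fully
    degenerate input (zero within-group variance everywhere) is flagged
    rather than raising.  ``compute_pairwise=False`` skips the Tukey
    comparisons and returns only the omnibus ANOVA (cheap when many
    replicates are screened for overall significance).
    """
    clean: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for name, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < 2:
            excluded.append(name)
            logger.info("group %r excluded from ANOVA: fewer than 2 values", name)
            continue
        clean[name] = arr
    if len(clean) < 2:
        raise ValueError("need at least two groups with >= 2 values each")
    names = sorted(clean)
    samples = [clean[g] for g in names]
    n_total = sum(a.size for a in samples)
    k = len(samples)
    df_within = n_total - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in samples) / df_within
    degenerate = mse == 0.0

    if degenerate:
        f_stat, p_val = math.nan, math.nan
    else:
        f_stat, p_val = stats.f_oneway(*samples)
        f_stat, p_val = float(f_stat), float(p_val)

    group_rows = []
    for g, arr in zip(names, samples):
        mean = float(arr.mean())
        sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
        half = stats.t.ppf(1.0 - alpha / 2.0, arr.size - 1) * sem
        group_rows.append(
            {"group": g, "n": arr.size, "mean": mean,
             "ci_low": mean - half, "ci_high": mean + half}
        )
    group_stats = pd.DataFrame(group_rows, columns=["group", "n", "mean", "ci_low", "ci_high"])

    pair_rows = []
    q_crit = (
        float(stats.studentized_range.ppf(1.0 - alpha, k, df_within))
        if (compute_pairwise and not degenerate)
        else math.nan
    )
    for i in range(k if compute_pairwise else 0):
        for j in range(i + 1, k):
            a, b = samples[i], samples[j]
            diff = float(a.mean() - b.mean())
            if degenerate:
                p_adj, half = (1.0 if diff == 0 else 0.0), 0.0
            else:
                se = math.sqrt(mse / 2.0 * (1.0 / a.size + 1.0 / b.size))
                q = abs(diff) / se if se > 0 else math.inf
                p_adj = float(stats.studentized_range.sf(q, k, df_within))
                half = q_crit * se
            pair_rows.append(
                {
                    "group_1": names[i],
                    "group_2": names[j],
                    "diff": diff,
                    "p_adj": min(p_adj, 1.0),
                    "ci_low": diff - half,
                    "ci_high": diff + half,
                }
            )
    pairwise = pd.DataFrame(
        pair_rows, columns=["group_1", "group_2", "diff", "p_adj", "ci_low", "ci_high"]
    )
    return TukeyResult(f_stat, p_val, degenerate, group_stats, pairwise, excluded)
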