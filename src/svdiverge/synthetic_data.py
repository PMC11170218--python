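"""Seeded synthetic two-population fixtures with known ground truth.

The generator emulates the data a two-species structural-variant study
consumes: an ancestral population splits into two non-interbreeding
groups, structural variants segregate at controlled frequencies per
SD/SP/SSP category, SNP allele frequencies drift apart under a
Balding-Nichols model with differentiation parameter F (the expected
fixation index), and a windowed recombination-rate track varies by
region type.  Every emitted file is paired with a truth table the
downstream stages can be scored against, and a fixed seed determines
every output byte.

The drift model draws each population's allele frequency independently
from Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency p;
diploid genotypes then follow Hardy-Weinberg within populations.  This
gives exactly the statistical structure the downstream estimators
assume — two diverged allele-frequency spectra — without claiming to be
a coalescent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    GenomeRegion,
    GenotypeMatrix,
    RegionType,
    SampleRecord,
    SVEvent,
    Window,
    WindowTrack,
    write_genotype_vcf,
    write_regions_tsv,
    write_samples,
    write_track,
)
from .sv_classify import Category

# independent random substreams per stage, all derived from the one seed
_STAGE = {"layout": 1, "svs": 2, "snps": 3, "rho": 4, "samples": 5}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STAGE[stage]])


#: Default symmetric-SV counts per sv_type, mirroring the category
#: proportions observed between recently diverged tree species at desk
#: scale: divergences are rare, most events are private/artifactual,
#: and polymorphisms outnumber shared polymorphisms roughly 3:1.
DEFAULT_SV_COUNTS = {
    Category.SD: 2,
    Category.SP: 31,
    Category.SSP: 11,
    Category.PRIVATE_OR_ARTIFACT: 81,
}

#: Region-type multipliers for the recombination track: genes, TEs and
#: duplications recombine above the syntenic baseline; translocated and
#: unaligned regions below it.
DEFAULT_RHO_EFFECTS = {
    RegionType.GENE: 2.0,
    RegionType.TRANSPOSON: 1.8,
    RegionType.DUPLICATION: 1.5,
    RegionType.INVERSION: 1.2,
    RegionType.TRANSLOCATION: 0.8,
    RegionType.UNALIGNED: 0.7,
    RegionType.SYNTENIC: 1.0,
}


@dataclass
class SimulationConfig:
    """All generator parameters; the seed fully determines every output."""

    seed: int = 0
    n_samples_a: int = 100
    n_samples_b: int = 100
    #: symmetric-SV counts per category, applied to each symmetric sv_type
    n_sv_per_category: dict[Category, int] = field(
        default_factory=lambda: dict(DEFAULT_SV_COUNTS)
    )
    n_duplications: int = 10  # asymmetric, per host genome
    n_unaligned: int = 10
    n_genes: int = 40
    n_transposons: int = 40
    polymorphic_freq_range: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.2  # matches ~80% genotyping success rates
    n_snps: int = 2000
    drift_f: float = 0.1
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    genome: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 3_000_000), ("chr2", 3_000_000)]
    )
    sv_length_range: tuple[int, int] = (2_000, 8_000)
    gap_length_range: tuple[int, int] = (1_000, 3_000)
    rho_base: float = 0.05  # genome-wide scale of the track
    rho_effects: dict[RegionType, float] = field(
        default_factory=lambda: dict(DEFAULT_RHO_EFFECTS)
    )
    rho_sigma: float = 0.1  # lognormal noise sd (mean-one noise)
    rho_window: int = 1_000
    depth_mean: float = 15.4  # per-call supporting-read depth (Poisson)
    coverage_range: tuple[float, float] = (10.0, 48.7)
    alignment_range: tuple[float, float] = (0.78, 0.988)
    linked_block_size: int = 0  # >=2 copies one carrier indicator across k SSPs

    def __post_init__(self) -> None:
        # coerce YAML-friendly forms (string keys, nested lists) to types
        self.n_sv_per_category = {
            Category(k): int(v) for k, v in self.n_sv_per_category.items()
        }
        self.rho_effects = {
            RegionType(k): float(v) for k, v in self.rho_effects.items()
        }
        self.genome = [(str(c), int(n)) for c, n in self.genome]
        for name in ("polymorphic_freq_range", "ancestral_freq_range",
                     "sv_length_range", "gap_length_range", "coverage_range",
                     "alignment_range"):
            setattr(self, name, tuple(getattr(self, name)))
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 < self.drift_f < 1.0):
            raise ValueError("drift_f must be in (0, 1)")
        if any(v < 0 for v in self.n_sv_per_category.values()):
            raise ValueError("SV category counts must be non-negative")

    @property
    def assembly_length(self) -> int:
        return sum(length for _, length in self.genome)


@dataclass
class Fixture:
    """Everything one simulated study comprises, plus its ground truth."""

    config: SimulationConfig
    samples: list[SampleRecord]
    regions: list[GenomeRegion]  # both genomes
    events: list[SVEvent]
    sv_matrix_a: GenotypeMatrix  # population A genotyped against reference A
    sv_matrix_b: GenotypeMatrix  # population B genotyped against reference B
    snp_matrix: GenotypeMatrix  # both populations against reference A
    rho_track: WindowTrack
    sv_truth: pd.DataFrame  # sv_id, sv_type, category, p_B_in_A, p_B_in_B
    snp_truth: pd.DataFrame  # chrom, pos, p_A, p_B
    region_rho_truth: pd.DataFrame  # region_id, region_type, expected_mean

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(exist_ok=True)
        contigs = self.config.genome
        write_regions_tsv(self.regions, outdir / "regions.tsv")
        write_samples(self.samples, outdir / "samples.tsv")
        write_genotype_vcf(self.sv_matrix_a, outdir / "svs_A.vcf", contigs)
        write_genotype_vcf(self.sv_matrix_b, outdir / "svs_B.vcf", contigs)
        write_genotype_vcf(self.snp_matrix, outdir / "snps_A.vcf", contigs)
        write_track(self.rho_track, outdir / "rho.bedgraph")
        self._write_features(outdir)
        self.sv_truth.to_csv(outdir / "truth" / "sv_truth.tsv", sep="\t", index=False)
        self.snp_truth.to_csv(outdir / "truth" / "snp_truth.tsv", sep="\t", index=False)
        self.region_rho_truth.to_csv(
            outdir / "truth" / "region_rho_truth.tsv", sep="\t", index=False
        )

    def _write_features(self, outdir: Path) -> None:
        genes = [r for r in self.regions
                 if r.region_type is RegionType.GENE and r.genome_id == "A"]
        tes = [r for r in self.regions
               if r.region_type is RegionType.TRANSPOSON and r.genome_id == "A"]
        with open(outdir / "genes.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for g in genes:  # internal half-open -> GFF3 1-based inclusive
                fh.write(
                    f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                    f"ID={g.region_id}\n"
                )
        with open(outdir / "tes.bed", "w") as fh:
            for t in tes:
                fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.region_id}\n")


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------


def _layout_regions(
    config: SimulationConfig,
) -> tuple[list[GenomeRegion], list[SVEvent], dict[str, Category]]:
    """Place all features non-overlapping along the toy genome.

    Features are laid left to right with syntenic gaps between them;
    leftover gap sequence becomes explicit SYNTENIC regions.  Symmetric
    SVs get mirrored coordinates in both genomes (the toy genomes are
    collinear apart from the annotated events).
    """
    rng = _rng(config.seed, "layout")
    spec: list[tuple[RegionType, str, Category | None, str | None]] = []
    for sv_type in (RegionType.INVERSION, RegionType.TRANSLOCATION):
        prefix = "inv" if sv_type is RegionType.INVERSION else "trans"
        for cat, count in config.n_sv_per_category.items():
            for _ in range(count):
                spec.append((sv_type, prefix, cat, None))
    for host in ("A", "B"):
        for _ in range(config.n_duplications):
            spec.append((RegionType.DUPLICATION, "dup", None, host))
        for _ in range(config.n_unaligned):
            spec.append((RegionType.UNALIGNED, "notal", None, host))
    for _ in range(config.n_genes):
        spec.append((RegionType.GENE, "gene", None, "A"))
    for _ in range(config.n_transposons):
        spec.append((RegionType.TRANSPOSON, "te", None, "A"))
    order = rng.permutation(len(spec))

    regions: list[GenomeRegion] = []
    events: list[SVEvent] = []
    categories: dict[str, Category] = {}
    counters: dict[str, int] = {}
    chrom_iter = iter(config.genome)
    chrom, chrom_len = next(chrom_iter)
    cursor = int(rng.integers(*config.gap_length_range))
    syn_count = 0

    def _close_chrom_gap(end: int) -> None:
        nonlocal syn_count
        if end - cursor >= 1:
            syn_count += 1
            for gid in ("A", "B"):
                regions.append(
                    GenomeRegion(f"syn{syn_count}", gid, chrom, cursor, end,
                                 RegionType.SYNTENIC)
                )

    for k in order:
        rtype, prefix, cat, host = spec[k]
        length = int(rng.integers(config.sv_length_range[0], config.sv_length_range[1] + 1))
        gap = int(rng.integers(*config.gap_length_range))
        while cursor + length + gap > chrom_len:
            _close_chrom_gap(chrom_len)
            try:
                chrom, chrom_len = next(chrom_iter)
            except StopIteration as exc:
                raise ValueError(
                    "toy genome too small for the requested feature counts; "
                    "enlarge config.genome"
                ) from exc
            cursor = int(rng.integers(*config.gap_length_range))
        start, end = cursor, cursor + length
        # the gap before the next feature is syntenic background
        syn_count += 1
        for gid in ("A", "B"):
            regions.append(
                GenomeRegion(f"syn{syn_count}", gid, chrom, end, end + gap,
                             RegionType.SYNTENIC)
            )
        counters[prefix] = counters.get(prefix, 0) + 1
        rid = f"{prefix}{counters[prefix]}"
        if rtype in (RegionType.INVERSION, RegionType.TRANSLOCATION):
            reg_a = GenomeRegion(rid, "A", chrom, start, end, rtype)
            reg_b = GenomeRegion(rid, "B", chrom, start, end, rtype)
            regions.extend([reg_a, reg_b])
            events.append(SVEvent(rid, rtype, reg_a, reg_b))
            categories[rid] = cat
        elif rtype in (RegionType.DUPLICATION, RegionType.UNALIGNED):
            reg = GenomeRegion(rid, host, chrom, start, end, rtype)
            regions.append(reg)
            if host == "A":
                events.append(SVEvent(rid, rtype, region_a=reg))
            else:
                events.append(SVEvent(rid, rtype, region_b=reg))
        else:  # gene / transposon annotations live on genome A only
            regions.append(GenomeRegion(rid, "A", chrom, start, end, rtype))
        cursor = end + gap
    _close_chrom_gap(chrom_len)
    return regions, events, categories


# ---------------------------------------------------------------------------
# SV genotypes
# ---------------------------------------------------------------------------


def _draw_category_freqs(
    cat: Category, rng: np.random.Generator, freq_range: tuple[float, float]
) -> tuple[float, float]:
    """True (p_B_in_A, p_B_in_B) for one symmetric SV of a category."""
    lo, hi = freq_range
    if cat is Category.SD:
        return 0.0, 1.0
    if cat is Category.SSP:
        return float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi))
    if cat is Category.SP:
        poly = float(rng.uniform(lo, hi))
        if rng.random() < 0.5:  # polymorphic in A
            return poly, float(rng.integers(0, 2))
        return float(rng.integers(0, 2)), poly
    # PRIVATE_OR_ARTIFACT: unsupported (both absent) or saturating (both fixed)
    both = float(rng.integers(0, 2))
    return both, both


def simulate_svs(
    config: SimulationConfig,
    events: list[SVEvent],
    categories: dict[str, Category],
) -> tuple[GenotypeMatrix, GenotypeMatrix, pd.DataFrame]:
    """Genotype every SV event in both populations, with missingness.

    Population A is genotyped against reference A, where ALT is the
    genome-B arrangement (frequency p_B_in_A); population B against
    reference B, where ALT is the genome-A arrangement (frequency
    1 - p_B_in_B).  Asymmetric events (duplications, unaligned) are
    genotyped only in their host population, with a per-host truth
    status drawn mostly fixed and otherwise high-frequency polymorphic.
    Missing calls are i.i.d. at ``missing_rate``.
    """
    rng = _rng(config.seed, "svs")
    samples_a = [f"A{i:03d}" for i in range(config.n_samples_a)]
    samples_b = [f"B{i:03d}" for i in range(config.n_samples_b)]
    truth_rows = []
    cols_a: dict[str, np.ndarray] = {}
    cols_b: dict[str, np.ndarray] = {}
    meta_a, meta_b = [], []
    ssp_block: list[str] = []
    latent_a: np.ndarray | None = None
    latent_b: np.ndarray | None = None

    def _genotypes(n: int, p: float, reuse: np.ndarray | None = None) -> np.ndarray:
        geno = reuse if reuse is not None else rng.binomial(2, p, size=n)
        geno = geno.astype(np.int16).copy()
        if config.missing_rate > 0:
            geno[rng.random(n) < config.missing_rate] = MISSING
        return geno

    for ev in events:
        if ev.symmetric:
            cat = categories.get(ev.sv_id, Category.SSP)
            p_b_in_a, p_b_in_b = _draw_category_freqs(
                cat, rng, config.polymorphic_freq_range
            )
            reuse_a = reuse_b = None
            if (
                config.linked_block_size >= 2
                and cat is Category.SSP
                and len(ssp_block) < config.linked_block_size
            ):
                # linked block: one latent carrier indicator shared by k SSPs
                if latent_a is None:
                    latent_a = rng.binomial(2, p_b_in_a, size=config.n_samples_a)
                    latent_b = rng.binomial(2, 1.0 - p_b_in_b, size=config.n_samples_b)
                reuse_a, reuse_b = latent_a, latent_b
                ssp_block.append(ev.sv_id)
            cols_a[ev.sv_id] = _genotypes(config.n_samples_a, p_b_in_a, reuse_a)
            cols_b[ev.sv_id] = _genotypes(config.n_samples_b, 1.0 - p_b_in_b, reuse_b)
            reg = ev.region_a
            meta_a.append((ev.sv_id, reg.chrom, reg.start, ev.sv_type.value))
            meta_b.append((ev.sv_id, ev.region_b.chrom, ev.region_b.start, ev.sv_type.value))
            truth_rows.append(
                {
                    "sv_id": ev.sv_id,
                    "sv_type": ev.sv_type.value,
                    "category": cat.value,
                    "p_B_in_A": p_b_in_a,
                    "p_B_in_B": p_b_in_b,
                    "host_genome": "",
                    "in_linked_block": ev.sv_id in ssp_block,
                }
            )
        else:
            # asymmetric: mostly fixed, remainder high-frequency polymorphic
            if rng.random() < 0.7:
                freq, status = 1.0, "FIXED"
            else:
                freq = float(rng.uniform(0.9, 0.995))
                status = "POLYMORPHIC"
            host = "A" if ev.region_a is not None else "B"
            reg = ev.region_a if host == "A" else ev.region_b
            n = config.n_samples_a if host == "A" else config.n_samples_b
            col = _genotypes(n, freq)
            if host == "A":
                cols_a[ev.sv_id] = col
                meta_a.append((ev.sv_id, reg.chrom, reg.start, ev.sv_type.value))
            else:
                cols_b[ev.sv_id] = col
                meta_b.append((ev.sv_id, reg.chrom, reg.start, ev.sv_type.value))
            truth_rows.append(
                {
                    "sv_id": ev.sv_id,
                    "sv_type": ev.sv_type.value,
                    "category": status,
                    "p_B_in_A": freq if host == "A" else np.nan,
                    "p_B_in_B": freq if host == "B" else np.nan,
                    "host_genome": host,
                    "in_linked_block": False,
                }
            )

    def _build(cols, meta, sample_ids) -> GenotypeMatrix:
        ids = [m[0] for m in meta]
        calls = (
            np.column_stack([cols[v] for v in ids])
            if ids
            else np.zeros((len(sample_ids), 0), dtype=np.int16)
        )
        depths = rng.poisson(config.depth_mean, size=calls.shape).astype(np.int32)
        frame = pd.DataFrame(
            {
                "variant_id": ids,
                "chrom": [m[1] for m in meta],
                "pos": [m[2] for m in meta],
                "ref": "N",
                "alts": [f"<{m[3][:3]}>" for m in meta],
                "is_indel": False,
                "is_multiallelic": False,
            }
        )
        return GenotypeMatrix(sample_ids, ids, calls, depths, frame)

    matrix_a = _build(cols_a, meta_a, samples_a)
    matrix_b = _build(cols_b, meta_b, samples_b)
    truth = pd.DataFrame(truth_rows)
    return matrix_a, matrix_b, truth


# ---------------------------------------------------------------------------
# SNPs under Balding-Nichols drift
# ---------------------------------------------------------------------------


def simulate_snps(config: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate biallelic SNPs for both populations against reference A.

    Ancestral frequencies are uniform on ``ancestral_freq_range``; each
    population's frequency is an independent Beta draw with drift
    parameter F; diploid genotypes are Binomial(2, p_pop) under
    Hardy-Weinberg; per-call depths are Poisson(depth_mean).
    """
    rng = _rng(config.seed, "snps")
    n_a, n_b = config.n_samples_a, config.n_samples_b
    f = config.drift_f
    p_anc = rng.uniform(*config.ancestral_freq_range, size=config.n_snps)
    shape = (1.0 - f) / f
    p_a = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
    p_b = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
    geno_a = rng.binomial(2, p_a, size=(n_a, config.n_snps))
    geno_b = rng.binomial(2, p_b, size=(n_b, config.n_snps))
    calls = np.vstack([geno_a, geno_b]).astype(np.int16)
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING
    depths = rng.poisson(config.depth_mean, size=calls.shape).astype(np.int32)

    # unique sorted positions across the toy genome
    per_chrom = np.array_split(np.arange(config.n_snps), len(config.genome))
    chroms, positions = [], []
    for (chrom, length), idx in zip(config.genome, per_chrom):
        pos = np.sort(rng.choice(length, size=len(idx), replace=False))
        chroms.extend([chrom] * len(idx))
        positions.extend(int(p) for p in pos)

    sample_ids = [f"A{i:03d}" for i in range(n_a)] + [f"B{i:03d}" for i in range(n_b)]
    variant_ids = [f"snp{i + 1}" for i in range(config.n_snps)]
    bases = np.array(["A", "C", "G", "T"])
    refs = bases[rng.integers(0, 4, size=config.n_snps)]
    alts = np.array([bases[(list(bases).index(r) + 1) % 4] for r in refs])
    meta = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": chroms,
            "pos": positions,
            "ref": refs,
            "alts": alts,
            "is_indel": False,
            "is_multiallelic": False,
        }
    )
    matrix = GenotypeMatrix(sample_ids, variant_ids, calls, depths, meta)
    truth = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": chroms,
            "pos": positions,
            "p_ancestral": p_anc,
            "p_A": p_a,
            "p_B": p_b,
        }
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Recombination track
# ---------------------------------------------------------------------------


def simulate_rho_track(
    config: SimulationConfig,
    regions: list[GenomeRegion],
) -> tuple[WindowTrack, pd.DataFrame]:
    """A 1-kb windowed rho track structured by region type.

    Each window's value is rho_base x effect(region type covering the
    window midpoint; syntenic baseline 1) x mean-one lognormal noise, so
    a region's expected mean is exactly rho_base x effect.  Feature
    regions are laid out non-overlapping by the generator, making the
    midpoint lookup unambiguous (genome-A annotations define the layout).
    """
    rng = _rng(config.seed, "rho")
    sigma = config.rho_sigma
    feature_regions = [
        r for r in regions
        if r.genome_id == "A" and r.region_type is not RegionType.SYNTENIC
    ]
    by_chrom: dict[str, list[GenomeRegion]] = {}
    for r in feature_regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for c in by_chrom:
        by_chrom[c].sort(key=lambda r: r.start)

    windows = []
    for chrom, length in config.genome:
        regs = by_chrom.get(chrom, [])
        starts = np.array([r.start for r in regs])
        for w_start in range(0, length, config.rho_window):
            w_end = min(w_start + config.rho_window, length)
            mid = (w_start + w_end) // 2
            effect = config.rho_effects.get(RegionType.SYNTENIC, 1.0)
            if regs:
                i = int(np.searchsorted(starts, mid, "right")) - 1
                if i >= 0 and regs[i].start <= mid < regs[i].end:
                    effect = config.rho_effects.get(regs[i].region_type, 1.0)
            noise = 1.0 if sigma == 0 else float(
                rng.lognormal(-0.5 * sigma * sigma, sigma)
            )
            windows.append(Window(chrom, w_start, w_end, config.rho_base * effect * noise))
    track = WindowTrack(windows)

    truth_rows = []
    for r in regions:
        if r.genome_id != "A":
            continue
        effect = config.rho_effects.get(r.region_type, 1.0)
        truth_rows.append(
            {
                "region_id": r.region_id,
                "region_type": r.region_type.value,
                "expected_mean": config.rho_base * effect,
            }
        )
    return track, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Samples and the full fixture
# ---------------------------------------------------------------------------


def simulate_samples(config: SimulationConfig) -> list[SampleRecord]:
    """Sample metadata with coverage/alignment in realistic study ranges."""
    rng = _rng(config.seed, "samples")
    out = []
    for species, n in (("A", config.n_samples_a), ("B", config.n_samples_b)):
        for i in range(n):
            cov = float(rng.uniform(*config.coverage_range))
            out.append(
                SampleRecord(
                    sample_id=f"{species}{i:03d}",
                    species=species,
                    total_bases=int(cov * config.assembly_length),
                    est_coverage=round(cov, 2),
                    pct_aligned=round(float(rng.uniform(*config.alignment_range)), 4),
                    excluded_by_pca=False,
                )
            )
    return out


def simulate(config: SimulationConfig) -> Fixture:
    """Run every generator stage and assemble the full fixture."""
    regions, events, categories = _layout_regions(config)
    sv_matrix_a, sv_matrix_b, sv_truth = simulate_svs(config, events, categories)
    snp_matrix, snp_truth = simulate_snps(config)
    rho_track, region_rho_truth = simulate_rho_track(config, regions)
    samples = simulate_samples(config)
    return Fixture(
        config=config,
        samples=samples,
        regions=regions,
        events=events,
        sv_matrix_a=sv_matrix_a,
        sv_matrix_b=sv_matrix_b,
        snp_matrix=snp_matrix,
        rho_track=rho_track,
        sv_truth=sv_truth,
        snp_truth=snp_truth,
        region_rho_truth=region_rho_truth,
    )
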