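"""Readers and writers for every external format the pipeline touches.

All genomic intervals are normalized to a single internal convention:
0-based, half-open ``[start, end)``.  Dialects that are 1-based inclusive
(SyRI tables, GFF3, VCF POS) are converted on read and restored on write,
so overlap and length arithmetic elsewhere in the package never needs to
know where a record came from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

MISSING: int = -1
"""Sentinel for an unresolved diploid genotype call."""


class RegionType(str, Enum):
    SYNTENIC = "SYNTENIC"
    INVERSION = "INVERSION"
    TRANSLOCATION = "TRANSLOCATION"
    DUPLICATION = "DUPLICATION"
    UNALIGNED = "UNALIGNED"
    GENE = "GENE"
    TRANSPOSON = "TRANSPOSON"


#: Structural classes that describe an SV event (subset of RegionType).
SV_TYPES = (
    RegionType.INVERSION,
    RegionType.TRANSLOCATION,
    RegionType.DUPLICATION,
    RegionType.UNALIGNED,
)

#: Inversions and translocations are equivalently describable in both
#: genomes and hence genotypable in both populations.
SYMMETRIC_SV_TYPES = (RegionType.INVERSION, RegionType.TRANSLOCATION)


class FormatError(ValueError):
    """A malformed input file; the message names the file and line."""


@dataclass(frozen=True)
class GenomeRegion:
    """An annotated interval on one reference genome (0-based half-open)."""

    region_id: str
    genome_id: str
    chrom: str
    start: int
    end: int
    region_type: RegionType

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"region {self.region_id}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SVEvent:
    """A structural variant, possibly described in both reference genomes.

    Inversions and translocations are symmetric: the same event is an
    interval in each genome.  Duplications and unaligned regions are
    unique to their host genome and carry a single region.
    """

    sv_id: str
    sv_type: RegionType
    region_a: GenomeRegion | None = None
    region_b: GenomeRegion | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"{self.sv_type} is not a structural-variant type")
        if self.symmetric and (self.region_a is None or self.region_b is None):
            raise ValueError(
                f"symmetric SV {self.sv_id} must have a region in both genomes"
            )
        if self.region_a is None and self.region_b is None:
            raise ValueError(f"SV {self.sv_id} has no region in either genome")

    @property
    def symmetric(self) -> bool:
        return self.sv_type in SYMMETRIC_SV_TYPES


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample sequencing metadata used by the QC filters."""

    sample_id: str
    species: str  # population label, "A" or "B"
    total_bases: int = 0
    est_coverage: float = 0.0
    pct_aligned: float = 0.0  # fraction in [0, 1]
    excluded_by_pca: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_aligned <= 1.0):
            raise ValueError(
                f"sample {self.sample_id}: pct_aligned must be a fraction "
                f"in [0, 1], got {self.pct_aligned}"
            )


@dataclass
class Window:
    """One fixed-width window of a value track (0-based half-open)."""

    chrom: str
    start: int
    end: int
    value: float


class WindowTrack:
    """A per-chromosome, sorted, non-overlapping value track (e.g. rho).

    Windows are validated on construction: within a chromosome they must
    not overlap.  Unsorted input is sorted with a logged notice.
    """

    def __init__(self, windows: Iterable[Window]):
        windows = list(windows)
        ordered = sorted(windows, key=lambda w: (w.chrom, w.start))
        if [id(w) for w in ordered] != [id(w) for w in windows]:
            logger.info("track windows were unsorted; sorting")
        prev: Window | None = None
        for w in ordered:
            if w.end <= w.start:
                raise ValueError(f"window [{w.start}, {w.end}) on {w.chrom} is empty")
            if prev is not None and prev.chrom == w.chrom and w.start < prev.end:
                raise ValueError(
                    f"overlapping track windows on {w.chrom}: "
                    f"[{prev.start}, {prev.end}) and [{w.start}, {w.end})"
                )
            prev = w
        self.windows: list[Window] = ordered

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Return per-chromosome (starts, ends, values) arrays."""
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        frame = pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "value": [w.value for w in self.windows],
            }
        )
        for chrom, grp in frame.groupby("chrom", sort=False):
            out[str(chrom)] = (
                grp["start"].to_numpy(),
                grp["end"].to_numpy(),
                grp["value"].to_numpy(),
            )
        return out


class GenotypeMatrix:
    """Samples x variants diploid genotype table.

    Calls count alternate-arrangement alleles per diploid sample: 0, 1, 2,
    or ``MISSING`` (-1).  Missing calls propagate through all downstream
    counts and are never imputed.  ``depths`` optionally carries the
    supporting read depth per call.  Per-variant site metadata (chrom,
    pos, ref, alts) is retained when read from a VCF so that site-level
    filters can see indel/multiallelic status.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        variant_ids: Sequence[str],
        calls: np.ndarray,
        depths: np.ndarray | None = None,
        variant_meta: pd.DataFrame | None = None,
    ):
        self.sample_ids = list(sample_ids)
        self.variant_ids = list(variant_ids)
        calls = np.asarray(calls, dtype=np.int16)
        if calls.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if not np.isin(calls, (MISSING, 0, 1, 2)).all():
            raise ValueError("genotype calls must be 0, 1, 2 or MISSING (-1)")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids")
        if depths is not None:
            depths = np.asarray(depths)
            if depths.shape != calls.shape:
                raise ValueError("depths shape must match calls shape")
        self.calls = calls
        self.depths = depths
        self.variant_meta = variant_meta

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            self.variant_ids,
            self.calls[idx, :],
            None if self.depths is None else self.depths[idx, :],
            self.variant_meta,
        )

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.variant_ids.index(v) for v in variant_ids]
        meta = None
        if self.variant_meta is not None:
            meta = self.variant_meta.iloc[idx].reset_index(drop=True)
        return GenotypeMatrix(
            self.sample_ids,
            [self.variant_ids[i] for i in idx],
            self.calls[:, idx],
            None if self.depths is None else self.depths[:, idx],
            meta,
        )

    def to_frame(self) -> pd.DataFrame:
        """Samples x variants DataFrame with missing calls as NaN."""
        arr = self.calls.astype(float)
        arr[self.calls == MISSING] = np.nan
        return pd.DataFrame(arr, index=self.sample_ids, columns=self.variant_ids)


# ---------------------------------------------------------------------------
# SyRI / native region tables
# ---------------------------------------------------------------------------

#: Top-level SyRI annotation codes mapped onto internal region types.
SYRI_TYPE_MAP = {
    "SYN": RegionType.SYNTENIC,
    "INV": RegionType.INVERSION,
    "TRANS": RegionType.TRANSLOCATION,
    "INVTR": RegionType.TRANSLOCATION,
    "DUP": RegionType.DUPLICATION,
    "INVDP": RegionType.DUPLICATION,
    "NOTAL": RegionType.UNALIGNED,
}

#: Child/alignment records nested inside a top-level block, plus the
#: small-variant codes SyRI reports alongside structural records.  These
#: are recognized but not converted into regions.
_SYRI_NESTED_CODES = {code + "AL" for code in SYRI_TYPE_MAP}
_SYRI_SMALL_VARIANT_CODES = {
    "SNP", "INS", "DEL", "CPG", "CPL", "HDR", "TDM", "DUPAL", "INVAL",
}

_NATIVE_COLUMNS = ["region_id", "genome_id", "chrom", "start", "end", "region_type"]


def _syri_rows(path: Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 11 tab-separated SyRI "
                    f"columns, found {len(fields)}"
                )
            yield lineno, fields


def read_sv_annotations(
    path: str | Path,
    dialect: str = "syri",
    genome_a: str = "A",
    genome_b: str = "B",
    keep_nested: bool = False,
) -> tuple[list[SVEvent], list[GenomeRegion]]:
    """Read a synteny/SV annotation table into events and regions.

    ``dialect="syri"`` reads SyRI's tabular output (1-based inclusive
    reference and query coordinates, "-" for absent fields); by default
    only top-level records are kept and nested alignment records are
    dropped (``keep_nested`` retains them as extra regions).
    ``dialect="native"`` reads the package's own region TSV, which is
    already 0-based half-open.

    Returns ``(events, regions)``: one SVEvent per non-syntenic record
    plus the flat region list for both genomes (syntenic blocks included).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "native":
        regions = read_regions_tsv(path)
        return _events_from_regions(regions), regions
    if dialect != "syri":
        raise ValueError(f"unknown dialect {dialect!r}; expected 'syri' or 'native'")

    events: list[SVEvent] = []
    regions: list[GenomeRegion] = []
    counters: dict[str, int] = {}
    for lineno, fields in _syri_rows(path):
        chr_a, start_a, end_a = fields[0], fields[1], fields[2]
        chr_b, start_b, end_b = fields[5], fields[6], fields[7]
        code = fields[10]
        nested = code in _SYRI_NESTED_CODES or code in _SYRI_SMALL_VARIANT_CODES
        if nested and not keep_nested:
            continue
        base_code = code[:-2] if code.endswith("AL") and code not in SYRI_TYPE_MAP else code
        if base_code not in SYRI_TYPE_MAP:
            if code in _SYRI_SMALL_VARIANT_CODES:
                continue  # small variants never become regions
            raise FormatError(
                f"{path}:{lineno}: unknown SyRI type code {code!r}; accepted "
                f"codes: {sorted(SYRI_TYPE_MAP)} (+'AL' nested forms)"
            )
        rtype = SYRI_TYPE_MAP[base_code]
        counters[base_code] = counters.get(base_code, 0) + 1
        rec_id = f"{base_code}{counters[base_code]}"

        def _region(genome: str, chrom: str, start: str, end: str) -> GenomeRegion | None:
            if chrom == "-" or start == "-" or end == "-":
                return None
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate {start!r}/{end!r}"
                ) from exc
            # 1-based inclusive -> 0-based half-open
            return GenomeRegion(rec_id, genome, chrom, s - 1, e, rtype)

        reg_a = _region(genome_a, chr_a, start_a, end_a)
        reg_b = _region(genome_b, chr_b, start_b, end_b)
        if reg_a is None and reg_b is None:
            raise FormatError(f"{path}:{lineno}: record has no coordinates")
        for reg in (reg_a, reg_b):
            if reg is not None:
                regions.append(reg)
        if rtype in SV_TYPES:
            if rtype in SYMMETRIC_SV_TYPES and (reg_a is None or reg_b is None):
                raise FormatError(
                    f"{path}:{lineno}: symmetric SV {code} must have "
                    "coordinates in both genomes"
                )
            events.append(SVEvent(rec_id, rtype, reg_a, reg_b))
    return events, regions


def _events_from_regions(regions: list[GenomeRegion]) -> list[SVEvent]:
    """Pair SV-typed regions sharing an id across genomes into events."""
    by_id: dict[str, dict[str, GenomeRegion]] = {}
    order: list[str] = []
    for reg in regions:
        if reg.region_type not in SV_TYPES:
            continue
        if reg.region_id not in by_id:
            order.append(reg.region_id)
        by_id.setdefault(reg.region_id, {})[reg.genome_id] = reg
    events = []
    for rid in order:
        group = by_id[rid]
        genomes = sorted(group)
        reg_a = group[genomes[0]]
        reg_b = group[genomes[1]] if len(genomes) > 1 else None
        events.append(SVEvent(rid, reg_a.region_type, reg_a, reg_b))
    return events


def read_regions_tsv(path: str | Path) -> list[GenomeRegion]:
    """Read the native region TSV (header row, 0-based half-open)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.empty and list(frame.columns) != _NATIVE_COLUMNS:
        if len(frame.columns) <= 1:  # empty file without header
            return []
    missing = set(_NATIVE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    regions = []
    for i, row in frame.iterrows():
        try:
            rtype = RegionType(row["region_type"])
        except ValueError as exc:
            raise FormatError(
                f"{path}: line {i + 2}: unknown region_type "
                f"{row['region_type']!r}; accepted: {[t.value for t in RegionType]}"
            ) from exc
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {i + 2}: malformed coordinates") from exc
        regions.append(
            GenomeRegion(row["region_id"], row["genome_id"], row["chrom"], start, end, rtype)
        )
    return regions


def write_regions_tsv(regions: Iterable[GenomeRegion], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "genome_id": r.genome_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "region_type": r.region_type.value,
            }
            for r in regions
        ],
        columns=_NATIVE_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_genotype_vcf(
    path: str | Path,
    id_fallback: bool = False,
) -> GenotypeMatrix:
    """Read FORMAT/GT (and FORMAT/DP when present) into a GenotypeMatrix.

    Diploid calls map as 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2; ./., half
    calls and any call touching an allele index > 1 are MISSING.  Variant
    identity comes from the ID column; with ``id_fallback`` a missing ID
    becomes the deterministic key ``chrom:pos:alt``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = pysam.VariantFile(str(path))
    sample_ids = list(vcf.header.samples)
    variant_ids: list[str] = []
    call_rows: list[list[int]] = []
    depth_rows: list[list[int]] = []
    meta_rows: list[dict] = []
    any_depth = False
    for rec in vcf:
        if rec.id is not None:
            vid = rec.id
        elif id_fallback:
            alt = rec.alts[0] if rec.alts else "."
            vid = f"{rec.chrom}:{rec.pos}:{alt}"
        else:
            raise FormatError(
                f"{path}: record {rec.chrom}:{rec.pos} has no ID and no "
                "fallback key is configured (id_fallback=False)"
            )
        if vid in set(variant_ids):
            raise FormatError(f"{path}: duplicate variant ID {vid!r}")
        variant_ids.append(vid)
        calls: list[int] = []
        depths: list[int] = []
        for sample in sample_ids:
            data = rec.samples[sample]
            gt = data.get("GT", (None, None))
            if gt is None:
                gt = (None, None)
            if len(gt) != 2:
                raise FormatError(
                    f"{path}: non-diploid GT for sample {sample} at "
                    f"{rec.chrom}:{rec.pos}"
                )
            if None in gt or any(a not in (0, 1) for a in gt):
                calls.append(MISSING)
            else:
                calls.append(int(gt[0]) + int(gt[1]))
            dp = data.get("DP", None)
            if dp is not None:
                any_depth = True
                depths.append(int(dp))
            else:
                depths.append(0)
        call_rows.append(calls)
        depth_rows.append(depths)
        ref = rec.ref or ""
        alts = list(rec.alts) if rec.alts else []
        meta_rows.append(
            {
                "variant_id": vid,
                "chrom": rec.chrom,
                "pos": rec.pos - 1,  # internal 0-based
                "ref": ref,
                "alts": ",".join(alts),
                "is_indel": any(len(a) != len(ref) for a in alts if a is not None),
                "is_multiallelic": len(alts) > 1,
            }
        )
    calls_arr = (
        np.array(call_rows, dtype=np.int16).T
        if call_rows
        else np.zeros((len(sample_ids), 0), dtype=np.int16)
    )
    depths_arr = (
        np.array(depth_rows, dtype=np.int32).T if (call_rows and any_depth) else None
    )
    meta = pd.DataFrame(
        meta_rows,
        columns=[
            "variant_id", "chrom", "pos", "ref", "alts", "is_indel", "is_multiallelic",
        ],
    )
    return GenotypeMatrix(sample_ids, variant_ids, calls_arr, depths_arr, meta)


def write_genotype_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    contigs: Sequence[tuple[str, int]] = (),
) -> None:
    """Write a GenotypeMatrix back to a minimal VCF 4.2 text file.

    Site fields come from the matrix's variant metadata when present
    (falling back to placeholder coordinates otherwise); genotypes are
    encoded 0 -> 0/0, 1 -> 0/1, 2 -> 1/1, MISSING -> ./., with FORMAT/DP
    emitted when the matrix carries depths.
    """
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    has_dp = matrix.depths is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        fmt = "GT:DP" if has_dp else "GT"
        for j, vid in enumerate(matrix.variant_ids):
            if matrix.variant_meta is not None:
                row = matrix.variant_meta.iloc[j]
                chrom, pos = str(row["chrom"]), int(row["pos"]) + 1
                ref = str(row["ref"]) or "N"
                alts = str(row["alts"]) or "<SV>"
            else:
                chrom, pos, ref, alts = "chr1", j + 1, "N", "<SV>"
            cells = []
            for i in range(matrix.n_samples):
                cell = gt_code[int(matrix.calls[i, j])]
                if has_dp:
                    cell += f":{int(matrix.depths[i, j])}"
                cells.append(cell)
            fh.write(
                f"{chrom}\t{pos}\t{vid}\t{ref}\t{alts}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph / BED / GFF3 / sample tables
# ---------------------------------------------------------------------------


def read_track(path: str | Path) -> WindowTrack:
    """Read a bedGraph (0-based half-open) into a WindowTrack."""
    path = Path(path)
    windows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(
                    f"{path}:{lineno}: bedGraph needs 4 columns, found {len(fields)}"
                )
            try:
                windows.append(
                    Window(fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed bedGraph row") from exc
    return WindowTrack(windows)


def write_track(track: WindowTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in track:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.value:.6g}\n")


def read_features(
    path: str | Path,
    genome_id: str = "A",
    te_feature_names: Sequence[str] = ("transposable_element", "transposon", "TE"),
    default_type: RegionType = RegionType.GENE,
) -> list[GenomeRegion]:
    """Read gene/TE annotations from BED (0-based) or GFF3 (1-based).

    GFF3 feature type ``gene`` maps to GENE; the configurable
    ``te_feature_names`` map to TRANSPOSON; other feature types are
    skipped.  BED records take their type from the name column when it is
    a recognized region type, else ``default_type`` (BED carries no
    feature-type field of its own).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        return _read_gff3(path, genome_id, te_feature_names)
    if suffix == ".bed":
        return _read_bed(path, genome_id, te_feature_names, default_type)
    raise ValueError(f"cannot infer feature format from extension of {path}")


def _read_gff3(path: Path, genome_id: str, te_names: Sequence[str]) -> list[GenomeRegion]:
    regions = []
    counter = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: GFF3 needs 9 columns, found {len(fields)}"
                )
            ftype = fields[2]
            if ftype == "gene":
                rtype = RegionType.GENE
            elif ftype in te_names:
                rtype = RegionType.TRANSPOSON
            else:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            counter += 1
            rid = attrs.get("ID", f"{rtype.value.lower()}{counter}")
            try:
                start, end = int(fields[3]) - 1, int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed coordinates") from exc
            regions.append(GenomeRegion(rid, genome_id, fields[0], start, end, rtype))
    return sorted(regions, key=lambda r: (r.chrom, r.start))


def _read_bed(
    path: Path,
    genome_id: str,
    te_names: Sequence[str],
    default_type: RegionType = RegionType.GENE,
) -> list[GenomeRegion]:
    regions = []
    counter = 0
    known = {t.value for t in RegionType}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: BED needs >= 3 columns, found {len(fields)}"
                )
            name = fields[3] if len(fields) > 3 else ""
            if name in known:
                rtype = RegionType(name)
                counter += 1
                rid = f"{rtype.value.lower()}{counter}"
            elif name in te_names:
                rtype = RegionType.TRANSPOSON
                counter += 1
                rid = f"transposon{counter}"
            else:
                rtype = default_type
                counter += 1
                rid = name or f"{rtype.value.lower()}{counter}"
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed coordinates") from exc
            regions.append(GenomeRegion(rid, genome_id, fields[0], start, end, rtype))
    return sorted(regions, key=lambda r: (r.chrom, r.start))


_SAMPLE_COLUMNS = [
    "sample_id", "species", "total_bases", "est_coverage", "pct_aligned", "excluded_by_pca",
]


def read_samples(path: str | Path) -> list[SampleRecord]:
    """Read the sample metadata TSV (header row)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_SAMPLE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    samples = []
    for _, row in frame.iterrows():
        samples.append(
            SampleRecord(
                sample_id=row["sample_id"],
                species=row["species"],
                total_bases=int(row["total_bases"]),
                est_coverage=float(row["est_coverage"]),
                pct_aligned=float(row["pct_aligned"]),
                excluded_by_pca=str(row["excluded_by_pca"]).lower()
                in ("true", "1", "yes"),
            )
        )
    return samples


def write_samples(samples: Iterable[SampleRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "species": s.species,
                "total_bases": s.total_bases,
                "est_coverage": s.est_coverage,
                "pct_aligned": s.pct_aligned,
                "excluded_by_pca": s.excluded_by_pca,
            }
            for s in samples
        ],
        columns=_SAMPLE_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)
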