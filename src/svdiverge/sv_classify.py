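"""Per-population SV status calling and cross-species SD/SP/SSP classification.

An interspecies SV discovered between two reference genomes is genotyped
within each species' population.  Per population, the SV is ABSENT,
POLYMORPHIC, or FIXED by allele frequency (all counting is per allele,
2 x population size, never per sample).  For symmetric SVs (inversions,
translocations) the two per-population statuses combine into one of:

* SD  — structural divergence: fixed in one species, absent in the other;
* SP  — structural polymorphism: polymorphic in exactly one species;
* SSP — shared structural polymorphism: polymorphic in both, implying the
  arrangement predates the species split;
* PRIVATE_OR_ARTIFACT — supported by neither population (both absent) or
  by both entirely (both fixed), attributable to a private allele of a
  reference individual or an assembly artifact.

Frequencies are harmonized to a single polarity first: the frequency of
the genome-B arrangement in each population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, SampleRecord


class Status(str, Enum):
    ABSENT = "ABSENT"
    POLYMORPHIC = "POLYMORPHIC"
    FIXED = "FIXED"
    UNRESOLVED = "UNRESOLVED"


class Category(str, Enum):
    SD = "SD"
    SP = "SP"
    SSP = "SSP"
    PRIVATE_OR_ARTIFACT = "PRIVATE_OR_ARTIFACT"
    UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class PopulationStatus:
    """Allele-frequency status of one SV within one population."""

    sv_id: str
    population: str
    n_alleles_genotyped: int
    carrier_alleles: int
    status: Status

    @property
    def freq(self) -> float:
        """Carrier-allele frequency; NaN when nothing was genotyped."""
        if self.n_alleles_genotyped == 0:
            return math.nan
        return self.carrier_alleles / self.n_alleles_genotyped


@dataclass(frozen=True)
class SVClassification:
    """Cross-species category of a symmetric SV in harmonized polarity."""

    sv_id: str
    p_b_in_a: float  # frequency of the genome-B arrangement in population A
    p_b_in_b: float
    category: Category
    polarity_inverted: bool = False
    sub_label: str = ""  # for PRIVATE_OR_ARTIFACT: "both_absent" | "both_fixed"


def _status_from_freq(freq: float, fixed_tolerance: float) -> Status:
    if freq <= fixed_tolerance:
        return Status.ABSENT
    if freq >= 1.0 - fixed_tolerance:
        return Status.FIXED
    return Status.POLYMORPHIC


def call_population_status(
    matrix: GenotypeMatrix,
    samples: list[SampleRecord],
    population: str,
    min_alleles: int = 10,
    fixed_tolerance: float = 0.0,
) -> list[PopulationStatus]:
    """Call ABSENT/POLYMORPHIC/FIXED/UNRESOLVED for every SV in one population.

    Only samples of the named population that are not flagged for
    exclusion contribute.  Missing genotypes reduce the allele count;
    an SV genotyped in fewer than ``min_alleles`` alleles is UNRESOLVED
    rather than risk misclassification.
    """
    keep = [
        s.sample_id
        for s in samples
        if s.species == population and not s.excluded_by_pca
    ]
    if not keep:
        raise ValueError(f"population {population!r} has no usable samples")
    keep = [s for s in keep if s in matrix.sample_ids]
    if not keep:
        raise ValueError(
            f"no samples of population {population!r} are present in the matrix"
        )
    sub = matrix.subset_samples(keep)
    calls = sub.calls
    genotyped = calls != MISSING
    n_alleles = 2 * genotyped.sum(axis=0)
    carriers = np.where(genotyped, calls, 0).sum(axis=0)
    out = []
    for j, sv_id in enumerate(sub.variant_ids):
        n_a = int(n_alleles[j])
        carr = int(carriers[j])
        if n_a < min_alleles:
            status = Status.UNRESOLVED
        else:
            status = _status_from_freq(carr / n_a, fixed_tolerance)
        out.append(PopulationStatus(sv_id, population, n_a, carr, status))
    return out


def harmonize_polarity(
    status_vs_ref_a: PopulationStatus,
    status_vs_ref_b: PopulationStatus,
    single_reference: bool = False,
) -> tuple[float, float]:
    """Express both populations' frequencies in genome-B-arrangement polarity.

    Population A genotyped against reference A carries the genome-B
    arrangement as ALT, so its frequency passes through.  Population B
    genotyped against reference B carries the genome-A arrangement as
    ALT, so its frequency flips (p_B = 1 - p_A).  When both populations
    were genotyped against one shared reference (``single_reference``),
    both frequencies already share a polarity and pass through unflipped.
    """
    if status_vs_ref_a.sv_id != status_vs_ref_b.sv_id:
        raise ValueError(
            f"sv_id mismatch: {status_vs_ref_a.sv_id!r} vs {status_vs_ref_b.sv_id!r}"
        )
    p_b_in_a = status_vs_ref_a.freq
    if single_reference:
        return p_b_in_a, status_vs_ref_b.freq
    return p_b_in_a, 1.0 - status_vs_ref_b.freq


def _flip(status: Status) -> Status:
    if status is Status.ABSENT:
        return Status.FIXED
    if status is Status.FIXED:
        return Status.ABSENT
    return status


def classify_interspecies_sv(
    status_vs_ref_a: PopulationStatus,
    status_vs_ref_b: PopulationStatus,
    single_reference: bool = False,
) -> SVClassification:
    """Combine two per-population statuses into an SD/SP/SSP category.

    The decision table operates on the status of the genome-B arrangement
    in each population: (ABSENT, FIXED) -> SD; (FIXED, ABSENT) -> SD with
    the polarity flag raised (both references carry the arrangement their
    own species lacks); exactly one POLYMORPHIC -> SP; both POLYMORPHIC ->
    SSP; both ABSENT or both FIXED -> PRIVATE_OR_ARTIFACT.  Either
    population UNRESOLVED makes the SV UNRESOLVED.
    """
    p_b_in_a, p_b_in_b = harmonize_polarity(
        status_vs_ref_a, status_vs_ref_b, single_reference
    )
    st_a = status_vs_ref_a.status
    st_b = (
        status_vs_ref_b.status if single_reference else _flip(status_vs_ref_b.status)
    )
    sv_id = status_vs_ref_a.sv_id
    if st_a is Status.UNRESOLVED or st_b is Status.UNRESOLVED:
        return SVClassification(sv_id, p_b_in_a, p_b_in_b, Category.UNRESOLVED)
    if st_a is Status.ABSENT and st_b is Status.FIXED:
        return SVClassification(sv_id, p_b_in_a, p_b_in_b, Category.SD)
    if st_a is Status.FIXED and st_b is Status.ABSENT:
        return SVClassification(
            sv_id, p_b_in_a, p_b_in_b, Category.SD, polarity_inverted=True
        )
    if st_a is Status.POLYMORPHIC and st_b is Status.POLYMORPHIC:
        return SVClassification(sv_id, p_b_in_a, p_b_in_b, Category.SSP)
    if st_a is Status.POLYMORPHIC or st_b is Status.POLYMORPHIC:
        return SVClassification(sv_id, p_b_in_a, p_b_in_b, Category.SP)
    # both ABSENT or both FIXED
    sub = "both_absent" if st_a is Status.ABSENT else "both_fixed"
    return SVClassification(
        sv_id, p_b_in_a, p_b_in_b, Category.PRIVATE_OR_ARTIFACT, sub_label=sub
    )


def frequency_spectrum(
    statuses: list[PopulationStatus],
    bin_width: float = 0.05,
    sv_types: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Histogram of carrier-allele frequencies per population (and sv_type).

    Returns one row per (population, sv_type, bin) with the SV count, and
    attaches the two tail masses among polymorphic SVs — the fractions
    genotyped at freq > 0.90 and freq < 0.10 — as ``frame.attrs['tails']``.
    """
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    tails: dict[tuple[str, str], dict[str, int]] = {}
    resolved = [s for s in statuses if s.status is not Status.UNRESOLVED]
    groups: dict[tuple[str, str], list[PopulationStatus]] = {}
    for s in resolved:
        stype = (sv_types or {}).get(s.sv_id, "ALL")
        groups.setdefault((s.population, stype), []).append(s)
    for (pop, stype), members in sorted(groups.items()):
        freqs = np.array([m.freq for m in members])
        counts, _ = np.histogram(freqs, bins=edges)
        # freq == 1.0 falls in the last bin via histogram's closed right edge
        for b in range(n_bins):
            rows.append(
                {
                    "population": pop,
                    "sv_type": stype,
                    "bin_low": edges[b],
                    "bin_high": edges[b + 1],
                    "count": int(counts[b]),
                }
            )
        poly = np.array(
            [m.freq for m in members if m.status is Status.POLYMORPHIC]
        )
        tails[(pop, stype)] = {
            "n_low": int((poly < 0.10).sum()) if poly.size else 0,
            "n_high": int((poly > 0.90).sum()) if poly.size else 0,
            "n_polymorphic": int(poly.size),
        }
    if not rows:  # no resolved statuses: an all-zero single histogram
        for b in range(n_bins):
            rows.append(
                {
                    "population": "",
                    "sv_type": "ALL",
                    "bin_low": edges[b],
                    "bin_high": edges[b + 1],
                    "count": 0,
                }
            )
    frame = pd.DataFrame(rows)
    frame.attrs["tails"] = tails
    return frame


def genotyping_summary(
    statuses: list[PopulationStatus],
    sv_types: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Counts and rates of genotyping outcomes per population and sv_type.

    ``genotyping_rate`` is resolved SVs / total SVs; the four status
    counts partition the total exactly.
    """
    rows = []
    groups: dict[tuple[str, str], list[PopulationStatus]] = {}
    for s in statuses:
        stype = (sv_types or {}).get(s.sv_id, "ALL")
        groups.setdefault((s.population, stype), []).append(s)
    for (pop, stype), members in sorted(groups.items()):
        total = len(members)
        by_status = {st: 0 for st in Status}
        for m in members:
            by_status[m.status] += 1
        resolved = total - by_status[Status.UNRESOLVED]
        rows.append(
            {
                "population": pop,
                "sv_type": stype,
                "n_svs": total,
                "n_absent": by_status[Status.ABSENT],
                "n_polymorphic": by_status[Status.POLYMORPHIC],
                "n_fixed": by_status[Status.FIXED],
                "n_unresolved": by_status[Status.UNRESOLVED],
                "genotyping_rate": resolved / total if total else math.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "population", "sv_type", "n_svs", "n_absent", "n_polymorphic",
            "n_fixed", "n_unresolved", "genotyping_rate",
        ],
    )


def classifications_to_frame(classifications: list[SVClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sv_id": c.sv_id,
                "p_B_in_A": c.p_b_in_a,
                "p_B_in_B": c.p_b_in_b,
                "category": c.category.value,
                "polarity_inverted": c.polarity_inverted,
                "sub_label": c.sub_label,
            }
            for c in classifications
        ],
        columns=[
            "sv_id", "p_B_in_A", "p_B_in_B", "category", "polarity_inverted", "sub_label",
        ],
    )


def statuses_to_frame(statuses: list[PopulationStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sv_id": s.sv_id,
                "population": s.population,
                "n_alleles_genotyped": s.n_alleles_genotyped,
                "carrier_alleles": s.carrier_alleles,
                "freq": s.freq,
                "status": s.status.value,
            }
            for s in statuses
        ],
        columns=[
            "sv_id", "population", "n_alleles_genotyped", "carrier_alleles",
            "freq", "status",
        ],
    )
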