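"""Shared domain types for the yeast virome / killer-phenotype pipeline.

The pipeline surveys a cohort of *S. cerevisiae* strains for cytoplasmic
RNA viruses (the totiviruses L-A and L-BC, the narnaviruses 20S and 23S),
L-A-dependent M satellites (M1, M2, M28, Mlus), killer phenotypes scored
on methylene-blue plates, and the chromosomal killer genes KHS1/KHR1.
Everything downstream (typing, scoring, association, contingency tests)
speaks in terms of the records defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "VIRUSES",
    "M_SATELLITES",
    "PRIMER_PAIR_COUNTS",
    "BIN_VALUES",
    "MISSING_DOSAGE",
    "ValidationError",
    "ReferentialIntegrityError",
    "CuringState",
    "StopType",
    "GenotypeClass",
    "SpeciesOrigin",
    "KillerStatus",
    "LbcLevel",
    "StrainRecord",
    "PcrPanel",
    "VirusStatus",
    "KillerAssay",
    "QuantRecord",
    "OrfRecord",
    "KillerCall",
    "ResistanceCall",
    "Khs1Class",
    "GenotypeMatrix",
    "GRM",
]

#: Viruses and satellites the PCR panels cover, in reporting order.
VIRUSES = ("L-A", "L-BC", "20S", "23S", "M1", "M2", "M28", "Mlus")

#: The L-A-dependent satellites (subject to helper-dependence and exclusion).
M_SATELLITES = ("M1", "M2", "M28", "Mlus")

#: Number of diagnostic primer pairs per virus/satellite (survey design).
PRIMER_PAIR_COUNTS = {
    "L-A": 7,
    "L-BC": 3,
    "20S": 2,
    "23S": 2,
    "M1": 2,
    "M2": 2,
    "M28": 2,
    "Mlus": 5,
}

#: Allowed ordinal bin values for killing-zone and staining scores,
#: in increasing order of killing.
BIN_VALUES = (0.0, 0.5, 1.0, 2.0)

#: Sentinel for a missing diploid dosage (distinct from {0, 1, 2}).
MISSING_DOSAGE = -1


class ValidationError(ValueError):
    """A record violates its declared vocabulary or shape."""


class ReferentialIntegrityError(ValueError):
    """A table refers to a strain that is not in the cohort."""


class CuringState(str, Enum):
    """Curing status of a strain relative to its parent.

    ``parent`` is an uncured isolate; ``LA0_M0`` lost L-A (cocuring any M
    satellite); ``LAplus_M0`` retained L-A but lost its M satellite.
    """

    parent = "parent"
    LA0_M0 = "LA0_M0"
    LAplus_M0 = "LAplus_M0"


class StopType(str, Enum):
    """Stop codon nomenclature: TAA=ochre, TAG=amber, TGA=opal."""

    ochre = "ochre"
    amber = "amber"
    opal = "opal"


class GenotypeClass(str, Enum):
    """Category of a chromosomal killer ORF allele."""

    absent = "absent"
    full_length = "full_length"
    opal = "opal"
    opal_ochre = "opal_ochre"
    other = "other"


class SpeciesOrigin(str, Enum):
    cerevisiae = "cerevisiae"
    paradoxus = "paradoxus"
    ambiguous = "ambiguous"


class KillerStatus(str, Enum):
    """Killer phenotype: K+ (clear killing), K+/- (partial), K- (none)."""

    Kplus = "K+"
    Kpartial = "K+/-"
    Kminus = "K-"


class LbcLevel(str, Enum):
    """L-BC abundance category: hi (visible ~4.6-kb gel band) vs lo."""

    hi = "hi"
    lo = "lo"


@dataclass
class StrainRecord:
    """Identity and metadata of one cohort strain.

    ``derivative_of`` links a cured derivative back to its parent isolate;
    parents themselves carry ``curing_state=parent``.
    """

    strain_id: str
    population_label: str = ""
    clinical_origin: bool = False
    derivative_of: str | None = None
    curing_state: CuringState = CuringState.parent

    def __post_init__(self) -> None:
        self.curing_state = CuringState(self.curing_state)
        if self.derivative_of is not None and self.curing_state == CuringState.parent:
            raise ValidationError(
                f"{self.strain_id}: a derivative must not have curing_state=parent"
            )


@dataclass
class PcrPanel:
    """Per-strain, per-virus results of the multi-primer-pair PCR panel.

    ``pair_results`` holds one 0/1 entry per diagnostic primer pair, in the
    declared pair order. ``cdna_mask`` marks pair indices (0-based) whose
    product is attributable to a nuclear cDNA copy rather than the RNA
    element itself; masked positives never count toward presence.
    """

    strain_id: str
    virus: str
    pair_results: tuple[int, ...]
    cdna_mask: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.virus not in VIRUSES:
            raise ValidationError(f"unknown virus {self.virus!r}")
        self.pair_results = tuple(int(v) for v in self.pair_results)
        if any(v not in (0, 1) for v in self.pair_results):
            raise ValidationError(f"{self.strain_id}/{self.virus}: pair results must be 0/1")
        expected = PRIMER_PAIR_COUNTS[self.virus]
        if len(self.pair_results) != expected:
            raise ValidationError(
                f"{self.strain_id}/{self.virus}: expected {expected} primer pairs, "
                f"got {len(self.pair_results)}"
            )
        self.cdna_mask = frozenset(int(i) for i in self.cdna_mask)
        if not self.cdna_mask <= set(range(len(self.pair_results))):
            raise ValidationError(
                f"{self.strain_id}/{self.virus}: cdna_mask outside valid pair indices"
            )


@dataclass
class VirusStatus:
    """Final presence call for one (strain, virus) after panel interpretation."""

    strain_id: str
    virus: str
    present: bool
    pcr_genotype: str = ""
    gel_band_kb: float | None = None
    lbc_level: LbcLevel | None = None
    cdna_signal: bool = False

    def __post_init__(self) -> None:
        if self.lbc_level is not None:
            self.lbc_level = LbcLevel(self.lbc_level)


@dataclass
class KillerAssay:
    """One killer-by-lawn plate assay under a stated condition.

    ``zone_bin`` is the qualitative killing-zone size and ``stain_bin`` the
    methylene-blue staining category; both are drawn from {2, 1, 0.5, 0}
    in decreasing order of killing.
    """

    killer_id: str
    lawn_id: str
    ph: float = 4.7
    temp_c: float = 20.0
    medium: str = "MB"
    zone_bin: float = 0.0
    stain_bin: float = 0.0

    def __post_init__(self) -> None:
        if self.medium not in ("MB", "SD_MB"):
            raise ValidationError(f"unknown medium {self.medium!r}")
        for name in ("zone_bin", "stain_bin"):
            v = float(getattr(self, name))
            if v not in BIN_VALUES:
                raise ValidationError(
                    f"{self.killer_id} vs {self.lawn_id}: {name}={v} not in {BIN_VALUES}"
                )
            setattr(self, name, v)


@dataclass
class QuantRecord:
    """RT-qPCR quantification cycles for relative (2^-ddCq) quantification.

    The target is quantified against a reference transcript (e.g. UBC6) in
    both the sample of interest and a calibrator sample.
    """

    strain_id: str
    target_cq: float
    ref_cq: float
    calibrator_target_cq: float
    calibrator_ref_cq: float

    def __post_init__(self) -> None:
        for name in ("target_cq", "ref_cq", "calibrator_target_cq", "calibrator_ref_cq"):
            if not float(getattr(self, name)) > 0:
                raise ValidationError(f"{self.strain_id}: {name} must be positive")


@dataclass
class OrfRecord:
    """A chromosomal killer ORF allele for one strain.

    ``stops`` lists premature stop codons as (1-based codon index, type);
    an absent gene is represented by ``sequence=None``.
    """

    gene: str
    strain_id: str
    sequence: str | None = None
    stops: tuple[tuple[int, StopType], ...] = ()
    genotype_class: GenotypeClass | None = None
    species_origin: SpeciesOrigin | None = None

    def __post_init__(self) -> None:
        if self.gene not in ("KHS1", "KHR1"):
            raise ValidationError(f"unknown killer gene {self.gene!r}")
        self.stops = tuple((int(i), StopType(t)) for i, t in self.stops)


@dataclass
class KillerCall:
    strain_id: str
    toxin_context: str = "unknown"
    status: KillerStatus = KillerStatus.Kminus
    max_zone_bin: float = 0.0
    m_dependent: bool | None = None
    residual_killing: bool = False
    note: str = ""


@dataclass
class ResistanceCall:
    lawn_id: str
    toxin: str
    resistant: bool
    m_independent: bool | None = None


@dataclass
class Khs1Class:
    strain_id: str
    class_label: str  # one of 1, 2, 3A, 3B, 4A, 4B, unclassifiable


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix, strains x sites, entries in {0,1,2} or -1 missing."""

    strain_ids: list[str]
    site_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        n, m = self.dosages.shape
        if n != len(self.strain_ids) or m != len(self.site_ids):
            raise ValidationError("dosage matrix shape does not match id lists")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING_DOSAGE))
        if not valid.all():
            raise ValidationError("dosages must be in {0,1,2} or the missing sentinel")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def allele_freqs(self) -> np.ndarray:
        """Per-site alternate allele frequency, ignoring missing entries."""
        d = np.ma.masked_equal(self.dosages, MISSING_DOSAGE)
        return np.asarray(d.mean(axis=0) / 2.0)

    def minor_allele_freqs(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def imputed(self) -> np.ndarray:
        """Float dosages with missing entries replaced by the per-site mean."""
        x = self.dosages.astype(float)
        miss = self.dosages == MISSING_DOSAGE
        if miss.any():
            x[miss] = np.nan
            means = np.nanmean(x, axis=0)
            means = np.where(np.isnan(means), 0.0, means)
            idx = np.where(miss)
            x[idx] = means[idx[1]]
        return x

    def subset_sites(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            strain_ids=list(self.strain_ids),
            site_ids=[self.site_ids[i] for i in index],
            dosages=self.dosages[:, index],
        )


@dataclass
class GRM:
    """Genetic relationship matrix over cohort strains (symmetric n x n)."""

    strain_ids: list[str]
    values: np.ndarray
    sparse_threshold_applied: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.strain_ids)
        if self.values.shape != (n, n):
            raise ValidationError("GRM shape does not match strain list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("GRM must be symmetric")
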