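"""Chromosomal killer ORF screening.

Detects premature stop codons in annotated killer-gene ORFs (KHS1, KHR1),
categorizes alleles, and assigns a species of origin by percent identity to
reference ORFs (introgressed alleles match the sister-species reference).
Codon indexing is 1-based from the initiator ATG, so the classic tryptophan-66
opal allele reports as codon 66.
"""

from __future__ import annotations

import edlib

from .types import GenotypeClass, OrfRecord, SpeciesOrigin, StopType, ValidationError

__all__ = [
    "STOP_CODONS",
    "detect_premature_stops",
    "classify_genotype",
    "annotate_orf",
    "assign_species_origin",
]

STOP_CODONS = {"TAA": StopType.ochre, "TAG": StopType.amber, "TGA": StopType.opal}

_ACGT = set("ACGT")


def _validate_orf(seq: str) -> str:
    seq = seq.upper()
    if set(seq) - _ACGT:
        raise ValidationError(f"non-ACGT character in sequence: {sorted(set(seq) - _ACGT)}")
    if len(seq) % 3 != 0:
        raise ValidationError(f"ORF length {len(seq)} not divisible by 3")
    if not seq.startswith("ATG"):
        raise ValidationError("ORF must start with ATG (frame 0, forward strand)")
    return seq


def detect_premature_stops(seq: str) -> list[tuple[int, StopType]]:
    """In-frame stop codons strictly before the final codon, 1-based.

    The terminal stop is normal termination, not a premature stop. Reverse
    complement input fails the ATG/frame validation rather than being
    silently scanned.
    """
    seq = _validate_orf(seq)
    n_codons = len(seq) // 3
    stops = []
    for i in range(1, n_codons - 1):  # skip ATG, skip final codon
        codon = seq[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            stops.append((i + 1, STOP_CODONS[codon]))
    return stops


def classify_genotype(rec: OrfRecord) -> GenotypeClass:
    """Allele category from the detected premature stops.

    absent (no sequence) / full_length (no premature stops) / opal (a
    single opal stop) / opal_ochre (one opal plus one ochre) / other.
    """
    if rec.sequence is None:
        return GenotypeClass.absent
    stops = rec.stops
    if not stops:
        return GenotypeClass.full_length
    types = sorted(t.value for _, t in stops)
    if types == ["opal"]:
        return GenotypeClass.opal
    if types == ["ochre", "opal"]:
        return GenotypeClass.opal_ochre
    return GenotypeClass.other


def annotate_orf(rec: OrfRecord) -> OrfRecord:
    """Fill in stops and genotype_class for a raw ORF record, in place."""
    if rec.sequence is not None:
        rec.stops = tuple(detect_premature_stops(rec.sequence))
    rec.genotype_class = classify_genotype(rec)
    return rec


def _identity(a: str, b: str) -> float:
    """Percent identity: ungapped positionwise for equal lengths, else
    edit-distance based (1 - d / max length)."""
    if len(a) == len(b):
        matches = sum(x == y for x, y in zip(a, b))
        return 100.0 * matches / len(a)
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 100.0 * (1.0 - d / max(len(a), len(b)))


def assign_species_origin(
    seq: str,
    ref_cerevisiae: str,
    ref_paradoxus: str,
    margin: float = 1.0,
) -> tuple[SpeciesOrigin, dict[str, float]]:
    """Species of origin by higher percent identity to either reference.

    Identity margins below ``margin`` percentage points are called
    ambiguous. Returns the call plus both identities.
    """
    if not ref_cerevisiae or not ref_paradoxus:
        raise ValidationError("both reference sequences must be non-empty")
    ids = {
        "cerevisiae": _identity(seq.upper(), ref_cerevisiae.upper()),
        "paradoxus": _identity(seq.upper(), ref_paradoxus.upper()),
    }
    diff = ids["cerevisiae"] - ids["paradoxus"]
    if abs(diff) < margin:
        return SpeciesOrigin.ambiguous, ids
    return (SpeciesOrigin.cerevisiae if diff > 0 else SpeciesOrigin.paradoxus), ids
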