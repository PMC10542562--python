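"""Killer phenotype calling and the KHS1 genotype-by-phenotype classes.

A strain's killer status comes from its maximum killing-zone bin across all
tested lawns: any zone of 1 or 2 is a killer (K+), a best zone of 0.5 is a
partial killer (K+/-), and all-zero zones are nonkiller (K-). M-satellite
dependence is decided by comparing a parent with its virus-cured derivative.
The six KHS1 classes cross the allele category (functional full-length ORF
vs premature-stop/absent) with two phenotypes: killing of the *C. glabrata*
tester and being killed by the strong reference Khs1 killer strain.
"""

from __future__ import annotations

import numpy as np

from .types import (
    BIN_VALUES,
    GenotypeClass,
    Khs1Class,
    KillerAssay,
    KillerCall,
    KillerStatus,
    ResistanceCall,
    ValidationError,
)

__all__ = [
    "call_killer",
    "parse_killer_label",
    "call_m_dependence",
    "call_resistance",
    "flag_m_dependent_resistance",
    "normalize_ordinal",
    "assign_khs1_class",
]

#: Ordinal bins (0, 0.5, 1, 2) -> the standard analysis scale (0, 1, 2, 3).
_NORMALIZE = {0.0: 0, 0.5: 1, 1.0: 2, 2.0: 3}

#: Allele categories grouped as non-functional for class assignment.
_NONFUNCTIONAL = {
    GenotypeClass.absent,
    GenotypeClass.opal,
    GenotypeClass.opal_ochre,
    GenotypeClass.other,
}


def call_killer(assays: list[KillerAssay], toxin_context: str = "unknown") -> KillerCall:
    """Killer status of one strain from its assays across lawns."""
    if not assays:
        raise ValidationError("call_killer needs at least one assay row")
    killer_ids = {a.killer_id for a in assays}
    if len(killer_ids) != 1:
        raise ValidationError(f"assays span multiple killer strains: {sorted(killer_ids)}")
    max_zone = max(a.zone_bin for a in assays)
    if max_zone >= 1.0:
        status = KillerStatus.Kplus
    elif max_zone == 0.5:
        status = KillerStatus.Kpartial
    else:
        status = KillerStatus.Kminus
    return KillerCall(
        strain_id=assays[0].killer_id,
        toxin_context=toxin_context,
        status=status,
        max_zone_bin=max_zone,
    )


def parse_killer_label(label: str) -> tuple[str, KillerStatus]:
    """Split a phenotype label like ``K1+``, ``Klus-`` or ``K1+/-`` into
    (toxin context, status)."""
    label = label.strip()
    for suffix, status in (
        ("+/-", KillerStatus.Kpartial),
        ("+", KillerStatus.Kplus),
        ("-", KillerStatus.Kminus),
    ):
        if label.endswith(suffix):
            toxin = label[: -len(suffix)]
            return (toxin if toxin != "K" else "unknown"), status
    raise ValidationError(f"unparseable killer label {label!r}")


def call_m_dependence(parent: KillerCall, cured: KillerCall) -> KillerCall:
    """Decide whether a parent's killing is M-satellite dependent.

    Dependence holds when a killing parent (K+ or K+/-) loses all killing
    upon curing. A cured derivative that retains any killing raises the
    residual flag (the signature of a chromosomally encoded toxin). For a
    nonkiller parent the question is undefined and reported as False with
    a note.
    """
    parent_kills = parent.status in (KillerStatus.Kplus, KillerStatus.Kpartial)
    cured_kills = cured.status in (KillerStatus.Kplus, KillerStatus.Kpartial)
    out = KillerCall(
        strain_id=parent.strain_id,
        toxin_context=parent.toxin_context,
        status=parent.status,
        max_zone_bin=parent.max_zone_bin,
        residual_killing=cured_kills,
    )
    if not parent_kills:
        out.m_dependent = False
        out.note = "parent is nonkiller; M dependence undefined"
    else:
        out.m_dependent = not cured_kills
    return out


def call_resistance(
    assays: list[KillerAssay],
    toxin: str,
    reference_killers: list[KillerCall],
) -> ResistanceCall:
    """Resistance of a lawn strain to one toxin.

    Resistant iff, against every K+ reference killer of that toxin, the
    lawn shows zone 0 and staining at most 0.5. Requires at least one K+
    reference; otherwise there is no evidence of active toxin.
    """
    active = {
        k.strain_id for k in reference_killers if k.status == KillerStatus.Kplus
    }
    if not active:
        raise ValidationError(f"no K+ reference killer available for {toxin}")
    lawn_ids = {a.lawn_id for a in assays}
    if len(lawn_ids) != 1:
        raise ValidationError("assays must concern a single lawn strain")
    relevant = [a for a in assays if a.killer_id in active]
    if not relevant:
        raise ValidationError(f"no assays against K+ {toxin} references")
    resistant = all(a.zone_bin == 0.0 and a.stain_bin <= 0.5 for a in relevant)
    return ResistanceCall(lawn_id=assays[0].lawn_id, toxin=toxin, resistant=resistant)


def flag_m_dependent_resistance(
    parent: ResistanceCall, cured: ResistanceCall
) -> ResistanceCall:
    """Annotate a parent's resistance call with its satellite dependence.

    A resistant parent whose virus-cured derivative is sensitive owes its
    resistance to the satellite-encoded antitoxin (``m_independent=False``);
    a derivative that stays resistant shows chromosomal resistance.
    """
    if parent.toxin != cured.toxin:
        raise ValidationError("parent and derivative calls concern different toxins")
    out = ResistanceCall(
        lawn_id=parent.lawn_id, toxin=parent.toxin, resistant=parent.resistant
    )
    if parent.resistant:
        out.m_independent = cured.resistant
    return out


def normalize_ordinal(scores) -> np.ndarray:
    """Map assay bins {0, 0.5, 1, 2} onto the standard scale {0, 1, 2, 3}.

    Strictly monotone and bijective on the bin vocabulary; anything
    outside it is rejected.
    """
    arr = np.asarray(scores, dtype=float)
    if not np.isin(arr, BIN_VALUES).all():
        bad = sorted(set(arr[~np.isin(arr, BIN_VALUES)].tolist()))
        raise ValidationError(f"scores outside the bin vocabulary: {bad}")
    out = np.empty(arr.shape, dtype=int)
    for raw, rank in _NORMALIZE.items():
        out[arr == raw] = rank
    return out


def assign_khs1_class(
    strain_id: str,
    genotype_class: GenotypeClass | str | None,
    kills_cglabrata: bool | None,
    killed_by_reference: bool | None,
) -> Khs1Class:
    """Assign one of the six KHS1 classes from genotype and two phenotypes.

    Decision table (kill = kills the *C. glabrata* tester; killed = killed
    by the reference Khs1 killer):

    ======================  =========================================
    (no kill, killed)       class 1 (consistent non-functional allele)
    (no kill, resistant)    class 2 (allele-independent resistance)
    (kill, resistant)       class 3A if full-length ORF else 3B
    (kill, killed)          class 4A if premature-stop/absent else 4B
    ======================  =========================================

    Missing genotype or either phenotype yields ``unclassifiable``.
    """
    if genotype_class is None or kills_cglabrata is None or killed_by_reference is None:
        return Khs1Class(strain_id=strain_id, class_label="unclassifiable")
    genotype_class = GenotypeClass(genotype_class)
    functional = genotype_class == GenotypeClass.full_length
    if not kills_cglabrata:
        label = "1" if killed_by_reference else "2"
    elif not killed_by_reference:
        label = "3A" if functional else "3B"
    else:
        label = "4A" if genotype_class in _NONFUNCTIONAL else "4B"
    return Khs1Class(strain_id=strain_id, class_label=label)
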