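"""Virome typing: presence calls, PCR genotypes, L-BC levels, dependency checks.

Presence of an RNA virus or M satellite is called from a multi-primer-pair
PCR panel: one positive pair suffices, except that pairs flagged as hitting
a nuclear cDNA copy of the element are masked and can only yield a
"genomic cDNA signal" annotation, never presence. L-BC abundance is
dichotomized (hi/lo) from gel-band evidence or, for strains that cannot be
cured of L-A, from relative RT-qPCR quantification. Helper-dependence rules
(M satellites require L-A; at most one M species per strain; curing L-A
must cocure M) are validated over cohorts of presence calls.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import (
    M_SATELLITES,
    LbcLevel,
    PcrPanel,
    QuantRecord,
    ValidationError,
    VirusStatus,
)

__all__ = [
    "PresenceCall",
    "Violation",
    "CuringReport",
    "call_presence",
    "pcr_genotype",
    "status_from_panel",
    "relative_quant",
    "classify_lbc_level",
    "validate_dependencies",
    "check_curing",
]

DEFAULT_HI_THRESHOLD = 2.0  # relative units; gel-calibrated, configurable


@dataclass
class PresenceCall:
    present: bool
    n_positive_unmasked: int
    cdna_signal: bool  # a masked pair was positive


@dataclass
class Violation:
    strain_id: str
    kind: str  # "dependency" | "exclusion" | "cocuring" | "inconsistent_curing"
    detail: str


@dataclass
class CuringReport:
    parent_id: str
    derivative_id: str
    violations: list[Violation]

    @property
    def ok(self) -> bool:
        return not self.violations


def call_presence(panel: PcrPanel) -> PresenceCall:
    """Present iff at least one unmasked primer pair gave a product.

    A positive result from a masked (nuclear-cDNA) pair alone does not
    make the element present; it is reported as a cDNA signal so that
    curing checks can exempt it. Adding positive unmasked pairs can never
    flip a present call to absent (monotonicity).
    """
    unmasked_pos = sum(
        r for i, r in enumerate(panel.pair_results) if i not in panel.cdna_mask
    )
    masked_pos = any(
        panel.pair_results[i] for i in panel.cdna_mask
    )
    return PresenceCall(
        present=unmasked_pos >= 1,
        n_positive_unmasked=unmasked_pos,
        cdna_signal=bool(masked_pos),
    )


def pcr_genotype(panel: PcrPanel) -> str:
    """Comma-joined 0/1 string over the declared primer-pair order."""
    return ",".join(str(v) for v in panel.pair_results)


def status_from_panel(panel: PcrPanel) -> VirusStatus:
    call = call_presence(panel)
    return VirusStatus(
        strain_id=panel.strain_id,
        virus=panel.virus,
        present=call.present,
        pcr_genotype=pcr_genotype(panel),
        cdna_signal=call.cdna_signal,
    )


def relative_quant(q: QuantRecord) -> float:
    """Relative level by the 2^-ddCq method.

    ddCq = (target - reference) cycles in the sample minus the same
    difference in the calibrator; equal deltas give exactly 1.0, and each
    extra cycle of sample delta halves the level.
    """
    ddcq = (q.target_cq - q.ref_cq) - (q.calibrator_target_cq - q.calibrator_ref_cq)
    return float(2.0 ** (-ddcq))


def classify_lbc_level(
    gel_band_present: bool | None = None,
    quant: float | None = None,
    hi_threshold: float = DEFAULT_HI_THRESHOLD,
) -> LbcLevel:
    """hi/lo call from exactly one evidence path (gel band or qPCR level)."""
    if (gel_band_present is None) == (quant is None):
        raise ValidationError("supply exactly one of gel_band_present or quant")
    if gel_band_present is not None:
        return LbcLevel.hi if gel_band_present else LbcLevel.lo
    return LbcLevel.hi if quant >= hi_threshold else LbcLevel.lo


def validate_dependencies(statuses: list[VirusStatus]) -> list[Violation]:
    """Check helper-dependence and satellite exclusion over a cohort.

    Emits one violation per (a) M-satellite-positive strain that is L-A
    negative and (b) strain carrying more than one M species. Violations
    are data, not exceptions.
    """
    by_strain: dict[str, dict[str, VirusStatus]] = {}
    for s in statuses:
        by_strain.setdefault(s.strain_id, {})[s.virus] = s
    violations: list[Violation] = []
    for sid, viruses in sorted(by_strain.items()):
        m_present = [v for v in M_SATELLITES if v in viruses and viruses[v].present]
        la = viruses.get("L-A")
        if m_present and (la is None or not la.present):
            violations.append(
                Violation(sid, "dependency", f"{'/'.join(m_present)} present without L-A")
            )
        if len(m_present) > 1:
            violations.append(
                Violation(sid, "exclusion", f"multiple M species: {'/'.join(m_present)}")
            )
    return violations


def check_curing(
    parent: list[VirusStatus], derivative: list[VirusStatus]
) -> CuringReport:
    """Verify that curing L-A from a parent cocured its M satellites.

    The derivative must be L-A negative (else the curing claim is
    inconsistent) and must have lost every M species the parent carried.
    Masked nuclear-cDNA signals are chromosomal and are exempt: a
    derivative may keep producing a cDNA-derived PCR product.
    """
    p = {s.virus: s for s in parent}
    d = {s.virus: s for s in derivative}
    pid = parent[0].strain_id if parent else "?"
    did = derivative[0].strain_id if derivative else "?"
    violations: list[Violation] = []

    la = d.get("L-A")
    if la is not None and la.present:
        violations.append(
            Violation(did, "inconsistent_curing", "derivative still L-A positive")
        )
    for m in M_SATELLITES:
        if m in p and p[m].present and m in d and d[m].present:
            violations.append(Violation(did, "cocuring", f"{m} retained after L-A loss"))
    return CuringReport(parent_id=pid, derivative_id=did, violations=violations)
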