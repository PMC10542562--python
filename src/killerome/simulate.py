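"""Synthetic cohorts with the statistical structure the analysis assumes.

Generates (i) structured diploid genotypes via the Balding-Nichols model,
(ii) ordinal killer phenotypes from a latent liability with an optional
planted causal site and a GRM-structured polygenic background, (iii) virome
PCR panels obeying the helper-dependence rules (M satellites only in L-A+
strains, one M species per strain, L-BC ubiquitous with a hi/lo split),
(iv) killer-gene ORF sets with planted premature stops, and (v) killer-by-
lawn assay matrices from a toxin/resistance truth. Default prevalences
reproduce the observed cohort rates of the 100-strain survey (30% L-A+,
L-BC universal, 26% 20S+, 14% 23S+, and 5/3/0/7 of the 30 L-A+ strains
carrying M1/M2/M28/Mlus). Everything is reproducible from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import child_rng
from .types import (
    BIN_VALUES,
    GRM,
    GenotypeMatrix,
    KillerAssay,
    OrfRecord,
    PcrPanel,
    PRIMER_PAIR_COUNTS,
    StopType,
    ValidationError,
    VirusStatus,
)
from .assoc import compute_grm
from .orfs import STOP_CODONS

__all__ = [
    "SimConfig",
    "KillerTruth",
    "simulate_population",
    "simulate_ordinal_phenotype",
    "simulate_virome",
    "simulate_orf_set",
    "simulate_killer_assays",
]

_DEFAULT_PREVALENCES = {
    "L-A": 0.30,
    "L-BC": 1.0,
    "20S": 0.26,
    "23S": 0.14,
    # M satellites: probability conditional on the strain being L-A+
    "M1": 5 / 30,
    "M2": 3 / 30,
    "M28": 0.0,
    "Mlus": 7 / 30,
}

#: Latent-liability quantile cuts for bins 0 / 0.5 / 1 / 2 (strong killers rare).
ORDINAL_QUANTILES = (0.5, 0.75, 0.9)

_TOXIN_CONDITIONS = {
    # toxin -> (pH, temperature C, medium)
    "K1": (4.7, 20.0, "MB"),
    "K2": (4.7, 20.0, "MB"),
    "Khs1": (4.7, 20.0, "MB"),
    "K28": (6.0, 30.0, "MB"),
    "Klus": (6.0, 30.0, "MB"),
    "Khr1": (6.0, 20.0, "SD_MB"),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    ``fst`` controls between-subpopulation differentiation of allele
    frequencies; ``causal_effect`` is on the latent-liability scale per
    standard deviation of dosage; ``heritability_background`` is the
    latent-scale variance fraction of the GRM-structured polygenic term
    (the residual takes up the remainder).
    """

    n_strains: int = 100
    n_sites: int = 500
    n_subpops: int = 3
    fst: float = 0.2
    causal_site_index: int | None = None
    causal_effect: float = 0.0
    heritability_background: float = 0.3
    virus_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCES)
    )
    lbc_hi_prob: float = 0.33
    pair_dropout: float = 0.15
    n_m28_cdna_strains: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValidationError(f"fst={self.fst} must be in [0, 1)")
        if self.n_strains < 2 or self.n_sites < 1 or self.n_subpops < 1:
            raise ValidationError("need n_strains >= 2, n_sites >= 1, n_subpops >= 1")
        if not 0 <= self.heritability_background < 1:
            raise ValidationError("heritability_background must be in [0, 1)")
        for v, p in self.virus_prevalences.items():
            if not 0 <= p <= 1:
                raise ValidationError(f"prevalence of {v} must be in [0, 1]")
        m_total = sum(self.virus_prevalences.get(m, 0.0) for m in ("M1", "M2", "M28", "Mlus"))
        if m_total > 1:
            raise ValidationError("conditional M-satellite prevalences must sum to <= 1")
        if not 0 <= self.pair_dropout < 1:
            raise ValidationError("pair_dropout must be in [0, 1)")
        if self.causal_site_index is not None and not (
            0 <= self.causal_site_index < self.n_sites
        ):
            raise ValidationError("causal_site_index out of range")


def _strain_ids(n: int) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(n)]


def simulate_population(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, np.ndarray, GRM]:
    """Structured diploid genotypes under the Balding-Nichols model.

    Ancestral frequencies are Uniform(0.1, 0.9); each subpopulation draws
    its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) so that the expected
    differentiation equals ``fst`` (F = 0 collapses to identical
    frequencies). Strains are split into equal-size subpopulations and
    dosages are two binomial draws from the subpopulation frequency.
    Returns the genotype matrix, subpopulation labels, and the realized
    GRM of the simulated cohort.
    """
    rng = child_rng(cfg.seed, "simulate_population")
    n, m, k = cfg.n_strains, cfg.n_sites, cfg.n_subpops
    p_anc = rng.uniform(0.1, 0.9, size=m)
    if cfg.causal_site_index is not None:
        # A planted causal locus is by definition a common variant: pin its
        # ancestral frequency at 0.5 (subpopulation drift still applies) so
        # the recovery experiment is well-posed.
        p_anc[cfg.causal_site_index] = 0.5
    if cfg.fst > 0 and k > 1:
        ratio = (1.0 - cfg.fst) / cfg.fst
        p_sub = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio, size=(k, m))
    else:
        p_sub = np.tile(p_anc, (k, 1))
    labels = np.sort(np.arange(n) % k)
    dosages = rng.binomial(2, p_sub[labels, :])
    gm = GenotypeMatrix(
        strain_ids=_strain_ids(n),
        site_ids=[f"site{j + 1:05d}" for j in range(m)],
        dosages=dosages,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # simulated sites may go monomorphic
        grm = compute_grm(gm)
    return gm, labels, grm


def simulate_ordinal_phenotype(
    gm: GenotypeMatrix, grm: GRM, cfg: SimConfig
) -> np.ndarray:
    """Ordinal scores in {0, 0.5, 1, 2} from a latent liability.

    latent = causal_effect * standardized causal dosage
           + polygenic term (covariance proportional to the GRM,
             variance = heritability_background)
           + Gaussian residual (variance = 1 - heritability_background).

    The liability is cut at its empirical 50/75/90% quantiles into the
    four assay bins, mimicking the rarity of strong killers.
    """
    rng = child_rng(cfg.seed, "simulate_ordinal_phenotype")
    n = gm.n_strains
    latent = np.zeros(n)
    if cfg.causal_site_index is not None and cfg.causal_effect != 0.0:
        x = gm.imputed()[:, cfg.causal_site_index]
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        latent = latent + cfg.causal_effect * z
    h2 = cfg.heritability_background
    if h2 > 0:
        K = grm.values + 1e-6 * np.eye(n)
        L = np.linalg.cholesky(K)
        latent = latent + np.sqrt(h2) * (L @ rng.standard_normal(n))
    latent = latent + np.sqrt(1.0 - h2) * rng.standard_normal(n)
    cuts = np.quantile(latent, ORDINAL_QUANTILES)
    return np.asarray(BIN_VALUES)[np.searchsorted(cuts, latent, side="right")]


def _panel_results(
    rng: np.random.Generator, n_pairs: int, present: bool, dropout: float
) -> tuple[int, ...]:
    if not present:
        return (0,) * n_pairs
    res = (rng.random(n_pairs) >= dropout).astype(int)
    if res.sum() == 0:
        res[rng.integers(n_pairs)] = 1  # presence implies >= 1 positive pair
    return tuple(int(v) for v in res)


def simulate_virome(
    cfg: SimConfig, strain_ids: list[str] | None = None
) -> tuple[list[PcrPanel], list[VirusStatus]]:
    """PCR panels plus ground-truth presence calls for a cohort.

    Enforces the dependency structure by construction: M satellites are
    assigned only to L-A+ strains and at most one M species per strain
    (satellite exclusion). L-BC presence follows its prevalence (1.0 by
    default: universal) with a hi/lo abundance split; hi strains carry a
    4.6-kb gel band. Per-pair dropout generates PCR-genotype variety for
    the viruses; M satellites show no genotype variation. Optionally a few
    strains carry a masked nuclear M28 cDNA signal.
    """
    rng = child_rng(cfg.seed, "simulate_virome")
    ids = strain_ids or _strain_ids(cfg.n_strains)
    prev = cfg.virus_prevalences
    m_species = ("M1", "M2", "M28", "Mlus")
    m_probs = np.array([prev.get(s, 0.0) for s in m_species])
    panels: list[PcrPanel] = []
    statuses: list[VirusStatus] = []
    cdna_ids = set(
        rng.choice(len(ids), size=min(cfg.n_m28_cdna_strains, len(ids)), replace=False).tolist()
    )
    for i, sid in enumerate(ids):
        la = rng.random() < prev.get("L-A", 0.0)
        lbc = rng.random() < prev.get("L-BC", 1.0)
        s20 = rng.random() < prev.get("20S", 0.0)
        s23 = rng.random() < prev.get("23S", 0.0)
        chosen_m: str | None = None
        if la:
            u = rng.random()
            acc = 0.0
            for s, p in zip(m_species, m_probs):
                acc += p
                if u < acc:
                    chosen_m = s
                    break
        lbc_hi = bool(lbc and rng.random() < cfg.lbc_hi_prob)
        present_map = {"L-A": la, "L-BC": lbc, "20S": s20, "23S": s23}
        for virus, present in present_map.items():
            res = _panel_results(rng, PRIMER_PAIR_COUNTS[virus], present, cfg.pair_dropout)
            panel = PcrPanel(sid, virus, res)
            panels.append(panel)
            statuses.append(
                VirusStatus(
                    strain_id=sid,
                    virus=virus,
                    present=bool(present),
                    pcr_genotype=",".join(str(v) for v in res),
                    gel_band_kb=4.6 if virus == "L-BC" and lbc_hi else None,
                    lbc_level=("hi" if lbc_hi else "lo") if virus == "L-BC" and lbc else None,
                )
            )
        for sat in m_species:
            present = chosen_m == sat
            n_pairs = PRIMER_PAIR_COUNTS[sat]
            res = (1,) * n_pairs if present else (0,) * n_pairs
            mask: frozenset[int] = frozenset()
            cdna = False
            if sat == "M28" and not present and i in cdna_ids:
                res = (1,) + (0,) * (n_pairs - 1)
                mask = frozenset({0})
                cdna = True
            panel = PcrPanel(sid, sat, res, mask)
            panels.append(panel)
            statuses.append(
                VirusStatus(
                    strain_id=sid,
                    virus=sat,
                    present=bool(present),
                    pcr_genotype=",".join(str(v) for v in res),
                    cdna_signal=cdna,
                )
            )
    return panels, statuses


def simulate_orf_set(
    n: int,
    stop_spec: list[tuple[int, StopType | str, float]],
    seed: int = 0,
    gene: str = "KHS1",
    n_codons: int = 100,
) -> list[OrfRecord]:
    """ORF alleles with premature stops planted at requested fractions.

    All records share one clean backbone (ATG + non-stop codons + terminal
    ochre); each (codon_index, stop_type, fraction) entry independently
    converts that codon to the stated stop in a Bernoulli(fraction) subset
    of records. Codon indices are 1-based and must fall strictly inside
    the ORF.
    """
    rng = child_rng(seed, "simulate_orf_set")
    stop_to_codon = {v: k for k, v in STOP_CODONS.items()}
    spec = [(int(i), StopType(t), float(f)) for i, t, f in stop_spec]
    for idx, _, frac in spec:
        if not 2 <= idx <= n_codons - 1:
            raise ValidationError(f"stop codon index {idx} outside ORF interior")
        if not 0 <= frac <= 1:
            raise ValidationError("stop fraction must be in [0, 1]")
    bases = "ACGT"
    codons = []
    while len(codons) < n_codons - 2:
        c = "".join(rng.choice(list(bases), size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    backbone = ["ATG"] + codons + ["TAA"]
    records = []
    for i in range(n):
        allele = list(backbone)
        for idx, stype, frac in spec:
            if rng.random() < frac:
                allele[idx - 1] = stop_to_codon[stype]
        records.append(
            OrfRecord(gene=gene, strain_id=f"S{i + 1:04d}", sequence="".join(allele))
        )
    return records


@dataclass
class KillerTruth:
    """Ground-truth toxin/resistance genotype of one strain.

    ``toxin`` is the toxin the strain secretes (None for nonkillers);
    ``strength`` the zone bin a successful kill produces; ``m_dependent``
    whether the toxin is satellite-encoded (lost on curing); ``cured``
    marks an L-A0 M0 derivative; ``resistances`` the toxins the strain
    withstands when used as a lawn.
    """

    strain_id: str
    toxin: str | None = None
    strength: float = 2.0
    m_dependent: bool = True
    cured: bool = False
    resistances: frozenset[str] = frozenset()


def _perturb_bin(rng: np.random.Generator, value: float) -> float:
    """Swap a bin with an adjacent bin (assay noise is local)."""
    bins = list(BIN_VALUES)
    i = bins.index(value)
    if i == 0:
        j = 1
    elif i == len(bins) - 1:
        j = i - 1
    else:
        j = i + (1 if rng.random() < 0.5 else -1)
    return bins[j]


def simulate_killer_assays(
    truths: list[KillerTruth],
    noise: float = 0.0,
    seed: int = 0,
    lawn_ids: list[str] | None = None,
) -> list[KillerAssay]:
    """Killer-by-lawn assay matrix from a toxin/resistance truth.

    A toxin-positive killer (with its satellite intact, if M-dependent)
    produces its strength bin on any lawn lacking the matching resistance;
    everything else scores zero. Assay conditions follow the toxin (pH,
    temperature, medium). Each zone/stain bin is independently swapped
    with an adjacent bin at the stated misclassification rate.
    """
    if not 0 <= noise < 0.5:
        raise ValidationError("noise must be in [0, 0.5)")
    rng = child_rng(seed, "simulate_killer_assays")
    by_id = {t.strain_id: t for t in truths}
    lawns = lawn_ids or [t.strain_id for t in truths]
    assays: list[KillerAssay] = []
    for killer in truths:
        active = killer.toxin is not None and not (killer.m_dependent and killer.cured)
        ph, temp, medium = _TOXIN_CONDITIONS.get(killer.toxin or "", (4.7, 20.0, "MB"))
        for lawn_id in lawns:
            if lawn_id == killer.strain_id:
                continue
            lawn = by_id[lawn_id]
            kills = active and killer.toxin not in lawn.resistances
            zone = killer.strength if kills else 0.0
            stain = zone
            if noise > 0:
                if rng.random() < noise:
                    zone = _perturb_bin(rng, zone)
                if rng.random() < noise:
                    stain = _perturb_bin(rng, stain)
            assays.append(
                KillerAssay(
                    killer_id=killer.strain_id,
                    lawn_id=lawn_id,
                    ph=ph,
                    temp_c=temp,
                    medium=medium,
                    zone_bin=zone,
                    stain_bin=stain,
                )
            )
    return assays
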