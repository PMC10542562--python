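"""Shared driver plumbing: the study cohort and the results directory."""

from pathlib import Path

import numpy as np

from killerome import io
from killerome.assoc import AssocConfig
from killerome.killer import normalize_ordinal
from killerome.simulate import (
    KillerTruth,
    SimConfig,
    simulate_killer_assays,
    simulate_ordinal_phenotype,
    simulate_orf_set,
    simulate_population,
    simulate_virome,
)

REPO = Path(__file__).resolve().parent.parent
RESULTS = REPO / "results"
COHORT_DIR = RESULTS / "cohort"

#: The synthetic study cohort: 100 strains, 3 subpopulations at Fst 0.2,
#: 500 sites, one planted causal locus of 1.5 latent SD driving the
#: killing phenotype over a 0.3-heritability polygenic background.
STUDY = dict(
    n_strains=100,
    n_sites=500,
    n_subpops=3,
    fst=0.2,
    causal_site_index=250,
    causal_effect=1.5,
    heritability_background=0.3,
    n_m28_cdna_strains=1,
)


def study_config(seed: int) -> SimConfig:
    return SimConfig(seed=seed, **STUDY)


def build_cohort(seed: int):
    """Generate the full study cohort in memory."""
    cfg = study_config(seed)
    gm, labels, grm = simulate_population(cfg)
    y = normalize_ordinal(simulate_ordinal_phenotype(gm, grm, cfg)).astype(float)
    panels, statuses = simulate_virome(cfg, strain_ids=list(gm.strain_ids))
    orfs = simulate_orf_set(
        cfg.n_strains, [(66, "opal", 0.35), (88, "ochre", 0.02)], seed=seed
    )
    truths = [
        KillerTruth("S0001", toxin="K1", m_dependent=True),
        KillerTruth("S0002", toxin="K1", m_dependent=True, cured=True),
        KillerTruth("S0003", toxin="Khs1", m_dependent=False),
        KillerTruth("S0004"),
        KillerTruth("S0005", resistances=frozenset({"K1"})),
    ]
    assays = simulate_killer_assays(truths, noise=0.0, seed=seed)
    return cfg, gm, labels, grm, y, panels, statuses, orfs, assays


def load_or_build(seed: int):
    """Prefer the cohort written by 01_simulate_cohort.py; else rebuild."""
    paths = {
        "strains": COHORT_DIR / "strains.tsv",
        "panels": COHORT_DIR / "panels.tsv",
        "assays": COHORT_DIR / "assays.tsv",
        "statuses": COHORT_DIR / "virome.tsv",
        "genotypes_tsv": COHORT_DIR / "genotypes.tsv",
        "orfs": COHORT_DIR / "orfs.fasta",
    }
    if all(p.exists() for p in paths.values()) and (COHORT_DIR / "phenotype.tsv").exists():
        cohort = io.read_cohort(paths)
        pheno = np.loadtxt(COHORT_DIR / "phenotype.tsv", skiprows=1, usecols=1, delimiter="\t")
        return cohort, pheno
    cfg, gm, labels, grm, y, panels, statuses, orfs, assays = build_cohort(seed)
    cohort = io.Cohort(
        panels=panels, assays=assays, statuses=statuses, genotypes=gm, orfs=orfs
    )
    return cohort, y


def assoc_config(seed: int) -> AssocConfig:
    return AssocConfig(seed=seed)
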