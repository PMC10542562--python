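"""Packaged reference tables.

Three small fixtures encode the survey's published summary tables for a
100-strain *S. cerevisiae* cohort, and a fourth is a synthetic per-strain
stand-in for the unpublished supplementary table behind the chromosomal
killer (KHS1) classification.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_pcr_summary",
    "load_lbc_genotype_table",
    "load_m_satellite_table",
    "load_khs1_cohort_synthetic",
]


def _load(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("killerome.data").joinpath(name).open("r") as f:
        return pd.read_csv(f, sep="\t", **kwargs)


def load_pcr_summary() -> pd.DataFrame:
    """PCR survey design and outcome per virus/satellite.

    Columns: virus, number of positive strains out of 100, number of
    diagnostic primer pairs, number of distinct PCR genotypes observed
    (blank where the element was absent from the cohort).
    """
    return _load("table1_pcr_summary.tsv")


def load_lbc_genotype_table() -> pd.DataFrame:
    """L-BC PCR genotype by abundance level (hi/lo), counts as printed.

    The published hi-level total is internally inconsistent across the
    source (gel text: 31; table legend: 32; column sum: 33, the legend and
    column implicitly adding the two qPCR-typed uncurable strains). This
    fixture encodes the table column as printed: 33 hi / 67 lo.
    """
    return _load("table2_lbc_genotypes.tsv", dtype={"pcr_genotype": str})


def load_m_satellite_table() -> pd.DataFrame:
    """The 17 L-A+ strains carrying (or gel-suggesting) an M satellite.

    Columns: strain_id; m_species (M1/M2/Mlus, or ``0`` for strains whose
    small dsRNA gel band matched no known satellite by PCR); gel_band_kb
    (sub-4.6-kb band size, blank if none); killer (phenotype label, e.g.
    ``K1+``, ``K1+/-``, ``Klus-``, ``K-``).
    """
    return _load(
        "table3_m_satellites.tsv", dtype={"m_species": str, "killer": str}
    )


def load_khs1_cohort_synthetic() -> pd.DataFrame:
    """Synthetic per-strain KHS1 genotype/phenotype table (100 strains).

    This is a constructed stand-in, not measured data: it realizes, strain
    by strain, the published class-level description of the cohort (KHS1
    allele category, species of origin, whether the strain kills
    *C. glabrata*, and whether it is killed by the strong reference Khs1
    killer), so the class-assignment logic can be exercised end to end.
    Where the source names individual strains (the khs1-null strain and
    the two class-3B strains) those names are kept; all other strain ids
    are synthetic.
    """
    return _load("khs1_cohort_synthetic.tsv", dtype={"khs1_genotype": str})
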