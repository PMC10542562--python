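"""Readers and writers for the pipeline's on-disk formats.

All tabular inputs/outputs are UTF-8 TSV with a header row and deterministic
column order; genotypes come in either as a plain dosage TSV (rows=strains,
columns=sites, missing coded -1) or as a diploid VCF; ORFs travel as FASTA
with record ids ``GENE|strain``. ``read_cohort`` bundles and cross-validates
everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    MISSING_DOSAGE,
    GenotypeMatrix,
    KillerAssay,
    OrfRecord,
    PcrPanel,
    QuantRecord,
    ReferentialIntegrityError,
    StrainRecord,
    ValidationError,
    VirusStatus,
)

__all__ = [
    "Cohort",
    "read_strains",
    "write_strains",
    "read_panels",
    "write_panels",
    "read_assays",
    "write_assays",
    "read_virus_statuses",
    "write_virus_statuses",
    "read_quant_records",
    "write_quant_records",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "read_orfs_fasta",
    "write_orfs_fasta",
    "read_cohort",
    "write_cohort",
    "write_report",
]

STRAIN_COLUMNS = ["strain_id", "population_label", "clinical_origin", "derivative_of", "curing_state"]
PANEL_COLUMNS = ["strain_id", "virus", "pair_results", "cdna_mask"]
ASSAY_COLUMNS = ["killer_id", "lawn_id", "ph", "temp_c", "medium", "zone_bin", "stain_bin"]
STATUS_COLUMNS = ["strain_id", "virus", "present", "pcr_genotype", "gel_band_kb", "lbc_level", "cdna_signal"]
QUANT_COLUMNS = ["strain_id", "target_cq", "ref_cq", "calibrator_target_cq", "calibrator_ref_cq"]


@dataclass
class Cohort:
    """Validated bundle of all per-strain tables the pipeline consumes."""

    strains: dict[str, StrainRecord] = field(default_factory=dict)
    panels: list[PcrPanel] = field(default_factory=list)
    assays: list[KillerAssay] = field(default_factory=list)
    statuses: list[VirusStatus] = field(default_factory=list)
    genotypes: GenotypeMatrix | None = None
    orfs: list[OrfRecord] = field(default_factory=list)

    def validate_references(self) -> None:
        """Every table row must name a known strain; parents must exist."""
        known = set(self.strains)
        if not known:
            return

        def check(sid: str, where: str) -> None:
            if sid not in known:
                raise ReferentialIntegrityError(f"{where}: unknown strain_id {sid!r}")

        for rec in self.strains.values():
            if rec.derivative_of is not None:
                check(rec.derivative_of, f"strain {rec.strain_id} derivative_of")
                parent = self.strains[rec.derivative_of]
                if parent.curing_state.value != "parent":
                    raise ReferentialIntegrityError(
                        f"{rec.strain_id}: parent {parent.strain_id} is itself a derivative"
                    )
        for p in self.panels:
            check(p.strain_id, "panel")
        for a in self.assays:
            check(a.killer_id, "assay killer")
            check(a.lawn_id, "assay lawn")
        for s in self.statuses:
            check(s.strain_id, "virus status")
        for o in self.orfs:
            check(o.strain_id, "orf record")
        if self.genotypes is not None:
            for sid in self.genotypes.strain_ids:
                check(sid, "genotype matrix")


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def read_strains(path: str | Path) -> dict[str, StrainRecord]:
    df = _read_tsv(path, STRAIN_COLUMNS)
    out: dict[str, StrainRecord] = {}
    for row in df.itertuples(index=False):
        if row.strain_id in out:
            raise ValidationError(f"duplicate strain_id {row.strain_id!r}")
        out[row.strain_id] = StrainRecord(
            strain_id=row.strain_id,
            population_label=row.population_label,
            clinical_origin=row.clinical_origin == "1",
            derivative_of=row.derivative_of or None,
            curing_state=row.curing_state,
        )
    return out


def write_strains(strains: dict[str, StrainRecord] | list[StrainRecord], path: str | Path) -> None:
    recs = list(strains.values()) if isinstance(strains, dict) else list(strains)
    df = pd.DataFrame(
        [
            {
                "strain_id": r.strain_id,
                "population_label": r.population_label,
                "clinical_origin": int(r.clinical_origin),
                "derivative_of": r.derivative_of or "",
                "curing_state": r.curing_state.value,
            }
            for r in recs
        ],
        columns=STRAIN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_panels(path: str | Path) -> list[PcrPanel]:
    df = _read_tsv(path, PANEL_COLUMNS)
    panels = []
    for row in df.itertuples(index=False):
        results = tuple(int(v) for v in row.pair_results.split(",")) if row.pair_results else ()
        mask = frozenset(int(i) for i in row.cdna_mask.split(";") if i != "")
        panels.append(PcrPanel(row.strain_id, row.virus, results, mask))
    return panels


def write_panels(panels: list[PcrPanel], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "strain_id": p.strain_id,
                "virus": p.virus,
                "pair_results": ",".join(str(v) for v in p.pair_results),
                "cdna_mask": ";".join(str(i) for i in sorted(p.cdna_mask)),
            }
            for p in panels
        ],
        columns=PANEL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_assays(path: str | Path) -> list[KillerAssay]:
    df = _read_tsv(path, ASSAY_COLUMNS)
    return [
        KillerAssay(
            killer_id=row.killer_id,
            lawn_id=row.lawn_id,
            ph=float(row.ph),
            temp_c=float(row.temp_c),
            medium=row.medium,
            zone_bin=float(row.zone_bin),
            stain_bin=float(row.stain_bin),
        )
        for row in df.itertuples(index=False)
    ]


def write_assays(assays: list[KillerAssay], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "killer_id": a.killer_id,
                "lawn_id": a.lawn_id,
                "ph": a.ph,
                "temp_c": a.temp_c,
                "medium": a.medium,
                "zone_bin": a.zone_bin,
                "stain_bin": a.stain_bin,
            }
            for a in assays
        ],
        columns=ASSAY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_virus_statuses(path: str | Path) -> list[VirusStatus]:
    df = _read_tsv(path, STATUS_COLUMNS)
    return [
        VirusStatus(
            strain_id=row.strain_id,
            virus=row.virus,
            present=row.present == "1",
            pcr_genotype=row.pcr_genotype,
            gel_band_kb=float(row.gel_band_kb) if row.gel_band_kb else None,
            lbc_level=row.lbc_level or None,
            cdna_signal=row.cdna_signal == "1",
        )
        for row in df.itertuples(index=False)
    ]


def write_virus_statuses(statuses: list[VirusStatus], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "strain_id": s.strain_id,
                "virus": s.virus,
                "present": int(s.present),
                "pcr_genotype": s.pcr_genotype,
                "gel_band_kb": "" if s.gel_band_kb is None else f"{s.gel_band_kb:g}",
                "lbc_level": s.lbc_level.value if s.lbc_level is not None else "",
                "cdna_signal": int(s.cdna_signal),
            }
            for s in statuses
        ],
        columns=STATUS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_quant_records(path: str | Path) -> list[QuantRecord]:
    df = _read_tsv(path, QUANT_COLUMNS)
    return [
        QuantRecord(
            strain_id=row.strain_id,
            target_cq=float(row.target_cq),
            ref_cq=float(row.ref_cq),
            calibrator_target_cq=float(row.calibrator_target_cq),
            calibrator_ref_cq=float(row.calibrator_ref_cq),
        )
        for row in df.itertuples(index=False)
    ]


def write_quant_records(records: list[QuantRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "strain_id": q.strain_id,
                "target_cq": q.target_cq,
                "ref_cq": q.ref_cq,
                "calibrator_target_cq": q.calibrator_target_cq,
                "calibrator_ref_cq": q.calibrator_ref_cq,
            }
            for q in records
        ],
        columns=QUANT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """Dosage TSV: first column ``strain_id``, remaining columns are sites."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dosages = df.to_numpy()
    if not np.issubdtype(dosages.dtype, np.integer):
        dosages = np.where(np.isnan(dosages.astype(float)), MISSING_DOSAGE, dosages).astype(int)
    return GenotypeMatrix(
        strain_ids=[str(s) for s in df.index],
        site_ids=[str(c) for c in df.columns],
        dosages=dosages,
    )


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(gm.dosages, index=gm.strain_ids, columns=gm.site_ids)
    df.index.name = "strain_id"
    df.to_csv(path, sep="\t")


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Diploid GT field -> dosage of the first ALT allele; ./. -> missing."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    strain_ids = list(vcf.samples)
    site_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        site_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING_DOSAGE)
        rows.append(dosage)
    vcf.close()
    dosages = (
        np.column_stack(rows) if rows else np.zeros((len(strain_ids), 0), dtype=int)
    )
    return GenotypeMatrix(strain_ids=strain_ids, site_ids=site_ids, dosages=dosages)


def read_orfs_fasta(path: str | Path) -> list[OrfRecord]:
    """FASTA ids are ``GENE|strain``; strains without a record lack the gene."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, _, strain = rec.id.partition("|")
        if not strain:
            raise ValidationError(f"FASTA id {rec.id!r} is not GENE|strain")
        out.append(OrfRecord(gene=gene, strain_id=strain, sequence=str(rec.seq).upper()))
    return out


def write_orfs_fasta(orfs: list[OrfRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(o.sequence), id=f"{o.gene}|{o.strain_id}", description="")
        for o in orfs
        if o.sequence is not None
    ]
    SeqIO.write(records, str(path), "fasta")


def read_cohort(paths: dict[str, str | Path]) -> Cohort:
    """Assemble and validate a cohort bundle from a mapping of file paths.

    Recognized keys: ``strains``, ``panels``, ``assays``, ``statuses``,
    ``genotypes_tsv``, ``genotypes_vcf``, ``orfs``, all optional. Raises
    :class:`ReferentialIntegrityError` when any table names an unknown
    strain, and :class:`ValidationError` for out-of-vocabulary values.
    """
    cohort = Cohort()
    if "strains" in paths:
        cohort.strains = read_strains(paths["strains"])
    if "panels" in paths:
        cohort.panels = read_panels(paths["panels"])
    if "assays" in paths:
        cohort.assays = read_assays(paths["assays"])
    if "statuses" in paths:
        cohort.statuses = read_virus_statuses(paths["statuses"])
    if "genotypes_tsv" in paths and "genotypes_vcf" in paths:
        raise ValidationError("give genotypes as TSV or VCF, not both")
    if "genotypes_tsv" in paths:
        cohort.genotypes = read_genotypes_tsv(paths["genotypes_tsv"])
    if "genotypes_vcf" in paths:
        cohort.genotypes = read_genotypes_vcf(paths["genotypes_vcf"])
    if "orfs" in paths:
        cohort.orfs = read_orfs_fasta(paths["orfs"])
    cohort.validate_references()
    return cohort


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write every populated part of the bundle; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if cohort.strains:
        paths["strains"] = outdir / "strains.tsv"
        write_strains(cohort.strains, paths["strains"])
    paths["panels"] = outdir / "panels.tsv"
    write_panels(cohort.panels, paths["panels"])
    paths["assays"] = outdir / "assays.tsv"
    write_assays(cohort.assays, paths["assays"])
    if cohort.statuses:
        paths["statuses"] = outdir / "virome.tsv"
        write_virus_statuses(cohort.statuses, paths["statuses"])
    if cohort.genotypes is not None:
        paths["genotypes_tsv"] = outdir / "genotypes.tsv"
        write_genotypes_tsv(cohort.genotypes, paths["genotypes_tsv"])
    if cohort.orfs:
        paths["orfs"] = outdir / "orfs.fasta"
        write_orfs_fasta(cohort.orfs, paths["orfs"])
    return paths


def write_report(tables: dict[str, pd.DataFrame], outdir: str | Path) -> dict[str, Path]:
    """Write result DataFrames as TSV, one file per table name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths
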