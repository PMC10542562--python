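"""Domain-type validation, TSV/FASTA/VCF round trips, cohort integrity."""

import numpy as np
import pandas as pd
import pytest

from killerome import io
from killerome.datasets import (
    load_khs1_cohort_synthetic,
    load_lbc_genotype_table,
    load_m_satellite_table,
    load_pcr_summary,
)
from killerome.types import (
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


class TestTypeValidation:
    def test_assay_rejects_out_of_vocabulary_bin(self):
        with pytest.raises(ValidationError):
            KillerAssay("a", "b", zone_bin=3.0)
        with pytest.raises(ValidationError):
            KillerAssay("a", "b", stain_bin=1.5)

    def test_panel_rejects_wrong_pair_count(self):
        with pytest.raises(ValidationError):
            PcrPanel("s", "L-A", (1, 0))  # L-A has 7 diagnostic pairs

    def test_panel_rejects_mask_outside_pairs(self):
        with pytest.raises(ValidationError):
            PcrPanel("s", "M28", (1, 0), cdna_mask={5})

    def test_parent_cannot_be_its_own_derivative_kind(self):
        with pytest.raises(ValidationError):
            StrainRecord("d", derivative_of="p", curing_state="parent")

    def test_genotype_matrix_rejects_bad_dosage(self):
        with pytest.raises(ValidationError):
            GenotypeMatrix(["a", "b"], ["s"], np.array([[0], [5]]))

    def test_quant_record_requires_positive_cycles(self):
        with pytest.raises(ValidationError):
            QuantRecord("s", -1.0, 15.0, 18.0, 15.0)


def _random_cohort(rng, n=12):
    strains = {}
    for i in range(n):
        sid = f"S{i:03d}"
        strains[sid] = StrainRecord(
            sid,
            population_label=rng.choice(["wine", "mosaic", "sake"]),
            clinical_origin=bool(rng.integers(2)),
        )
    panels = [
        PcrPanel(
            sid,
            virus,
            tuple(rng.integers(0, 2, size=npairs)),
            frozenset({0}) if virus == "M28" and rng.random() < 0.2 else frozenset(),
        )
        for sid in strains
        for virus, npairs in (("L-A", 7), ("L-BC", 3), ("M28", 2))
    ]
    assays = [
        KillerAssay(
            a,
            b,
            ph=float(rng.choice([4.7, 6.0])),
            temp_c=float(rng.choice([20.0, 30.0])),
            medium=str(rng.choice(["MB", "SD_MB"])),
            zone_bin=float(rng.choice([0, 0.5, 1, 2])),
            stain_bin=float(rng.choice([0, 0.5, 1, 2])),
        )
        for a in list(strains)[:4]
        for b in list(strains)[4:8]
    ]
    statuses = [
        VirusStatus(
            sid,
            "L-BC",
            True,
            pcr_genotype="0,1,0",
            gel_band_kb=4.6 if rng.random() < 0.3 else None,
            lbc_level=str(rng.choice(["hi", "lo"])),
        )
        for sid in strains
    ]
    quants = [QuantRecord(sid, 20.0 + i, 15.0, 18.0, 15.0) for i, sid in enumerate(strains)]
    gm = GenotypeMatrix(
        strain_ids=list(strains),
        site_ids=[f"site{j}" for j in range(7)],
        dosages=rng.choice([0, 1, 2, -1], size=(n, 7), p=[0.4, 0.3, 0.25, 0.05]),
    )
    orfs = [
        OrfRecord("KHS1", sid, sequence="ATG" + "AAA" * 5 + "TAA")
        for sid in list(strains)[: n // 2]
    ]
    return strains, panels, assays, statuses, quants, gm, orfs


class TestRoundTrips:
    """read(write(x)) == x for every table type on randomized fixtures."""

    def test_all_table_types_round_trip(self, rng, tmp_path):
        strains, panels, assays, statuses, quants, gm, orfs = _random_cohort(rng)

        io.write_strains(strains, tmp_path / "s.tsv")
        assert io.read_strains(tmp_path / "s.tsv") == strains

        io.write_panels(panels, tmp_path / "p.tsv")
        assert io.read_panels(tmp_path / "p.tsv") == panels

        io.write_assays(assays, tmp_path / "a.tsv")
        assert io.read_assays(tmp_path / "a.tsv") == assays

        io.write_virus_statuses(statuses, tmp_path / "v.tsv")
        assert io.read_virus_statuses(tmp_path / "v.tsv") == statuses

        io.write_quant_records(quants, tmp_path / "q.tsv")
        assert io.read_quant_records(tmp_path / "q.tsv") == quants

        io.write_genotypes_tsv(gm, tmp_path / "g.tsv")
        gm2 = io.read_genotypes_tsv(tmp_path / "g.tsv")
        assert gm2.strain_ids == gm.strain_ids
        assert gm2.site_ids == gm.site_ids
        assert (gm2.dosages == gm.dosages).all()

        io.write_orfs_fasta(orfs, tmp_path / "o.fasta")
        assert io.read_orfs_fasta(tmp_path / "o.fasta") == orfs

    def test_cohort_write_then_read(self, small_cohort, tmp_path):
        paths = io.write_cohort(small_cohort, tmp_path)
        back = io.read_cohort({k: v for k, v in paths.items()})
        assert back.strains == small_cohort.strains
        assert back.panels == small_cohort.panels
        assert back.assays == small_cohort.assays
        assert (back.genotypes.dosages == small_cohort.genotypes.dosages).all()


class TestCohortValidation:
    def test_unknown_strain_in_assays_is_integrity_error(self, small_cohort):
        small_cohort.assays.append(KillerAssay("GHOST", "P2", zone_bin=1.0))
        with pytest.raises(ReferentialIntegrityError):
            small_cohort.validate_references()

    def test_empty_assay_table_is_fine(self, tmp_path, small_cohort):
        io.write_assays([], tmp_path / "a.tsv")
        assert io.read_assays(tmp_path / "a.tsv") == []

    def test_bad_bin_in_assay_file_is_validation_error(self, tmp_path):
        (tmp_path / "a.tsv").write_text(
            "killer_id\tlawn_id\tph\ttemp_c\tmedium\tzone_bin\tstain_bin\n"
            "x\ty\t4.7\t20\tMB\t3\t0\n"
        )
        with pytest.raises(ValidationError):
            io.read_assays(tmp_path / "a.tsv")


class TestVcf:
    def test_vcf_gt_to_dosage(self, tmp_path):
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t100\tv1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\t.\tC\tT\t.\t.\t.\tGT\t./.\t1/1\t0/0\n"
        )
        gm = io.read_genotypes_vcf(vcf)
        assert gm.strain_ids == ["A", "B", "C"]
        assert gm.site_ids == ["v1", "1:200"]
        assert gm.dosages.tolist() == [[0, -1], [1, 2], [2, 0]]


class TestReport:
    def test_write_report_is_deterministic(self, tmp_path):
        df = pd.DataFrame({"site_id": ["a", "b"], "p_value": [0.1, 0.2]})
        p1 = io.write_report({"assoc": df}, tmp_path / "r1")["assoc"]
        p2 = io.write_report({"assoc": df}, tmp_path / "r2")["assoc"]
        assert p1.read_text() == p2.read_text()

    def test_empty_results_give_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["site_id", "p_value"])
        p = io.write_report({"assoc": df}, tmp_path)["assoc"]
        assert p.read_text().strip() == "site_id\tp_value"


class TestPackagedFixtures:
    def test_m_satellite_table_has_17_strains(self):
        t3 = load_m_satellite_table()
        assert len(t3) == 17
        assert t3["strain_id"].is_unique

    def test_pcr_summary_shape(self):
        t1 = load_pcr_summary()
        assert list(t1["virus"]) == ["L-A", "L-BC", "20S", "23S", "M1", "M2", "M28", "Mlus"]
        assert t1.loc[t1["virus"] == "L-BC", "n_strains"].item() == 100

    def test_lbc_table_totals(self):
        t2 = load_lbc_genotype_table()
        assert t2["n_hi"].sum() == 33
        assert t2["n_lo"].sum() == 67

    def test_khs1_synthetic_cohort_is_complete(self):
        k = load_khs1_cohort_synthetic()
        assert len(k) == 100
        assert k["strain_id"].is_unique
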