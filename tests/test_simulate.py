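"""Generator properties: determinism, differentiation, planted structure."""

import numpy as np
import pytest
from scipy import stats

from killerome.orfs import annotate_orf
from killerome.simulate import (
    KillerTruth,
    SimConfig,
    simulate_killer_assays,
    simulate_ordinal_phenotype,
    simulate_orf_set,
    simulate_population,
    simulate_virome,
)
from killerome.types import GenotypeClass, ValidationError


def hudson_fst(d1, d2):
    """Two-population Hudson estimator (ratio of averages) as oracle."""
    n1, n2 = d1.shape[0] * 2, d2.shape[0] * 2
    p1, p2 = d1.sum(0) / n1, d2.sum(0) / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return num[keep].sum() / den[keep].sum()


class TestPopulation:
    def test_fst_parameter_recovered_by_hudson_estimator(self):
        cfg = SimConfig(n_strains=200, n_sites=2000, n_subpops=2, fst=0.2, seed=42)
        gm, labels, _ = simulate_population(cfg)
        f = hudson_fst(gm.dosages[labels == 0], gm.dosages[labels == 1])
        assert f == pytest.approx(0.2, abs=0.05)

    def test_no_differentiation_at_fst_zero(self):
        cfg = SimConfig(n_strains=200, n_sites=2000, n_subpops=2, fst=0.0, seed=42)
        gm, labels, _ = simulate_population(cfg)
        f = hudson_fst(gm.dosages[labels == 0], gm.dosages[labels == 1])
        assert abs(f) < 0.02

    def test_fst_one_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(fst=1.0)

    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_strains=50, n_sites=100, seed=9)
        gm1, l1, g1 = simulate_population(cfg)
        gm2, l2, g2 = simulate_population(cfg)
        assert (gm1.dosages == gm2.dosages).all()
        assert (l1 == l2).all()
        assert (g1.values == g2.values).all()


class TestOrdinalPhenotype:
    def test_fixed_seed_identical_scores(self):
        cfg = SimConfig(n_strains=60, n_sites=50, causal_site_index=10, causal_effect=1.0, seed=3)
        gm, _, grm = simulate_population(cfg)
        y1 = simulate_ordinal_phenotype(gm, grm, cfg)
        y2 = simulate_ordinal_phenotype(gm, grm, cfg)
        assert (y1 == y2).all()

    def test_huge_effect_orders_bins_by_causal_dosage(self):
        cfg = SimConfig(
            n_strains=100, n_sites=50, n_subpops=1, fst=0.0,
            causal_site_index=25, causal_effect=50.0,
            heritability_background=0.0, seed=5,
        )
        gm, _, grm = simulate_population(cfg)
        y = simulate_ordinal_phenotype(gm, grm, cfg)
        x = gm.dosages[:, 25]
        for lo, hi in [(0, 1), (1, 2)]:
            if (x == lo).any() and (x == hi).any():
                assert y[x == lo].max() <= y[x == hi].min()

    def test_null_scores_independent_of_genotype(self):
        """Under zero effect and zero heritability the planted site shows no
        association (chi-square independence test) in >= 94 of 100 seeds."""
        nonsig = 0
        binmap = {0.0: 0, 0.5: 1, 1.0: 2, 2.0: 3}
        for seed in range(100):
            cfg = SimConfig(
                n_strains=100, n_sites=50, n_subpops=1, fst=0.0,
                causal_site_index=25, causal_effect=0.0,
                heritability_background=0.0, seed=seed,
            )
            gm, _, grm = simulate_population(cfg)
            y = simulate_ordinal_phenotype(gm, grm, cfg)
            x = gm.dosages[:, 25]
            tab = np.zeros((3, 4), int)
            for xi, yi in zip(x, y):
                tab[xi, binmap[yi]] += 1
            t = tab[tab.sum(1) > 0][:, tab.sum(0) > 0]
            if min(t.shape) < 2:
                nonsig += 1
                continue
            _, p, _, _ = stats.chi2_contingency(t)
            nonsig += p > 0.05
        assert nonsig >= 94


class TestVirome:
    def test_cohorts_respect_dependency_rules(self):
        from killerome.virome import validate_dependencies

        for seed in range(3):
            _, statuses = simulate_virome(SimConfig(n_strains=100, seed=seed))
            assert validate_dependencies(statuses) == []

    def test_zero_m_prevalence_gives_no_m_strains(self):
        cfg = SimConfig(n_strains=100, seed=1)
        for m in ("M1", "M2", "M28", "Mlus"):
            cfg.virus_prevalences[m] = 0.0
        _, statuses = simulate_virome(cfg)
        assert not any(s.present for s in statuses if s.virus in ("M1", "M2", "M28", "Mlus"))

    def test_lbc_prevalence_one_makes_all_positive(self):
        _, statuses = simulate_virome(SimConfig(n_strains=100, seed=2))
        lbc = [s for s in statuses if s.virus == "L-BC"]
        assert len(lbc) == 100 and all(s.present for s in lbc)

    def test_masked_m28_cdna_strains_flagged_not_present(self):
        cfg = SimConfig(n_strains=50, n_m28_cdna_strains=2, seed=7)
        _, statuses = simulate_virome(cfg)
        m28 = [s for s in statuses if s.virus == "M28" and s.cdna_signal]
        assert len(m28) == 2 and not any(s.present for s in m28)


class TestOrfSet:
    def test_full_fraction_plant_round_trips_through_detector(self):
        recs = simulate_orf_set(20, [(66, "opal", 1.0)], seed=1)
        for r in recs:
            assert r.sequence[3 * 65 : 3 * 66] == "TGA"
            assert annotate_orf(r).genotype_class == GenotypeClass.opal

    def test_empty_spec_is_all_full_length(self):
        recs = simulate_orf_set(20, [], seed=1)
        assert all(annotate_orf(r).genotype_class == GenotypeClass.full_length for r in recs)

    def test_secondary_stop_fraction_within_binomial_bounds(self):
        recs = simulate_orf_set(1000, [(66, "opal", 1.0), (88, "ochre", 0.05)], seed=3)
        n_ochre = sum(
            any(t.value == "ochre" for _, t in annotate_orf(r).stops) for r in recs
        )
        lo, hi = stats.binom.interval(0.99, 1000, 0.05)
        assert lo <= n_ochre <= hi

    def test_stop_index_outside_orf_rejected(self):
        with pytest.raises(ValidationError):
            simulate_orf_set(5, [(100, "opal", 1.0)], seed=1)


class TestKillerAssays:
    def test_noiseless_rules(self):
        truths = [
            KillerTruth("tox", toxin="K1"),
            KillerTruth("sens"),
            KillerTruth("res", resistances=frozenset({"K1"})),
            KillerTruth("cured", toxin="K1", m_dependent=True, cured=True),
        ]
        assays = {(a.killer_id, a.lawn_id): a for a in simulate_killer_assays(truths, 0.0, seed=1)}
        assert assays[("tox", "sens")].zone_bin == 2.0
        assert assays[("tox", "res")].zone_bin == 0.0
        assert assays[("cured", "sens")].zone_bin == 0.0  # enables dependence calling

    def test_noise_swaps_only_adjacent_bins(self):
        truths = [KillerTruth("tox", toxin="K1"), KillerTruth("sens")]
        zones = {
            a.zone_bin
            for seed in range(50)
            for a in simulate_killer_assays(truths, 0.45, seed=seed)
            if a.killer_id == "tox"
        }
        assert zones <= {1.0, 2.0}  # from bin 2, one step reaches only bin 1

    def test_noise_bound_enforced(self):
        with pytest.raises(ValidationError):
            simulate_killer_assays([KillerTruth("a")], noise=0.6)
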