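import numpy as np
import pandas as pd
import pytest

from com6ar import (ConfigurationError, SimulationConfig, pcor_screen,
                    simulate_expression, simulate_genome_annotations)
from com6ar.synthetic import assign_genes_to_chroms, default_offsets


def tiny_cfg(**kw):
    base = dict(n_samples=30, n_case=15, n_regulators=2, n_controls=4,
                n_direct=2, n_confounded=2, n_null=2, n_regulators_de=1,
                n_controls_de=2, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateExpression:
    def test_shape_and_categories(self):
        cfg = tiny_cfg()
        em, truth = simulate_expression(cfg)
        assert em.data.shape == (cfg.n_genes, cfg.n_samples)
        counts = truth.table["category"].value_counts().to_dict()
        assert counts == {"control": 4, "regulator": 2, "direct": 2,
                          "confounded": 2, "null": 2}
        assert list(em.data.index) == list(truth.table.index)

    def test_pure_noise_degenerate_size(self):
        cfg = SimulationConfig(n_samples=4, n_case=2, n_regulators=0,
                               n_controls=0, n_direct=0, n_confounded=0,
                               n_null=1, n_regulators_de=0, n_controls_de=0,
                               seed=5)
        em, truth = simulate_expression(cfg)
        assert em.data.shape == (1, 4)
        assert truth.category_of("NULL001") == "null"

    def test_determinism_bit_identical(self):
        cfg = tiny_cfg(seed=7)
        em1, t1 = simulate_expression(cfg)
        em2, t2 = simulate_expression(cfg)
        assert np.array_equal(em1.values(), em2.values())
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_seed_changes_data(self):
        em1, _ = simulate_expression(tiny_cfg(seed=1))
        em2, _ = simulate_expression(tiny_cfg(seed=2))
        assert not np.array_equal(em1.values(), em2.values())

    def test_vanishing_noise_gives_near_perfect_direct_correlation(self):
        cfg = SimulationConfig(n_samples=20, n_case=0, n_regulators=1,
                               n_controls=2, n_direct=1, n_confounded=0,
                               n_null=0, n_regulators_de=0, n_controls_de=0,
                               beta_direct=1.0, sigma_noise=1e-8, seed=3)
        em, truth = simulate_expression(cfg)
        r = np.corrcoef(em.data.loc["REG001"], em.data.loc["DIR001"])[0, 1]
        assert abs(r) > 0.99

    def test_all_values_finite(self):
        em, _ = simulate_expression(tiny_cfg())
        assert np.isfinite(em.values()).all()

    def test_de_shift_applied_to_case_samples_only(self):
        cfg = tiny_cfg(de_shift=100.0)
        em, truth = simulate_expression(cfg)
        case, ctrl = em.split_groups()
        de_gene = truth.table.index[truth.table["is_de"]][0]
        diff = case.loc[de_gene].mean() - ctrl.loc[de_gene].mean()
        assert diff == pytest.approx(100.0, abs=5.0)

    @pytest.mark.parametrize("bad", [
        dict(n_case=50, n_samples=30),
        dict(n_samples=-1),
        dict(sigma_noise=0.0),
        dict(n_regulators_de=5, n_regulators=2),
        dict(n_direct=1, n_regulators=0),
        dict(control_loading=1.0),
    ])
    def test_invalid_config_raises(self, bad):
        with pytest.raises(ConfigurationError):
            tiny_cfg(**bad).validate()


class TestConfoundingRealism:
    def test_partial_separates_direct_from_confounded_over_seeds(self):
        """At study-scale defaults the confounded targets' partial
        correlations concentrate near 0 while direct targets' stay high."""
        direct_abs, conf_abs, conf_plain = [], [], []
        for seed in range(50):
            cfg = SimulationConfig(n_regulators=5, n_controls=46,
                                   n_direct=5, n_confounded=5, n_null=0,
                                   n_regulators_de=5, n_controls_de=40,
                                   seed=seed)
            em, truth = simulate_expression(cfg)
            regs = truth.genes("regulator")
            ctls = truth.genes("control")
            res = pcor_screen(em, regs, ctls)
            by_pair = {(r.gene, r.regulator): r.rho for r in res}
            for g in truth.genes("direct"):
                direct_abs.append(abs(by_pair[(g, truth.source_of(g))]))
            for g in truth.genes("confounded"):
                for m in regs:
                    conf_abs.append(abs(by_pair[(g, m)]))
                    conf_plain.append(abs(np.corrcoef(
                        em.data.loc[g], em.data.loc[m])[0, 1]))
        assert np.mean(conf_abs) < np.mean(direct_abs)
        # removing the control set is what kills the confounded association
        assert np.mean(conf_plain) > np.mean(conf_abs)
        # and marginally the designed confounding is positive on average
        assert np.mean(conf_plain) > 0.1


class TestGenomeAnnotations:
    def test_zero_offset_snp_inside_its_window(self):
        cfg = tiny_cfg()
        ann = simulate_genome_annotations(cfg, {"chrS1": ["DIR001"]},
                                          offsets=(0,))
        assert len(ann.sites) == 1 and ann.sites[0].pos == 10_000
        assert ann.truth["in_window"].all()
        assert ann.eqtls[0].pos == 10_000

    def test_offset_beyond_window_is_out(self):
        ann = simulate_genome_annotations(tiny_cfg(), {"chrS1": ["DIR001"]},
                                          offsets=(200,))
        assert not ann.truth["in_window"].any()

    def test_boundary_offsets_by_construction(self):
        ann = simulate_genome_annotations(tiny_cfg(), {"chrS1": ["NULL001"]},
                                          offsets=(-50, 49, -51, 50),
                                          width=100)
        expected = {-50: True, 49: True, -51: False, 50: False}
        got = dict(zip(ann.truth["offset"], ann.truth["in_window"]))
        assert got == expected

    def test_unknown_gene_symbol_raises(self):
        with pytest.raises(ConfigurationError, match="NOSUCH"):
            simulate_genome_annotations(tiny_cfg(), {"chrS1": ["NOSUCH"]})

    def test_determinism(self):
        cfg = tiny_cfg(seed=9)
        chroms = {"chrS1": ["DIR001", "CONF001"]}
        a = simulate_genome_annotations(cfg, chroms)
        b = simulate_genome_annotations(cfg, chroms)
        assert a.sites == b.sites and a.eqtls == b.eqtls
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_every_offset_schedule_position_covered(self):
        offs = default_offsets(100)
        assert set(offs) == {0, -50, 49, -51, 50, 200, -200}

    def test_assign_genes_round_robin(self):
        out = assign_genes_to_chroms(["A", "B", "C", "D"], n_chroms=3)
        assert out == {"chrS1": ["A", "D"], "chrS2": ["B"], "chrS3": ["C"]}
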