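"""Generator contracts: determinism, population moments, evidence calibration."""

import numpy as np
import pandas as pd
import pytest

from coregnet.module_detection import Module
from coregnet.regulator_inference import RegulatorAssignment
from coregnet.synthetic_data import SimConfig, generate_dataset, jaccard, score_recovery


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        a = generate_dataset(SimConfig(seed=11, n_genes=80, n_mirnas=8, modules=((10, 0.9),)))
        b = generate_dataset(SimConfig(seed=11, n_genes=80, n_mirnas=8, modules=((10, 0.9),)))
        pd.testing.assert_frame_equal(a.gene_expr.data, b.gene_expr.data)
        pd.testing.assert_frame_equal(a.mirna_expr.data, b.mirna_expr.data)
        pd.testing.assert_frame_equal(a.evidence_table, b.evidence_table)
        assert a.truth == b.truth

    def test_different_seeds_differ(self):
        a = generate_dataset(SimConfig(seed=1, n_genes=50, n_mirnas=5, modules=((8, 0.9),)))
        b = generate_dataset(SimConfig(seed=2, n_genes=50, n_mirnas=5, modules=((8, 0.9),)))
        assert not a.gene_expr.data.equals(b.gene_expr.data)


class TestLatentFactorModel:
    def test_unit_loading_gives_perfect_correlation(self):
        sim = generate_dataset(
            SimConfig(seed=3, n_genes=30, n_mirnas=3, modules=((6, 1.0),))
        )
        case = [s for s in sim.gene_expr.sample_ids if sim.labels[s] == "case"]
        block = sim.gene_expr.data.loc[list(sim.truth.module_genes["M1"]), case]
        r = np.corrcoef(block.to_numpy())
        iu = np.triu_indices(len(block), 1)
        assert np.allclose(r[iu], 1.0, atol=1e-9)

    def test_within_module_correlation_approaches_lambda_squared(self):
        """With many samples the mean member correlation converges to lambda^2."""
        lam = 0.9
        sim = generate_dataset(
            SimConfig(seed=4, n_case=100, n_control=2, n_genes=120, n_mirnas=3,
                      modules=((50, lam), (50, lam)))
        )
        case = [s for s in sim.gene_expr.sample_ids if sim.labels[s] == "case"]
        m1 = list(sim.truth.module_genes["M1"])
        block = sim.gene_expr.data.loc[m1, case].to_numpy()
        r = np.corrcoef(block)
        iu = np.triu_indices(len(m1), 1)
        assert np.mean(r[iu]) == pytest.approx(lam * lam, abs=0.02)

    def test_cross_module_correlation_near_zero(self):
        """Cross-module correlations average to ~0 (dominated by the realized
        correlation of the two latent factors, ~N(0, 1/n) at n samples)."""
        means = []
        for seed in (5, 15, 25, 35):
            sim = generate_dataset(
                SimConfig(seed=seed, n_case=200, n_control=2, n_genes=120, n_mirnas=3,
                          modules=((50, 0.9), (50, 0.9)))
            )
            case = [s for s in sim.gene_expr.sample_ids if sim.labels[s] == "case"]
            a = sim.gene_expr.data.loc[list(sim.truth.module_genes["M1"]), case].to_numpy()
            b = sim.gene_expr.data.loc[list(sim.truth.module_genes["M2"]), case].to_numpy()
            means.append(np.corrcoef(a, b)[: len(a), len(a):].mean())
        assert abs(np.mean(means)) < 0.08

    def test_repressor_population_anticorrelation(self):
        """miRNA-target correlation converges to lambda * rho (negative)."""
        lam, rho = 0.98, -0.82
        sim = generate_dataset(
            SimConfig(seed=6, n_case=300, n_control=2, n_genes=40, n_mirnas=3,
                      modules=((25, lam),), repressor_loading=rho)
        )
        case = [s for s in sim.gene_expr.sample_ids if sim.labels[s] == "case"]
        mir = sim.truth.module_repressor["M1"]
        x = sim.mirna_expr.data.loc[mir, case].to_numpy()
        rs = [
            np.corrcoef(x, sim.gene_expr.data.loc[g, case].to_numpy())[0, 1]
            for g in sim.truth.module_genes["M1"]
        ]
        assert np.mean(rs) == pytest.approx(lam * rho, abs=0.03)


class TestEvidenceCalibration:
    def test_per_source_sensitivity_and_fpr_within_binomial_bands(self):
        cfg = SimConfig(seed=7, n_genes=400, n_mirnas=60, modules=((10, 0.9),),
                        background_target_rate=0.5, source_sensitivity=0.8,
                        source_fpr=0.05, experimental_rate=0.0)
        sim = generate_dataset(cfg)
        true_pairs = set(sim.truth.true_targets)
        n_pairs = cfg.n_mirnas * cfg.n_genes
        n_true = len(true_pairs)
        n_false = n_pairs - n_true
        by_source = {
            src: {(m, g) for m, g, s, _ in sim.evidence_table.itertuples(index=False) if s == src}
            for src in cfg.source_names
        }
        for src, detected in by_source.items():
            tp = len(detected & true_pairs)
            fp = len(detected - true_pairs)
            for rate, hits, total in ((0.8, tp, n_true), (0.05, fp, n_false)):
                # 99% joint band over the 8 simultaneous checks (Bonferroni)
                band = 3.23 * np.sqrt(rate * (1 - rate) / total)
                assert abs(hits / total - rate) < band, f"{src} off-calibration"

    def test_consensus_pairs_are_mostly_true(self):
        from coregnet.regulator_inference import build_consensus_targets

        sim = generate_dataset(SimConfig(seed=8, n_genes=400, n_mirnas=20,
                                         modules=((10, 0.9),)))
        consensus = build_consensus_targets(sim.evidence)
        pairs = {(m, g) for m, genes in consensus.items() for g in genes}
        true_pairs = set(sim.truth.true_targets)
        precision = len(pairs & true_pairs) / len(pairs)
        assert precision > 0.9


class TestConfigValidation:
    def test_oversized_modules_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(SimConfig(n_genes=10, modules=((8, 0.9), (8, 0.9))))

    def test_bad_loading_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(SimConfig(modules=((10, 1.5),)))

    def test_positive_repressor_loading_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(SimConfig(repressor_loading=0.5))


class TestScoreRecovery:
    def _truth(self):
        sim = generate_dataset(SimConfig(seed=9, n_genes=60, n_mirnas=6,
                                         modules=((10, 0.9), (10, 0.9))))
        return sim.truth

    def _as_modules(self, gene_sets):
        return [Module(i + 1, frozenset(s), 0.5, 0, 0.0, 0.0)
                for i, s in enumerate(gene_sets)]

    def test_perfect_recovery_scores_one(self):
        truth = self._truth()
        mods = self._as_modules(truth.module_genes.values())
        assignments = {
            i + 1: RegulatorAssignment(i + 1, ((truth.module_repressor[name], 1e-9),), ("tf",))
            for i, name in enumerate(truth.module_genes)
        }
        m = score_recovery(truth, modules=mods, assignments=assignments)
        assert m["jaccard_mean"] == 1.0
        assert m["regulator_precision"] == 1.0
        assert m["regulator_recall"] == 1.0

    def test_empty_inference_scores_zero(self):
        truth = self._truth()
        m = score_recovery(truth, modules=[], assignments={})
        assert m["jaccard_mean"] == 0.0
        assert m["regulator_recall"] == 0.0

    def test_half_module_gives_jaccard_half(self):
        truth = self._truth()
        halves = [list(v)[: len(v) // 2] for v in truth.module_genes.values()]
        m = score_recovery(truth, modules=self._as_modules(halves))
        for name in truth.module_genes:
            assert m[f"jaccard_{name}"] == pytest.approx(0.5)

    def test_de_sensitivity_and_specificity(self):
        truth = self._truth()
        universe = {f"G{i:05d}" for i in range(60)}
        called = set(truth.de_genes)  # perfect calls
        m = score_recovery(truth, de_genes=called, gene_universe=universe)
        assert m["de_gene_sensitivity"] == 1.0
        assert m["de_gene_specificity"] == 1.0

    def test_jaccard_helper(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0
        assert jaccard(set(), set()) == 1.0
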