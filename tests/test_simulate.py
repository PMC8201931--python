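"""Generative-model tests: mutation under selection, ortholog evolution,
LAIC count sampling, expression coupling, and bundle determinism."""

from dataclasses import replace

import numpy as np
import pytest

from pseudom6a.motifs import encode, strand_bias_test
from pseudom6a.simulate import (
    SimulationConfig,
    evolve_orthologs,
    generate_cohort,
    mutate_many_neutral,
    mutate_with_selection,
    simulate_expression,
    simulate_laic_counts,
    strand_gain_flags,
)


class TestMutateWithSelection:
    def test_zero_rate_is_identity(self):
        seq = "ACGT" * 2500
        rng = np.random.default_rng(0)
        assert mutate_with_selection(seq, 0.0, 5.0, rng) == seq

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            mutate_with_selection("ACGN", 0.1, 0.0, np.random.default_rng(0))
        with pytest.raises(ValueError, match="empty"):
            mutate_with_selection("", 0.1, 0.0, np.random.default_rng(0))

    def test_length_preserved_and_rate_scale(self):
        rng = np.random.default_rng(1)
        seq = "".join(np.random.default_rng(2).choice(list("ACGT"), 2000))
        mut = mutate_with_selection(seq, 0.05, 0.0, rng)
        assert len(mut) == len(seq)
        n_diff = sum(a != b for a, b in zip(seq, mut))
        # s=0 accepts every proposal: expected 100 substitutions, sd ~9.7
        assert 50 <= n_diff <= 150

    def test_neutral_process_is_strand_symmetric(self):
        """At s=0 sense and antisense DRACH gains have equal rates: the
        two-proportion chi-square on independent replicate sets does not
        reject, and the gain proportions agree closely."""
        rng = np.random.default_rng(42)
        n = 3000
        root = rng.integers(0, 4, size=(2 * n, 1000)).astype(np.uint8)
        mut = mutate_many_neutral(root, 0.05, rng)
        sense, anti = strand_gain_flags(root, mut)
        res = strand_bias_test(int(sense[:n].sum()), n, int(anti[n:].sum()), n)
        assert res.p > 0.01
        assert abs(sense.mean() - anti.mean()) < 0.03

    def test_selection_biases_sense_gains(self):
        """With s>0, sense-strand gains exceed antisense gains."""
        rng = np.random.default_rng(7)
        n, L = 400, 1000
        sense_n = anti_n = 0
        for _ in range(n):
            root = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=L)])
            mut = mutate_with_selection(root, 0.05, 5.0, rng)
            f_s, f_a = strand_gain_flags(encode(root)[None, :], encode(mut)[None, :])
            sense_n += int(f_s[0])
            anti_n += int(f_a[0])
        assert sense_n > anti_n
        res = strand_bias_test(sense_n, n, anti_n, n)
        assert res.p_yates < 0.05


class TestEvolveOrthologs:
    TREE = ["chimp", "gorilla", "orangutan", "rhesus"]

    def test_zero_rates_identity(self):
        seqs, subs = evolve_orthologs(
            "ACGTACGTAC" * 20, self.TREE, [0.0] * 4, np.random.default_rng(0)
        )
        assert all(s == "ACGTACGTAC" * 20 for s in seqs.values())
        assert all(len(v) == 0 for v in subs.values())

    def test_saturated_rate_identity_one_quarter(self):
        """Under the uniform multi-hit model a saturating branch rate drives
        per-site identity to the stationary 1/4."""
        rng = np.random.default_rng(3)
        root = "".join(rng.choice(list("ACGT"), 20000))
        seqs, _ = evolve_orthologs(root, ["far"], [50.0], rng)
        ident = np.mean([a == b for a, b in zip(root, seqs["far"])])
        assert abs(ident - 0.25) < 0.02

    def test_divergence_monotone_with_distance(self):
        rng = np.random.default_rng(4)
        root = "".join(rng.choice(list("ACGT"), 5000))
        seqs, _ = evolve_orthologs(root, self.TREE, [0.03, 0.06, 0.1, 0.2], rng)
        divs = [
            np.mean([a != b for a, b in zip(root, seqs[sp])]) for sp in self.TREE
        ]
        assert all(d1 <= d2 + 1e-12 for d1, d2 in zip(divs, divs[1:]))

    def test_empty_tree_errors(self):
        with pytest.raises(ValueError, match="empty"):
            evolve_orthologs("ACGT", [], [], np.random.default_rng(0))


class TestSimulateLaicCounts:
    def test_zero_level_gives_zero_eluate(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            _, elu, _ = simulate_laic_counts(0.0, 200.0, rng)
            assert elu == 0

    def test_half_level_converges_to_half(self):
        rng = np.random.default_rng(1)
        _, elu, sup = simulate_laic_counts(0.5, 200_000.0, rng)
        assert abs(elu / (elu + sup) - 0.5) < 0.01

    def test_estimator_unbiased_within_binomial_error(self):
        """Mean estimated level over replicates sits within 3 binomial
        standard errors of the truth."""
        rng = np.random.default_rng(2)
        level, depth, reps = 0.8, 10_000.0, 500
        ests = []
        for _ in range(reps):
            _, elu, sup = simulate_laic_counts(level, depth, rng)
            ests.append(elu / (elu + sup))
        se = np.sqrt(level * (1 - level) / depth) / np.sqrt(reps)
        assert abs(np.mean(ests) - level) < 3 * se

    def test_invalid_level_errors(self):
        with pytest.raises(ValueError):
            simulate_laic_counts(1.5, 100.0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            simulate_laic_counts(0.5, 0.0, np.random.default_rng(0))


class TestSimulateExpression:
    def _pairs_levels(self):
        from pseudom6a.simulate import GenePair

        rng = np.random.default_rng(5)
        pairs, levels = [], {}
        for i in range(60):
            p = GenePair(f"P{i}", f"C{i}", "processed", 1)
            pairs.append(p)
            levels[p.pseudogene_id] = float(rng.uniform(0, 1))
            levels[p.cognate_id] = float(rng.uniform(0, 0.4))
        return pairs, levels

    def test_decay_raises_nuclear_index_of_methylated(self):
        pairs, levels = self._pairs_levels()
        comp, _ = simulate_expression(
            pairs, levels, 3.0, 0.5, 0.0, 10, np.random.default_rng(6)
        )
        hi = [n / c for g, (n, c) in comp.items()
              if g.startswith("P") and levels[g] >= 0.6]
        lo = [n / c for g, (n, c) in comp.items()
              if g.startswith("P") and levels[g] < 0.3]
        assert np.median(hi) > np.median(lo)

    def test_no_decay_no_stratum_difference(self):
        pairs, levels = self._pairs_levels()
        comp, _ = simulate_expression(
            pairs, levels, 0.0, 0.5, 0.0, 10, np.random.default_rng(7)
        )
        from scipy.stats import ranksums

        hi = [n / c for g, (n, c) in comp.items()
              if g.startswith("P") and levels[g] >= 0.6]
        lo = [n / c for g, (n, c) in comp.items()
              if g.startswith("P") and levels[g] < 0.3]
        assert ranksums(hi, lo).pvalue > 0.05

    def test_attenuation_zero_correlation_level_independent(self):
        """coupling_attenuation=0: pair correlation strength does not
        reference the m6A level."""
        pairs, levels = self._pairs_levels()
        _, mat = simulate_expression(
            pairs, levels, 0.0, 0.7, 0.0, 400, np.random.default_rng(8)
        )
        lm = np.log2(mat + 1)
        rs_hi, rs_lo = [], []
        for p in pairs:
            r = np.corrcoef(lm.loc[p.pseudogene_id], lm.loc[p.cognate_id])[0, 1]
            (rs_hi if levels[p.pseudogene_id] >= 0.5 else rs_lo).append(r)
        assert abs(np.mean(rs_hi) - np.mean(rs_lo)) < 0.1

    def test_too_few_samples_errors(self):
        pairs, levels = self._pairs_levels()
        with pytest.raises(ValueError, match="n_samples"):
            simulate_expression(pairs, levels, 0.0, 0.5, 0.0, 2, np.random.default_rng(0))


class TestCohortBundle:
    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(n_pairs=15, n_samples=10, seed=5)
        b1 = generate_cohort(cfg)
        b2 = generate_cohort(replace(cfg))
        assert b1.sequences == b2.sequences
        assert b1.fraction_counts == b2.fraction_counts
        assert b1.orthologs == b2.orthologs
        assert b1.snps == b2.snps
        assert all(
            np.array_equal(b1.coverages[g][0], b2.coverages[g][0])
            and np.array_equal(b1.coverages[g][1], b2.coverages[g][1])
            for g in b1.coverages
        )
        assert b1.population_expression.equals(b2.population_expression)
        assert b1.truth == b2.truth

    def test_bundle_consistency(self, cohort):
        for pair in cohort.pairs:
            assert pair.pseudogene_id in cohort.sequences
            assert pair.cognate_id in cohort.sequences
        for gid, counts in cohort.fraction_counts.items():
            assert all(c >= 0 and isinstance(c, int) for c in counts)
            assert gid in cohort.truth["true_levels"]
        for gid in cohort.sequences:
            assert gid in cohort.fraction_counts

    def test_level_recovery_improves_with_depth(self):
        """RMSE of estimated m6A level decreases with sequencing depth."""
        rng = np.random.default_rng(9)
        truths = rng.uniform(0.05, 0.95, size=300)
        rmses = []
        for depth in (100.0, 400.0, 1600.0):
            errs = []
            for t in truths:
                _, elu, sup = simulate_laic_counts(float(t), depth, rng)
                if elu + sup > 0:
                    errs.append(elu / (elu + sup) - t)
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_pairs=0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(frac_processed=1.2).validate()
        with pytest.raises(ValueError):
            SimulationConfig(branch_rates=[0.1]).validate()
        with pytest.raises(ValueError):
            SimulationConfig(site_choice="oldest_first").validate()
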