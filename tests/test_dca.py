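"""DCA chain: profiles, correlations, clustering, scores, classification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import dcapipe as dp
from dcapipe.dca import (
    ConservationScores,
    RatioProfilePair,
    min_subcluster_size,
)


def make_pair(ref: pd.DataFrame, tgt: pd.DataFrame, genotypes=("A", "B")):
    return RatioProfilePair(genotypes=genotypes, data={"A": ref, "B": tgt})


def block_profiles(blocks, timepoints=6, seed=0, noise=0.0):
    """Profiles whose genes follow per-block latents (+1/-1 the same latent)."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, timepoints)
    latent = np.sin(2 * np.pi * t) + t
    rows, names = [], []
    for b, (n, sign) in enumerate(blocks):
        for i in range(n):
            rows.append(sign * latent + rng.normal(0, noise, timepoints))
            names.append(f"b{b}g{i}")
    return pd.DataFrame(rows, index=names)


class TestRatioProfiles:
    @staticmethod
    def _experiment(ws_counts, ww_counts, n_stable=30, stable_value=50):
        rows = []
        for g in ("A", "B"):
            for trt in ("WW", "WS"):
                for r in (1, 2):
                    rows.append(
                        {
                            "sample_id": f"{g}_{trt}_T1_r{r}",
                            "genotype": g,
                            "treatment": trt,
                            "timepoint": "T1",
                            "replicate": r,
                        }
                    )
        samples = pd.DataFrame(rows)
        data = {}
        for s in samples.itertuples():
            value = ws_counts if s.treatment == "WS" else ww_counts
            data[s.sample_id] = [value] + [stable_value] * n_stable
        counts = pd.DataFrame(data, index=["gx"] + [f"s{i}" for i in range(n_stable)])
        return counts, samples

    def test_equal_treatments_give_zero_profiles(self):
        counts, samples = self._experiment(10, 10)
        pair = dp.ratio_profiles(counts, samples)
        for g in pair.genotypes:
            assert np.allclose(pair.data[g].to_numpy(), 0.0)

    def test_hand_arithmetic_with_pseudocount(self):
        # normalized means WS=20, WW=10, pseudocount 1 -> log2(21/11)
        counts, samples = self._experiment(20, 10)
        pair = dp.ratio_profiles(counts, samples, pseudocount=1.0)
        for g in pair.genotypes:
            assert pair.data[g].loc["gx", "T1"] == pytest.approx(
                math.log2(21 / 11), abs=1e-9
            )

    def test_label_swap_negates_profiles(self):
        counts, samples = self._experiment(20, 10)
        fwd = dp.ratio_profiles(counts, samples, pseudocount=0.0)
        swapped = samples.copy()
        swapped["treatment"] = swapped["treatment"].map({"WW": "WS", "WS": "WW"})
        rev = dp.ratio_profiles(counts, swapped, pseudocount=0.0)
        for g in fwd.genotypes:
            assert np.allclose(fwd.data[g].to_numpy(), -rev.data[g].to_numpy())

    def test_missing_cell_is_named(self):
        counts, samples = self._experiment(20, 10)
        keep = ~((samples["genotype"] == "B") & (samples["treatment"] == "WS"))
        with pytest.raises(ValueError, match=r"\(B, WS, T1\)"):
            dp.ratio_profiles(counts[samples[keep]["sample_id"]], samples[keep])


class TestCorrelationMatrix:
    def test_diagonal_and_hand_pearson(self):
        profiles = pd.DataFrame(
            [[1, 2, 3, 4], [1, 3, 2, 4], [-1, -2, -3, -4]], index=list("abc")
        )
        corr = dp.correlation_matrix(profiles)
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(0.8)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(corr, corr.T)

    def test_zero_variance_profile_excluded_with_warning(self, caplog):
        profiles = pd.DataFrame(
            [[1, 2, 3, 4], [5, 5, 5, 5], [4, 3, 2, 1]], index=list("abc")
        )
        with caplog.at_level("WARNING"):
            corr = dp.correlation_matrix(profiles)
        assert list(corr.index) == ["a", "c"]
        assert "b" in caplog.text

    def test_requires_three_timepoints(self):
        with pytest.raises(ValueError):
            dp.correlation_matrix(pd.DataFrame([[1, 2], [2, 1]]))


class TestPrimaryClusters:
    def test_perfect_two_block_structure(self):
        corr = dp.correlation_matrix(block_profiles([(4, 1), (4, -1)]))
        part = dp.primary_clusters(corr)
        assert [sorted(c) for c in part.clusters] == [
            [f"b0g{i}" for i in range(4)],
            [f"b1g{i}" for i in range(4)],
        ]
        assert part.unassigned == []

    def test_all_low_correlation_leaves_everything_unassigned(self):
        n = 6
        mat = np.full((n, n), 0.2)
        np.fill_diagonal(mat, 1.0)
        corr = pd.DataFrame(mat, index=list("abcdef"), columns=list("abcdef"))
        part = dp.primary_clusters(corr, cut_h=0.5)
        assert part.clusters == []
        assert part.unassigned == list("abcdef")

    def test_too_few_genes_gives_empty_partition(self, caplog):
        corr = dp.correlation_matrix(block_profiles([(3, 1)]))
        with caplog.at_level("WARNING"):
            part = dp.primary_clusters(corr, min_cluster_size=4)
        assert part.clusters == [] and len(part.unassigned) == 3

    def test_recovers_planted_three_block_structure(self):
        hits = 0
        for seed in range(100):
            profiles = block_profiles(
                [(4, 1), (4, -1), (5, 1)], timepoints=8, seed=seed, noise=0.15
            )
            # third block follows an independent latent
            rng = np.random.default_rng(seed + 10_000)
            shape = np.cos(2 * np.pi * np.linspace(0, 1, 8)) - np.linspace(0, 1, 8)
            profiles.iloc[8:] = shape + rng.normal(0, 0.15, size=(5, 8))
            part = dp.primary_clusters(dp.correlation_matrix(profiles))
            got = {frozenset(c) for c in part.clusters}
            want = {
                frozenset(f"b0g{i}" for i in range(4)),
                frozenset(f"b1g{i}" for i in range(4)),
                frozenset(f"b2g{i}" for i in range(5)),
            }
            hits += got == want
        assert hits >= 95


def brute_force_subclusters(genes, corr):
    """Independent enumeration of the best near-balanced 2-partition."""
    genes = sorted(genes)
    n = len(genes)
    floor = min_subcluster_size(n)
    best, best_val = None, -np.inf
    for r in range(1, n):
        for combo in itertools.combinations(range(1, n), r):
            a = [0] + list(combo)
            # keep gene 0 in the first group to halve the enumeration
            b = [i for i in range(n) if i not in a]
            if len(a) < floor or len(b) < floor:
                continue
            w_sum = w_n = 0.0
            for group in (a, b):
                for i, j in itertools.combinations(group, 2):
                    w_sum += corr.iloc[i, j]
                    w_n += 1
            btw = float(
                np.mean([corr.iloc[i, j] for i in a for j in b])
            )
            val = w_sum / w_n - btw
            if val > best_val + 1e-12:
                best_val = val
                best = ([genes[i] for i in a], [genes[i] for i in b])
    return best


class TestSubclusterTarget:
    def test_planted_split_recovered_exactly_without_noise(self):
        sim = dp.simulate_dca_geneset(
            dp.DcaClassSpec(planted_class="split", noise_sd=0.0, seed=3)
        )
        corr = dp.correlation_matrix(sim.profiles.data[sim.profiles.genotypes[1]])
        sub1, sub2 = dp.subcluster_target(list(sim.profiles.genes), corr)
        assert {frozenset(sub1), frozenset(sub2)} == {
            frozenset(sim.halves[0]),
            frozenset(sim.halves[1]),
        }

    def test_agrees_with_brute_force_on_small_instances(self, rng):
        for n in (4, 5, 6, 7, 8):
            for _ in range(10):
                profiles = pd.DataFrame(
                    rng.normal(size=(n, 6)), index=[f"g{i}" for i in range(n)]
                )
                corr = dp.correlation_matrix(profiles)
                got = dp.subcluster_target(list(corr.index), corr)
                want = brute_force_subclusters(list(corr.index), corr)
                assert got == want

    def test_greedy_path_matches_exhaustive_on_medium_instances(self, rng):
        for _ in range(5):
            profiles = pd.DataFrame(
                rng.normal(size=(10, 8)), index=[f"g{i}" for i in range(10)]
            )
            corr = dp.correlation_matrix(profiles)
            exact = dp.subcluster_target(list(corr.index), corr, exhaustive_limit=12)
            greedy = dp.subcluster_target(list(corr.index), corr, exhaustive_limit=4)
            # the local search may stop at a local optimum, but on these
            # instances it must reach an objective no worse than 95% of exact
            from dcapipe.dca import _partition_objective

            mat = corr.to_numpy()
            genes = sorted(corr.index)
            def value(parts):
                mask = np.array([g in parts[0] for g in genes])
                return _partition_objective(mat, mask)
            assert value(greedy) >= value(exact) - 0.05

    def test_small_cluster_rejected(self):
        corr = dp.correlation_matrix(block_profiles([(3, 1)]))
        with pytest.raises(ValueError):
            dp.subcluster_target(list(corr.index), corr)


class TestConservationScores:
    @staticmethod
    def _block_corr(within=0.8, cross=0.0, n_half=4):
        n = 2 * n_half
        mat = np.full((n, n), cross)
        mat[:n_half, :n_half] = within
        mat[n_half:, n_half:] = within
        np.fill_diagonal(mat, 1.0)
        genes = [f"g{i}" for i in range(n)]
        return pd.DataFrame(mat, index=genes, columns=genes), genes

    def test_all_unit_correlations(self):
        corr, genes = self._block_corr(within=1.0, cross=1.0)
        s = dp.conservation_scores(genes, genes[:4], genes[4:], corr, corr)
        assert s.r_tgt_all == pytest.approx(1.0)
        assert s.r_tgt_diag == (pytest.approx(1.0), pytest.approx(1.0))
        assert s.r_tgt_off == pytest.approx(1.0)

    def test_hand_averaging_oracle(self):
        # within halves 0.8, cross 0: all-mean = 2*C(4,2)*0.8 / C(8,2) = 9.6/28
        corr, genes = self._block_corr()
        s = dp.conservation_scores(genes, genes[:4], genes[4:], corr, corr)
        assert s.r_tgt_diag == (pytest.approx(0.8), pytest.approx(0.8))
        assert s.r_tgt_off == pytest.approx(0.0)
        assert s.r_tgt_all == pytest.approx(9.6 / 28)

    def test_permutation_invariance(self, rng):
        from conftest import random_corr_frame

        corr = random_corr_frame(rng, 8)
        genes = list(corr.index)
        s0 = dp.conservation_scores(genes, genes[:4], genes[4:], corr, corr)
        perm = list(rng.permutation(genes[:4])) + list(rng.permutation(genes[4:]))
        s1 = dp.conservation_scores(
            list(rng.permutation(genes)), perm[:4], perm[4:], corr, corr
        )
        assert s0.r_tgt_all == pytest.approx(s1.r_tgt_all)
        assert s0.r_tgt_off == pytest.approx(s1.r_tgt_off)

    def test_singleton_subcluster_scores_nan_and_classifies_low(self):
        corr, genes = self._block_corr()
        s = dp.conservation_scores(genes, genes[:1], genes[1:], corr, corr)
        assert math.isnan(s.r_tgt_diag[0])
        assert dp.classify_conservation(s) in ("partial", "absent")

    def test_subclusters_must_partition_cluster(self):
        corr, genes = self._block_corr()
        with pytest.raises(ValueError):
            dp.conservation_scores(genes, genes[:3], genes[4:], corr, corr)


class TestClassifyConservation:
    def test_rule_table(self):
        mk = lambda all_, d1, d2, off: ConservationScores(1.0, all_, (d1, d2), off)
        assert dp.classify_conservation(mk(0.9, 0.9, 0.9, 0.9)) == "full"
        assert dp.classify_conservation(mk(0.34, 0.8, 0.8, 0.0)) == "split"
        assert dp.classify_conservation(mk(0.2, 0.8, 0.1, 0.05)) == "partial"
        assert dp.classify_conservation(mk(0.1, 0.2, 0.1, 0.0)) == "absent"

    def test_precedence_full_beats_split(self):
        s = ConservationScores(1.0, 0.9, (0.9, 0.9), 0.1)
        assert dp.classify_conservation(s) == "full"

    def test_total_function_over_random_scores(self, rng):
        for _ in range(200):
            vals = rng.uniform(-1, 1, size=5)
            s = ConservationScores(vals[0], vals[1], (vals[2], vals[3]), vals[4])
            assert dp.classify_conservation(s) in dp.DCA_CLASSES

    def test_invalid_thresholds(self):
        s = ConservationScores(1.0, 0.9, (0.9, 0.9), 0.1)
        with pytest.raises(ValueError):
            dp.classify_conservation(s, c_high=0.3, c_low=0.6)


class TestRunDca:
    def test_self_comparison_is_full(self):
        ref = block_profiles([(6, 1)], timepoints=8, noise=0.1, seed=5)
        pair = make_pair(ref, ref.copy())
        res = dp.run_dca(pair)
        assert res.calls and all(
            c.conservation_class == "full" for c in res.calls
        )

    def test_scale_invariance_of_classes(self):
        sim = dp.simulate_dca_geneset(dp.DcaClassSpec(planted_class="split", seed=8))
        base = dp.run_dca(sim.profiles)
        scaled_data = {
            g: df * (3.0 if i else 1.0)
            for i, (g, df) in enumerate(sim.profiles.data.items())
        }
        scaled = RatioProfilePair(sim.profiles.genotypes, scaled_data)
        res = dp.run_dca(scaled)
        assert [c.conservation_class for c in res.calls] == [
            c.conservation_class for c in base.calls
        ]

    def test_reference_swap_preserves_correlation_matrices(self):
        sim = dp.simulate_dca_geneset(dp.DcaClassSpec(planted_class="partial", seed=12))
        res = dp.run_dca(sim.profiles)
        direct = {
            g: dp.correlation_matrix(sim.profiles.data[g])
            for g in sim.profiles.genotypes
        }
        for ref, mats in res.matrices.items():
            for g, mat in mats.items():
                genes = list(mat.index)
                pd.testing.assert_frame_equal(
                    mat, direct[g].loc[genes, genes], atol=1e-12
                )

    def test_calls_carry_reference_label_both_directions(self):
        sim = dp.simulate_dca_geneset(dp.DcaClassSpec(planted_class="full", seed=2))
        res = dp.run_dca(sim.profiles)
        refs = {c.reference_genotype for c in res.calls}
        assert refs == set(sim.profiles.genotypes)

    def test_gene_set_must_exist(self):
        sim = dp.simulate_dca_geneset(dp.DcaClassSpec(seed=0))
        with pytest.raises(ValueError, match="gene_set"):
            dp.run_dca(sim.profiles, gene_set=["nope"])


class TestDivergentGenes:
    @staticmethod
    def _pair(ref_val, tgt_val):
        ref = pd.DataFrame(
            [[ref_val, 0.0, 0.0]], index=["g1"], columns=["T1", "T2", "T3"]
        )
        tgt = pd.DataFrame(
            [[tgt_val, 0.0, 0.0]], index=["g1"], columns=["T1", "T2", "T3"]
        )
        return make_pair(ref, tgt)

    def test_opposite_signs_above_threshold_reported(self):
        out = dp.divergent_genes(self._pair(1.0, -1.0), min_abs_lfc=0.585)
        assert len(out) == 1
        assert out.iloc[0]["timepoint"] == "T1"

    def test_same_sign_not_reported(self):
        assert dp.divergent_genes(self._pair(1.0, 1.0), min_abs_lfc=0.585).empty

    def test_magnitude_gate_applies_to_both_genotypes(self):
        assert dp.divergent_genes(self._pair(0.3, -2.0), min_abs_lfc=0.585).empty
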