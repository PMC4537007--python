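"""Candidate union, Spearman filtering and BH adjustment."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirmodscore import (
    ExpressionMatrix,
    bh_adjust,
    integrate,
    simulate_experiment,
    simulate_predictions,
    spearman_pairs,
    union_candidates,
)


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def spearman_oracle(x, y):
    """Average-rank Spearman rho via the explicit rank-Pearson formula."""
    from scipy.stats import rankdata
    rx, ry = rankdata(x), rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return (rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry))


def _paired_matrices(x_rows, y_rows):
    samples = [f"s{i}" for i in range(len(x_rows[0]))]
    sheet = pd.DataFrame(index=pd.Index(samples, name="sample"))
    mx = ExpressionMatrix(
        pd.DataFrame(x_rows, index=[f"m{i}" for i in range(len(x_rows))],
                     columns=samples), sheet)
    my = ExpressionMatrix(
        pd.DataFrame(y_rows, index=[f"g{i}" for i in range(len(y_rows))],
                     columns=samples), sheet.copy())
    return mx, my


class TestUnion:
    def test_disjoint_sources_add(self):
        a = pd.DataFrame({"mir_id": ["m1"] * 3, "mrna_id": ["g1", "g2", "g3"]})
        b = pd.DataFrame({"mir_id": ["m2"] * 4, "mrna_id": list("wxyz")})
        out = union_candidates([a, b])
        assert len(out) == 7

    def test_identical_sources_tagged_with_both(self):
        a = pd.DataFrame({"mir_id": ["m1"], "mrna_id": ["g1"]})
        out = union_candidates([a, a.copy()], source_names=["pita", "miranda"])
        assert len(out) == 1
        assert out.loc[0, "sources"] == ("miranda", "pita")

    def test_union_matches_set_oracle(self, experiment, default_config):
        truth = experiment[2]
        sources = simulate_predictions(truth, default_config)
        out = union_candidates(sources)
        brute = set()
        for s in sources:
            brute |= set(map(tuple, s.to_numpy()))
        assert set(zip(out["mir_id"], out["mrna_id"])) == brute

    def test_unknown_ids_dropped(self):
        a = pd.DataFrame({"mir_id": ["m1", "bogus"], "mrna_id": ["g1", "g1"]})
        out = union_candidates([a], known_mirs={"m1"}, known_mrnas={"g1"})
        assert len(out) == 1


class TestSpearman:
    def test_perfect_anti_ranking(self):
        mx, my = _paired_matrices([[1, 2, 3, 4]], [[8, 6, 4, 2]])
        cands = pd.DataFrame({"mir_id": ["m0"], "mrna_id": ["g0"]})
        out = spearman_pairs(mx, my, cands)
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_ties_average_rank_formula(self):
        mx, my = _paired_matrices([[1, 2, 2, 3]], [[3, 2, 2, 1]])
        cands = pd.DataFrame({"mir_id": ["m0"], "mrna_id": ["g0"]})
        out = spearman_pairs(mx, my, cands)
        expected = spearman_oracle([1, 2, 2, 3], [3, 2, 2, 1])
        assert out.loc[0, "rho"] == pytest.approx(expected, abs=1e-12)

    def test_exact_permutation_p_matches_enumeration(self, rng):
        """n=6 permutation p equals exhaustive enumeration of 720 orderings."""
        for _ in range(5):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            mx, my = _paired_matrices([x], [y])
            cands = pd.DataFrame({"mir_id": ["m0"], "mrna_id": ["g0"]})
            out = spearman_pairs(mx, my, cands)
            rho_obs = spearman_oracle(x, y)
            count = sum(
                abs(spearman_oracle(x, np.asarray(y)[list(perm)])) >= abs(rho_obs) - 1e-12
                for perm in itertools.permutations(range(6)))
            assert out.loc[0, "p_corr"] == pytest.approx(count / 720)

    def test_constant_profile_reported_missing(self):
        mx, my = _paired_matrices([[5, 5, 5, 5]], [[1, 2, 3, 4]])
        cands = pd.DataFrame({"mir_id": ["m0"], "mrna_id": ["g0"]})
        out = spearman_pairs(mx, my, cands)
        assert np.isnan(out.loc[0, "rho"])

    def test_too_few_paired_samples(self):
        mx, my = _paired_matrices([[1, 2]], [[2, 1]])
        cands = pd.DataFrame({"mir_id": ["m0"], "mrna_id": ["g0"]})
        with pytest.raises(ValueError, match="3"):
            spearman_pairs(mx, my, cands)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60),
           st.integers(0, 999))
    def test_matches_brute_force_and_permutation_invariant(self, p, seed):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(p))
        q_perm = bh_adjust(np.asarray(p)[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)

    def test_q_at_least_p(self, rng):
        p = rng.random(200)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestIntegrate:
    def _scored(self, rho, p):
        return pd.DataFrame({
            "mir_id": [f"m{i}" for i in range(len(rho))],
            "mrna_id": [f"g{i}" for i in range(len(rho))],
            "rho": rho, "p_corr": p,
        })

    def test_uncorrelated_all_filtered(self):
        edges, counts = integrate(self._scored([0.0, 0.1], [0.9, 0.8]))
        assert counts["n_edges"] == 0 and len(edges) == 0

    def test_strict_boundary(self):
        scored = self._scored([-0.9, -0.91], [1e-6, 1e-6])
        edges, _ = integrate(scored, rho_cutoff=-0.9)
        assert list(edges["mir_id"]) == ["m1"]
        edges, _ = integrate(scored, rho_cutoff=-1.0)
        assert len(edges) == 0

    def test_monotone_in_cutoffs(self, rng):
        scored = self._scored(rng.uniform(-1, 0, 200), rng.random(200) * 0.2)
        tight, _ = integrate(scored, rho_cutoff=-0.95, q_cutoff=0.01)
        loose, _ = integrate(scored, rho_cutoff=-0.8, q_cutoff=0.1)
        assert set(tight["mir_id"]) <= set(loose["mir_id"])

    def test_invalid_cutoffs(self):
        with pytest.raises(ValueError):
            integrate(self._scored([0], [0.5]), rho_cutoff=-2)
        with pytest.raises(ValueError):
            integrate(self._scored([0], [0.5]), q_cutoff=0)

    def test_near_noiseless_recovery(self, small_config):
        """Integrated set equals planted edges intersected with prediction union."""
        cfg = dataclasses.replace(small_config, noise_sd=1e-3,
                                  pred_sensitivity=0.7, pred_fpr=0.01)
        mir, mrna, truth = simulate_experiment(cfg)
        sources = simulate_predictions(truth, cfg)
        cands = union_candidates(sources)
        scored = spearman_pairs(mir, mrna, cands)
        edges, _ = integrate(scored)
        got = set(zip(edges["mir_id"], edges["mrna_id"]))
        union = set()
        for s in sources:
            union |= set(map(tuple, s.to_numpy()))
        assert got == (truth.edges & union)
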