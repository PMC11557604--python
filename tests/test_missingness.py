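"""Clipped-normal missingness draws and ESS-weighted element removal."""

import numpy as np
import pytest
from scipy import stats

from traumasim import (
    MISSING,
    PRESENT_1,
    BoneESS,
    MissingnessConfig,
    Specimen,
    allocate_missing,
    apply_missingness,
    draw_missing_count,
    element_removal_weights,
    prob_completeness_at_least,
    sample_without_replacement,
    summarize_specimen,
)
from traumasim.anatomy import N_ELEMENTS
from traumasim.missingness import draw_missing_counts, weight_array


def successive_draw_inclusion_probs(w, k):
    """Exact per-item inclusion probabilities of k successive weighted draws
    without replacement (renormalizing after each draw), by enumerating all
    ordered draw sequences. Oracle for the exponential-race implementation."""
    m = len(w)
    probs = np.zeros(m)

    def rec(avail, depth, p):
        if depth == 0:
            return
        tot = sum(w[i] for i in avail)
        for i in avail:
            pi = p * w[i] / tot
            probs[i] += pi
            rec(avail - {i}, depth - 1, pi)

    rec(frozenset(range(m)), k, 1.0)
    return probs


class TestDrawMissingCount:
    def test_degenerate_bounds(self, rng):
        assert draw_missing_count(MissingnessConfig(0, 0), rng) == 0
        assert draw_missing_count(MissingnessConfig(100, 0), rng) == 48

    def test_counts_within_range(self, rng):
        counts = draw_missing_counts(MissingnessConfig(50, 40), rng, 10_000)
        assert counts.min() >= 0 and counts.max() <= 48

    def test_clipped_normal_closed_form(self, rng):
        """P(count <= 12) at mean 80, sd 20 matches the clipped-normal CDF
        Phi((12.5/48*100 - 80)/20) to three decimals over 10^6 draws."""
        counts = draw_missing_counts(MissingnessConfig(80, 20), rng, 1_000_000)
        empirical = np.mean(counts <= 12)
        expected = stats.norm.cdf((12.5 / 48 * 100 - 80) / 20)
        assert empirical == pytest.approx(expected, abs=1e-3)

    def test_realized_mean_shifted_by_clipping(self, rng):
        """Clipping at 0/100 pulls the realized mean missingness below the
        nominal mean when mass is clipped at 100 (mean 80, sd 20)."""
        mu, sd = 80.0, 20.0
        counts = draw_missing_counts(MissingnessConfig(mu, sd), rng, 200_000)
        realized = counts.mean() / N_ELEMENTS * 100
        a, b = (0 - mu) / sd, (100 - mu) / sd
        expected = (
            100 * (1 - stats.norm.cdf(b))
            + mu * (stats.norm.cdf(b) - stats.norm.cdf(a))
            - sd * (stats.norm.pdf(b) - stats.norm.pdf(a))
        )
        assert expected < mu
        assert realized == pytest.approx(expected, abs=0.3)


class TestRemovalWeights:
    def test_uniform_ess_gives_uniform_weights(self, schema):
        ess = BoneESS({b: 7.0 for b in schema.bones})
        w = element_removal_weights(schema, ess)
        assert all(v == pytest.approx(1 / 48) for v in w.values())

    def test_underrepresented_bones_weigh_more(self, schema, weights):
        assert weights["nasal_L_1"] > weights["mandible_L_1"]
        assert weights["zygomatic_R_1"] > weights["parietal_R_1"]

    def test_scale_invariance(self, schema, bone_ess):
        doubled = BoneESS({b: 2 * v for b, v in bone_ess.ess.items()})
        w1 = element_removal_weights(schema, bone_ess)
        w2 = element_removal_weights(schema, doubled)
        assert w1 == pytest.approx(w2)

    @pytest.mark.parametrize("transform", ["inverse", "max_minus", "rank"])
    def test_all_transforms_monotone_and_normalized(self, schema, bone_ess, transform):
        w = element_removal_weights(schema, bone_ess, transform=transform)
        assert sum(w.values()) == pytest.approx(1.0)
        assert w["nasal_L_1"] > w["mandible_L_1"]

    def test_unknown_transform_rejected(self, schema, bone_ess):
        with pytest.raises(ValueError, match="transform"):
            element_removal_weights(schema, bone_ess, transform="sqrt")

    def test_nonpositive_ess_rejected(self, schema):
        ess = BoneESS({b: 1.0 for b in schema.bones} | {"nasal_L": 0.0})
        with pytest.raises(ValueError, match="> 0"):
            element_removal_weights(schema, ess)


class TestAllocateMissing:
    def test_identity_and_total_removal(self, schema, weights, rng):
        spec = Specimen(np.zeros(48, dtype=np.int8))
        same = allocate_missing(spec, 0, weights, rng, schema=schema)
        assert np.array_equal(same.state, spec.state)
        gone = allocate_missing(spec, 48, weights, rng, schema=schema)
        assert gone.completeness == 0.0

    def test_exact_count_and_completeness(self, schema, weights, rng):
        spec = Specimen(np.zeros(48, dtype=np.int8))
        for count in (1, 12, 30, 47):
            out = allocate_missing(spec, count, weights, rng, schema=schema)
            assert int(np.count_nonzero(out.state == MISSING)) == count
            assert out.completeness == pytest.approx(100 * (48 - count) / 48)

    def test_count_out_of_range(self, schema, weights, rng):
        spec = Specimen(np.zeros(48, dtype=np.int8))
        with pytest.raises(ValueError):
            allocate_missing(spec, 49, weights, rng, schema=schema)

    def test_trauma_monotonicity(self, schema, pool, weights, rng):
        """Removal can only flip trauma presence 1 -> 0, never 0 -> 1."""
        for case in pool.cases[:10]:
            spec = Specimen((case.pattern * PRESENT_1).astype(np.int8))
            out = allocate_missing(spec, 30, weights, rng, schema=schema)
            assert out.has_trauma or spec.has_trauma  # no 0 -> 1
        clean = Specimen(np.zeros(48, dtype=np.int8))
        out = allocate_missing(clean, 40, weights, rng, schema=schema)
        assert not out.has_trauma

    def test_partial_fracture_survives(self, schema, weights, rng):
        """Removing 2 of a fracture's 3 injured elements leaves trauma = 1."""
        state = np.zeros(48, dtype=np.int8)
        injured = [0, 1, 2]
        state[injured] = PRESENT_1
        spec = Specimen(state)
        out = spec.state.copy()
        out[[0, 1]] = MISSING
        completeness, trauma = summarize_specimen(Specimen(out))
        assert trauma == 1
        assert completeness == pytest.approx(100 * 46 / 48)

    def test_matches_successive_draw_enumeration(self, rng):
        """Empirical inclusion frequencies on a 6-element schema agree with
        exhaustive enumeration of the successive-weighted-draw process to
        two decimals."""
        w = np.array([5.0, 3.0, 2.0, 1.0, 1.0, 0.5])
        k = 3
        exact = successive_draw_inclusion_probs(w, k)
        hits = np.zeros(6)
        reps = 60_000
        for _ in range(reps):
            hits[sample_without_replacement(w, k, rng)] += 1
        assert np.allclose(hits / reps, exact, atol=0.01)
        # heavier-weighted items are removed more often
        assert (np.diff(exact) <= 1e-12).all()

    def test_uniform_weights_equal_srs(self, rng):
        """With uniform weights the scheme is simple random sampling without
        replacement: all C(5,2) subsets equally likely (chi-square)."""
        from itertools import combinations

        w = np.ones(5)
        subsets = {c: 0 for c in combinations(range(5), 2)}
        reps = 20_000
        for _ in range(reps):
            idx = tuple(sorted(sample_without_replacement(w, 2, rng)))
            subsets[idx] += 1
        observed = np.array(list(subsets.values()))
        chi2, p = stats.chisquare(observed)
        assert p > 1e-3

    def test_nasal_removed_more_often_than_mandible(self, schema, weights, rng):
        w = weight_array(schema, weights)
        nasal = schema.index_of("nasal_L_1")
        mandible = schema.index_of("mandible_L_1")
        reps = 20_000
        mask_cfg = MissingnessConfig(mean_pct=25, sd_pct=0)
        states = np.zeros((reps, 48), dtype=np.int8)
        out = apply_missingness(states, mask_cfg, w, rng)
        freq = (out == MISSING).mean(axis=0)
        assert freq[nasal] > freq[mandible]


class TestSummaries:
    def test_summarize_examples(self):
        clean = Specimen(np.zeros(48, dtype=np.int8))
        assert summarize_specimen(clean) == (100.0, 0)
        state = np.full(48, MISSING, dtype=np.int8)
        state[:36] = 0
        state[0] = PRESENT_1
        assert summarize_specimen(Specimen(state)) == (75.0, 1)

    def test_empty_specimen_vacuous_trauma(self):
        empty = Specimen(np.full(48, MISSING, dtype=np.int8))
        assert summarize_specimen(empty) == (0.0, 0)

    def test_prob_completeness_closed_form_vs_empirical(self, rng):
        cfg = MissingnessConfig(60, 20)
        counts = draw_missing_counts(cfg, rng, 400_000)
        completeness = 100 * (N_ELEMENTS - counts) / N_ELEMENTS
        for threshold in (50.0, 75.0):
            p = prob_completeness_at_least(threshold, 60, 20)
            emp = np.mean(completeness >= threshold)
            assert emp == pytest.approx(p, abs=4 * np.sqrt(p * (1 - p) / 400_000) + 1e-6)

    def test_prob_completeness_degenerate(self):
        assert prob_completeness_at_least(75, 0, 0) == 1.0
        assert prob_completeness_at_least(75, 100, 0) == 0.0
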