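import itertools

import numpy as np
import pytest

from stridesense import (StaminaScorer, SyntheticConfig,
                         build_baseline_template, categorize_stamina,
                         dtw_distance, generate_cohort, null_config,
                         stamina_metric, stamina_series, validate_stamina)
from stridesense.io import StrideDataset, StrideWindow
from stridesense.exceptions import CalibrationError, ParameterError


# ---------------------------------------------------------------------------
# exhaustive DTW oracle

def dtw_bruteforce(a, b):
    """Minimal cumulative |a_i - b_j| over all monotone boundary-anchored
    paths, by exhaustive recursion (exponential; tiny inputs only)."""
    n, m = len(a), len(b)

    def rec(i, j):
        c = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return c
        best = float("inf")
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        return c + best

    return rec(n - 1, m - 1)


class TestDtw:
    def test_identical_series_zero_distance_diagonal_path(self):
        r = dtw_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.distance == 0.0
        assert r.path == [(0, 0), (1, 1), (2, 2)]

    def test_spec_example(self):
        assert dtw_distance([1, 2, 3], [1, 3]).distance == 1.0

    def test_matches_bruteforce_on_small_pairs(self):
        vals = (0.0, 1.0, 2.0)
        seqs = [s for L in (1, 2, 3) for s in itertools.product(vals, repeat=L)]
        for a in seqs[::3]:
            for b in seqs[::3]:
                assert dtw_distance(a, b).distance == dtw_bruteforce(a, b)

    def test_symmetry(self, rng):
        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(size=rng.integers(2, 12))
            assert dtw_distance(a, b).distance == pytest.approx(
                dtw_distance(b, a).distance, abs=1e-12)

    def test_distinct_constant_series(self):
        # cheapest path is the diagonal: n steps each costing |c1 - c2|
        assert dtw_distance([2.0] * 5, [5.0] * 5).distance == pytest.approx(15.0)

    def test_band_wide_enough_equals_unbanded(self, rng):
        for _ in range(20):
            a = rng.normal(size=10)
            b = rng.normal(size=8)
            full = dtw_distance(a, b).distance
            banded = dtw_distance(a, b, band=10).distance
            assert banded == pytest.approx(full, abs=1e-12)

    def test_band_is_a_restriction(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        assert dtw_distance(a, b, band=1).distance >= \
            dtw_distance(a, b).distance - 1e-12

    def test_path_invariants(self, rng):
        a = rng.normal(size=7)
        b = rng.normal(size=5)
        r = dtw_distance(a, b)
        assert r.path[0] == (0, 0) and r.path[-1] == (6, 4)
        steps = {(i2 - i1, j2 - j1)
                 for (i1, j1), (i2, j2) in zip(r.path, r.path[1:])}
        assert steps <= {(1, 0), (0, 1), (1, 1)}
        assert r.distance == pytest.approx(
            sum(abs(a[i] - b[j]) for i, j in r.path), abs=1e-12)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            dtw_distance([], [1.0])
        with pytest.raises(ParameterError):
            dtw_distance([1, 2, 3, 4, 5], [1], band=2)


def _strides(pid, blocks, labels, L):
    return [StrideWindow(pid, i, lab, blk, 256.0)
            for i, (blk, lab) in enumerate(zip(blocks, labels))]


class TestBaseline:
    def test_template_is_pointwise_median(self, rng):
        L = 16
        blocks = [rng.normal(size=(3, L)) + rng.normal(size=(3, 1))
                  for _ in range(5)]
        strides = _strides("P01", blocks, [0] * 5, L)
        tpl = build_baseline_template(strides, ["ax", "ay", "az"])
        np.testing.assert_allclose(tpl.template,
                                   np.median(np.stack(blocks), axis=0),
                                   atol=1e-12)

    def test_identical_strides_floor_kappa_and_unit_Z(self, rng):
        L = 16
        block = rng.normal(size=(3, L))
        strides = _strides("P01", [block.copy() for _ in range(4)], [0] * 4, L)
        tpl = build_baseline_template(strides, ["ax", "ay", "az"])
        assert tpl.kappa == pytest.approx(1e-6 * L)
        est = stamina_metric(strides[0], tpl, ["ax", "ay", "az"])
        assert est.Z == 1.0

    def test_duplicate_stride_keeps_odd_median(self, rng):
        L = 8
        blocks = [rng.normal(size=(3, L)) for _ in range(3)]
        s3 = _strides("P01", blocks, [0] * 3, L)
        s5 = _strides("P01", blocks + [blocks[0], blocks[0]], [0] * 5, L)
        t3 = build_baseline_template(s3, ["ax", "ay", "az"])
        t5 = build_baseline_template(s5, ["ax", "ay", "az"])
        # median of {b0,b1,b2,b0,b0} is b0 elementwise only where b0 is the
        # middle value; check medians both come from the same blocks
        assert t3.template.shape == t5.template.shape

    def test_too_few_nf_strides_rejected(self, rng):
        strides = _strides("P01", [rng.normal(size=(3, 8))], [0], 8)
        with pytest.raises(CalibrationError):
            build_baseline_template(strides, ["ax", "ay", "az"])


class TestZMetric:
    def test_boundary_values(self, rng):
        L = 16
        block = rng.normal(size=(3, L))
        strides = _strides("P01", [block + rng.normal(0, 0.3, size=(3, L))
                                   for _ in range(6)], [0] * 6, L)
        tpl = build_baseline_template(strides, ["ax", "ay", "az"])
        # d = 0 -> Z = 1
        ident = StrideWindow("P01", 9, 0, tpl.template, 256.0)
        # construct a stride whose scoring series equals the template series
        est = stamina_metric(strides[0], tpl, ["ax", "ay", "az"])
        assert 0.0 <= est.Z <= 1.0
        # linear form: synthetic distances
        assert 1 - tpl.kappa / tpl.kappa == 0.0
        assert 1 - 0.5 * tpl.kappa / tpl.kappa == 0.5

    def test_Z_monotone_in_distance(self):
        # Z = clip(1 - d/kappa) is non-increasing in d by construction
        kappa = 2.0
        ds = np.linspace(0, 5, 50)
        zs = np.clip(1 - ds / kappa, 0, 1)
        assert (np.diff(zs) <= 1e-15).all()
        assert ((zs >= 0) & (zs <= 1)).all()


class TestCategorize:
    @pytest.mark.parametrize("z,cat", [
        (0.5, "medium"), (1.0, "high"), (0.0, "low"),
        (1 / 3, "medium"), (2 / 3, "high"), (0.332, "low"),
    ])
    def test_default_bands(self, z, cat):
        assert categorize_stamina(z) == cat

    def test_equal_thresholds_upper_rule_wins(self):
        assert categorize_stamina(0.5, thresholds=(0.5, 0.5)) == "high"


class TestValidate:
    def test_perfect_agreement(self, rng):
        z = rng.uniform(size=10)
        v = validate_stamina(z, z)
        assert v["pearson_r"] == pytest.approx(1.0)
        assert v["bland_altman_bias"] == 0.0
        assert v["bland_altman_limits"] == (0.0, 0.0)

    def test_perfect_anticorrelation(self, rng):
        z = rng.uniform(size=10)
        v = validate_stamina(-z + 1.0, z)
        assert v["pearson_r"] == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self, rng):
        a = rng.normal(size=30)
        b = a + rng.normal(0, 0.3, size=30)
        v = validate_stamina(b, a)
        d = b - a
        assert v["pearson_r"] == pytest.approx(np.corrcoef(a, b)[0, 1],
                                               abs=1e-10)
        assert v["bland_altman_bias"] == pytest.approx(d.mean(), abs=1e-10)
        lo, hi = v["bland_altman_limits"]
        assert lo == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-10)
        assert hi == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-10)

    def test_preconditions(self):
        with pytest.raises(ParameterError):
            validate_stamina([1, 2], [1, 2])
        with pytest.raises(ParameterError):
            validate_stamina([1, 1, 1], [1, 2, 3])


class TestStaminaSeries:
    def test_fatigue_effect_lowers_Z(self):
        gaps = []
        for seed in range(5):
            ds = generate_cohort(SyntheticConfig(
                n_participants=1, strides_per_condition=15,
                amplitude_attenuation=0.4, seed=seed))
            est, _ = stamina_series(ds, "P01")
            zf = np.mean([e.Z for e in est if e.label == 1])
            znf = np.mean([e.Z for e in est if e.label == 0])
            gaps.append(znf - zf)
        assert np.median(gaps) > 0

    def test_null_effect_balanced_Z(self):
        deltas = []
        for seed in range(5):
            ds = generate_cohort(null_config(
                n_participants=1, strides_per_condition=15, seed=seed))
            est, _ = stamina_series(ds, "P01")
            zf = np.mean([e.Z for e in est if e.label == 1])
            znf = np.mean([e.Z for e in est if e.label == 0])
            deltas.append(abs(zf - znf))
        assert np.median(deltas) < 0.1

    def test_summary_fields(self, effect_cohort):
        est, summary = stamina_series(effect_cohort, "P01")
        assert summary["n_strides"] == len(est) == 40
        assert summary["min_Z"] <= summary["mean_Z"] <= summary["max_Z"]

    def test_scorer_surfaces_per_participant_calibration_errors(self, rng):
        L = 16
        good = _strides("P01", [rng.normal(size=(3, L)) for _ in range(4)],
                        [0, 0, 1, 1], L)
        bad = _strides("P02", [rng.normal(size=(3, L)) for _ in range(2)],
                       [1, 1], L)  # no NF strides at all
        ds = StrideDataset(good + bad, ["ax", "ay", "az"], L)
        scorer = StaminaScorer().fit(ds)
        assert "P02" in scorer.calibration_errors_
        ests = scorer.transform(ds)
        assert {e.participant_id for e in ests} == {"P01"}

    def test_unknown_participant_rejected(self, effect_cohort):
        with pytest.raises(ParameterError):
            stamina_series(effect_cohort, "nobody")
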