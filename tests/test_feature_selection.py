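import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbbkit.data_model import DescriptorTable
from bbbkit.exceptions import InputError, ScoringError
from bbbkit.feature_selection import (
    bin_feature,
    midse,
    select_continuous_features,
    select_structural_keys,
    shannon_entropy,
)


def brute_force_midse(a, b, n_bins):
    """Independent literal evaluation of the differential-entropy score."""
    a = [x for x in a if math.isfinite(x)]
    b = [x for x in b if math.isfinite(x)]
    lo = min(min(a), min(b))
    hi = max(max(a), max(b))
    if lo == hi:
        return 0.0
    step = (hi - lo) / n_bins
    edges = [lo + k * step for k in range(n_bins)] + [hi]

    def hist(vals):
        counts = [0] * n_bins
        for v in vals:
            for k in range(n_bins):
                last = k == n_bins - 1
                if edges[k] <= v < edges[k + 1] or (last and v == hi):
                    counts[k] += 1
                    break
        total = sum(counts)
        return [c / total for c in counts]

    pa, pb = hist(a), hist(b)
    pc = [(x + y) / 2 for x, y in zip(pa, pb)]

    def H(p):
        return -sum(q * math.log2(q) for q in p if q > 0)

    return H(pc) - (H(pa) + H(pb)) / 2


class TestShannonEntropy:
    def test_uniform_two_bins(self):
        assert shannon_entropy([0.5, 0.5]) == pytest.approx(1.0)

    def test_degenerate(self):
        assert shannon_entropy([1.0, 0.0]) == 0.0

    def test_skewed(self):
        assert shannon_entropy([0.25, 0.75]) == pytest.approx(0.8113, abs=5e-5)

    def test_non_normalized_rejected(self):
        with pytest.raises(InputError):
            shannon_entropy([0.5, 0.6])

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            shannon_entropy([1.5, -0.5])


class TestBinFeature:
    def test_identical_inputs(self):
        h = bin_feature([0.1, 0.9], [0.1, 0.9], 2)
        assert h.p_active == h.p_inactive == h.p_combined == (0.5, 0.5)

    def test_disjoint_single_bins_class_size_free(self):
        for k, m in [(1, 1), (3, 7), (10, 2)]:
            h = bin_feature([0.1] * k, [0.9] * m, 2)
            assert h.p_active == (1.0, 0.0)
            assert h.p_inactive == (0.0, 1.0)
            assert h.p_combined == (0.5, 0.5)  # mean, not pooled

    def test_zero_range_single_bin(self):
        h = bin_feature([2.0, 2.0], [2.0], 5)
        assert h.p_active == (1.0,)
        assert shannon_entropy(h.p_active) == 0.0

    def test_combined_is_mean(self):
        h = bin_feature([0, 1, 2, 3], [1, 1, 2, 5], 4)
        for k in range(4):
            assert h.p_combined[k] == pytest.approx(
                (h.p_active[k] + h.p_inactive[k]) / 2)

    def test_missing_excluded(self):
        h = bin_feature([0.1, np.nan, 0.9], [0.1, 0.9, np.nan], 2)
        assert h.p_active == (0.5, 0.5)

    def test_all_missing_errors(self):
        with pytest.raises(ScoringError):
            bin_feature([np.nan], [0.1, 0.9], 2)


class TestMidse:
    def test_identical_distributions_zero(self):
        s = midse([1, 2, 3, 4], [1, 2, 3, 4], 4)
        assert s.midse == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_is_one(self):
        s = midse([0.0] * 5, [1.0] * 3, 2)
        assert s.midse == pytest.approx(1.0, abs=1e-12)
        assert s.h_active == 0.0 and s.h_inactive == 0.0
        assert s.h_combined == pytest.approx(1.0)

    def test_hand_worked_example(self):
        s = midse([0.1, 0.1, 0.9, 0.9], [0.1, 0.9, 0.9, 0.9], 2)
        assert s.midse == pytest.approx(0.0488, abs=5e-5)
        assert s.h_active == pytest.approx(1.0)
        assert s.h_inactive == pytest.approx(0.8113, abs=5e-5)
        assert s.h_combined == pytest.approx(0.9544, abs=5e-5)

    def test_score_consistency_invariant(self):
        s = midse([0.1, 0.4, 0.9], [0.2, 0.3, 0.8], 3)
        assert s.midse == pytest.approx(
            s.h_combined - (s.h_active + s.h_inactive) / 2, abs=1e-9)

    def test_class_size_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=30)
        b = rng.normal(loc=1.0, size=20)
        base = midse(a, b, 10).midse
        for r in (2, 5, 10):
            assert midse(np.tile(a, r), b, 10).midse == pytest.approx(
                base, abs=1e-9)
            assert midse(a, np.tile(b, r), 10).midse == pytest.approx(
                base, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=15), rng.normal(size=25)
        assert midse(a, b, 8).midse == pytest.approx(midse(b, a, 8).midse,
                                                     abs=1e-12)

    @given(
        a=st.lists(st.floats(-50, 50), min_size=2, max_size=20),
        b=st.lists(st.floats(-50, 50), min_size=2, max_size=20),
        n_bins=st.integers(2, 12),
    )
    @settings(max_examples=150, deadline=None)
    def test_range_and_oracle(self, a, b, n_bins):
        s = midse(a, b, n_bins)
        assert 0.0 <= s.midse <= 1.0
        assert s.midse == pytest.approx(brute_force_midse(a, b, n_bins),
                                        abs=1e-9)


def _table(frame, tags=None):
    return DescriptorTable(frame=frame, dimension_tags=tags or {}, set_tag="2D")


class TestStructuralKeys:
    def _mk(self, freqs, n_act=20, n_ina=20, names=None):
        rng = np.random.default_rng(0)
        cols = {}
        for i, (fa, fi) in enumerate(freqs):
            name = names[i] if names else f"d{i}"
            col = rng.normal(size=n_act + n_ina)
            na = int(round(fa * n_act))
            ni = int(round(fi * n_ina))
            col[:na] = np.nan
            col[n_act:n_act + ni] = np.nan
            cols[name] = col
        frame = pd.DataFrame(cols, index=[f"c{i}" for i in range(n_act + n_ina)])
        labels = np.array([1] * n_act + [0] * n_ina)
        return _table(frame), labels

    def test_large_discrepancy_retained(self):
        table, labels = self._mk([(0.9, 0.2)])
        keys = select_structural_keys(table, labels)
        assert [k.descriptor_name for k in keys] == ["d0"]
        assert keys[0].absence_freq_active == pytest.approx(0.9)
        assert keys[0].absence_freq_inactive == pytest.approx(0.2)

    def test_small_discrepancy_dropped(self):
        table, labels = self._mk([(0.55, 0.45)])
        assert select_structural_keys(table, labels) == []

    def test_boundary_inclusive(self):
        table, labels = self._mk([(0.4, 0.2)])
        assert len(select_structural_keys(table, labels)) == 1

    def test_min_max_pair_keeps_only_max(self):
        table, labels = self._mk([(0.9, 0.1), (0.9, 0.1)],
                                 names=["MINtsC", "MAXtsC"])
        keys = select_structural_keys(table, labels)
        assert [k.descriptor_name for k in keys] == ["MAXtsC"]

    def test_min_without_max_twin_is_eligible(self):
        table, labels = self._mk([(0.9, 0.1)], names=["MINxyz"])
        assert [k.descriptor_name
                for k in select_structural_keys(table, labels)] == ["MINxyz"]

    def test_sum_estate_excluded(self):
        table, labels = self._mk([(0.9, 0.1)], names=["SdO"])
        assert select_structural_keys(table, labels) == []

    def test_3d_descriptors_ignored(self):
        table, labels = self._mk([(0.9, 0.1)])
        table.dimension_tags["d0"] = "3D"
        assert select_structural_keys(table, labels) == []


class TestSelectContinuous:
    def _two_descriptor_table(self, rho):
        rng = np.random.default_rng(42)
        n_act, n_ina = 60, 60
        # strong: well-separated classes; weak: less separated
        strong = np.concatenate([rng.normal(3, 1, n_act), rng.normal(0, 1, n_ina)])
        weak = rho * strong + math.sqrt(max(1 - rho * rho, 0)) * rng.normal(
            0, 1, n_act + n_ina) + 0.5
        frame = pd.DataFrame({"strong": strong, "weak": weak},
                             index=[f"c{i}" for i in range(n_act + n_ina)])
        labels = np.array([1] * n_act + [0] * n_ina)
        return _table(frame), labels

    def test_perfectly_correlated_keeps_higher_score(self):
        table, labels = self._two_descriptor_table(rho=1.0)
        sel = select_continuous_features(table, labels, min_score=0.0)
        assert sel.descriptor_names == ["strong"]

    def test_below_cut_keeps_both(self):
        table, labels = self._two_descriptor_table(rho=0.5)
        sel = select_continuous_features(table, labels, min_score=0.0)
        assert set(sel.descriptor_names) == {"strong", "weak"}

    def test_cap_at_max_n(self):
        rng = np.random.default_rng(9)
        n_act, n_ina = 80, 80
        shift = np.concatenate([np.full(n_act, 4.0), np.zeros(n_ina)])
        cols = {f"d{i:02d}": shift + rng.normal(0, 1, n_act + n_ina)
                for i in range(60)}
        frame = pd.DataFrame(cols, index=[f"c{i}" for i in range(160)])
        labels = np.array([1] * n_act + [0] * n_ina)
        sel = select_continuous_features(_table(frame), labels,
                                         max_n=50, pcc_cut=1.1)
        assert len(sel.continuous_descriptors) == 50
        scores = [fs.midse for fs in sel.continuous_descriptors]
        assert scores == sorted(scores, reverse=True)

    def test_min_score_threshold(self, descriptor_table):
        table, labels = descriptor_table
        sel = select_continuous_features(table, labels, min_score=0.99)
        assert sel.continuous_descriptors == []

    def test_posthoc_invariants(self, small_synthetic):
        table, labels, _ = small_synthetic
        sel = select_continuous_features(table, labels, min_score=0.1)
        names = sel.descriptor_names
        assert len(names) <= 50
        assert all(fs.midse >= 0.1 for fs in sel.continuous_descriptors)
        # exhaustive pairwise PCC check on pairwise-complete observations
        frame = table.frame
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                x = frame[a].to_numpy(float)
                y = frame[b].to_numpy(float)
                m = np.isfinite(x) & np.isfinite(y)
                pcc = np.corrcoef(x[m], y[m])[0, 1]
                assert abs(pcc) < 0.8

    def test_planted_informative_beats_noise(self, small_synthetic):
        table, labels, manifest = small_synthetic
        frame = table.frame
        act, ina = labels == 1, labels == 0

        def score(name):
            col = frame[name].to_numpy(float)
            return midse(col[act], col[ina], 10).midse

        worst_inf = min(score(n) for n in manifest["informative"])
        best_noise = max(score(n) for n in manifest["noise"])
        assert worst_inf > best_noise

    def test_selection_json_roundtrip(self, small_synthetic):
        from bbbkit.feature_selection import FeatureSelection

        table, labels, _ = small_synthetic
        keys = select_structural_keys(table, labels)
        sel = select_continuous_features(table, labels, structural_keys=keys)
        back = FeatureSelection.from_json(sel.to_json())
        assert back.descriptor_names == sel.descriptor_names
        assert back.structural_key_names == sel.structural_key_names
        assert [f.midse for f in back.continuous_descriptors] == [
            f.midse for f in sel.continuous_descriptors]
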