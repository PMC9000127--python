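"""ICA block: subset enumeration, separation quality, role assignment."""

import numpy as np
import pytest

import fecghybrid as fh
from fecghybrid.errors import RoleAssignmentError, ValidationError

FS = 500.0


def two_source_mixture(seed=0, duration=30.0):
    m, _ = fh.generate_single_ecg(FS, duration, 75, 2.0, seed=1)
    f, _ = fh.generate_single_ecg(FS, duration, 140, 2.0, seed=2)
    m = (m - m.mean()) / m.std()
    f = (f - f.mean()) / f.std()
    A = np.array([[1.0, 0.4], [0.6, 1.0]])
    X = np.column_stack([m, f]) @ A.T
    rec = fh.MultichannelRecord(X, FS, ["c0", "c1"])
    return rec, m, f


class TestSubsets:
    @pytest.mark.parametrize("n,count", [(2, 1), (4, 11), (6, 57)])
    def test_counts(self, n, count):
        assert len(fh.select_channel_subsets(n)) == count

    def test_order_by_size_then_lexicographic(self):
        subs = [s.indices for s in fh.select_channel_subsets(4)]
        assert subs[:3] == [(0, 1), (0, 2), (0, 3)]
        assert subs[-1] == (0, 1, 2, 3)
        sizes = [len(s) for s in subs]
        assert sizes == sorted(sizes)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValidationError):
            fh.select_channel_subsets(1)

    def test_subset_type_invariants(self):
        s = fh.ChannelSubset((3, 1, 3))
        assert s.indices == (1, 3)
        with pytest.raises(ValidationError):
            fh.ChannelSubset((2,))


class TestSeparate:
    def test_recovers_sources_on_noiseless_mixture(self):
        rec, m, f = two_source_mixture()
        out = fh.separate(rec, seed=0)
        corr = np.abs(np.corrcoef(
            np.column_stack([m, f]).T, out.components.T))[:2, 2:]
        # best assignment: each source matched by some component
        assert corr.max(axis=1).min() > 0.95

    def test_components_unit_variance_positive_extremum(self):
        rec, *_ = two_source_mixture()
        out = fh.separate(rec, seed=0)
        np.testing.assert_allclose(out.components.std(axis=0), 1.0, atol=1e-6)
        for j in range(out.k):
            col = out.components[:, j]
            assert col.max() >= abs(col.min())

    def test_fixed_seed_bit_identical(self):
        rec, *_ = two_source_mixture()
        a = fh.separate(rec, seed=3)
        b = fh.separate(rec, seed=3)
        assert np.array_equal(a.unmixing, b.unmixing)
        assert np.array_equal(a.components, b.components)

    def test_channel_permutation_recovers_same_components(self):
        rec, *_ = two_source_mixture()
        perm = fh.MultichannelRecord(rec.samples[:, ::-1], FS, ["c1", "c0"])
        a = fh.separate(rec, seed=0).components
        b = fh.separate(perm, seed=0).components
        corr = np.abs(np.corrcoef(a.T, b.T))[:2, 2:]
        assert corr.max(axis=1).min() > 0.99

    def test_rank_deficient_rejected(self):
        x = np.random.default_rng(0).standard_normal(2000)
        rec = fh.MultichannelRecord(np.column_stack([x, 2 * x]), FS, ["a", "b"])
        with pytest.raises(ValidationError):
            fh.separate(rec, seed=0)


class TestAssignRoles:
    def make_outputs(self, cols):
        S = np.column_stack([c / c.std() for c in cols])
        return fh.ICAOutputs(components=S, unmixing=np.eye(S.shape[1]))

    def test_pure_trains_assigned_by_rate(self):
        m, _ = fh.generate_single_ecg(FS, 60, 75, 0.0, seed=1)
        f, _ = fh.generate_single_ecg(FS, 60, 140, 0.0, seed=2)
        out = fh.assign_roles(self.make_outputs([m, f]), FS)
        assert out.roles == {0: "mECG*", 1: "aECG*"}
        assert out.rate_bpm[0] == pytest.approx(75, abs=3)
        assert out.rate_bpm[1] == pytest.approx(140, abs=5)

    def test_invariant_to_permutation_and_sign(self):
        m, _ = fh.generate_single_ecg(FS, 60, 75, 0.0, seed=1)
        f, _ = fh.generate_single_ecg(FS, 60, 140, 0.0, seed=2)
        a = fh.assign_roles(self.make_outputs([m, f]), FS)
        b = fh.assign_roles(self.make_outputs([-f, m]), FS)
        assert a.roles[0] == "mECG*" and b.roles[1] == "mECG*"
        assert a.roles[1] == "aECG*" and b.roles[0] == "aECG*"

    def test_white_noise_components_rejected(self):
        rng = np.random.default_rng(0)
        out = self.make_outputs([rng.standard_normal(20000),
                                 rng.standard_normal(20000)])
        with pytest.raises(RoleAssignmentError):
            fh.assign_roles(out, FS)

    def test_mecg_aecg_accessors(self):
        m, _ = fh.generate_single_ecg(FS, 60, 75, 0.0, seed=1)
        f, _ = fh.generate_single_ecg(FS, 60, 140, 0.0, seed=2)
        out = fh.assign_roles(self.make_outputs([m, f]), FS)
        assert out.mecg.shape == out.aecg.shape


class TestBestSubset:
    def test_single_subset_returned(self, monkeypatch):
        import fecghybrid.pipeline as pl
        calls = []

        def fake_run(record, subset, config, reference=None):
            calls.append(subset.indices)
            return None, None, fh.EvaluationReport(tp=9, fp=1, fn=1, f1=90.0)

        monkeypatch.setattr(pl, "run_extraction", fake_run)
        rec = fh.MultichannelRecord(np.random.default_rng(0)
                                    .standard_normal((100, 2)), FS, ["a", "b"])
        sub, f1v = fh.best_subset(rec, None)
        assert sub.indices == (0, 1) and f1v == 90.0

    def test_tie_breaks_to_earlier_subset(self, monkeypatch):
        import fecghybrid.pipeline as pl

        def fake_run(record, subset, config, reference=None):
            return None, None, fh.EvaluationReport(tp=9, fp=1, fn=1, f1=90.0)

        monkeypatch.setattr(pl, "run_extraction", fake_run)
        rec = fh.MultichannelRecord(np.random.default_rng(0)
                                    .standard_normal((100, 3)), FS,
                                    ["a", "b", "c"])
        sub, _ = fh.best_subset(rec, None)
        assert sub.indices == (0, 1)

    def test_winner_at_least_as_good_as_signal_pair(self):
        spec = fh.SyntheticSpec(duration_s=60, n_channels=2, seed=3)
        record, fetal_ann, *_ = fh.generate_recording(spec)
        rng = np.random.default_rng(11)
        noise = 0.5 * rng.standard_normal(record.n_samples)
        rec3 = fh.MultichannelRecord(
            np.column_stack([record.samples, noise]), spec.fs,
            ["a", "b", "noise"])
        sub, f1v = fh.best_subset(rec3, fetal_ann)
        _, _, rep01 = fh.run_extraction(rec3, fh.ChannelSubset((0, 1)),
                                        fh.PipelineConfig(),
                                        reference=fetal_ann)
        assert f1v >= rep01.f1
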