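import numpy as np
import pytest

from swirtrack import (
    ChannelSet,
    CrosstalkMatrix,
    FrameStack,
    crosstalk_report,
    unmix_pixelwise,
)


def channel_set(arrays, labels=None):
    labels = labels or [f"ch{i}" for i in range(len(arrays))]
    members = {
        l: FrameStack(np.asarray(a, dtype=np.float64), exposure_ms=7.8,
                      channel_label=l)
        for l, a in zip(labels, arrays)
    }
    return ChannelSet(channels=members, cycle_length=len(arrays), source_offset=0)


class TestUnmixPixelwise:
    def test_identity_matrix_is_identity_map(self, rng):
        arrays = [rng.integers(0, 1000, (3, 4, 4)).astype(float) for _ in range(2)]
        M = CrosstalkMatrix.identity(("ch0", "ch1"))
        out = unmix_pixelwise(channel_set(arrays), M)
        for i, label in enumerate(("ch0", "ch1")):
            assert np.allclose(out.channels[label].data, arrays[i], atol=1e-9)

    def test_known_mixture_recovered_exactly(self):
        """Oracle: forward-mix known abundances, solve back (noiseless)."""
        M = CrosstalkMatrix(
            np.array([[1.0, 0.2], [0.1, 1.0]]), ("ch0", "ch1"), ("dyeA", "dyeB")
        )
        a_true = np.array([10.0, 5.0])
        mixed = M.matrix @ a_true  # per-pixel observation
        arrays = [np.full((2, 3, 3), mixed[c]) for c in range(2)]
        out = unmix_pixelwise(channel_set(arrays), M)
        assert np.allclose(out.channels["dyeA"].data, 10.0, atol=1e-9)
        assert np.allclose(out.channels["dyeB"].data, 5.0, atol=1e-9)

    def test_unconstrained_solve_is_linear(self, rng):
        M = CrosstalkMatrix(
            np.array([[1.0, 0.3], [0.2, 1.0]]), ("ch0", "ch1"), ("dyeA", "dyeB")
        )
        x = [rng.random((2, 3, 3)) * 100 for _ in range(2)]
        y = [rng.random((2, 3, 3)) * 100 for _ in range(2)]
        combo = [2.0 * a + 3.0 * b for a, b in zip(x, y)]
        out_combo = unmix_pixelwise(channel_set(combo), M)
        out_x = unmix_pixelwise(channel_set(x), M)
        out_y = unmix_pixelwise(channel_set(y), M)
        for f in ("dyeA", "dyeB"):
            expected = 2.0 * out_x.channels[f].data + 3.0 * out_y.channels[f].data
            assert np.allclose(out_combo.channels[f].data, expected, atol=1e-8)

    def test_nonneg_solution_satisfies_kkt(self):
        """Active-set contract: at the NNLS solution, clamped abundances have
        non-positive gradient (KKT) and free ones have zero gradient."""
        M = CrosstalkMatrix(
            np.array([[1.0, 0.9], [0.9, 1.0]]), ("ch0", "ch1"), ("dyeA", "dyeB")
        )
        # observation pulling one abundance negative in the OLS solution
        obs = np.array([1.0, 0.0])
        arrays = [np.full((1, 2, 2), obs[c]) for c in range(2)]
        free = unmix_pixelwise(channel_set(arrays), M)
        assert free.channels["dyeB"].data.min() < 0  # OLS goes negative
        out = unmix_pixelwise(channel_set(arrays), M, nonneg=True)
        a = np.array(
            [out.channels["dyeA"].data[0, 0, 0], out.channels["dyeB"].data[0, 0, 0]]
        )
        assert np.all(a >= 0)
        grad = M.matrix.T @ (M.matrix @ a - obs)
        for j in range(2):
            if a[j] > 1e-12:
                assert abs(grad[j]) < 1e-9
            else:
                assert grad[j] >= -1e-9

    def test_rank_deficient_matrix_reports_condition(self):
        M = CrosstalkMatrix(
            np.array([[1.0, 1.0], [1.0, 1.0]]), ("ch0", "ch1"), ("dyeA", "dyeB")
        )
        with pytest.raises(ValueError, match="condition number"):
            unmix_pixelwise(channel_set([np.ones((1, 2, 2))] * 2), M)

    def test_more_fluorophores_than_channels_rejected(self):
        M = CrosstalkMatrix(
            np.array([[1.0, 0.5, 0.2]]), ("ch0",), ("a", "b", "c")
        )
        with pytest.raises(ValueError, match="underdetermined"):
            unmix_pixelwise(channel_set([np.ones((1, 2, 2))]), M)

    def test_abundance_error_decreases_with_noise(self):
        """Recovery error shrinks as shot noise shrinks (two noise levels)."""
        M = CrosstalkMatrix(
            np.array([[1.0, 0.25], [0.2, 1.0]]), ("ch0", "ch1"), ("dyeA", "dyeB")
        )
        a_true = np.array([400.0, 250.0])
        expected = M.matrix @ a_true
        rng = np.random.default_rng(13)
        errs = []
        for scale in (1.0, 25.0):
            arrays = [
                rng.poisson(expected[c] * scale, size=(4, 12, 12)) / scale
                for c in range(2)
            ]
            out = unmix_pixelwise(channel_set(arrays), M)
            err = sum(
                abs(float(out.channels[f].data.mean()) - a_true[i])
                for i, f in enumerate(("dyeA", "dyeB"))
            )
            errs.append(err)
        assert errs[1] < errs[0]


class TestCrosstalkReport:
    def make_channels(self, M, abundance=500.0, noise=0.0, seed=3):
        """Two blobs, each pure in its own fluorophore region."""
        rng = np.random.default_rng(seed)
        H = W = 20
        regions = {
            "dyeA": np.zeros((H, W), bool),
            "dyeB": np.zeros((H, W), bool),
        }
        regions["dyeA"][4:8, 4:8] = True
        regions["dyeB"][12:16, 12:16] = True
        arrays = []
        for c in range(2):
            img = np.zeros((H, W))
            img[regions["dyeA"]] = M[c, 0] * abundance
            img[regions["dyeB"]] = M[c, 1] * abundance
            frames = np.repeat(img[None], 5, axis=0)
            if noise:
                frames = frames + rng.normal(0, noise, frames.shape)
                frames = np.clip(frames, 0, None)
            arrays.append(frames)
        return channel_set(arrays), regions

    def test_zero_crosstalk_yields_identity(self):
        M = np.eye(2)
        channels, regions = self.make_channels(M)
        est = crosstalk_report(channels, regions)
        assert np.allclose(est.matrix, np.eye(2), atol=1e-12)

    def test_off_diagonal_recovered_within_tolerance_at_snr20(self):
        M = np.array([[1.0, 0.2], [0.2, 1.0]])
        # SNR 20: signal 500, noise σ 25
        channels, regions = self.make_channels(M, abundance=500.0, noise=25.0)
        est = crosstalk_report(channels, regions)
        assert np.all(np.abs(est.matrix - M) < 0.05)

    def test_empty_region_rejected(self):
        channels, regions = self.make_channels(np.eye(2))
        regions["dyeA"][:] = False
        with pytest.raises(ValueError, match="empty"):
            crosstalk_report(channels, regions)

    def test_signal_free_region_rejected(self):
        channels, regions = self.make_channels(np.eye(2))
        dark = np.zeros_like(regions["dyeA"])
        dark[0:2, 0:2] = True  # background-only corner
        with pytest.raises(ValueError, match="no signal"):
            crosstalk_report(channels, {"dyeA": dark, "dyeB": regions["dyeB"]})


class TestCrosstalkMatrixCsv:
    def test_csv_round_trip(self, tmp_path):
        M = CrosstalkMatrix(
            np.array([[1.0, 0.3], [0.15, 1.0]]), ("ch0", "ch1"), ("dyeA", "dyeB")
        )
        path = tmp_path / "M.csv"
        M.to_csv(path)
        back = CrosstalkMatrix.from_csv(path)
        assert back.channel_labels == M.channel_labels
        assert back.fluor_labels == M.fluor_labels
        assert np.allclose(back.matrix, M.matrix)
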