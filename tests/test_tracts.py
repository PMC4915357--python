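import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixhist.io import MASKED, UNRESOLVED, LocalAncestryPanel, WindowGrid
from admixhist.simulate import (
    AdmixtureHistorySpec,
    desk_genome,
    expected_tract_length,
    simulate_history,
)
from admixhist.tracts import (
    SignalError,
    block_lengths,
    encode_signal,
    haar_power,
    mask_ancestry,
    merge_ancestries,
    wavelet_center,
)


def _panel(grid, calls, labels=("EUR", "WSIB", "CSIB", "EAS")):
    calls = np.asarray(calls, dtype=np.int16)
    return LocalAncestryPanel(
        [f"h{i}" for i in range(calls.shape[0])], grid, list(labels), calls
    )


class TestMergeAncestries:
    def test_older_labels_collapse_to_population_one(self, small_genome):
        _, grid = small_genome
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 4, size=(4, grid.total_windows))
        panel = _panel(grid, calls)
        merged = merge_ancestries(panel, {"EUR", "WSIB", "CSIB"}, "EAS")
        assert merged.labels == ["pop1", "pop2"]
        frac_pop1 = (merged.calls == 0).mean()
        frac_older = (calls < 3).mean()
        assert frac_pop1 == pytest.approx(frac_older)

    def test_binary_panel_identity(self, small_genome):
        _, grid = small_genome
        calls = np.zeros((2, grid.total_windows), dtype=np.int16)
        calls[1] = 1
        panel = _panel(grid, calls, labels=("pop1", "pop2"))
        merged = merge_ancestries(panel, {"pop1"}, "pop2")
        np.testing.assert_array_equal(merged.calls, panel.calls)

    def test_stray_label_named_in_error(self, small_genome):
        _, grid = small_genome
        calls = np.zeros((1, grid.total_windows), dtype=np.int16)
        calls[0, 5] = 3
        panel = _panel(grid, calls, labels=("EUR", "WSIB", "CSIB", "X"))
        with pytest.raises(SignalError, match="X"):
            merge_ancestries(panel, {"EUR", "WSIB"}, "CSIB")

    def test_masked_and_unresolved_preserved(self, small_genome):
        _, grid = small_genome
        calls = np.zeros((1, grid.total_windows), dtype=np.int16)
        calls[0, 0] = MASKED
        calls[0, 1] = UNRESOLVED
        calls[0, 2] = 3
        panel = _panel(grid, calls)
        merged = merge_ancestries(panel, {"EUR", "WSIB", "CSIB"}, "EAS")
        assert merged.calls[0, 0] == MASKED
        assert merged.calls[0, 1] == UNRESOLVED
        assert merged.calls[0, 2] == 1


class TestEncodeSignal:
    def test_encoding_values(self, small_genome):
        _, grid = small_genome
        calls = np.zeros((1, grid.total_windows), dtype=np.int16)
        calls[0, :10] = 1
        calls[0, 10:20] = MASKED
        panel = _panel(grid, calls, labels=("pop1", "pop2"))
        sig = encode_signal(panel, grid)
        assert (sig[0, :10] == 1.0).all()
        assert (sig[0, 10:20] == 0.0).all()
        assert (sig[0, 20:] == -1.0).all()

    def test_multiway_panel_rejected(self, small_genome):
        _, grid = small_genome
        calls = np.zeros((1, grid.total_windows), dtype=np.int16)
        panel = _panel(grid, calls)
        with pytest.raises(SignalError, match="merge"):
            encode_signal(panel, grid)


class TestHaarPower:
    def test_single_coarse_step(self):
        x = np.array([1, 1, 1, 1, -1, -1, -1, -1], dtype=float)
        p = haar_power(x)
        norm = p * np.array([4, 2, 1]) / 8
        norm = norm / norm.sum()
        assert norm == pytest.approx([0.0, 0.0, 1.0])

    def test_finest_alternation(self):
        x = np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
        p = haar_power(x)
        assert p[0] > 0 and p[1] == 0 and p[2] == 0

    def test_constant_signal_all_zero(self):
        assert haar_power(np.ones(16)) == pytest.approx(np.zeros(4))

    def test_non_power_of_two_rejected(self):
        with pytest.raises(SignalError):
            haar_power(np.ones(12))

    @settings(max_examples=30, deadline=None)
    @given(
        n=st.integers(2, 6),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_parseval_identity(self, n, seed):
        """Coefficient-count-weighted power sums to the population variance."""
        rng = np.random.default_rng(seed)
        x = rng.choice([-1.0, 0.0, 1.0], size=2**n)
        p = haar_power(x)
        counts = 2 ** (n - 1 - np.arange(n))  # coefficients per scale, fine->coarse
        total = np.sum(p * counts) / 2**n
        assert abs(total - x.var()) < 1e-9


class TestWaveletCenter:
    def test_half_split_center_is_coarsest(self, genome):
        _, grid = genome
        n = grid.n_scales("1")
        sig = np.ones((2, grid.total_windows))
        for chrom in grid.chromosomes:
            sl = grid.chrom_slice(chrom)
            half = (sl.stop - sl.start) // 2
            sig[:, sl.start + half:sl.stop] = -1.0
        ws = wavelet_center(sig, grid)
        assert ws.center == pytest.approx(n)

    def test_pooling_invariance(self):
        # duplicating a chromosome's signal across two chromosomes leaves the
        # pooled center unchanged
        _, grid1 = desk_genome(n_chromosomes=1, length_cm=64.0, windows=64)
        _, grid2 = desk_genome(n_chromosomes=2, length_cm=64.0, windows=64)
        rng = np.random.default_rng(1)
        row = rng.choice([-1.0, 1.0], size=64)
        c1 = wavelet_center(row[None, :], grid1).center
        c2 = wavelet_center(np.concatenate([row, row])[None, :], grid2).center
        assert c1 == pytest.approx(c2)

    def test_mixed_window_schemes_align_on_genetic_width(self):
        # the same physical half/half pattern on chromosomes with different
        # window counts pools to the same genetic scale
        gmap, _ = desk_genome(n_chromosomes=2, length_cm=64.0)
        grid = WindowGrid(["1", "2"], {"1": 64, "2": 32}, {"1": 64.0, "2": 64.0})
        sig = np.ones((1, grid.total_windows))
        sig[0, 32:64] = -1.0   # second half of chrom 1 (64 windows)
        sig[0, 64 + 16:] = -1.0  # second half of chrom 2 (32 windows)
        ws = wavelet_center(sig, grid)
        # all energy at the 64-cM block width on both chromosomes
        w = ws.scale_widths_cm[ws.powers > 1e-12]
        assert w == pytest.approx([64.0])

    def test_constant_everything_errors(self, small_genome):
        _, grid = small_genome
        with pytest.raises(SignalError, match="single ancestry"):
            wavelet_center(np.ones((3, grid.total_windows)), grid)

    def test_older_admixture_has_finer_center(self, genome):
        gmap, grid = genome
        centers = {}
        for g in (20, 100):
            spec = AdmixtureHistorySpec(
                g, ("pop1", "pop2"), 0.7, population_size=300, sample_size=20
            )
            s = simulate_history(spec, gmap, grid, seed=40 + g, build_tracts=False)
            centers[g] = wavelet_center(encode_signal(s.panel, grid), grid).center
        assert centers[100] < centers[20]


class TestBlockLengths:
    def test_run_length_arithmetic(self):
        _, grid = desk_genome(n_chromosomes=1, length_cm=128.0, windows=256)
        calls = np.zeros((1, 256), dtype=np.int16)
        calls[0, 100:110] = 1
        panel = _panel(grid, calls, labels=("bg", "C"))
        bl = block_lengths(panel, grid)
        assert bl.lengths["C"].tolist() == [5.0]

    def test_masked_windows_split_runs(self):
        _, grid = desk_genome(n_chromosomes=1, length_cm=128.0, windows=256)
        calls = np.zeros((1, 256), dtype=np.int16)
        calls[0, 100:110] = 1
        calls[0, 104] = MASKED
        panel = _panel(grid, calls, labels=("bg", "C"))
        bl = block_lengths(panel, grid)
        assert sorted(bl.lengths["C"].tolist()) == [2.0, 2.5]

    def test_all_masked_contributes_nothing(self, small_genome):
        _, grid = small_genome
        calls = np.full((2, grid.total_windows), MASKED, dtype=np.int16)
        panel = _panel(grid, calls, labels=("bg", "C"))
        bl = block_lengths(panel, grid)
        assert bl.lengths["C"].size == 0 and bl.lengths["bg"].size == 0

    def test_simulated_mean_block_length_near_closed_form(self):
        # fine grid (0.125 cM windows) keeps rasterization quantization small
        gmap, grid = desk_genome(n_chromosomes=8, length_cm=128.0, windows=1024)
        spec = AdmixtureHistorySpec(
            50, ("A", "B"), 0.8, population_size=1000, sample_size=60
        )
        s = simulate_history(spec, gmap, grid, seed=77, build_tracts=False)
        bl = block_lengths(s.panel, grid, ancestries=["B"])
        assert bl.mean("B") == pytest.approx(expected_tract_length(50, 0.2), rel=0.10)


class TestMaskAncestry:
    def test_masked_fraction_arithmetic(self):
        _, grid = desk_genome(n_chromosomes=1, length_cm=128.0, windows=1024)
        calls = np.zeros((1, 1024), dtype=np.int16)
        calls[0, :256] = 1
        panel = _panel(grid, calls, labels=("bg", "recent"))
        masked, pos, frac = mask_ancestry(panel, "recent")
        assert frac == 0.25
        assert pos.sum() == 256
        assert (masked.calls[0, :256] == MASKED).all()

    def test_absent_label_errors(self, small_genome):
        _, grid = small_genome
        calls = np.zeros((1, grid.total_windows), dtype=np.int16)
        panel = _panel(grid, calls, labels=("bg", "C"))
        with pytest.raises(SignalError, match="C"):
            mask_ancestry(panel, "C")

    def test_double_masking_additive(self, small_genome):
        _, grid = small_genome
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(3, grid.total_windows)).astype(np.int16)
        panel = _panel(grid, calls, labels=("a", "b", "c"))
        p1, _, f1 = mask_ancestry(panel, "b")
        p2, _, f2 = mask_ancestry(p1, "c")
        assert f1 + f2 == pytest.approx(p2.masked_fraction)

    def test_masking_preserves_other_ancestry_blocks(self):
        _, grid = desk_genome(n_chromosomes=1, length_cm=128.0, windows=256)
        calls = np.zeros((1, 256), dtype=np.int16)
        calls[0, 50:60] = 1
        calls[0, 100:120] = 2
        panel = _panel(grid, calls, labels=("a", "b", "c"))
        before = block_lengths(panel, grid, ancestries=["b"]).lengths["b"]
        masked, _, _ = mask_ancestry(panel, "c")
        after = block_lengths(masked, grid, ancestries=["b"]).lengths["b"]
        np.testing.assert_array_equal(before, after)
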