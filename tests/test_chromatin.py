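"""Promoter binning, the positivity rule, class statistics, strata."""

import numpy as np
import pandas as pd
import pytest

from prc2screen import (
    ChromConfig,
    SimConfig,
    bin_promoter_signal,
    call_positivity,
    control_levels,
    expression_strata,
    fisher_exact_2x2,
    h3k27me3_positive,
    mann_whitney_u,
    meta_profile,
    simulate_chromatin,
    simulate_experiment,
)
from prc2screen.io import SignalTrack, TssAnnotation, read_bedgraph


def tss_of(genes: dict[str, tuple[str, int, str]]) -> TssAnnotation:
    return TssAnnotation(
        pd.DataFrame.from_dict(genes, orient="index", columns=["chrom", "tss", "strand"])
    )


def brute_force_bin_means(starts, ends, values, win_start, win_end, bin_width):
    """Per-base oracle: expand the track and average each bin."""
    base = np.zeros(max(win_end, int(max(ends))) + 1)
    for s, e, v in zip(starts, ends, values):
        base[int(s):int(e)] = v
    out = []
    for b0 in range(win_start, win_end, bin_width):
        window = [base[p] if p >= 0 else 0.0 for p in range(b0, b0 + bin_width)]
        out.append(float(np.mean(window)))
    return np.array(out)


class TestBinning:
    def test_constant_track_all_bins_equal(self):
        track = SignalTrack({"c": (np.array([0]), np.array([20000]), np.array([3.0]))})
        mat = bin_promoter_signal(track, tss_of({"g": ("c", 10000, "+")}), 5000, 100)
        assert np.allclose(mat.values.loc["g"], 3.0)

    def test_partial_interval_coverage_weighted(self):
        # value 4 over [1000, 1050) inside bin [1000, 1100) -> mean 2.0
        track = SignalTrack({"c": (np.array([1000]), np.array([1050]), np.array([4.0]))})
        mat = bin_promoter_signal(track, tss_of({"g": ("c", 1000, "+")}), 1000, 100)
        row = mat.values.loc["g"].to_numpy()
        assert row[10] == pytest.approx(2.0)  # bin starting at offset 0
        assert row[:10].sum() == 0 and row[11:].sum() == 0

    def test_minus_strand_row_is_reverse_of_plus(self):
        rng = np.random.default_rng(3)
        starts = np.arange(0, 20000, 200)
        track = SignalTrack({"c": (starts, starts + 200, rng.random(len(starts)))})
        tss = tss_of({"p": ("c", 10000, "+"), "m": ("c", 10000, "-")})
        mat = bin_promoter_signal(track, tss, 5000, 100)
        assert np.allclose(
            mat.values.loc["p"].to_numpy(), mat.values.loc["m"].to_numpy()[::-1]
        )

    def test_agrees_with_per_base_oracle(self):
        rng = np.random.default_rng(7)
        edges = np.sort(rng.choice(np.arange(500, 4000), size=10, replace=False))
        starts, ends = edges[:-1:2], edges[1::2]
        values = rng.random(len(starts)) * 5
        track = SignalTrack({"c": (starts, ends, values)})
        mat = bin_promoter_signal(track, tss_of({"g": ("c", 2000, "+")}), 1000, 100)
        oracle = brute_force_bin_means(starts, ends, values, 1000, 3000, 100)
        assert np.allclose(mat.values.loc["g"].to_numpy(), oracle)

    def test_mass_conservation(self):
        rng = np.random.default_rng(9)
        starts = np.arange(0, 30000, 150)
        track = SignalTrack({"c": (starts, starts + 120, rng.random(len(starts)))})
        mat = bin_promoter_signal(track, tss_of({"g": ("c", 15000, "+")}), 5000, 100)
        integral = track.integral("c", np.array([20000]))[0] - track.integral(
            "c", np.array([10000])
        )[0]
        assert mat.values.loc["g"].sum() * 100 == pytest.approx(integral)

    def test_window_below_zero_clipped_and_flagged(self):
        track = SignalTrack({"c": (np.array([0]), np.array([5000]), np.array([2.0]))})
        mat = bin_promoter_signal(track, tss_of({"g": ("c", 100, "+")}), 1000, 100)
        assert bool(mat.clipped["g"])
        # most-upstream bin [-900 rel] covers bases -900..-800 -> all clipped
        assert mat.values.loc["g"].iloc[0] == 0.0


class TestPositivity:
    def test_below_threshold_negative(self):
        call = h3k27me3_positive(np.full(10, 1.4), control_level=1.0)
        assert not call.positive

    def test_single_bin_above_threshold_positive(self):
        bins = np.full(10, 0.5)
        bins[3] = 1.6
        assert h3k27me3_positive(bins, control_level=1.0).positive

    def test_boundary_ratio_inclusive(self):
        bins = np.full(10, 0.5)
        bins[0] = 1.5
        call = h3k27me3_positive(bins, control_level=1.0)
        assert call.positive and call.max_ratio == pytest.approx(1.5)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError, match="control_level"):
            h3k27me3_positive(np.ones(3), control_level=0.0)

    def test_planted_marks_recovered_and_noise_degrades(self):
        _, truth = simulate_experiment(SimConfig(n_genes=300, seed=21))
        marked = truth.table["chrom_state"].isin(["bivalent", "k27_only"])
        freqs = []
        for noise in (0.0, 0.3, 0.8):
            tracks, tss = simulate_chromatin(
                truth, ChromConfig(seed=4, noise_sigma=noise)
            )
            mat = bin_promoter_signal(tracks["h3k27me3"], tss, 5000, 100)
            pos = call_positivity(mat, control_levels(tracks["control"], tss), 1.5)
            freqs.append(pos.loc[marked[marked].index, "positive"].mean())
        assert freqs[0] == 1.0  # noise-free: every planted promoter called
        assert freqs[0] >= freqs[1] >= freqs[2]

    def test_trimmed_mean_fallback_control(self):
        track = read_bedgraph("c\t0\t10000\t2.0\n")
        levels = control_levels(None, tss_of({"g": ("c", 5000, "+")}), signal=track)
        assert levels["g"] == pytest.approx(2.0)


class TestMetaProfile:
    def test_group_of_identical_rows_returns_row(self):
        track = SignalTrack({"c": (np.array([0]), np.array([40000]), np.array([1.5]))})
        tss = tss_of({"a": ("c", 10000, "+"), "b": ("c", 30000, "+")})
        mat = bin_promoter_signal(track, tss, 1000, 100)
        prof = meta_profile(mat, {"grp": ["a", "b"]})
        assert np.allclose(prof["mean"], 1.5)
        assert np.allclose(prof["sd"], 0.0)

    def test_two_flat_groups_keep_levels(self):
        tr1 = SignalTrack({"c": (np.array([0]), np.array([40000]), np.array([1.0]))})
        tss = tss_of({"a": ("c", 10000, "+"), "b": ("c", 30000, "+")})
        mat = bin_promoter_signal(tr1, tss, 1000, 100)
        mat.values.loc["b"] *= 3.0
        prof = meta_profile(mat, {"lo": ["a"], "hi": ["b"]})
        assert np.allclose(prof.loc[prof["group"] == "lo", "mean"], 1.0)
        assert np.allclose(prof.loc[prof["group"] == "hi", "mean"], 3.0)

    def test_central_subwindow_selects_20_bins(self):
        track = SignalTrack({"c": (np.array([0]), np.array([40000]), np.array([1.0]))})
        mat = bin_promoter_signal(track, tss_of({"g": ("c", 20000, "+")}), 5000, 100)
        sub = mat.subwindow(1000)
        assert sub.n_bins == 20
        assert sub.offsets[0] == -1000 and sub.offsets[-1] == 900

    def test_empty_group_rejected(self):
        track = SignalTrack({"c": (np.array([0]), np.array([40000]), np.array([1.0]))})
        mat = bin_promoter_signal(track, tss_of({"g": ("c", 20000, "+")}), 1000, 100)
        with pytest.raises(ValueError, match="empty"):
            meta_profile(mat, {"grp": []})


class TestFisherExact:
    def test_printed_contingency(self):
        p, odds = fisher_exact_2x2([[15, 1], [4, 5]])
        assert p == pytest.approx(0.0119, abs=5e-5)
        assert p < 0.05
        assert odds == pytest.approx(75 / 4)

    def test_balanced_table_p_one(self):
        p, _ = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == 1.0

    def test_diagonal_table(self):
        p, odds = fisher_exact_2x2([[3, 0], [0, 3]])
        assert p == pytest.approx(0.1)  # 2 extreme tables of C(6,3) = 20
        assert np.isinf(odds)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fisher_exact_2x2([[1.5, 1], [2, 3]])


class TestMannWhitney:
    def test_separated_samples_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3) = 20 orderings

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_p_nonincreasing_with_shift(self):
        x = [1.0, 2.0, 3.0, 4.0]
        ps = [mann_whitney_u(x, [v + s for v in x])[1] for s in (0.5, 1.5, 3.5)]
        assert ps == sorted(ps, reverse=True)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


class TestExpressionStrata:
    def test_nine_genes_in_tertiles(self):
        basal = pd.Series(range(1, 10), index=[f"g{i}" for i in range(1, 10)],
                          dtype=float)
        strata = expression_strata(basal, silent_threshold=0.5)
        assert list(strata[[f"g{i}" for i in (1, 2, 3)]]) == ["low"] * 3
        assert list(strata[[f"g{i}" for i in (4, 5, 6)]]) == ["medium"] * 3
        assert list(strata[[f"g{i}" for i in (7, 8, 9)]]) == ["high"] * 3

    def test_all_below_threshold_silent(self):
        basal = pd.Series([0.1, 0.2], index=["a", "b"])
        assert (expression_strata(basal, 1.0) == "silent").all()

    def test_ties_resolved_by_gene_id_sizes_balanced(self):
        basal = pd.Series([2.0] * 7, index=[f"g{i}" for i in range(7)])
        strata = expression_strata(basal, 1.0)
        sizes = strata.value_counts()
        assert sizes.max() - sizes.min() <= 1
        # deterministic: first ids land in the lower stratum
        assert strata["g0"] == "low"

    def test_negative_basal_rejected(self):
        with pytest.raises(ValueError):
            expression_strata(pd.Series([-1.0], index=["g"]), 1.0)
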