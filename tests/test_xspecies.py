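"""Shared-peak detection: alignment projection, three-Spearman score, filters."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from gclipp.coverage import CoverageTrack
from gclipp.peakcall import gaussian_template
from gclipp.xspecies import (
    StringencyParams,
    _spearman,
    call_shared_peaks,
    load_alignment,
    passes_stringency,
    shared_score_profile,
)


def write_afa(tmp_path, seq_a, seq_b, name="pair.afa"):
    p = tmp_path / name
    p.write_text(f">a\n{seq_a}\n>b\n{seq_b}\n")
    return str(p)


def bump_track(utr_id, length, center, amp=50.0, sigma=10.0):
    pos = np.arange(length)
    depth = np.round(amp * np.exp(-((pos - center) ** 2) / (2 * sigma**2)))
    return CoverageTrack(utr_id, depth.astype(int))


class TestLoadAlignment:
    def test_gapless_alignment_is_identity_projection(self, tmp_path):
        path = write_afa(tmp_path, "ACGT", "ACGT")
        ta = CoverageTrack("a", np.array([1, 2, 3, 4]))
        tb = CoverageTrack("b", np.array([4, 3, 2, 1]))
        pair = load_alignment(path, ta, tb)
        assert np.array_equal(pair.raw_a, [1, 2, 3, 4])
        assert np.array_equal(pair.raw_b, [4, 3, 2, 1])
        assert np.array_equal(pair.pos_a, [0, 1, 2, 3])

    def test_gap_column_carries_zero_density(self, tmp_path):
        path = write_afa(tmp_path, "AC-GT", "ACCGT")
        ta = CoverageTrack("a", np.array([5, 5, 5, 5]))
        tb = CoverageTrack("b", np.array([7, 7, 7, 7, 7]))
        pair = load_alignment(path, ta, tb)
        assert pair.raw_a[2] == 0 and pair.norm_a[2] == 0
        assert pair.pos_a[2] == -1
        assert pair.raw_b[2] == 7

    def test_normalisation_is_fraction_of_utr_max(self, tmp_path):
        path = write_afa(tmp_path, "ACGT", "ACGT")
        ta = CoverageTrack("a", np.array([10, 20, 40, 0]))
        tb = CoverageTrack("b", np.array([0, 0, 0, 0]))
        pair = load_alignment(path, ta, tb)
        assert np.allclose(pair.norm_a, [0.25, 0.5, 1.0, 0.0])
        assert np.all(pair.norm_b == 0)  # zero-max UTR stays zero

    def test_three_record_fasta_rejected(self, tmp_path):
        p = tmp_path / "three.afa"
        p.write_text(">a\nAC\n>b\nAC\n>c\nAC\n")
        with pytest.raises(ValueError, match="exactly 2"):
            load_alignment(str(p), CoverageTrack("a", np.zeros(2, int)),
                           CoverageTrack("b", np.zeros(2, int)))

    def test_track_length_mismatch_names_record(self, tmp_path):
        path = write_afa(tmp_path, "ACGT", "ACGT")
        with pytest.raises(ValueError, match="'a'"):
            load_alignment(path, CoverageTrack("a", np.zeros(3, int)),
                           CoverageTrack("b", np.zeros(4, int)))


class TestSpearman:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, 40).astype(float)  # heavy ties
        y = rng.integers(0, 5, 40).astype(float)
        expected = spearmanr(x, y).statistic
        assert _spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_hand_ranked_window(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 3.0])
        tmpl = gaussian_template(5, 1.0)
        # average ranks: x -> [1, 2, 3.5, 5, 3.5]; template -> [1.5, 3.5, 5, 3.5, 1.5]
        rx = np.array([1, 2, 3.5, 5, 3.5])
        rt = np.array([1.5, 3.5, 5, 3.5, 1.5])
        expected = np.corrcoef(rx, rt)[0, 1]
        assert _spearman(x, tmpl) == pytest.approx(expected, abs=1e-12)

    def test_constant_input_is_undefined(self):
        assert np.isnan(_spearman(np.ones(5), np.arange(5.0)))

    def test_perfect_rank_reversal(self):
        x = np.arange(10.0)
        assert _spearman(x, -x) == pytest.approx(-1.0)


class TestScoreProfile:
    def test_identical_tracks_score_one_plus_twice_template_rho(self, tmp_path):
        n = 301
        seq = "A" * n
        path = write_afa(tmp_path, seq, seq)
        track = bump_track("a", n, 150)
        pair = load_alignment(path, track, CoverageTrack("b", track.depth.copy()))
        prof = shared_score_profile(pair)
        c = 150
        assert prof["rho_ab"].iloc[c] == pytest.approx(1.0)
        assert prof["score"].iloc[c] == pytest.approx(
            1.0 + 2 * prof["rho_a_tmpl"].iloc[c]
        )

    def test_opposed_monotone_windows_give_rho_ab_minus_one(self, tmp_path):
        n = 101
        path = write_afa(tmp_path, "A" * n, "A" * n)
        up = CoverageTrack("a", np.arange(1, n + 1))
        down = CoverageTrack("b", np.arange(n, 0, -1))
        pair = load_alignment(path, up, down)
        prof = shared_score_profile(pair)
        assert prof["rho_ab"].iloc[50] == pytest.approx(-1.0)


class TestStringency:
    BASE = dict(rho_ab=0.9, norm_a=0.8, norm_b=0.4, raw_a=50, raw_b=50)

    @pytest.mark.parametrize("tweak,expected", [
        (dict(), True),
        (dict(rho_ab=0.74), False),           # strict > 0.75
        (dict(rho_ab=0.75), False),
        (dict(rho_ab=0.76), True),
        (dict(norm_a=0.49, norm_b=0.4), False),   # no track above 0.5
        (dict(norm_a=0.51, norm_b=0.21), True),
        (dict(norm_a=0.6, norm_b=0.15), False),   # minor track below 0.2
        (dict(norm_a=0.6, norm_b=0.2), False),    # strict > 0.2
        (dict(raw_a=10), False),                  # strict > 10 reads
        (dict(raw_b=10), False),
        (dict(raw_a=11, raw_b=11), True),
    ])
    def test_threshold_flips_exactly_at_printed_values(self, tweak, expected):
        kwargs = {**self.BASE, **tweak}
        assert passes_stringency(**kwargs) is expected

    def test_filter_is_species_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            rho = rng.uniform(0.5, 1.0)
            na, nb = rng.uniform(0, 1, 2)
            ra, rb = rng.integers(0, 40, 2)
            assert passes_stringency(rho, na, nb, ra, rb) == passes_stringency(
                rho, nb, na, rb, ra
            )


class TestCallSharedPeaks:
    def _pair_with_bumps(self, tmp_path, both=True):
        n = 301
        path = write_afa(tmp_path, "A" * n, "A" * n)
        ta = bump_track("a", n, 150)
        depth_b = bump_track("b", n, 150).depth if both else np.full(n, 12)
        return load_alignment(path, ta, CoverageTrack("b", depth_b))

    def test_identical_planted_bump_yields_one_shared_peak(self, tmp_path):
        pair = self._pair_with_bumps(tmp_path, both=True)
        peaks = call_shared_peaks(pair)
        assert len(peaks) == 1
        assert abs(peaks[0].column - 150) <= 2
        p = peaks[0]
        assert p.rho_ab > 0.75 and max(p.norm_a, p.norm_b) > 0.5
        assert min(p.norm_a, p.norm_b) > 0.2 and p.raw_a > 10 and p.raw_b > 10
        assert p.score == pytest.approx(p.rho_ab + p.rho_a_tmpl + p.rho_b_tmpl)

    def test_single_species_bump_is_not_shared(self, tmp_path):
        pair = self._pair_with_bumps(tmp_path, both=False)
        assert call_shared_peaks(pair) == []

    def test_species_swap_symmetry(self):
        from gclipp.simulate import sim_species_pair

        pair, _ = sim_species_pair(seed=9, shared_frac=1.0)
        fwd = call_shared_peaks(pair)
        rev = call_shared_peaks(pair.swapped())
        assert [p.column for p in fwd] == [p.column for p in rev]
        for a, b in zip(fwd, rev):
            assert a.score == pytest.approx(b.score, abs=1e-12)
            assert a.rho_ab == pytest.approx(b.rho_ab, abs=1e-12)

    def test_raw_scaling_only_affects_read_filter(self, tmp_path):
        n = 301
        path = write_afa(tmp_path, "A" * n, "A" * n)
        ta = bump_track("a", n, 150)
        tb = bump_track("b", n, 150)
        pair1 = load_alignment(path, ta, tb)
        pair2 = load_alignment(
            path, CoverageTrack("a", ta.depth * 3), CoverageTrack("b", tb.depth * 3)
        )
        prof1 = shared_score_profile(pair1)
        prof2 = shared_score_profile(pair2)
        assert np.allclose(prof1["score"], prof2["score"],
                           atol=1e-12, equal_nan=True)
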