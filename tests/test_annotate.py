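"""Peak annotation: conservation profiles, motif windows, variants, stop CDFs."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from gclipp.annotate import (
    conservation_profile,
    distance_to_stop_cdf,
    iupac_regex,
    motif_enrichment,
    variants_in_peaks,
)
from gclipp.coverage import UTRAnnotation
from gclipp.overlapstat import GenomicInterval


class TestConservationProfile:
    def test_three_offset_means_standardise_to_unit_steps(self):
        track = {"chr1": np.array([1.0, 2.0, 3.0])}
        prof = conservation_profile([("chr1", 1)], track, half_width=1)
        assert np.allclose(prof.mean_score, [1, 2, 3])
        assert np.allclose(prof.normalized, [-1, 0, 1])

    def test_normalised_profile_has_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        track = {"chr1": rng.normal(0, 1, 2000)}
        centers = [("chr1", int(c)) for c in rng.integers(200, 1800, 40)]
        prof = conservation_profile(centers, track, half_width=100)
        assert prof.normalized.mean() == pytest.approx(0.0, abs=1e-12)
        assert prof.normalized.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_track_warns_and_returns_zeros(self):
        track = {"chr1": np.full(500, 3.0)}
        with pytest.warns(UserWarning, match="sd = 0"):
            prof = conservation_profile([("chr1", 250)], track, half_width=10)
        assert np.allclose(prof.normalized, 0.0)

    def test_single_peak_profile_is_its_window_standardised(self):
        rng = np.random.default_rng(1)
        track = {"chr1": rng.normal(0, 1, 400)}
        prof = conservation_profile([("chr1", 200)], track, half_width=50)
        raw = track["chr1"][150:251]
        expected = (raw - raw.mean()) / raw.std(ddof=1)
        assert np.allclose(prof.normalized, expected)

    def test_peak_ordering_and_affine_track_rescale_are_absorbed(self):
        rng = np.random.default_rng(2)
        track = {"chr1": rng.normal(0, 1, 1000)}
        centers = [("chr1", int(c)) for c in rng.integers(100, 900, 10)]
        p1 = conservation_profile(centers, track, half_width=30)
        p2 = conservation_profile(centers[::-1],
                                  {"chr1": 5.0 * track["chr1"] + 2.0},
                                  half_width=30)
        assert np.allclose(p1.normalized, p2.normalized)

    def test_truncated_windows_use_defined_offsets_only(self):
        track = {"chr1": np.arange(10.0)}
        prof = conservation_profile([("chr1", 0)], track, half_width=2)
        assert np.isnan(prof.mean_score[0])  # offset -2 undefined
        assert prof.mean_score[2] == 0.0

    def test_no_overlapping_peak_errors(self):
        with pytest.raises(ValueError, match="no peak"):
            conservation_profile([("chrX", 5)], {"chr1": np.ones(10)}, 2)


class TestMotifEnrichment:
    def test_iupac_codes_expand(self):
        assert iupac_regex("ARN").search("AAG")
        assert iupac_regex("ARN").search("AGT")
        assert not iupac_regex("ARY").search("ATT")
        with pytest.raises(ValueError, match="invalid IUPAC"):
            iupac_regex("AXZ")

    def test_fold_is_site_rate_over_background_rate(self):
        seqs = {f"u{i}": ("ATTTA" + "C" * 95 if i < 5 else "G" * 100)
                for i in range(10)}
        sites = [(f"u{i}", 2) for i in range(10)]
        out = motif_enrichment(sites, seqs, ["ATTTA"])
        row = out.iloc[0]
        assert row["site_hits"] == 5
        assert row["fold"] == pytest.approx(
            row["site_rate"] / row["background_rate"])
        expected_p = binom.sf(4, 10, row["background_rate"])
        assert row["p"] == pytest.approx(expected_p)

    def test_degenerate_motif_has_fold_one(self):
        seqs = {"u": "ACGTACGTACGTACGT"}
        out = motif_enrichment([("u", 8)], seqs, ["NNNN"])
        assert out.iloc[0]["fold"] == pytest.approx(1.0)

    def test_absent_motif_is_nan_sentinel(self):
        out = motif_enrichment([("u", 8)], {"u": "A" * 30}, ["CCCCC"])
        assert np.isnan(out.iloc[0]["fold"])

    def test_background_only_absence_gives_inf(self):
        # site window reaches the motif but no full background window does
        out = motif_enrichment([("u", 2)], {"u": "ACGTT"}, ["ACGTT"])
        assert np.isinf(out.iloc[0]["fold"])

    def test_iid_background_sites_concentrate_near_fold_one(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        seqs = {f"u{i}": "".join(rng.choice(bases, 300)) for i in range(20)}
        sites = []
        for _ in range(500):
            uid = f"u{int(rng.integers(20))}"
            sites.append((uid, int(rng.integers(4, 296))))
        out = motif_enrichment(sites, seqs, ["GCA"])
        assert out.iloc[0]["fold"] == pytest.approx(1.0, abs=0.25)


class TestVariantsInPeaks:
    UTRS = [UTRAnnotation("u1", "chr1", 0, 200, "+", gene="G1")]

    def test_half_open_boundary_convention(self):
        peaks = [GenomicInterval("chr1", 50, 60, "p1")]
        hits = variants_in_peaks([("chr1", 50, "vS"), ("chr1", 60, "vE")],
                                 peaks, self.UTRS)
        assert hits["variant"].tolist() == ["vS"]

    def test_snp_outside_peaks_absent(self):
        peaks = [GenomicInterval("chr1", 50, 60, "p1")]
        hits = variants_in_peaks([("chr1", 100, "v")], peaks, self.UTRS)
        assert hits.empty

    def test_overlapping_peaks_give_two_rows(self):
        peaks = [GenomicInterval("chr1", 40, 70, "p1"),
                 GenomicInterval("chr1", 50, 90, "p2")]
        hits = variants_in_peaks([("chr1", 55, "v")], peaks, self.UTRS)
        assert sorted(hits["peak"]) == ["p1", "p2"]

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(4)
        utrs = [UTRAnnotation(f"u{k}", "chr1", 300 * k, 300 * k + 250, "+")
                for k in range(3)]
        peaks = [GenomicInterval("chr1", int(s), int(s) + 20, f"p{i}")
                 for i, s in enumerate(rng.integers(0, 880, 15))]
        variants = [("chr1", int(p), f"v{i}")
                    for i, p in enumerate(rng.integers(0, 900, 40))]
        got = variants_in_peaks(variants, peaks, utrs)
        expected = set()
        for chrom, pos, vid in variants:
            in_utr = any(u.start <= pos < u.end for u in utrs)
            if not in_utr:
                continue
            for p in peaks:
                if p.start <= pos < p.end:
                    expected.add((vid, p.name))
        assert set(zip(got["variant"], got["peak"])) == expected


class TestDistanceToStopCdf:
    def test_plus_strand_steps(self):
        utrs = [UTRAnnotation("u1", "chr1", 100, 400, "+")]
        regions = [GenomicInterval("chr1", 100 + d, 110 + d, "u1")
                   for d in (0, 10, 20)]
        out = distance_to_stop_cdf(regions, utrs)
        assert out["distance"].tolist() == [0, 10, 20]
        assert np.allclose(out["cum_frac"], [1 / 3, 2 / 3, 1.0])

    def test_all_regions_at_stop_codon_degenerate(self):
        utrs = [UTRAnnotation("u1", "chr1", 100, 400, "+")]
        regions = [GenomicInterval("chr1", 100, 110, "u1") for _ in range(4)]
        out = distance_to_stop_cdf(regions, utrs)
        assert (out["distance"] == 0).all()

    def test_minus_strand_distance_measured_from_genomic_end(self):
        utrs = [UTRAnnotation("u1", "chr1", 100, 400, "-")]
        regions = [GenomicInterval("chr1", 370, 380, "u1")]
        out = distance_to_stop_cdf(regions, utrs)
        assert out["distance"].tolist() == [20]  # 400 - 380

    def test_region_outside_utr_excluded_with_warning(self):
        utrs = [UTRAnnotation("u1", "chr1", 100, 400, "+")]
        regions = [GenomicInterval("chr2", 0, 10, "zzz"),
                   GenomicInterval("chr1", 150, 160)]
        with pytest.warns(UserWarning, match="excluded"):
            out = distance_to_stop_cdf(regions, utrs)
        assert len(out) == 1
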