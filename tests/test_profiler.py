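"""Window extraction, dedup, averaging, smoothing and profile analysis."""

import numpy as np
import pytest

from nomeprofile.genome_sites import SitePositions, find_sites
from nomeprofile.profiler import (EXCLUDED, Anchor, AnchorSet, Profile, ProfilerError,
                                  Window, average_profiles, dedup_cpg_indicators,
                                  dominant_period, extract_window, fit_gaussian_dip,
                                  locate_extremum, smooth)
from tests.conftest import make_site_table


def cpg_at(chrom, positions):
    return SitePositions(chrom, np.array(positions, dtype=np.int64), "CpG")


def window_from(occ, meth, cpg, anchor=None, flipped=False):
    H = (len(occ) - 1) // 2
    a = anchor or Anchor("w", "chr1", 5000)
    return Window(a, H, np.array(occ, float), np.array(meth, float),
                  np.array(cpg, np.int8), flipped)


# -- extract_window --------------------------------------------------------

def test_extract_window_coordinates_and_values():
    sites = make_site_table([
        ("chr1", 5003, "CpG", 1, 4),    # level 0.25 at +3
        ("chr1", 4998, "GpC", 1, 4),    # level 0.25 -> occupancy 0.75 at -2
        ("chr1", 5004, "CpG", 0, 0),    # uncovered -> missing
    ])
    w = extract_window(sites, cpg_at("chr1", [5003, 5004]), Anchor("a", "chr1", 5000, "+"),
                       halfwidth=5)
    H = 5
    assert w.methylation[H + 3] == 0.25
    assert np.isnan(w.methylation[H + 4])  # zero coverage is missing
    assert w.occupancy[H - 2] == 0.75
    assert w.cpg[H + 3] == 1 and w.cpg[H + 4] == 1
    assert w.cpg.sum() == 2


def test_extract_window_minus_strand_flips():
    sites = make_site_table([("chr1", 5003, "CpG", 1, 2)])
    minus = Anchor("a", "chr1", 5000, "-")
    w = extract_window(sites, cpg_at("chr1", [5003]), minus, halfwidth=5)
    H = 5
    assert w.cpg[H - 3] == 1  # genomically right of a minus-strand TSS = upstream (-3)
    assert w.methylation[H - 3] == 0.5
    assert w.genomic_coord(H - 3) == 5003
    unoriented = extract_window(sites, cpg_at("chr1", [5003]), minus, halfwidth=5,
                                orient=False)
    assert unoriented.cpg[H + 3] == 1


def test_extract_window_empty_table_and_bounds():
    empty = make_site_table([])
    w = extract_window(empty, cpg_at("chr1", []), Anchor("a", "chr1", 100), halfwidth=10)
    assert np.all(np.isnan(w.occupancy)) and np.all(np.isnan(w.methylation))
    assert not w.cpg.any()
    assert extract_window(empty, cpg_at("chr1", []), Anchor("b", "chr1", 5),
                          halfwidth=10) is None
    assert extract_window(empty, cpg_at("chr1", []), Anchor("c", "chr1", 95),
                          halfwidth=10, chrom_length=100) is None


# -- dedup -----------------------------------------------------------------

def _blank(anchor, H, cpg_positions):
    sites = make_site_table([])
    return extract_window(sites, cpg_at("chr1", cpg_positions), anchor, H)


def test_dedup_disjoint_windows_unchanged():
    cpgs = [1000, 3000]
    w1 = _blank(Anchor("a", "chr1", 1000), 500, cpgs)
    w2 = _blank(Anchor("b", "chr1", 3000), 500, cpgs)
    out = dedup_cpg_indicators([w1, w2])
    assert np.array_equal(out[0].cpg, w1.cpg)
    assert np.array_equal(out[1].cpg, w2.cpg)


def test_dedup_shared_site_excluded_in_later_window():
    shared = 1400
    w1 = _blank(Anchor("a", "chr1", 1000), 500, [shared])
    w2 = _blank(Anchor("b", "chr1", 1800), 500, [shared])
    out = dedup_cpg_indicators([w2, w1])  # input order is not genomic order
    # genomically first window (anchor 1000) keeps the indicator
    assert out[1].cpg[500 + 400] == 1
    assert out[0].cpg[500 - 400] == EXCLUDED


def test_dedup_duplicated_window_fully_excluded():
    w = _blank(Anchor("a", "chr1", 1000), 500, [800, 1000, 1200])
    w2 = _blank(Anchor("b", "chr1", 1000), 500, [800, 1000, 1200])
    out = dedup_cpg_indicators([w, w2])
    assert (out[0].cpg == 1).sum() == 3
    assert (out[1].cpg == EXCLUDED).sum() == 3


# -- average_profiles ------------------------------------------------------

def test_average_single_window_identity():
    w = window_from([0.6] * 5, [0.2] * 5, [0, 1, 0, 0, 1])
    p = average_profiles([w])
    assert np.all(p.occ_mean == 0.6) and np.all(p.occ_n == 1)
    assert np.all(p.meth_mean == 0.2)
    assert p.cpg_density.tolist() == [0, 1, 0, 0, 1]
    assert p.n_windows == 1


def test_average_masks_missing_measurements():
    w1 = window_from([np.nan, 0.5, 1.0], [0.2, np.nan, np.nan], [0, 0, 0])
    w2 = window_from([np.nan, np.nan, 0.0], [np.nan, np.nan, np.nan], [1, 0, 0])
    p = average_profiles([w1, w2])
    assert np.isnan(p.occ_mean[0]) and p.occ_n[0] == 0
    assert p.occ_mean[1] == 0.5 and p.occ_n[1] == 1
    assert p.occ_mean[2] == 0.5 and p.occ_n[2] == 2
    assert p.meth_mean[0] == 0.2 and p.meth_n[0] == 1  # missing partner disregarded
    assert p.cpg_density[0] == 0.5


def test_average_excluded_indicator_counts_zero_but_stays_in_denominator():
    w1 = window_from([np.nan] * 3, [np.nan] * 3, [1, 1, 0])
    w2 = window_from([np.nan] * 3, [np.nan] * 3, [EXCLUDED, 0, 1])
    p = average_profiles([w1, w2])
    assert p.cpg_density.tolist() == [0.5, 0.5, 0.5]


def test_average_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    H = 100
    n = 2 * H + 1
    windows = []
    for k in range(50):
        occ = rng.random(n)
        occ[rng.random(n) < 0.4] = np.nan
        meth = rng.random(n)
        meth[rng.random(n) < 0.4] = np.nan
        cpg = rng.choice(np.array([0, 1, EXCLUDED], dtype=np.int8), size=n,
                         p=[0.7, 0.2, 0.1])
        windows.append(window_from(occ, meth, cpg, Anchor(f"w{k}", "chr1", 5000)))
    p = average_profiles(windows)
    for i in range(n):
        occs = [w.occupancy[i] for w in windows if np.isfinite(w.occupancy[i])]
        meths = [w.methylation[i] for w in windows if np.isfinite(w.methylation[i])]
        ones = sum(1 for w in windows if w.cpg[i] == 1)
        assert p.occ_n[i] == len(occs)
        if occs:
            assert p.occ_mean[i] == pytest.approx(np.mean(occs))
        else:
            assert np.isnan(p.occ_mean[i])
        if meths:
            assert p.meth_mean[i] == pytest.approx(np.mean(meths))
        assert p.cpg_density[i] == pytest.approx(ones / 50)


def test_average_rejects_empty_and_mixed_halfwidths():
    with pytest.raises(ProfilerError):
        average_profiles([])
    w1 = window_from([0.1] * 3, [0.1] * 3, [0, 0, 0])
    w2 = window_from([0.1] * 5, [0.1] * 5, [0] * 5)
    with pytest.raises(ProfilerError):
        average_profiles([w1, w2])


def test_density_conservation_under_dedup():
    """Sum over positions of density * n_windows = number of distinct CpGs."""
    rng = np.random.default_rng(3)
    cpgs = np.unique(rng.integers(500, 4500, 60))
    anchors = [Anchor(f"a{i}", "chr1", int(p), "+")
               for i, p in enumerate(sorted(rng.integers(700, 4300, 12)))]
    sites = make_site_table([])
    windows = [extract_window(sites, cpg_at("chr1", cpgs), a, 200) for a in anchors]
    windows = dedup_cpg_indicators(windows)
    p = average_profiles(windows)
    counted = p.cpg_density.sum() * p.n_windows
    distinct = len({int(c) for a in anchors for c in cpgs
                    if a.pos - 200 <= c <= a.pos + 200})
    assert counted == pytest.approx(distinct)
    assert np.all((p.cpg_density >= 0) & (p.cpg_density <= 1))


# -- smoothing -------------------------------------------------------------

def _smooth_oracle(values, w):
    n = len(values)
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - w // 2), min(n - 1, i + (w - 1 - w // 2))
        vals = [v for v in values[lo:hi + 1] if np.isfinite(v)]
        if vals:
            out[i] = np.mean(vals)
    return out


def profile_of(track):
    n = len(track)
    H = (n - 1) // 2
    z = np.zeros(n)
    return Profile(np.arange(-H, H + 1), np.array(track, float), np.ones(n, np.int64),
                   z.copy(), np.ones(n, np.int64), z.copy(), 1)


def test_smooth_constant_invariance():
    p = smooth(profile_of([0.4] * 61), 30)
    assert np.allclose(p.occ_mean, 0.4)


def test_smooth_single_spike():
    track = np.zeros(201)
    track[100] = 1.0
    p = smooth(profile_of(track), 30)
    # the window at i spans i-15 .. i+14, so positions 86..115 cover the spike
    assert p.occ_mean[100] == pytest.approx(1 / 30)
    assert p.occ_mean[115] == pytest.approx(1 / 30)
    assert p.occ_mean[116] == pytest.approx(0.0)
    assert p.occ_mean[86] == pytest.approx(1 / 30)
    assert p.occ_mean[85] == pytest.approx(0.0)


def test_smooth_window_one_is_identity():
    rng = np.random.default_rng(0)
    track = rng.random(41)
    p = smooth(profile_of(track), 1)
    assert np.allclose(p.occ_mean, track)


def test_smooth_matches_oracle_with_missing_values():
    rng = np.random.default_rng(7)
    track = rng.random(301)
    track[rng.random(301) < 0.3] = np.nan
    for w in (2, 5, 30, 31):
        got = smooth(profile_of(track), w).occ_mean
        want = _smooth_oracle(track, w)
        assert np.allclose(got, want, equal_nan=True)


def test_smooth_leaves_counts_untouched():
    p0 = profile_of(np.arange(21, dtype=float))
    p = smooth(p0, 30)
    assert np.array_equal(p.occ_n, p0.occ_n)
    assert np.array_equal(p.meth_n, p0.meth_n)


# -- strand handling at the profile level ----------------------------------

def test_profile_strand_symmetry_on_mirrored_genome():
    """A minus-strand anchor on the reverse complement reproduces the
    plus-strand CpG density track exactly (dinucleotide starts mirror as
    i -> L-2-i), and the occupancy track up to the 2 bp left/right swap of
    the GpC cytosine."""
    rng = np.random.default_rng(11)
    L = 4000
    seq = "".join(rng.choice(list("ACGT"), L))
    rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    a = 2000
    H = 500

    def table_for(s):
        rows = []
        for motif, ctx in (("CG", "CpG"), ("GC", "GpC")):
            for pos in find_sites(s, motif).positions:
                rows.append(("chr1", int(pos), ctx, 1, 2))
        return make_site_table(rows)

    w_plus = extract_window(table_for(seq), find_sites(seq, "CG", "chr1"),
                            Anchor("p", "chr1", a, "+"), H)
    w_minus = extract_window(table_for(rc), find_sites(rc, "CG", "chr1"),
                             Anchor("m", "chr1", L - 2 - a, "-"), H)
    assert np.array_equal(w_plus.cpg, w_minus.cpg)
    occ_p = np.isfinite(w_plus.occupancy)
    occ_m = np.isfinite(w_minus.occupancy)
    assert np.array_equal(occ_p[2:], occ_m[:-2])


# -- profile I/O and analysis utilities ------------------------------------

def test_profile_tsv_round_trip(tmp_path):
    p = profile_of(np.array([0.1, np.nan, 0.3, 0.4, np.nan]))
    path = tmp_path / "p.tsv"
    p.write_tsv(path)
    back = Profile.read_tsv(path)
    assert np.allclose(back.occ_mean, p.occ_mean, equal_nan=True)
    assert back.n_windows == p.n_windows
    assert np.array_equal(back.rel, p.rel)


def test_locate_extremum_recovers_parabola_vertex():
    rel = np.arange(-300, 301)
    y = 0.5 + ((rel - 37) / 1000.0) ** 2
    assert locate_extremum(rel, y, "min") == pytest.approx(37, abs=1)
    assert locate_extremum(rel, -y, "max") == pytest.approx(37, abs=1)


def test_fit_gaussian_dip_recovers_noiseless_parameters():
    rel = np.arange(-1000, 1001)
    y = 0.8 - 0.45 * np.exp(-((rel + 120) ** 2) / (2 * 70.0**2))
    fit = fit_gaussian_dip(rel, y)
    assert fit["center"] == pytest.approx(-120, abs=1)
    assert fit["depth"] == pytest.approx(0.45, abs=0.01)
    assert fit["baseline"] == pytest.approx(0.8, abs=0.01)


def test_dominant_period_recovers_cosine():
    rel = np.arange(-1000, 1001)
    y = 0.7 + 0.1 * np.cos(2 * np.pi * rel / 200.0)
    per = dominant_period(rel, y, rel_range=(1, 1000))
    assert per["bin"] == pytest.approx(per["n"] / 200.0, abs=1)
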