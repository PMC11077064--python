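"""Feature-profiling tests: charge tracks, pI, motif scans, PFMs, OLS."""

import numpy as np
import pytest
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint as _BioPI
from hypothesis import given, settings
from hypothesis import strategies as st

from comphom import (
    AMINO_ACIDS,
    SequenceRecord,
    cdk_sites,
    fcr,
    feature_profile,
    find_at_hooks,
    isoelectric_point,
    ncpr_track,
    net_charge,
    phospho_dead,
    sample_sequence,
    site_window_matrix,
    sites_vs_length_fit,
)
from comphom.synthetic import IDR_COMPOSITION

aa_text = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60)


class TestNcpr:
    @pytest.mark.parametrize("seq,value", [("KKKKK", 1.0), ("DDDDD", -1.0)])
    def test_pure_charge_runs(self, seq, value, rec):
        assert np.all(ncpr_track(rec(seq), 3) == value)

    def test_alternating_center_value(self, rec):
        track = ncpr_track(rec("KDKDK"), 5)
        assert track[2] == pytest.approx(0.2)

    def test_even_window_rejected(self, rec):
        with pytest.raises(ValueError, match="odd"):
            ncpr_track(rec("KDKDK"), 4)

    @given(residues=aa_text)
    @settings(max_examples=50, deadline=None)
    def test_values_bounded(self, residues):
        r = SequenceRecord("x", residues)
        w = min(len(residues), 5)
        if w % 2 == 0:
            w -= 1
        assert np.all(np.abs(ncpr_track(r, w)) <= 1.0)


class TestFcr:
    @pytest.mark.parametrize(
        "seq,value", [("KRDE", 1.0), ("GGGG", 0.0), ("KAAA", 0.25)]
    )
    def test_examples(self, seq, value, rec):
        assert fcr(rec(seq)) == pytest.approx(value)


class TestIsoelectricPoint:
    def test_root_property(self, rec):
        r = rec("MKRHDESPTYKK")
        pi = isoelectric_point(r)
        assert abs(net_charge(r, pi)) < 1e-2

    def test_sign_structure(self, rec):
        assert isoelectric_point(rec("KKKK")) > 7 > isoelectric_point(rec("DDDD"))

    def test_bisection_matches_dense_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            L = int(rng.integers(20, 120))
            r = sample_sequence(IDR_COMPOSITION, L, seed=int(rng.integers(2**31)))
            pi = isoelectric_point(r)
            grid = np.arange(0.0, 14.0, 1e-3)
            q = np.array([net_charge(r, ph) for ph in grid])
            root = grid[np.argmin(np.abs(q))]
            assert pi == pytest.approx(root, abs=2e-3)

    def test_agrees_with_biopython_within_pka_tolerance(self):
        """Independent oracle: Biopython's Bjellqvist implementation."""
        for i in range(10):
            r = sample_sequence(IDR_COMPOSITION, 200, seed=40 + i)
            ours = isoelectric_point(r, "bjellqvist")
            theirs = _BioPI(r.residues).pi()
            assert ours == pytest.approx(theirs, abs=0.3)

    def test_basic_idr_composition_has_basic_pi(self):
        # K+R fraction 0.16 vs D+E 0.10 in the preset: pI must be > 7
        r = sample_sequence(IDR_COMPOSITION, 400, seed=77)
        assert isoelectric_point(r) > 7.0


class TestCdkSites:
    @pytest.mark.parametrize(
        "seq,n_min,n_opt",
        [("SPSPTP", 3, 0), ("TPAR", 1, 1), ("STP", 1, 0), ("GGGG", 0, 0)],
    )
    def test_examples(self, seq, n_min, n_opt, rec):
        minimal, optimal = cdk_sites(rec(seq))
        assert len(minimal) == n_min
        assert len(optimal) == n_opt

    @given(residues=aa_text)
    @settings(max_examples=50, deadline=None)
    def test_optimal_subset_of_minimal_and_append_invariance(self, residues):
        r = SequenceRecord("x", residues)
        minimal, optimal = cdk_sites(r)
        assert set(optimal) <= set(minimal)
        extended = SequenceRecord("x", residues + "GG")
        assert cdk_sites(extended)[0][: len(minimal)] == minimal


class TestPhosphoDead:
    def test_example_transform(self, rec):
        assert phospho_dead(rec("MSPATPK")).residues == "MAPAAPK"

    def test_no_sites_is_identity(self, rec):
        assert phospho_dead(rec("MKRHGW")).residues == "MKRHGW"

    @given(residues=aa_text)
    @settings(max_examples=50, deadline=None)
    def test_kills_all_sites_idempotently(self, residues):
        r = SequenceRecord("x", residues)
        dead = phospho_dead(r)
        assert len(dead) == len(r)
        assert cdk_sites(dead)[0] == ()
        assert phospho_dead(dead).residues == dead.residues
        # only S/T at former site positions changed, and only to A
        changed = [
            (i + 1, a, b)
            for i, (a, b) in enumerate(zip(r.residues, dead.residues))
            if a != b
        ]
        sites = set(cdk_sites(r)[0])
        assert all(pos in sites and a in "ST" and b == "A" for pos, a, b in changed)


class TestAtHooks:
    def test_sponge_orc1_motif(self, rec):
        assert len(find_at_hooks(rec("RKRGRPRKEE"))) == 1

    def test_echinoderm_degenerate_motif(self, rec):
        assert len(find_at_hooks(rec("KQGRPKK"))) == 1

    def test_no_core_no_hits(self, rec):
        assert find_at_hooks(rec("AAAAAA")) == ()

    def test_core_without_basic_context_rejected(self, rec):
        assert find_at_hooks(rec("AAAGRPAAA")) == ()

    def test_no_duplicate_overlapping_cores(self, rec):
        hits = find_at_hooks(rec("KKGRPGRPKK"))
        starts = [h[0] for h in hits]
        assert len(starts) == len(set(starts))


class TestSiteWindowMatrix:
    def test_single_site_is_one_hot(self, rec):
        r = rec("AAAASPAAAA")
        pfm = site_window_matrix([(r, [5])], flank=4)
        assert pfm.shape == (20, 9)
        assert np.allclose(pfm.sum(axis=0), 1.0)
        assert pfm.loc["S", 0] == 1.0
        assert pfm.loc["P", 1] == 1.0

    def test_identical_windows_stay_one_hot(self, rec):
        r = rec("AAAASPAAAASPAAAA")
        pfm = site_window_matrix([(r, [5, 11])], flank=2)
        assert np.allclose((pfm == 1.0).sum(axis=0), 1.0)

    @given(residues=st.text(alphabet=AMINO_ACIDS, min_size=9, max_size=40))
    @settings(max_examples=25, deadline=None)
    def test_columns_normalized(self, residues):
        r = SequenceRecord("x", residues)
        pfm = site_window_matrix([(r, [5])], flank=4)
        assert np.allclose(pfm.sum(axis=0), 1.0)

    def test_edge_sites_use_gap_padding(self, rec):
        pfm = site_window_matrix([(rec("SPAAA"), [1])], flank=4)
        # column -1 has no observations: all-zero, not NaN
        assert pfm[-1].sum() == 0.0
        assert pfm.loc["S", 0] == 1.0

    def test_empty_site_list_rejected(self, rec):
        with pytest.raises(ValueError):
            site_window_matrix([(rec("AAAA"), [])], flank=2)


class TestSitesVsLength:
    def _profile(self, length, seed):
        return feature_profile(
            sample_sequence(IDR_COMPOSITION, length, seed=seed), ncpr_window=25
        )

    def test_exact_line_recovered(self, rec):
        profs = []
        for n_sites, L in [(2, 40), (5, 100), (10, 200)]:
            residues = ("SP" * n_sites) + "G" * (L - 2 * n_sites)
            profs.append(feature_profile(rec(residues, f"p{L}"), ncpr_window=25))
        slope, intercept, r = sites_vs_length_fit(profs)
        assert slope == pytest.approx(0.05)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(1.0)

    def test_matches_closed_form_ols(self):
        profs = [self._profile(L, seed=L) for L in (100, 150, 220, 300, 410)]
        x = np.array([p.length for p in profs], dtype=float)
        y = np.array([len(p.cdk_minimal) for p in profs], dtype=float)
        # normal-equations oracle
        beta = np.linalg.solve(
            np.array([[len(x), x.sum()], [x.sum(), (x * x).sum()]]),
            np.array([y.sum(), (x * y).sum()]),
        )
        slope, intercept, _ = sites_vs_length_fit(profs)
        assert intercept == pytest.approx(beta[0], abs=1e-9)
        assert slope == pytest.approx(beta[1], abs=1e-9)

    def test_constant_counts_give_zero_slope(self, rec):
        profs = [
            feature_profile(rec("SP" + "G" * L, f"c{L}"), ncpr_window=3)
            for L in (20, 40, 60)
        ]
        slope, _, r = sites_vs_length_fit(profs)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_zero_length_variance_rejected(self, rec):
        profs = [
            feature_profile(rec("SPGGGG", f"z{i}"), ncpr_window=3) for i in range(3)
        ]
        with pytest.raises(ValueError):
            sites_vs_length_fit(profs)
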