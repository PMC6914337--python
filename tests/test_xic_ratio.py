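"""XIC extraction and peptide ratio estimation."""
import numpy as np
import pytest

from silamq.spectra_io import PSMRecord, Scan, ScanSeries
from silamq.xic_ratio import (
    FAIL_CORRELATION,
    LIGHT_ONLY,
    NO_SIGNAL,
    PASS,
    XICTrace,
    assign_channel_psms,
    channel_mz_offset,
    estimate_peptide_ratio,
    extract_xic,
)


def _trace(light, heavy, rts=None):
    light = np.asarray(light, dtype=float)
    heavy = np.asarray(heavy, dtype=float)
    if rts is None:
        rts = np.arange(light.size, dtype=float)
    return XICTrace(rts=rts, light=light, heavy=heavy,
                    ppm_tol=10.0, rt_window=120.0, psm_rt=float(rts[len(rts) // 2]))


def _psm(seq="PEPTIDEK", charge=2, rt=50.0, precursor_mz=None):
    return PSMRecord(scan_id="s", sequence=seq, prev_aa="K", next_aa="A",
                     charge=charge, rt=rt, proteins=("P1",),
                     precursor_mz=precursor_mz)


class TestExtractXIC:
    def test_ppm_boundary_inclusive_at_10ppm(self):
        # centroids at 8, exactly 10, and 12 ppm from the 500.0 target
        mz = np.array([500.0 * (1 + 8e-6), 500.0 * (1 + 10e-6),
                       500.0 * (1 + 12e-6)])
        scans = ScanSeries(scans=[
            Scan(rt=50.0, mz=mz, intensity=np.array([1.0, 10.0, 100.0]))])
        trace = extract_xic(scans, _psm(), [500.0], [600.0], ppm_tol=10.0)
        assert trace.light[0] == pytest.approx(11.0)  # 8 and 10 ppm in, 12 out

    def test_overlapping_target_windows_count_centroids_once(self):
        scans = ScanSeries(scans=[
            Scan(rt=50.0, mz=np.array([500.0]), intensity=np.array([7.0]))])
        trace = extract_xic(scans, _psm(), [500.0, 500.001], [600.0])
        assert trace.light[0] == pytest.approx(7.0)

    def test_no_cross_contamination_at_50ppm(self):
        # two co-eluting species 50 ppm apart: each XIC sees only its own
        mz_a, mz_b = 500.0, 500.0 * (1 + 50e-6)
        scans = ScanSeries(scans=[
            Scan(rt=50.0, mz=np.array([mz_a, mz_b]),
                 intensity=np.array([100.0, 900.0]))])
        ta = extract_xic(scans, _psm(), [mz_a], [700.0])
        tb = extract_xic(scans, _psm(), [mz_b], [700.0])
        assert ta.light[0] == pytest.approx(100.0)
        assert tb.light[0] == pytest.approx(900.0)

    def test_window_restricts_scans_and_keeps_zero_scans(self):
        scans = ScanSeries(scans=[
            Scan(rt=t, mz=np.array([500.0]), intensity=np.array([1.0]))
            for t in (0.0, 40.0, 50.0, 60.0, 200.0)])
        trace = extract_xic(scans, _psm(rt=50.0), [500.0], [600.0],
                            rt_window=40.0)
        assert trace.rts.tolist() == [40.0, 50.0, 60.0]
        assert trace.heavy.tolist() == [0.0, 0.0, 0.0]  # zeros retained

    def test_empty_window_flagged(self):
        scans = ScanSeries(scans=[
            Scan(rt=500.0, mz=np.array([500.0]), intensity=np.array([1.0]))])
        trace = extract_xic(scans, _psm(rt=50.0), [500.0], [600.0])
        assert trace.empty
        rec = estimate_peptide_ratio(trace)
        assert rec.status == NO_SIGNAL


class TestEstimateRatio:
    def test_exact_proportionality(self):
        rec = estimate_peptide_ratio(_trace([10, 20, 30], [5, 10, 15]))
        assert rec.ratio == pytest.approx(2.0)
        assert rec.correlation == pytest.approx(1.0)
        assert rec.status == PASS

    def test_heavy_absent_light_peaked(self):
        rec = estimate_peptide_ratio(_trace([0, 0, 5, 80, 5, 0, 0, 0],
                                            [0] * 8))
        assert rec.status == LIGHT_ONLY
        assert not rec.heavy_present and rec.light_present
        assert rec.ratio is None

    def test_extreme_asymmetric_ratio_recovered(self):
        # a long-lived-protein-like peptide: light far above heavy
        true = 7.19
        h = np.array([0, 2.0, 9.0, 30.0, 9.0, 2.0, 0, 0])
        rec = estimate_peptide_ratio(_trace(true * h, h))
        assert rec.ratio == pytest.approx(true, rel=1e-6)
        assert rec.status == PASS

    def test_swap_inverts_ratio_on_noiseless_data(self):
        h = np.array([1.0, 4.0, 9.0, 4.0, 1.0])
        fwd = estimate_peptide_ratio(_trace(3.0 * h, h))
        rev = estimate_peptide_ratio(_trace(h, 3.0 * h))
        assert fwd.ratio * rev.ratio == pytest.approx(1.0, rel=1e-9)

    def test_correlation_invariant_to_channel_rescaling(self):
        rng = np.random.default_rng(4)
        h = rng.uniform(1, 100, 12)
        l = 2.0 * h + rng.normal(0, 5, 12)
        r1 = estimate_peptide_ratio(_trace(l, h)).correlation
        r2 = estimate_peptide_ratio(_trace(l * 37.5, h)).correlation
        r3 = estimate_peptide_ratio(_trace(l, h * 0.01)).correlation
        assert r1 == pytest.approx(r2) == pytest.approx(r3)

    def test_uncorrelated_channels_fail_the_filter(self):
        rng = np.random.default_rng(5)
        l = rng.uniform(10, 100, 16)
        h = rng.permutation(l)
        rec = estimate_peptide_ratio(_trace(l, h))
        if rec.correlation is not None and rec.correlation <= 0.5:
            assert rec.status == FAIL_CORRELATION

    def test_correlation_filter_enriches_for_low_error(self):
        """Failing the r > 0.5 filter is associated with larger ratio error:
        the filter removes a higher fraction of bad measurements."""
        rng = np.random.default_rng(6)
        true = 2.0
        profile = np.exp(-0.5 * ((np.arange(30) - 15) / 4.0) ** 2) * 100
        errors_pass, errors_fail = [], []
        for i in range(300):
            h = profile * np.exp(rng.normal(0, 0.1, 30))
            l = true * profile * np.exp(rng.normal(0, 0.1, 30))
            if i % 2:  # corrupt half the traces with a co-eluting interferent
                l = l + np.roll(profile, rng.integers(5, 12)) * rng.uniform(1, 4)
            rec = estimate_peptide_ratio(_trace(l, h))
            if rec.ratio is None:
                continue
            err = abs(rec.ratio - true) / true
            (errors_pass if rec.status == PASS else errors_fail).append(err)
        assert np.median(errors_fail) > np.median(errors_pass)

    def test_both_channels_empty(self):
        rec = estimate_peptide_ratio(_trace([0, 0, 0], [0, 0, 0]))
        assert rec.status == NO_SIGNAL


class TestChannelAssignment:
    def test_light_precursor_assigned_light(self):
        from silamq.isotopes import (
            Channel, PROTON_MASS, elemental_composition, monoisotopic_mass,
        )
        comp = elemental_composition("PEPTIDEK")
        mz = (monoisotopic_mass(comp, Channel.LIGHT) + 2 * PROTON_MASS) / 2
        psm = _psm(precursor_mz=mz * (1 + 2e-6))  # 2 ppm off
        out = assign_channel_psms([psm])[0]
        assert out.channel == "LIGHT"
        assert abs(out.ppm_error) == pytest.approx(2.0, abs=0.1)

    def test_heavy_precursor_assigned_heavy(self):
        from silamq.isotopes import (
            Channel, PROTON_MASS, elemental_composition, monoisotopic_mass,
        )
        comp = elemental_composition("PEPTIDEK")
        mz = (monoisotopic_mass(comp, Channel.HEAVY) + 2 * PROTON_MASS) / 2
        out = assign_channel_psms([_psm(precursor_mz=mz)])[0]
        assert out.channel == "HEAVY"

    def test_midway_precursor_unknown(self):
        from silamq.isotopes import (
            Channel, PROTON_MASS, elemental_composition, monoisotopic_mass,
        )
        comp = elemental_composition("PEPTIDEK")
        lo = (monoisotopic_mass(comp, Channel.LIGHT) + 2 * PROTON_MASS) / 2
        hi = (monoisotopic_mass(comp, Channel.HEAVY) + 2 * PROTON_MASS) / 2
        out = assign_channel_psms([_psm(precursor_mz=(lo + hi) / 2)])[0]
        assert out.channel == "UNKNOWN"

    def test_channel_offset_closed_form(self):
        # 7 nitrogens at charge 2: offset = 7 x 0.9970349 / 2
        assert channel_mz_offset("PEPTIDE", 2, {}) == pytest.approx(
            7 * 0.9970349 / 2, abs=1e-6)

    def test_prelabeled_psm_without_precursor_kept(self):
        psm = _psm()
        psm.channel = "LIGHT"
        out = assign_channel_psms([psm])[0]
        assert out.channel == "LIGHT"
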