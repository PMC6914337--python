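"""Extracted ion chromatograms and per-peptide 14N/15N ratio estimation.

For each identified peptide the two channels' theoretical envelope peaks
are turned into m/z target sets; MS1 scans around the identification's
retention time are summed within a ppm tolerance of those targets to give
one light and one heavy chromatographic profile. Because the two isotopic
forms of a peptide co-elute, the per-scan light and heavy intensities are
proportional when the measurement is clean, and

* the ratio is the slope of a zero-intercept least-squares fit of light on
  heavy intensity (directly the reported 14N/15N), and
* the Pearson correlation between the paired profiles is the quality score:
  records only PASS when r exceeds the threshold (default 0.5, strict).

Channel presence is decided against a noise floor estimated from the
flanks of the extraction window, so "14N-only" / "15N-only" evidence is an
explicit, configurable detection rule rather than an implicit zero test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ValidationError
from .isotopes import (
    Channel,
    DEFAULT_ENRICHMENT,
    DELTA_N15,
    PROTON_MASS,
    elemental_composition,
    monoisotopic_mass,
    nitrogen_count,
)
from .spectra_io import PSMRecord, ScanSeries

logger = logging.getLogger("silamq.xic_ratio")

__all__ = [
    "XICTrace",
    "PeptideRatioRecord",
    "extract_xic",
    "estimate_peptide_ratio",
    "assign_channel_psms",
    "DEFAULT_PPM_TOL",
    "DEFAULT_RT_WINDOW",
]

DEFAULT_PPM_TOL = 10.0      # precursor mass tolerance, ppm (boundary inclusive)
DEFAULT_RT_WINDOW = 120.0   # seconds around the identifying PSM
DEFAULT_MIN_POINTS = 3
DEFAULT_R_THRESHOLD = 0.5
DEFAULT_PRESENCE_SNR = 3.0

# record status codes
PASS = "PASS"
FAIL_CORRELATION = "FAIL_CORRELATION"
FAIL_POINTS = "FAIL_POINTS"
LIGHT_ONLY = "LIGHT_ONLY"
HEAVY_ONLY = "HEAVY_ONLY"
NO_SIGNAL = "NO_SIGNAL"


@dataclass
class XICTrace:
    """Per-scan channel-summed intensities around one peptide."""

    rts: np.ndarray           # seconds, one per MS1 scan in the window
    light: np.ndarray         # summed intensity over the light m/z targets
    heavy: np.ndarray         # summed intensity over the heavy m/z targets
    ppm_tol: float
    rt_window: float
    psm_rt: float
    empty: bool = False       # no MS1 scans fell inside the window

    def __post_init__(self):
        if not (len(self.rts) == len(self.light) == len(self.heavy)):
            raise ValidationError("XIC arrays differ in length")


@dataclass
class PeptideRatioRecord:
    """One peptide's light/heavy (= 14N/15N) ratio measurement."""

    sequence: str
    charge: int
    proteins: Tuple[str, ...] = ()
    ratio: Optional[float] = None        # light/heavy; None when undefined
    correlation: Optional[float] = None  # Pearson r; None when undefined
    n_points: int = 0
    light_present: bool = False
    heavy_present: bool = False
    light_area: float = 0.0
    heavy_area: float = 0.0
    status: str = NO_SIGNAL

    @property
    def passed(self) -> bool:
        return self.status == PASS


def _sum_targets(mz: np.ndarray, intensity: np.ndarray,
                 targets: np.ndarray, ppm_tol: float) -> float:
    """Sum intensities of centroids within ppm_tol of any target m/z.

    A centroid matching several (overlapping) target windows is counted
    once. The tolerance boundary is inclusive: a centroid exactly ppm_tol
    away still matches.
    """
    if mz.size == 0:
        return 0.0
    mask = np.zeros(mz.size, dtype=bool)
    for t in targets:
        # tiny relative epsilon keeps the inclusive boundary robust to
        # floating-point rounding of "exactly ppm_tol away" centroids
        half = t * ppm_tol * 1e-6 * (1.0 + 1e-9) + t * 1e-12
        lo = np.searchsorted(mz, t - half, side="left")
        hi = np.searchsorted(mz, t + half, side="right")
        mask[lo:hi] = True
    return float(intensity[mask].sum())


def extract_xic(
    scans: ScanSeries,
    psm: PSMRecord,
    light_targets: Sequence[float],
    heavy_targets: Sequence[float],
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_window: float = DEFAULT_RT_WINDOW,
) -> XICTrace:
    """Reconstruct the two-channel ion chromatogram around a PSM.

    Every MS1 scan within +/- rt_window/2 of the PSM's retention time
    contributes one point per channel: the sum of centroid intensities
    within ``ppm_tol`` of any of that channel's target m/z values. Scans
    with zero signal in both channels are retained as zeros — they carry
    information about the elution profile.
    """
    light_targets = np.asarray(light_targets, dtype=float)
    heavy_targets = np.asarray(heavy_targets, dtype=float)
    if light_targets.size == 0 or heavy_targets.size == 0:
        raise ValidationError("empty m/z target list")
    if ppm_tol <= 0:
        raise ValidationError(f"ppm_tol must be positive, got {ppm_tol}")
    half = rt_window / 2.0
    rts, light, heavy = [], [], []
    for scan in scans:
        if abs(scan.rt - psm.rt) > half:
            continue
        rts.append(scan.rt)
        light.append(_sum_targets(scan.mz, scan.intensity, light_targets, ppm_tol))
        heavy.append(_sum_targets(scan.mz, scan.intensity, heavy_targets, ppm_tol))
    empty = len(rts) == 0
    if empty:
        logger.debug("extract_xic: no MS1 scans within %.1f s of rt=%.1f",
                     half, psm.rt)
    return XICTrace(
        rts=np.array(rts), light=np.array(light), heavy=np.array(heavy),
        ppm_tol=ppm_tol, rt_window=rt_window, psm_rt=psm.rt, empty=empty,
    )


def _noise_floor(values: np.ndarray) -> float:
    """Noise floor: median of nonzero intensities in the flanking 25% of
    scans on each side of the window (0 when the flanks are silent or the
    trace is too short to have flanks)."""
    n = values.size
    k = n // 4
    if k == 0:
        return 0.0
    flanks = np.concatenate([values[:k], values[n - k:]])
    nz = flanks[flanks > 0]
    return float(np.median(nz)) if nz.size else 0.0


def _present(values: np.ndarray, snr: float) -> bool:
    floor = _noise_floor(values)
    peak = float(values.max()) if values.size else 0.0
    if floor == 0.0:
        return peak > 0.0
    return peak > snr * floor


def estimate_peptide_ratio(
    trace: XICTrace,
    sequence: str = "",
    charge: int = 0,
    proteins: Tuple[str, ...] = (),
    min_points: int = DEFAULT_MIN_POINTS,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    presence_snr: float = DEFAULT_PRESENCE_SNR,
    estimator: str = "ols",
) -> PeptideRatioRecord:
    """Estimate one peptide's 14N/15N ratio from its XIC trace.

    The ratio is the slope of the zero-intercept least-squares fit of light
    on heavy intensity over scans where at least one channel rises above
    ``presence_snr`` times its noise floor; the quality score is the
    Pearson r of the paired per-scan profiles over the same scans. The
    record PASSes only when r > r_threshold (strict) and enough scans were
    used. ``estimator="gmr"`` selects the symmetric geometric-mean
    (total-least-squares-like) slope sqrt(sum l^2 / sum h^2) instead.

    Channel presence against the noise floor also provides the explicit
    detection rule behind "14N-only" / "15N-only" evidence.
    """
    rec = PeptideRatioRecord(sequence=sequence, charge=charge, proteins=proteins)
    if trace.empty or (trace.light.sum() == 0 and trace.heavy.sum() == 0):
        rec.status = NO_SIGNAL
        return rec
    rec.light_area = float(trace.light.sum())
    rec.heavy_area = float(trace.heavy.sum())
    rec.light_present = _present(trace.light, presence_snr)
    rec.heavy_present = _present(trace.heavy, presence_snr)
    if rec.light_present and not rec.heavy_present:
        rec.status = LIGHT_ONLY
        return rec
    if rec.heavy_present and not rec.light_present:
        rec.status = HEAVY_ONLY
        return rec
    if not rec.light_present and not rec.heavy_present:
        rec.status = NO_SIGNAL
        return rec

    floor_l = _noise_floor(trace.light)
    floor_h = _noise_floor(trace.heavy)
    use = (trace.light > presence_snr * floor_l) | (trace.heavy > presence_snr * floor_h)
    l, h = trace.light[use], trace.heavy[use]
    rec.n_points = int(use.sum())
    denom = float(np.dot(h, h))
    if denom == 0.0:
        rec.status = LIGHT_ONLY
        return rec
    if estimator == "gmr":
        rec.ratio = float(np.sqrt(np.dot(l, l) / denom))
    elif estimator == "ols":
        rec.ratio = float(np.dot(l, h) / denom)
    else:
        raise ValidationError(f"unknown estimator {estimator!r}")
    if rec.n_points >= 3 and np.ptp(l) > 0 and np.ptp(h) > 0:
        rec.correlation = float(stats.pearsonr(l, h).statistic)
    else:
        rec.correlation = None  # undefined: too few points or constant channel
    if rec.n_points < min_points:
        rec.status = FAIL_POINTS
    elif rec.correlation is not None and rec.correlation > r_threshold:
        rec.status = PASS
    else:
        rec.status = FAIL_CORRELATION
    return rec


def assign_channel_psms(
    psms: Sequence[PSMRecord],
    ppm_tol: float = DEFAULT_PPM_TOL,
    enrichment: float = DEFAULT_ENRICHMENT,
    fixed_mods=None,
) -> List[PSMRecord]:
    """Label each PSM LIGHT or HEAVY by its observed precursor m/z.

    The search is run against combined light and heavy peptide databases,
    so each identification corresponds to one isotopic form. A PSM is
    assigned to the channel whose theoretical monoisotopic m/z (heavy = the
    fully 15N-substituted reference) is nearest, provided it is within
    ``ppm_tol``; otherwise the channel is UNKNOWN, the PSM is excluded from
    quantification downstream, and the decision is logged. PSMs without an
    observed precursor m/z keep their pre-assigned label. ``ppm_error`` is
    filled in against the assigned channel.
    """
    out: List[PSMRecord] = []
    for psm in psms:
        if psm.precursor_mz is None:
            out.append(psm)
            continue
        comp = elemental_composition(psm.sequence, fixed_mods)
        z = psm.charge
        mz_light = (monoisotopic_mass(comp, Channel.LIGHT) + z * PROTON_MASS) / z
        mz_heavy = (monoisotopic_mass(comp, Channel.HEAVY) + z * PROTON_MASS) / z
        err_l = (psm.precursor_mz - mz_light) / mz_light * 1e6
        err_h = (psm.precursor_mz - mz_heavy) / mz_heavy * 1e6
        if abs(err_l) <= abs(err_h) and abs(err_l) <= ppm_tol:
            out.append(replace(psm, channel="LIGHT", ppm_error=float(err_l)))
        elif abs(err_h) < abs(err_l) and abs(err_h) <= ppm_tol:
            out.append(replace(psm, channel="HEAVY", ppm_error=float(err_h)))
        else:
            logger.debug(
                "PSM %s (%s/%d): precursor %.4f is %.1f/%.1f ppm "
                "from light/heavy, UNKNOWN",
                psm.scan_id, psm.sequence, z, psm.precursor_mz, err_l, err_h,
            )
            out.append(replace(psm, channel="UNKNOWN", ppm_error=None))
    return out


def channel_mz_offset(sequence: str, charge: int, fixed_mods=None) -> float:
    """Heavy-minus-light monoisotopic m/z offset: N x 0.9970349 / z."""
    comp = elemental_composition(sequence, fixed_mods)
    return nitrogen_count(comp) * DELTA_N15 / charge
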