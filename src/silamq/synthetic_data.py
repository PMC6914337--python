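"""Synthetic 15N pulse-labeled LC-MS1 runs with known ground truth.

The generative model mirrors the physics the quantification relies on:

* each tryptic peptide elutes as a Gaussian profile, and its light (14N,
  natural abundance) and heavy (15N-enriched) isotopic forms share the
  elution center and width exactly — the co-elution premise that makes the
  per-scan intensity ratio meaningful;
* per-channel apex amplitudes are set by the protein's true 14N/15N ratio
  (UNLABELED proteins inject zero heavy signal, FULLY_LABELED zero light);
* each channel contributes its top-k theoretical envelope peaks at the
  chosen charge state's m/z, within the instrument scan range
  (300-1500 m/z by default);
* noise is multiplicative lognormal per emitted centroid (intensities are
  positive, so Gaussian noise would be wrong near zero), parameterized by
  its coefficient of variation, plus an optional additive noise floor of
  random low-intensity centroids;
* one PSM row per detectable channel is emitted at the peptide's apex
  scan, and decoy-scored PSMs can be generated separately for FDR tests.

Every output is a pure function of (configuration, seed): rerunning with
the same seed produces byte-identical mzML, PSM, FASTA and truth files.

An interference guard (on by default) drops peptides whose m/z targets
collide within twice the ppm tolerance while co-eluting with an already
placed peptide; collisions between unrelated envelopes are a real-data
phenomenon the single-peptide XIC model does not deconvolve, and the
guard keeps the planted truth exactly recoverable. Dropped peptides are
logged and never enter the truth tables.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .isotopes import (
    Channel,
    DEFAULT_ENRICHMENT,
    PROTON_MASS,
    elemental_composition,
    isotope_envelope,
    monoisotopic_mass,
    mz_targets,
)
from .spectra_io import (
    PSMRecord,
    Scan,
    ScanSeries,
    write_fasta,
    write_ms1,
    write_psm_table,
)

logger = logging.getLogger("silamq.synthetic_data")

__all__ = [
    "DigestPeptide",
    "PeptideTruth",
    "ProteinTruth",
    "GroundTruth",
    "SyntheticBundle",
    "generate_proteome",
    "digest",
    "build_ground_truth",
    "simulate_run",
    "generate_fdr_psms",
    "UNLABELED",
    "FULLY_LABELED",
    "RATIO",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# turnover states a planted protein can be in
RATIO = "RATIO"                  # both channels present, true ratio defined
UNLABELED = "UNLABELED"          # never labeled: 14N only
FULLY_LABELED = "FULLY_LABELED"  # completely replaced: 15N only

DEFAULT_SCAN_RANGE = (300.0, 1500.0)  # instrument MS1 scan range, m/z


def _aa_probabilities(kr_frequency: float = 0.10) -> np.ndarray:
    """Residue sampling probabilities with boosted K/R frequency.

    K and R together at ``kr_frequency`` gives a mean tryptic fragment
    length near 1/kr_frequency, i.e. typical tryptic-peptide sizes.
    """
    p = np.full(len(AMINO_ACIDS), (1.0 - kr_frequency) / (len(AMINO_ACIDS) - 2))
    for aa in "KR":
        p[AMINO_ACIDS.index(aa)] = kr_frequency / 2.0
    return p


def generate_proteome(
    n_proteins: int,
    length_range: Tuple[int, int] = (200, 400),
    seed: int = 0,
    kr_frequency: float = 0.10,
) -> List[Tuple[str, str]]:
    """Reproducible random protein sequences as (accession, sequence).

    Sequences are drawn over the 20 standard residues with K/R frequency
    tuned so tryptic digestion yields peptides of typical length; the same
    seed always produces identical records.
    """
    if n_proteins < 1:
        raise ValidationError(f"n_proteins must be >= 1, got {n_proteins}")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValidationError(f"bad length range {length_range}")
    rng = np.random.default_rng(seed)
    p = _aa_probabilities(kr_frequency)
    out = []
    for i in range(n_proteins):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=n, p=p))
        out.append((f"SYNP{i:04d}", seq))
    return out


@dataclass(frozen=True)
class DigestPeptide:
    """A tryptic peptide in its protein context."""

    sequence: str
    prev_aa: str       # residue before the peptide, '-' at protein N-terminus
    next_aa: str       # residue after, '-' at protein C-terminus
    missed: int        # internal uncut K/R sites
    start: int         # 0-based position in the protein


def digest(sequence: str, max_missed_cleavages: int = 0) -> List[DigestPeptide]:
    """In-silico trypsin/Lys-C digestion with the proline rule.

    Cleaves C-terminal to K or R unless the next residue is proline;
    produces all products with up to ``max_missed_cleavages`` internal
    uncut sites. Concatenating the zero-missed-cleavage products restores
    the protein sequence.
    """
    if not sequence:
        raise ValidationError("cannot digest an empty sequence")
    cuts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    fragments = [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]
    peptides: List[DigestPeptide] = []
    for i in range(len(fragments)):
        for mc in range(max_missed_cleavages + 1):
            j = i + mc
            if j >= len(fragments):
                break
            start, end = fragments[i][0], fragments[j][1]
            peptides.append(DigestPeptide(
                sequence=sequence[start:end],
                prev_aa=sequence[start - 1] if start > 0 else "-",
                next_aa=sequence[end] if end < len(sequence) else "-",
                missed=mc,
                start=start,
            ))
    return peptides


@dataclass
class PeptideTruth:
    """One simulated peptide's injected signal parameters."""

    accession: str
    sequence: str
    prev_aa: str
    next_aa: str
    charge: int
    rt_center: float            # seconds
    rt_sigma: float             # Gaussian elution sigma, seconds
    light_area: float           # apex amplitude of the light channel
    heavy_area: float           # apex amplitude of the heavy channel
    mz_light: Tuple[float, ...] = ()
    mz_heavy: Tuple[float, ...] = ()
    ab_light: Tuple[float, ...] = ()
    ab_heavy: Tuple[float, ...] = ()


@dataclass
class ProteinTruth:
    """Planted per-protein truth."""

    accession: str
    sequence: str
    state: str                   # RATIO | UNLABELED | FULLY_LABELED
    true_ratio: Optional[float]  # 14N/15N; None for the sentinel states
    abundance: float
    tissue: str
    peptides: List[PeptideTruth] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Complete description of a synthetic labeled run."""

    proteins: List[ProteinTruth]
    enrichment: float
    top_k: int
    run_length: float            # seconds
    scan_range: Tuple[float, float]
    tissue: str
    seed: int

    @property
    def peptides(self) -> List[PeptideTruth]:
        return [p for prot in self.proteins for p in prot.peptides]


def build_ground_truth(
    proteome: Sequence[Tuple[str, str]],
    seed: int = 0,
    tissue: str = "lens",
    ratio_range: Tuple[float, float] = (0.05, 20.0),
    frac_unlabeled: float = 0.0,
    frac_fully_labeled: float = 0.0,
    peptides_per_protein: Tuple[int, int] = (3, 10),
    charges: Sequence[int] = (2, 3),
    run_length: float = 1500.0,
    rt_margin: float = 120.0,
    width_range: Tuple[float, float] = (20.0, 60.0),
    enrichment: float = DEFAULT_ENRICHMENT,
    top_k: int = 3,
    scan_range: Tuple[float, float] = DEFAULT_SCAN_RANGE,
    avoid_interference: bool = True,
    interference_ppm: float = 20.0,
    true_ratios: Optional[Dict[str, float]] = None,
) -> GroundTruth:
    """Plant per-protein turnover truth over a proteome.

    Protein states are drawn with the given UNLABELED / FULLY_LABELED
    fractions (the channel-absent classes of a turnover study); the rest
    get a true 14N/15N ratio log-uniform over ``ratio_range`` — matching
    the dynamic range the protein-level caps are designed for — unless
    ``true_ratios`` pins specific accessions. Peptides are sampled from
    the tryptic digest (length 6-25, all envelope targets inside the scan
    range), each with a Gaussian elution profile of width drawn from
    ``width_range`` (full width ~4 sigma) shared exactly between channels.

    With ``avoid_interference``, a peptide whose targets fall within
    ``interference_ppm`` of an already placed, chromatographically
    overlapping peptide is dropped (deterministically, in placement
    order); a protein that loses all its peptides is dropped from the
    truth and logged.
    """
    rng = np.random.default_rng(seed)
    log_lo, log_hi = np.log(ratio_range[0]), np.log(ratio_range[1])
    placed_targets: List[Tuple[float, float, np.ndarray]] = []  # (t0, t1, targets)
    proteins: List[ProteinTruth] = []
    for acc, seq in proteome:
        u = rng.random()
        if true_ratios is not None and acc in true_ratios:
            state, ratio = RATIO, float(true_ratios[acc])
        elif u < frac_unlabeled:
            state, ratio = UNLABELED, None
        elif u < frac_unlabeled + frac_fully_labeled:
            state, ratio = FULLY_LABELED, None
        else:
            state = RATIO
            ratio = float(np.exp(rng.uniform(log_lo, log_hi)))
        abundance = float(np.exp(rng.normal(np.log(1e6), 0.5)))
        candidates = [
            p for p in digest(seq)
            if 6 <= len(p.sequence) <= 25
        ]
        rng.shuffle(candidates)
        lo_k, hi_k = peptides_per_protein
        want = int(rng.integers(lo_k, hi_k + 1))
        prot = ProteinTruth(acc, seq, state, ratio, abundance, tissue)
        for pep in candidates:
            if len(prot.peptides) >= want:
                break
            charge = int(rng.choice(charges))
            comp = elemental_composition(pep.sequence)
            env_l = isotope_envelope(comp, Channel.LIGHT, enrichment, top_k)
            env_h = isotope_envelope(comp, Channel.HEAVY, enrichment, top_k)
            tl = mz_targets(env_l, charge)
            th = mz_targets(env_h, charge)
            allmz = np.concatenate([tl, th])
            if allmz.min() < scan_range[0] or allmz.max() > scan_range[1]:
                logger.debug("peptide %s/%d outside scan range, excluded",
                             pep.sequence, charge)
                continue
            center = float(rng.uniform(rt_margin, run_length - rt_margin))
            sigma = float(rng.uniform(*width_range)) / 4.0
            if avoid_interference:
                t0, t1 = center - 4 * sigma, center + 4 * sigma
                clash = False
                for (q0, q1, qmz) in placed_targets:
                    if t0 <= q1 and q0 <= t1:
                        dppm = np.min(np.abs(
                            allmz[:, None] - qmz[None, :]
                        ) / allmz[:, None]) * 1e6
                        if dppm <= interference_ppm:
                            clash = True
                            break
                if clash:
                    logger.debug("peptide %s/%d dropped: m/z collision with a "
                                 "co-eluting peptide", pep.sequence, charge)
                    continue
            area = abundance * float(rng.uniform(0.5, 2.0))
            if state == UNLABELED:
                la, ha = area, 0.0
            elif state == FULLY_LABELED:
                la, ha = 0.0, area
            else:
                la = area * ratio / (1.0 + ratio)
                ha = area / (1.0 + ratio)
            prot.peptides.append(PeptideTruth(
                accession=acc, sequence=pep.sequence,
                prev_aa=pep.prev_aa, next_aa=pep.next_aa, charge=charge,
                rt_center=center, rt_sigma=sigma,
                light_area=la, heavy_area=ha,
                mz_light=tuple(tl), mz_heavy=tuple(th),
                ab_light=tuple(env_l.abundances), ab_heavy=tuple(env_h.abundances),
            ))
            placed_targets.append(
                (center - 4 * sigma, center + 4 * sigma, allmz)
            )
        if prot.peptides:
            proteins.append(prot)
        else:
            logger.info("protein %s dropped: no usable peptides", acc)
    return GroundTruth(
        proteins=proteins, enrichment=enrichment, top_k=top_k,
        run_length=run_length, scan_range=scan_range, tissue=tissue, seed=seed,
    )


@dataclass
class SyntheticBundle:
    """File paths and in-memory objects of one simulated run."""

    mzml_path: str
    psm_path: str
    fasta_path: str
    truth_protein_path: str
    truth_peptide_path: str
    truth: GroundTruth
    scans: ScanSeries
    psms: List[PSMRecord]


def _lognormal_factors(rng, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


def simulate_run(
    truth: GroundTruth,
    out_dir: str,
    scan_interval: float = 1.0,
    noise_cv: float = 0.0,
    additive_floor: float = 0.0,
    n_noise_peaks: int = 0,
    seed: int = 0,
    prefix: str = "run",
    fasta_records: Optional[Sequence[Tuple[str, str]]] = None,
) -> SyntheticBundle:
    """Render a ground truth into mzML + PSM table + FASTA + truth tables.

    MS1 scans sit on a regular retention-time grid; each peptide adds its
    top-k envelope peaks per channel, scaled by the shared Gaussian
    profile and the channel amplitude, with multiplicative lognormal noise
    of coefficient of variation ``noise_cv`` per centroid. When
    ``additive_floor`` > 0, ``n_noise_peaks`` random centroids per scan
    (exponentially distributed intensities of that scale) form a noise
    floor. One PSM row per detectable channel is emitted at each
    peptide's apex scan with the channel's theoretical monoisotopic
    precursor m/z.
    """
    if noise_cv < 0 or additive_floor < 0:
        raise ValidationError("noise parameters must be non-negative")
    import os

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_scans = int(np.floor(truth.run_length / scan_interval)) + 1
    times = np.arange(n_scans) * scan_interval
    peak_mz: List[List[float]] = [[] for _ in range(n_scans)]
    peak_int: List[List[float]] = [[] for _ in range(n_scans)]

    for pep in truth.peptides:
        i0 = max(0, int(np.ceil((pep.rt_center - 4 * pep.rt_sigma) / scan_interval)))
        i1 = min(n_scans - 1,
                 int(np.floor((pep.rt_center + 4 * pep.rt_sigma) / scan_interval)))
        if i1 < i0:
            continue
        t = times[i0:i1 + 1]
        profile = np.exp(-0.5 * ((t - pep.rt_center) / pep.rt_sigma) ** 2)
        for targets, abunds, area in (
            (pep.mz_light, pep.ab_light, pep.light_area),
            (pep.mz_heavy, pep.ab_heavy, pep.heavy_area),
        ):
            if area <= 0:
                continue
            for mz, ab in zip(targets, abunds):
                intens = area * ab * profile
                intens = intens * _lognormal_factors(rng, noise_cv, intens.size)
                for k, v in zip(range(i0, i1 + 1), intens):
                    if v > 0:
                        peak_mz[k].append(mz)
                        peak_int[k].append(float(v))

    if additive_floor > 0 and n_noise_peaks > 0:
        lo, hi = truth.scan_range
        for k in range(n_scans):
            noise_mz = rng.uniform(lo, hi, n_noise_peaks)
            noise_i = additive_floor * rng.exponential(1.0, n_noise_peaks)
            peak_mz[k].extend(noise_mz.tolist())
            peak_int[k].extend(noise_i.tolist())

    scans = ScanSeries(scans=[
        Scan(rt=float(times[k]), mz=np.array(peak_mz[k]),
             intensity=np.array(peak_int[k]), native_id=f"scan={k + 1}")
        for k in range(n_scans)
    ])

    psms: List[PSMRecord] = []
    for pep in truth.peptides:
        apex = int(round(pep.rt_center / scan_interval))
        apex = min(max(apex, 0), n_scans - 1)
        comp = elemental_composition(pep.sequence)
        z = pep.charge
        for channel, area in (("LIGHT", pep.light_area), ("HEAVY", pep.heavy_area)):
            if area <= 0:
                continue
            mono = monoisotopic_mass(comp, Channel(channel))
            psms.append(PSMRecord(
                scan_id=f"scan={apex + 1}",
                sequence=pep.sequence,
                prev_aa=pep.prev_aa,
                next_aa=pep.next_aa,
                charge=z,
                rt=float(times[apex]),
                proteins=(pep.accession,),
                precursor_mz=(mono + z * PROTON_MASS) / z,
                score=float(rng.normal(8.0, 1.0)),
                decoy=False,
                channel="UNKNOWN",  # the pipeline re-derives the channel
            ))

    mzml_path = f"{out_dir}/{prefix}.mzML"
    psm_path = f"{out_dir}/{prefix}_psms.tsv"
    fasta_path = f"{out_dir}/{prefix}_proteins.fasta"
    tp_path = f"{out_dir}/{prefix}_truth_proteins.tsv"
    tpep_path = f"{out_dir}/{prefix}_truth_peptides.tsv"

    write_ms1(scans, mzml_path, run_id=prefix)
    write_psm_table(psms, psm_path)
    if fasta_records is None:
        fasta_records = [(p.accession, p.sequence) for p in truth.proteins]
    write_fasta(fasta_records, fasta_path)

    pd.DataFrame([{
        "accession": p.accession,
        "state": p.state,
        "true_ratio": "" if p.true_ratio is None else repr(p.true_ratio),
        "abundance": repr(p.abundance),
        "tissue": p.tissue,
        "n_peptides": len(p.peptides),
    } for p in truth.proteins]).to_csv(tp_path, sep="\t", index=False,
                                       lineterminator="\n")
    pd.DataFrame([{
        "accession": pep.accession,
        "sequence": pep.sequence,
        "charge": pep.charge,
        "rt_center": repr(pep.rt_center),
        "rt_sigma": repr(pep.rt_sigma),
        "light_area": repr(pep.light_area),
        "heavy_area": repr(pep.heavy_area),
    } for pep in truth.peptides]).to_csv(tpep_path, sep="\t", index=False,
                                         lineterminator="\n")

    return SyntheticBundle(
        mzml_path=mzml_path, psm_path=psm_path, fasta_path=fasta_path,
        truth_protein_path=tp_path, truth_peptide_path=tpep_path,
        truth=truth, scans=scans, psms=psms,
    )


def generate_fdr_psms(
    n_true: int = 200,
    n_false: int = 200,
    n_decoys: int = 200,
    separation: float = 3.0,
    seed: int = 0,
) -> Tuple[List[PSMRecord], np.ndarray]:
    """Score-labeled PSMs for target-decoy FDR experiments.

    True-target scores follow N(separation, 1); false targets and decoys
    both follow N(0, 1) — the exchangeable-null premise of target-decoy
    estimation. Returns (psms, is_true) where ``is_true`` marks the
    correct identifications among all PSMs (decoys are never true).
    Sequences are random tryptic-looking 8-mers, charge 2, with a clean
    protein context so they pass the deterministic filters.
    """
    rng = np.random.default_rng(seed)
    psms: List[PSMRecord] = []
    is_true: List[bool] = []

    def _mk(i: int, score: float, decoy: bool, acc: str) -> PSMRecord:
        seq = "".join(rng.choice(list("ACDEFGHILMNQSTVWY"), size=7)) + "K"
        return PSMRecord(
            scan_id=f"fdr_scan_{i}", sequence=seq, prev_aa="K", next_aa="A",
            charge=2, rt=0.0, proteins=(acc,), precursor_mz=None,
            score=float(score), decoy=decoy, channel="LIGHT",
        )

    i = 0
    for score in rng.normal(separation, 1.0, n_true):
        psms.append(_mk(i, score, False, f"TGT{i:05d}"))
        is_true.append(True)
        i += 1
    for score in rng.normal(0.0, 1.0, n_false):
        psms.append(_mk(i, score, False, f"TGT{i:05d}"))
        is_true.append(False)
        i += 1
    for score in rng.normal(0.0, 1.0, n_decoys):
        psms.append(_mk(i, score, True, f"DECOY_TGT{i:05d}"))
        is_true.append(False)
        i += 1
    return psms, np.array(is_true)
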