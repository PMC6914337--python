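"""Target-decoy FDR control and identification filtering.

The identification filters mirror the conventions of classic
DTASelect-style post-search filtering:

* minimum peptide length (default 6 residues),
* at least one tryptic end (cleavage C-terminal to K/R, blocked by a
  following proline; protein termini count as tryptic),
* unlimited missed cleavages by default,
* precursor mass error within 10 ppm,
* a peptide score threshold chosen as the *loosest* threshold whose
  accepted set satisfies the peptide FDR target, estimated by target-decoy
  counting against a reversed-sequence decoy database,
* a protein-level FDR threshold applied to best-peptide-score protein
  ranking.

FDR is estimated as (#decoys)/(#targets) among accepted entries — the
simplest reading of an appended reversed-sequence database; the
2d/(t+d) variant is available via ``estimate_fdr(..., paired=True)``.

Every rejected PSM carries a reason code; nothing is dropped silently.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import ValidationError
from .spectra_io import PSMRecord

logger = logging.getLogger("silamq.fdr_filter")

__all__ = [
    "FilterCriteria",
    "build_decoy_db",
    "tryptic_end_count",
    "missed_cleavage_count",
    "apply_filters",
    "estimate_fdr",
    "DECOY_PREFIX",
]

DECOY_PREFIX = "DECOY_"

# rejection reason codes
MIN_LENGTH = "MIN_LENGTH"
TRYPTIC_ENDS = "TRYPTIC_ENDS"
MISSED_CLEAVAGES = "MISSED_CLEAVAGES"
PPM = "PPM"
CHARGE = "CHARGE"
FDR_SCORE = "FDR_SCORE"
PROTEIN_FDR = "PROTEIN_FDR"
MIN_PEPTIDES = "MIN_PEPTIDES"


@dataclass
class FilterCriteria:
    """Identification filter thresholds.

    Defaults follow common practice for a single-peptide-per-protein,
    one-tryptic-end, 6-residue-minimum filter with a 10 ppm precursor
    window and 1% FDR at both the peptide and protein level. The stricter
    0.001 peptide FDR used by some filter configurations is available by
    setting ``peptide_fdr=0.001``.
    """

    min_peptides_per_protein: int = 1
    min_tryptic_ends: int = 1
    min_length: int = 6
    max_missed_cleavages: Optional[int] = None  # None = unlimited
    ppm_window: float = 10.0
    peptide_fdr: float = 0.01
    protein_fdr: float = 0.01

    def __post_init__(self):
        if not (0.0 < self.peptide_fdr <= 1.0 and 0.0 < self.protein_fdr <= 1.0):
            raise ValidationError("FDR thresholds must be in (0, 1]")
        if self.min_length < 1:
            raise ValidationError("min_length must be >= 1")


def build_decoy_db(
    targets: Sequence[Tuple[str, str]]
) -> List[Tuple[str, str]]:
    """Append one reversed-sequence decoy per target protein.

    Decoy accessions carry the ``DECOY_`` prefix; the combined list has
    exactly twice as many entries as the target list. A target accession
    already bearing the prefix would collide and is rejected. A palindromic
    sequence yields a decoy identical to its target; that is logged, not
    an error.
    """
    colliding = [acc for acc, _ in targets if acc.startswith(DECOY_PREFIX)]
    if colliding:
        raise ValidationError(
            "target accession(s) collide with the decoy prefix: "
            + ", ".join(sorted(colliding))
        )
    combined = list(targets)
    for acc, seq in targets:
        rev = seq[::-1]
        if rev == seq:
            logger.warning("palindromic sequence: decoy for %s equals target", acc)
        combined.append((DECOY_PREFIX + acc, rev))
    return combined


def tryptic_end_count(peptide: str, prev_aa: str, next_aa: str) -> int:
    """Number of tryptic termini of a peptide in its protein context.

    N-terminal end: preceding residue is K or R and the peptide does not
    start with proline, or the peptide sits at the protein N-terminus
    (``prev_aa == '-'``). C-terminal end: peptide ends in K or R and the
    following residue is not proline, or it sits at the protein C-terminus
    (``next_aa == '-'``).
    """
    n_term = prev_aa == "-" or (prev_aa in "KR" and peptide[:1] != "P")
    c_term = next_aa == "-" or (peptide[-1:] in "KR" and next_aa != "P")
    return int(n_term) + int(c_term)


def missed_cleavage_count(peptide: str, next_aa: str) -> int:
    """Internal K/R sites not followed by proline (uncut tryptic sites)."""
    n = 0
    for i, aa in enumerate(peptide[:-1]):
        if aa in "KR" and peptide[i + 1] != "P":
            n += 1
    return n


def estimate_fdr(accepted: Sequence, paired: bool = False) -> Optional[float]:
    """Target-decoy FDR of an accepted list.

    Entries need a ``decoy`` attribute (PSMs) or are (accession, ...)
    tuples whose accession may carry the decoy prefix. Returns
    decoys/targets (or 2d/(t+d) when ``paired``); None — flagged undefined
    — when no targets are accepted.
    """
    n_decoy = n_target = 0
    for item in accepted:
        if hasattr(item, "decoy"):
            is_decoy = bool(item.decoy)
        else:
            is_decoy = str(item[0]).startswith(DECOY_PREFIX)
        if is_decoy:
            n_decoy += 1
        else:
            n_target += 1
    if n_target == 0:
        logger.warning("FDR undefined: no target entries accepted")
        return None
    if paired:
        return 2.0 * n_decoy / (n_target + n_decoy)
    return n_decoy / n_target


def _loosest_fdr_threshold(
    scores: np.ndarray, decoy: np.ndarray, fdr_target: float
) -> Optional[float]:
    """Loosest score threshold whose accepted set meets the FDR target.

    Scans prefixes of the score-descending ranking and returns the score
    of the last (lowest-scoring) entry of the largest prefix with
    decoys/targets <= target; None when no prefix qualifies.
    """
    order = np.argsort(-scores, kind="stable")
    d = np.cumsum(decoy[order].astype(int))
    t = np.cumsum(~decoy[order])
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(t > 0, d / np.maximum(t, 1), np.inf)
    ok = np.nonzero(fdr <= fdr_target)[0]
    if ok.size == 0:
        return None
    return float(scores[order[ok[-1]]])


def apply_filters(
    psms: Sequence[PSMRecord],
    criteria: FilterCriteria = FilterCriteria(),
) -> Tuple[List[PSMRecord], List[Tuple[PSMRecord, str]]]:
    """Apply identification filters and target-decoy FDR control.

    Stage 1 enforces the deterministic rules (charge range as flagged at
    parse, peptide length, tryptic ends, missed cleavages if bounded,
    precursor ppm window when a precursor error is available). Stage 2
    chooses the loosest score threshold meeting the peptide FDR target.
    Stage 3 ranks proteins by their best peptide score and applies the
    protein FDR target; PSMs whose every accession fails are rejected.
    Stage 4 enforces the minimum-peptides-per-protein count.

    Returns (accepted PSMs, rejection log of (psm, reason)).
    """
    rejected: List[Tuple[PSMRecord, str]] = []
    stage1: List[PSMRecord] = []
    for psm in psms:
        if not psm.charge_in_range:
            rejected.append((psm, CHARGE))
        elif len(psm.sequence) < criteria.min_length:
            rejected.append((psm, MIN_LENGTH))
        elif tryptic_end_count(psm.sequence, psm.prev_aa, psm.next_aa) \
                < criteria.min_tryptic_ends:
            rejected.append((psm, TRYPTIC_ENDS))
        elif criteria.max_missed_cleavages is not None and \
                missed_cleavage_count(psm.sequence, psm.next_aa) \
                > criteria.max_missed_cleavages:
            rejected.append((psm, MISSED_CLEAVAGES))
        elif psm.ppm_error is not None and abs(psm.ppm_error) > criteria.ppm_window:
            rejected.append((psm, PPM))
        else:
            stage1.append(psm)

    if not stage1:
        return [], rejected

    scores = np.array([p.score for p in stage1])
    decoy = np.array([p.decoy for p in stage1])
    if decoy.any():
        thr = _loosest_fdr_threshold(scores, decoy, criteria.peptide_fdr)
        if thr is None:
            logger.warning("no score threshold achieves peptide FDR <= %g; "
                           "all PSMs rejected", criteria.peptide_fdr)
            rejected.extend((p, FDR_SCORE) for p in stage1)
            return [], rejected
        stage2 = [p for p in stage1 if p.score >= thr]
        rejected.extend((p, FDR_SCORE) for p in stage1 if p.score < thr)
    else:
        stage2 = stage1  # no decoys present: FDR estimate is 0 at any threshold

    # protein-level FDR on best peptide score per protein
    best: Dict[str, float] = {}
    for p in stage2:
        for acc in p.proteins:
            if acc not in best or p.score > best[acc]:
                best[acc] = p.score
    accs = sorted(best)
    p_scores = np.array([best[a] for a in accs])
    p_decoy = np.array([a.startswith(DECOY_PREFIX) for a in accs])
    if p_decoy.any():
        thr_p = _loosest_fdr_threshold(p_scores, p_decoy, criteria.protein_fdr)
        accepted_prot: Set[str] = (
            set() if thr_p is None
            else {a for a, s in zip(accs, p_scores) if s >= thr_p}
        )
    else:
        accepted_prot = set(accs)

    stage3 = []
    for p in stage2:
        if any(acc in accepted_prot for acc in p.proteins):
            stage3.append(p)
        else:
            rejected.append((p, PROTEIN_FDR))

    # minimum unique peptides per protein
    pep_per_prot: Dict[str, Set[str]] = {}
    for p in stage3:
        for acc in p.proteins:
            if acc in accepted_prot:
                pep_per_prot.setdefault(acc, set()).add(p.sequence)
    ok_prot = {a for a, peps in pep_per_prot.items()
               if len(peps) >= criteria.min_peptides_per_protein}
    accepted = []
    for p in stage3:
        if any(acc in ok_prot for acc in p.proteins):
            accepted.append(p)
        else:
            rejected.append((p, MIN_PEPTIDES))
    return accepted, rejected
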