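"""Peptide-to-protein rollup of 14N/15N ratios.

Per protein:

1. collect the PASS peptide ratios assigned to it;
2. when more than two peptides are available, iteratively remove outliers
   with the two-sided Grubbs test (default p < 0.01), applied to
   log-ratios because ratios are multiplicative;
3. form the composite ratio — by default the intensity-weighted geometric
   mean of the surviving peptide ratios (weights = light + heavy XIC
   area); an unweighted median is available by configuration;
4. clamp into the configured cap interval. Whole-lens mode uses
   [0.05, 20]; the cortex/nucleus comparison raises the ceiling to 100
   because nuclear proteins can be essentially all-14N.

Proteins are then classified three ways, mirroring how turnover studies
partition their identifications: QUANTIFIED (at least one PASS ratio),
LIGHT_ONLY (14N evidence, no heavy), HEAVY_ONLY (the reverse). Proteins
with evidence in both channels but no ratio of sufficient quality are
reported separately as AMBIGUOUS rather than silently merged into a class.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ValidationError
from .xic_ratio import PeptideRatioRecord

logger = logging.getLogger("silamq.protein_rollup")

__all__ = [
    "ProteinTurnoverRecord",
    "grubbs_critical_value",
    "grubbs_filter",
    "composite_protein_ratio",
    "classify_protein",
    "rank_light_only_by_abundance",
    "rollup_proteins",
    "CAP_LO",
    "CAP_HI_LENS",
    "CAP_HI_CORTEX_NUCLEUS",
    "QUANTIFIED",
    "LIGHT_ONLY",
    "HEAVY_ONLY",
    "AMBIGUOUS",
]

CAP_LO = 0.05
CAP_HI_LENS = 20.0
CAP_HI_CORTEX_NUCLEUS = 100.0
DEFAULT_GRUBBS_ALPHA = 0.01

QUANTIFIED = "QUANTIFIED"
LIGHT_ONLY = "LIGHT_ONLY"
HEAVY_ONLY = "HEAVY_ONLY"
AMBIGUOUS = "AMBIGUOUS"


@dataclass
class ProteinTurnoverRecord:
    """Protein-level turnover summary."""

    accession: str
    turnover_class: str
    ratio: Optional[float] = None        # 14N/15N, only when QUANTIFIED
    capped: bool = False
    cap_lo: float = CAP_LO
    cap_hi: float = CAP_HI_LENS
    n_peptides_used: int = 0
    n_peptides_removed: int = 0
    n_peptides_total: int = 0
    spectral_count_light: int = 0
    spectral_count_heavy: int = 0
    tissue: str = "lens"

    @property
    def total_spectral_count(self) -> int:
        return self.spectral_count_light + self.spectral_count_heavy


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t_(1 - alpha/(2n), n-2).
    """
    if n < 3:
        raise ValidationError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_filter(
    values: Sequence[float], alpha: float = DEFAULT_GRUBBS_ALPHA
) -> Tuple[List[float], List[float]]:
    """Iterative two-sided Grubbs outlier removal.

    Repeatedly computes G = max|x_i - mean| / sd, removes the most extreme
    value while G exceeds the critical value at ``alpha``, and stops when
    no outlier remains or only two values are left. Inputs with n <= 2 or
    zero spread are returned unchanged. The test is applied to the values
    exactly as given — the protein rollup passes log-ratios.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    kept = [float(v) for v in values]
    removed: List[float] = []
    while len(kept) > 2:
        arr = np.asarray(kept)
        sd = arr.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(arr - arr.mean())
        i = int(dev.argmax())
        if dev[i] / sd > grubbs_critical_value(len(kept), alpha):
            removed.append(kept.pop(i))
        else:
            break
    return kept, removed


def _clamp(ratio: float, cap_lo: float, cap_hi: float) -> Tuple[float, bool]:
    if ratio < cap_lo:
        return cap_lo, True
    if ratio > cap_hi:
        return cap_hi, True
    return ratio, False


def composite_protein_ratio(
    records: Sequence[PeptideRatioRecord],
    cap_lo: float = CAP_LO,
    cap_hi: float = CAP_HI_LENS,
    alpha: float = DEFAULT_GRUBBS_ALPHA,
    method: str = "weighted_geomean",
) -> Tuple[Optional[float], bool, int, int]:
    """Composite 14N/15N ratio of one protein from its PASS peptides.

    Grubbs-filters the log-ratios (only when more than two peptides are
    available), aggregates the survivors, and clamps into
    [cap_lo, cap_hi]. Extremely low signal in one channel makes the raw
    ratio mathematically unbounded, hence the caps.

    Returns (ratio, capped, n_used, n_removed); ratio is None when no PASS
    peptide ratio exists (the protein falls through to the
    classification-only path).
    """
    ratios, weights = [], []
    for r in records:
        if r.passed and r.ratio is not None and r.ratio > 0:
            ratios.append(r.ratio)
            weights.append(max(r.light_area + r.heavy_area, 0.0))
    if not ratios:
        return None, False, 0, 0
    logs = np.log(ratios)
    w = np.asarray(weights)
    if len(logs) > 2:
        kept_logs, removed = grubbs_filter(logs.tolist(), alpha)
        keep_mask = np.ones(len(logs), dtype=bool)
        for rv in removed:
            # remove one matching entry per removed value
            for i in np.nonzero(keep_mask)[0]:
                if logs[i] == rv:
                    keep_mask[i] = False
                    break
        logs, w = logs[keep_mask], w[keep_mask]
        n_removed = len(removed)
    else:
        n_removed = 0
    if method == "weighted_geomean":
        if w.sum() <= 0:
            w = np.ones_like(w)
        ratio = float(np.exp(np.average(logs, weights=w)))
    elif method == "median":
        ratio = float(np.exp(np.median(logs)))
    else:
        raise ValidationError(f"unknown aggregation method {method!r}")
    ratio, capped = _clamp(ratio, cap_lo, cap_hi)
    return ratio, capped, int(len(logs)), int(n_removed)


def classify_protein(
    light_evidence: int, heavy_evidence: int, quantified: bool
) -> str:
    """Three-way turnover class (plus AMBIGUOUS).

    QUANTIFIED if at least one PASS ratio exists; LIGHT_ONLY / HEAVY_ONLY
    when all peptide evidence sits in one channel; AMBIGUOUS when both
    channels were seen but no ratio passed the quality filter.
    """
    if light_evidence == 0 and heavy_evidence == 0 and not quantified:
        raise ValidationError("protein reached rollup with no channel evidence")
    if quantified:
        return QUANTIFIED
    if light_evidence > 0 and heavy_evidence == 0:
        return LIGHT_ONLY
    if heavy_evidence > 0 and light_evidence == 0:
        return HEAVY_ONLY
    return AMBIGUOUS


def rank_light_only_by_abundance(
    records: Sequence[ProteinTurnoverRecord], top_n: Optional[int] = None
) -> List[ProteinTurnoverRecord]:
    """Most abundant 14N-only proteins, by total spectral count.

    Spectral counts are the abundance proxy; ties break by accession so the
    ranking is deterministic.
    """
    ranked = sorted(
        (r for r in records if r.turnover_class == LIGHT_ONLY),
        key=lambda r: (-r.total_spectral_count, r.accession),
    )
    return ranked[:top_n] if top_n is not None else ranked


def rollup_proteins(
    peptide_records: Sequence[PeptideRatioRecord],
    psm_channel_counts: Optional[Dict[str, Tuple[int, int]]] = None,
    cap_lo: float = CAP_LO,
    cap_hi: float = CAP_HI_LENS,
    alpha: float = DEFAULT_GRUBBS_ALPHA,
    method: str = "weighted_geomean",
    tissue: str = "lens",
) -> List[ProteinTurnoverRecord]:
    """Aggregate peptide ratio records into protein turnover records.

    A peptide mapping to several accessions contributes to each of them
    (shared-peptide assignment; razor attribution is out of scope).
    ``psm_channel_counts`` maps accession -> (light, heavy) spectral
    counts; when omitted, counts are derived from peptide channel-presence
    flags.
    """
    by_protein: Dict[str, List[PeptideRatioRecord]] = {}
    for rec in peptide_records:
        for acc in rec.proteins:
            by_protein.setdefault(acc, []).append(rec)
    out: List[ProteinTurnoverRecord] = []
    for acc in sorted(by_protein):
        recs = by_protein[acc]
        ratio, capped, n_used, n_removed = composite_protein_ratio(
            recs, cap_lo=cap_lo, cap_hi=cap_hi, alpha=alpha, method=method
        )
        light_ev = sum(1 for r in recs if r.light_present)
        heavy_ev = sum(1 for r in recs if r.heavy_present)
        if light_ev == 0 and heavy_ev == 0:
            logger.debug("protein %s: no channel evidence, skipped", acc)
            continue
        cls = classify_protein(light_ev, heavy_ev, quantified=ratio is not None)
        if psm_channel_counts is not None:
            sc_l, sc_h = psm_channel_counts.get(acc, (0, 0))
        else:
            sc_l, sc_h = light_ev, heavy_ev
        out.append(ProteinTurnoverRecord(
            accession=acc,
            turnover_class=cls,
            ratio=ratio if cls == QUANTIFIED else None,
            capped=capped,
            cap_lo=cap_lo,
            cap_hi=cap_hi,
            n_peptides_used=n_used,
            n_peptides_removed=n_removed,
            n_peptides_total=len(recs),
            spectral_count_light=sc_l,
            spectral_count_heavy=sc_h,
            tissue=tissue,
        ))
    return out
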