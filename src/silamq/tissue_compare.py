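"""Cross-tissue and cortex-vs-nucleus turnover summaries.

Summaries over classified protein records: per-tissue class counts and
fractions (the three-way 14N-only / 15N-only / quantified partition, with
AMBIGUOUS reported alongside but excluded from the fractions), sorted
ratio distributions with log-spaced histograms (cap bins isolated, since
the caps pile probability mass at the boundaries), the paired
cortex-vs-nucleus protein table, and light/heavy spectral-count splits.

Optional plot helpers render the ratio rank curve and the paired scatter.
"""
from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .protein_rollup import (
    AMBIGUOUS,
    HEAVY_ONLY,
    LIGHT_ONLY,
    QUANTIFIED,
    ProteinTurnoverRecord,
)

__all__ = [
    "classification_summary",
    "ratio_distribution",
    "paired_fraction_compare",
    "abundance_split",
    "plot_ratio_rank",
    "plot_paired_scatter",
]

THREE_CLASSES = [LIGHT_ONLY, HEAVY_ONLY, QUANTIFIED]


def classification_summary(
    records: Sequence[ProteinTurnoverRecord],
) -> pd.DataFrame:
    """Per-tissue counts and fractions of the three turnover classes.

    Fractions are over LIGHT_ONLY + HEAVY_ONLY + QUANTIFIED only and sum
    to 1 per tissue; AMBIGUOUS proteins are counted in their own column.
    An empty record list yields an empty frame.
    """
    if not records:
        return pd.DataFrame(
            columns=["tissue"] + [f"n_{c}" for c in THREE_CLASSES]
            + ["n_AMBIGUOUS"] + [f"frac_{c}" for c in THREE_CLASSES]
        )
    rows = []
    by_tissue: Dict[str, List[ProteinTurnoverRecord]] = {}
    for r in records:
        by_tissue.setdefault(r.tissue, []).append(r)
    for tissue in sorted(by_tissue):
        recs = by_tissue[tissue]
        counts = {c: sum(1 for r in recs if r.turnover_class == c)
                  for c in THREE_CLASSES + [AMBIGUOUS]}
        total3 = sum(counts[c] for c in THREE_CLASSES)
        row = {"tissue": tissue}
        row.update({f"n_{c}": counts[c] for c in THREE_CLASSES})
        row["n_AMBIGUOUS"] = counts[AMBIGUOUS]
        for c in THREE_CLASSES:
            row[f"frac_{c}"] = counts[c] / total3 if total3 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def ratio_distribution(
    records: Sequence[ProteinTurnoverRecord],
    n_bins: int = 20,
) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Sorted 14N/15N ratios of quantified proteins plus a histogram.

    Returns (table, bin_edges, bin_counts). The table lists ratios
    ascending with the protein's capped flag. Bins are log-spaced across
    the cap interval; capped values sit in dedicated first/last bins so
    the artificial mass at the boundaries stays visible and separate.
    """
    quant = [r for r in records if r.turnover_class == QUANTIFIED]
    quant.sort(key=lambda r: (r.ratio, r.accession))
    table = pd.DataFrame({
        "accession": [r.accession for r in quant],
        "ratio_14N_15N": [r.ratio for r in quant],
        "capped": [r.capped for r in quant],
    })
    if not quant:
        return table, np.array([]), np.array([])
    cap_lo = quant[0].cap_lo
    cap_hi = quant[0].cap_hi
    inner_edges = np.logspace(np.log10(cap_lo), np.log10(cap_hi), n_bins + 1)
    uncapped = np.array([r.ratio for r in quant if not r.capped])
    counts, _ = np.histogram(uncapped, bins=inner_edges)
    n_cap_lo = sum(1 for r in quant if r.capped and r.ratio <= cap_lo)
    n_cap_hi = sum(1 for r in quant if r.capped and r.ratio >= cap_hi)
    # isolate cap bins: one below and one above the log-spaced interior
    edges = np.concatenate([[cap_lo * 0.99], inner_edges, [cap_hi * 1.01]])
    counts = np.concatenate([[n_cap_lo], counts, [n_cap_hi]])
    return table, edges, counts


def _unique_by_accession(
    records: Sequence[ProteinTurnoverRecord], label: str
) -> Dict[str, ProteinTurnoverRecord]:
    out: Dict[str, ProteinTurnoverRecord] = {}
    for r in records:
        if r.accession in out:
            raise ValidationError(
                f"duplicate accession {r.accession!r} in {label} records"
            )
        out[r.accession] = r
    return out


def paired_fraction_compare(
    cortex_records: Sequence[ProteinTurnoverRecord],
    nucleus_records: Sequence[ProteinTurnoverRecord],
) -> Dict[str, object]:
    """Join cortex and nucleus protein records by accession.

    Returns a dict with ``joined`` (DataFrame of proteins seen in both
    fractions: per-fraction ratio, class and spectral counts) plus sorted
    ``cortex_only`` and ``nucleus_only`` accession lists. Inputs are
    expected to come from cortex/nucleus-mode runs (ratio ceiling 100);
    ceiling ties are reported as ties.
    """
    cortex = _unique_by_accession(cortex_records, "cortex")
    nucleus = _unique_by_accession(nucleus_records, "nucleus")
    shared = sorted(set(cortex) & set(nucleus))
    joined = pd.DataFrame({
        "accession": shared,
        "cortex_ratio": [cortex[a].ratio for a in shared],
        "nucleus_ratio": [nucleus[a].ratio for a in shared],
        "cortex_class": [cortex[a].turnover_class for a in shared],
        "nucleus_class": [nucleus[a].turnover_class for a in shared],
        "cortex_spectral_count": [cortex[a].total_spectral_count for a in shared],
        "nucleus_spectral_count": [nucleus[a].total_spectral_count for a in shared],
    })
    return {
        "joined": joined,
        "cortex_only": sorted(set(cortex) - set(nucleus)),
        "nucleus_only": sorted(set(nucleus) - set(cortex)),
    }


def abundance_split(
    records: Sequence[ProteinTurnoverRecord],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Light and heavy spectral-count tables keyed by accession x tissue.

    The two tables together conserve the total PSM count of the input
    records (old-protein abundance vs. new-protein abundance).
    """
    keys = sorted({(r.accession, r.tissue) for r in records})
    idx: Dict[Tuple[str, str], ProteinTurnoverRecord] = {
        (r.accession, r.tissue): r for r in records
    }
    if len(idx) != len(records):
        raise ValidationError("duplicate accession/tissue pair in records")
    light = pd.DataFrame({
        "accession": [k[0] for k in keys],
        "tissue": [k[1] for k in keys],
        "spectral_count": [idx[k].spectral_count_light for k in keys],
    })
    heavy = pd.DataFrame({
        "accession": [k[0] for k in keys],
        "tissue": [k[1] for k in keys],
        "spectral_count": [idx[k].spectral_count_heavy for k in keys],
    })
    return light, heavy


def plot_ratio_rank(
    records: Sequence[ProteinTurnoverRecord], path: str
) -> None:
    """Rank-ordered 14N/15N ratio curve (log y), written as an image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table, _, _ = ratio_distribution(records)
    fig, ax = plt.subplots(figsize=(6, 4))
    if len(table):
        ax.plot(range(1, len(table) + 1), table["ratio_14N_15N"], ".-", ms=4)
        ax.set_yscale("log")
    ax.set_xlabel("protein rank (low to high ratio)")
    ax.set_ylabel(r"$^{14}$N/$^{15}$N ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_paired_scatter(compare: Dict[str, object], path: str) -> None:
    """Cortex vs. nucleus per-protein ratio scatter, written as an image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    joined: pd.DataFrame = compare["joined"]  # type: ignore[assignment]
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(joined))
    ax.plot(x, joined["cortex_ratio"], "d", color="tab:red", label="cortex")
    ax.plot(x, joined["nucleus_ratio"], "o", color="tab:blue", label="nucleus",
            mfc="none")
    if len(joined):
        ax.set_yscale("log")
    ax.set_xlabel("protein (shared accessions)")
    ax.set_ylabel(r"$^{14}$N/$^{15}$N ratio")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
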