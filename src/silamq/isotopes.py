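"""Peptide chemistry for metabolic 15N labeling.

Elemental compositions of tryptic peptides, and theoretical isotope
envelopes for the two MS1 channels of a pulse-labeling experiment:

* LIGHT — the pre-existing ("old") protein pool at natural isotopic
  abundance, dominated by 14N;
* HEAVY — the newly synthesized pool, in which the nitrogen isotope
  distribution is replaced by the dietary 15N enrichment (all other
  elements stay natural).

Envelopes are *aggregate* (unit-mass-binned): isotopologues are grouped by
their nominal mass offset from the monoisotopic peak, and each bin carries
the abundance-weighted mean mass of its members. At the 60K Orbitrap
resolution of typical MS1 surveys the fine structure within a bin is not
resolved, so this is the quantity the instrument actually measures.

The isotope masses/abundances and residue formulas live in two documented
plain-text tables under ``silamq/data``.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "Channel",
    "ElementalComposition",
    "IsotopeEnvelope",
    "CARBAMIDOMETHYL",
    "DEFAULT_FIXED_MODS",
    "DEFAULT_ENRICHMENT",
    "DELTA_N15",
    "PROTON_MASS",
    "elemental_composition",
    "nitrogen_count",
    "monoisotopic_mass",
    "isotope_envelope",
    "mz_targets",
]

PROTON_MASS = 1.00727646688  # Da, mass of a proton (charge carrier in ESI+)

DEFAULT_ENRICHMENT = 0.99
"""Default 15N atom fraction of the heavy channel.

The labeling literature reports serum *protein* labeling "greater than 99%"
after a full SILAM course; the atom enrichment of the diet is not stated, so
0.99 is the conservative reading and is configurable everywhere it is used.
"""

ELEMENTS = ("C", "H", "N", "O", "S")


def _load_table(name: str) -> List[List[str]]:
    text = resources.files("silamq.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows[1:]  # drop header


def _load_isotopes() -> Dict[str, List[Tuple[int, float, float]]]:
    table: Dict[str, List[Tuple[int, float, float]]] = {}
    for el, nominal, mass, ab in _load_table("elements.tsv"):
        table.setdefault(el, []).append((int(nominal), float(mass), float(ab)))
    for el in table:
        table[el].sort()
    return table


def _load_residues() -> Dict[str, Dict[str, int]]:
    out: Dict[str, Dict[str, int]] = {}
    for row in _load_table("residues.tsv"):
        code, counts = row[0], row[1:]
        out[code] = {el: int(c) for el, c in zip(ELEMENTS, counts) if int(c)}
    return out


ISOTOPES: Dict[str, List[Tuple[int, float, float]]] = _load_isotopes()
RESIDUE_FORMULAS: Dict[str, Dict[str, int]] = _load_residues()

#: 15N - 14N mass difference in Da; the per-nitrogen channel spacing.
DELTA_N15 = ISOTOPES["N"][1][1] - ISOTOPES["N"][0][1]

WATER = {"H": 2, "O": 1}


class Channel(str, enum.Enum):
    """MS1 quantification channel of a labeled peptide pair."""

    LIGHT = "LIGHT"   # pre-existing, natural-abundance (14N) pool
    HEAVY = "HEAVY"   # newly synthesized, 15N-enriched pool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ElementalComposition:
    """Integer atom counts per element for a peptide plus modifications.

    Behaves like an immutable mapping from element symbol to a non-negative
    count; supports ``+`` (element-wise sum, commutative/associative) and
    integer ``*``.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Optional[Mapping[str, int]] = None, **kw: int):
        merged: Dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, n in src.items():
                merged[el] = merged.get(el, 0) + int(n)
        for el, n in merged.items():
            if n < 0:
                raise ValueError(f"negative atom count for element {el!r}: {n}")
        self._counts = {el: n for el, n in sorted(merged.items()) if n > 0}

    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def get(self, el: str, default: int = 0) -> int:
        return self._counts.get(el, default)

    def items(self):
        return self._counts.items()

    def keys(self):
        return self._counts.keys()

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementalComposition):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = dict(self._counts)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ElementalComposition(out)

    def __mul__(self, k: int) -> "ElementalComposition":
        if not isinstance(k, int) or k < 0:
            raise ValueError("composition can only be scaled by a non-negative integer")
        return ElementalComposition({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def total_atoms(self) -> int:
        return sum(self._counts.values())

    def formula(self) -> str:
        return "".join(f"{el}{n}" for el, n in self._counts.items())

    def __repr__(self) -> str:
        return f"ElementalComposition({self._counts!r})"


#: Carbamidomethylation of cysteine (iodoacetamide alkylation), +57.02146 Da.
CARBAMIDOMETHYL = ElementalComposition({"C": 2, "H": 3, "N": 1, "O": 1})

#: Default fixed-modification table: residue code -> composition added.
DEFAULT_FIXED_MODS: Dict[str, ElementalComposition] = {"C": CARBAMIDOMETHYL}


def elemental_composition(
    sequence: str,
    fixed_mods: Optional[Mapping[str, ElementalComposition]] = None,
) -> ElementalComposition:
    """Elemental composition of a peptide with fixed modifications applied.

    Sum of residue formulas plus one water; every residue listed in
    ``fixed_mods`` additionally carries its modification composition.
    ``fixed_mods`` defaults to carbamidomethyl cysteine; pass ``{}`` for an
    unmodified peptide.

    Raises
    ------
    ValueError
        If the sequence is empty or contains a character outside the 20
        standard one-letter residue codes (the error names the offending
        character and its 1-based position).
    """
    if fixed_mods is None:
        fixed_mods = DEFAULT_FIXED_MODS
    if not sequence:
        raise ValueError("empty peptide sequence")
    counts: Dict[str, int] = dict(WATER)
    for pos, aa in enumerate(sequence, start=1):
        try:
            formula = RESIDUE_FORMULAS[aa]
        except KeyError:
            raise ValueError(
                f"unknown residue code {aa!r} at position {pos} in {sequence!r}"
            ) from None
        for el, n in formula.items():
            counts[el] = counts.get(el, 0) + n
        mod = fixed_mods.get(aa)
        if mod is not None:
            for el, n in mod.items():
                counts[el] = counts.get(el, 0) + n
    return ElementalComposition(counts)


def nitrogen_count(composition: ElementalComposition) -> int:
    """Number of nitrogen atoms (sets the heavy channel's mass shift)."""
    return composition["N"]


def _isotope_table(channel: Channel, enrichment: float):
    """Per-element isotope table for a channel.

    For HEAVY, nitrogen's two-isotope distribution becomes
    (1 - enrichment, enrichment); every other element stays natural.
    """
    if not 0.0 <= enrichment <= 1.0:
        raise ValueError(f"enrichment must be in [0, 1], got {enrichment}")
    table = {el: list(iso) for el, iso in ISOTOPES.items()}
    if channel == Channel.HEAVY:
        (n14, m14, _), (n15, m15, _) = ISOTOPES["N"]
        table["N"] = [(n14, m14, 1.0 - enrichment), (n15, m15, enrichment)]
    return table


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Aggregate isotope envelope of one channel of a peptide.

    ``masses`` are neutral, monoisotopic-aligned (abundance-weighted mean
    mass per nominal bin), strictly increasing; ``abundances`` are relative
    and sum to 1 for the full distribution. When truncated to the top-k most
    abundant peaks the stored abundances are renormalized to sum to 1 and
    both flags record that.
    """

    masses: np.ndarray
    abundances: np.ndarray
    channel: Channel
    enrichment: float
    truncated: bool = False
    renormalized: bool = False

    @property
    def peaks(self) -> List[Tuple[float, float]]:
        return list(zip(self.masses.tolist(), self.abundances.tolist()))

    @property
    def monoisotopic_mass(self) -> float:
        return float(self.masses[0])


def _convolve_bins(p1, mp1, p2, mp2):
    """Convolve two binned (probability, probability*mass) distributions."""
    p = np.convolve(p1, p2)
    mp = np.convolve(mp1, p2) + np.convolve(p1, mp2)
    return p, mp


def _element_distribution(n_atoms: int, isotopes) -> Tuple[np.ndarray, np.ndarray]:
    """Binned isotopologue distribution of ``n_atoms`` of one element.

    Bins are nominal-mass offsets from the all-lightest-isotope state.
    Computed by exponentiation-by-squaring of the single-atom distribution;
    the expansion is exact (no pruning), so the full distribution conserves
    probability to floating-point rounding.
    """
    base_nominal = isotopes[0][0]
    max_off = isotopes[-1][0] - base_nominal
    p1 = np.zeros(max_off + 1)
    mp1 = np.zeros(max_off + 1)
    for nominal, mass, ab in isotopes:
        off = nominal - base_nominal
        p1[off] += ab
        mp1[off] += ab * mass
    # identity for convolution: single bin, probability 1, mass 0
    p, mp = np.array([1.0]), np.array([0.0])
    sq_p, sq_mp = p1, mp1
    k = n_atoms
    while k:
        if k & 1:
            p, mp = _convolve_bins(p, mp, sq_p, sq_mp)
        k >>= 1
        if k:
            sq_p, sq_mp = _convolve_bins(sq_p, sq_mp, sq_p, sq_mp)
    return p, mp


def isotope_envelope(
    composition: ElementalComposition,
    channel: Channel = Channel.LIGHT,
    enrichment: float = DEFAULT_ENRICHMENT,
    top_k: Optional[int] = 3,
) -> IsotopeEnvelope:
    """Aggregate isotope envelope of a composition in one channel.

    Per-element multinomial isotopologue distributions are expanded on
    nominal-mass-offset bins and convolved across elements; each aggregate
    bin carries the abundance-weighted mean mass of its isotopologues. The
    untruncated distribution sums to 1 (checked to 1e-9). ``top_k`` keeps
    only the k most abundant peaks (renormalized); ``None`` keeps all.

    The default ``top_k=3`` captures >=95% of the envelope intensity for
    tryptic-size peptides while limiting chromatographic interference.
    """
    channel = Channel(channel)
    table = _isotope_table(channel, enrichment)
    p, mp = np.array([1.0]), np.array([0.0])
    for el, n_atoms in composition.items():
        if el not in table:
            raise ValueError(f"no isotope data for element {el!r}")
        if n_atoms:
            ep, emp = _element_distribution(n_atoms, table[el])
            p, mp = _convolve_bins(p, mp, ep, emp)
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"envelope abundance not conserved: sum={total!r}")
    # drop numerically negligible bins: below ~1e-13 the weighted bin mass
    # loses accuracy (denormal probabilities), and the total abundance lost
    # stays orders of magnitude under the 1e-9 conservation guarantee
    keep = p > 1e-13
    masses = mp[keep] / p[keep]
    abundances = p[keep]
    truncated = renormalized = False
    if top_k is not None and top_k < len(abundances):
        idx = np.sort(np.argsort(abundances)[::-1][:top_k])
        masses, abundances = masses[idx], abundances[idx]
        abundances = abundances / abundances.sum()
        truncated = renormalized = True
    return IsotopeEnvelope(
        masses=masses,
        abundances=abundances,
        channel=channel,
        enrichment=enrichment if channel == Channel.HEAVY else 0.0,
        truncated=truncated,
        renormalized=renormalized,
    )


def monoisotopic_mass(
    composition: ElementalComposition, channel: Channel = Channel.LIGHT
) -> float:
    """Neutral monoisotopic mass of a composition.

    LIGHT: all-lightest-isotope mass. HEAVY: the fully 15N-substituted
    reference mass, i.e. light monoisotopic + N x 0.9970349 Da — the peak
    the search engine matches for the heavy form at high enrichment.
    """
    m = sum(ISOTOPES[el][0][1] * n for el, n in composition.items())
    if Channel(channel) == Channel.HEAVY:
        m += composition["N"] * DELTA_N15
    return m


def mz_targets(envelope: IsotopeEnvelope, charge: int) -> np.ndarray:
    """m/z values of the envelope's peaks at a charge state.

    Each neutral mass M maps to (M + z * m_proton) / z; peak order is
    preserved.
    """
    if not isinstance(charge, (int, np.integer)) or charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge!r}")
    return (envelope.masses + charge * PROTON_MASS) / charge
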