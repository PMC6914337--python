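"""Peptide chemistry: compositions, envelopes, and the enumeration oracle.

The aggregate-envelope code is checked against an exhaustive isotopologue
enumeration built independently on pyteomics' NIST mass/abundance tables.
"""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pyteomics.mass import nist_mass

from silamq.isotopes import (
    CARBAMIDOMETHYL,
    Channel,
    DELTA_N15,
    ElementalComposition,
    PROTON_MASS,
    elemental_composition,
    isotope_envelope,
    monoisotopic_mass,
    mz_targets,
    nitrogen_count,
)

# ---------------------------------------------------------------------------
# independent oracle: exhaustive isotopologue enumeration
# ---------------------------------------------------------------------------

def _nist_isotopes(element, heavy_enrichment=None):
    """(mass, abundance) list from pyteomics' NIST table, most-common first
    nominal order; optionally overriding nitrogen with an enrichment."""
    entries = sorted(
        (k, v) for k, v in nist_mass[element].items() if k != 0 and v[1] > 0
    )
    iso = [(m, ab) for _, (m, ab) in entries]
    if element == "N" and heavy_enrichment is not None:
        iso = [(iso[0][0], 1.0 - heavy_enrichment), (iso[1][0], heavy_enrichment)]
    return iso


def _multinomial_combos(n, k):
    """All tuples of k non-negative integers summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _multinomial_combos(n - first, k - 1):
            yield (first,) + rest


def brute_force_envelope(counts, heavy_enrichment=None):
    """Aggregate envelope by enumerating every isotopologue combination.

    Returns dict: nominal-offset bin -> (weighted mean mass, abundance).
    Only feasible for small compositions (<= ~30 atoms).
    """
    per_element = []
    for el, n in counts.items():
        if n == 0:
            continue
        iso = _nist_isotopes(el, heavy_enrichment if el == "N" else None)
        states = []
        for combo in _multinomial_combos(n, len(iso)):
            p = math.factorial(n)
            mass = 0.0
            for c, (m, ab) in zip(combo, iso):
                p = p // math.factorial(c)
                mass += c * m
            prob = p
            for c, (m, ab) in zip(combo, iso):
                prob *= ab ** c
            offset = sum(
                c * round(m - iso[0][0]) for c, (m, ab) in zip(combo, iso)
            )
            states.append((offset, mass, prob))
        per_element.append(states)
    bins = {}
    for assignment in itertools.product(*per_element) if per_element else [()]:
        off = sum(s[0] for s in assignment)
        mass = sum(s[1] for s in assignment)
        prob = math.prod(s[2] for s in assignment)
        m_acc, p_acc = bins.get(off, (0.0, 0.0))
        bins[off] = (m_acc + mass * prob, p_acc + prob)
    return {
        off: (m / p, p) for off, (m, p) in bins.items() if p > 0
    }


def _random_small_composition(rng):
    """Random CHNOS composition with <= 30 atoms (N and S guaranteed off/on)."""
    while True:
        counts = {
            "C": int(rng.integers(0, 9)),
            "H": int(rng.integers(0, 13)),
            "N": int(rng.integers(0, 5)),
            "O": int(rng.integers(0, 5)),
            "S": int(rng.integers(0, 2)),
        }
        total = sum(counts.values())
        if 1 <= total <= 30:
            return {k: v for k, v in counts.items() if v}


@pytest.mark.parametrize("channel,enrichment", [
    (Channel.LIGHT, None),
    (Channel.HEAVY, 0.99),
    (Channel.HEAVY, 0.9),
])
def test_envelope_matches_exhaustive_enumeration(channel, enrichment):
    """Aggregate envelopes equal the brute-force isotopologue enumeration
    for >= 50 random small compositions (1e-9 abundance, 1e-6 Da mass)."""
    rng = np.random.default_rng(7)
    for _ in range(55):
        counts = _random_small_composition(rng)
        comp = ElementalComposition(counts)
        env = isotope_envelope(
            comp, channel, enrichment if enrichment is not None else 0.99,
            top_k=None,
        )
        oracle = brute_force_envelope(
            counts, enrichment if channel == Channel.HEAVY else None
        )
        assert abs(env.abundances.sum() - 1.0) < 1e-9
        # align bins by nominal offset from the monoisotopic peak; the
        # package omits numerically negligible bins, so compare every
        # oracle bin that carries real abundance
        env_bins = {
            int(round(m - env.masses[0])): (m, p)
            for m, p in zip(env.masses, env.abundances)
        }
        for off in sorted(oracle):
            m_exp, p_exp = oracle[off]
            if p_exp < 1e-12:
                continue
            m_got, p_got = env_bins[off]
            assert abs(p_got - p_exp) < 1e-9
            assert abs(m_got - m_exp) < 1e-6


# ---------------------------------------------------------------------------
# elemental composition
# ---------------------------------------------------------------------------

def test_glycine_composition_is_free_glycine():
    comp = elemental_composition("G", {})
    assert comp == {"C": 2, "H": 5, "N": 1, "O": 2}


def test_peptide_nitrogen_counts():
    assert nitrogen_count(elemental_composition("PEPTIDE", {})) == 7
    assert nitrogen_count(elemental_composition("K", {})) == 2
    assert nitrogen_count(elemental_composition("R", {})) == 4
    assert nitrogen_count(ElementalComposition({"C": 4, "H": 8})) == 0


def test_lysine_matches_free_amino_acid_formula():
    assert elemental_composition("K", {}) == {"C": 6, "H": 14, "N": 2, "O": 2}


def test_carbamidomethyl_adds_57_02146_da():
    modified = elemental_composition("C")          # default fixed mods
    plain = elemental_composition("C", {})
    delta = monoisotopic_mass(modified) - monoisotopic_mass(plain)
    assert delta == pytest.approx(57.02146, abs=1e-4)


def test_unknown_residue_is_named_with_position():
    with pytest.raises(ValueError, match=r"'B' at position 3"):
        elemental_composition("AABAA")


def test_empty_sequence_rejected():
    with pytest.raises(ValueError, match="empty"):
        elemental_composition("")


def test_negative_atom_count_rejected():
    with pytest.raises(ValueError, match="negative"):
        ElementalComposition({"C": -1})


@given(st.lists(
    st.dictionaries(st.sampled_from("CHNOS"), st.integers(0, 20), max_size=5),
    min_size=3, max_size=3,
))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_composition_addition_commutative_associative(dicts):
    a, b, c = (ElementalComposition(d) for d in dicts)
    assert a + b == b + a
    assert (a + b) + c == a + (b + c)


# ---------------------------------------------------------------------------
# envelope invariants
# ---------------------------------------------------------------------------

@given(st.dictionaries(
    st.sampled_from("CHNOS"), st.integers(1, 60), min_size=1, max_size=5,
))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_untruncated_envelope_conserves_abundance(counts):
    comp = ElementalComposition(counts)
    for channel in (Channel.LIGHT, Channel.HEAVY):
        env = isotope_envelope(comp, channel, 0.99, top_k=None)
        assert abs(env.abundances.sum() - 1.0) < 1e-9
        assert np.all(np.diff(env.masses) > 0)


def test_empty_composition_single_zero_peak():
    env = isotope_envelope(ElementalComposition({}), Channel.LIGHT)
    assert env.masses.tolist() == [0.0]
    assert env.abundances.tolist() == [1.0]


@pytest.mark.parametrize("sequence", ["PEPTIDE", "GKR", "MCWY", "AAAAAAK"])
def test_full_enrichment_shift_is_nitrogen_count_times_delta(sequence):
    """HEAVY at enrichment 1.0 starts exactly N x 0.9970349 Da above LIGHT."""
    comp = elemental_composition(sequence, {})
    light = isotope_envelope(comp, Channel.LIGHT, top_k=None)
    heavy = isotope_envelope(comp, Channel.HEAVY, enrichment=1.0, top_k=None)
    shift = heavy.monoisotopic_mass - light.monoisotopic_mass
    assert shift == pytest.approx(nitrogen_count(comp) * 0.9970349, abs=1e-6)
    assert DELTA_N15 == pytest.approx(0.9970349, abs=1e-7)


def test_sub_monoisotopic_heavy_abundance_decreases_with_enrichment():
    """Raising 15N enrichment drains the heavy channel's 14N-containing
    (sub-all-15N) peaks."""
    comp = elemental_composition("PEPTIDEK", {})
    n = nitrogen_count(comp)
    prev = None
    for e in (0.9, 0.95, 0.99, 1.0):
        env = isotope_envelope(comp, Channel.HEAVY, enrichment=e, top_k=None)
        light_mono = isotope_envelope(comp, Channel.LIGHT, top_k=None).monoisotopic_mass
        sub = env.abundances[env.masses < light_mono + n * DELTA_N15 - 0.5].sum()
        if prev is not None:
            assert sub < prev
        prev = sub
    assert prev == pytest.approx(0.0, abs=1e-12)


def test_top_k_truncation_renormalizes_and_flags():
    comp = elemental_composition("PEPTIDEK", {})
    env = isotope_envelope(comp, Channel.LIGHT, top_k=3)
    assert len(env.masses) == 3
    assert env.truncated and env.renormalized
    assert env.abundances.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# m/z targets
# ---------------------------------------------------------------------------

def test_mz_targets_closed_form():
    env = isotope_envelope(ElementalComposition({}), Channel.LIGHT)
    env = type(env)(masses=np.array([1000.0]), abundances=np.array([1.0]),
                    channel=Channel.LIGHT, enrichment=0.0)
    assert mz_targets(env, 2)[0] == pytest.approx(501.007276, abs=1e-6)
    assert mz_targets(env, 1)[0] == pytest.approx(1001.007276, abs=1e-6)


def test_mz_targets_rejects_charge_zero():
    env = isotope_envelope(elemental_composition("PEPTIDE", {}), Channel.LIGHT)
    with pytest.raises(ValueError, match="charge"):
        mz_targets(env, 0)
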