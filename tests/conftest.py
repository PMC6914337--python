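"""Shared fixtures: small synthetic labeled runs with known ground truth."""
import numpy as np
import pytest

from silamq.cli import quantify_run, resolve_params
from silamq.spectra_io import read_ms1, read_psm_table
from silamq.synthetic_data import (
    build_ground_truth,
    generate_proteome,
    simulate_run,
)


@pytest.fixture(scope="session")
def noiseless_bundle(tmp_path_factory):
    """Noiseless run: 15 proteins incl. unlabeled and fully labeled ones."""
    proteome = generate_proteome(15, seed=101)
    truth = build_ground_truth(
        proteome, seed=102, frac_unlabeled=0.2, frac_fully_labeled=0.1
    )
    out = tmp_path_factory.mktemp("noiseless")
    return simulate_run(truth, str(out), seed=103)


@pytest.fixture(scope="session")
def noiseless_results(noiseless_bundle):
    """Quantification of the noiseless bundle, via the on-disk files."""
    scans = read_ms1(noiseless_bundle.mzml_path)
    psms = read_psm_table(noiseless_bundle.psm_path)
    params = resolve_params()
    pep, prot, rejections = quantify_run(scans, psms, params)
    return noiseless_bundle.truth, pep, prot, rejections


def quantify_synthetic(seed, n_proteins=50, noise_cv=0.0, tmpdir=".",
                       run_length=2400.0, **truth_kw):
    """Simulate one run and quantify it; returns (truth, protein records)."""
    proteome = generate_proteome(n_proteins, seed=seed)
    truth = build_ground_truth(proteome, seed=seed + 1,
                               run_length=run_length, **truth_kw)
    bundle = simulate_run(truth, str(tmpdir), noise_cv=noise_cv, seed=seed + 2)
    scans = read_ms1(bundle.mzml_path)
    psms = read_psm_table(bundle.psm_path)
    _, prot, _ = quantify_run(scans, psms, resolve_params())
    return truth, prot
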