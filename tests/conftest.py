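import numpy as np
import pytest

import seedqnmr as sq


@pytest.fixture(scope="session")
def library():
    return sq.load_signature_library()


@pytest.fixture(scope="session")
def noiseless_params():
    return sq.AcquisitionParams(noise_sd=0.0, baseline_amplitude=0.0)


@pytest.fixture(scope="session")
def default_params():
    return sq.AcquisitionParams()


@pytest.fixture(scope="session")
def tsp_only_spectrum(noiseless_params):
    truth = sq.LineGroundTruth("tsp-only", {})
    return sq.simulate_spectrum(truth, noiseless_params, seed=0)


def panel_recovery(library, params, n_lines, seed):
    """Simulate a panel, quantify it, and collect recovery statistics."""
    spectra, truths = sq.simulate_panel(
        n_lines, seed=seed, params=params, library=library
    )
    rel_errs, correct, total = [], 0, 0
    for spec, truth in zip(spectra, truths):
        prof = sq.quantify_spectrum(spec, library=library)
        for entry in library.entries:
            truly_present = entry.name in truth.masses_mg
            total += 1
            if prof.present[entry.name] == truly_present:
                correct += 1
            if truly_present:
                true_conc = truth.masses_mg[entry.name] / 0.5
                rel_errs.append(
                    abs(prof.conc_mg_per_g[entry.name] - true_conc) / true_conc
                )
    return np.asarray(rel_errs), 100.0 * correct / total
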