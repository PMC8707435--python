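import numpy as np
import pytest

from specphenonet.mgf_io import PROTEOMIC, SpectraFile, Spectrum
from specphenonet.pipeline import GEOMETRY_OVERLAP, run_1d_experiment
from specphenonet.synthetic_data import (GeneratorConfig, default_profiles,
                                         generate_cohort)


def make_spectrum(rt, mz, intensity=None, title=None, precursor=500.0):
    mz = np.asarray(mz, dtype=float)
    if intensity is None:
        intensity = np.ones_like(mz)
    return Spectrum(
        title=title or f"scan RT={rt}",
        precursor_mz=precursor,
        rt_seconds=float(rt),
        mz=mz,
        intensity=np.asarray(intensity, dtype=float),
        charge=2,
    )


def make_file(n_spectra, file_id="f", layer=PROTEOMIC, rt_step=1.0,
              peaks_per_spectrum=3, seed=0):
    rng = np.random.default_rng(seed)
    spectra = [
        make_spectrum(i * rt_step,
                      np.sort(rng.uniform(100, 2000, peaks_per_spectrum)),
                      rng.lognormal(0, 0.5, peaks_per_spectrum),
                      title=f"{file_id} scan {i} RT={i * rt_step}")
        for i in range(n_spectra)
    ]
    return SpectraFile(file_id=file_id, omics_layer=layer, spectra=spectra)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny paired cohort for unit-level pipeline tests."""
    cfg = GeneratorConfig(n_files_per_class=2, spectra_per_file=40,
                          rt_span=200.0, seed=11)
    profiles = default_profiles(seed=5)
    return generate_cohort(profiles, cfg) + (cfg, profiles)


@pytest.fixture(scope="session")
def default_experiment():
    """Full seeded run on the default (no planted overlap) synthetic cohort."""
    return run_1d_experiment(seed=1)


@pytest.fixture(scope="session")
def geometry_experiment():
    """Full seeded run on the cohort with planted inter-class marker overlap."""
    return run_1d_experiment(overlap_map=GEOMETRY_OVERLAP, seed=1)
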