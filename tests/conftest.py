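import numpy as np
import pytest

from regulonseq.differential_expression import CountMatrix
from regulonseq.peak_calling import (call_peaks_nb_gc, call_peaks_poisson,
                                     consensus_peaks, number_peaks)
from regulonseq.synthetic_data import (SimulationConfig, generate_genome,
                                       simulate_counts, simulate_coverage)


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_dataset(default_cfg):
    """The reference synthetic dataset: annotation, truth, tracks, counts."""
    ann, truth = generate_genome(default_cfg)
    ip, inp = simulate_coverage(ann, truth, default_cfg)
    counts = simulate_counts(ann, truth, default_cfg)
    return ann, truth, ip, inp, counts


@pytest.fixture(scope="session")
def default_count_matrix(default_dataset):
    _ann, _truth, _ip, _inp, counts = default_dataset
    samples = [c for c in counts.columns if c != "length_bp"]
    return CountMatrix(
        counts[samples], counts["length_bp"],
        {s: ("wt" if s.startswith("wt") else "mutant") for s in samples})


@pytest.fixture(scope="session")
def consensus(default_cfg, default_dataset):
    """Consensus peaks of both callers on the reference dataset."""
    ann, _truth, ip, inp, _counts = default_dataset
    pa = call_peaks_poisson(ip, inp, fragment_size=default_cfg.fragment_size)
    pb = call_peaks_nb_gc(ip, inp, ann.sequence,
                          fragment_size=default_cfg.fragment_size)
    return pa, pb, number_peaks(consensus_peaks(pa, pb))


def make_track(values):
    return np.asarray(values, dtype=float)
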