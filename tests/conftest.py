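import numpy as np
import pandas as pd
import pytest

from cnahet.calling import GAIN, LOSS
from cnahet.genome import GenomeModel
from cnahet.probes import apply_qc, median_center, profile_from_frame, to_log2
from cnahet.segment import Segment
from cnahet.simulate import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def small_genome():
    return GenomeModel.toy(n_chromosomes=2, probes_per_chromosome=300)


@pytest.fixture(scope="session")
def small_cohort(small_genome):
    params = SimulationParams(
        n_patients=3,
        lnm_per_patient=(1, 3),
        om_per_patient=(0, 1),
        event_length_bp=(2e6, 2e7),
        seed=11,
    )
    return simulate_cohort(small_genome, params)


def make_segment(mean_log2, n_probes, sample="S1", chrom="1", start=0):
    """Segment with the given amplitude/extent; 1 Mb per probe for convenience."""
    return Segment(
        sample_id=sample,
        chromosome=chrom,
        first_probe_index=0,
        last_probe_index=n_probes - 1,
        start_bp=start,
        end_bp=start + n_probes * 1_000_000,
        n_probes=n_probes,
        mean_log2=mean_log2,
    )


def clean_in_memory(table: pd.DataFrame, sample_id: str, policy=None):
    """QC -> log2 -> center without touching disk (simulated file-layout table)."""
    return median_center(to_log2(apply_qc(profile_from_frame(table, sample_id), policy)))


def call_matrix_from_intervals(intervals_by_sample, sample_sheet=None):
    """Harmonize plain (chrom, start, end, state) interval dicts."""
    from cnahet.heterogeneity import harmonize

    return harmonize(intervals_by_sample, sample_sheet)


@pytest.fixture
def hand_pair_matrix():
    """A={r1,r2,r3}, B={r3,r4}: disjoint footprints, same direction at r3."""
    intervals = {
        "A": [("1", 0, 10, GAIN), ("1", 20, 30, LOSS), ("2", 0, 10, GAIN)],
        "B": [("2", 0, 10, GAIN), ("2", 50, 60, LOSS)],
    }
    return call_matrix_from_intervals(intervals)
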