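"""Shared fixtures.

The expensive coevolution runs used by several acceptance checks are
computed once per session; everything else is cheap and generated inline.
"""

from __future__ import annotations

import numpy as np
import pytest

import redqueen as rq

#: problem sizes used for scenario runs throughout the suite: host
#: population 1000 (within the study's 10^3-10^4 range), parasite pool 2000
#: with 1% seeding, 1500 generations, statistics taken after a burn-in of
#: half the run.
SCALED = dict(
    host_pop_size=1000,
    parasite_pop_size=2000,
    generations=1500,
    record_every=50,
)
BURN_IN = 750
SEEDS = (1, 2, 3, 4, 5)


def late_records(records, burn_in=BURN_IN):
    return [r for r in records if r.generation >= burn_in]


def supertype_shares(record):
    """Copy-count share of each supertype in a snapshot, descending."""
    sizes: dict[int, int] = {}
    for coord, lab in record.supertype_assignment.items():
        sizes[lab] = sizes.get(lab, 0) + record.allele_counts[coord]
    total = sum(sizes.values())
    return sorted((v / total for v in sizes.values()), reverse=True)


@pytest.fixture(scope="session")
def original_runs():
    """Original-scenario trajectories for five seeds at the scaled sizes."""
    return {
        seed: rq.run_scenario("original", SCALED, rng_seed=seed)
        for seed in SEEDS
    }


@pytest.fixture(scope="session")
def original_medians(original_runs):
    """(median supertype count, median effective alleles) across seeds."""
    st_meds, ena_meds = [], []
    for records in original_runs.values():
        late = late_records(records)
        st_meds.append(np.median([r.n_supertypes for r in late]))
        ena_meds.append(np.median([r.effective_num_alleles for r in late]))
    return float(np.median(st_meds)), float(np.median(ena_meds))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
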