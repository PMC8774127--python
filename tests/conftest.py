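"""Shared builders for random graphs, profiles, and small synthetic cohorts."""

import numpy as np
import pytest

from neurocouple.io_formats import Connectome, ParcellatedBold, SubjectRecord
from neurocouple import gsp_coupling, pls_brain_age, synthetic_cohort


def random_connectome(n, rng, density=0.5, n_networks=2):
    """Random connected weighted graph; a ring backbone guarantees connectivity."""
    w = rng.random((n, n)) * (rng.random((n, n)) < density)
    w = np.triu(w, 1)
    w = w + w.T
    for i in range(n):
        j = (i + 1) % n
        if w[i, j] == 0:
            w[i, j] = w[j, i] = 0.1 + rng.random()
    ids = tuple(f"n{i:02d}" for i in range(n))
    nets = {ids[i]: f"net{i % n_networks}" for i in range(n)}
    return Connectome(ids, w, nets)


def random_bold(connectome, n_trs, rng):
    return ParcellatedBold(connectome.node_ids,
                           rng.standard_normal((connectome.n_nodes, n_trs)))


def make_subjects(n_control, n_athlete, rng, age_lo=19, age_hi=49):
    subs = [SubjectRecord(f"ctl{i:02d}", float(rng.uniform(age_lo, age_hi)),
                          "control", float(rng.uniform(0.03, 0.2)))
            for i in range(n_control)]
    subs += [SubjectRecord(f"ath{i:02d}", float(rng.uniform(age_lo, age_hi)),
                           "athlete", float(rng.uniform(0.03, 0.2)))
             for i in range(n_athlete)]
    return subs


def make_profiles(subjects, n_nodes, rng, node_ids=None):
    """Random coupling profiles over a shared node set."""
    if node_ids is None:
        node_ids = tuple(f"n{i:02d}" for i in range(n_nodes))
    return {
        s.subject_id: gsp_coupling.CouplingProfile(
            node_ids, rng.random(n_nodes) + 0.1, rng.random(n_nodes) + 0.1)
        for s in subjects
    }


def cohort_stack_from_cohort(config):
    """Generate a cohort and push it through coupling into a CohortStack."""
    subjects, conns, bolds, truth = synthetic_cohort.generate_cohort(config)
    profiles = {
        s.subject_id: gsp_coupling.subject_coupling(
            conns[s.subject_id], bolds[s.subject_id])
        for s in subjects
    }
    return pls_brain_age.stack_cohort(profiles, subjects), subjects, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
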