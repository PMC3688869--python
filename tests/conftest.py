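import logging

import pytest

import mircohort as mc

# the equal-split warning for zero-unique multimap groups is expected noise
# in randomly generated cohorts
logging.getLogger("mircohort.quantify").setLevel(logging.ERROR)


def make_read(rid, *alns, length=None):
    """Build an AlignedRead from (chrom, start, end, strand, nm) tuples."""
    recs = tuple(mc.AlignmentRecord(c, s, e, st, nm)
                 for (c, s, e, st, nm) in alns)
    if length is None:
        length = recs[0].end - recs[0].start
    return mc.AlignedRead(rid, length, recs)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort reused across read-level tests."""
    cfg = mc.SimConfig(n_mirnas=100, n_clusters=3, n_samples=12,
                       reads_per_sample=8000, seed=11)
    ann = mc.generate_annotation(cfg)
    cohort = mc.generate_cohort(ann, cfg)
    return cfg, ann, cohort


@pytest.fixture(scope="session")
def small_quant(small_cohort):
    cfg, ann, cohort = small_cohort
    return mc.build_count_matrix(cohort.alignments, ann)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the default study conditions (88 samples)."""
    cfg = mc.SimConfig(seed=5)
    ann = mc.generate_annotation(cfg)
    return cfg, ann, mc.generate_cohort(ann, cfg)


@pytest.fixture(scope="session")
def default_quant(default_cohort):
    cfg, ann, cohort = default_cohort
    return mc.build_count_matrix(cohort.alignments, ann)
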