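from __future__ import annotations

import numpy as np
import pytest

from mirscout import discovery, preprocess
from mirscout.demo import make_demo_study


def study_to_tags(study, with_contaminants=True):
    """Trim + filter + collapse a synthetic study's reads."""
    inserts = {}
    raw = {}
    for lib, reads in study.reads.items():
        raw[lib] = len(reads)
        inserts[lib] = [
            ins for ins in (preprocess.trim_adapter(seq) for _rid, seq, _o in reads)
            if ins is not None
        ]
    cont = [s for _i, s in study.contaminants] if with_contaminants else []
    return preprocess.filter_and_collapse(inserts, cont, raw)


@pytest.fixture(scope="session")
def demo_study():
    """Thirty planted canonical loci, ten libraries, 20% noise."""
    return make_demo_study(seed=1)


@pytest.fixture(scope="session")
def demo_tags(demo_study):
    tags, stats = study_to_tags(demo_study)
    return tags, stats


@pytest.fixture(scope="session")
def demo_candidates(demo_study, demo_tags):
    tags, _stats = demo_tags
    cands, stats = discovery.discover(tags, demo_study.genome, seed=1,
                                      return_stats=True)
    return cands, stats


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
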