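"""Canonical synthetic study used by the demo CLI and the validation suite.

Thirty bulged canonical hairpin loci across three chromosomes, expressed in
a ten-library stress design (two pathogen, four drought, four salt
libraries).  Each locus gets at least five mature reads in every library
where it is expressed; star reads are sampled at 10% of mature reads
(rounded up) for loci designated star-positive, and not at all for the
rest, so class assignment has a known answer.  A fifth of reads are noise.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .synthetic import (
    DEFAULT_LIBRARY_DESIGN,
    PlantedLocus,
    SyntheticStudy,
    build_study,
    make_hairpin_locus,
)

__all__ = ["make_demo_loci", "make_demo_study"]

N_LOCI = 30
STAR_EVERY = 5  # every 5th locus has no star reads (expected class II)


def make_demo_loci(seed: int = 0, n_loci: int = N_LOCI) -> List[PlantedLocus]:
    rng = np.random.default_rng([seed, 101])
    libs = list(DEFAULT_LIBRARY_DESIGN)
    loci = []
    for i in range(n_loci):
        length = int(rng.choice([20, 21, 21, 21, 24, 24]))
        mature = "".join("ACGT"[b] for b in rng.integers(0, 4, length))
        locus = make_hairpin_locus(
            mature, arm_len=length + 13, loop_len=int(rng.integers(9, 14)),
            n_bulges=int(rng.integers(1, 3)),
            seed=int(rng.integers(2**31)), name=f"locus{i:02d}",
        )
        # expressed in 2-6 random libraries, 5-200 mature reads each
        n_libs = int(rng.integers(2, 7))
        chosen = rng.choice(libs, size=n_libs, replace=False)
        locus.per_library_abundance = {
            lib: int(rng.integers(5, 200)) for lib in chosen
        }
        if i % STAR_EVERY != STAR_EVERY - 1:
            locus.star_abundance = {
                lib: int(np.ceil(0.1 * c))
                for lib, c in locus.per_library_abundance.items()
            }
        loci.append(locus)
    return loci


def make_demo_study(seed: int = 0, n_loci: int = N_LOCI,
                    noise_fraction: float = 0.2) -> SyntheticStudy:
    loci = make_demo_loci(seed, n_loci)
    return build_study(
        n_chrom=3, chrom_len=60_000, loci=loci,
        n_contaminants=5, noise_fraction=noise_fraction,
        seed=int(np.random.default_rng([seed, 202]).integers(2**31)),
    )
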