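"""Synthetic study generator: genomes with planted hairpin loci and reads.

Every downstream stage is exercised on data with known truth: a random
genome carrying planted pre-miRNA stem-loops, contaminant sequences,
condition-labelled read libraries (insert + 3' adapter), transcripts with
planted target sites, and decoy studies for specificity testing.  Defaults
emulate a ten-library stress-condition design (two pathogen-infection, four
drought, four salt libraries); star reads default to 10% of mature reads,
reflecting the low sequencing frequency of the passenger strand.

Quality filtering is treated as already applied upstream of this model:
reads are emitted as FASTQ with constant quality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .discovery import validate_hairpin
from .fold import fold, reverse_complement
from .preprocess import ADAPTER

__all__ = [
    "PlantedLocus",
    "SyntheticTruth",
    "SyntheticStudy",
    "make_hairpin_locus",
    "build_study",
    "build_decoy_study",
    "random_transcripts",
    "build_target_site",
    "plant_target_sites",
    "DEFAULT_LIBRARY_DESIGN",
]

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE = {"G": "T", "T": "G"}
#: a base pairing with neither Watson-Crick nor wobble rules against the key
_MISMATCH = {"A": "A", "C": "C", "G": "A", "T": "C"}

#: the ten-library stress design: assay -> condition label per library
DEFAULT_LIBRARY_DESIGN: Dict[str, str] = {
    "biotic_CT": "biotic", "biotic_AA": "biotic",
    "drought_T0h": "drought", "drought_T24h": "drought",
    "drought_S0h": "drought", "drought_S24h": "drought",
    "salt_0h": "salt", "salt_1h": "salt", "salt_6h": "salt", "salt_24h": "salt",
}

DEFAULT_READ_LEN = 36
STAR_FRACTION = 0.1


@dataclass
class PlantedLocus:
    """A planted MIR hairpin locus and its per-library read abundances."""

    name: str
    mature_seq: str
    star_seq: str
    precursor_seq: str
    mature_span: Tuple[int, int]  # within precursor
    star_span: Tuple[int, int]
    strand: str = "+"
    chrom_id: Optional[str] = None
    start: Optional[int] = None
    per_library_abundance: Dict[str, int] = field(default_factory=dict)
    star_abundance: Dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.mature_seq not in self.precursor_seq:
            raise ValueError("mature not a substring of precursor")
        if self.star_seq not in self.precursor_seq:
            raise ValueError("star not a substring of precursor")
        m0, m1 = self.mature_span
        s0, s1 = self.star_span
        if not (m1 <= s0 or s1 <= m0):
            raise ValueError("mature and star overlap")


@dataclass
class SyntheticTruth:
    loci: List[PlantedLocus]
    contaminant_ids: Set[str]
    decoy_regions: List[Tuple[str, int, int]]
    target_sites: List[Tuple[str, str, int, list]]  # mature id, transcript id, start, pattern


@dataclass
class SyntheticStudy:
    genome: Dict[str, str]
    contaminants: List[Tuple[str, str]]
    reads: Dict[str, List[Tuple[str, str, str]]]  # lib -> (read id, read seq, origin)
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, Path] = {}
        gpath = outdir / "genome.fa"
        with open(gpath, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n{seq}\n")
        paths["genome"] = gpath
        cpath = outdir / "contaminants.fa"
        with open(cpath, "w") as fh:
            for cid, seq in self.contaminants:
                fh.write(f">{cid}\n{seq}\n")
        paths["contaminants"] = cpath
        for lib, reads in self.reads.items():
            rpath = outdir / f"reads_{lib}.fastq"
            with open(rpath, "w") as fh:
                for rid, seq, _origin in reads:
                    fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            paths[f"reads:{lib}"] = rpath
        bpath = outdir / "loci.bed"
        with open(bpath, "w") as fh:
            for loc in self.truth.loci:
                fh.write(f"{loc.chrom_id}\t{loc.start}\t{loc.start + len(loc.precursor_seq)}"
                         f"\t{loc.name}\t0\t{loc.strand}\n")
        paths["loci_bed"] = bpath
        tpath = outdir / "truth.json"
        tpath.write_text(json.dumps({
            "loci": [{
                "name": l.name, "chrom": l.chrom_id, "start": l.start,
                "strand": l.strand, "mature": l.mature_seq, "star": l.star_seq,
                "precursor": l.precursor_seq,
                "mature_counts": l.per_library_abundance,
                "star_counts": l.star_abundance,
            } for l in self.truth.loci],
            "contaminants": sorted(self.truth.contaminant_ids),
        }, indent=2))
        paths["truth"] = tpath
        return paths


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def make_hairpin_locus(
    mature: str,
    arm_len: int,
    loop_len: int,
    n_bulges: int = 0,
    seed: int = 0,
    name: str = "locus",
) -> PlantedLocus:
    """Construct a precursor whose fold passes all four hairpin checks.

    The mature sits at the 3' end of the 5' arm; the 3' arm is its reverse
    complement (perfect stem) with *n_bulges* isolated mismatches introduced
    opposite the mature.  The star is the arm-opposite segment of the mature
    under the 2 nt 3'-overhang convention.  Parameter sets that cannot yield
    a >= 75 nt precursor, or that leave no room for the star offset, are
    rejected.
    """
    mature = mature.upper().replace("U", "T")
    L = len(mature)
    if not (20 <= L <= 24):
        raise ValueError(f"mature length {L} outside 20-24 nt")
    if arm_len < L + 2:
        raise ValueError("arm_len must be >= mature length + 2 (star offset)")
    n = 2 * arm_len + loop_len
    if n < 75:
        raise ValueError(f"precursor would be {n} nt < 75 nt minimum")
    i0 = arm_len - L  # mature start in precursor
    bulge_positions = list(range(i0 + 4, arm_len - 4, 8))[:n_bulges]
    if len(bulge_positions) < n_bulges:
        raise ValueError("too many bulges for the mature window")
    rng = np.random.default_rng(seed)
    for _attempt in range(50):
        left = _random_seq(rng, arm_len - L) + mature
        loop = _random_seq(rng, loop_len)
        right = reverse_complement(left)
        right_l = list(right)
        # isolated mismatches opposite the mature, away from its ends
        if n_bulges:
            for p in bulge_positions:
                q = n - 1 - p  # partner index in precursor
                right_l[q - (arm_len + loop_len)] = _MISMATCH[mature[p - i0]]
        precursor = left + loop + "".join(right_l)
        fr = fold(precursor)
        mspan = (i0, arm_len)
        checks = validate_hairpin(fr, mspan)
        if checks["pass"]:
            break
        rng = np.random.default_rng([seed, _attempt + 1])
    else:
        raise ValueError("could not build a passing hairpin for these parameters")
    j = arm_len
    sspan = (n - j + 2, n - i0 + 2)
    locus = PlantedLocus(
        name=name,
        mature_seq=mature,
        star_seq=precursor[sspan[0]:sspan[1]],
        precursor_seq=precursor,
        mature_span=mspan,
        star_span=sspan,
    )
    locus.validate()
    return locus


def _make_read(insert: str, adapter: str, read_len: int) -> str:
    read = insert + adapter
    return read[:read_len]


def build_study(
    n_chrom: int,
    chrom_len: int,
    loci: Sequence[PlantedLocus],
    n_contaminants: int = 0,
    library_design: Mapping[str, str] = DEFAULT_LIBRARY_DESIGN,
    noise_fraction: float = 0.0,
    seed: int = 0,
    contaminant_copies: int = 5,
    low_complexity_fraction: float = 0.1,
    n_base_fraction: float = 0.05,
    adapter: str = ADAPTER,
    read_len: int = DEFAULT_READ_LEN,
) -> SyntheticStudy:
    """Emit a genome, contaminant set and adaptered multi-library reads.

    Loci without coordinates are placed on random chromosomes without
    overlap; each library receives the locus's mature/star reads plus
    contaminant reads and uniform-random noise reads (a configurable slice
    of which are low-complexity or N-containing, to exercise the filters).
    Deterministic for a fixed seed.
    """
    if not 0 <= noise_fraction < 1:
        raise ValueError("noise_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genome = {f"chr{i + 1}": list(_random_seq(rng, chrom_len)) for i in range(n_chrom)}
    chrom_names = list(genome)
    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_names}

    def overlaps(chrom: str, s: int, e: int) -> bool:
        return any(s < pe and ps < e for ps, pe in placed[chrom])

    for loc in loci:
        plen = len(loc.precursor_seq)
        if loc.chrom_id is None:
            for _ in range(1000):
                chrom = chrom_names[rng.integers(n_chrom)]
                s = int(rng.integers(100, chrom_len - plen - 100))
                if not overlaps(chrom, s - 250, s + plen + 250):
                    loc.chrom_id, loc.start = chrom, s
                    break
            else:
                raise ValueError("could not place locus without overlap")
        if overlaps(loc.chrom_id, loc.start, loc.start + plen):
            raise ValueError(f"locus {loc.name} overlaps a previously placed locus")
        placed[loc.chrom_id].append((loc.start, loc.start + plen))
        emb = loc.precursor_seq if loc.strand == "+" else reverse_complement(loc.precursor_seq)
        genome[loc.chrom_id][loc.start:loc.start + plen] = list(emb)
    genome_s = {c: "".join(s) for c, s in genome.items()}

    contaminants = [(f"contam{i + 1}", _random_seq(rng, int(rng.integers(20, 25))))
                    for i in range(n_contaminants)]

    reads: Dict[str, List[Tuple[str, str, str]]] = {}
    for lib in library_design:
        lib_reads: List[Tuple[str, str, str]] = []
        for loc in loci:
            for _ in range(loc.per_library_abundance.get(lib, 0)):
                lib_reads.append((f"{loc.name}_m", _make_read(loc.mature_seq, adapter, read_len),
                                  f"locus:{loc.name}:mature"))
            for _ in range(loc.star_abundance.get(lib, 0)):
                lib_reads.append((f"{loc.name}_s", _make_read(loc.star_seq, adapter, read_len),
                                  f"locus:{loc.name}:star"))
        for cid, cseq in contaminants:
            for _ in range(contaminant_copies):
                lib_reads.append((cid, _make_read(cseq, adapter, read_len),
                                  f"contaminant:{cid}"))
        n_signal = len(lib_reads)
        n_noise = int(round(noise_fraction * n_signal / (1 - noise_fraction)))
        for i in range(n_noise):
            ilen = int(rng.integers(20, 31))
            u = rng.random()
            if u < low_complexity_fraction:
                two = rng.choice(list(BASES), size=2, replace=False)
                ins = "".join(two[i] for i in rng.integers(0, 2, size=ilen))
            elif u < low_complexity_fraction + n_base_fraction:
                ins_l = list(_random_seq(rng, ilen))
                ins_l[rng.integers(ilen)] = "N"
                ins = "".join(ins_l)
            else:
                ins = _random_seq(rng, ilen)
            lib_reads.append((f"noise{i}", _make_read(ins, adapter, read_len), "noise"))
        reads[lib] = [(f"{lib}_r{i}_{rid}", seq, origin)
                      for i, (rid, seq, origin) in enumerate(lib_reads)]

    # decoy regions: gaps between planted loci
    decoys: List[Tuple[str, int, int]] = []
    for chrom in chrom_names:
        ivs = sorted(placed[chrom])
        prev = 0
        for s, e in ivs:
            if s - prev > 500:
                decoys.append((chrom, prev, s))
            prev = e
        if chrom_len - prev > 500:
            decoys.append((chrom, prev, chrom_len))

    truth = SyntheticTruth(
        loci=list(loci),
        contaminant_ids={seq for _cid, seq in contaminants},
        decoy_regions=decoys,
        target_sites=[],
    )
    return SyntheticStudy(genome=genome_s, contaminants=contaminants, reads=reads, truth=truth)


def build_decoy_study(
    chrom_len: int = 100_000,
    n_tags: int = 50,
    copies: int = 10,
    library_design: Mapping[str, str] = DEFAULT_LIBRARY_DESIGN,
    seed: int = 0,
    adapter: str = ADAPTER,
    read_len: int = DEFAULT_READ_LEN,
) -> SyntheticStudy:
    """A locus-free genome whose reads are sampled from its own sequence.

    Emulates degradation products: tags map back to the genome (so clusters
    and folds are attempted) but no hairpin was planted, which measures the
    structural pipeline's false-positive behavior.
    """
    rng = np.random.default_rng(seed)
    genome = {"decoy1": _random_seq(rng, chrom_len)}
    libs = list(library_design)
    reads: Dict[str, List[Tuple[str, str, str]]] = {lib: [] for lib in libs}
    for i in range(n_tags):
        tlen = int(rng.integers(20, 25))
        pos = int(rng.integers(0, chrom_len - tlen))
        tag = genome["decoy1"][pos:pos + tlen]
        lib = libs[int(rng.integers(len(libs)))]
        for c in range(copies):
            reads[lib].append((f"decoy_t{i}_c{c}", _make_read(tag, adapter, read_len),
                               "noise"))
    truth = SyntheticTruth(loci=[], contaminant_ids=set(),
                           decoy_regions=[("decoy1", 0, chrom_len)], target_sites=[])
    return SyntheticStudy(genome=genome, contaminants=[], reads=reads, truth=truth)


# ---------------------------------------------------------------------------
# target-site planting


def random_transcripts(n: int, length: int, seed: int = 0, prefix: str = "TC") -> Dict[str, str]:
    rng = np.random.default_rng(seed)
    return {f"{prefix}{100000 + i}": _random_seq(rng, length) for i in range(n)}


def build_target_site(mature: str, mismatch_pattern: Sequence[Tuple[int, str]] = ()) -> str:
    """Target site (5'->3') whose duplex with *mature* shows the given pattern.

    *mismatch_pattern* lists (miRNA position 1-based from the 5' end, kind)
    with kind "GU" (wobble; miRNA base must be G or T) or "other" (a base
    pairing with neither rule).  An empty pattern yields the perfect reverse
    complement.
    """
    mature = mature.upper().replace("U", "T")
    L = len(mature)
    site = list(reverse_complement(mature))
    for pos, kind in mismatch_pattern:
        if not 1 <= pos <= L:
            raise ValueError(f"position {pos} outside miRNA 1..{L}")
        x = mature[pos - 1]
        if kind == "GU":
            if x not in _WOBBLE:
                raise ValueError(f"no G:U wobble possible at position {pos} (base {x})")
            y = _WOBBLE[x]
        elif kind == "other":
            y = _MISMATCH[x]
        else:
            raise ValueError(f"unknown mismatch kind: {kind}")
        site[L - pos] = y
    return "".join(site)


def plant_target_sites(
    transcripts: Dict[str, str],
    mature: str,
    mismatch_pattern: Sequence[Tuple[int, str]] = (),
    seed: int = 0,
    mature_id: str = "mir",
) -> Tuple[Dict[str, str], List[Tuple[str, str, int, list]]]:
    """Plant one designed duplex site into a random transcript.

    Returns the modified transcript set and the truth records
    (mature id, transcript id, site start, pattern).
    """
    rng = np.random.default_rng(seed)
    out = dict(transcripts)
    tid = list(out)[int(rng.integers(len(out)))]
    site = build_target_site(mature, mismatch_pattern)
    tx = out[tid]
    if len(tx) < len(site):
        raise ValueError("transcript shorter than the site")
    pos = int(rng.integers(0, len(tx) - len(site) + 1))
    out[tid] = tx[:pos] + site + tx[pos + len(site):]
    return out, [(mature_id, tid, pos, list(mismatch_pattern))]
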