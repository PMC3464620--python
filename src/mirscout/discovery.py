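"""miRCat-style miRNA locus discovery.

Tags are mapped exactly to the genome, chained into clusters, and the most
abundant tag of each cluster nominates a candidate mature miRNA.  Genomic
windows around the candidate are folded, trimmed to the enclosing stem-loop
and put through four structural hairpin checks; surviving precursors are
scored (MFE, AMFE, MFEI, randfold permutation p) and classified by whether
the star strand was itself sequenced (class I) or not (class II).

Coordinates are 0-based half-open throughout; the GFF3 writer converts to
1-based inclusive on output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import fold as _fold
from .fold import FoldResult, fold, gc_percent, randfold_p, reverse_complement
from .preprocess import SequenceTag

__all__ = [
    "GenomeHit",
    "Cluster",
    "HairpinCandidate",
    "map_tags",
    "build_clusters",
    "select_candidate",
    "extract_windows",
    "validate_hairpin",
    "trim_and_choose",
    "compute_mfei",
    "infer_star",
    "assign_class",
    "discover",
    "load_genome_fasta",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_ABUNDANCE = 5
DEFAULT_MAX_HITS = 16
DEFAULT_WINDOW_LADDER = (75, 150, 250)
MAX_CLUSTER_GAP = 200
MAX_NONOVERLAPPING_SRNAS = 4
MIN_STRAND_FRACTION = 0.9
MIN_HAIRPIN_LEN = 75


@dataclass
class GenomeHit:
    tag: SequenceTag
    chrom: str
    start: int  # 0-based; end = start + len(tag.seq)
    strand: str

    @property
    def end(self) -> int:
        return self.start + len(self.tag.seq)


@dataclass
class Cluster:
    chrom: str
    hits: List[GenomeHit]
    majority_strand: str


@dataclass
class HairpinCandidate:
    """A validated precursor locus with its scores and confidence class."""

    name: str
    locus: Tuple[str, int, int, str]  # chrom, start, end, strand
    precursor: FoldResult
    mature_span: Tuple[int, int]  # within precursor
    mature_seq: str
    star_span: Optional[Tuple[int, int]]
    star_seq: Optional[str]
    checks: Dict[str, bool]
    amfe: float
    mfei: float
    randfold_p: float
    confidence_class: str  # "I" or "II"
    gc_percent: float
    extra_loci: List[Tuple[str, int, int, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# mapping and clustering


def load_genome_fasta(path: str | Path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _find_all(haystack: str, needle: str) -> List[int]:
    out = []
    i = haystack.find(needle)
    while i >= 0:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def map_tags(
    tags: Iterable[SequenceTag],
    genome: Mapping[str, str],
    min_abundance: int = DEFAULT_MIN_ABUNDANCE,
    max_hits: int = DEFAULT_MAX_HITS,
) -> List[GenomeHit]:
    """Exact-match tags to both genome strands.

    Tags below *min_abundance* total reads are never mapped; tags with more
    than *max_hits* genomic occurrences (both strands summed) are discarded
    entirely as likely repeats.
    """
    genome = {c: s.upper() for c, s in genome.items()}
    hits: List[GenomeHit] = []
    for tag in tags:
        if tag.total_count < min_abundance:
            continue
        rc = reverse_complement(tag.seq)
        tag_hits: List[GenomeHit] = []
        for chrom, seq in genome.items():
            for pos in _find_all(seq, tag.seq):
                tag_hits.append(GenomeHit(tag, chrom, pos, "+"))
            for pos in _find_all(seq, rc):
                tag_hits.append(GenomeHit(tag, chrom, pos, "-"))
        if not tag_hits or len(tag_hits) > max_hits:
            if len(tag_hits) > max_hits:
                logger.debug("tag %s discarded: %d genome hits > %d",
                             tag.seq, len(tag_hits), max_hits)
            continue
        hits.extend(tag_hits)
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def _max_nonoverlapping(intervals: Sequence[Tuple[int, int]]) -> int:
    n = 0
    last_end = -1
    for s, e in sorted(intervals, key=lambda x: x[1]):
        if s >= last_end:
            n += 1
            last_end = e
    return n


def build_clusters(hits: Sequence[GenomeHit]) -> List[Cluster]:
    """Chain neighboring hits (gap <= 200 nt) and keep miRNA-like clusters.

    A chain is kept only if it has at most four mutually non-overlapping tag
    footprints and at least 90% of its hits share one orientation; rejected
    chains are logged with the failed criterion.
    """
    clusters: List[Cluster] = []
    chain: List[GenomeHit] = []

    def flush(chain: List[GenomeHit]) -> None:
        if not chain:
            return
        n_nonov = _max_nonoverlapping([(h.start, h.end) for h in chain])
        if n_nonov > MAX_NONOVERLAPPING_SRNAS:
            logger.debug("cluster %s:%d-%d rejected: %d non-overlapping sRNAs",
                         chain[0].chrom, chain[0].start, chain[-1].end, n_nonov)
            return
        n_plus = sum(1 for h in chain if h.strand == "+")
        frac = max(n_plus, len(chain) - n_plus) / len(chain)
        if frac < MIN_STRAND_FRACTION:
            logger.debug("cluster %s:%d-%d rejected: strand fraction %.2f",
                         chain[0].chrom, chain[0].start, chain[-1].end, frac)
            return
        majority = "+" if n_plus * 2 >= len(chain) else "-"
        clusters.append(Cluster(chain[0].chrom, list(chain), majority))

    prev: Optional[GenomeHit] = None
    for h in hits:
        if prev is not None and (h.chrom != prev.chrom or h.start - prev.end > MAX_CLUSTER_GAP):
            flush(chain)
            chain = []
        chain.append(h)
        if prev is None or h.chrom != prev.chrom or h.end > prev.end:
            prev = h
    flush(chain)
    return clusters


def select_candidate(cluster: Cluster) -> GenomeHit:
    """The most abundant tag's hit; ties broken by smallest sequence."""
    if not cluster.hits:
        raise ValueError("empty cluster")
    best = min(cluster.hits, key=lambda h: (-h.tag.total_count, h.tag.seq, h.start))
    return best


# ---------------------------------------------------------------------------
# windows, validation, trimming


def extract_windows(
    genome: Mapping[str, str],
    candidate: GenomeHit,
    window_ladder: Sequence[int] = DEFAULT_WINDOW_LADDER,
) -> List[Tuple[str, Tuple[int, int], Tuple[str, int, int, str]]]:
    """Genomic windows of each ladder flank size around the candidate.

    Returns (window sequence oriented to the candidate strand, mature span
    within the window, genomic interval (chrom, start, end, strand)).
    """
    chrom_seq = genome[candidate.chrom]
    L = len(candidate.tag.seq)
    out = []
    for w in window_ladder:
        s = max(0, candidate.start - w)
        e = min(len(chrom_seq), candidate.end + w)
        window = chrom_seq[s:e].upper()
        if candidate.strand == "+":
            span = (candidate.start - s, candidate.start - s + L)
        else:
            window = reverse_complement(window)
            span = (e - candidate.end, e - candidate.end + L)
        out.append((window, span, (candidate.chrom, s, e, candidate.strand)))
    return out


def validate_hairpin(fold_result: FoldResult, mature_span: Tuple[int, int]) -> Dict[str, bool]:
    """Apply the four structural hairpin checks to a folded precursor.

    c1: no more than 3 consecutive mature positions unpaired against the
    opposite arm; c2: at least 17 of the 25 positions centered on the mature
    paired; c3: hairpin at least 75 nt; c4: at least half of all bases
    paired.  Additionally the mature must sit on a single arm (all its
    pairing partners on one side, outside the mature itself).  G:U wobble
    counts as paired.  Returns per-check booleans plus an overall "pass".
    """
    m0, m1 = mature_span
    n = len(fold_result.seq)
    if not (0 <= m0 < m1 <= n):
        raise ValueError(f"mature span {mature_span} outside sequence of length {n}")
    pt = fold_result.pair_table

    def duplex_paired(p: int) -> bool:
        # a mature-region base counts as paired only when its partner lies
        # outside the mature (pairing against the star arm, not locally)
        if pt[p] < 0:
            return False
        if m0 <= p < m1:
            return not (m0 <= pt[p] < m1)
        return True

    # c1: longest run of mature positions unpaired against the opposite arm
    run = best_run = 0
    for p in range(m0, m1):
        if not duplex_paired(p):
            run += 1
            best_run = max(best_run, run)
        else:
            run = 0
    c1 = best_run <= 3

    # c2: pairing in the 25 nt centered on the mature
    center = (m0 + m1) // 2
    lo, hi = max(0, center - 12), min(n, center + 13)
    c2 = sum(duplex_paired(p) for p in range(lo, hi)) >= 17

    c3 = n >= MIN_HAIRPIN_LEN
    c4 = int(np.sum(pt >= 0)) >= 0.5 * n

    partners = [int(pt[p]) for p in range(m0, m1) if pt[p] >= 0]
    one_arm = bool(partners) and (all(q >= m1 for q in partners) or all(q < m0 for q in partners))

    checks = {
        "c1_mismatch_run": c1,
        "c2_pairing_window": c2,
        "c3_min_length": c3,
        "c4_paired_fraction": c4,
        "mature_one_arm": one_arm,
    }
    checks["pass"] = all(checks.values())
    return checks


def _trim_region(fold_result: FoldResult, mature_span: Tuple[int, int]) -> Optional[Tuple[int, int]]:
    """Smallest stem-loop region enclosing the mature and its pairing partners."""
    m0, m1 = mature_span
    pt = fold_result.pair_table
    partners = [int(pt[p]) for p in range(m0, m1) if pt[p] >= 0]
    if not partners:
        return None
    lo = min(m0, min(partners))
    hi = max(m1 - 1, max(partners))
    # nested chain of pairs enclosing [lo, hi], innermost first
    chain = sorted(
        ((a, int(pt[a])) for a in range(len(fold_result.seq))
         if pt[a] > a and a <= lo and pt[a] >= hi),
        key=lambda ab: -ab[0],
    )
    if not chain:
        return lo, hi + 1
    a, b = chain[0]
    # extend outward along the helix through bulges/internal loops only;
    # a paired base between consecutive enclosing pairs marks a multiloop
    # branch, where the mature's stem-loop ends
    for a2, b2 in chain[1:]:
        between = list(range(a2 + 1, a)) + list(range(b + 1, b2))
        if any(pt[p] >= 0 for p in between):
            break
        a, b = a2, b2
    return a, b + 1


def trim_and_choose(
    windows: Sequence[Tuple[str, Tuple[int, int], Tuple[str, int, int, str]]],
    fold_fn=fold,
) -> Optional[Tuple[FoldResult, Tuple[int, int], Tuple[str, int, int, str]]]:
    """Fold each window, trim to the mature's stem-loop, keep the most stable.

    Each window is folded, trimmed to the smallest stem-loop enclosing the
    mature's pairing region (dangling unpaired flanks removed), refolded and
    validated.  Among windows whose trimmed hairpin passes all checks, the
    lowest-MFE one is returned as (fold, mature span, genomic locus); None if
    every window fails.
    """
    if not windows:
        raise ValueError("no windows supplied")
    best = None
    for window, (m0, m1), (chrom, ws, we, strand) in windows:
        try:
            fr = fold_fn(window)
        except ValueError:
            continue
        region = _trim_region(fr, (m0, m1))
        if region is None:
            continue
        a, b = region
        a = min(a, m0)
        b = max(b, m1)
        trimmed = window[a:b]
        if len(trimmed) < _fold.MIN_FOLD_LEN:
            continue
        tfr = fold_fn(trimmed)
        tspan = (m0 - a, m1 - a)
        checks = validate_hairpin(tfr, tspan)
        if not checks["pass"]:
            continue
        if strand == "+":
            locus = (chrom, ws + a, ws + b, strand)
        else:
            locus = (chrom, we - b, we - a, strand)
        if best is None or tfr.mfe < best[0].mfe:
            best = (tfr, tspan, locus)
    return best


# ---------------------------------------------------------------------------
# scoring and classification


def compute_mfei(mfe: float, length: int, gc: float) -> Tuple[float, float]:
    """AMFE (|MFE| per 100 nt) and MFEI (AMFE / GC%) as positive magnitudes."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0 < gc <= 100):
        raise ValueError("gc_percent must be in (0, 100]")
    amfe = abs(mfe) / length * 100.0
    return amfe, amfe / gc


def infer_star(fold_result: FoldResult, mature_span: Tuple[int, int]) -> Optional[Tuple[int, int]]:
    """Star span: the mature's pairing partners shifted to 2 nt 3' overhangs.

    For a perfect stem this reproduces the canonical duplex geometry (star =
    arm-opposite segment of the mature offset by two positions); bulged stems
    may yield a star of different length than the mature.
    """
    m0, m1 = mature_span
    pt = fold_result.pair_table
    paired = [p for p in range(m0, m1) if pt[p] >= 0]
    if not paired:
        return None
    # each paired mature position implies where the duplex ends fall under
    # antiparallel geometry; the median over positions is robust to end
    # slippage and unaffected by interior (substitution) bulges
    from statistics import median_low

    lo = median_low(int(pt[p]) - ((m1 - 1) - p) for p in paired) + 2
    hi = median_low(int(pt[p]) + (p - m0) for p in paired) + 1 + 2
    n = len(fold_result.seq)
    lo = max(0, lo)
    hi = min(n, hi)
    if hi <= lo:
        return None
    return lo, hi


def assign_class(star_seq: Optional[str], tags: Iterable[SequenceTag]) -> str:
    """Class I iff the exact star sequence was sequenced in any library."""
    if star_seq is None:
        return "II"
    tagset = {t.seq for t in tags}
    return "I" if star_seq in tagset else "II"


# ---------------------------------------------------------------------------
# end-to-end discovery


def discover(
    tags: Sequence[SequenceTag],
    genome: Mapping[str, str],
    min_abundance: int = DEFAULT_MIN_ABUNDANCE,
    max_hits: int = DEFAULT_MAX_HITS,
    window_ladder: Sequence[int] = DEFAULT_WINDOW_LADDER,
    randfold_shuffles: int = 99,
    randfold_cutoff: float = 0.1,
    randfold_mode: str = "dinucleotide",
    seed: int = 0,
    fold_fn=fold,
    return_stats: bool = False,
):
    """Run the full locus-discovery pipeline over collapsed tags.

    Candidates sharing an identical mature sequence are merged into a single
    record carrying every locus (one mature can arise from several genomic
    copies).  With ``return_stats=True`` also returns stage-by-stage counts
    (hits, clusters, folds attempted, hairpin and randfold survivors).
    """
    hits = map_tags(tags, genome, min_abundance=min_abundance, max_hits=max_hits)
    clusters = build_clusters(hits)
    stats = {
        "n_hits": len(hits),
        "n_clusters": len(clusters),
        "n_folds_attempted": 0,
        "n_hairpin_pass": 0,
        "n_randfold_pass": 0,
    }
    candidates: List[HairpinCandidate] = []
    for idx, cluster in enumerate(clusters):
        cand_hit = select_candidate(cluster)
        windows = extract_windows(genome, cand_hit, window_ladder)
        stats["n_folds_attempted"] += len(windows)
        best = trim_and_choose(windows, fold_fn=fold_fn)
        if best is None:
            continue
        stats["n_hairpin_pass"] += 1
        fr, mspan, locus = best
        gc = gc_percent(fr.seq)
        amfe, mfei = compute_mfei(fr.mfe, len(fr.seq), gc)
        rng = np.random.default_rng([seed, idx])
        p = randfold_p(fr.seq, n_shuffles=randfold_shuffles, mode=randfold_mode,
                       rng=rng, fold_fn=fold_fn)
        if p > randfold_cutoff:
            logger.debug("candidate at %s:%d-%d dropped by randfold p=%.3f",
                         locus[0], locus[1], locus[2], p)
            continue
        stats["n_randfold_pass"] += 1
        sspan = infer_star(fr, mspan)
        sseq = fr.seq[sspan[0]:sspan[1]] if sspan else None
        checks = validate_hairpin(fr, mspan)
        candidates.append(HairpinCandidate(
            name=f"cand{idx}",
            locus=locus,
            precursor=fr,
            mature_span=mspan,
            mature_seq=cand_hit.tag.seq,
            star_span=sspan,
            star_seq=sseq,
            checks=checks,
            amfe=amfe,
            mfei=mfei,
            randfold_p=p,
            confidence_class=assign_class(sseq, tags),
            gc_percent=gc,
        ))
    # merge candidates with identical mature sequence
    by_mature: Dict[str, HairpinCandidate] = {}
    for c in candidates:
        prev = by_mature.get(c.mature_seq)
        if prev is None:
            by_mature[c.mature_seq] = c
        else:
            keep, drop = (c, prev) if c.precursor.mfe < prev.precursor.mfe else (prev, c)
            keep.extra_loci = sorted(set(keep.extra_loci + drop.extra_loci
                                         + [drop.locus]))
            if drop.confidence_class == "I":
                keep.confidence_class = "I"
            by_mature[c.mature_seq] = keep
    merged = sorted(by_mature.values(), key=lambda c: (c.locus[0], c.locus[1]))
    for i, c in enumerate(merged, start=1):
        c.name = f"mir-cand-{i:03d}"
    if return_stats:
        return merged, stats
    return merged


# ---------------------------------------------------------------------------
# report IO


def write_candidate_report(candidates: Sequence[HairpinCandidate], path: str | Path) -> None:
    cols = ["id", "locus", "length", "mature", "star", "mfe", "amfe", "mfei",
            "randfold_p", "checks", "class"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            chrom, s, e, strand = c.locus
            checks = ",".join(k for k, v in c.checks.items() if v and k != "pass")
            fh.write("\t".join([
                c.name, f"{chrom}:{s}-{e}({strand})", str(len(c.precursor.seq)),
                c.mature_seq, c.star_seq or "-", f"{c.precursor.mfe:.2f}",
                f"{c.amfe:.2f}", f"{c.mfei:.3f}", f"{c.randfold_p:.3f}",
                checks, c.confidence_class,
            ]) + "\n")


def write_precursor_gff3(candidates: Sequence[HairpinCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in candidates:
            for chrom, s, e, strand in [c.locus] + list(c.extra_loci):
                fh.write("\t".join([
                    chrom, "mirscout", "miRNA_primary_transcript",
                    str(s + 1), str(e), ".", strand, ".",
                    f"ID={c.name};class={c.confidence_class};mfei={c.mfei:.3f}",
                ]) + "\n")


def write_precursor_fasta(candidates: Sequence[HairpinCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f">{c.name}\n{c.precursor.seq}\n")


def write_structures(candidates: Sequence[HairpinCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f">{c.name}\n{c.precursor.seq}\n"
                     f"{c.precursor.structure} ({c.precursor.mfe:.2f})\n")
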