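"""Known/novel classification and cross-genome conservation scanning.

A candidate mature is *known* when it aligns to a reference mature-miRNA set
(miRBase-style FASTA) with a Karlin-Altschul e-value at or below threshold,
and *novel* otherwise.  Alignment is local, same-sense (mature vs mature),
with blastn-like scoring (+1/-3, gap -5); the e-value is computed over the
total reference length, so the decision matches what a standalone BLAST
search against the same database would conclude for near-identical hits.

Conservation of a candidate in another genome is decided by re-running the
structural half of the discovery pipeline there: the mature must map exactly
and at least one extracted window must fold into a hairpin passing all
checks — read abundance plays no role.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio import Align, SeqIO
from scipy.optimize import brentq

from .discovery import (
    DEFAULT_WINDOW_LADDER,
    GenomeHit,
    extract_windows,
    trim_and_choose,
)
from .fold import reverse_complement
from .preprocess import SequenceTag

__all__ = [
    "MatureRecord",
    "classify_known_novel",
    "conservation_scan",
    "read_mature_fasta",
]

DEFAULT_E_THRESHOLD = 1e-3

_MATCH = 1.0
_MISMATCH = -3.0
_GAP = -5.0
#: Karlin-Altschul K for +1/-3 ungapped scoring with uniform composition
_KA_K = 0.711


@dataclass
class MatureRecord:
    id: str
    seq: str
    status: str  # "known" | "novel"
    best_hit: Optional[Tuple[str, float]] = None  # (reference id, e-value)
    conservation: Dict[str, str] = field(default_factory=dict)


@lru_cache(maxsize=None)
def _ka_lambda(match: float = _MATCH, mismatch: float = _MISMATCH) -> float:
    """Karlin-Altschul lambda for uniform base composition."""
    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0
    return float(brentq(f, 1e-6, 10.0))


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = _MATCH
    al.mismatch_score = _MISMATCH
    al.open_gap_score = _GAP
    al.extend_gap_score = _GAP
    return al


def e_value(score: float, query_len: int, db_len: int) -> float:
    """Karlin-Altschul expectation for a local alignment score."""
    return _KA_K * query_len * db_len * math.exp(-_ka_lambda() * score)


def read_mature_fasta(path: str | Path) -> List[Tuple[str, str]]:
    """miRBase mature.fa dialect: U-containing sequences converted to T."""
    return [(rec.id, str(rec.seq).upper().replace("U", "T"))
            for rec in SeqIO.parse(str(path), "fasta")]


def classify_known_novel(
    matures: Mapping[str, str],
    reference: Sequence[Tuple[str, str]],
    e_threshold: float = DEFAULT_E_THRESHOLD,
) -> List[MatureRecord]:
    """Assign known/novel status against one or more reference mature sets.

    *reference* is a flat list of (id, sequence) records (concatenate
    multiple databases to make a hit in any of them count).  With an empty
    reference every candidate is novel.
    """
    al = _aligner()
    db_len = sum(len(s) for _i, s in reference)
    records: List[MatureRecord] = []
    for mid, seq in matures.items():
        seq = seq.upper().replace("U", "T")
        best: Optional[Tuple[str, float]] = None
        if reference:
            best_score = 0.0
            best_id = None
            for rid, rseq in reference:
                score = al.score(seq, rseq)
                if score > best_score:
                    best_score, best_id = score, rid
            if best_id is not None:
                best = (best_id, e_value(best_score, len(seq), db_len))
        status = "known" if best is not None and best[1] <= e_threshold else "novel"
        records.append(MatureRecord(id=mid, seq=seq, status=status, best_hit=best))
    return records


def conservation_scan(
    matures: Mapping[str, str],
    genome: Mapping[str, str],
    window_ladder: Sequence[int] = DEFAULT_WINDOW_LADDER,
    max_loci_checked: int = 16,
    fold_fn=None,
) -> Dict[str, str]:
    """Flag each mature "conserved" or "absent" in another genome.

    Conserved means: the mature maps exactly (either strand) and at least
    one mapped locus yields a trimmed hairpin passing every structural
    check.  A mature matching only non-hairpin context stays absent.
    """
    from .fold import fold as _default_fold

    fold_fn = fold_fn or _default_fold
    genome = {c: s.upper() for c, s in genome.items()}
    out: Dict[str, str] = {}
    for mid, seq in matures.items():
        seq = seq.upper().replace("U", "T")
        rc = reverse_complement(seq)
        tag = SequenceTag(seq=seq, counts={})
        verdict = "absent"
        checked = 0
        for chrom, chrom_seq in genome.items():
            for strand, needle in (("+", seq), ("-", rc)):
                start = chrom_seq.find(needle)
                while start >= 0 and checked < max_loci_checked:
                    checked += 1
                    hit = GenomeHit(tag=tag, chrom=chrom, start=start, strand=strand)
                    windows = extract_windows(genome, hit, window_ladder)
                    if trim_and_choose(windows, fold_fn=fold_fn) is not None:
                        verdict = "conserved"
                        break
                    start = chrom_seq.find(needle, start + 1)
                if verdict == "conserved":
                    break
            if verdict == "conserved":
                break
        out[mid] = verdict
    return out


def write_mature_table(records: Sequence[MatureRecord], path: str | Path) -> None:
    genomes = sorted({g for r in records for g in r.conservation})
    with open(path, "w") as fh:
        fh.write("id\tseq\tstatus\tbest_hit_id\te_value"
                 + "".join(f"\t{g}" for g in genomes) + "\n")
        for r in records:
            hit_id = r.best_hit[0] if r.best_hit else "-"
            ev = f"{r.best_hit[1]:.3g}" if r.best_hit else "-"
            cons = "".join(f"\t{r.conservation.get(g, '-')}" for g in genomes)
            fh.write(f"{r.id}\t{r.seq}\t{r.status}\t{hit_id}\t{ev}{cons}\n")
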