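"""Rule-based plant miRNA target prediction and GO enrichment.

Plant miRNAs act mostly by near-perfect complementarity to a single site on
the transcript, so prediction slides an ungapped window of miRNA length
over each transcript and scores the duplex position by position (miRNA
position 1 = 5' end): Watson-Crick pair, G:U wobble (half a mismatch), or
mismatch.  A site is reported when it satisfies all six duplex rules:

  R1  total weighted mismatches <= 4
  R2  no run of more than two consecutive non-WC positions anywhere
  R3  no two adjacent non-WC positions within miRNA positions 2-12
  R4  positions 10-11 (the cleavage site) strictly Watson-Crick
  R5  weighted mismatches within positions 1-12 <= 2.5
  R6  duplex free energy >= 74% of the perfect-complement duplex's
      (magnitude ratio)

G:U counts toward every mismatch tally at weight 0.5.  Whether a wobble is
tolerated at the cleavage site is configurable (``allow_gu_cleavage_site``,
default strict).  The duplex model is ungapped (no bulges).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .fold import _BASE_CODE, _PAIR_INDEX, _STACK, reverse_complement

__all__ = [
    "DuplexAlignment",
    "TargetReport",
    "score_duplex",
    "rules_pass",
    "duplex_mfe",
    "scan_transcripts",
    "go_enrichment",
    "average_targets_per_mirna",
]

RULE_NAMES = ("R1_total", "R2_run", "R3_adjacent_2_12", "R4_cleavage_wc",
              "R5_seed_total", "R6_mfe_ratio")

WC = "WC"
GU = "GU"
MM = "MM"

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class DuplexAlignment:
    """Position-wise classification of a miRNA:site duplex."""

    mirna_seq: str
    site_seq: str  # transcript site, 5'->3'
    classes: List[str]  # per miRNA position from the 5' end
    mismatch_total: float
    duplex_mfe: float
    perfect_mfe: float
    mfe_ratio: float
    mirna_id: Optional[str] = None
    transcript_id: Optional[str] = None
    site_start: Optional[int] = None  # 0-based half-open on the transcript

    @property
    def site_end(self) -> Optional[int]:
        return None if self.site_start is None else self.site_start + len(self.site_seq)


@dataclass
class TargetReport:
    rows: List[Tuple[DuplexAlignment, Tuple[Tuple[str, bool], ...]]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        data = [{
            "mirna": a.mirna_id, "transcript": a.transcript_id,
            "site_start": a.site_start, "site_end": a.site_end,
            "mismatch_total": a.mismatch_total, "mfe_ratio": a.mfe_ratio,
        } for a, _trace in self.rows]
        return pd.DataFrame(data, columns=["mirna", "transcript", "site_start",
                                           "site_end", "mismatch_total", "mfe_ratio"])

    def targets_per_mirna(self) -> float:
        """Average targets per miRNA with at least one target."""
        df = self.to_frame()
        if df.empty:
            return 0.0
        return len(df) / df["mirna"].nunique()


def _classify_position(x: str, y: str) -> str:
    if _COMP[x] == y:
        return WC
    if (x, y) in (("G", "T"), ("T", "G")):
        return GU
    return MM


def score_duplex(mirna: str, site: str) -> DuplexAlignment:
    """Score an ungapped duplex between *mirna* and a same-length site.

    The site is the transcript subsequence 5'->3'; miRNA position i pairs
    the site base opposite it in the antiparallel duplex (site position
    L - i).  Weighted mismatch total counts G:U as 0.5 and a mismatch as 1.
    """
    mirna = mirna.upper().replace("U", "T")
    site = site.upper().replace("U", "T")
    if len(mirna) != len(site):
        raise ValueError("site length must equal miRNA length (ungapped model)")
    L = len(mirna)
    classes = [_classify_position(mirna[i], site[L - 1 - i]) for i in range(L)]
    mismatch_total = 0.5 * classes.count(GU) + 1.0 * classes.count(MM)
    dmfe = duplex_mfe(mirna, site)
    pmfe = duplex_mfe(mirna, reverse_complement(mirna))
    ratio = abs(dmfe) / abs(pmfe) if pmfe != 0 else 0.0
    return DuplexAlignment(
        mirna_seq=mirna, site_seq=site, classes=classes,
        mismatch_total=mismatch_total, duplex_mfe=dmfe,
        perfect_mfe=pmfe, mfe_ratio=ratio,
    )


def duplex_mfe(mirna: str, site: str) -> float:
    """Stacking free energy of the ungapped duplex (kcal/mol, <= 0).

    Sums nearest-neighbor stack energies over consecutive paired positions
    (WC or G:U); a mismatch interrupts stacking and contributes nothing.
    """
    mirna = mirna.upper().replace("U", "T")
    site = site.upper().replace("U", "T")
    L = len(mirna)
    pts = []
    for i in range(L):
        x, y = mirna[i], site[L - 1 - i]
        pts.append(int(_PAIR_INDEX[_BASE_CODE[x], _BASE_CODE[y]]))
    e = 0.0
    for i in range(L - 1):
        if pts[i] >= 0 and pts[i + 1] >= 0:
            e += float(_STACK[pts[i], pts[i + 1]])
    return e


def rules_pass(
    alignment: DuplexAlignment,
    mfe_ratio_min: float = 0.74,
    allow_gu_cleavage_site: bool = False,
) -> Tuple[bool, Tuple[Tuple[str, bool], ...]]:
    """Evaluate the six duplex rules; returns (pass, per-rule trace).

    The trace lists every rule in order with its verdict; the overall
    verdict is the conjunction, and the first failing rule is the first
    False entry.
    """
    cls = alignment.classes
    L = len(cls)
    weights = [0.0 if c == WC else (0.5 if c == GU else 1.0) for c in cls]

    r1 = alignment.mismatch_total <= 4.0

    run = best_run = 0
    for c in cls:
        run = run + 1 if c != WC else 0
        best_run = max(best_run, run)
    r2 = best_run <= 2

    r3 = True
    for i in range(1, min(11, L - 1)):  # positions 2..11 paired with 3..12 (1-based)
        if cls[i] != WC and cls[i + 1] != WC:
            r3 = False
            break

    if allow_gu_cleavage_site:
        r4 = all(cls[p] != MM for p in (9, 10) if p < L)
    else:
        r4 = all(cls[p] == WC for p in (9, 10) if p < L)

    r5 = sum(weights[:12]) <= 2.5
    r6 = alignment.mfe_ratio >= mfe_ratio_min

    trace = tuple(zip(RULE_NAMES, (r1, r2, r3, r4, r5, r6)))
    return all(v for _n, v in trace), trace


def scan_transcripts(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    mfe_ratio_min: float = 0.74,
    allow_gu_cleavage_site: bool = False,
) -> TargetReport:
    """Slide each miRNA over every transcript and report rule-passing sites."""
    report = TargetReport()
    for mid, mseq in mirnas.items():
        mseq = mseq.upper().replace("U", "T")
        L = len(mseq)
        for tid, tseq in transcripts.items():
            tseq = tseq.upper().replace("U", "T")
            for p in range(len(tseq) - L + 1):
                aln = score_duplex(mseq, tseq[p:p + L])
                ok, trace = rules_pass(aln, mfe_ratio_min=mfe_ratio_min,
                                       allow_gu_cleavage_site=allow_gu_cleavage_site)
                if ok:
                    aln.mirna_id, aln.transcript_id, aln.site_start = mid, tid, p
                    report.rows.append((aln, trace))
    return report


def average_targets_per_mirna(n_targets: int, n_mirnas: int) -> float:
    """Catalog-level average: predicted targets per miRNA with targets."""
    if n_mirnas <= 0:
        raise ValueError("n_mirnas must be positive")
    return n_targets / n_mirnas


# ---------------------------------------------------------------------------
# GO singular enrichment


def go_enrichment(
    target_ids: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe_ids: Iterable[str],
) -> pd.DataFrame:
    """Singular enrichment analysis of GO terms among predicted targets.

    For each term with K annotated genes in a universe of N, and k annotated
    among the n targets, p is the upper-tail hypergeometric probability of
    observing >= k; Benjamini-Hochberg adjustment is applied across terms.
    """
    universe = set(universe_ids)
    targets = set(target_ids)
    if not targets <= universe:
        raise ValueError("targets must be a subset of the universe")
    term_genes: Dict[str, set] = {}
    for gene, terms in annotation.items():
        if gene not in universe:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    N, n = len(universe), len(targets)
    rows = []
    for term, genes in sorted(term_genes.items()):
        K = len(genes)
        k = len(genes & targets)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if not df.empty:
        df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_bh"] = []
    return df


def write_target_report(
    report: TargetReport,
    mirnas: Mapping[str, str],
    path: str | Path,
) -> None:
    """Per-miRNA target lists in the catalog layout: comma-joined transcript
    ids, or "No target found" when the miRNA had no rule-passing site."""
    df = report.to_frame()
    with open(path, "w") as fh:
        fh.write("mirna\ttargets\n")
        for mid in mirnas:
            hits = df[df["mirna"] == mid]["transcript"].drop_duplicates().tolist()
            fh.write(f"{mid}\t{','.join(hits) if hits else 'No target found'}\n")
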