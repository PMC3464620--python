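"""Read preprocessing: adapter trimming, filtering, collapsing to unique tags.

Raw small-RNA reads are single-end sequences in which the 20-24 nt insert is
followed by the 3' sequencing adapter.  Preprocessing removes the adapter,
discards inserts that cannot be miRNA evidence (wrong size, Ns, low
complexity, exact contaminant matches) and collapses the survivors to unique
sequence tags carrying per-library counts — the unit every later stage
consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .fold import reverse_complement

__all__ = [
    "ADAPTER",
    "SequenceTag",
    "LibraryStats",
    "trim_adapter",
    "filter_and_collapse",
    "size_distribution",
    "read_reads_file",
    "write_tag_fasta",
    "write_count_table",
]

#: Illumina 3' small-RNA adapter
ADAPTER = "CTGTAGGCACCATCAAT"

MIN_TAG_LEN = 20
MAX_TAG_LEN = 24
MIN_DISTINCT_BASES = 3


@dataclass
class SequenceTag:
    """A unique insert sequence with per-library read counts."""

    seq: str
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def validate(self) -> None:
        if not (MIN_TAG_LEN <= len(self.seq) <= MAX_TAG_LEN):
            raise ValueError(f"tag length {len(self.seq)} outside [{MIN_TAG_LEN},{MAX_TAG_LEN}]")
        if set(self.seq) - set("ACGT"):
            raise ValueError(f"tag contains non-ACGT characters: {self.seq}")
        if len(set(self.seq)) < MIN_DISTINCT_BASES:
            raise ValueError("low-complexity tag (<3 distinct bases)")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative count")


@dataclass
class LibraryStats:
    library_id: str
    raw_reads: int
    filtered_reads: int
    unique_tags: int
    size_histogram: Dict[int, Tuple[int, int]]  # length -> (redundant, unique)


def trim_adapter(read: str, adapter: str = ADAPTER, min_overlap: int = 8) -> Optional[str]:
    """Return the insert preceding the leftmost adapter occurrence, or None.

    An occurrence is either the full adapter anywhere in the read, or a
    >= *min_overlap* prefix of the adapter flush with the read's 3' end (the
    adapter running off the read).  Reads with no adapter evidence return
    None, which signals discard: an insert shorter than the read implies the
    adapter must be visible.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    read = read.upper().replace("U", "T")
    adapter = adapter.upper().replace("U", "T")
    cut: Optional[int] = None
    idx = read.find(adapter)
    if idx >= 0:
        cut = idx
    # partial adapter running off the 3' end; longest prefix = leftmost cut
    for k in range(min(len(adapter) - 1, len(read)), min_overlap - 1, -1):
        if read.endswith(adapter[:k]):
            if cut is None or len(read) - k < cut:
                cut = len(read) - k
            break
    return read[:cut] if cut is not None else None


def _passes_filters(insert: str, contaminant_blob: str, contaminant_rc_blob: str) -> bool:
    if "N" in insert:
        return False
    if not (MIN_TAG_LEN <= len(insert) <= MAX_TAG_LEN):
        return False
    if len(set(insert)) < MIN_DISTINCT_BASES:
        return False
    # exact full-length match (the whole insert) against a contaminant,
    # sense or antisense
    if contaminant_blob and insert in contaminant_blob:
        return False
    if contaminant_rc_blob and insert in contaminant_rc_blob:
        return False
    return True


def filter_and_collapse(
    inserts_per_library: Mapping[str, Sequence[str]],
    contaminants: Iterable[str] = (),
    raw_reads: Optional[Mapping[str, int]] = None,
) -> Tuple[List[SequenceTag], Dict[str, LibraryStats]]:
    """Filter adapter-free inserts and collapse them into unique tags.

    Drops inserts containing N, outside 20-24 nt, with fewer than 3 distinct
    bases, or exactly matching a contaminant sequence full-length in sense or
    antisense orientation.  Survivors are collapsed to :class:`SequenceTag`
    objects with per-library counts; *raw_reads* (pre-trimming totals) feeds
    the per-library bookkeeping when supplied.
    """
    cont = ["\n" + c.upper().replace("U", "T") + "\n" for c in contaminants]
    blob = "".join(cont)
    rc_blob = "".join("\n" + reverse_complement(c.strip()) + "\n" for c in cont)
    tag_counts: Dict[str, Dict[str, int]] = {}
    stats: Dict[str, LibraryStats] = {}
    for lib, inserts in inserts_per_library.items():
        kept = 0
        hist: Dict[int, List[int]] = {l: [0, 0] for l in range(MIN_TAG_LEN, MAX_TAG_LEN + 1)}
        for ins in inserts:
            ins = ins.upper().replace("U", "T")
            if not _passes_filters(ins, blob, rc_blob):
                continue
            kept += 1
            tag_counts.setdefault(ins, {}).setdefault(lib, 0)
            tag_counts[ins][lib] += 1
        for seq, counts in tag_counts.items():
            if lib in counts:
                hist[len(seq)][0] += counts[lib]
                hist[len(seq)][1] += 1
        stats[lib] = LibraryStats(
            library_id=lib,
            raw_reads=(raw_reads or {}).get(lib, len(inserts)),
            filtered_reads=kept,
            unique_tags=sum(v[1] for v in hist.values()),
            size_histogram={l: tuple(v) for l, v in hist.items()},
        )
    tags = [SequenceTag(seq=s, counts=c) for s, c in sorted(tag_counts.items())]
    for t in tags:
        t.validate()
    return tags, stats


def size_distribution(tags: Sequence[SequenceTag]) -> Dict[int, Tuple[int, int]]:
    """Redundant and unique counts per tag length over the 20-24 nt range."""
    hist: Dict[int, List[int]] = {l: [0, 0] for l in range(MIN_TAG_LEN, MAX_TAG_LEN + 1)}
    for t in tags:
        hist[len(t.seq)][0] += t.total_count
        hist[len(t.seq)][1] += 1
    return {l: (r, u) for l, (r, u) in hist.items()}


# ---------------------------------------------------------------------------
# IO


def read_reads_file(path: str | Path) -> List[str]:
    """Read sequences from FASTQ or FASTA (plain text)."""
    from Bio import SeqIO

    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]


def write_tag_fasta(tags: Sequence[SequenceTag], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(tags, start=1):
            fh.write(f">tag{i}_x{t.total_count}\n{t.seq}\n")


def write_count_table(tags: Sequence[SequenceTag], libraries: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq\ttotal\t" + "\t".join(libraries) + "\n")
        for t in tags:
            row = "\t".join(str(t.counts.get(lib, 0)) for lib in libraries)
            fh.write(f"{t.seq}\t{t.total_count}\t{row}\n")


def read_count_table(path: str | Path) -> List[SequenceTag]:
    """Inverse of :func:`write_count_table`."""
    lines = Path(path).read_text().splitlines()
    libs = lines[0].split("\t")[2:]
    tags = []
    for line in lines[1:]:
        parts = line.split("\t")
        counts = {lib: int(c) for lib, c in zip(libs, parts[2:]) if int(c) > 0}
        tags.append(SequenceTag(seq=parts[0], counts=counts))
    return tags


def write_stats_json(stats: Mapping[str, LibraryStats], path: str | Path) -> None:
    payload = {
        lib: {
            "raw_reads": s.raw_reads,
            "filtered_reads": s.filtered_reads,
            "unique_tags": s.unique_tags,
            "size_histogram": {str(k): list(v) for k, v in s.size_histogram.items()},
        }
        for lib, s in stats.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))
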