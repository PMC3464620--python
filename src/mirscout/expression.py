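"""Cross-library expression profiling — the "electronic northern".

Abundance of a mature miRNA in a library is inferred from its read count
normalised to transcripts per million (TPM) over that library's filtered
reads.  On top of the TPM matrix this module provides presence/absence set
partitions across condition groups, assay-specific and high-abundance
selections, and 5' nucleotide composition by length.

The printed electronic-northern table of high-confidence (class I) miRNAs
and the printed target catalog ship as packaged TSV fixtures so their
summary logic can be recomputed offline.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

__all__ = [
    "normalize_tpm",
    "set_partition",
    "count_assay_specific",
    "high_abundance",
    "five_prime_composition",
    "load_electronic_northern_table",
    "load_target_catalog_table",
    "load_target_catalog_totals",
    "TABLE_ASSAYS",
]

#: assay -> library columns of the packaged electronic-northern fixture
TABLE_ASSAYS: Dict[str, List[str]] = {
    "biotic": ["biotic_CT", "biotic_AA"],
    "drought": ["drought_T0h", "drought_T24h", "drought_S0h", "drought_S24h"],
    "salt": ["salt_0h", "salt_1h", "salt_6h", "salt_24h"],
}


def normalize_tpm(raw: pd.DataFrame, filtered_reads: Mapping[str, int]) -> pd.DataFrame:
    """TPM matrix: ``tpm[m, L] = raw[m, L] * 1e6 / filtered_reads[L]``.

    *raw* has miRNA ids as the index and library ids as columns.  Libraries
    with any nonzero count must have positive filtered totals.
    """
    tpm = raw.astype(float).copy()
    for lib in raw.columns:
        total = filtered_reads.get(lib, 0)
        if total <= 0:
            if raw[lib].any():
                raise ValueError(f"library {lib} has counts but no filtered total")
            tpm[lib] = 0.0
        else:
            tpm[lib] = raw[lib] * 1e6 / total
    return tpm


def _detected(tpm: pd.DataFrame, libraries: Sequence[str], threshold: float) -> pd.Series:
    return (tpm[list(libraries)] > threshold).any(axis=1)


def set_partition(
    tpm: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    detection_threshold: float = 0.0,
) -> Dict[Tuple[str, ...], int]:
    """Exclusive region counts of the detection set diagram over *groups*.

    Each miRNA detected in at least one group contributes to exactly one
    region, keyed by the sorted tuple of group names where it is detected;
    region counts therefore sum to the number of detected miRNAs.
    """
    regions: Dict[Tuple[str, ...], int] = {}
    for m in tpm.index:
        present = tuple(sorted(
            g for g, libs in groups.items()
            if (tpm.loc[m, list(libs)] > detection_threshold).any()
        ))
        if present:
            regions[present] = regions.get(present, 0) + 1
    return regions


def count_assay_specific(
    tpm: pd.DataFrame,
    assays: Mapping[str, Sequence[str]],
    detection_threshold: float = 0.0,
) -> Tuple[int, List[str]]:
    """miRNAs detected in exactly one assay's libraries."""
    if len(assays) < 2:
        raise ValueError("need at least two assays")
    ids = []
    for m in tpm.index:
        n = sum(
            1 for libs in assays.values()
            if (tpm.loc[m, list(libs)] > detection_threshold).any()
        )
        if n == 1:
            ids.append(m)
    return len(ids), ids


def high_abundance(tpm: pd.DataFrame, threshold: float = 50.0) -> List[str]:
    """miRNAs whose maximum normalised abundance exceeds *threshold*."""
    return list(tpm.index[tpm.max(axis=1) > threshold])


def five_prime_composition(seqs: Iterable[str]) -> pd.DataFrame:
    """Percentage of A/C/G/U at the 5' position, per sequence length.

    Rows are lengths present in the input; columns A, C, G, U sum to 100%
    per row.
    """
    rows: Dict[int, Dict[str, int]] = {}
    for s in seqs:
        s = s.upper().replace("U", "T")
        first = s[0]
        rows.setdefault(len(s), {"A": 0, "C": 0, "G": 0, "T": 0})
        rows[len(s)][first] += 1
    out = {}
    for length, counts in sorted(rows.items()):
        total = sum(counts.values())
        out[length] = {
            ("U" if b == "T" else b): 100.0 * counts[b] / total
            for b in ("A", "C", "G", "T")
        }
    return pd.DataFrame(out).T[["A", "C", "G", "U"]]


# ---------------------------------------------------------------------------
# packaged fixtures (printed tables)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mirscout") / "data" / name))


def load_electronic_northern_table() -> Tuple[pd.DataFrame, pd.DataFrame]:
    """The printed class-I electronic-northern matrix.

    Returns (metadata, tpm): metadata has columns ``mirna`` and
    ``mirna_star`` (sequences, T alphabet) indexed by miRNA id; tpm is the
    10-library normalised matrix with absent ("-") rendered as 0.0.
    """
    df = pd.read_csv(_data_path("electronic_northern_classI.tsv"), sep="\t", index_col=0)
    meta = df[["mirna", "mirna_star"]]
    libs = [c for c in df.columns if c not in ("mirna", "mirna_star")]
    tpm = df[libs].replace("-", 0.0).astype(float)
    return meta, tpm


def load_target_catalog_table() -> pd.DataFrame:
    """The printed class-I target catalog: per-miRNA sugarcane target lists
    ("No TC found" / "No target found" kept verbatim) and the sorghum
    conservation flag (+/-)."""
    return pd.read_csv(_data_path("classI_target_catalog.tsv"), sep="\t", index_col=0)


def load_target_catalog_totals() -> pd.DataFrame:
    """Printed totals of the full (all-candidate) target search: number of
    predicted targets and of miRNAs with targets, per transcript database."""
    return pd.read_csv(_data_path("target_catalog_totals.tsv"), sep="\t", index_col=0)


def write_expression_matrix(tpm: pd.DataFrame, path: str | Path) -> None:
    """Human-readable electronic northern: zeros rendered as "-"."""
    disp = tpm.round(2).astype(object)
    disp[tpm <= 0] = "-"
    disp.to_csv(path, sep="\t")
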