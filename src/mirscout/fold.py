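"""RNA secondary-structure folding and stability statistics.

Everything downstream of read mapping rests on a folding backend that, given a
genomic window, returns a non-crossing secondary structure and its free energy.
The default backend is a nearest-neighbor *stacking* energy minimisation: base
pairs contribute energy only through stacks of adjacent pairs (Turner-style
stack table, kcal/mol), hairpin loops must hold at least three unpaired bases,
and isolated pairs are energetically neutral.  This captures what the hairpin
checks and the randfold permutation test need — long helices score strongly
negative, random sequence scores near zero — while staying dependency-free.
An optional backend delegates to ViennaRNA when its python bindings or the
``RNAfold`` binary are available; all structural checks are written against the
:class:`FoldResult` contract so they hold under either backend.

Sequences are handled in DNA alphabet (T, not U) throughout the package; the
fold treats T as U.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "FoldResult",
    "fold",
    "fold_vienna",
    "reverse_complement",
    "gc_percent",
    "dinucleotide_shuffle",
    "mononucleotide_shuffle",
    "randfold_p",
    "MIN_FOLD_LEN",
]

MIN_FOLD_LEN = 10
MIN_LOOP = 3  # minimum unpaired bases closed by a hairpin pair

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair-type index for (5' base, 3' base); -1 = cannot pair
_PAIR_INDEX = -np.ones((4, 4), dtype=np.int64)
for _i, (_a, _b) in enumerate([("A", "T"), ("C", "G"), ("G", "C"),
                               ("T", "A"), ("G", "T"), ("T", "G")]):
    _PAIR_INDEX[_BASE_CODE[_a], _BASE_CODE[_b]] = _i

# Stacking free energies (kcal/mol) for pair (i,j) stacked on (i+1,j-1),
# indexed [pair_type(i,j), pair_type(i+1,j-1)].  Values follow the magnitude
# pattern of measured RNA nearest-neighbor stacks (GC-rich stacks strongest,
# wobble stacks weakest); wobble-on-wobble is clamped mildly negative so that
# added pairing never destabilises a helix in this model.
# order: AU, CG, GC, UA, GU, UG
_STACK = np.array([
    #  AU     CG     GC     UA     GU     UG
    [-0.93, -2.24, -2.08, -1.10, -0.55, -1.36],  # AU
    [-2.11, -3.26, -2.36, -2.08, -1.41, -2.11],  # CG
    [-2.24, -3.42, -3.26, -2.35, -1.53, -2.51],  # GC
    [-1.33, -2.35, -2.11, -0.93, -1.00, -1.27],  # UA
    [-1.27, -2.51, -2.11, -1.36, -0.50, -0.30],  # GU
    [-1.00, -1.53, -1.41, -0.55, -0.30, -0.50],  # UG
], dtype=np.float64)

#: cost of opening a new helix (hairpin/interior/multi loop closure), kcal/mol.
#: Penalises isolated and very short helices the way measured loop
#: initiation terms do; without it random sequence over-pairs.
HELIX_INIT = 4.0

_INF = 1e9


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content of *seq* as a percentage (0-100)."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def _encode(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq.upper()):
        out[i] = _BASE_CODE.get(c, -1)
    return out


@njit(cache=True)
def _fill(enc, pair_index, stack):  # pragma: no cover - numba kernel
    n = enc.shape[0]
    V = np.full((n, n), _INF)
    W = np.zeros((n, n))
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            a = enc[i]
            b = enc[j]
            pt = -1
            if a >= 0 and b >= 0:
                pt = pair_index[a, b]
            if pt >= 0:
                best = W[i + 1, j - 1] + HELIX_INIT
                if V[i + 1, j - 1] < _INF / 2:
                    a2 = enc[i + 1]
                    b2 = enc[j - 1]
                    pt2 = pair_index[a2, b2]
                    cand = V[i + 1, j - 1] + stack[pt, pt2]
                    if cand < best:
                        best = cand
                V[i, j] = best
            # W recurrence
            w = W[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if V[i, k] < _INF / 2:
                    rest = W[k + 1, j] if k + 1 <= j else 0.0
                    cand = V[i, k] + rest
                    if cand < w:
                        w = cand
            W[i, j] = w
    return V, W


def _traceback(enc: np.ndarray, V: np.ndarray, W: np.ndarray) -> List[tuple]:
    """Recover one optimal set of pairs; prefers unpaired over neutral pairs
    and stacked continuations over interior restarts when energies tie."""
    eps = 1e-6
    n = enc.shape[0]
    pairs: List[tuple] = []
    stack_frames = [("W", 0, n - 1)]
    while stack_frames:
        kind, i, j = stack_frames.pop()
        if j - i < MIN_LOOP + 1:
            continue
        if kind == "W":
            if abs(W[i, j] - W[i + 1, j]) < eps:
                stack_frames.append(("W", i + 1, j))
                continue
            done = False
            for k in range(i + MIN_LOOP + 1, j + 1):
                if V[i, k] < _INF / 2:
                    rest = W[k + 1, j] if k + 1 <= j else 0.0
                    if abs(W[i, j] - (V[i, k] + rest)) < eps:
                        stack_frames.append(("V", i, k))
                        if k + 1 <= j:
                            stack_frames.append(("W", k + 1, j))
                        done = True
                        break
            if not done:  # numerical fallback
                stack_frames.append(("W", i + 1, j))
        else:  # V: (i, j) pair
            pairs.append((i, j))
            pt = _PAIR_INDEX[enc[i], enc[j]]
            if V[i + 1, j - 1] < _INF / 2:
                pt2 = _PAIR_INDEX[enc[i + 1], enc[j - 1]]
                if abs(V[i, j] - (V[i + 1, j - 1] + _STACK[pt, pt2])) < eps:
                    stack_frames.append(("V", i + 1, j - 1))
                    continue
            stack_frames.append(("W", i + 1, j - 1))  # interior closed with HELIX_INIT
    return pairs


@dataclass
class FoldResult:
    """A sequence, its predicted non-crossing structure and free energy."""

    seq: str
    structure: str
    mfe: float
    _pair_table: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.seq):
            raise ValueError("structure length must equal sequence length")

    @property
    def pair_table(self) -> np.ndarray:
        """Array mapping position -> partner index, -1 if unpaired."""
        if self._pair_table is None:
            pt = np.full(len(self.seq), -1, dtype=np.int64)
            stack: List[int] = []
            for i, c in enumerate(self.structure):
                if c == "(":
                    stack.append(i)
                elif c == ")":
                    if not stack:
                        raise ValueError("unbalanced structure")
                    a = stack.pop()
                    pt[a] = i
                    pt[i] = a
            if stack:
                raise ValueError("unbalanced structure")
            self._pair_table = pt
        return self._pair_table

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")


def _structure_string(n: int, pairs: Sequence[tuple]) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i] = "("
        s[j] = ")"
    return "".join(s)


def fold(seq: str) -> FoldResult:
    """Fold *seq* with the in-package nearest-neighbor stacking model.

    Returns the minimum free energy structure under the stack-only energy
    model.  MFE is 0 exactly when the optimal structure has no pairs (e.g.
    a homopolymer).  Raises ``ValueError`` for sequences shorter than 10 nt.
    """
    if len(seq) < MIN_FOLD_LEN:
        raise ValueError(f"sequence too short to fold ({len(seq)} < {MIN_FOLD_LEN} nt)")
    enc = _encode(seq)
    V, W = _fill(enc, _PAIR_INDEX, _STACK)
    mfe = float(W[0, len(seq) - 1])
    pairs = _traceback(enc, V, W)
    if not pairs:
        mfe = 0.0
    return FoldResult(seq=seq, structure=_structure_string(len(seq), pairs), mfe=mfe)


def fold_vienna(seq: str) -> FoldResult:
    """Fold with ViennaRNA (python bindings, else the RNAfold binary).

    Optional established-thermodynamics backend; raises ``RuntimeError`` when
    neither route is available.
    """
    if len(seq) < MIN_FOLD_LEN:
        raise ValueError(f"sequence too short to fold ({len(seq)} < {MIN_FOLD_LEN} nt)")
    rna = seq.upper().replace("T", "U")
    try:
        import RNA  # type: ignore

        structure, mfe = RNA.fold(rna)
        return FoldResult(seq=seq, structure=structure, mfe=float(mfe))
    except ImportError:
        pass
    try:
        proc = subprocess.run(
            ["RNAfold", "--noPS"], input=rna + "\n", text=True,
            capture_output=True, check=True,
        )
    except (OSError, subprocess.CalledProcessError) as exc:  # pragma: no cover
        raise RuntimeError("no ViennaRNA backend available") from exc
    lines = proc.stdout.strip().splitlines()
    struct_line = lines[-1]
    structure = struct_line.split()[0]
    mfe = float(struct_line.rsplit("(", 1)[1].rstrip(")").strip())
    return FoldResult(seq=seq, structure=structure, mfe=mfe)


# ---------------------------------------------------------------------------
# shuffles and the randfold permutation test


def mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving the exact dinucleotide count vector.

    Altschul–Erikson Euler-path construction: treat each adjacent base pair as
    a directed edge, fix, for every vertex except the last base, one terminal
    edge such that terminal edges form a tree into the last base, then emit a
    random Euler path.  First and last bases are preserved by construction.
    """
    if len(seq) < 3 or len(set(seq)) < 2:
        return seq
    edges: dict = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    # pick terminal edges until they connect every vertex to `last`
    while True:
        terminal = {}
        for v in vertices:
            if v == last:
                continue
            terminal[v] = edges[v][rng.integers(len(edges[v]))]
        ok = True
        for v in terminal:
            seen = {v}
            cur = v
            while cur != last:
                cur = terminal.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    shuffled_edges = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v != last:
            rest.remove(terminal[v])
        rng.shuffle(rest)
        if v != last:
            rest.append(terminal[v])
        shuffled_edges[v] = rest
    out = [seq[0]]
    pos = {v: 0 for v in edges}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def randfold_p(
    seq: str,
    n_shuffles: int = 99,
    mode: str = "dinucleotide",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    fold_fn: Callable[[str], FoldResult] = fold,
) -> float:
    """Permutation p-value for folding stability.

    ``p = (k + 1) / (n_shuffles + 1)`` where *k* counts shuffled sequences
    whose fold MFE is at least as low as the original's.  Low p means the
    sequence folds more stably than its (di)nucleotide composition predicts.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if mode not in ("mononucleotide", "dinucleotide"):
        raise ValueError(f"unknown shuffle mode: {mode}")
    if rng is None:
        rng = np.random.default_rng(seed)
    shuffle = dinucleotide_shuffle if mode == "dinucleotide" else mononucleotide_shuffle
    m0 = fold_fn(seq).mfe
    k = 0
    for _ in range(n_shuffles):
        if fold_fn(shuffle(seq, rng)).mfe <= m0 + 1e-9:
            k += 1
    return (k + 1) / (n_shuffles + 1)
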