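"""Secondary-structure prediction behind a pluggable backend contract.

Two backends implement the same interface:

* :class:`ReferenceFolder` — a deterministic, dependency-free folder
  built into the package.  It minimizes a nearest-neighbor-lite energy:
  fixed energies per base pair, a stacking bonus graded by G:C content,
  and a hairpin-loop length penalty; no dangles, no multiloop penalty.
  It is not meant to reproduce Turner-model energies — only to give a
  consistent, deterministic energy scale and correct structure
  *orderings* on small instances — which is all the scoring model needs,
  since |MFE| only enters through a fitted score function.
* :class:`ViennaRNAFolder` — shells out to a Vienna-compatible
  ``RNAfold`` executable for production-scale runs.

Ties in the reference model are broken by the lexicographically
smallest dot-bracket string, so results are fully reproducible.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import sys
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .io_formats import FormatError, normalize_sequence

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


class FoldingError(RuntimeError):
    """Backend failure (missing executable, unparsable output)."""


@dataclass(frozen=True)
class FoldResult:
    sequence: str
    structure: str
    mfe: float  # kcal/mol, <= 0 by convention


MIN_LOOP = 3  # minimum hairpin loop length, nt

# base encoding: A=0 C=1 G=2 T(U)=3 N=4
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}

# pair energies, kcal/mol-like: G:C, A:U, G:U; N never pairs
_PAIR_E = np.full((5, 5), np.inf)
for _i, _j, _e in [(2, 1, -2.0), (1, 2, -2.0), (0, 3, -1.0), (3, 0, -1.0), (2, 3, -0.5), (3, 2, -0.5)]:
    _PAIR_E[_i, _j] = _e

_HAIRPIN_A = 3.0   # penalty at minimal loop
_HAIRPIN_B = 0.2   # per-nt penalty beyond minimal loop
_STACK_GC2 = -1.0  # both stacked pairs contain G:C
_STACK_GC1 = -0.5  # one does
_STACK_GC0 = -0.25  # neither does

_INF = 1.0e9


def encode(sequence: str) -> np.ndarray:
    seq = normalize_sequence(sequence, context="fold input")
    return np.array([_ENC[c] for c in seq], dtype=np.int8)


def _is_gc(a: int, b: int) -> bool:
    return (a == 2 and b == 1) or (a == 1 and b == 2)


def hairpin_penalty(loop_len: int) -> float:
    return _HAIRPIN_A + _HAIRPIN_B * (loop_len - MIN_LOOP)


def stack_energy(a: int, b: int, c: int, d: int) -> float:
    """Stacking bonus for pair (a,b) sitting on inner pair (c,d)."""
    n_gc = int(_is_gc(a, b)) + int(_is_gc(c, d))
    return _STACK_GC2 if n_gc == 2 else (_STACK_GC1 if n_gc == 1 else _STACK_GC0)


@njit(cache=True)
def _fill(enc, pair_e, hp_a, hp_b, st2, st1, st0):  # pragma: no cover - numba kernel
    n = enc.shape[0]
    INF = 1.0e9
    P = np.full((n, n), INF)
    M = np.zeros((n, n))
    Mp = np.full((n, n), INF)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            # P[i, j]: best energy with (i, j) paired
            pe = pair_e[enc[i], enc[j]]
            if pe < INF:
                best = hp_a + hp_b * (span - 1 - MIN_LOOP)
                if span - 2 > MIN_LOOP and P[i + 1, j - 1] < INF:
                    gc_out = 1 if ((enc[i] == 2 and enc[j] == 1) or (enc[i] == 1 and enc[j] == 2)) else 0
                    gc_in = 1 if ((enc[i + 1] == 2 and enc[j - 1] == 1) or (enc[i + 1] == 1 and enc[j - 1] == 2)) else 0
                    ngc = gc_out + gc_in
                    st = st2 if ngc == 2 else (st1 if ngc == 1 else st0)
                    cand = P[i + 1, j - 1] + st
                    if cand < best:
                        best = cand
                if Mp[i + 1, j - 1] < best:
                    best = Mp[i + 1, j - 1]
                P[i, j] = pe + best
            # M / Mp
            m = M[i + 1, j]
            mp = Mp[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if P[i, k] < INF:
                    rest = 0.0 if k + 1 > j else M[k + 1, j]
                    cand = P[i, k] + rest
                    if cand < m:
                        m = cand
                    if cand < mp:
                        mp = cand
            M[i, j] = m
            Mp[i, j] = mp
    return P, M, Mp


# numba cannot see module globals in all versions; pass constants explicitly
def _dp_tables(enc: np.ndarray):
    return _fill(enc, _PAIR_E, _HAIRPIN_A, _HAIRPIN_B, _STACK_GC2, _STACK_GC1, _STACK_GC0)


_TOL = 1e-6


def _traceback_lex(enc: np.ndarray, P: np.ndarray, M: np.ndarray, Mp: np.ndarray) -> str:
    """Lexicographically smallest dot-bracket among minimum-energy structures."""
    n = enc.shape[0]
    memo: dict = {}
    sys.setrecursionlimit(max(10000, 50 * n))

    def close(i: int, j: int) -> str:
        key = ("P", i, j)
        if key in memo:
            return memo[key]
        target = P[i, j] - _PAIR_E[enc[i], enc[j]]
        span = j - i
        cands = []
        hp = hairpin_penalty(span - 1)
        if abs(hp - target) < _TOL:
            cands.append("." * (span - 1))
        if span - 2 > MIN_LOOP and P[i + 1, j - 1] < _INF:
            st = stack_energy(enc[i], enc[j], enc[i + 1], enc[j - 1])
            if abs(P[i + 1, j - 1] + st - target) < _TOL:
                cands.append(close(i + 1, j - 1))
        if Mp[i + 1, j - 1] < _INF and abs(Mp[i + 1, j - 1] - target) < _TOL:
            cands.append(region(i + 1, j - 1, paired_only=True))
        s = "(" + min(cands) + ")"
        memo[key] = s
        return s

    def region(i: int, j: int, paired_only: bool = False) -> str:
        if j < i:
            return ""
        key = ("Mp" if paired_only else "M", i, j)
        if key in memo:
            return memo[key]
        if j - i < MIN_LOOP + 1:
            # too short to hold a pair
            s = "." * (j - i + 1)
            memo[key] = s
            return s
        T = Mp if paired_only else M
        target = T[i, j]
        cands = []
        sub = T[i + 1, j]
        if np.isfinite(sub) and abs(sub - target) < _TOL:
            cands.append("." + region(i + 1, j, paired_only))
        for k in range(i + MIN_LOOP + 1, j + 1):
            if P[i, k] < _INF:
                rest = M[k + 1, j] if k + 1 <= j else 0.0
                if abs(P[i, k] + rest - target) < _TOL:
                    cands.append(close(i, k) + (region(k + 1, j) if k + 1 <= j else ""))
        s = min(cands)
        memo[key] = s
        return s

    return region(0, n - 1)


def structure_energy(sequence: str, structure: str) -> float:
    """Energy of a given structure under the reference model.

    Sums pair energies, stacking bonuses for directly nested adjacent
    pairs, and one loop penalty per hairpin (a pair enclosing only
    unpaired bases).  Used by the folder and usable as a standalone
    scoring rule for externally supplied structures.
    """
    enc = encode(sequence)
    pt = pair_table(structure)
    if len(structure) != len(sequence):
        raise FormatError("structure length != sequence length")
    e = 0.0
    pairs = [(i, j) for i, j in enumerate(pt) if j is not None and i < j]
    pairset = set(pairs)
    for i, j in pairs:
        pe = _PAIR_E[enc[i], enc[j]]
        if not np.isfinite(pe):
            raise FormatError(f"non-complementary pair at positions {i},{j}")
        e += pe
        if (i + 1, j - 1) in pairset:
            e += stack_energy(enc[i], enc[j], enc[i + 1], enc[j - 1])
        if all(pt[k] is None for k in range(i + 1, j)):  # hairpin closing pair
            e += hairpin_penalty(j - i - 1)
    return e


class ReferenceFolder:
    """Built-in deterministic folder (nearest-neighbor-lite energy model)."""

    name = "reference"

    def fold(self, sequence: str) -> FoldResult:
        enc = encode(sequence)
        n = enc.shape[0]
        if n < 10:
            raise ValueError("fold requires sequence length >= 10")
        P, M, Mp = _dp_tables(enc)
        mfe = float(M[0, n - 1])
        structure = _traceback_lex(enc, P, M, Mp)
        return FoldResult(normalize_sequence(sequence), structure, mfe)

    def energy(self, sequence: str) -> float:
        """MFE only (no traceback) — used for shuffle ensembles."""
        enc = encode(sequence)
        n = enc.shape[0]
        _, M, _ = _dp_tables(enc)
        return min(float(M[0, n - 1]), 0.0)

    def energy_many(self, sequences: Sequence[str]) -> List[float]:
        return [self.energy(s) for s in sequences]

    def fold_many(self, sequences: Sequence[str]) -> List[FoldResult]:
        return [self.fold(s) for s in sequences]


_VIENNA_LINE = re.compile(r"^([().]+)\s*\(\s*(-?\d+(?:\.\d+)?)\s*\)")


class ViennaRNAFolder:
    """External backend: shells out to a Vienna-compatible ``RNAfold``.

    Input is converted to RNA space (T→U) on this boundary; results are
    reported back against the internal DNA-space sequence.
    """

    name = "external"

    def __init__(self, executable: str = "RNAfold"):
        if shutil.which(executable) is None:
            raise FoldingError(
                f"external folding backend {executable!r} not found on PATH; "
                "install ViennaRNA or use the reference backend"
            )
        self.executable = executable

    def _run(self, sequences: Sequence[str]) -> List[FoldResult]:
        norm = [normalize_sequence(s) for s in sequences]
        stdin = "".join(f">s{i}\n{s.replace('T', 'U')}\n" for i, s in enumerate(norm))
        proc = subprocess.run(
            [self.executable, "--noPS"],
            input=stdin,
            capture_output=True,
            text=True,
            check=False,
        )
        if proc.returncode != 0:
            raise FoldingError(f"{self.executable} failed: {proc.stderr.strip()[:500]}")
        results: List[FoldResult] = []
        idx = 0
        for line in proc.stdout.splitlines():
            m = _VIENNA_LINE.match(line.strip())
            if m:
                if idx >= len(norm):
                    raise FoldingError("unexpected extra structure lines in RNAfold output")
                structure, energy = m.group(1), float(m.group(2))
                if len(structure) != len(norm[idx]):
                    raise FoldingError("RNAfold structure length mismatch")
                results.append(FoldResult(norm[idx], structure, energy))
                idx += 1
        if idx != len(norm):
            raise FoldingError(f"parsed {idx} structures for {len(norm)} inputs")
        return results

    def fold(self, sequence: str) -> FoldResult:
        if len(sequence) < 10:
            raise ValueError("fold requires sequence length >= 10")
        return self._run([sequence])[0]

    def fold_many(self, sequences: Sequence[str]) -> List[FoldResult]:
        if not sequences:
            return []
        return self._run(list(sequences))

    def energy(self, sequence: str) -> float:
        return self.fold(sequence).mfe

    def energy_many(self, sequences: Sequence[str]) -> List[float]:
        return [r.mfe for r in self.fold_many(sequences)]


def get_backend(backend="reference"):
    """Resolve a backend name or pass through a backend object."""
    if hasattr(backend, "fold"):
        return backend
    if backend == "reference":
        return ReferenceFolder()
    if backend == "external":
        return ViennaRNAFolder()
    raise ValueError(f"unknown folding backend {backend!r}")


def fold(sequence: str, backend="reference") -> FoldResult:
    """Fold a sequence with the chosen backend; deterministic per backend."""
    return get_backend(backend).fold(sequence)


def pair_table(structure: str) -> List[Optional[int]]:
    """Partner index per position (None if unpaired); errors on unbalanced input."""
    stack: List[int] = []
    table: List[Optional[int]] = [None] * len(structure)
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise FormatError("unbalanced dot-bracket: unmatched ')'")
            j = stack.pop()
            table[i], table[j] = j, i
        elif ch != ".":
            raise FormatError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise FormatError("unbalanced dot-bracket: unmatched '('")
    return table


def has_bifurcation(structure: str, region: Optional[tuple[int, int]] = None) -> bool:
    """True iff the region holds more than one outermost helix."""
    if region is None:
        region = (0, len(structure))
    pair_table(structure)  # validates balance
    lo, hi = region
    depth = 0
    helices = 0
    for ch in structure[lo:hi]:
        if ch == "(":
            if depth == 0:
                helices += 1
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
    return helices > 1
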