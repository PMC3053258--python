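"""The five statistical features scored for each candidate precursor.

For a candidate hairpin with mapped reads the model evaluates:

* ``abs`` — the absolute minimum free energy, used length-normalized
  (kcal/mol per nt) so hairpins of different length are comparable;
* ``rel`` — stability: does the native fold beat an ensemble of
  shuffled versions of the sequence (randfold-style p = R/(N+1))?
* ``nuc`` — is the mature's nucleus (positions 2–12 in plants)
  identical to the nucleus of any known mature miRNA?
* ``star`` — does at least one read map to the star arm?
* ``sig`` — are read 5' ends consistent with Dicer processing
  (stacked on the mature/star 5' ends or confined to the loop)?
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .excision import Duplex, Precursor
from .folding import FoldResult, get_backend
from .io_formats import ReadAlignment
from .params import ParameterSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureVector:
    precursor_id: str
    abs_mfe: float            # |MFE|, kcal/mol
    normalized_mfe: float     # mfe / length, signed, kcal/mol/nt
    rel: int                  # 1 = stable under shuffling
    rel_pvalue: float
    nuc: int                  # 1 = nucleus conserved
    star: int                 # 1 = star read present
    sig_loglik_real: float
    sig_loglik_bgr: float

    @property
    def sig_logodds(self) -> float:
        return self.sig_loglik_real - self.sig_loglik_bgr


# --------------------------------------------------------------- abs

def normalized_mfe(fold_result: FoldResult, length: Optional[int] = None) -> float:
    """MFE per nucleotide (signed, <= 0); invariant to precursor length
    for equal per-nt energies."""
    L = length if length is not None else len(fold_result.sequence)
    if L <= 0:
        raise ValueError("length must be positive")
    return fold_result.mfe / L


# ------------------------------------------------------------ shuffling

def shuffle(sequence: str, mode: str = "mono", rng: Optional[np.random.Generator] = None) -> str:
    """Shuffle preserving mononucleotide or dinucleotide counts exactly.

    ``mono`` is a Fisher–Yates permutation of the letters.  ``di`` is an
    Altschul–Erickson Euler-path shuffle: the 16-entry dinucleotide count
    table is preserved exactly, with first and last letters fixed.
    """
    if len(sequence) < 2:
        raise ValueError("shuffle requires length >= 2")
    rng = rng if rng is not None else np.random.default_rng()
    if mode == "mono":
        chars = list(sequence)
        rng.shuffle(chars)
        return "".join(chars)
    if mode == "di":
        return _dinucleotide_shuffle(sequence, rng)
    raise ValueError(f"unknown shuffle mode {mode!r}")


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul–Erickson shuffle: sample a random Euler path through the
    dinucleotide multigraph from seq[0] to seq[-1]."""
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    vertices = list(edges)
    last = seq[-1]
    if len(vertices) == 1 and vertices[0] == last:
        return seq  # single-vertex graph: any Euler path is the identity multiset

    # pick a random "last edge" per non-terminal vertex such that the
    # chosen edges form a spanning arborescence into the terminal vertex
    for _ in range(10000):
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        if _reaches_terminal(last_edge, last):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("failed to sample a valid Euler-path ordering")

    ordering: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        ordering[v] = rest

    out = [seq[0]]
    pos = {v: 0 for v in vertices}
    v = seq[0]
    for _ in range(len(seq) - 1):
        nxt = ordering[v][pos[v]]
        pos[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def _reaches_terminal(last_edge: dict[str, str], terminal: str) -> bool:
    for start in last_edge:
        v, seen = start, set()
        while v != terminal:
            if v in seen or v not in last_edge:
                return False
            seen.add(v)
            v = last_edge[v]
    return True


# ------------------------------------------------------------ stability

def stability_pvalue_from_count(r: int, n_shuffles: int) -> float:
    """p = R/(N+1), floored at 1/(N+1): the smallest p a finite shuffle
    ensemble can attest."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    return max(r, 1) / (n_shuffles + 1)


def stability_pvalue(
    sequence: str,
    n_shuffles: int = 999,
    mode: str = "mono",
    rng: Optional[np.random.Generator] = None,
    backend="reference",
    threshold: float = 0.05,
) -> tuple[float, int]:
    """Shuffling-stability test: fraction of shuffles folding at least as
    stably as the native sequence (ties count, conservatively).

    Returns ``(p_value, rel)`` with ``rel = 1`` iff ``p <= threshold``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    folder = get_backend(backend)
    native = folder.energy(sequence)
    shuffled = [shuffle(sequence, mode, rng) for _ in range(n_shuffles)]
    energies = folder.energy_many(shuffled)
    r = sum(1 for e in energies if e <= native)  # lower energy = more stable
    p = stability_pvalue_from_count(r, n_shuffles)
    return p, int(p <= threshold)


# ------------------------------------------------------------- nucleus

def nucleus_conserved(
    mature_sequence: str,
    known_matures: Sequence[str],
    positions: tuple[int, int] = (2, 12),
    max_mismatches: int = 0,
) -> int:
    """1 iff the 1-based inclusive ``positions`` window of the mature
    matches the same window of at least one known mature."""
    lo, hi = positions
    if len(mature_sequence) < hi:
        logger.info("mature shorter than nucleus window %s; scored non-conserved", positions)
        return 0
    window = mature_sequence[lo - 1:hi].upper().replace("U", "T")
    for known in known_matures:
        if len(known) < hi:
            continue
        kw = known[lo - 1:hi].upper().replace("U", "T")
        mism = sum(1 for a, b in zip(window, kw) if a != b)
        if mism <= max_mismatches:
            return 1
    return 0


# ---------------------------------------------------------------- star

def _to_precursor_offsets(precursor: Precursor, aln: ReadAlignment) -> Optional[tuple[int, int]]:
    if aln.ref_id != precursor.ref_id or aln.strand != precursor.strand:
        return None
    if aln.start < precursor.start or aln.end > precursor.end:
        return None
    if precursor.strand == "+":
        return aln.start - precursor.start, aln.end - precursor.start
    return precursor.end - aln.end, precursor.end - aln.start


def star_present(
    precursor: Precursor,
    duplex: Duplex,
    alignments: Sequence[ReadAlignment],
    slack: int = 2,
) -> int:
    """1 iff at least one alignment lies within the star interval
    (± ``slack`` nt)."""
    for a in alignments:
        off = _to_precursor_offsets(precursor, a)
        if off is None:
            continue
        r0, r1 = off
        if r0 >= duplex.star_start - slack and r1 <= duplex.star_end + slack:
            return 1
    return 0


# ------------------------------------------------------------ signature

def _loop_interval(duplex: Duplex) -> tuple[int, int]:
    if duplex.mature_end <= duplex.star_start:
        return duplex.mature_end, duplex.star_start
    return duplex.star_end, duplex.mature_start


def signature_logliks(
    precursor: Precursor,
    duplex: Duplex,
    alignments: Sequence[ReadAlignment],
    params: ParameterSet,
) -> tuple[float, float]:
    """Count-weighted log-likelihood of the read stack under the real
    model (inconsistent count ~ geometric) and the background model
    (uniform read start positions)."""
    tol = params.signature_tolerance
    loop_lo, loop_hi = _loop_interval(duplex)
    n = k = 0
    for a in alignments:
        off = _to_precursor_offsets(precursor, a)
        if off is None:
            continue
        r0, r1 = off
        consistent = (
            abs(r0 - duplex.mature_start) <= tol
            or abs(r0 - duplex.star_start) <= tol
            or (loop_lo <= r0 and r1 <= loop_hi)
        )
        n += a.count
        k += a.count if consistent else 0
    if n == 0:
        raise ValueError("signature requires at least one alignment on the precursor")
    L = len(precursor.sequence)
    width = 2 * (2 * tol + 1) + max(0, loop_hi - loop_lo)
    u = min(max(width / L, 1e-6), 0.99)
    p = params.signature_geometric_p
    loglik_real = math.log(p) + (n - k) * math.log1p(-p)
    loglik_bgr = k * math.log(u) + (n - k) * math.log1p(-u)
    return loglik_real, loglik_bgr


def signature_logodds(
    precursor: Precursor,
    duplex: Duplex,
    alignments: Sequence[ReadAlignment],
    params: ParameterSet,
) -> float:
    real, bgr = signature_logliks(precursor, duplex, alignments, params)
    return real - bgr


# ------------------------------------------------------------- assembly

def compute_features(
    precursor: Precursor,
    duplex: Duplex,
    alignments: Sequence[ReadAlignment],
    known_matures: Sequence[str],
    params: ParameterSet,
    rng: Optional[np.random.Generator] = None,
    backend="reference",
    skip_stability: bool = False,
) -> FeatureVector:
    """Evaluate all five features for one candidate."""
    nm = normalized_mfe(precursor.fold)
    if skip_stability:
        p_val, rel = 1.0, 0
    else:
        p_val, rel = stability_pvalue(
            precursor.sequence,
            n_shuffles=params.stability_shuffles,
            mode=params.shuffle_mode,
            rng=rng,
            backend=backend,
            threshold=params.stability_pvalue_threshold,
        )
    nuc = nucleus_conserved(
        precursor.mature_sequence,
        known_matures,
        positions=params.nucleus_positions,
        max_mismatches=params.nucleus_mismatches,
    )
    star = star_present(precursor, duplex, alignments, slack=params.signature_tolerance)
    loglik_real, loglik_bgr = signature_logliks(precursor, duplex, alignments, params)
    return FeatureVector(
        precursor_id=precursor.id,
        abs_mfe=abs(precursor.fold.mfe),
        normalized_mfe=nm,
        rel=rel,
        rel_pvalue=p_val,
        nuc=nuc,
        star=star,
        sig_loglik_real=loglik_real,
        sig_loglik_bgr=loglik_bgr,
    )
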