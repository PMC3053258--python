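"""From filtered read alignments to candidate hairpin precursors.

The pipeline stage this module implements: drop reads that fail the
mapping filters or overlap coding/ncRNA annotations, cluster the
survivors per reference and strand, excise genomic windows (up to the
plant excision length, 300 nt by default) around each cluster's
highest-count read, fold each window, and extract the mature:star
duplex with the plant-specific pairing constraints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

from intervaltree import IntervalTree

from .folding import FoldResult, get_backend, pair_table
from .io_formats import AnnotationInterval, GenomeSequence, ReadAlignment, revcomp
from .params import ParameterSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Precursor:
    """An excised candidate hairpin with genomic provenance.

    ``sequence`` is strand-oriented (reverse-complemented for minus-strand
    windows); ``mature_start``/``mature_end`` are offsets within it.
    """

    id: str
    ref_id: str
    start: int
    end: int
    strand: str
    sequence: str
    fold: FoldResult
    mature_start: int
    mature_end: int

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.mature_start:self.mature_end]


@dataclass(frozen=True)
class Duplex:
    """Mature:star pairing statistics read off the precursor's pair table."""

    mature_start: int
    mature_end: int
    star_start: int
    star_end: int
    n_paired: int
    n_unpaired_total: int
    max_consecutive_unpaired: int
    bulge_total: int
    max_consecutive_bulge: int


@dataclass(frozen=True)
class ReadCluster:
    ref_id: str
    strand: str
    start: int
    end: int
    reads: tuple
    mature: ReadAlignment  # highest-count read


# ------------------------------------------------------------ filtering

def filter_reads(
    alignments: Sequence[ReadAlignment],
    annotations: Sequence[AnnotationInterval],
    params: ParameterSet,
) -> List[ReadAlignment]:
    """Keep reads with few mismatches, few genomic hits, and zero overlap
    with any exclusion annotation; input order is preserved."""
    trees: dict[str, IntervalTree] = {}
    for ann in annotations:
        trees.setdefault(ann.ref_id, IntervalTree()).addi(ann.start, ann.end)
    kept = []
    for a in alignments:
        if a.mismatches > params.max_mapping_mismatches:
            continue
        if a.n_hits > params.max_multi_hits:
            continue
        tree = trees.get(a.ref_id)
        if tree is not None and tree.overlap(a.start, a.end):
            continue
        kept.append(a)
    logger.info("filter_reads: %d of %d alignments kept", len(kept), len(alignments))
    return kept


# ------------------------------------------------------------ clustering

def cluster_reads(alignments: Sequence[ReadAlignment], max_gap: int = 30) -> List[ReadCluster]:
    """Single-linkage clustering of alignments overlapping or within
    ``max_gap`` nt, per (reference, strand).  The highest-count read in
    each cluster is the putative mature (ties: leftmost, then read id)."""
    by_key: dict[tuple, list[ReadAlignment]] = {}
    for a in alignments:
        by_key.setdefault((a.ref_id, a.strand), []).append(a)
    clusters: List[ReadCluster] = []
    for (ref, strand), group in sorted(by_key.items()):
        group.sort(key=lambda a: (a.start, a.end, a.read_id))
        current: list[ReadAlignment] = []
        cur_end = None
        for a in group:
            if current and a.start > cur_end + max_gap:
                clusters.append(_finish_cluster(ref, strand, current))
                current = []
                cur_end = None
            current.append(a)
            cur_end = a.end if cur_end is None else max(cur_end, a.end)
        if current:
            clusters.append(_finish_cluster(ref, strand, current))
    return clusters


def _finish_cluster(ref: str, strand: str, reads: list[ReadAlignment]) -> ReadCluster:
    mature = max(reads, key=lambda a: (a.count, -a.start, a.read_id))
    return ReadCluster(
        ref_id=ref,
        strand=strand,
        start=min(a.start for a in reads),
        end=max(a.end for a in reads),
        reads=tuple(reads),
        mature=mature,
    )


# ------------------------------------------------------------- excision

def excise_candidates(
    genome: Sequence[GenomeSequence],
    cluster: ReadCluster,
    params: ParameterSet,
    backend="reference",
) -> List[Precursor]:
    """Excise and fold up to two candidate windows for a cluster.

    One window assumes the mature read sits on the 5' arm (short
    upstream flank, long downstream flank up to the excision cap); the
    other mirrors it for a 3'-arm mature.  Minus-strand windows are
    reverse-complemented before folding.  Windows are clipped at
    chromosome ends.
    """
    folder = get_backend(backend)
    chrom = {g.id: g for g in genome}.get(cluster.ref_id)
    if chrom is None:
        raise ValueError(f"cluster reference {cluster.ref_id!r} not in genome")
    L = params.excision_length_max
    if cluster.end - cluster.start > L:
        logger.warning(
            "cluster %s:%d-%d longer than excision cap %d; skipped",
            cluster.ref_id, cluster.start, cluster.end, L,
        )
        return []
    mat = cluster.mature
    short = params.flank_short
    n = len(chrom.sequence)
    # genomic upstream/downstream depends on strand: for '-', the 5' side
    # of the transcript is the genomic right
    if cluster.strand == "+":
        windows = [
            ("5p", max(0, mat.start - short), min(n, max(0, mat.start - short) + L)),
            ("3p", max(0, min(n, mat.end + short) - L), min(n, mat.end + short)),
        ]
    else:
        windows = [
            ("5p", max(0, min(n, mat.end + short) - L), min(n, mat.end + short)),
            ("3p", max(0, mat.start - short), min(n, max(0, mat.start - short) + L)),
        ]
    out: List[Precursor] = []
    for arm, w_start, w_end in windows:
        if not (w_start <= mat.start and mat.end <= w_end):
            continue  # clipping removed the read itself
        seq = chrom.sequence[w_start:w_end]
        if cluster.strand == "-":
            seq = revcomp(seq)
            m_start = w_end - mat.end
            m_end = w_end - mat.start
        else:
            m_start = mat.start - w_start
            m_end = mat.end - w_start
        fold_res = folder.fold(seq)
        out.append(
            Precursor(
                id=f"{cluster.ref_id}:{w_start}-{w_end}:{cluster.strand}:{arm}",
                ref_id=cluster.ref_id,
                start=w_start,
                end=w_end,
                strand=cluster.strand,
                sequence=seq,
                fold=fold_res,
                mature_start=m_start,
                mature_end=m_end,
            )
        )
    return out


# -------------------------------------------------------------- duplex

def extract_duplex(precursor: Precursor, star_overhang: int = 2) -> Optional[Duplex]:
    """Extract mature:star duplex statistics from the precursor fold.

    Returns None when the mature arm spans the terminal loop (its paired
    positions point in both directions) or pairs with nothing.  The star
    interval is the region pairing the mature, shifted to carry the
    canonical 2-nt 3' overhang on each duplex strand.
    """
    pt = pair_table(precursor.fold.structure)
    m0, m1 = precursor.mature_start, precursor.mature_end
    partners = {i: pt[i] for i in range(m0, m1) if pt[i] is not None}
    if not partners:
        return None
    upstream = [p for p in partners.values() if p < m0]
    downstream = [p for p in partners.values() if p >= m1]
    inside = [p for p in partners.values() if m0 <= p < m1]
    if inside or (upstream and downstream):
        return None  # mature lies across the terminal loop
    star_positions = sorted(partners.values())
    lo, hi = star_positions[0], star_positions[-1] + 1
    n = len(precursor.sequence)
    if downstream:
        # mature on 5' arm: star's 3' end is opposite the mature 5' end
        star_start, star_end = lo + star_overhang, min(n, hi + star_overhang)
    else:
        star_start, star_end = max(0, lo - star_overhang), hi - star_overhang
    if star_start >= star_end:
        return None

    # pairing statistics over the mature arm
    paired_pos = sorted(partners)
    n_paired = len(paired_pos)
    unpaired_flags = [pt[i] is None for i in range(m0, m1)]
    n_unpaired = sum(unpaired_flags)
    max_run = _longest_run(unpaired_flags)

    bulge_total = 0
    max_bulge = 0
    for a, b in zip(paired_pos, paired_pos[1:]):
        gap_m = b - a - 1
        gap_s = abs(partners[a] - partners[b]) - 1
        if gap_m > 0 and gap_s == 0:
            bulge_total += gap_m
            max_bulge = max(max_bulge, gap_m)
        elif gap_s > 0 and gap_m == 0:
            bulge_total += gap_s
            max_bulge = max(max_bulge, gap_s)
        # gaps on both arms form an internal loop: counted via unpaired, not bulge
    return Duplex(
        mature_start=m0,
        mature_end=m1,
        star_start=star_start,
        star_end=star_end,
        n_paired=n_paired,
        n_unpaired_total=n_unpaired,
        max_consecutive_unpaired=max_run,
        bulge_total=bulge_total,
        max_consecutive_bulge=max_bulge,
    )


def _longest_run(flags: Iterable[bool]) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def duplex_passes(duplex: Duplex, params: ParameterSet) -> bool:
    """Plant duplex constraints: enough pairing, limited unpaired bases,
    short unpaired runs, small bulges."""
    return (
        duplex.n_paired >= params.min_paired
        and duplex.n_unpaired_total <= params.max_unpaired_total
        and duplex.max_consecutive_unpaired <= params.max_unpaired_consecutive
        and duplex.bulge_total <= params.max_bulge_total
    )
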