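"""Seeded generator of synthetic inputs for the whole pipeline.

Emulates what the method sees in real data: stem-loop precursors
planted in a toy genome, coding-like background sequence (codon-triplet
sampling, echoing the use of protein-coding regions as the negative
class), Dicer-like read stacks over mature/star/loop, noise reads, a
CDS annotation covering decoy loci, and miRNA families sharing a
conserved 2–12 nucleus.  Identical specs (including the seed) produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import (
    AnnotationInterval,
    GenomeSequence,
    ReadAlignment,
    revcomp,
    write_alignments_tab,
    write_fasta,
)

_NT = np.array(list("ACGT"))

# a compact codon usage table: common plant codons, heavier G/C3 usage
_CODONS = (
    "ATG GCT GCC GAG GAA GAT GAC AAG AAA CTT CTC GTT GTC TCT TCC ACT ACC "
    "GGT GGC GCA CCA CCT CAG CAA CGT AGA ATT ATC TTT TTC TAT TAC CAT CAC "
    "TGG AAT AAC AGT AGC TGA"
).split()


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_hairpins: int = 5
    stem_length: int = 30           # nt per arm
    loop_length: int = 8            # nt
    planted_mismatches: int = 0     # substitutions in the 3' arm
    n_background: int = 100
    background_length_range: Tuple[int, int] = (60, 300)
    genome_length: int = 10000
    reads_per_locus: int = 50       # collapsed count on the mature
    read_noise_fraction: float = 0.0
    n_families: int = 10
    family_size: int = 10
    nucleus_identity: bool = True   # planted matures share a family nucleus
    n_decoys: int = 1               # extra hairpins placed inside a CDS
    mature_length: int = 21

    def __post_init__(self):
        if self.stem_length < 15:
            raise ValueError("stem_length must be >= 15")
        if not (0.0 <= self.read_noise_fraction <= 1.0):
            raise ValueError("read_noise_fraction must be in [0, 1]")
        for name in ("n_hairpins", "n_background", "n_families", "family_size", "n_decoys"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PlantedLocus:
    locus_id: str
    ref_id: str
    start: int
    end: int
    strand: str
    mature_start: int  # genomic
    mature_end: int
    mature_sequence: str
    is_decoy: bool


@dataclass(frozen=True)
class SyntheticDataset:
    spec: SyntheticSpec
    genome: List[GenomeSequence]
    alignments: List[ReadAlignment]
    annotations: List[AnnotationInterval]
    matures: List[GenomeSequence]       # known-mature library (family members)
    background: List[GenomeSequence]    # coding-like background sequences
    truth: List[PlantedLocus]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def coding_like_sequence(rng: np.random.Generator, n: int) -> str:
    """Background sequence assembled from sampled codon triplets."""
    idx = rng.integers(0, len(_CODONS), size=n // 3 + 1)
    return "".join(_CODONS[i] for i in idx)[:n]


def make_hairpin(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    arm: str = "5p",
) -> Tuple[str, Tuple[int, int], Tuple[int, int]]:
    """One planted stem-loop: random 5' arm, loop, reverse-complement 3'
    arm with ``planted_mismatches`` substitutions.

    Returns (sequence, mature interval, star interval) as offsets in the
    hairpin; the mature sits on the requested arm, inset 2 nt from the
    duplex end so the star carries the canonical 2-nt 3' overhang.
    """
    arm5 = _random_seq(rng, spec.stem_length)
    loop = _random_seq(rng, spec.loop_length)
    arm3 = list(revcomp(arm5))
    if spec.planted_mismatches:
        # plant the substitutions as one block opposite the mature; both
        # strands of the block are set to the same self-incompatible base so
        # the disruption cannot be rescued by register-shifted re-pairing
        lo_idx = max(0, spec.stem_length - spec.mature_length - 2)
        hi_idx = spec.stem_length - 3
        k = min(spec.planted_mismatches, hi_idx - lo_idx)
        start_idx = int(rng.integers(lo_idx, hi_idx - k + 1))
        base = "C" if rng.integers(2) == 0 else "A"
        arm5 = list(arm5)
        for p in range(start_idx, start_idx + k):
            arm3[p] = base
            arm5[spec.stem_length - 1 - p] = base
        arm5 = "".join(arm5)
        arm3 = list(revcomp(arm5))
        for p in range(start_idx, start_idx + k):
            arm3[p] = base
    seq = arm5 + loop + "".join(arm3)
    L = spec.stem_length
    m = spec.mature_length
    if arm == "5p":
        mature = (2, 2 + m)
    else:
        mature = (len(seq) - 2 - m, len(seq) - 2)
    # star = positions pairing the mature on the opposite arm, +2-nt 3' overhang
    if arm == "5p":
        star_hi = len(seq) - mature[0]
        star = (star_hi - m + 2, star_hi + 2)
    else:
        star_lo = len(seq) - mature[1]
        star = (star_lo - 2, star_lo - 2 + m)
    return seq, mature, star


def make_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the full input bundle for an end-to-end run."""
    rng = np.random.default_rng(spec.seed)
    n_loci = spec.n_hairpins + spec.n_decoys
    hp_len = 2 * spec.stem_length + spec.loop_length
    slot = hp_len + 200  # spacing between planted loci
    if n_loci * slot + 400 > spec.genome_length:
        raise ValueError("genome too short to host all planted loci without overlap")

    genome_chars = list(coding_like_sequence(rng, spec.genome_length))
    ref_id = "chr_syn"
    truth: List[PlantedLocus] = []
    alignments: List[ReadAlignment] = []
    annotations: List[AnnotationInterval] = []
    matures_lib: List[GenomeSequence] = []

    positions = [200 + i * slot for i in range(n_loci)]

    def add_reads(locus_id, g_m_start, g_m_end, g_star_start, g_star_end, strand, mature_seq, star_seq, loop_iv):
        alignments.append(ReadAlignment(
            read_id=f"{locus_id}_mature_x{spec.reads_per_locus}",
            read_sequence=mature_seq if strand == "+" else revcomp(mature_seq),
            count=spec.reads_per_locus,
            ref_id=ref_id, start=g_m_start, end=g_m_end, strand=strand,
            mismatches=0, n_hits=1,
        ))
        # 5'-end heterogeneity: a minority read jittered by 1 nt
        alignments.append(ReadAlignment(
            read_id=f"{locus_id}_jitter_x2",
            read_sequence="".join(genome_chars[g_m_start + 1:g_m_end + 1]),
            count=2,
            ref_id=ref_id, start=g_m_start + 1, end=g_m_end + 1, strand=strand,
            mismatches=0, n_hits=1,
        ))
        star_count = max(1, spec.reads_per_locus // 10)
        alignments.append(ReadAlignment(
            read_id=f"{locus_id}_star_x{star_count}",
            read_sequence=star_seq if strand == "+" else revcomp(star_seq),
            count=star_count,
            ref_id=ref_id, start=g_star_start, end=g_star_end, strand=strand,
            mismatches=0, n_hits=1,
        ))
        lo, hi = loop_iv
        if hi - lo >= 15:
            alignments.append(ReadAlignment(
                read_id=f"{locus_id}_loop_x1",
                read_sequence="".join(genome_chars[lo:hi]),
                count=1,
                ref_id=ref_id, start=lo, end=hi, strand=strand,
                mismatches=0, n_hits=1,
            ))

    for i in range(n_loci):
        is_decoy = i >= spec.n_hairpins
        arm = "5p" if i % 2 == 0 else "3p"
        strand = "+" if i % 3 != 2 else "-"
        hp_seq, (m0, m1), (s0, s1) = make_hairpin(spec, rng, arm=arm)
        start = positions[i]
        end = start + len(hp_seq)
        planted = hp_seq if strand == "+" else revcomp(hp_seq)
        genome_chars[start:end] = list(planted)
        if strand == "+":
            g_m, g_s = (start + m0, start + m1), (start + s0, start + s1)
        else:
            g_m, g_s = (end - m1, end - m0), (end - s1, end - s0)
        mature_seq = hp_seq[m0:m1]
        star_seq = hp_seq[s0:s1]
        loop_lo, loop_hi = (min(m1, s1), max(m0, s0))
        if strand == "+":
            g_loop = (start + loop_lo, start + loop_hi)
        else:
            g_loop = (end - loop_hi, end - loop_lo)
        locus_id = ("decoy" if is_decoy else "locus") + f"{i}"
        add_reads(locus_id, *g_m, *g_s, strand, mature_seq, star_seq, g_loop)
        truth.append(PlantedLocus(
            locus_id=locus_id, ref_id=ref_id, start=start, end=end, strand=strand,
            mature_start=g_m[0], mature_end=g_m[1],
            mature_sequence=mature_seq, is_decoy=is_decoy,
        ))
        if is_decoy:
            annotations.append(AnnotationInterval(ref_id, start - 50, end + 50, "CDS"))

    # known-mature library: families sharing a 2-12 nucleus
    for f in range(spec.n_families):
        if spec.nucleus_identity and f < spec.n_hairpins:
            seed_mature = truth[f].mature_sequence
        else:
            seed_mature = _random_seq(rng, spec.mature_length)
        nucleus = seed_mature[1:12]
        for m in range(spec.family_size):
            member = (
                _random_seq(rng, 1)
                + nucleus
                + _random_seq(rng, spec.mature_length - 12)
            )
            matures_lib.append(GenomeSequence(f"fam{f}_m{m}", member))

    # uniform noise reads
    n_noise = int(round(spec.read_noise_fraction * len(alignments)))
    for j in range(n_noise):
        pos = int(rng.integers(0, spec.genome_length - 25))
        alignments.append(ReadAlignment(
            read_id=f"noise{j}_x1",
            read_sequence="".join(genome_chars[pos:pos + 21]),
            count=1, ref_id=ref_id, start=pos, end=pos + 21,
            strand="+" if rng.integers(2) == 0 else "-",
            mismatches=0, n_hits=1,
        ))

    background = [
        GenomeSequence(
            f"bgr{i}",
            coding_like_sequence(
                rng, int(rng.integers(spec.background_length_range[0], spec.background_length_range[1] + 1))
            ),
        )
        for i in range(spec.n_background)
    ]

    genome = [GenomeSequence(ref_id, "".join(genome_chars))]
    return SyntheticDataset(spec, genome, alignments, annotations, matures_lib, background, truth)


def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """Write the dataset as plain-text files (FASTA / tab alignments /
    BED / truth TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.genome, out / "genome.fa")
    write_fasta(dataset.matures, out / "matures.fa")
    write_fasta(dataset.background, out / "background.fa")
    write_alignments_tab(dataset.alignments, out / "alignments.tab")
    with open(out / "exclude.bed", "w") as fh:
        for ann in dataset.annotations:
            fh.write(f"{ann.ref_id}\t{ann.start}\t{ann.end}\t{ann.kind}\n")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("locus_id\tref_id\tstart\tend\tstrand\tmature_start\tmature_end\tmature_sequence\tis_decoy\n")
        for t in dataset.truth:
            fh.write(
                f"{t.locus_id}\t{t.ref_id}\t{t.start}\t{t.end}\t{t.strand}\t"
                f"{t.mature_start}\t{t.mature_end}\t{t.mature_sequence}\t{int(t.is_decoy)}\n"
            )
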