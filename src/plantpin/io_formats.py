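"""Readers and writers for the external formats the pipeline consumes.

Genomes arrive as FASTA, read alignments as SAM or a simple
tab-separated dialect, exclusion annotations as BED or GFF3, known
matures as FASTA, folded precursors as Vienna-style dot-bracket
records, and trained constants as parameter JSON.

Coordinates are 0-based half-open everywhere inside the package;
1-based external conventions (SAM POS, GFF3) are converted at this
boundary.  The internal nucleotide alphabet is DNA: U is normalized
to T on input, and the folding backend converts back to RNA space on
its own boundary.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam
from Bio import SeqIO

from .params import ParameterSet, parameter_set_from_dict

_VALID_NT = set("ACGTN")
_COUNT_SUFFIX = re.compile(r"_x(\d+)$")


class FormatError(ValueError):
    """Malformed input file content."""


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase and map U→T; reject characters outside {A,C,G,T,U,N}."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_NT
    if bad:
        raise FormatError(f"{context}: invalid nucleotide characters {sorted(bad)}")
    return s


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadAlignment:
    """One mapped (collapsed) small-RNA read.

    ``count`` is the collapsed-read multiplicity (parsed from an
    ``_xN`` read-id suffix when present), ``n_hits`` the number of
    genomic loci the read maps to.
    """

    read_id: str
    read_sequence: str
    count: int
    ref_id: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str
    mismatches: int = 0
    n_hits: int = 1

    def __post_init__(self):
        if self.end <= self.start:
            raise FormatError(f"{self.read_id}: end must exceed start")
        if self.count < 1 or self.n_hits < 1:
            raise FormatError(f"{self.read_id}: count and n_hits must be >= 1")
        if self.strand not in "+-":
            raise FormatError(f"{self.read_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class AnnotationInterval:
    ref_id: str
    start: int
    end: int
    kind: str = "CDS"  # {CDS, rRNA, tRNA, other_ncRNA}

    def __post_init__(self):
        if self.end <= self.start:
            raise FormatError(f"annotation on {self.ref_id}: end must exceed start")


@dataclass(frozen=True)
class DotBracketRecord:
    id: str
    sequence: str
    structure: str
    mfe: Optional[float]


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> list[GenomeSequence]:
    """Read a FASTA file into normalized (DNA-alphabet) records."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"FASTA record {rec.id!r}: empty sequence")
        records.append(GenomeSequence(rec.id, normalize_sequence(seq, context=f"record {rec.id!r}")))
    return records


def write_fasta(records: Iterable[GenomeSequence], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ----------------------------------------------------------- alignments

def _parse_count(read_id: str) -> int:
    m = _COUNT_SUFFIX.search(read_id)
    return int(m.group(1)) if m else 1


def _read_sam(path) -> list[ReadAlignment]:
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            # SAM stores reverse-strand reads genome-forward already; keep that orientation
            seq = aln.query_sequence or ""
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            nh = aln.get_tag("NH") if aln.has_tag("NH") else 0
            out.append(
                ReadAlignment(
                    read_id=aln.query_name,
                    read_sequence=normalize_sequence(seq, context=aln.query_name),
                    count=_parse_count(aln.query_name),
                    ref_id=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    mismatches=int(nm),
                    n_hits=int(nh) if nh else 1,
                )
            )
    return out


TAB_COLUMNS = ("read_id", "read_sequence", "count", "ref_id", "start", "strand", "mismatches", "n_hits")


def _read_tab(path) -> list[ReadAlignment]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(TAB_COLUMNS):
                raise FormatError(f"tab alignment line {ln}: expected {len(TAB_COLUMNS)} columns, got {len(parts)}")
            rid, seq, count, ref, start, strand, mm, nh = parts
            seq = normalize_sequence(seq, context=rid)
            start_i = int(start)
            out.append(
                ReadAlignment(
                    read_id=rid,
                    read_sequence=seq,
                    count=int(count),
                    ref_id=ref,
                    start=start_i,
                    end=start_i + len(seq),
                    strand=strand,
                    mismatches=int(mm),
                    n_hits=int(nh),
                )
            )
    return out


def read_alignments(path, dialect: str = "sam", genome: Optional[Sequence[GenomeSequence]] = None) -> list[ReadAlignment]:
    """Read alignments from SAM or the tab dialect.

    n_hits falls back to counting identical read_ids when no NH-style
    metadata is present.  When ``genome`` is given, coordinates are
    validated against reference lengths.
    """
    if dialect == "sam":
        alignments = _read_sam(path)
    elif dialect == "tab":
        alignments = _read_tab(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    # derive n_hits by grouping identical read ids when metadata understates it
    id_counts: dict[str, int] = {}
    for a in alignments:
        id_counts[a.read_id] = id_counts.get(a.read_id, 0) + 1
    alignments = [
        a if a.n_hits >= id_counts[a.read_id]
        else ReadAlignment(a.read_id, a.read_sequence, a.count, a.ref_id, a.start, a.end,
                           a.strand, a.mismatches, id_counts[a.read_id])
        for a in alignments
    ]

    if genome is not None:
        lengths = {g.id: len(g.sequence) for g in genome}
        for a in alignments:
            if a.ref_id in lengths and a.end > lengths[a.ref_id]:
                raise FormatError(f"{a.read_id}: alignment end {a.end} exceeds length of {a.ref_id}")
    return alignments


def write_alignments_tab(alignments: Iterable[ReadAlignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(TAB_COLUMNS) + "\n")
        for a in alignments:
            fh.write("\t".join(map(str, (a.read_id, a.read_sequence, a.count, a.ref_id,
                                         a.start, a.strand, a.mismatches, a.n_hits))) + "\n")


# ---------------------------------------------------------- annotations

_GFF_KINDS = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}


def read_annotations(path, fmt: Optional[str] = None) -> list[AnnotationInterval]:
    """Read exclusion intervals from BED (0-based half-open) or GFF3 (1-based inclusive)."""
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if fmt == "bed":
                if len(parts) < 3:
                    raise FormatError(f"BED line {ln}: fewer than 3 columns")
                kind = parts[3] if len(parts) > 3 else "CDS"
                out.append(AnnotationInterval(parts[0], int(parts[1]), int(parts[2]), kind))
            else:
                if len(parts) < 5:
                    raise FormatError(f"GFF3 line {ln}: fewer than 5 columns")
                kind = _GFF_KINDS.get(parts[2], "other_ncRNA" if parts[2] != "CDS" else "CDS")
                out.append(AnnotationInterval(parts[0], int(parts[3]) - 1, int(parts[4]), kind))
    return out


# ---------------------------------------------------------- dot-bracket

_ENERGY_RE = re.compile(r"^([().]+)(?:\s*\(\s*(-?\d+(?:\.\d+)?)\s*\))?\s*$")


def _check_balanced(structure: str, context: str) -> None:
    depth = 0
    for ch in structure:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"{context}: unbalanced brackets")
    if depth != 0:
        raise FormatError(f"{context}: unbalanced brackets")


def read_dotbracket(path) -> list[DotBracketRecord]:
    """Read Vienna-style records: header / sequence / structure [( energy)]."""
    out = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise FormatError(f"dot-bracket record at line {i + 1}: expected '>' header")
        rid = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise FormatError(f"record {rid!r}: truncated")
        seq = normalize_sequence(lines[i + 1], context=rid)
        m = _ENERGY_RE.match(lines[i + 2].strip())
        if not m:
            raise FormatError(f"record {rid!r}: cannot parse structure line")
        structure, energy = m.group(1), m.group(2)
        _check_balanced(structure, f"record {rid!r}")
        if len(structure) != len(seq):
            raise FormatError(f"record {rid!r}: structure length {len(structure)} != sequence length {len(seq)}")
        out.append(DotBracketRecord(rid, seq, structure, float(energy) if energy is not None else None))
        i += 3
    return out


def write_dotbracket(records: Iterable[DotBracketRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n{rec.structure}")
            if rec.mfe is not None:
                fh.write(f" ({rec.mfe:.2f})")
            fh.write("\n")


# ------------------------------------------------------- parameter JSON

def read_parameter_set(path) -> ParameterSet:
    """Read a parameter JSON; missing keys fall back to the clade preset (monocot default)."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise FormatError("parameter file must contain a JSON object")
    return parameter_set_from_dict(data)


def write_parameter_set(params: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
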