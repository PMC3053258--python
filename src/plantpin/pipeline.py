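"""End-to-end candidate discovery: filter → cluster → excise → features → score."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from . import __version__
from .excision import (
    Duplex,
    Precursor,
    cluster_reads,
    duplex_passes,
    excise_candidates,
    extract_duplex,
    filter_reads,
)
from .features import FeatureVector, compute_features
from .folding import has_bifurcation
from .io_formats import AnnotationInterval, GenomeSequence, ReadAlignment
from .params import ParameterSet
from .scoring import ReportRow, ScoredCandidate, rank_and_threshold, score_candidate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateResult:
    precursor: Precursor
    duplex: Duplex
    features: FeatureVector
    scored: ScoredCandidate
    passes_threshold: bool


@dataclass(frozen=True)
class RunResult:
    params: ParameterSet
    seed: int
    candidates: List[CandidateResult]

    def to_rows(self) -> List[dict]:
        rows = []
        for c in self.candidates:
            rows.append(dict(
                id=c.precursor.id,
                ref_id=c.precursor.ref_id,
                start=c.precursor.start,
                end=c.precursor.end,
                strand=c.precursor.strand,
                length=len(c.precursor.sequence),
                mature=c.precursor.mature_sequence,
                mfe=round(c.precursor.fold.mfe, 3),
                normalized_mfe=round(c.features.normalized_mfe, 4),
                rel=c.features.rel,
                rel_pvalue=round(c.features.rel_pvalue, 4),
                nuc=c.features.nuc,
                star=c.features.star,
                component_mfe=round(c.scored.component_mfe, 4),
                component_rel=round(c.scored.component_rel, 4),
                component_nuc=round(c.scored.component_nuc, 4),
                component_star=round(c.scored.component_star, 4),
                component_sig=round(c.scored.component_sig, 4),
                total_score=round(c.scored.total_score, 4),
                passes=int(c.passes_threshold),
            ))
        return rows


def run_all(
    genome: Sequence[GenomeSequence],
    alignments: Sequence[ReadAlignment],
    annotations: Sequence[AnnotationInterval],
    known_matures: Sequence[str],
    params: Optional[ParameterSet] = None,
    seed: int = 0,
    threshold: float = 0.0,
    backend="reference",
    skip_stability: bool = False,
) -> RunResult:
    """Run the full discovery pipeline on in-memory inputs.

    Deterministic for a fixed seed; per-cluster the better-scoring of the
    two excision windows is reported.
    """
    params = params if params is not None else ParameterSet()
    rng = np.random.default_rng(seed)
    filtered = filter_reads(alignments, annotations, params)
    clusters = cluster_reads(filtered, max_gap=params.cluster_max_gap)
    logger.info("run_all: %d read clusters", len(clusters))

    results: List[CandidateResult] = []
    for cluster in clusters:
        window_results: List[CandidateResult] = []
        for precursor in excise_candidates(genome, cluster, params, backend=backend):
            if params.bifurcation_filter and has_bifurcation(precursor.fold.structure):
                continue
            duplex = extract_duplex(precursor, star_overhang=params.star_overhang)
            if duplex is None or not duplex_passes(duplex, params):
                continue
            feats = compute_features(
                precursor, duplex, filtered, known_matures, params,
                rng=rng, backend=backend, skip_stability=skip_stability,
            )
            scored = score_candidate(feats, params)
            window_results.append(CandidateResult(
                precursor, duplex, feats, scored, scored.total_score >= threshold,
            ))
        if window_results:
            best = max(window_results, key=lambda c: (c.scored.total_score, c.precursor.id))
            results.append(best)

    order = {row.candidate.precursor_id: i for i, row in enumerate(
        rank_and_threshold([c.scored for c in results], threshold)
    )}
    results.sort(key=lambda c: order[c.scored.precursor_id])
    logger.info("run_all: %d candidates scored", len(results))
    return RunResult(params=params, seed=seed, candidates=results)


def write_results_tsv(result: RunResult, path) -> None:
    rows = result.to_rows()
    header = [
        "id", "ref_id", "start", "end", "strand", "length", "mature", "mfe",
        "normalized_mfe", "rel", "rel_pvalue", "nuc", "star",
        "component_mfe", "component_rel", "component_nuc", "component_star",
        "component_sig", "total_score", "passes",
    ]
    with open(path, "w") as fh:
        fh.write(f"# plantpin {__version__} params={result.params.digest()} seed={result.seed}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[h]) for h in header) + "\n")
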