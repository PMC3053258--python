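"""Bayesian log-odds scoring of candidate precursors.

The total score is the natural-log posterior odds of a candidate being
a real precursor versus background, factorized over the five features:

    score = ln[P(data|pre) P(pre) / (P(data|bgr) P(bgr))]
          = component_mfe + component_rel + component_nuc
            + component_star + component_sig + component_prior

The MFE component uses the plant-fitted modified sigmoid
``f(x) = a / (b + e^{c x})`` of the length-normalized MFE; the discrete
features contribute fixed log-odds (ln of real/background frequency
ratios); an alternative Gumbel-CDF MFE path reproduces the original
animal model for comparison runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional

from .features import FeatureVector
from .params import ParameterSet


@dataclass(frozen=True)
class ScoredCandidate:
    precursor_id: str
    component_mfe: float
    component_rel: float
    component_nuc: float
    component_star: float
    component_sig: float
    component_prior: float

    @property
    def total_score(self) -> float:
        return (
            self.component_mfe
            + self.component_rel
            + self.component_nuc
            + self.component_star
            + self.component_sig
            + self.component_prior
        )


def sigmoid_logodds(normalized_mfe: float, a: float, b: float, c: float) -> float:
    """Modified sigmoid f(x) = a / (b + e^{c x}); strictly decreasing in x
    for a, c > 0, bounded above by a/b.  Overflow in the exponent yields
    the asymptote."""
    if b <= 0:
        raise ValueError("sigmoid_logodds requires b > 0")
    z = c * normalized_mfe
    if z > 700.0:
        return 0.0
    return a / (b + math.exp(z))


def gumbel_cdf(x: float, location: float, scale: float) -> float:
    """Minimum-Gumbel form F(x) = exp(-exp((x - location)/scale)):
    1 as x -> -inf, 0 as x -> +inf."""
    if scale <= 0:
        raise ValueError("gumbel_cdf requires scale > 0")
    z = (x - location) / scale
    if z > 700.0:
        return 0.0
    return math.exp(-math.exp(z))


def discrete_logodds(p_real: float, p_bgr: float) -> float:
    """Natural log of a real/background frequency ratio."""
    if not (0.0 < p_real <= 1.0) or not (0.0 < p_bgr <= 1.0):
        raise ValueError(
            "frequencies must be in (0, 1]; substitute a pseudo-count for empty cells"
        )
    return math.log(p_real / p_bgr)


def _mfe_component(features: FeatureVector, params: ParameterSet) -> float:
    if params.mfe_mode == "sigmoid":
        return sigmoid_logodds(
            features.normalized_mfe, params.sigmoid_a, params.sigmoid_b, params.sigmoid_c
        )
    # comparison mode: the original animal model's Gumbel CDFs of |MFE|.
    # The tail probability F(|mfe|) under the known-precursor CDF versus the
    # background CDF is converted to log-odds at the observed |MFE|.
    # ln F(x) = -exp((x - loc)/scale), so the ratio is computed in log
    # space and stays finite deep in either tail
    x = features.abs_mfe
    z_real = min((x - params.gumbel_location) / params.gumbel_scale, 700.0)
    z_bgr = min((x - params.gumbel_location_bgr) / params.gumbel_scale_bgr, 700.0)
    return math.exp(z_bgr) - math.exp(z_real)


def score_candidate(features: FeatureVector, params: ParameterSet) -> ScoredCandidate:
    """Combine a feature vector into per-feature log-odds components."""
    return ScoredCandidate(
        precursor_id=features.precursor_id,
        component_mfe=_mfe_component(features, params),
        component_rel=params.logodds_stable if features.rel else params.logodds_unstable,
        component_nuc=(
            params.logodds_nucleus_conserved
            if features.nuc
            else params.logodds_nucleus_nonconserved
        ),
        component_star=(
            params.logodds_star_present if features.star else params.logodds_star_absent
        ),
        component_sig=features.sig_logodds,
        component_prior=params.log_prior_ratio,
    )


@dataclass(frozen=True)
class ReportRow:
    candidate: ScoredCandidate
    passes: bool


def rank_and_threshold(
    scored: Iterable[ScoredCandidate], threshold: float = 0.0
) -> List[ReportRow]:
    """Sort descending by total score (ties by id); rows below the
    threshold are flagged, not dropped."""
    ordered = sorted(scored, key=lambda s: (-s.total_score, s.precursor_id))
    return [ReportRow(s, s.total_score >= threshold) for s in ordered]
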