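"""Trained scoring parameters and pipeline knobs.

A :class:`ParameterSet` bundles everything the scorer and the excision
filters need: the fitted sigmoid constants for the MFE log-odds, the
Gumbel constants of the original animal model (kept for comparison
runs), the discrete log-odds for stability / nucleus conservation /
star presence, the duplex pairing constraints, and the read-filtering
thresholds.  Three presets ship: ``monocot`` (the default),
``dicot``, and ``animal_original``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from typing import Tuple


class ParameterError(ValueError):
    """Raised when a parameter set fails validation; lists offending keys."""

    def __init__(self, problems: dict[str, str]):
        self.problems = dict(problems)
        msg = "; ".join(f"{k}: {v}" for k, v in sorted(problems.items()))
        super().__init__(f"invalid parameter set — {msg}")


@dataclass
class ParameterSet:
    """All tunable constants of the scoring model and candidate filters.

    The sigmoid constants parameterize the MFE log-odds
    ``f(x) = a / (b + exp(c * x))`` where ``x`` is the length-normalized
    minimum free energy in kcal/mol/nt.  The Gumbel location/scale pairs
    describe the original animal-model CDF ``exp(-exp((x - loc)/scale))``
    for known and background precursors and are only used when
    ``mfe_mode == "gumbel"``.
    """

    clade: str = "monocot"
    mfe_mode: str = "sigmoid"  # {"sigmoid", "gumbel"}

    # MFE sigmoid log-odds, f(x) = a / (b + e^{c x})
    sigmoid_a: float = 1.339e-12
    sigmoid_b: float = 2.778e-13
    sigmoid_c: float = 45.843

    # original animal Gumbel CDFs (known and background), comparison mode
    gumbel_location: float = 32.0
    gumbel_scale: float = 5.5
    gumbel_location_bgr: float = 23.0
    gumbel_scale_bgr: float = 4.8

    # discrete feature log-odds (natural log)
    logodds_stable: float = 1.37
    logodds_unstable: float = -3.624
    logodds_nucleus_conserved: float = 7.63
    logodds_nucleus_nonconserved: float = -1.17
    logodds_star_present: float = 1.386
    logodds_star_absent: float = -1.386

    signature_geometric_p: float = 0.7
    signature_tolerance: int = 2
    log_prior_ratio: float = 0.0

    # excision and duplex constraints
    excision_length_max: int = 300
    flank_short: int = 20
    cluster_max_gap: int = 30
    min_paired: int = 15
    max_unpaired_total: int = 5
    max_unpaired_consecutive: int = 3
    max_bulge_total: int = 2
    star_overhang: int = 2

    # read filtering
    max_multi_hits: int = 20
    max_mapping_mismatches: int = 1

    # stability (shuffling) test
    stability_pvalue_threshold: float = 0.05
    stability_shuffles: int = 999
    shuffle_mode: str = "mono"  # {"mono", "di"}

    # nucleus conservation
    nucleus_positions: Tuple[int, int] = (2, 12)  # 1-based inclusive on the mature
    nucleus_mismatches: int = 0

    bifurcation_filter: bool = False

    def __post_init__(self) -> None:
        self.nucleus_positions = tuple(self.nucleus_positions)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        problems: dict[str, str] = {}
        if self.sigmoid_b <= 0:
            problems["sigmoid_b"] = "must be > 0"
        if self.mfe_mode not in ("sigmoid", "gumbel"):
            problems["mfe_mode"] = "must be 'sigmoid' or 'gumbel'"
        if self.gumbel_scale is not None and self.gumbel_scale <= 0:
            problems["gumbel_scale"] = "must be > 0"
        if self.gumbel_scale_bgr is not None and self.gumbel_scale_bgr <= 0:
            problems["gumbel_scale_bgr"] = "must be > 0"
        if not (0.0 < self.signature_geometric_p < 1.0):
            problems["signature_geometric_p"] = "must be in (0, 1)"
        if not (0.0 < self.stability_pvalue_threshold < 1.0):
            problems["stability_pvalue_threshold"] = "must be in (0, 1)"
        if self.stability_shuffles < 1:
            problems["stability_shuffles"] = "must be >= 1"
        if self.shuffle_mode not in ("mono", "di"):
            problems["shuffle_mode"] = "must be 'mono' or 'di'"
        lo, hi = self.nucleus_positions
        if not (1 <= lo <= hi <= 23):
            problems["nucleus_positions"] = "range must lie within [1, 23]"
        for key in ("excision_length_max", "max_multi_hits"):
            if getattr(self, key) < 1:
                problems[key] = "must be >= 1"
        for key in (
            "min_paired",
            "max_unpaired_total",
            "max_unpaired_consecutive",
            "max_bulge_total",
            "max_mapping_mismatches",
            "flank_short",
            "cluster_max_gap",
            "star_overhang",
            "signature_tolerance",
            "nucleus_mismatches",
        ):
            if getattr(self, key) < 0:
                problems[key] = "must be >= 0"
        if problems:
            raise ParameterError(problems)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nucleus_positions"] = list(self.nucleus_positions)
        return d

    def digest(self) -> str:
        """Short stable hash of the full parameter set, for provenance headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


_DICOT_OVERRIDES = dict(
    clade="dicot",
    sigmoid_a=4.46e-4,
    sigmoid_b=9.125e-5,
    sigmoid_c=26.929,
    logodds_stable=0.63,
    logodds_unstable=-3.17,
)

# Original animal model: Gumbel CDF MFE scoring, shorter nucleus, laxer duplex.
_ANIMAL_OVERRIDES = dict(
    clade="animal_original",
    mfe_mode="gumbel",
    logodds_stable=1.6,
    logodds_unstable=-2.2,
    logodds_nucleus_conserved=3.0,
    logodds_nucleus_nonconserved=-0.6,
    excision_length_max=140,
    min_paired=14,
    max_unpaired_total=8,
    max_unpaired_consecutive=8,
    max_bulge_total=5,
    max_multi_hits=5,
    nucleus_positions=(2, 8),
)

_PRESETS = {
    "monocot": {},
    "dicot": _DICOT_OVERRIDES,
    "animal_original": _ANIMAL_OVERRIDES,
}


def preset(clade: str = "monocot") -> ParameterSet:
    """Return the shipped parameter set for a clade.

    ``monocot`` and ``dicot`` carry the plant-estimated constants;
    ``animal_original`` carries the inherited animal model for
    comparison runs.
    """
    try:
        overrides = _PRESETS[clade]
    except KeyError:
        raise ParameterError({"clade": f"unknown clade {clade!r}; choose from {sorted(_PRESETS)}"})
    return ParameterSet(**overrides)


_FIELDS = {f for f in ParameterSet.__dataclass_fields__}


def parameter_set_from_dict(data: dict) -> ParameterSet:
    """Build a ParameterSet from a (possibly partial) JSON-style dict.

    Missing keys are filled from the preset named by ``clade``
    (monocot when absent); unknown keys raise :class:`ParameterError`.
    """
    unknown = set(data) - _FIELDS
    if unknown:
        raise ParameterError({k: "unknown key" for k in unknown})
    clade = data.get("clade", "monocot")
    base = preset(clade).to_dict()
    base.update(data)
    if "nucleus_positions" in base:
        base["nucleus_positions"] = tuple(base["nucleus_positions"])
    return ParameterSet(**base)
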