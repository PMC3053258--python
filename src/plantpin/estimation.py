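"""Re-estimation of the scoring constants from training precursor sets.

Given real and background precursor collections this module derives
everything the scorer consumes: the minimum-Gumbel fit of the MFE
distribution, the binned MFE log-odds curve and its modified-sigmoid
fit, the discrete stability/conservation frequencies (with pseudo-count
substitution for empty cells), the positional conservation profile of
mature families, the 10-fold cross-validated nucleus conservation
frequency, the coverage-based excision-length choice, two-sample KS
comparisons, and the |MFE|-versus-length regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scoring import discrete_logodds


# ----------------------------------------------------------- Gumbel fit

@dataclass(frozen=True)
class GumbelFit:
    location: float
    scale: float
    cdf_error: float  # sum of |fitted CDF - empirical CDF| at the sample points

    def cdf(self, x):
        return stats.gumbel_l.cdf(x, loc=self.location, scale=self.scale)


def empirical_cdf_error(samples: Sequence[float], cdf: Callable) -> float:
    """Sum of absolute deviations between a candidate CDF and the
    empirical CDF (midpoint convention) at the sorted sample points."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    ecdf = (np.arange(1, n + 1) - 0.5) / n
    return float(np.abs(np.asarray(cdf(x)) - ecdf).sum())


def fit_gumbel_min(samples: Sequence[float]) -> GumbelFit:
    """Maximum-likelihood fit of the minimum-Gumbel (Gumbel-left) family.

    The fitted survival function ``exp(-exp((x - location)/scale))`` is
    the form the original animal model tabulates.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 30:
        raise ValueError("fit_gumbel_min requires at least 30 samples")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) samples")
    loc, scale = stats.gumbel_l.fit(x)
    fit = GumbelFit(float(loc), float(scale), 0.0)
    err = empirical_cdf_error(x, fit.cdf)
    return GumbelFit(fit.location, fit.scale, err)


# ------------------------------------------------------ binned log-odds

@dataclass(frozen=True)
class BinnedLogOdds:
    """Per-bin ln(freq_real / freq_bgr) on a shared normalized-MFE grid.

    Log-odds are NaN where either class has an empty bin.
    """

    bin_left_edges: np.ndarray
    bin_width: float
    counts_real: np.ndarray
    counts_bgr: np.ndarray
    logodds: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return self.bin_left_edges + self.bin_width / 2.0

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.logodds)


def binned_logodds(
    real_mfe_normalized: Sequence[float],
    bgr_mfe_normalized: Sequence[float],
    bin_width: float = 0.01,
) -> BinnedLogOdds:
    real = np.asarray(real_mfe_normalized, dtype=float)
    bgr = np.asarray(bgr_mfe_normalized, dtype=float)
    if real.size == 0 or bgr.size == 0:
        raise ValueError("both samples must be non-empty")
    lo = min(real.min(), bgr.min())
    hi = max(real.max(), bgr.max())
    first = np.floor(lo / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((hi - first) / bin_width + 1e-9)))
    edges = first + bin_width * np.arange(n_bins + 1)
    c_real, _ = np.histogram(real, bins=edges)
    c_bgr, _ = np.histogram(bgr, bins=edges)
    f_real = c_real / real.size
    f_bgr = c_bgr / bgr.size
    with np.errstate(divide="ignore", invalid="ignore"):
        lo_arr = np.where((c_real > 0) & (c_bgr > 0), np.log(f_real / f_bgr), np.nan)
    return BinnedLogOdds(edges[:-1], bin_width, c_real, c_bgr, lo_arr)


# ----------------------------------------------------------- sigmoid fit

@dataclass(frozen=True)
class SigmoidFit:
    a: float
    b: float
    c: float
    rss: float

    def __call__(self, x):
        return self.a / (self.b + np.exp(self.c * np.asarray(x, dtype=float)))


_C_STARTS = (5.0, 15.0, 30.0, 45.0, 60.0)


def fit_sigmoid_xy(x: Sequence[float], y: Sequence[float]) -> SigmoidFit:
    """Nonlinear least squares of f(x) = a/(b + e^{c x}).

    Multi-start over a fixed grid of c values; for each start, (a, b)
    are initialized by linearizing 1/y = b/a + e^{c x}/a on the positive
    observations, then all three parameters are refined jointly in log
    space (a, b > 0).  The best residual sum of squares wins.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("fit_sigmoid requires at least 5 defined bins")

    def residuals(theta):
        a, b = np.exp(theta[0]), np.exp(theta[1])
        c = theta[2]
        z = np.clip(c * x, -700, 700)
        return a / (b + np.exp(z)) - y

    best: Optional[SigmoidFit] = None
    pos = y > 0
    for c0 in _C_STARTS:
        starts = []
        if pos.sum() >= 2:
            ex = np.exp(np.clip(c0 * x[pos], -700, 700))
            A = np.vstack([np.ones_like(ex), ex]).T
            coef, *_ = np.linalg.lstsq(A, 1.0 / y[pos], rcond=None)
            intercept, slope = coef
            if slope > 0 and intercept > 0:
                a0 = 1.0 / slope
                b0 = intercept * a0
                starts.append((a0, b0))
        starts.append((max(y.max(), 1e-3), 1.0))  # fallback start
        for a0, b0 in starts:
            try:
                sol = optimize.least_squares(
                    residuals, x0=[np.log(a0), np.log(b0), c0], method="lm", max_nfev=5000
                )
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            fit = SigmoidFit(float(np.exp(sol.x[0])), float(np.exp(sol.x[1])), float(sol.x[2]), rss)
            if best is None or rss < best.rss:
                best = fit
    if best is None:
        raise RuntimeError("sigmoid fit failed to converge from any start")
    return best


def fit_sigmoid(binned: BinnedLogOdds) -> SigmoidFit:
    mask = binned.defined
    if mask.sum() < 5:
        raise ValueError("fit_sigmoid requires at least 5 defined bins")
    return fit_sigmoid_xy(binned.centers[mask], binned.logodds[mask])


# ------------------------------------------------- discrete frequencies

def estimate_discrete_frequencies(
    real_flags: Sequence[int],
    bgr_flags: Sequence[int],
    pseudo_count: float = 1.0 / 3000.0,
) -> Tuple[float, float, Tuple[float, float]]:
    """Frequencies of a binary feature in real and background sets, with
    pseudo-count substitution for empty cells.

    Returns ``(p_real, p_bgr, (logodds_present, logodds_absent))``.
    """
    real = np.asarray(real_flags, dtype=float)
    bgr = np.asarray(bgr_flags, dtype=float)
    if (real.size == 0 or bgr.size == 0) and pseudo_count <= 0:
        raise ValueError("empty flag sets require a positive pseudo-count")

    def clipped_freq(flags: np.ndarray) -> float:
        f = float(flags.mean()) if flags.size else 0.0
        return min(max(f, pseudo_count), 1.0 - pseudo_count)

    p_real = clipped_freq(real)
    p_bgr = clipped_freq(bgr)
    pair = (
        discrete_logodds(p_real, p_bgr),
        discrete_logodds(1.0 - p_real, 1.0 - p_bgr),
    )
    return p_real, p_bgr, pair


# -------------------------------------------------- conservation profile

@dataclass(frozen=True)
class ConservationProfile:
    """Across-family positional conservation of aligned mature sets."""

    n_families: int
    counts: np.ndarray  # per alignment position: number of families conserved there
    family_fractions: Dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def blocks(self, threshold: float = 0.75) -> List[Tuple[int, int]]:
        """Contiguous 1-based inclusive position runs conserved in at
        least ``threshold`` of families."""
        ok = self.counts / self.n_families >= threshold
        out: List[Tuple[int, int]] = []
        start = None
        for i, flag in enumerate(ok):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                out.append((start + 1, i))
                start = None
        if start is not None:
            out.append((start + 1, len(ok)))
        return out


_GAP_CHARS = set("-.")


def conservation_profile(
    families: Dict[str, Sequence[str]],
    within_threshold: float = 0.9,
) -> ConservationProfile:
    """Per-position conservation counted over families.

    Within a family a position is conserved iff the modal (non-gap)
    residue reaches ``within_threshold`` of members; gaps always count
    as mismatches.  Families with fewer than two members are excluded.
    """
    usable: Dict[str, List[str]] = {}
    for name in sorted(families):
        members = [s.upper().replace("U", "T") for s in families[name]]
        if len(members) < 2:
            continue
        if len({len(s) for s in members}) != 1:
            raise ValueError(f"family {name!r}: members must be aligned to equal length")
        usable[name] = members
    if not usable:
        raise ValueError("no family with >= 2 members")
    max_len = max(len(m[0]) for m in usable.values())
    counts = np.zeros(max_len, dtype=int)
    fractions: Dict[str, np.ndarray] = {}
    for name, members in usable.items():
        L = len(members[0])
        frac = np.zeros(L)
        for pos in range(L):
            col = [s[pos] for s in members]
            tallies = {}
            for ch in col:
                if ch not in _GAP_CHARS:
                    tallies[ch] = tallies.get(ch, 0) + 1
            frac[pos] = max(tallies.values(), default=0) / len(members)
        fractions[name] = frac
        counts[:L] += (frac >= within_threshold).astype(int)
    return ConservationProfile(len(usable), counts, fractions)


# ----------------------------------------------- nucleus CV frequency

def nucleus_frequency_cv(
    matures: Sequence[str],
    positions: Tuple[int, int] = (2, 12),
    folds: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """10-fold cross-validated frequency of nucleus conservation.

    The matures are shuffled once and partitioned into ``folds`` disjoint
    test folds; per fold, the fraction of test matures whose nucleus
    window matches any training mature's window is recorded, and the
    fold mean is returned.
    """
    if len(matures) < folds:
        raise ValueError(f"need at least {folds} matures")
    rng = rng if rng is not None else np.random.default_rng()
    lo, hi = positions

    def window(seq: str) -> Optional[str]:
        s = seq.upper().replace("U", "T")
        return s[lo - 1:hi] if len(s) >= hi else None

    order = rng.permutation(len(matures))
    fold_indices = np.array_split(order, folds)
    freqs = []
    for test_idx in fold_indices:
        test_set = set(test_idx.tolist())
        train_windows = {
            w for i, m in enumerate(matures) if i not in test_set and (w := window(m)) is not None
        }
        hits = total = 0
        for i in test_idx:
            w = window(matures[i])
            if w is None:
                continue
            total += 1
            hits += int(w in train_windows)
        freqs.append(hits / total if total else 0.0)
    return float(np.mean(freqs))


# --------------------------------------------------- excision length

def select_excision_length(
    precursor_lengths: Sequence[int],
    coverage: float,
    min_tail_sample: int = 30,
    window: int = 30,
) -> int:
    """Smallest observed length covering ``coverage`` of precursors while
    keeping at least ``min_tail_sample`` precursors within ± ``window``
    nt of the chosen length (so the constants near that length remain
    estimable)."""
    lengths = np.sort(np.asarray(precursor_lengths, dtype=int))
    if lengths.size == 0:
        raise ValueError("no precursor lengths supplied")
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must be in (0, 1]")
    n = lengths.size
    best_feasible = None
    for L in np.unique(lengths):
        ecdf = np.searchsorted(lengths, L, side="right") / n
        tail = int(((lengths >= L - window) & (lengths <= L + window)).sum())
        if tail >= min_tail_sample:
            best_feasible = max(best_feasible or 0.0, ecdf)
            if ecdf >= coverage:
                return int(L)
    raise ValueError(
        f"coverage {coverage} unattainable with tail constraint; best feasible "
        f"coverage is {best_feasible if best_feasible is not None else 0.0:.3f}"
    )


# ------------------------------------------------------------- KS test

def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov statistic and asymptotic p-value.

    D is the exact sup of |ECDF_x - ECDF_y| over the pooled sample
    points; p uses the asymptotic Kolmogorov distribution.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size < 5 or y.size < 5:
        raise ValueError("both samples must have at least 5 observations")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    n_eff = x.size * y.size / (x.size + y.size)
    p = float(stats.kstwobign.sf(np.sqrt(n_eff) * d))
    return d, min(max(p, 0.0), 1.0)


# -------------------------------------------- |MFE| vs length regression

@dataclass(frozen=True)
class MfeLengthRegression:
    slope: float
    intercept: float
    table: pd.DataFrame  # per bin: mean_length, mean_abs_mfe, sd_abs_mfe, n


def mfe_length_regression(
    lengths: Sequence[float],
    abs_mfe: Sequence[float],
    bin_plan: Optional[Sequence[Tuple[float, float]]] = None,
) -> MfeLengthRegression:
    """Group |MFE| into length bins and regress the per-bin mean |MFE|
    on the per-bin mean length (least squares)."""
    lengths = np.asarray(lengths, dtype=float)
    mfe = np.asarray(abs_mfe, dtype=float)
    if bin_plan is None:
        qs = np.quantile(lengths, np.linspace(0, 1, 7))
        qs[-1] += 1e-9
        bin_plan = list(zip(qs[:-1], qs[1:]))
    rows = []
    for lo, hi in bin_plan:
        mask = (lengths >= lo) & (lengths < hi)
        if not mask.any():
            continue
        rows.append(
            dict(
                bin_lo=lo,
                bin_hi=hi,
                n=int(mask.sum()),
                mean_length=float(lengths[mask].mean()),
                mean_abs_mfe=float(mfe[mask].mean()),
                sd_abs_mfe=float(mfe[mask].std(ddof=0)),
            )
        )
    if len(rows) < 2:
        raise ValueError("need at least 2 populated length bins")
    table = pd.DataFrame(rows)
    slope, intercept = np.polyfit(table["mean_length"], table["mean_abs_mfe"], 1)
    return MfeLengthRegression(float(slope), float(intercept), table)


# ------------------------------------------------- family pre-alignment

def align_family(sequences: Sequence[str]) -> List[str]:
    """Light-weight center-star alignment (match/mismatch/gap = +1/-1/-2).

    A convenience for unaligned family input; deliberately simple, not a
    progressive multiple aligner.  Pre-aligned input (equal lengths) is
    returned unchanged.
    """
    seqs = [s.upper().replace("U", "T") for s in sequences]
    if len({len(s) for s in seqs}) == 1:
        return list(seqs)
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    center_idx = max(range(len(seqs)), key=lambda i: (len(seqs[i]), -i))
    center = seqs[center_idx]
    master = list(center)  # center with accumulated gaps
    aligned: Dict[int, List[str]] = {center_idx: list(center)}
    for i, seq in enumerate(seqs):
        if i == center_idx:
            continue
        aln = aligner.align(center, seq)[0]
        a_center, a_seq = str(aln[0]), str(aln[1])
        # merge the pairwise gap pattern into the master alignment
        merged_master, merged_rows = [], {k: [] for k in aligned}
        new_row = []
        mi = pi = 0
        while mi < len(master) or pi < len(a_center):
            m_ch = master[mi] if mi < len(master) else None
            p_ch = a_center[pi] if pi < len(a_center) else None
            if m_ch == "-" and p_ch != "-":
                merged_master.append("-")
                for k in merged_rows:
                    merged_rows[k].append(aligned[k][mi])
                new_row.append("-")
                mi += 1
            elif p_ch == "-" and m_ch != "-":
                merged_master.append("-")
                for k in merged_rows:
                    merged_rows[k].append("-")
                new_row.append(a_seq[pi])
                pi += 1
            else:
                merged_master.append(m_ch if m_ch is not None else "-")
                for k in merged_rows:
                    merged_rows[k].append(aligned[k][mi] if mi < len(master) else "-")
                new_row.append(a_seq[pi] if pi < len(a_center) else "-")
                mi += 1
                pi += 1
        master = merged_master
        aligned = {k: merged_rows[k] for k in merged_rows}
        aligned[i] = new_row
    width = len(master)
    out = []
    for i in range(len(seqs)):
        row = aligned[i]
        out.append("".join(row) + "-" * (width - len(row)))
    return out
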