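"""The binomial window statistic for conversion detection.

Given a triplet profile of L informative sites, a candidate window of N
sites containing M target–parentB matches is scored by the binomial tail
Pr(X >= M) with X ~ Binomial(N, p), where p is the proportion of matches
among the L−N sites *outside* the window (excluding the examined region
keeps a real conversion tract from inflating the background). Two
multiple-window correction factors are applied to the tail: L/N (the
number of non-overlapping windows of size N) and L−N (the number of
sliding windows, an upper bound since sliding windows are not
independent). Both corrected values are reported.

Window width is variable: from each start site, the window whose
corrected P is smallest is kept. Across-sequence multiple testing is
handled separately by a Bonferroni correction over the number of
comparisons k (see :func:`count_comparisons`), never by the window terms.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import binom

from .informative import TripletProfile

__all__ = [
    "CorrectionMode",
    "ScanConfig",
    "WindowStat",
    "ConversionSegment",
    "binomial_tail",
    "background_p",
    "window_pvalue",
    "window_table",
    "scan_profile",
    "apply_bonferroni",
    "bonferroni_threshold",
    "count_comparisons",
]


class CorrectionMode(str, enum.Enum):
    """Which multiple-window correction factor(s) drive the scan."""

    L_OVER_N = "L_over_N"
    L_MINUS_N = "L_minus_N"
    BOTH = "both"


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of one scan.

    alpha
        Significance level for the uncorrected window P-values (and, after
        Bonferroni, for the corrected ones).
    min_window
        Smallest window width in informative sites. One- and two-site
        windows are dominated by the background clamping rule and give
        unstable P-values, hence the default of 3.
    correction_mode
        Which correction factor(s) to compute and select on. When both are
        active the conservative L−N value is the selection key.
    require_both
        With ``correction_mode=BOTH``, demand that *both* corrected
        P-values clear alpha for a segment to count (the conservative
        reading); otherwise either suffices.
    max_reported
        Optional cap on segments reported per profile.
    max_window_frac
        A window may cover at most this fraction of the informative
        sites (default 0.5): a conversion tract is a minority segment of
        the gene, and the out-of-window background must be estimated
        from at least as much data as the window scores. Without this
        bound near-total windows leave so few outside sites that the
        background estimate collapses and the scan fires everywhere.
    require_window_majority
        Admit only windows where the target matches the putative donor
        at a majority of sites (M/N > 1/2, default True): a donor tract
        must locally favor the donor, not merely enrich a sparse
        background.
    whole_profile_p
        Compute the background proportion from the entire profile,
        window included — the original fixed-background variant, kept for
        head-to-head evaluation. Default False (out-of-window background).
    """

    alpha: float = 0.05
    min_window: int = 3
    correction_mode: CorrectionMode = CorrectionMode.BOTH
    require_both: bool = True
    max_reported: int | None = None
    max_window_frac: float = 0.5
    require_window_majority: bool = True
    whole_profile_p: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.min_window < 1:
            raise ValueError(f"min_window must be >= 1, got {self.min_window}")
        if not 0.0 < self.max_window_frac <= 1.0:
            raise ValueError(
                f"max_window_frac must be in (0,1], got {self.max_window_frac}"
            )

    def passes(self, p_lover_n: float, p_lminus_n: float) -> bool:
        """Does a (possibly corrected) P-value pair clear alpha?"""
        if self.correction_mode is CorrectionMode.BOTH:
            if self.require_both:
                return p_lover_n < self.alpha and p_lminus_n < self.alpha
            return p_lover_n < self.alpha or p_lminus_n < self.alpha
        if self.correction_mode is CorrectionMode.L_MINUS_N:
            return p_lminus_n < self.alpha
        return p_lover_n < self.alpha

    def selection_key(self, p_lover_n, p_lminus_n):
        """The P-value minimised during window growth and segment ranking."""
        if self.correction_mode is CorrectionMode.L_OVER_N:
            return p_lover_n
        return p_lminus_n


@dataclass(frozen=True)
class WindowStat:
    """One window's statistic. Indices are informative-site, half-open."""

    start_idx: int
    end_idx: int
    N: int
    M: int
    p: float
    binom_tail: float
    P_LoverN: float
    P_LminusN: float


@dataclass(frozen=True)
class ConversionSegment:
    """A reported conversion tract.

    ``aln_start``/``aln_end`` are 1-based inclusive alignment columns of
    the first/last informative site in the window. ``k`` is the number of
    comparisons used for the Bonferroni correction; corrected values are
    ``min(1, k * P)``.
    """

    target_id: str
    donor_label: str
    aln_start: int
    aln_end: int
    stat: WindowStat
    k: int
    P_LoverN_corrected: float
    P_LminusN_corrected: float
    significant: bool


def binomial_tail(n: int, m: int, p: float) -> float:
    """Pr(X >= m) for X ~ Binomial(n, p); exactly 1.0 when m == 0."""
    if not 0 <= m <= n:
        raise ValueError(f"require 0 <= M <= N, got M={m}, N={n}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"require 0 < p < 1, got p={p}")
    return float(binom.sf(m - 1, n, p))


def _clamp_p(matches: int, total: int) -> float:
    """Background proportion with half-count clamping off the 0/1 boundary."""
    if matches == 0:
        return 0.5 / total
    if matches == total:
        return 1.0 - 0.5 / total
    return matches / total


def background_p(profile: TripletProfile, start_idx: int, end_idx: int) -> float:
    """Match proportion among the sites outside ``[start_idx, end_idx)``.

    Requires at least one site outside the window. A boundary proportion
    (0 or 1) is clamped by half a count to keep the binomial tail
    non-degenerate.
    """
    L = profile.L
    if not 0 <= start_idx < end_idx <= L:
        raise ValueError(f"invalid window [{start_idx}, {end_idx}) for L={L}")
    n_out = L - (end_idx - start_idx)
    if n_out < 1:
        raise ValueError("window must leave at least one site outside")
    m_out = int(profile.matches_b.sum() - profile.matches_b[start_idx:end_idx].sum())
    return _clamp_p(m_out, n_out)


def _whole_profile_p(profile: TripletProfile) -> float:
    return _clamp_p(int(profile.matches_b.sum()), profile.L)


def window_pvalue(
    profile: TripletProfile,
    start_idx: int,
    end_idx: int,
    whole_profile_p: bool = False,
) -> WindowStat:
    """Full statistic for one window of *profile*."""
    L = profile.L
    N = end_idx - start_idx
    if N >= L:
        raise ValueError("window must be a proper subset of the profile")
    M = int(profile.matches_b[start_idx:end_idx].sum())
    p = (
        _whole_profile_p(profile)
        if whole_profile_p
        else background_p(profile, start_idx, end_idx)
    )
    tail = binomial_tail(N, M, p)
    return WindowStat(
        start_idx=start_idx,
        end_idx=end_idx,
        N=N,
        M=M,
        p=p,
        binom_tail=tail,
        P_LoverN=min(1.0, (L / N) * tail),
        P_LminusN=min(1.0, (L - N) * tail),
    )


def _empty_table() -> tuple[np.ndarray, ...]:
    empty = np.empty(0)
    ie = np.empty(0, dtype=np.intp)
    return ie, ie, ie, ie, empty, empty


def window_table(
    matches_b: np.ndarray,
    min_window: int,
    whole_profile_p: bool = False,
    max_window_frac: float = 0.5,
    require_window_majority: bool = True,
) -> tuple[np.ndarray, ...]:
    """Vectorised statistics for every admissible window of a profile.

    Admissible windows are half-open ``[s, e)`` with
    ``min_window <= e - s <= floor(L * max_window_frac)`` and, when
    ``require_window_majority``, a majority of matches inside. Returns
    arrays ``(s, e, N, M, p, tail)`` ordered by start then end (within
    one start, N ascends). Internal workhorse of :func:`scan_profile`
    and of the simulation harness.
    """
    L = int(matches_b.size)
    max_n = min(L - 1, int(L * max_window_frac))
    if L < min_window + 1 or max_n < min_window:
        return _empty_table()
    s, e = np.triu_indices(L + 1, k=min_window)
    keep = (e - s) <= max_n
    s, e = s[keep], e[keep]
    cs = np.concatenate(([0], np.cumsum(matches_b, dtype=np.int64)))
    M = cs[e] - cs[s]
    N = e - s
    if require_window_majority:
        keep = 2 * M > N
        s, e, M, N = s[keep], e[keep], M[keep], N[keep]
        if s.size == 0:
            return _empty_table()
    if whole_profile_p:
        p = np.full(s.size, _clamp_p(int(cs[L]), L))
    else:
        n_out = L - N
        m_out = cs[L] - M
        p = m_out / n_out
        half = 0.5 / n_out
        p = np.where(m_out == 0, half, p)
        p = np.where(m_out == n_out, 1.0 - half, p)
    tail = binom.sf(M - 1, N, p)
    return s, e, N, M, p, tail


def scan_profile(
    profile: TripletProfile,
    config: ScanConfig | None = None,
    donor_label: str | None = None,
) -> list[ConversionSegment]:
    """Scan one triplet profile for candidate conversion segments.

    From every start site the window minimising the selection P-value is
    kept (ties: smaller width, then smaller start); per-start winners whose
    uncorrected P-values clear ``config.alpha`` become candidates; finally
    non-overlapping candidates are selected greedily in ascending P order.
    Profiles shorter than ``min_window + 1`` sites yield an empty list.

    The returned segments carry ``k = 1``; drivers rescale with
    :func:`apply_bonferroni`.
    """
    config = config or ScanConfig()
    donor = donor_label if donor_label is not None else profile.parent_b_id
    L = profile.L
    if L < config.min_window + 1:
        return []
    s, e, N, M, p, tail = window_table(
        profile.matches_b,
        config.min_window,
        config.whole_profile_p,
        config.max_window_frac,
        config.require_window_majority,
    )
    if s.size == 0:
        return []
    P1 = np.minimum(1.0, (L / N) * tail)
    P2 = np.minimum(1.0, (L - N) * tail)
    key = np.asarray(config.selection_key(P1, P2))

    # per-start best window; first occurrence within a block = smallest N
    _, offsets = np.unique(s, return_index=True)
    block = np.repeat(
        np.arange(offsets.size), np.diff(np.append(offsets, s.size))
    )
    best_val = np.minimum.reduceat(key, offsets)
    pos = np.arange(key.size)
    first_hit = np.where(key == best_val[block], pos, key.size)
    best_idx = np.minimum.reduceat(first_hit, offsets)

    candidates = [
        int(i) for i in best_idx if config.passes(float(P1[i]), float(P2[i]))
    ]
    # ascending P, ties to narrower then earlier windows
    candidates.sort(key=lambda i: (float(key[i]), int(N[i]), int(s[i])))

    segments: list[ConversionSegment] = []
    taken: list[tuple[int, int]] = []
    for i in candidates:
        si, ei = int(s[i]), int(e[i])
        if any(si < te and ts < ei for ts, te in taken):
            continue
        taken.append((si, ei))
        stat = WindowStat(
            start_idx=si,
            end_idx=ei,
            N=int(N[i]),
            M=int(M[i]),
            p=float(p[i]),
            binom_tail=float(tail[i]),
            P_LoverN=float(P1[i]),
            P_LminusN=float(P2[i]),
        )
        segments.append(
            ConversionSegment(
                target_id=profile.target_id,
                donor_label=donor,
                aln_start=int(profile.columns[si]) + 1,
                aln_end=int(profile.columns[ei - 1]) + 1,
                stat=stat,
                k=1,
                P_LoverN_corrected=stat.P_LoverN,
                P_LminusN_corrected=stat.P_LminusN,
                significant=config.passes(stat.P_LoverN, stat.P_LminusN),
            )
        )
        if config.max_reported is not None and len(segments) >= config.max_reported:
            break
    return segments


def apply_bonferroni(
    segment: ConversionSegment, k: int, config: ScanConfig
) -> ConversionSegment:
    """Rescale a segment's corrected P-values for *k* comparisons."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    p1 = min(1.0, k * segment.stat.P_LoverN)
    p2 = min(1.0, k * segment.stat.P_LminusN)
    return replace(
        segment,
        k=k,
        P_LoverN_corrected=p1,
        P_LminusN_corrected=p2,
        significant=config.passes(p1, p2),
    )


def bonferroni_threshold(k: int, alpha: float = 0.05) -> float:
    """Per-comparison significance level alpha/k for k comparisons."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    return alpha / k


def count_comparisons(n1: int, n2: int, mode: str) -> int:
    """Number of comparisons k performed by each program mode.

    consensus
        Each of the n1+n2 sequences is tested once against the two group
        consensuses.
    pairs
        All sequence pairs among n1+n2 (the pairwise-program reference
        point).
    triplets_onepop
        All C(n, 3) triplets within a single group.
    triplets_twopop
        All (examined, within-group parent, other-group parent) triplets:
        n1(n1-1)n2 + n2(n2-1)n1.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("sequence counts must be >= 0")
    n = n1 + n2
    if mode == "consensus":
        return n
    if mode == "pairs":
        return math.comb(n, 2)
    if mode == "triplets_onepop":
        return math.comb(n, 3)
    if mode == "triplets_twopop":
        return n1 * (n1 - 1) * n2 + n2 * (n2 - 1) * n1
    raise ValueError(f"unknown comparison mode {mode!r}")
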