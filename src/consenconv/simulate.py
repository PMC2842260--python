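"""Three-taxon sequence simulation and detection-performance evaluation.

The simulator draws a root sequence with equal base frequencies and
evolves it along a three-taxon tree (two close taxa sharing a recent
internal node, one distant taxon) under the Kimura two-parameter model.
Branch lengths are in expected substitutions per site; the
transition/transversion *ratio* R (default 2, the Seq-Gen convention)
maps to the rate ratio kappa = 2R under equal base frequencies.

A conversion event replaces the first ``segment_length`` columns of one
close taxon with the distant taxon's columns and then re-evolves the
tract for ``residual_branch`` substitutions/site, so recent events leave
a near-identical tract and ancient events a partly decayed one.

``evaluate_fpr`` and ``evaluate_power`` scan each simulated triplet with
the directed core comparison the consensus method makes: the examined
taxon (``close1``, the conversion recipient in power runs) against its
close relative as within-group parent and the distant taxon as putative
donor. Per-statistic-variant detection rates are tallied. Variants:

- ``rdp_original``      — background p over the whole profile, L/N term;
- ``improved_LoverN``   — out-of-window p, L/N term;
- ``improved_LminusN``  — out-of-window p, L−N term.

Per-iteration RNG streams are derived from one master seed by counter, so
runs differing only in statistic or planted tract see identical base
alignments (paired comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .alignment_io import Alignment
from .convstat import CorrectionMode, ScanConfig, scan_profile, window_table
from .informative import TripletProfile

__all__ = [
    "ConversionSpec",
    "SimConfig",
    "SimResult",
    "VARIANTS",
    "simulate_triplet",
    "plant_conversion",
    "evaluate_fpr",
    "evaluate_power",
    "simulate_two_groups",
]

TAXA = ("close1", "close2", "distant")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

VARIANTS = ("rdp_original", "improved_LoverN", "improved_LminusN")

#: ScanConfig overrides realising each statistic variant.
_VARIANT_CONFIG = {
    "rdp_original": dict(
        correction_mode=CorrectionMode.L_OVER_N, whole_profile_p=True
    ),
    "improved_LoverN": dict(
        correction_mode=CorrectionMode.L_OVER_N, whole_profile_p=False
    ),
    "improved_LminusN": dict(
        correction_mode=CorrectionMode.L_MINUS_N, whole_profile_p=False
    ),
}


@dataclass(frozen=True)
class ConversionSpec:
    """A planted conversion tract at the start of the recipient sequence.

    ``timing`` sets the default residual divergence of the tract after
    transfer (recent: 0.01, ancient: 0.05 substitutions/site); an explicit
    ``residual_branch`` overrides it.
    """

    segment_length: int = 60
    timing: str = "recent"
    residual_branch: float | None = None

    def __post_init__(self) -> None:
        if self.timing not in ("recent", "ancient"):
            raise ValueError(f"timing must be recent|ancient, got {self.timing!r}")
        if self.segment_length < 1:
            raise ValueError("segment_length must be >= 1")

    @property
    def residual(self) -> float:
        if self.residual_branch is not None:
            return self.residual_branch
        return 0.01 if self.timing == "recent" else 0.05


@dataclass(frozen=True)
class SimConfig:
    """One simulation condition.

    Defaults are the study conditions: 1500-nt sequences, equal base
    frequencies, ts/tv ratio 2, 1000 iterations; close-taxa branches and
    the distant branch are set per experiment.
    """

    seq_length: int = 1500
    tstv_ratio: float = 2.0
    b_close1: float = 0.01
    b_close2: float = 0.01
    b_distant: float = 0.1
    conversion: ConversionSpec | None = None
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.b_close1, self.b_close2, self.b_distant) < 0:
            raise ValueError("branch lengths must be >= 0")
        if self.seq_length < 1 or self.iterations < 1:
            raise ValueError("seq_length and iterations must be >= 1")
        if self.tstv_ratio <= 0:
            raise ValueError("tstv_ratio must be > 0")
        if (
            self.conversion is not None
            and self.conversion.segment_length >= self.seq_length
        ):
            raise ValueError("conversion tract must be shorter than the sequence")


@dataclass(frozen=True)
class SimResult:
    """Per-variant detection rates for one simulation condition."""

    config: SimConfig
    scan: ScanConfig
    iterations: int
    fpr: dict[str, float]
    power: dict[str, float]


def k2p_transition_matrix(d: float, tstv_ratio: float = 2.0) -> np.ndarray:
    """K2P substitution probabilities after *d* expected subs/site.

    Base order A, C, G, T; transitions are A<->G and C<->T. Rates are
    normalised so one unit of branch length is one expected substitution
    per site; kappa = 2 * tstv_ratio under equal base frequencies.
    """
    kappa = 2.0 * tstv_ratio
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e_tv = np.exp(-4.0 * beta * d)
    e_ts = np.exp(-2.0 * (alpha + beta) * d)
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_tv = 0.25 - 0.25 * e_tv
    p_same = 1.0 - p_ts - 2.0 * p_tv
    P = np.full((4, 4), p_tv)
    for i in range(4):
        P[i, i] = p_same
        P[i, (i + 2) % 4] = p_ts  # transition partner
    return P


def expected_k2p_difference(d: float, tstv_ratio: float = 2.0) -> float:
    """Expected proportion of differing sites at K2P distance *d*."""
    P = k2p_transition_matrix(d, tstv_ratio)
    return float(1.0 - P[0, 0])


def _evolve(codes: np.ndarray, d: float, tstv_ratio: float, rng) -> np.ndarray:
    """Evolve base codes (0..3) along a branch of length *d*."""
    if d == 0.0:
        return codes.copy()
    cum = k2p_transition_matrix(d, tstv_ratio).cumsum(axis=1)
    u = rng.random(codes.size)
    return (u[:, None] > cum[codes]).sum(axis=1).astype(np.int8)


def _simulate_codes(config: SimConfig, rng) -> np.ndarray:
    """Simulate the triplet as a (3, seq_length) array of base codes."""
    root = rng.integers(0, 4, size=config.seq_length, dtype=np.int8)
    return np.stack(
        [
            _evolve(root, config.b_close1, config.tstv_ratio, rng),
            _evolve(root, config.b_close2, config.tstv_ratio, rng),
            _evolve(root, config.b_distant, config.tstv_ratio, rng),
        ]
    )


def _plant_codes(codes: np.ndarray, config: SimConfig, rng) -> np.ndarray:
    """Overwrite the tract in close1 with the distant taxon's segment."""
    spec = config.conversion
    if spec is None:
        raise ValueError("config has no conversion spec")
    out = codes.copy()
    tract = codes[2, : spec.segment_length]
    out[0, : spec.segment_length] = _evolve(
        tract, spec.residual, config.tstv_ratio, rng
    )
    return out


def _codes_to_alignment(codes: np.ndarray) -> Alignment:
    return Alignment(
        [
            (name, _BASES[row].tobytes().decode("ascii"))
            for name, row in zip(TAXA, codes)
        ]
    )


def simulate_triplet(config: SimConfig, rng=None) -> Alignment:
    """Simulate one three-taxon alignment (no conversion planted).

    Deterministic for a given ``config.seed`` when *rng* is omitted.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _codes_to_alignment(_simulate_codes(config, rng))


def plant_conversion(aln: Alignment, config: SimConfig, rng=None) -> Alignment:
    """Plant the configured conversion tract into taxon ``close1``."""
    if config.conversion is None:
        raise ValueError("config has no conversion spec")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    lookup = np.zeros(256, dtype=np.int8)
    for i, c in enumerate(b"ACGT"):
        lookup[c] = i
    codes = np.stack(
        [
            lookup[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            for _, seq in aln
        ]
    )
    return _codes_to_alignment(_plant_codes(codes, config, rng))


def _iter_rng(config: SimConfig, iteration: int):
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(iteration)])
    )


def _directed_profile(codes: np.ndarray) -> TripletProfile:
    """The core comparison: close1 examined, close2 = within-group parent,
    distant = putative donor."""
    tt, aa, bb = codes[0], codes[1], codes[2]
    informative = (aa != bb) & ((tt == aa) | (tt == bb))
    columns = np.flatnonzero(informative)
    return TripletProfile(
        target_id=TAXA[0],
        parent_a_id=TAXA[1],
        parent_b_id=TAXA[2],
        columns=columns,
        matches_b=tt[columns] == bb[columns],
    )


def _min_pvalues(
    b: np.ndarray, scan: ScanConfig, variants: Sequence[str]
) -> dict[str, float]:
    """Smallest corrected window P per variant over the admissible windows
    of one profile (equivalent to: does a scan report any candidate)."""
    out = {v: 1.0 for v in variants}
    L = b.size
    if L < scan.min_window + 1 or not b.any():
        return out
    if any(v.startswith("improved") for v in variants):
        _, _, N, M, _, tail = window_table(
            b,
            scan.min_window,
            False,
            scan.max_window_frac,
            scan.require_window_majority,
        )
        if N.size:
            if "improved_LoverN" in out:
                out["improved_LoverN"] = float(
                    np.minimum(1.0, (L / N) * tail).min()
                )
            if "improved_LminusN" in out:
                out["improved_LminusN"] = float(
                    np.minimum(1.0, (L - N) * tail).min()
                )
    if "rdp_original" in out:
        _, _, N, M, _, tail = window_table(
            b,
            scan.min_window,
            True,
            scan.max_window_frac,
            scan.require_window_majority,
        )
        if N.size:
            out["rdp_original"] = float(np.minimum(1.0, (L / N) * tail).min())
    return out


def evaluate_fpr(
    config: SimConfig,
    scan: ScanConfig | None = None,
    variants: Sequence[str] = VARIANTS,
) -> SimResult:
    """False-positive rate under the no-conversion null.

    Per iteration a triplet is simulated and the directed comparison is
    scanned (k = 1, window-level alpha); any admissible window whose
    corrected P falls below ``scan.alpha`` for a variant marks that
    iteration a false positive for it.
    """
    if config.conversion is not None:
        raise ValueError("evaluate_fpr requires a config without conversion")
    scan = scan or ScanConfig()
    hits = {v: 0 for v in variants}
    for it in range(config.iterations):
        rng = _iter_rng(config, it)
        codes = _simulate_codes(config, rng)
        profile = _directed_profile(codes)
        mins = _min_pvalues(profile.matches_b, scan, variants)
        for v in variants:
            hits[v] += mins[v] < scan.alpha
    fpr = {v: hits[v] / config.iterations for v in variants}
    return SimResult(
        config=config, scan=scan, iterations=config.iterations, fpr=fpr, power={}
    )


def _variant_scan(scan: ScanConfig, variant: str) -> ScanConfig:
    return replace(scan, require_both=False, **_VARIANT_CONFIG[variant])


def evaluate_power(
    config: SimConfig,
    scan: ScanConfig | None = None,
    variants: Sequence[str] = ("improved_LminusN",),
) -> SimResult:
    """Power and residual false-positive rate with a planted tract.

    A detected segment lying entirely inside the planted tract counts
    toward power; any segment extending outside it counts as a false
    positive. Both rates are per-iteration indicator averages.
    """
    if config.conversion is None:
        raise ValueError("evaluate_power requires a conversion spec")
    scan = scan or ScanConfig()
    configs = {v: _variant_scan(scan, v) for v in variants}
    tract_end = config.conversion.segment_length  # 1-based inclusive column
    power_hits = {v: 0 for v in variants}
    fp_hits = {v: 0 for v in variants}
    for it in range(config.iterations):
        rng = _iter_rng(config, it)
        codes = _plant_codes(_simulate_codes(config, rng), config, rng)
        profile = _directed_profile(codes)
        for v in variants:
            inside = outside = False
            for seg in scan_profile(profile, configs[v]):
                if seg.aln_end <= tract_end:
                    inside = True
                else:
                    outside = True
            power_hits[v] += inside
            fp_hits[v] += outside
    n = config.iterations
    return SimResult(
        config=config,
        scan=scan,
        iterations=n,
        fpr={v: fp_hits[v] / n for v in variants},
        power={v: power_hits[v] / n for v in variants},
    )


def simulate_two_groups(
    n1: int = 10,
    n2: int = 10,
    length: int = 1200,
    between_divergence: float = 0.3,
    within_noise: float = 0.005,
    tract: tuple[int, int] | None = (300, 360),
    converted_index: int = 0,
    seed: int = 0,
) -> tuple[Alignment, Alignment]:
    """Synthetic two-group alignment pair with an optional planted tract.

    Group ancestors differ at a ``between_divergence`` fraction of
    columns; each sequence carries independent substitutions at rate
    ``within_noise`` (within-group identity ~= 1 - 2*within_noise).
    ``tract=(start, end)`` (0-based half-open columns) replaces that span
    of group-1 sequence ``converted_index`` with the group-2 ancestor —
    a conversion event from the other group's typical state.
    """
    rng = np.random.default_rng(seed)
    anc1 = rng.integers(0, 4, size=length, dtype=np.int8)
    anc2 = anc1.copy()
    diff = rng.random(length) < between_divergence
    anc2[diff] = (anc2[diff] + rng.integers(1, 4, size=int(diff.sum()))) % 4

    def _descend(anc: np.ndarray, n: int, prefix: str) -> list[tuple[str, str]]:
        recs = []
        for i in range(n):
            seq = anc.copy()
            mut = rng.random(length) < within_noise
            seq[mut] = (seq[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
            recs.append((f"{prefix}{i}", _BASES[seq].tobytes().decode("ascii")))
        return recs

    recs1 = _descend(anc1, n1, "g1_s")
    recs2 = _descend(anc2, n2, "g2_s")
    if tract is not None:
        start, end = tract
        donor = _BASES[anc2[start:end]].tobytes().decode("ascii")
        rid, seq = recs1[converted_index]
        recs1[converted_index] = (rid, seq[:start] + donor + seq[end:])
    return Alignment(recs1), Alignment(recs2)
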