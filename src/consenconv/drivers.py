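"""The five program modes and the report layer.

- ``run_mtcpconv``  — two groups, each sequence vs the two group consensuses
  (linear in sequence count; the feature mode).
- ``run_twopop``    — two groups, every (examined, own-group parent,
  other-group parent) triplet.
- ``run_onepop``    — one group, every sequence triplet, every target role.
- ``run_seq3comp``  — exactly one triplet.
- ``run_seqconsen`` — consensus construction only.

All modes share the window statistic; they differ only in which parent
pair each examined sequence is compared against and in the number of
comparisons k entering the Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .alignment_io import Alignment, AlignmentShapeError
from .consensus import ConsensusResult, build_consensus
from .convstat import (
    ConversionSegment,
    ScanConfig,
    apply_bonferroni,
    bonferroni_threshold,
    count_comparisons,
    scan_profile,
)
from .informative import extract_profile

__all__ = [
    "RunReport",
    "run_mtcpconv",
    "run_twopop",
    "run_onepop",
    "run_seq3comp",
    "run_seqconsen",
    "write_report_tsv",
]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = (
    "program",
    "target_id",
    "donor_group",
    "aln_start",
    "aln_end",
    "L",
    "N",
    "M",
    "p",
    "tail",
    "P_LoverN",
    "P_LminusN",
    "k",
    "P_LoverN_corrected",
    "P_LminusN_corrected",
    "significant",
)


@dataclass(frozen=True)
class RunReport:
    """Result of one program run: configuration echo plus ranked segments."""

    program: str
    group1_label: str
    group2_label: str | None
    n1: int
    n2: int
    k: int
    config: ScanConfig
    segments: tuple[ConversionSegment, ...]
    profile_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def significant_segments(self) -> tuple[ConversionSegment, ...]:
        return tuple(s for s in self.segments if s.significant)

    def summary(self) -> str:
        thr = bonferroni_threshold(self.k, self.config.alpha)
        lines = [
            f"program: {self.program}",
            f"groups: {self.group1_label} (n={self.n1})"
            + (
                f" vs {self.group2_label} (n={self.n2})"
                if self.group2_label
                else ""
            ),
            f"comparisons k={self.k}; per-comparison threshold "
            f"alpha/k={thr:.3g}",
            f"segments: {len(self.segments)} candidate, "
            f"{len(self.significant_segments)} significant after Bonferroni",
        ]
        return "\n".join(lines)

    def rows(self) -> list[dict]:
        out = []
        for seg in self.segments:
            st = seg.stat
            out.append(
                {
                    "program": self.program,
                    "target_id": seg.target_id,
                    "donor_group": seg.donor_label,
                    "aln_start": seg.aln_start,
                    "aln_end": seg.aln_end,
                    "L": self.profile_lengths.get(seg.target_id, ""),
                    "N": st.N,
                    "M": st.M,
                    "p": f"{st.p:.6g}",
                    "tail": f"{st.binom_tail:.6g}",
                    "P_LoverN": f"{st.P_LoverN:.6g}",
                    "P_LminusN": f"{st.P_LminusN:.6g}",
                    "k": seg.k,
                    "P_LoverN_corrected": f"{seg.P_LoverN_corrected:.6g}",
                    "P_LminusN_corrected": f"{seg.P_LminusN_corrected:.6g}",
                    "significant": int(seg.significant),
                }
            )
        return out


def write_report_tsv(report: RunReport, path: str | Path) -> None:
    """Write a report as TSV with one row per segment."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in report.rows():
            fh.write("\t".join(str(row[c]) for c in REPORT_COLUMNS) + "\n")


def _segment_sort_key(config: ScanConfig):
    def key(seg: ConversionSegment):
        return (
            config.selection_key(
                seg.P_LoverN_corrected, seg.P_LminusN_corrected
            ),
            seg.stat.N,
            seg.target_id,
            seg.aln_start,
        )

    return key


def _best_per_span(
    segments: list[ConversionSegment], config: ScanConfig
) -> list[ConversionSegment]:
    """Per reported window span, keep the parent combination (triplet or
    orientation) with the smallest P. Distinct overlapping spans nominated
    by different parent pairs are all kept — they are competing tract
    hypotheses, and the Bonferroni-corrected P says how seriously to take
    each."""
    best: dict[tuple[str, int, int], ConversionSegment] = {}
    for seg in segments:
        span = (seg.target_id, seg.aln_start, seg.aln_end)
        old = best.get(span)
        if old is None or config.selection_key(
            seg.stat.P_LoverN, seg.stat.P_LminusN
        ) < config.selection_key(old.stat.P_LoverN, old.stat.P_LminusN):
            best[span] = seg
    return list(best.values())


def _finalize(
    program: str,
    group1_label: str,
    group2_label: str | None,
    n1: int,
    n2: int,
    k: int,
    config: ScanConfig,
    segments: list[ConversionSegment],
    profile_lengths: dict[str, int],
) -> RunReport:
    corrected = [apply_bonferroni(s, k, config) for s in segments]
    corrected.sort(key=_segment_sort_key(config))
    logger.info(
        "%s: n1=%d n2=%d k=%d threshold=%.3g segments=%d significant=%d",
        program,
        n1,
        n2,
        k,
        bonferroni_threshold(k, config.alpha),
        len(corrected),
        sum(s.significant for s in corrected),
    )
    return RunReport(
        program=program,
        group1_label=group1_label,
        group2_label=group2_label,
        n1=n1,
        n2=n2,
        k=k,
        config=config,
        segments=tuple(corrected),
        profile_lengths=profile_lengths,
    )


def _check_same_columns(group1: Alignment, group2: Alignment) -> None:
    if group1.length != group2.length:
        raise AlignmentShapeError(
            "the two group alignments must share one column coordinate "
            f"system, got lengths {group1.length} and {group2.length}"
        )


def run_mtcpconv(
    group1: Alignment,
    group2: Alignment,
    config: ScanConfig | None = None,
    labels: tuple[str, str] = ("group1", "group2"),
    targets: str = "both",
) -> RunReport:
    """Consensus mode: every sequence vs (own consensus, other consensus).

    ``targets`` selects which group(s) are examined ("group1", "group2",
    or "both"); k is the number of sequences actually examined.
    """
    config = config or ScanConfig()
    _check_same_columns(group1, group2)
    if targets not in ("group1", "group2", "both"):
        raise ValueError(f"targets must be group1|group2|both, got {targets!r}")
    for label, grp in zip(labels, (group1, group2)):
        if len(grp) == 1:
            logger.warning(
                "group %s has a single sequence; its consensus is that "
                "sequence itself",
                label,
            )
    cons = {labels[0]: build_consensus(group1), labels[1]: build_consensus(group2)}
    plan = []
    if targets in ("group1", "both"):
        plan.append((group1, labels[0], labels[1]))
    if targets in ("group2", "both"):
        plan.append((group2, labels[1], labels[0]))

    segments: list[ConversionSegment] = []
    lengths: dict[str, int] = {}
    examined = 0
    for grp, own, other in plan:
        own_seq = cons[own].seq
        other_seq = cons[other].seq
        for seq_id, seq in grp:
            examined += 1
            profile = extract_profile(
                seq,
                own_seq,
                other_seq,
                target_id=seq_id,
                parent_a_id=f"{own}_consensus",
                parent_b_id=f"{other}_consensus",
            )
            lengths[seq_id] = profile.L
            segments.extend(scan_profile(profile, config, donor_label=other))
    return _finalize(
        "mtcpconv",
        labels[0],
        labels[1],
        len(group1),
        len(group2),
        examined,
        config,
        segments,
        lengths,
    )


def run_twopop(
    group1: Alignment,
    group2: Alignment,
    config: ScanConfig | None = None,
    labels: tuple[str, str] = ("group1", "group2"),
) -> RunReport:
    """Exhaustive two-group mode.

    For each examined sequence x, every (a, b) with a != x from x's group
    and b from the other group is scanned; per reported window the best
    triplet's P is kept.
    """
    config = config or ScanConfig()
    _check_same_columns(group1, group2)
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError(
            "twopop requires >= 2 sequences per group (a within-group "
            "parent must exist)"
        )
    segments: list[ConversionSegment] = []
    lengths: dict[str, int] = {}
    for own_grp, other_grp, other_label in (
        (group1, group2, labels[1]),
        (group2, group1, labels[0]),
    ):
        for x_id, x_seq in own_grp:
            per_target: list[ConversionSegment] = []
            for a_id, a_seq in own_grp:
                if a_id == x_id:
                    continue
                for b_id, b_seq in other_grp:
                    profile = extract_profile(
                        x_seq,
                        a_seq,
                        b_seq,
                        target_id=x_id,
                        parent_a_id=a_id,
                        parent_b_id=b_id,
                    )
                    lengths[x_id] = max(lengths.get(x_id, 0), profile.L)
                    per_target.extend(
                        scan_profile(profile, config, donor_label=other_label)
                    )
            segments.extend(_best_per_span(per_target, config))
    k = count_comparisons(len(group1), len(group2), "triplets_twopop")
    return _finalize(
        "twopop",
        labels[0],
        labels[1],
        len(group1),
        len(group2),
        k,
        config,
        segments,
        lengths,
    )


def _attribute_events(
    candidates: list[ConversionSegment], config: ScanConfig
) -> list[ConversionSegment]:
    """Within one triplet, overlapping candidate windows from different
    target roles (or parent orientations) describe the same event seen
    from different sides; attribute each event to the role with the
    smallest P."""
    ordered = sorted(
        candidates,
        key=lambda s: (
            config.selection_key(s.stat.P_LoverN, s.stat.P_LminusN),
            s.stat.N,
            s.aln_start,
        ),
    )
    kept: list[ConversionSegment] = []
    for seg in ordered:
        if any(
            seg.aln_start <= k.aln_end and k.aln_start <= seg.aln_end
            for k in kept
        ):
            continue
        kept.append(seg)
    return kept


def _scan_all_roles(
    aln: Alignment, config: ScanConfig, lengths: dict[str, int]
) -> dict[str, list[ConversionSegment]]:
    """Scan every triplet with each sequence in the target role (both
    parent orientations) and attribute each detected event within the
    triplet to its best-supported role."""
    per_target: dict[str, list[ConversionSegment]] = {i: [] for i in aln.ids}
    n = len(aln)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                candidates: list[ConversionSegment] = []
                for t, u, v in ((i, j, k), (j, i, k), (k, i, j)):
                    t_id, t_seq = aln[t]
                    u_id, u_seq = aln[u]
                    v_id, v_seq = aln[v]
                    profile = extract_profile(
                        t_seq,
                        u_seq,
                        v_seq,
                        target_id=t_id,
                        parent_a_id=u_id,
                        parent_b_id=v_id,
                    )
                    lengths[t_id] = max(lengths.get(t_id, 0), profile.L)
                    candidates.extend(scan_profile(profile, config))
                    candidates.extend(scan_profile(profile.swapped(), config))
                for seg in _attribute_events(candidates, config):
                    per_target[seg.target_id].append(seg)
    return per_target


def run_onepop(aln: Alignment, config: ScanConfig | None = None) -> RunReport:
    """Single-group mode: all C(n,3) triplets, every sequence as target.

    Within a triplet both parent orientations are evaluated; per reported
    window the direction (and triplet) with the smaller P-value is kept.
    k = C(n, 3).
    """
    config = config or ScanConfig()
    if len(aln) < 3:
        raise ValueError("onepop requires at least 3 sequences")
    lengths: dict[str, int] = {}
    per_target = _scan_all_roles(aln, config, lengths)
    segments = [
        seg
        for cand in per_target.values()
        for seg in _best_per_span(cand, config)
    ]
    k = count_comparisons(len(aln), 0, "triplets_onepop")
    return _finalize(
        "onepop", "group", None, len(aln), 0, k, config, segments, lengths
    )


def run_seq3comp(aln: Alignment, config: ScanConfig | None = None) -> RunReport:
    """Single-triplet mode (exactly 3 sequences, k = 1)."""
    config = config or ScanConfig()
    if len(aln) != 3:
        raise ValueError(f"seq3comp requires exactly 3 sequences, got {len(aln)}")
    lengths: dict[str, int] = {}
    per_target = _scan_all_roles(aln, config, lengths)
    segments = [
        seg
        for cand in per_target.values()
        for seg in _best_per_span(cand, config)
    ]
    return _finalize(
        "seq3comp", "triplet", None, 3, 0, 1, config, segments, lengths
    )


def run_seqconsen(aln: Alignment) -> ConsensusResult:
    """Consensus construction mode (delegates to :func:`build_consensus`)."""
    return build_consensus(aln)
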