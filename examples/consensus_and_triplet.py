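"""Consensus construction and single-triplet scanning on a toy alignment.

A chimeric sequence carries a 32-column block from a diverged donor; the
triplet mode (chimera, clean relative, donor) localizes the block and
attributes it to the chimera.
"""

from consenconv import Alignment, build_consensus, run_seq3comp

S = ("ACGT" * 16)  # 64-column "native" sequence
T = ("TGCA" * 16)  # diverged donor, differs at every column
chimera = S[:16] + T[16:48] + S[48:]

consensus = build_consensus(Alignment([("s1", S), ("s2", S), ("s3", chimera)]))
print("consensus of three group members:", consensus.seq[:32], "...")
print("mean per-column support:", float(consensus.support.mean()))

report = run_seq3comp(Alignment([("chimera", chimera), ("clean", S), ("donor", T)]))
print()
print(report.summary())
for seg in report.significant_segments:
    print(
        f"{seg.target_id}: columns {seg.aln_start}-{seg.aln_end}, "
        f"M={seg.stat.M}/{seg.stat.N} donor matches, "
        f"P(L/N)={seg.stat.P_LoverN:.3g}, P(L-N)={seg.stat.P_LminusN:.3g}"
    )
print()
print(
    "The donor block spans columns 17-48 and is the sharpest segment. In"
    " this fully informative toy the flanks are reported too, as the"
    " complementary signal (the chimera matching its own group against a"
    " donor-dominated background); on realistic data flanking background"
    " matches are diffuse and fall below alpha."
)
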