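"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive pure Python (direct counting,
math.comb summation, exhaustive enumeration) and shares no code with the
package's vectorised paths.
"""

import math


def binom_tail_oracle(n: int, m: int, p: float) -> float:
    """Pr(X >= m), X ~ Binomial(n, p), by direct pmf summation."""
    return sum(
        math.comb(n, k) * p**k * (1.0 - p) ** (n - k) for k in range(m, n + 1)
    )


def consensus_oracle(seqs):
    """Per-column plurality among ACGT-, tie order A<C<G<T<-."""
    order = "ACGT-"
    out_seq, out_support = [], []
    for col in zip(*seqs):
        counts = {c: 0 for c in order}
        for ch in col:
            if ch in counts:
                counts[ch] += 1
        total = sum(counts.values())
        if total == 0:
            out_seq.append("-")
            out_support.append(0.0)
            continue
        best = max(order, key=lambda c: (counts[c], -order.index(c)))
        out_seq.append(best)
        out_support.append(counts[best] / total)
    return "".join(out_seq), out_support


def profile_oracle(target, parent_a, parent_b):
    """Column-by-column informative-site reduction."""
    cols, flags = [], []
    for j, (t, a, b) in enumerate(zip(target, parent_a, parent_b)):
        if any(c not in "ACGT" for c in (t, a, b)):
            continue
        if a == b:
            continue
        if t == a:
            cols.append(j)
            flags.append(False)
        elif t == b:
            cols.append(j)
            flags.append(True)
    return cols, flags


def _background_oracle(flags, s, e, whole):
    L = len(flags)
    if whole:
        m, n = sum(flags), L
    else:
        m = sum(flags[:s]) + sum(flags[e:])
        n = L - (e - s)
    if m == 0:
        return 0.5 / n
    if m == n:
        return 1.0 - 0.5 / n
    return m / n


def enumerate_windows_oracle(flags, min_window=3, max_window_frac=0.5,
                             require_majority=True, whole_profile_p=False):
    """Every admissible window with its two corrected P-values."""
    L = len(flags)
    max_n = min(L - 1, math.floor(L * max_window_frac))
    out = []
    for s in range(L):
        for e in range(s + min_window, L + 1):
            n = e - s
            if n > max_n:
                continue
            m = sum(flags[s:e])
            if require_majority and 2 * m <= n:
                continue
            p = _background_oracle(flags, s, e, whole_profile_p)
            tail = binom_tail_oracle(n, m, p)
            p1 = min(1.0, (L / n) * tail)
            p2 = min(1.0, (L - n) * tail)
            out.append((s, e, n, m, p, tail, p1, p2))
    return out


def scan_oracle(flags, alpha=0.05, min_window=3, correction="both",
                require_both=True, max_window_frac=0.5,
                require_majority=True, whole_profile_p=False):
    """Exhaustive re-implementation of the scan's selection rules.

    Returns the selected windows as (s, e) pairs in report order.
    """
    L = len(flags)
    if L < min_window + 1:
        return []
    windows = enumerate_windows_oracle(
        flags, min_window, max_window_frac, require_majority, whole_profile_p
    )

    def sel_key(w):
        _, _, n, _, _, _, p1, p2 = w
        return p1 if correction == "L_over_N" else p2

    def passes(w):
        p1, p2 = w[6], w[7]
        if correction == "both":
            if require_both:
                return p1 < alpha and p2 < alpha
            return p1 < alpha or p2 < alpha
        if correction == "L_minus_N":
            return p2 < alpha
        return p1 < alpha

    # best window per start: min key, ties -> smaller N then smaller s
    best = {}
    for w in windows:
        s = w[0]
        if s not in best or (sel_key(w), w[2], w[0]) < (
            sel_key(best[s]), best[s][2], best[s][0]
        ):
            best[s] = w
    candidates = [w for w in best.values() if passes(w)]
    candidates.sort(key=lambda w: (sel_key(w), w[2], w[0]))
    chosen = []
    for w in candidates:
        s, e = w[0], w[1]
        if any(s < ce and cs < e for cs, ce in chosen):
            continue
        chosen.append((s, e))
    return chosen
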