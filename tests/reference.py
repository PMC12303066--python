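"""Independent reference implementations used only as test oracles.

These re-derive expected results from the rule definitions by direct,
naive computation — deliberately written without reusing any package
helper so disagreements point at real defects.
"""

from __future__ import annotations

import random
from math import comb

_STOPS = ("TAA", "TAG", "TGA")


def ref_scan(seq: str, kozak: str = "adequate", spacing_scope: str = "frame"):
    """Literal-rule uORF scan: returns [(start, frame, stop_end-or-None)]."""
    n = len(seq)

    def kozak_ok(i: int) -> bool:
        if kozak == "any":
            return True
        minus3 = i - 3 >= 0 and seq[i - 3] in ("A", "G")
        plus4 = i + 3 < n and seq[i + 3] == "G"
        return (minus3 and plus4) if kozak == "strong" else (minus3 or plus4)

    def stop_end(i: int):
        j = i + 3
        while j + 3 <= n:
            if seq[j : j + 3] in _STOPS:
                return j + 3
            j += 3
        return None

    accepted: list[tuple[int, int, int | None]] = []
    for i in range(max(0, n - 2)):
        if seq[i : i + 3] != "ATG":
            continue
        if not kozak_ok(i):
            continue
        same_frame = [a for a in accepted if a[1] == i % 3]
        if spacing_scope == "global":
            prev = accepted[-1][0] if accepted else None
        else:
            prev = same_frame[-1][0] if same_frame else None
        if prev is not None and i - prev < 30:
            continue
        if any(se is None and s < i for (s, f, se) in same_frame):
            continue  # inside an open same-frame uORF
        accepted.append((i, i % 3, stop_end(i)))
    return accepted


def ref_atf4like(accepted) -> int:
    """Frames with an open uORF starting at/after some terminated stop end."""
    ends = [se for (_, _, se) in accepted if se is not None]
    return len(
        {
            f
            for (s, f, se) in accepted
            if se is None and any(s >= e for e in ends)
        }
    )


def random_sequence(rng: random.Random, length: int, gc: float) -> str:
    """Plain random DNA at the given GC fraction (no structure planted)."""
    weights = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices("ACGT", weights=weights, k=length))


def ref_confusion(scores, uorfs, labels, threshold: float):
    """Brute-force confusion counts for the hit rule at one cutoff."""
    tp = fp = tn = fn = 0
    for s, a, y in zip(scores, uorfs, labels):
        pred = s > threshold and a >= 1
        if pred and y:
            tp += 1
        elif pred:
            fp += 1
        elif y:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def ref_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration over the fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def p_table(x: int) -> float:
        # hypergeometric P(X = x) for cell (1,1)
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = p_table(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(p_table(x) for x in range(lo, hi + 1) if p_table(x) <= p_obs + 1e-12)


def ref_chi_square(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square statistic from first principles."""
    n = a + b + c + d
    stat = 0.0
    obs = [[a, b], [c, d]]
    rows = [a + b, c + d]
    cols = [a + c, b + d]
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (obs[i][j] - e) ** 2 / e
    return stat
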