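"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions alone (anchor enumeration,
sorted-list quantiles, per-position membership counts) and shares no code
with the package.
"""

import math

FIVE_SS = {"gtatgt", "gtacgt", "gtaagt", "gtatga"}
BRANCHPOINTS = {"tactaac", "gactaac", "aactaac", "tgctaac", "cactaac"}
_COMP = {"a": "t", "c": "g", "g": "c", "t": "a", "n": "n",
         "A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _leftmost_shortest(w: str, from_pos: int):
    """First grammar match at/after from_pos: minimal start, then minimal
    spacer-1, then minimal spacer-2.  Returns (start, end, s1, s2)."""
    n = len(w)
    for i in range(from_pos, n - 46):
        if w[i:i + 6] not in FIVE_SS:
            continue
        for j in range(i + 36, n - 10):
            s1 = w[i + 6:j]
            if any(c not in "acgt" for c in s1):
                break
            if w[j:j + 7] not in BRANCHPOINTS:
                continue
            for s2_len in range(1, 51):
                k = j + 7 + s2_len
                if k + 3 > n:
                    break
                if any(c not in "acgt" for c in w[j + 7:k]):
                    break
                t = w[k:k + 3]
                if t[0] in "tca" and t[1:] == "ag":
                    return (i, k + 3, j - (i + 6), s2_len)
    return None


def brute_force_scan(window: str):
    """All non-overlapping leftmost-shortest grammar matches."""
    w = window.lower()
    out, pos = [], 0
    while True:
        m = _leftmost_shortest(w, pos)
        if m is None:
            return out
        out.append(m)
        pos = m[1]


def _quantile(sorted_vals, q: float) -> float:
    h = (len(sorted_vals) - 1) * q
    lo, hi = math.floor(h), math.ceil(h)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def brute_force_boxplot_classify(value: float, population) -> str:
    vals = sorted(float(v) for v in population)
    q1, med, q3 = (_quantile(vals, q) for q in (0.25, 0.5, 0.75))
    iqr = q3 - q1
    if value > q3 + 1.5 * iqr:
        return "OUTLIER_UP"
    if value < q1 - 1.5 * iqr:
        return "OUTLIER_DOWN"
    if value > med:
        return "UP"
    if value < med:
        return "DOWN"
    return "NONE"


def brute_force_coverage(alignments, region):
    """Per-position membership count over [region[0], region[1])."""
    start, end = region
    return [sum(1 for aln in alignments
                if any(s <= p < e for s, e in aln.blocks))
            for p in range(start, end)]


def brute_force_junctions(alignments, chrom_seq):
    """(gap -> support count) for gaps with GT..AG flanks, strand-aware."""
    counts = {}
    for aln in alignments:
        for i in range(len(aln.blocks) - 1):
            gs, ge = aln.blocks[i][1], aln.blocks[i + 1][0]
            left = chrom_seq[gs:gs + 2].upper()
            right = chrom_seq[ge - 2:ge].upper()
            if aln.strand == "+":
                ok = left == "GT" and right == "AG"
            else:
                ok = revcomp(right) == "GT" and revcomp(left) == "AG"
            if ok:
                counts[(gs, ge)] = counts.get((gs, ge), 0) + 1
    return counts


def brute_force_first_stop(spliced_seq: str, start_offset: int):
    """Transcript offset of the first stop codon read from start_offset."""
    s = spliced_seq.lower()
    for t in range(start_offset, len(s) - 2, 3):
        if s[t:t + 3] in ("taa", "tag", "tga"):
            return t
    return None
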