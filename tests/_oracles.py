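"""Independent brute-force oracles used by the test suite.

Everything here is written as the most direct transcription of each
definition — naive scans, direct formula evaluation, diagonal matching —
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def naive_kmer_count(seq: str, kmer: str) -> int:
    """Count overlapping occurrences by explicit position-by-position scan."""
    k = len(kmer)
    return sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] == kmer)


def naive_window_gc(seq: str, w: int) -> list[float]:
    if len(seq) <= w:
        win = [seq]
    else:
        win = [seq[i : i + w] for i in range(len(seq) - w + 1)]
    return [(x.count("G") + x.count("C")) / len(x) for x in win]


def longest_repeat_by_diagonals(seq: str) -> int:
    """Longest substring occurring at two distinct positions, via matching
    runs along every diagonal shift d >= 1 (occurrences may overlap)."""
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    best = 0
    for d in range(1, len(a)):
        eq = np.concatenate([[0], (a[:-d] == a[d:]).astype(np.int8), [0]])
        d2 = np.diff(eq)
        starts = np.flatnonzero(d2 == 1)
        if starts.size:
            run = int((np.flatnonzero(d2 == -1) - starts).max())
            if run > best:
                best = run
    return best


def naive_dup_kmers(seq: str, k: int) -> tuple[int, float]:
    subs = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    dup = {s for s in subs if subs.count(s) >= 2}
    covered = set()
    for i, s in enumerate(subs):
        if s in dup:
            covered.update(range(i, i + k))
    return len(dup), len(covered) / len(seq)


def naive_longest_inverted_stem(seq: str) -> int:
    best = 0
    L = len(seq)
    for k in range(best + 1, L // 2 + 1):
        found = False
        for i in range(L - k + 1):
            target = rc(seq[i : i + k])
            for j in range(i + k, L - k + 1):
                if seq[j : j + k] == target:
                    found = True
                    break
            if found:
                break
        if found:
            best = k
        else:
            break
    return best


def naive_count_inverted_10(seq: str) -> int:
    k, n = 10, 0
    for i in range(len(seq) - k + 1):
        target = rc(seq[i : i + k])
        if any(
            seq[j : j + k] == target for j in range(i + k, len(seq) - k + 1)
        ):
            n += 1
    return n


def naive_hairpins(seq: str, min_stem: int = 6, loop_lo: int = 3, loop_hi: int = 48):
    """All (start, stem, loop) stem-loops with exact reverse-complement
    stems, found by a different route than the package: every base pair of
    a hairpin's stem lies on one pairing axis a = i + j (i pairs j); along
    each axis, maximal runs of complementary pairs ending at an inner
    position with a loop in range are the hairpins. The stem is maximal
    outward (run maximality) and the loop cannot pair-shrink in range."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    L = len(seq)
    out = []
    for a in range(1, 2 * L - 2):  # pairing axis: i + j == a, i < j
        i_lo = max(0, a - L + 1)
        i_hi = (a - 1) // 2  # largest i with i < a - i
        # inner stem positions whose loop a - 2i - 1 lies in range
        first = max(i_lo, (a - loop_hi - 1 + 1) // 2)  # ceil((a-loop_hi-1)/2)
        last = min(i_hi, (a - loop_lo - 1) // 2)
        for i_in in range(first, last + 1):
            loop = a - 2 * i_in - 1
            if not (loop_lo <= loop <= loop_hi):
                continue
            # loop shrinkable: the next inner pair also matches
            if (
                loop - 2 >= loop_lo
                and i_in + 1 <= i_hi
                and comp[seq[i_in + 1]] == seq[a - i_in - 1]
            ):
                continue
            stem, i = 0, i_in
            while i >= i_lo and comp[seq[i]] == seq[a - i]:
                stem += 1
                i -= 1
            if stem >= min_stem:
                out.append((i_in - stem + 1, stem, loop))
    return out


def naive_restriction_count(seq: str, site: str) -> int:
    n = naive_kmer_count(seq, site)
    site_rc = rc(site)
    if site_rc != site:
        n += naive_kmer_count(seq, site_rc)
    return n


def naive_anf(seq: str) -> list[float]:
    out = []
    for i in range(len(seq)):
        prefix = seq[: i + 1]
        out.append(prefix.count(seq[i]) / (i + 1))
    return out


def naive_dft_power(x: list[float]) -> tuple[list[float], list[float]]:
    """Direct DFT of the mean-removed signal; returns (frequencies, power)
    for the positive frequencies up to 0.5."""
    n = len(x)
    mu = sum(x) / n
    y = [v - mu for v in x]
    freqs, power = [], []
    for k in range(1, n // 2 + 1):
        re = sum(y[t] * math.cos(2 * math.pi * k * t / n) for t in range(n))
        im = -sum(y[t] * math.sin(2 * math.pi * k * t / n) for t in range(n))
        freqs.append(k / n)
        power.append(re * re + im * im)
    return freqs, power


# --- unified nearest-neighbor melting temperature ---------------------------

_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}


def nn_tm(seq: str, na_mM: float = 50.0, dnac1_nM: float = 250.0, dnac2_nM: float = 250.0) -> float:
    """Two-state nearest-neighbor Tm with the unified parameter set and an
    entropic salt correction of 0.368 (N-1) ln[Na+]."""
    dH = dS = 0.0
    for end in (seq[0], seq[-1]):
        h, s = _INIT[end]
        dH += h
        dS += s
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dH += h
        dS += s
    if seq == rc(seq):
        dS += -1.4
        k = dnac1_nM * 1e-9
    else:
        k = (dnac1_nM - dnac2_nM / 2) * 1e-9
    dS += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    return dH * 1000.0 / (dS + 1.987 * math.log(k)) - 273.15


# --- metric formulas, recomputed directly ------------------------------------


def direct_f1(tp, fp, tn, fn):
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def direct_mcc(tp, fp, tn, fn):
    d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return (tp * tn - fp * fn) / math.sqrt(d) if d else 0.0


def direct_kappa(tp, fp, tn, fn):
    n = tp + fp + tn + fn
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    return (po - pe) / (1 - pe) if pe != 1 else 0.0


def confusion_to_labels(tp, fp, tn, fn):
    """Truth/prediction label vectors realizing the given counts."""
    truth = ["HARD"] * tp + ["EASY"] * fp + ["EASY"] * tn + ["HARD"] * fn
    pred = ["HARD"] * tp + ["HARD"] * fp + ["EASY"] * tn + ["EASY"] * fn
    return truth, pred
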