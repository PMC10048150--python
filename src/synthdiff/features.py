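"""The 426-feature DNA sequence descriptor and min-max normalization.

All extractors are deterministic pure functions of the (validated,
uppercase A/C/G/T) sequence. Window-based features slide by 1 bp; a
sequence shorter than the window contributes a single window equal to the
whole sequence. Internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .manifest import (
    BASES,
    TM_CONDITIONS,
    FeatureManifest,
    canonical_trimers,
    get_manifest,
    kmers,
    revcomp,
)
from .seqio import SequenceRecord

#: Electron-ion interaction potential of each base (Rydberg units).
EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}

#: Hairpin detection parameters: exact reverse-complement stems of at least
#: this length closing a loop in the given range.
HAIRPIN_MIN_STEM = 6
HAIRPIN_STRONG_STEM = 10
HAIRPIN_LOOP_RANGE = (3, 48)

#: Minimum length for the full descriptor: the spectral features need at
#: least this many bases. Below 100 bp extraction proceeds with a warning
#: (window features fall back to a single whole-sequence window).
MIN_FULL_LENGTH = 40
RECOMMENDED_LENGTH = 100


class FeatureExtractionError(ValueError):
    pass


def _check(seq: str, min_len: int, what: str) -> None:
    if len(seq) < min_len:
        raise FeatureExtractionError(
            f"{what}: sequence length {len(seq)} < required {min_len}"
        )


def _windows(seq: str, w: int) -> list[str]:
    """All windows of width w, step 1; one whole-sequence window if shorter."""
    if len(seq) <= w:
        return [seq]
    return [seq[i : i + w] for i in range(len(seq) - w + 1)]


def gc_fraction(seq: str) -> float:
    if not seq:
        raise FeatureExtractionError("gc_fraction: empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def _window_gc(seq: str, w: int) -> np.ndarray:
    """GC fraction of every w-window (step 1) via a cumulative-sum scan."""
    L = len(seq)
    if L <= w:
        return np.array([gc_fraction(seq)])
    is_gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(is_gc)])
    return (cs[w:] - cs[:-w]) / w


def gc_features(seq: str) -> list[float]:
    """8 GC statistics: global GC, dGC (100 bp window spread), low/high
    window counts at 20 bp (<0.40 / >0.60) and 100 bp (<0.30 / >0.70), and
    the 100 bp window extremes."""
    _check(seq, 1, "gc_features")
    g = gc_fraction(seq)
    w100 = _window_gc(seq, 100)
    w20 = _window_gc(seq, 20)
    return [
        g,
        float(w100.max() - w100.min()),
        float(np.sum(w20 < 0.40)),
        float(np.sum(w20 > 0.60)),
        float(np.sum(w100 < 0.30)),
        float(np.sum(w100 > 0.70)),
        float(w100.min()),
        float(w100.max()),
    ]


def composition_features(seq: str) -> list[float]:
    """84 k-mer frequencies: mono (4) + di (16) + tri (64), each count
    divided by the number of k-windows L-k+1, lexicographic order."""
    _check(seq, 3, "composition_features")
    out: list[float] = []
    for k in (1, 2, 3):
        n = len(seq) - k + 1
        counts = _kmer_counts(seq, k)
        out.extend(counts[m] / n for m in kmers(k))
    return out


def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    counts = dict.fromkeys(kmers(k), 0)
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] += 1
    return counts


def kmer_features(seq: str) -> list[float]:
    """112 k-mer features: raw di counts (16) + raw tri counts (64) +
    reverse-complement-collapsed trinucleotide frequencies (32)."""
    _check(seq, 3, "kmer_features")
    di = _kmer_counts(seq, 2)
    tri = _kmer_counts(seq, 3)
    out = [float(di[m]) for m in kmers(2)]
    out += [float(tri[m]) for m in kmers(3)]
    n3 = len(seq) - 2
    for m in canonical_trimers():
        rc = revcomp(m)
        c = tri[m] + (tri[rc] if rc != m else 0)
        out.append(c / n3)
    return out


def anf_features(seq: str) -> list[float]:
    """22 accumulated nucleotide frequency features.

    a(i) = (occurrences of base seq[i] in seq[0..i]) / (i+1); the signal is
    sampled at 20 evenly spaced relative positions (first and last
    included), plus its mean and variance.
    """
    _check(seq, 22, "anf_features")
    L = len(seq)
    counts = dict.fromkeys(BASES, 0)
    a = np.empty(L)
    for i, ch in enumerate(seq):
        counts[ch] += 1
        a[i] = counts[ch] / (i + 1)
    idx = np.round(np.linspace(0, L - 1, 20)).astype(int)
    return [*map(float, a[idx]), float(a.mean()), float(a.var())]


def eiip_features(seq: str) -> list[float]:
    """40 electron-ion interaction potential features: signal mean and
    variance plus normalized periodogram power in 38 equal bins over
    (0, 0.5]. Power is computed on the mean-removed signal and normalized
    by total power, so the bins sum to 1 (all 0 for a constant signal)."""
    _check(seq, 40, "eiip_features")
    x = np.array([EIIP[c] for c in seq])
    mean = float(x.mean())
    var = float(x.var())
    bins = np.zeros(38)
    if var > 0:
        y = x - x.mean()
        spec = np.abs(np.fft.rfft(y)) ** 2
        L = len(y)
        freqs = np.arange(len(spec)) / L
        keep = freqs > 0
        spec, freqs = spec[keep], freqs[keep]
        total = spec.sum()
        if total > 0:
            # bin b covers (b/76, (b+1)/76]; right edge inclusive
            which = np.ceil(freqs * 76).astype(int) - 1
            np.add.at(bins, which, spec / total)
    return [mean, var, *map(float, bins)]


# ---------------------------------------------------------------------------
# repeats


def _runs(seq: str) -> list[tuple[str, int]]:
    """Maximal homopolymer runs as (base, length)."""
    out = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        out.append((seq[i], j - i))
        i = j
    return out


def longest_repeated_substring(seq: str) -> int:
    """Length of the longest substring occurring at two distinct positions
    (occurrences may overlap). Binary search over the length; a repeat of
    length k implies one of length k-1."""
    lo, hi = 0, len(seq) - 1

    def has(k: int) -> bool:
        if k == 0:
            return True
        seen = set()
        for i in range(len(seq) - k + 1):
            s = seq[i : i + k]
            if s in seen:
                return True
            seen.add(s)
        return False

    while lo < hi:
        mid = (lo + hi + 1) // 2
        if has(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def _dup_kmers(seq: str, k: int) -> tuple[int, float]:
    """(number of distinct k-mers occurring >= 2x, fraction of positions
    covered by those k-mers)."""
    pos: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        pos.setdefault(seq[i : i + k], []).append(i)
    covered = np.zeros(len(seq), dtype=bool)
    ndup = 0
    for p in pos.values():
        if len(p) >= 2:
            ndup += 1
            for i in p:
                covered[i : i + k] = True
    return ndup, float(covered.mean()) if len(seq) else 0.0


def longest_tandem_repeat(seq: str) -> int:
    """Total length of the longest tandem repeat (unit >= 2 bp, >= 2 full
    copies). For each unit length u the longest stretch of positions with
    seq[i] == seq[i+u] of length r gives a tandem of total length r + u
    when r >= u."""
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    L = len(a)
    best = 0
    for u in range(2, L // 2 + 1):
        eq = (a[:-u] == a[u:]).astype(np.int8)
        d = np.diff(np.concatenate(([0], eq, [0])))
        starts = np.flatnonzero(d == 1)
        if starts.size == 0:
            continue
        run = int((np.flatnonzero(d == -1) - starts).max())
        if run >= u and run + u > best:
            best = run + u
    return best


def longest_inverted_repeat_stem(seq: str) -> int:
    """Longest s such that s and revcomp(s) both occur, with the
    reverse-complement copy starting at or after the end of the first."""
    lo, hi = 0, len(seq) // 2

    def has(k: int) -> bool:
        if k == 0:
            return True
        first: dict[str, int] = {}
        for i in range(len(seq) - k + 1):
            m = seq[i : i + k]
            first.setdefault(m, i)
        for i in range(len(seq) - k + 1):
            m = revcomp(seq[i : i + k])
            j = first.get(m)
            if j is not None and i >= j + k:
                return True
        return False

    while lo < hi:
        mid = (lo + hi + 1) // 2
        if has(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def count_inverted_repeats_stem10(seq: str, stem: int = 10) -> int:
    """Positions i whose stem-length k-mer has a reverse-complement copy
    starting at or after i + stem."""
    k = stem
    if len(seq) < 2 * k:
        return 0
    last: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        last[seq[i : i + k]] = i
    n = 0
    for i in range(len(seq) - k + 1):
        j = last.get(revcomp(seq[i : i + k]))
        if j is not None and j >= i + k:
            n += 1
    return n


def longest_palindromic_site(seq: str) -> int:
    """Longest even-length substring equal to its own reverse complement,
    found by expanding around every between-base center."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    best = 0
    L = len(seq)
    for c in range(1, L):
        i, j = c - 1, c
        while i >= 0 and j < L and comp[seq[i]] == seq[j]:
            i -= 1
            j += 1
        ln = j - i - 1
        if ln > best:
            best = ln
    return best


def longest_dinucleotide_run(seq: str) -> int:
    """Longest run of a repeated 2-bp unit with the two bases distinct
    (e.g. ATATAT...); total length of the run, 0 if no unit repeats."""
    best = 0
    L = len(seq)
    for i in range(L - 3):
        if seq[i] == seq[i + 1]:
            continue
        j = i + 2
        while j < L and seq[j] == seq[j - 2]:
            j += 1
        ln = j - i
        if ln >= 4 and ln > best:
            best = ln
    return best


def repeat_features(seq: str) -> list[float]:
    """15 repeat statistics (direct/tandem/inverted repeats, palindromes,
    homopolymer runs)."""
    _check(seq, 10, "repeat_features")
    runs = _runs(seq)
    per_base = {b: 0 for b in BASES}
    for b, ln in runs:
        per_base[b] = max(per_base[b], ln)
    ndup10, cov10 = _dup_kmers(seq, 10)
    ndup20, _ = _dup_kmers(seq, 20)
    return [
        float(longest_repeated_substring(seq)),
        float(ndup10),
        float(ndup20),
        cov10,
        float(longest_tandem_repeat(seq)),
        float(longest_inverted_repeat_stem(seq)),
        float(count_inverted_repeats_stem10(seq)),
        float(longest_palindromic_site(seq)),
        *(float(per_base[b]) for b in BASES),
        float(longest_dinucleotide_run(seq)),
        float(sum(1 for _, ln in runs if ln >= 5)),
        float(max(per_base.values())),
    ]


# ---------------------------------------------------------------------------
# melting temperature


def _tm(seq: str) -> float:
    return float(
        _mt.Tm_NN(
            seq,
            Na=TM_CONDITIONS["Na_mM"],
            dnac1=TM_CONDITIONS["dnac1_nM"],
            dnac2=TM_CONDITIONS["dnac2_nM"],
        )
    )


def tm_features(seq: str) -> list[float]:
    """3 nearest-neighbor melting temperatures (degC): the minimum and
    maximum over 20 bp windows and the whole-sequence value. Unified
    thermodynamic parameters at the conditions in the manifest."""
    _check(seq, 20, "tm_features")
    tms = [_tm(w) for w in _windows(seq, 20)]
    return [min(tms), max(tms), _tm(seq)]


# ---------------------------------------------------------------------------
# secondary structure (hairpins)


def find_hairpins(
    seq: str,
    min_stem: int = HAIRPIN_MIN_STEM,
    loop_range: tuple[int, int] = HAIRPIN_LOOP_RANGE,
) -> list[dict]:
    """Enumerate stem-loop candidates by exact reverse-complement pairing.

    For every loop placement (start j, length l in loop_range) the stem is
    extended outward from the loop while bases pair; a maximal stem of at
    least min_stem is one hairpin. A placement whose loop ends could pair
    (so the same stem-loop is recorded at the smaller loop) is skipped,
    making each physical hairpin one record per center. Returns dicts with
    start, stem, loop, end and stem_gc.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    L = len(seq)
    lo, hi = loop_range
    out = []
    for j in range(1, L - 1):  # loop start
        for l in range(lo, hi + 1):
            i, k = j - 1, j + l
            if k >= L:
                break
            if l - 2 >= lo and comp[seq[j]] == seq[j + l - 1]:
                continue  # shrinkable loop: counted at (j+1, l-2)
            s = 0
            while i >= 0 and k < L and comp[seq[i]] == seq[k]:
                s += 1
                i -= 1
                k += 1
            if s >= min_stem:
                start = i + 1
                stem_seq = seq[start : start + s]
                out.append(
                    {
                        "start": start,
                        "stem": s,
                        "loop": l,
                        "end": k,  # one past the last stem base
                        "stem_gc": gc_fraction(stem_seq),
                    }
                )
    return out


def structure_features(seq: str) -> list[float]:
    """7 hairpin statistics from exact inverted-repeat detection."""
    _check(seq, 20, "structure_features")
    hp = find_hairpins(seq)
    if not hp:
        return [0.0] * 7
    L = len(seq)
    return [
        float(len(hp)),
        float(max(h["stem"] for h in hp)),
        float(max(h["stem_gc"] for h in hp)),
        float(sum(1 for h in hp if h["stem"] >= HAIRPIN_STRONG_STEM)),
        float(min(h["loop"] for h in hp)),
        float(any(h["start"] < 50 for h in hp)),
        float(any(h["end"] > L - 50 for h in hp)),
    ]


# ---------------------------------------------------------------------------
# specific motifs and terminal statistics


def _count_overlapping(seq: str, motif: str) -> int:
    n = 0
    start = 0
    while True:
        i = seq.find(motif, start)
        if i == -1:
            return n
        n += 1
        start = i + 1


def _count_unit_tandems(seq: str, unit: str, min_units: int) -> int:
    """Maximal tandem runs of `unit` with at least min_units copies."""
    n = 0
    i = 0
    u = len(unit)
    L = len(seq)
    while i < L:
        if seq.startswith(unit, i):
            j = i
            while seq.startswith(unit, j):
                j += u
            if (j - i) // u >= min_units:
                n += 1
            i = j
        else:
            i += 1
    return n


def specific_features(seq: str) -> list[float]:
    """20 motif and terminal statistics (run counts, G-quadruplex-like
    tracts, terminal GC and homopolymer indicators, near-monotone windows)."""
    _check(seq, 30, "specific_features")
    runs = _runs(seq)
    n5 = {b: 0 for b in BASES}
    n8 = {b: 0 for b in BASES}
    for b, ln in runs:
        if ln >= 5:
            n5[b] += 1
        if ln >= 8:
            n8[b] += 1
    g_run = max((ln for b, ln in runs if b == "G"), default=0)
    win_mono = 0
    for w in _windows(seq, 20):
        if max(w.count(b) for b in BASES) >= 0.9 * len(w):
            win_mono += 1

    def has_run4(s: str) -> bool:
        return any(ln >= 4 for _, ln in _runs(s))

    return [
        *(float(n5[b]) for b in BASES),
        *(float(n8[b]) for b in BASES),
        float(_count_overlapping(seq, "GGGG")),
        float(_count_overlapping(seq, "CCCC")),
        float(_count_unit_tandems(seq, "AT", 3)),
        float(_count_unit_tandems(seq, "GC", 3)),
        gc_fraction(seq[:30]),
        gc_fraction(seq[-30:]),
        float(has_run4(seq[:10])),
        float(has_run4(seq[-10:])),
        float(win_mono),
        float(g_run if g_run >= 4 else 0),
        float(_count_overlapping(seq, "GCGCGC")),
        float(_count_overlapping(seq, "ATATAT")),
    ]


def restriction_features(seq: str) -> list[float]:
    """114 restriction-site counts (overlaps allowed). Non-palindromic
    sites are counted on both strands by also scanning the reverse
    complement of the site on the forward strand."""
    _check(seq, 1, "restriction_features")
    from .manifest import RESTRICTION_ENZYMES

    out = []
    for _, site in RESTRICTION_ENZYMES:
        n = _count_overlapping(seq, site)
        rc = revcomp(site)
        if rc != site:
            n += _count_overlapping(seq, rc)
        out.append(float(n))
    return out


# ---------------------------------------------------------------------------
# assembly


_GROUP_FUNCS = {
    "composition": composition_features,
    "anf": anf_features,
    "eiip": eiip_features,
    "kmer": kmer_features,
    "repeat": repeat_features,
    "gc": gc_features,
    "tm": tm_features,
    "structure": structure_features,
    "specific": specific_features,
    "restriction": restriction_features,
}


def extract_all(record: SequenceRecord) -> pd.Series:
    """The full 426-value descriptor of one validated record, indexed by
    manifest feature name. Sequences shorter than 100 bp are accepted with
    a warning down to 40 bp (window features then degrade to a single
    whole-sequence window)."""
    manifest = get_manifest()
    seq = record.seq
    if len(seq) < MIN_FULL_LENGTH:
        raise FeatureExtractionError(
            f"{record.id}: length {len(seq)} < minimum {MIN_FULL_LENGTH} for the full descriptor"
        )
    if len(seq) < RECOMMENDED_LENGTH:
        warnings.warn(
            f"{record.id}: length {len(seq)} < {RECOMMENDED_LENGTH} bp; "
            "window features use the whole sequence as a single window",
            stacklevel=2,
        )
    values: list[float] = []
    for group in manifest.group_sizes():
        if group == "length":
            values.append(float(len(seq)))
            continue
        try:
            values.extend(_GROUP_FUNCS[group](seq))
        except FeatureExtractionError as exc:
            raise FeatureExtractionError(f"group {group!r}: {exc}") from exc
    arr = np.asarray(values, dtype=float)
    if len(arr) != len(manifest):
        raise RuntimeError(
            f"descriptor length {len(arr)} != manifest length {len(manifest)}"
        )
    if not np.isfinite(arr).all():
        raise FeatureExtractionError(f"{record.id}: non-finite feature value")
    return pd.Series(arr, index=manifest.names, name=record.id)


def extract_matrix(records: list[SequenceRecord]) -> pd.DataFrame:
    """Feature matrix: one row per record, manifest columns, id index."""
    rows = [extract_all(r) for r in records]
    return pd.DataFrame(rows)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


@dataclass
class Normalizer:
    """Per-feature min-max scaling learned from a training matrix.

    apply maps x -> (x - min) / (max - min); constant features map to 0.
    Values from unseen data may fall outside [0, 1] and are not clipped.
    """

    mins: pd.Series
    maxs: pd.Series

    @classmethod
    def fit(cls, matrix: pd.DataFrame) -> "Normalizer":
        if matrix.shape[0] == 0:
            raise ValueError("cannot fit a normalizer on an empty matrix")
        return cls(mins=matrix.min(axis=0), maxs=matrix.max(axis=0))

    def apply(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if list(matrix.columns) != list(self.mins.index):
            raise ValueError("matrix columns do not match the fitted normalizer")
        span = self.maxs - self.mins
        out = matrix.sub(self.mins, axis=1)
        nonconst = span != 0
        out.loc[:, nonconst] = out.loc[:, nonconst].div(span[nonconst], axis=1)
        out.loc[:, ~nonconst] = 0.0
        return out


def fit_normalizer(matrix: pd.DataFrame) -> Normalizer:
    return Normalizer.fit(matrix)


def apply_normalizer(normalizer: Normalizer, matrix: pd.DataFrame) -> pd.DataFrame:
    return normalizer.apply(matrix)
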