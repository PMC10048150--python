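"""The pinned, versioned 426-feature manifest.

The descriptor is organized in 11 groups with fixed sizes
(composition 84, anf 22, eiip 40, kmer 112, repeat 15, gc 8, tm 3,
structure 7, specific 20, restriction 114, length 1) and a fixed order.
Feature names are stable identifiers: a trained model bundle records the
manifest version and refuses to score against a different one.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

MANIFEST_VERSION = "1.0"

BASES = "ACGT"

#: Thermodynamic conditions for the melting-temperature features
#: (nearest-neighbor model, unified parameter set).
TM_CONDITIONS = {"Na_mM": 50.0, "dnac1_nM": 250.0, "dnac2_nM": 250.0}

#: 114 restriction enzymes with unambiguous recognition sites, one per
#: distinct site. ApaI (GGGCCC) is always present. Frozen — the order of
#: the restriction feature block is the order of this tuple.
RESTRICTION_ENZYMES: tuple[tuple[str, str], ...] = (
    ("AanI", "TTATAA"), ("AarI", "CACCTGC"), ("AatII", "GACGTC"),
    ("AbsI", "CCTCGAGG"), ("Acc16I", "TGCGCA"), ("Acc36I", "ACCTGC"),
    ("Acc65I", "GGTACC"), ("AccBSI", "CCGCTC"), ("AccII", "CGCG"),
    ("AccIII", "TCCGGA"), ("AciI", "CCGC"), ("AclI", "AACGTT"),
    ("AclWI", "GGATC"), ("AcuI", "CTGAAG"), ("AcvI", "CACGTG"),
    ("AfaI", "GTAC"), ("AfeI", "AGCGCT"), ("AflII", "CTTAAG"),
    ("AgeI", "ACCGGT"), ("AhlI", "ACTAGT"), ("AjiI", "CACGTC"),
    ("AluBI", "AGCT"), ("Alw26I", "GTCTC"), ("Alw44I", "GTGCAC"),
    ("AoxI", "GGCC"), ("ApaI", "GGGCCC"), ("AscI", "GGCGCGCC"),
    ("AseI", "ATTAAT"), ("AsiSI", "GCGATCGC"), ("AspA2I", "CCTAGG"),
    ("AspLEI", "GCGC"), ("AsuHPI", "GGTGA"), ("AsuII", "TTCGAA"),
    ("AsuNHI", "GCTAGC"), ("BalI", "TGGCCA"), ("BamHI", "GGATCC"),
    ("BauI", "CACGAG"), ("BbsI", "GAAGAC"), ("BbvCI", "CCTCAGC"),
    ("BbvI", "GCAGC"), ("BccI", "CCATC"), ("BceAI", "ACGGC"),
    ("BciVI", "GTATCC"), ("BclI", "TGATCA"), ("BfaI", "CTAG"),
    ("BglII", "AGATCT"), ("BmcAI", "AGTACT"), ("BmrI", "ACTGGG"),
    ("BmsI", "GCATC"), ("BpmI", "CTGGAG"), ("BpuEI", "CTTGAG"),
    ("Bsa29I", "ATCGAT"), ("BsaI", "GGTCTC"), ("Bse1I", "ACTGG"),
    ("Bse3DI", "GCAATG"), ("BseGI", "GGATG"), ("BseMII", "CTCAG"),
    ("BsePI", "GCGCGC"), ("BseRI", "GAGGAG"), ("BseX3I", "CGGCCG"),
    ("BseYI", "CCCAGC"), ("BsgI", "GTGCAG"), ("BsiSI", "CCGG"),
    ("BsiWI", "CGTACG"), ("BslFI", "GGGAC"), ("BsmBI", "CGTCTC"),
    ("BsmI", "GAATGC"), ("Bsp1407I", "TGTACA"), ("Bsp19I", "CCATGG"),
    ("Bsp68I", "TCGCGA"), ("BspHI", "TCATGA"), ("BspMAI", "CTGCAG"),
    ("BspQI", "GCTCTTC"), ("BssNAI", "GTATAC"), ("Bst6I", "CTCTTC"),
    ("BstSNI", "TACGTA"), ("BtgZI", "GCGATG"), ("BtsI", "GCAGTG"),
    ("CciNI", "GCGGCCGC"), ("Cfr42I", "CCGCGG"), ("Cfr9I", "CCCGGG"),
    ("DinI", "GGCGCC"), ("DraI", "TTTAAA"), ("EciI", "GGCGGA"),
    ("Ecl136II", "GAGCTC"), ("Eco147I", "AGGCCT"), ("Eco32I", "GATATC"),
    ("EcoRI", "GAATTC"), ("EcoT22I", "ATGCAT"), ("FauNDI", "CATATG"),
    ("FseI", "GGCCGGCC"), ("HindIII", "AAGCTT"), ("HpaI", "GTTAAC"),
    ("KroI", "GCCGGC"), ("MauBI", "CGCGCGCG"), ("MfeI", "CAATTG"),
    ("MluI", "ACGCGT"), ("MreI", "CGCCGGCG"), ("MssI", "GTTTAAAC"),
    ("NmeAIII", "GCCGAG"), ("PacI", "TTAATTAA"), ("PaeI", "GCATGC"),
    ("PaeR7I", "CTCGAG"), ("PciI", "ACATGT"), ("Ple19I", "CGATCG"),
    ("PvuII", "CAGCTG"), ("SalI", "GTCGAC"), ("SbfI", "CCTGCAGG"),
    ("SgrDI", "CGTCGACG"), ("SmiI", "ATTTAAAT"), ("SrfI", "GCCCGGGC"),
    ("SspI", "AATATT"), ("TaqII", "GACCGA"), ("XbaI", "TCTAGA"),
)

GROUP_SIZES = {
    "composition": 84,
    "anf": 22,
    "eiip": 40,
    "kmer": 112,
    "repeat": 15,
    "gc": 8,
    "tm": 3,
    "structure": 7,
    "specific": 20,
    "restriction": 114,
    "length": 1,
}

GROUP_ORDER = tuple(GROUP_SIZES)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def kmers(k: int) -> list[str]:
    """All k-mers over ACGT in lexicographic order."""
    return ["".join(p) for p in product(BASES, repeat=k)]


def canonical_trimers() -> list[str]:
    """The 32 trinucleotide classes collapsed under reverse complement.

    Each class is named by its lexicographically smaller member; no odd-length
    k-mer equals its own reverse complement, so the 64 trimers pair exactly
    into 32 classes.
    """
    return sorted(t for t in kmers(3) if t <= revcomp(t))


@dataclass(frozen=True)
class ManifestEntry:
    name: str
    group: str
    description: str


def _build_entries() -> tuple[ManifestEntry, ...]:
    e: list[ManifestEntry] = []

    def add(name: str, group: str, desc: str) -> None:
        e.append(ManifestEntry(name, group, desc))

    for b in BASES:
        add(f"f_{b}", "composition", f"mononucleotide frequency of {b}")
    for m in kmers(2):
        add(f"f_{m}", "composition", f"dinucleotide frequency of {m}")
    for m in kmers(3):
        add(f"f_{m}", "composition", f"trinucleotide frequency of {m}")

    for i in range(1, 21):
        add(f"anf_p{i:02d}", "anf",
            f"accumulated nucleotide frequency at relative position {i}/20")
    add("anf_mean", "anf", "mean of the accumulated nucleotide frequency signal")
    add("anf_var", "anf", "variance of the accumulated nucleotide frequency signal")

    add("eiip_mean", "eiip", "mean of the electron-ion interaction potential signal")
    add("eiip_var", "eiip", "variance of the electron-ion interaction potential signal")
    for i in range(1, 39):
        add(f"eiip_bin{i:02d}", "eiip",
            f"normalized periodogram power in frequency bin {i}/38 over (0, 0.5]")

    for m in kmers(2):
        add(f"c_{m}", "kmer", f"raw count of dinucleotide {m}")
    for m in kmers(3):
        add(f"c_{m}", "kmer", f"raw count of trinucleotide {m}")
    for m in canonical_trimers():
        add(f"rc3_{m}", "kmer",
            f"frequency of trinucleotide class {m}/{revcomp(m)} (reverse-complement collapsed)")

    add("rep_longest_direct", "repeat", "longest exact direct repeat (two non-identical occurrences)")
    add("rep_n_dup10", "repeat", "distinct 10-mers occurring at least twice")
    add("rep_n_dup20", "repeat", "distinct 20-mers occurring at least twice")
    add("rep_cov10", "repeat", "fraction of positions covered by repeated 10-mers")
    add("rep_longest_tandem", "repeat", "longest tandem repeat total length (unit >= 2 bp, >= 2 copies)")
    add("rep_longest_inv_stem", "repeat", "longest inverted repeat stem length")
    add("rep_n_inv10", "repeat", "inverted repeats with stem >= 10 bp")
    add("rep_longest_palindrome", "repeat", "longest even-length reverse-complement palindrome")
    for b in BASES:
        add(f"run_{b}", "repeat", f"longest homopolymer run of {b}")
    add("rep_longest_dinuc_run", "repeat", "longest dinucleotide tandem run length")
    add("rep_n_homorun5", "repeat", "homopolymer runs >= 5 bp (any base)")
    add("rep_longest_homopolymer", "repeat", "longest homopolymer run over all bases")

    add("gc_global", "gc", "global GC fraction")
    add("dGC", "gc", "max minus min GC fraction over 100 bp sliding windows")
    add("GC_short_l", "gc", "20 bp windows with GC < 0.40")
    add("GC_short_h", "gc", "20 bp windows with GC > 0.60")
    add("GC_long_l", "gc", "100 bp windows with GC < 0.30")
    add("GC_long_h", "gc", "100 bp windows with GC > 0.70")
    add("gc_win100_min", "gc", "minimum 100 bp window GC fraction")
    add("gc_win100_max", "gc", "maximum 100 bp window GC fraction")

    add("Tm_low", "tm", "minimum nearest-neighbor Tm over 20 bp windows (degC)")
    add("Tm_high", "tm", "maximum nearest-neighbor Tm over 20 bp windows (degC)")
    add("Tm_global", "tm", "nearest-neighbor Tm of the whole sequence (degC)")

    add("hp_count", "structure", "hairpins (stem >= 6 bp exact reverse-complement, loop 3-48 bp)")
    add("hp_longest_stem", "structure", "longest hairpin stem length")
    add("hp_max_stem_gc", "structure", "maximum stem GC fraction over hairpins")
    add("hp_strong_count", "structure", "hairpins with stem >= 10 bp")
    add("hp_min_loop", "structure", "minimum loop length among hairpins (0 if none)")
    add("hp_in_first50", "structure", "hairpin starting within the first 50 bp (0/1)")
    add("hp_in_last50", "structure", "hairpin ending within the last 50 bp (0/1)")

    for b in BASES:
        add(f"nrun5_{b}", "specific", f"runs of {b} with length >= 5")
    for b in BASES:
        add(f"nrun8_{b}", "specific", f"runs of {b} with length >= 8")
    add("n_GGGG", "specific", "occurrences of GGGG (overlapping)")
    add("n_CCCC", "specific", "occurrences of CCCC (overlapping)")
    add("n_AT3", "specific", "maximal (AT)n tandems with >= 3 units")
    add("n_GC3", "specific", "maximal (GC)n tandems with >= 3 units")
    add("gc_first30", "specific", "GC fraction of the first 30 bp")
    add("gc_last30", "specific", "GC fraction of the last 30 bp")
    add("term5_homorun4", "specific", "homopolymer run >= 4 within the first 10 bp (0/1)")
    add("term3_homorun4", "specific", "homopolymer run >= 4 within the last 10 bp (0/1)")
    add("n_win20_mono90", "specific", "20 bp windows that are >= 90% a single base")
    add("longest_Grun4", "specific", "longest run of G if >= 4, else 0")
    add("n_GCGCGC", "specific", "occurrences of GCGCGC (overlapping)")
    add("n_ATATAT", "specific", "occurrences of ATATAT (overlapping)")

    for enz, site in RESTRICTION_ENZYMES:
        add(f"site_{enz}", "restriction",
            f"occurrences of {site} (both strands for non-palindromic sites)")

    add("length", "length", "sequence length in bp")
    return tuple(e)


_ENTRIES = _build_entries()


class FeatureManifest:
    """Ordered, named inventory of the 426-feature descriptor."""

    version = MANIFEST_VERSION

    def __init__(self) -> None:
        self.entries = _ENTRIES
        self.names = [en.name for en in self.entries]
        self._index = {n: i for i, n in enumerate(self.names)}
        assert len(self._index) == len(self.names), "feature names must be unique"

    def __len__(self) -> int:
        return len(self.entries)

    def index(self, name: str) -> int:
        return self._index[name]

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for en in self.entries:
            sizes[en.group] = sizes.get(en.group, 0) + 1
        return sizes

    def group_names(self, group: str) -> list[str]:
        return [en.name for en in self.entries if en.group == group]

    def to_table(self, path: str | Path) -> None:
        """Write the manifest as a three-column TSV (name, group, description)."""
        with open(path, "w") as fh:
            fh.write(f"# feature manifest version {self.version}\n")
            fh.write(f"# tm conditions: {TM_CONDITIONS}\n")
            fh.write("name\tgroup\tdescription\n")
            for en in self.entries:
                fh.write(f"{en.name}\t{en.group}\t{en.description}\n")


_MANIFEST: FeatureManifest | None = None


def get_manifest() -> FeatureManifest:
    """The package-wide manifest singleton."""
    global _MANIFEST
    if _MANIFEST is None:
        _MANIFEST = FeatureManifest()
    return _MANIFEST
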