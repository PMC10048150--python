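"""Synthetic DNA with planted synthesis-difficulty determinants.

Sequences are drawn i.i.d. at a target GC content and decorated with
planted elements — low/high-GC patches, direct/tandem/inverted repeats,
homopolymers, motifs — the same determinants the feature extractor
measures. A :class:`DifficultyRule` turns the planted truth into an
EASY/HARD label (optionally with label noise), giving labeled datasets
whose difficulty is by construction a known function of sequence
features. This is the package's test bed: it emulates the structure of a
real synthesis-outcome dataset without emulating synthesis chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .seqio import EASY, HARD, LabeledDataset, SequenceRecord
from .manifest import revcomp

ElementKind = Literal[
    "tandem_repeat",
    "direct_repeat",
    "inverted_repeat",
    "homopolymer",
    "motif",
    "low_gc_patch",
    "high_gc_patch",
]


@dataclass(frozen=True)
class Element:
    """One planted element; `position` None means 'place randomly'."""

    kind: ElementKind
    params: dict
    position: int | None = None

    def span(self) -> int:
        p = self.params
        if self.kind == "tandem_repeat":
            return len(p["unit"]) * p["copies"]
        if self.kind == "direct_repeat":
            return 2 * p["length"] + p["spacing"]
        if self.kind == "inverted_repeat":
            return 2 * p["stem"] + p["loop"]
        if self.kind == "homopolymer":
            return p["run"]
        if self.kind == "motif":
            return len(p["motif"])
        if self.kind in ("low_gc_patch", "high_gc_patch"):
            return p["length"]
        raise ValueError(f"unknown element kind {self.kind!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    length: int
    target_gc: float = 0.5
    elements: tuple[Element, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_gc < 1:
            raise ValueError("target_gc must be in (0, 1)")
        if self.length < 1:
            raise ValueError("length must be positive")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _render(element: Element, rng: np.random.Generator) -> str:
    p = element.params
    k = element.kind
    if k == "tandem_repeat":
        return p["unit"] * p["copies"]
    if k == "direct_repeat":
        unit = p.get("unit") or _random_bases(rng, p["length"], 0.5)
        spacer = _random_bases(rng, p["spacing"], 0.5)
        return unit + spacer + unit
    if k == "inverted_repeat":
        stem = p.get("stem_seq") or _random_bases(rng, p["stem"], p.get("stem_gc", 0.5))
        loop = _random_bases(rng, p["loop"], 0.5)
        return stem + loop + revcomp(stem)
    if k == "homopolymer":
        return p["base"] * p["run"]
    if k == "motif":
        return p["motif"]
    if k == "low_gc_patch":
        return _random_bases(rng, p["length"], p.get("gc", 0.1))
    if k == "high_gc_patch":
        return _random_bases(rng, p["length"], p.get("gc", 0.9))
    raise ValueError(f"unknown element kind {k!r}")


def generate_sequence(spec: SyntheticSpec, id: str = "synthetic") -> SequenceRecord:
    """Background bases i.i.d. at target_gc with planted elements written
    over non-overlapping spans. Deterministic given the spec seed."""
    rng = np.random.default_rng(spec.seed)
    seq = list(_random_bases(rng, spec.length, spec.target_gc))
    placed: list[tuple[int, int]] = []
    for el in spec.elements:
        rendered = _render(el, rng)
        span = len(rendered)
        if span > spec.length:
            raise ValueError(f"element {el.kind} (span {span}) exceeds length {spec.length}")
        if el.position is not None:
            start = el.position
            if start + span > spec.length:
                raise ValueError(f"element {el.kind} at {start} exceeds the sequence")
            if any(start < e and s < start + span for s, e in placed):
                raise ValueError(f"element {el.kind} at {start} overlaps another element")
        else:
            start = None
            for _ in range(200):
                cand = int(rng.integers(0, spec.length - span + 1))
                if not any(cand < e and s < cand + span for s, e in placed):
                    start = cand
                    break
            if start is None:
                raise ValueError("could not place all elements without overlap")
        seq[start : start + span] = rendered
        placed.append((start, start + span))
    return SequenceRecord(id=id, seq="".join(seq))


@dataclass(frozen=True)
class DifficultyRule:
    """HARD iff any planted-truth threshold fires, then label noise.

    The rule is evaluated on the *planted* elements of a spec (the ground
    truth), not on extracted features: a sequence is HARD when it carries
    a GC patch at least `gc_patch_len` long, a direct/tandem repeat of at
    least `repeat_len` total bases, or at least `min_hairpins` inverted
    repeats. `noise` flips each label independently.
    """

    gc_patch_len: int = 50
    repeat_len: int = 20
    min_hairpins: int = 1
    noise: float = 0.0

    def label(self, spec: SyntheticSpec) -> str:
        hairpins = 0
        for el in spec.elements:
            k, p = el.kind, el.params
            if k in ("low_gc_patch", "high_gc_patch") and p["length"] >= self.gc_patch_len:
                return HARD
            if k == "direct_repeat" and 2 * p["length"] >= self.repeat_len:
                return HARD
            if k == "tandem_repeat" and len(p["unit"]) * p["copies"] >= self.repeat_len:
                return HARD
            if k == "homopolymer" and p["run"] >= self.repeat_len:
                return HARD
            if k == "inverted_repeat":
                hairpins += 1
        if hairpins >= self.min_hairpins:
            return HARD
        return EASY


#: Planted element menus used by generate_labeled_dataset. HARD sequences
#: carry one or more strong determinants; EASY sequences carry none (their
#: background is plain i.i.d. sequence).
def _hard_elements(rng: np.random.Generator, length: int) -> tuple[Element, ...]:
    choices = []
    kind = rng.integers(3)
    if kind == 0:  # GC anomaly: a long low-GC patch (drives dGC and GC_long_l)
        choices.append(
            Element("low_gc_patch", {"length": int(rng.integers(100, 140)), "gc": 0.08})
        )
    elif kind == 1:  # long direct repeat
        choices.append(
            Element(
                "direct_repeat",
                {"length": int(rng.integers(20, 30)), "spacing": int(rng.integers(10, 40))},
            )
        )
    else:  # strong hairpin
        choices.append(
            Element(
                "inverted_repeat",
                {"stem": int(rng.integers(12, 18)), "loop": int(rng.integers(4, 9))},
            )
        )
    if rng.random() < 0.3:  # occasionally a second determinant
        choices.append(Element("homopolymer", {"base": "A", "run": int(rng.integers(20, 26))}))
    return tuple(choices)


def generate_labeled_dataset(
    n: int,
    rule: DifficultyRule = DifficultyRule(),
    class_balance: float = 0.5,
    length: int = 500,
    target_gc: float = 0.5,
    seed: int = 0,
    id_prefix: str = "syn",
) -> LabeledDataset:
    """n sequences whose HARD fraction is ~class_balance; labels come from
    the rule applied to the planted truth, then flipped at the rule's
    noise rate. Deterministic given seed."""
    if n < 20:
        raise ValueError("need at least 20 sequences for a labeled dataset")
    if not 0 < class_balance < 1:
        raise ValueError("class_balance must be in (0, 1)")
    # separate streams so the noise rate does not perturb the sequences
    ss = np.random.SeedSequence(seed)
    rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for i in range(n):
        make_hard = rng.random() < class_balance
        elements = _hard_elements(rng, length) if make_hard else ()
        spec = SyntheticSpec(
            length=length,
            target_gc=target_gc,
            elements=elements,
            seed=int(rng.integers(2**31)),
        )
        sid = f"{id_prefix}{i:04d}"
        records.append(generate_sequence(spec, id=sid))
        lab = rule.label(spec)
        if noise_rng.random() < rule.noise:
            lab = EASY if lab == HARD else HARD
        labels[sid] = lab
    n_hard = sum(1 for v in labels.values() if v == HARD)
    if n_hard == 0 or n_hard == n:
        raise ValueError(
            "generated dataset is single-class; adjust class_balance or rule"
        )
    return LabeledDataset(records=records, labels=labels)


def informative_noise_matrix(
    n_rows: int = 200,
    n_informative: int = 5,
    n_noise: int = 50,
    effect: float = 2.0,
    seed: int = 0,
):
    """A numeric benchmark for wrapper selection: `n_informative` features
    are the label plus Gaussian noise (effect = mean separation in sd
    units), the rest are pure noise. Returns (DataFrame, labels,
    informative_names)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n_rows)
    info = y[:, None] * effect + rng.normal(size=(n_rows, n_informative))
    noise = rng.normal(size=(n_rows, n_noise))
    names = [f"inf{i}" for i in range(n_informative)] + [
        f"noise{i}" for i in range(n_noise)
    ]
    X = pd.DataFrame(np.hstack([info, noise]), columns=names)
    labels = [HARD if v else EASY for v in y]
    return X, labels, names[:n_informative]
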