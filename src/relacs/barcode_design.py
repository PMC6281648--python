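"""Nuclear barcode sets and hairpin adapter construction.

RELACS marks each sample by ligating a hairpin adapter carrying a short inline
barcode to both blunt(-then-A-tailed) ends of every chromatin fragment.  After
sequencing, each mate of a read pair starts with the barcode, so sample
identity is decoded from the read prefix under a per-mate mismatch budget.

A barcode set tolerating up to ``m`` substitutions per mate decodes uniquely
iff its minimum pairwise Hamming distance is at least ``2m + 1`` — the classic
sphere-packing condition.  ``validate_barcode_set`` enforces exactly that and
additionally warns about homopolymer runs and extreme GC, which hurt synthesis
and sequencing quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from relacs.genome_digest import reverse_complement

_DNA = "ACGT"


@dataclass(frozen=True)
class Barcode:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"barcode {self.id!r}: empty sequence")
        bad = set(seq) - set(_DNA)
        if bad:
            raise ValueError(f"barcode {self.id!r}: non-ACGT characters {sorted(bad)}")


class BarcodeSet:
    """A collection of equal-length barcodes with unique ids."""

    def __init__(self, barcodes: list[Barcode]):
        if not barcodes:
            raise ValueError("barcode set is empty")
        ids = [b.id for b in barcodes]
        if len(set(ids)) != len(ids):
            raise ValueError("barcode ids must be unique")
        lengths = {len(b.sequence) for b in barcodes}
        if len(lengths) != 1:
            raise ValueError(f"barcodes must share one length, got {sorted(lengths)}")
        seqs = [b.sequence for b in barcodes]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate barcode sequences")
        self.barcodes = list(barcodes)
        self.length = lengths.pop()

    @property
    def ids(self) -> list[str]:
        return [b.id for b in self.barcodes]

    @property
    def sequences(self) -> list[str]:
        return [b.sequence for b in self.barcodes]

    @property
    def min_distance(self) -> int:
        return min_pairwise_distance(self)

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)

    def __getitem__(self, bc_id: str) -> Barcode:
        for b in self.barcodes:
            if b.id == bc_id:
                return b
        raise KeyError(bc_id)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    return sum(x != y for x, y in zip(a, b))


def min_pairwise_distance(bc_set: BarcodeSet) -> int:
    """Minimum Hamming distance over all unordered barcode pairs."""
    if len(bc_set) < 2:
        raise ValueError("need at least 2 barcodes")
    seqs = bc_set.sequences
    return min(
        hamming(seqs[i], seqs[j])
        for i in range(len(seqs))
        for j in range(i + 1, len(seqs))
    )


@dataclass
class ValidationReport:
    passed: bool
    min_distance: int
    required_distance: int
    max_mismatch: int
    violating_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "min_distance": self.min_distance,
            "required_distance": self.required_distance,
            "max_mismatch": self.max_mismatch,
            "violating_pairs": [list(p) for p in self.violating_pairs],
            "warnings": self.warnings,
        }


def validate_barcode_set(bc_set: BarcodeSet, max_mismatch: int = 1) -> ValidationReport:
    """Check that a set decodes uniquely under a per-mate mismatch budget.

    PASS iff the minimum pairwise Hamming distance is at least
    ``2 * max_mismatch + 1``, which guarantees that any read prefix carrying
    at most ``max_mismatch`` substitutions has a unique nearest barcode — its
    true one.  Homopolymer runs of 4+ and GC content outside 25–75% are
    reported as warnings only.
    """
    required = 2 * max_mismatch + 1
    seqs = bc_set.sequences
    ids = bc_set.ids
    violations = []
    min_d = bc_set.length
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d = hamming(seqs[i], seqs[j])
            min_d = min(min_d, d)
            if d < required:
                violations.append((ids[i], ids[j], d))
    warns = []
    for bc in bc_set:
        longest = 1
        current = 1
        for a, b in zip(bc.sequence, bc.sequence[1:]):
            current = current + 1 if a == b else 1
            longest = max(longest, current)
        if longest >= 4:
            warns.append(f"{bc.id}: homopolymer run of {longest}")
        gc = (bc.sequence.count("G") + bc.sequence.count("C")) / len(bc.sequence)
        if not 0.25 <= gc <= 0.75:
            warns.append(f"{bc.id}: GC content {gc:.0%} outside [25%, 75%]")
    return ValidationReport(
        passed=not violations,
        min_distance=min_d,
        required_distance=required,
        max_mismatch=max_mismatch,
        violating_pairs=violations,
        warnings=warns,
    )


def generate_barcode_set(
    n: int,
    length: int = 8,
    min_distance: int = 3,
    seed: int = 0,
    max_tries: int = 100_000,
) -> BarcodeSet:
    """Greedy seeded construction of a random barcode set.

    Draws random sequences and keeps those at Hamming distance at least
    ``min_distance`` from all accepted ones, until ``n`` are collected.
    """
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    tries = 0
    while len(accepted) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not build {n} barcodes of length {length} at distance "
                f">= {min_distance} in {max_tries} draws"
            )
        cand = "".join(_DNA[i] for i in rng.integers(0, 4, size=length))
        if all(hamming(cand, s) >= min_distance for s in accepted):
            accepted.append(cand)
    return BarcodeSet([Barcode(f"BC{i + 1:02d}", s) for i, s in enumerate(accepted)])


# --- hairpin adapters -------------------------------------------------------

#: Slot marker replaced by the barcode sequence inside a template.
BARCODE_SLOT = "[BC]"


@dataclass(frozen=True)
class HairpinTemplate:
    """Schematic single-strand hairpin adapter architecture.

    The oligo self-anneals: a 5' stem arm pairs with its reverse complement
    after a loop that carries one cleavable base (deoxyuridine, written ``U``)
    which is excised enzymatically to open the hairpin before PCR.  The
    barcode sits in the ``[BC]`` slot; a 3' T-overhang pairs with A-tailed
    fragment ends during ligation.  The default is a schematic stand-in, not
    a published oligo — real adapter sequences are supplied by the user.
    """

    name: str = "schematic-v1"
    stem: str = "GCTGACGT"
    loop: str = "ACUCA"  # exactly one cleavable U
    slot_length: int = 8
    t_overhang: bool = True

    @property
    def sequence(self) -> str:
        tail = "T" if self.t_overhang else ""
        return self.stem + self.loop + reverse_complement(self.stem.replace("U", "T")) + BARCODE_SLOT + tail


@dataclass(frozen=True)
class HairpinAdapter:
    barcode: Barcode
    full_sequence: str
    template_name: str
    t_overhang: bool


def build_hairpin(barcode: Barcode, template: HairpinTemplate = HairpinTemplate()) -> HairpinAdapter:
    """Substitute a barcode into a hairpin template's slot."""
    if len(barcode.sequence) != template.slot_length:
        raise ValueError(
            f"barcode {barcode.id!r} length {len(barcode.sequence)} != template "
            f"slot length {template.slot_length}"
        )
    tpl = template.sequence
    if tpl.count(BARCODE_SLOT) != 1:
        raise ValueError("template must contain exactly one barcode slot")
    return HairpinAdapter(
        barcode=barcode,
        full_sequence=tpl.replace(BARCODE_SLOT, barcode.sequence),
        template_name=template.name,
        t_overhang=template.t_overhang,
    )


def expected_read_prefix(barcode: Barcode, junction_bases: int = 1, junction_base: str = "T") -> str:
    """Prefix an error-free read of this sample starts with.

    After hairpin opening and A-tailing chemistry, each mate begins with the
    barcode followed by ``junction_bases`` fixed bases (one T by default)
    before the genomic insert.
    """
    if junction_bases < 0:
        raise ValueError("junction_bases must be >= 0")
    return barcode.sequence + junction_base * junction_bases
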