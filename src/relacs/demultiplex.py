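"""Paired-end inline-barcode demultiplexing.

Each mate of a RELACS read pair begins with the sample's nuclear barcode
(both fragment ends were ligated to the same sample's hairpin adapter).  Both
mates are decoded independently against the barcode set by Hamming distance
over the first ``L`` bases; pairs whose mates disagree, carry more than the
allowed mismatches, have no match, or tie between barcodes are discarded with
a categorized reason.  Assigned pairs have barcode + junction base(s) trimmed
from the 5' end of both mates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd

from relacs.barcode_design import BarcodeSet

DISCARD_REASONS = ("no_match", "mismatch_exceeded", "ambiguous", "mate_disagreement", "too_short")


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class DemuxOptions:
    max_mismatch: int = 1
    junction_bases: int = 1
    require_mate_agreement: bool = True
    count_N_as_mismatch: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatch < 0 or self.junction_bases < 0:
            raise ValueError("max_mismatch and junction_bases must be >= 0")


@dataclass(frozen=True)
class BarcodeCall:
    """Decoding outcome for a single mate's prefix."""

    barcode_id: Optional[str]
    mismatches: Optional[int]
    reason: Optional[str] = None

    @property
    def assigned(self) -> bool:
        return self.barcode_id is not None


@dataclass(frozen=True)
class Assignment:
    """Decoding outcome for a read pair."""

    read_id: str
    barcode_id: Optional[str]
    mismatches1: Optional[int] = None
    mismatches2: Optional[int] = None
    reason: Optional[str] = None

    @property
    def assigned(self) -> bool:
        return self.barcode_id is not None


def _mismatches(prefix: str, barcode: str, n_is_mismatch: bool) -> int:
    d = 0
    for p, b in zip(prefix, barcode):
        if p != b and (n_is_mismatch or p != "N"):
            d += 1
    return d


def assign_barcode(
    prefix: str,
    bc_set: BarcodeSet,
    max_mismatch: int = 1,
    count_N_as_mismatch: bool = True,
) -> BarcodeCall:
    """Decode a read prefix to the unique nearest barcode within budget.

    The first ``L`` bases are compared to every barcode; the unique barcode at
    minimal Hamming distance <= ``max_mismatch`` wins.  Ties at the minimal
    distance are ``ambiguous``; a best distance beyond the budget is
    ``no_match`` when the prefix does not resemble any barcode (best distance
    greater than L/2) and ``mismatch_exceeded`` otherwise.
    """
    if len(bc_set) == 0:
        raise ValueError("empty barcode set")
    L = bc_set.length
    if len(prefix) < L:
        return BarcodeCall(None, None, "too_short")
    head = prefix[:L]
    best_id = None
    best_d = L + 1
    tied = False
    for bc in bc_set:
        d = _mismatches(head, bc.sequence, count_N_as_mismatch)
        if d < best_d:
            best_d, best_id, tied = d, bc.id, False
        elif d == best_d:
            tied = True
    if best_d > max_mismatch:
        reason = "no_match" if best_d > L // 2 else "mismatch_exceeded"
        return BarcodeCall(None, None, reason)
    if tied:
        return BarcodeCall(None, None, "ambiguous")
    return BarcodeCall(best_id, best_d)


@dataclass
class DemuxStats:
    total: int = 0
    assigned: Counter = field(default_factory=Counter)  # barcode id -> pairs
    discarded: Counter = field(default_factory=Counter)  # reason -> pairs

    @property
    def n_assigned(self) -> int:
        return sum(self.assigned.values())

    @property
    def n_discarded(self) -> int:
        return sum(self.discarded.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("assigned", k, v) for k, v in sorted(self.assigned.items())]
        rows += [("discarded", k, v) for k, v in sorted(self.discarded.items())]
        return pd.DataFrame(rows, columns=["outcome", "category", "pairs"])

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "assigned": dict(self.assigned),
            "discarded": dict(self.discarded),
        }


def _strip_mate_suffix(read_id: str) -> str:
    rid = read_id.split()[0]
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid


def demux_pairs(
    pairs: Iterable[ReadPair],
    bc_set: BarcodeSet,
    options: DemuxOptions = DemuxOptions(),
    sink=None,
) -> tuple[list[Assignment], DemuxStats]:
    """Demultiplex a stream of read pairs.

    Both mates are decoded independently.  With ``require_mate_agreement``
    (the default; each fragment is barcoded at both ends with the same
    sample's adapter by construction) a pair is assigned only when both mates
    decode to the same barcode.  Assigned pairs are trimmed by barcode length
    plus junction bases on both mates and handed to ``sink.write(sample_id,
    pair)`` when a sink is given; discarded pairs go to the ``undetermined``
    sample.  Returns the per-pair assignments and aggregate stats.
    """
    trim = bc_set.length + options.junction_bases
    # exact-match shortcut: distance 0 is always the unique winner since
    # barcode sequences are distinct
    exact = {bc.sequence: bc.id for bc in bc_set}
    L = bc_set.length

    assignments: list[Assignment] = []
    stats = DemuxStats()
    for pair in pairs:
        stats.total += 1
        calls = []
        for seq in (pair.seq1, pair.seq2):
            head = seq[:L]
            hit = exact.get(head)
            if hit is not None:
                calls.append(BarcodeCall(hit, 0))
            else:
                calls.append(
                    assign_barcode(seq, bc_set, options.max_mismatch, options.count_N_as_mismatch)
                )
        c1, c2 = calls
        if not c1.assigned or not c2.assigned:
            reason = c1.reason or c2.reason
            asg = Assignment(pair.read_id, None, c1.mismatches, c2.mismatches, reason)
        elif options.require_mate_agreement and c1.barcode_id != c2.barcode_id:
            asg = Assignment(pair.read_id, None, c1.mismatches, c2.mismatches, "mate_disagreement")
        else:
            asg = Assignment(pair.read_id, c1.barcode_id, c1.mismatches, c2.mismatches)
        assignments.append(asg)
        if asg.assigned:
            stats.assigned[asg.barcode_id] += 1
            if sink is not None:
                sink.write(
                    asg.barcode_id,
                    ReadPair(
                        pair.read_id,
                        pair.seq1[trim:], pair.qual1[trim:],
                        pair.seq2[trim:], pair.qual2[trim:],
                    ),
                )
        else:
            stats.discarded[asg.reason] += 1
            if sink is not None:
                sink.write("undetermined", pair)
    return assignments, stats


def pair_fastq_records(records1, records2) -> Iterator[ReadPair]:
    """Zip two synchronized FASTQ record streams into read pairs.

    Raises on the first record-ID mismatch (desynchronized mate files) and
    when one file ends before the other.
    """
    _SENTINEL = object()
    from itertools import zip_longest

    for rec1, rec2 in zip_longest(records1, records2, fillvalue=_SENTINEL):
        if rec1 is _SENTINEL or rec2 is _SENTINEL:
            raise ValueError("mate FASTQ files have different record counts")
        id1, id2 = _strip_mate_suffix(rec1.id), _strip_mate_suffix(rec2.id)
        if id1 != id2:
            raise ValueError(f"desynchronized mate files at record {rec1.id!r} vs {rec2.id!r}")
        q1 = "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"])
        yield ReadPair(id1, str(rec1.seq).upper(), q1, str(rec2.seq).upper(), q2)


def contamination_matrix(assignments: list[Assignment], truth: dict[str, str]) -> pd.DataFrame:
    """Cross-tabulate truth barcode vs assigned barcode for assigned pairs.

    ``truth`` maps read id to the true barcode id (e.g. from a simulator
    manifest).  Off-diagonal mass over total assigned is the contamination
    rate.  Raises if any assigned read id is missing from the truth.
    """
    assigned = [a for a in assignments if a.assigned]
    missing = [a.read_id for a in assigned if a.read_id not in truth]
    if missing:
        raise KeyError(f"{len(missing)} assigned read id(s) missing from truth, e.g. {missing[:5]}")
    if not assigned:
        return pd.DataFrame(dtype=int).rename_axis(index="truth", columns="assigned")
    labels = sorted({truth[a.read_id] for a in assigned} | {a.barcode_id for a in assigned})
    t = pd.Categorical([truth[a.read_id] for a in assigned], categories=labels)
    s = pd.Categorical([a.barcode_id for a in assigned], categories=labels)
    mat = pd.crosstab(t, s, dropna=False)
    mat.index = pd.Index(labels, name="truth")
    mat.columns = pd.Index(labels, name="assigned")
    return mat


def contamination_rate(matrix: pd.DataFrame) -> float:
    """Off-diagonal fraction of a contamination matrix; 0.0 when empty."""
    total = int(matrix.to_numpy().sum())
    if total == 0:
        return 0.0
    import numpy as np

    diag = int(np.trace(matrix.to_numpy()))
    return (total - diag) / total
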