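"""In-silico restriction digestion with degenerate IUPAC motifs.

The RELACS protocol fragments chromatin with CviKI-1, a methylation-insensitive
blunt cutter whose degenerate recognition site is RG|CY (R = A/G, Y = C/T, the
bar marks the cut).  This module scans genome sequences for such motifs,
derives the fragment structure the digestion implies, and quantifies two
protocol biases:

* **gaps / blind regions** — inter-site intervals too long to be sequenced as
  a single fragment, hence invisible to the assay;
* **cutability and accessibility** — restriction-site density per chromatin
  state (sites/kbp) and how often existing sites are actually used as observed
  fragment ends (ends per site).

Coordinates are 0-based, half-open throughout.  A cut site is recorded as the
position of the first base 3' of the blunt cut (match start + ``cut_offset``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# IUPAC nucleotide codes mapped to the set of concrete bases they stand for.
# A genome base matches a pattern code only if it is a concrete A/C/G/T inside
# that code's set; an N (or any ambiguity code) in the *genome* never matches.
IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string, IUPAC ambiguity codes included."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DegenerateMotif:
    """A restriction recognition motif over the IUPAC alphabet.

    Parameters
    ----------
    pattern
        Recognition sequence, e.g. ``"RGCY"`` for CviKI-1.
    cut_offset
        Distance in bp from the pattern start to the cut; the recorded cut
        position is the first base 3' of the cut.
    blunt
        Whether the enzyme leaves blunt ends (CviKI-1 does, which is what
        makes single-base A-tailing/ligation chemistry possible).
    """

    pattern: str
    cut_offset: int = 2
    blunt: bool = True

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        if len(pat) < 1:
            raise ValueError("motif pattern must be non-empty")
        bad = sorted(set(pat) - set(IUPAC_CODES))
        if bad:
            raise ValueError(f"invalid IUPAC code(s) in motif pattern: {bad}")
        if not 0 <= self.cut_offset <= len(pat):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside [0, {len(pat)}]"
            )

    @property
    def is_palindromic(self) -> bool:
        """True if the motif equals its own reverse complement as a
        degenerate pattern (RGCY does), in which case forward-strand
        scanning already yields every cut site."""
        return reverse_complement(self.pattern) == self.pattern


#: The enzyme used by the RELACS protocol: CviKI-1, RG|CY, blunt.
CVIKI_1 = DegenerateMotif("RGCY", cut_offset=2, blunt=True)


class GenomeSequence:
    """Named chromosome sequences over the DNA alphabet (IUPAC codes allowed).

    Sequences are upper-cased on construction; chromosome order is preserved.
    """

    def __init__(self, chromosomes: Mapping[str, str]):
        if not chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        self.chromosomes: dict[str, str] = {}
        for name, seq in chromosomes.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if name in self.chromosomes:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            self.chromosomes[name] = seq.upper()

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for seq in self.chromosomes.values())

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __repr__(self) -> str:
        return (
            f"GenomeSequence({len(self)} chromosomes, "
            f"{self.total_length:,} bp)"
        )


@dataclass
class SiteIndex:
    """Per-chromosome sorted cut positions from a degenerate-motif digestion."""

    motif: DegenerateMotif
    sites: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, pos in self.sites.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: site positions must be 1-D")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{chrom}: cut positions must be strictly increasing")
            self.sites[chrom] = arr

    @property
    def total_sites(self) -> int:
        return int(sum(arr.size for arr in self.sites.values()))

    def __repr__(self) -> str:
        return f"SiteIndex({self.motif.pattern}, {self.total_sites:,} sites)"


@dataclass
class FragmentMap:
    """Half-open fragments between consecutive cut sites, per chromosome."""

    fragments: dict[str, np.ndarray]  # (n, 2) int64 arrays of [start, end)
    terminal_included: bool

    def lengths(self) -> np.ndarray:
        parts = [arr[:, 1] - arr[:, 0] for arr in self.fragments.values() if arr.size]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    @property
    def n_fragments(self) -> int:
        return int(sum(arr.shape[0] for arr in self.fragments.values()))


@dataclass
class GapReport:
    """Restriction gaps ("blind regions") longer than a threshold."""

    threshold: int
    gaps: list[tuple[str, int, int]]
    genome_length: int
    include_terminal: bool

    @property
    def n_gaps(self) -> int:
        return len(self.gaps)

    @property
    def gap_bases(self) -> int:
        return sum(end - start for _, start, end in self.gaps)

    @property
    def blind_fraction(self) -> float:
        return self.gap_bases / self.genome_length if self.genome_length else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.gaps, columns=["chrom", "start", "end"])

    def summary(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_gaps": self.n_gaps,
            "gap_bases": self.gap_bases,
            "blind_fraction": self.blind_fraction,
            "include_terminal": self.include_terminal,
        }


class IntervalSet:
    """Labelled genomic intervals (chromatin states, peaks, blacklists).

    Intervals are 0-based half-open ``(chrom, start, end, label)`` tuples.
    With ``merge=True`` abutting/overlapping intervals of the same class are
    merged per chromosome on construction.
    """

    def __init__(
        self,
        intervals: Iterable[tuple[str, int, int, str]],
        merge: bool = False,
    ):
        rows = []
        for chrom, start, end, label in intervals:
            if not 0 <= start < end:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
            rows.append((chrom, int(start), int(end), str(label)))
        self._df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
        if merge and len(self._df):
            self._df = self._merged_frame()

    def _merged_frame(self) -> pd.DataFrame:
        merged = []
        for (label, chrom), grp in self._df.groupby(["label", "chrom"], sort=False):
            ivs = grp[["start", "end"]].sort_values("start").to_numpy()
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e, label))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e, label))
        df = pd.DataFrame(merged, columns=["chrom", "start", "end", "label"])
        return df.sort_values(["chrom", "start"], ignore_index=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def classes(self) -> list[str]:
        return list(dict.fromkeys(self._df["label"]))

    def __len__(self) -> int:
        return len(self._df)

    def by_class(self, label: str) -> dict[str, np.ndarray]:
        """Merged intervals of one class as ``{chrom: (n, 2) array}``."""
        sub = self._df[self._df["label"] == label]
        out: dict[str, np.ndarray] = {}
        for chrom, grp in sub.groupby("chrom", sort=False):
            ivs = grp[["start", "end"]].sort_values("start").to_numpy(dtype=np.int64)
            merged = []
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((cur_s, cur_e))
            out[chrom] = np.asarray(merged, dtype=np.int64)
        return out

    def class_length(self, label: str) -> int:
        return int(
            sum((ivs[:, 1] - ivs[:, 0]).sum() for ivs in self.by_class(label).values())
        )


def _membership(positions: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask: which positions fall inside any half-open interval.

    ``intervals`` must be merged, sorted, non-overlapping (n, 2).
    """
    if intervals.size == 0 or positions.size == 0:
        return np.zeros(positions.size, dtype=bool)
    bounds = intervals.ravel()  # s1 e1 s2 e2 ... strictly increasing
    idx = np.searchsorted(bounds, positions, side="right")
    return idx % 2 == 1


def _pattern_luts(pattern: str) -> list[np.ndarray]:
    luts = []
    for ch in pattern:
        lut = np.zeros(256, dtype=bool)
        for base in IUPAC_CODES[ch]:
            lut[ord(base)] = True
        luts.append(lut)
    return luts


def _scan_one(seq_bytes: np.ndarray, pattern: str) -> np.ndarray:
    """Start positions of all (possibly overlapping) IUPAC pattern matches."""
    n, L = seq_bytes.size, len(pattern)
    if n < L:
        return np.empty(0, dtype=np.int64)
    match = np.ones(n - L + 1, dtype=bool)
    for i, lut in enumerate(_pattern_luts(pattern)):
        match &= lut[seq_bytes[i : n - L + 1 + i]]
    return np.nonzero(match)[0].astype(np.int64)


def scan_sites(
    genome: GenomeSequence,
    motif: DegenerateMotif = CVIKI_1,
    scan_reverse: bool | None = None,
) -> SiteIndex:
    """Find all cut positions of a degenerate motif in a genome.

    The forward strand is scanned for every (overlapping) match of the IUPAC
    pattern; each match at position ``s`` yields a cut at ``s + cut_offset``.
    Genome bases match a pattern code only when they are concrete A/C/G/T
    contained in the code's set — N runs therefore never produce sites.

    For palindromic degenerate motifs such as RGCY the forward scan is
    complete.  For non-palindromic motifs, pass ``scan_reverse=True`` (the
    default ``None`` auto-enables it) to also scan the reverse strand: a
    reverse-strand match starting at ``s`` cuts at ``s + len - cut_offset``.
    Cut positions from both strands are merged and deduplicated.
    """
    if scan_reverse is None:
        scan_reverse = not motif.is_palindromic
    L = len(motif.pattern)
    sites: dict[str, np.ndarray] = {}
    for chrom, seq in genome.chromosomes.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        pos = _scan_one(arr, motif.pattern) + motif.cut_offset
        if scan_reverse:
            rc_pos = _scan_one(arr, reverse_complement(motif.pattern))
            rc_cuts = rc_pos + (L - motif.cut_offset)
            pos = np.unique(np.concatenate([pos, rc_cuts]))
        sites[chrom] = pos
    return SiteIndex(motif=motif, sites=sites)


def build_fragments(
    sites: SiteIndex,
    genome: GenomeSequence,
    include_terminal: bool = False,
) -> FragmentMap:
    """Fragments implied by a digestion: intervals between consecutive cuts.

    With ``include_terminal`` the chromosome-leading segment ``[0, first)``
    and trailing segment ``[last, length)`` are appended (empty segments are
    dropped), so fragments tile each chromosome exactly.
    """
    fragments: dict[str, np.ndarray] = {}
    for chrom, pos in sites.sites.items():
        if chrom not in genome:
            raise ValueError(f"chromosome {chrom!r} in site index but not in genome")
        length = len(genome[chrom])
        if pos.size and (pos[0] < 0 or pos[-1] > length):
            raise ValueError(f"{chrom}: cut positions outside [0, {length}]")
        if include_terminal:
            bounds = np.concatenate([[0], pos, [length]])
        else:
            bounds = pos
        if bounds.size >= 2:
            frag = np.column_stack([bounds[:-1], bounds[1:]])
            frag = frag[frag[:, 1] > frag[:, 0]]  # drop empty edge segments
        else:
            frag = np.empty((0, 2), dtype=np.int64)
        fragments[chrom] = frag.astype(np.int64)
    return FragmentMap(fragments=fragments, terminal_included=include_terminal)


def gap_report(
    sites: SiteIndex,
    genome: GenomeSequence,
    threshold: int = 1000,
    include_terminal: bool = False,
) -> GapReport:
    """Inter-site intervals strictly longer than ``threshold`` bp.

    Fragments longer than what short-read sequencing can span are invisible to
    the assay; the blind fraction is their combined length over the total
    genome length.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fmap = build_fragments(sites, genome, include_terminal=include_terminal)
    gaps: list[tuple[str, int, int]] = []
    for chrom in genome:  # genome order
        frag = fmap.fragments.get(chrom)
        if frag is None or frag.size == 0:
            continue
        long = frag[(frag[:, 1] - frag[:, 0]) > threshold]
        gaps.extend((chrom, int(s), int(e)) for s, e in long)
    return GapReport(
        threshold=threshold,
        gaps=gaps,
        genome_length=genome.total_length,
        include_terminal=include_terminal,
    )


@dataclass
class SiteDensityTable:
    """Restriction sites per kbp of each region class ("cutability")."""

    frame: pd.DataFrame  # index: class; columns: site_count, class_kbp, sites_per_kbp
    skipped: list[str] = field(default_factory=list)


def site_density_by_class(sites: SiteIndex, states: IntervalSet) -> SiteDensityTable:
    """Count cut positions per region class and divide by class length in kbp.

    Intervals of a class are merged before counting, so splitting an interval
    into abutting sub-intervals of the same class does not change the result.
    Classes with zero total length are omitted with a warning record.
    """
    if len(states) == 0:
        raise ValueError("states interval set is empty")
    rows = {}
    skipped: list[str] = []
    for label in states.classes:
        ivs = states.by_class(label)
        class_bp = int(sum((a[:, 1] - a[:, 0]).sum() for a in ivs.values()))
        if class_bp == 0:
            skipped.append(label)
            warnings.warn(f"class {label!r} has zero total length; omitted")
            continue
        count = 0
        for chrom, arr in ivs.items():
            pos = sites.sites.get(chrom)
            if pos is not None and pos.size:
                count += int(_membership(pos, arr).sum())
        rows[label] = (count, class_bp / 1000.0, count / (class_bp / 1000.0))
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=["site_count", "class_kbp", "sites_per_kbp"]
    )
    frame.index.name = "class"
    return SiteDensityTable(frame=frame, skipped=skipped)


@dataclass
class CutUsageTable:
    """Observed fragment ends per restriction site ("accessibility")."""

    frame: pd.DataFrame  # index: class; n_sites, observed_fragment_ends, ends_per_site, relative_usage
    genome_wide_mean: float
    n_violations: int  # fragment ends not coinciding with any cut position


def cut_usage(
    sites: SiteIndex,
    observed_fragments: Sequence[tuple[str, int, int]],
    states: IntervalSet,
) -> CutUsageTable:
    """Accessibility per region class: observed fragment ends per cut site.

    Each observed fragment contributes its two boundary positions.  Ends that
    do not coincide with a cut position of the index are tallied as violations
    and excluded from usage.  ``relative_usage`` is each class's ends-per-site
    divided by the genome-wide mean, so equal accessibility everywhere reads
    as 1.0.
    """
    if len(observed_fragments) == 0:
        raise ValueError("empty observation set")
    # gather ends per chromosome
    ends_by_chrom: dict[str, list[int]] = {}
    for chrom, start, end in observed_fragments:
        ends_by_chrom.setdefault(chrom, []).extend((int(start), int(end)))

    n_violations = 0
    valid_by_chrom: dict[str, np.ndarray] = {}
    for chrom, ends in ends_by_chrom.items():
        pos = sites.sites.get(chrom, np.empty(0, dtype=np.int64))
        arr = np.asarray(ends, dtype=np.int64)
        if pos.size == 0:
            on_site = np.zeros(arr.size, dtype=bool)
        else:
            idx = np.searchsorted(pos, arr)
            on_site = (idx < pos.size) & (pos[np.minimum(idx, pos.size - 1)] == arr)
        n_violations += int((~on_site).sum())
        valid_by_chrom[chrom] = arr[on_site]

    total_sites = sites.total_sites
    total_ends = int(sum(a.size for a in valid_by_chrom.values()))
    genome_wide = total_ends / total_sites if total_sites else 0.0

    rows = {}
    for label in states.classes:
        ivs = states.by_class(label)
        n_sites = 0
        n_ends = 0
        for chrom, arr in ivs.items():
            pos = sites.sites.get(chrom)
            if pos is not None and pos.size:
                n_sites += int(_membership(pos, arr).sum())
            ve = valid_by_chrom.get(chrom)
            if ve is not None and ve.size:
                n_ends += int(_membership(ve, arr).sum())
        eps = n_ends / n_sites if n_sites > 0 else np.nan
        rel = eps / genome_wide if genome_wide > 0 and n_sites > 0 else np.nan
        rows[label] = (n_sites, n_ends, eps, rel)
    frame = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["n_sites", "observed_fragment_ends", "ends_per_site", "relative_usage"],
    )
    frame.index.name = "class"
    return CutUsageTable(frame=frame, genome_wide_mean=genome_wide, n_violations=n_violations)
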