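"""Synthetic RELACS experiment generator with ground truth.

Emulates the generative process of the protocol at desk scale: a random
genome with a chosen GC content partitioned into labelled region classes
(e.g. open vs closed chromatin), in-silico RG|CY digestion, fragment sampling
weighted by class accessibility (times a ChIP enrichment multiplier when
simulating a ChIP rather than an input), per-sample barcode + junction-base
prefixes on both mates, i.i.d. substitution sequencing errors, flat duplicate
re-emission, optional chimeric pairs, and a complete truth manifest linking
every read pair to its sample and genomic fragment.

What it deliberately does not model: PCR amplification bias beyond flat
duplicates, indels, quality-score error profiles, mappability, or the outer
Illumina-index multiplexing layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np

from relacs.barcode_design import Barcode, BarcodeSet, expected_read_prefix
from relacs.demultiplex import ReadPair
from relacs.genome_digest import (
    CVIKI_1,
    DegenerateMotif,
    GenomeSequence,
    IntervalSet,
    SiteIndex,
    build_fragments,
    reverse_complement,
    scan_sites,
)

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RegionClass:
    """A chromatin-context class of the simulated genome.

    ``fraction`` of the genome assigned to the class, ``weight`` the relative
    accessibility (how likely its candidate fragments are to be cut out and
    recovered), ``enrichment`` an extra multiplier applied when simulating a
    ChIP sample (1.0 for inputs).
    """

    label: str
    fraction: float
    weight: float = 1.0
    enrichment: float = 1.0


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 1_000_000
    gc: float = 0.5
    classes: tuple[RegionClass, ...] = (
        RegionClass("open", 0.3, weight=4.0, enrichment=1.0),
        RegionClass("closed", 0.7, weight=1.0, enrichment=1.0),
    )
    block_size: int = 5_000
    fragment_window: tuple[int, int] = (30, 1000)
    read_length: int = 75
    junction_bases: int = 1
    error_rate: float = 0.0
    duplicate_rate: float = 0.0
    chimera_rate: float = 0.0
    motif: DegenerateMotif = CVIKI_1

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        lo, hi = self.fragment_window
        if not 0 < lo < hi:
            raise ValueError("fragment window must satisfy 0 < min < max")
        if abs(sum(c.fraction for c in self.classes) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if any(c.weight <= 0 for c in self.classes):
            raise ValueError("class weights must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["motif"] = {"pattern": self.motif.pattern, "cut_offset": self.motif.cut_offset}
        return d


@dataclass
class TruthRecord:
    read_id: str
    sample: str
    chrom: str
    start: int
    end: int
    is_duplicate: bool = False
    is_chimera: bool = False
    barcode_errors_mate1: int = 0
    barcode_errors_mate2: int = 0


@dataclass
class TruthManifest:
    """Ground truth for every simulated read pair, JSON-serializable."""

    seed: int
    config: dict
    records: list[TruthRecord] = field(default_factory=list)
    schema_version: int = 1

    def truth_barcodes(self) -> dict[str, str]:
        return {r.read_id: r.sample for r in self.records}

    def fragments_by_sample(self) -> dict[str, list[tuple[str, int, int]]]:
        out: dict[str, list[tuple[str, int, int]]] = {}
        for r in self.records:
            out.setdefault(r.sample, []).append((r.chrom, r.start, r.end))
        return out

    def to_json(self, path) -> None:
        payload = {
            "schema_version": self.schema_version,
            "seed": self.seed,
            "config": self.config,
            "records": [asdict(r) for r in self.records],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            seed=payload["seed"],
            config=payload["config"],
            records=[TruthRecord(**r) for r in payload["records"]],
            schema_version=payload["schema_version"],
        )


def make_genome(cfg: SimConfig) -> tuple[GenomeSequence, IntervalSet]:
    """Random genome at the requested GC plus a block partition into classes."""
    rng = np.random.default_rng(cfg.seed)
    p_gc = cfg.gc / 2.0
    p_at = (1.0 - cfg.gc) / 2.0
    probs = np.array([p_at, p_gc, p_gc, p_at])  # A C G T
    chroms: dict[str, str] = {}
    intervals: list[tuple[str, int, int, str]] = []
    fracs = np.array([c.fraction for c in cfg.classes])
    for i in range(cfg.n_chroms):
        name = f"chr{i + 1}"
        draws = rng.choice(4, size=cfg.chrom_length, p=probs)
        chroms[name] = _DNA[draws].tobytes().decode("ascii")
        pos = 0
        while pos < cfg.chrom_length:
            end = min(pos + cfg.block_size, cfg.chrom_length)
            label = cfg.classes[rng.choice(len(cfg.classes), p=fracs)].label
            intervals.append((name, pos, end, label))
            pos = end
    return GenomeSequence(chroms), IntervalSet(intervals)


@dataclass
class SampledFragment:
    sample: str
    chrom: str
    start: int
    end: int
    is_duplicate: bool = False


def _classify_midpoints(
    mids: np.ndarray, chrom: str, states: IntervalSet, classes: Sequence[RegionClass]
) -> np.ndarray:
    """Class index per midpoint (block partitions are exhaustive)."""
    out = np.zeros(mids.size, dtype=np.int64)
    for ci, cls in enumerate(classes):
        ivs = states.by_class(cls.label).get(chrom)
        if ivs is not None and ivs.size:
            from relacs.genome_digest import _membership

            out[_membership(mids, ivs)] = ci
    return out


def sample_fragments(
    genome: GenomeSequence,
    sites: SiteIndex,
    cfg: SimConfig,
    states: IntervalSet,
    n_per_sample: Mapping[str, int],
    chip: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> list[SampledFragment]:
    """Accessibility-weighted sampling of digestion fragments per sample.

    Candidates are inter-site intervals inside the fragment-length window;
    each is drawn with probability proportional to its class weight (times
    the class enrichment when ``chip``).  Duplicates are injected at
    ``cfg.duplicate_rate`` by re-emitting already-sampled fragments, flagged.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    lo, hi = cfg.fragment_window
    fmap = build_fragments(sites, genome, include_terminal=False)
    cand_chrom: list[str] = []
    cand_arr: list[np.ndarray] = []
    for chrom, frag in fmap.fragments.items():
        if frag.size == 0:
            continue
        lens = frag[:, 1] - frag[:, 0]
        keep = frag[(lens >= lo) & (lens <= hi)]
        if keep.size:
            cand_chrom.append(chrom)
            cand_arr.append(keep)
    if not cand_arr:
        raise ValueError(
            f"no candidate fragments in window [{lo}, {hi}] "
            f"(genome has {fmap.n_fragments} inter-site fragments)"
        )
    all_frags = np.concatenate(cand_arr)
    chrom_of = np.concatenate(
        [np.full(a.shape[0], i) for i, a in enumerate(cand_arr)]
    )
    mids = (all_frags[:, 0] + all_frags[:, 1]) // 2
    class_idx = np.zeros(mids.size, dtype=np.int64)
    for i, chrom in enumerate(cand_chrom):
        sel = chrom_of == i
        class_idx[sel] = _classify_midpoints(mids[sel], chrom, states, cfg.classes)
    weights = np.array(
        [c.weight * (c.enrichment if chip else 1.0) for c in cfg.classes]
    )
    p = weights[class_idx].astype(float)
    p /= p.sum()

    out: list[SampledFragment] = []
    for sample, n in n_per_sample.items():
        n_dup = int(round(n * cfg.duplicate_rate))
        n_fresh = n - n_dup
        picks = rng.choice(all_frags.shape[0], size=n_fresh, replace=True, p=p)
        frags = [
            SampledFragment(
                sample,
                cand_chrom[chrom_of[k]],
                int(all_frags[k, 0]),
                int(all_frags[k, 1]),
            )
            for k in picks
        ]
        for k in rng.choice(n_fresh, size=n_dup, replace=True) if n_dup else []:
            src = frags[k]
            frags.append(
                SampledFragment(sample, src.chrom, src.start, src.end, is_duplicate=True)
            )
        out.extend(frags)
    return out


def _inject_errors(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    """Substitute bases i.i.d. at ``rate``; returns sequence and positions hit."""
    if rate <= 0 or not seq:
        return seq, np.empty(0, dtype=np.int64)
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq, np.empty(0, dtype=np.int64)
    pos = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for pidx in pos:
        alternatives = [b for b in "ACGT" if b != chars[pidx]]
        chars[pidx] = alternatives[rng.integers(0, 3)]
    return "".join(chars), np.sort(pos)


def emit_reads(
    fragments: Sequence[SampledFragment],
    barcode_map: Mapping[str, Barcode],
    genome: GenomeSequence,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[ReadPair], TruthManifest]:
    """Turn sampled fragments into barcoded, error-injected paired reads.

    Mate 1 reads the fragment 5'->3' behind ``barcode + junction``; mate 2
    reads the reverse complement (the fragment's other end), same prefix.
    Reads are truncated at the fragment end when the insert is shorter than
    the read length allows; substitution errors are injected i.i.d. and those
    falling in the barcode region are counted in the manifest.  Chimeric
    pairs (mates from two different samples' adapters) are injected at
    ``cfg.chimera_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    L = len(next(iter(barcode_map.values())).sequence)
    insert_len = cfg.read_length - L - cfg.junction_bases
    if insert_len < 1:
        raise ValueError("read_length must exceed barcode length + junction bases")
    sample_ids = sorted(barcode_map)
    reads: list[ReadPair] = []
    manifest = TruthManifest(seed=cfg.seed, config=cfg.to_dict())
    qual_cache: dict[int, str] = {}
    for i, frag in enumerate(fragments):
        bc = barcode_map[frag.sample]
        prefix1 = expected_read_prefix(bc, cfg.junction_bases)
        is_chimera = cfg.chimera_rate > 0 and rng.random() < cfg.chimera_rate
        if is_chimera:
            other = sample_ids[rng.integers(0, len(sample_ids))]
            while len(sample_ids) > 1 and other == frag.sample:
                other = sample_ids[rng.integers(0, len(sample_ids))]
            prefix2 = expected_read_prefix(barcode_map[other], cfg.junction_bases)
        else:
            prefix2 = prefix1
        frag_seq = genome[frag.chrom][frag.start : frag.end]
        mate1 = prefix1 + frag_seq[:insert_len]
        mate2 = prefix2 + reverse_complement(frag_seq)[:insert_len]
        mate1, err1 = _inject_errors(mate1, cfg.error_rate, rng)
        mate2, err2 = _inject_errors(mate2, cfg.error_rate, rng)
        rid = f"sim:{cfg.seed}:{i}"
        q1 = qual_cache.setdefault(len(mate1), "I" * len(mate1))
        q2 = qual_cache.setdefault(len(mate2), "I" * len(mate2))
        reads.append(ReadPair(rid, mate1, q1, mate2, q2))
        manifest.records.append(
            TruthRecord(
                read_id=rid,
                sample=frag.sample,
                chrom=frag.chrom,
                start=frag.start,
                end=frag.end,
                is_duplicate=frag.is_duplicate,
                is_chimera=is_chimera,
                barcode_errors_mate1=int((err1 < L).sum()),
                barcode_errors_mate2=int((err2 < L).sum()),
            )
        )
    return reads, manifest


def simulate_experiment(
    cfg: SimConfig,
    barcode_set: BarcodeSet,
    n_per_sample: Mapping[str, int],
    chip: bool = False,
):
    """Convenience pipeline: genome -> digestion -> fragments -> reads.

    ``n_per_sample`` maps sample names to read-pair counts; sample names must
    be ids of ``barcode_set``.  Returns (genome, states, sites, reads,
    manifest).  Everything derives from ``cfg.seed``.
    """
    genome, states = make_genome(cfg)
    sites = scan_sites(genome, cfg.motif)
    rng = np.random.default_rng(cfg.seed + 1)
    frags = sample_fragments(genome, sites, cfg, states, n_per_sample, chip=chip, rng=rng)
    barcode_map = {bc.id: bc for bc in barcode_set if bc.id in n_per_sample}
    missing = set(n_per_sample) - set(barcode_map)
    if missing:
        raise ValueError(f"sample(s) without barcode: {sorted(missing)}")
    reads, manifest = emit_reads(
        frags, barcode_map, genome, cfg, rng=np.random.default_rng(cfg.seed + 2)
    )
    return genome, states, sites, reads, manifest
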