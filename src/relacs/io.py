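"""File I/O: FASTA/FASTQ via Biopython, BED/TSV via pandas. Gzip-transparent."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from relacs.barcode_design import Barcode, BarcodeSet
from relacs.demultiplex import ReadPair
from relacs.genome_digest import GenomeSequence, IntervalSet, SiteIndex


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_genome_fasta(path, include_pattern: str | None = None) -> GenomeSequence:
    """Load a genome FASTA(.gz); optionally keep only names matching a regex."""
    import re

    pat = re.compile(include_pattern) if include_pattern else None
    chroms = {}
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if pat is None or pat.search(rec.id):
                chroms[rec.id] = str(rec.seq)
    if not chroms:
        raise ValueError(f"no sequences loaded from {path}")
    return GenomeSequence(chroms)


def write_genome_fasta(genome: GenomeSequence, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.chromosomes.items()]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_bed(path, labeled: bool = True, merge: bool = False) -> IntervalSet:
    """Read BED into an IntervalSet; column 4 is the class label when present."""
    rows = []
    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            label = parts[3] if labeled and len(parts) > 3 else "."
            rows.append((parts[0], int(parts[1]), int(parts[2]), label))
    return IntervalSet(rows, merge=merge)


def write_bed(intervals: Iterable[tuple[str, int, int]], path, name: str | None = None) -> None:
    with _open(path, "wt") as fh:
        for row in intervals:
            fields = [row[0], str(row[1]), str(row[2])]
            if name is not None:
                fields.append(name)
            fh.write("\t".join(fields) + "\n")


def write_sites_bed(sites: SiteIndex, path) -> None:
    # cut positions as zero-length features encoded [p, p+1)
    with _open(path, "wt") as fh:
        fh.write(f"# cut positions of {sites.motif.pattern}, encoded as [p, p+1)\n")
        for chrom, pos in sites.sites.items():
            for p in pos:
                fh.write(f"{chrom}\t{p}\t{p + 1}\n")


def read_sites_bed(path, motif) -> SiteIndex:
    import numpy as np

    sites: dict[str, list[int]] = {}
    with _open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, _end = line.split("\t")[:3]
            sites.setdefault(chrom, []).append(int(start))
    return SiteIndex(motif=motif, sites={c: np.asarray(sorted(v)) for c, v in sites.items()})


def read_barcode_tsv(path) -> BarcodeSet:
    """Barcode TSV: ``id<TAB>sequence``, no header, '#' comments."""
    barcodes = []
    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            bc_id, seq = line.split("\t")[:2]
            barcodes.append(Barcode(bc_id, seq))
    return BarcodeSet(barcodes)


def write_barcode_tsv(bc_set: BarcodeSet, path) -> None:
    with _open(path, "wt") as fh:
        for bc in bc_set:
            fh.write(f"{bc.id}\t{bc.sequence}\n")


def read_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    from relacs.demultiplex import pair_fastq_records

    with _open(r1_path) as fh1, _open(r2_path) as fh2:
        yield from pair_fastq_records(SeqIO.parse(fh1, "fastq"), SeqIO.parse(fh2, "fastq"))


class FastqPairSink:
    """Writes demultiplexed pairs to ``<sample>_R{1,2}.fastq[.gz]`` files."""

    def __init__(self, outdir, gzip_output: bool = True):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.gzip_output = gzip_output
        self._handles: dict[str, tuple] = {}

    def _get(self, sample: str):
        if sample not in self._handles:
            ext = ".fastq.gz" if self.gzip_output else ".fastq"
            fh1 = _open(self.outdir / f"{sample}_R1{ext}", "wt")
            fh2 = _open(self.outdir / f"{sample}_R2{ext}", "wt")
            self._handles[sample] = (fh1, fh2)
        return self._handles[sample]

    def write(self, sample: str, pair: ReadPair) -> None:
        fh1, fh2 = self._get(sample)
        fh1.write(f"@{pair.read_id}/1\n{pair.seq1}\n+\n{pair.qual1}\n")
        fh2.write(f"@{pair.read_id}/2\n{pair.seq2}\n+\n{pair.qual2}\n")

    def close(self) -> None:
        for fh1, fh2 in self._handles.values():
            fh1.close()
            fh2.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path, r2_path) -> None:
    with _open(r1_path, "wt") as fh1, _open(r2_path, "wt") as fh2:
        for pair in pairs:
            fh1.write(f"@{pair.read_id}/1\n{pair.seq1}\n+\n{pair.qual1}\n")
            fh2.write(f"@{pair.read_id}/2\n{pair.seq2}\n+\n{pair.qual2}\n")


def write_tsv(frame: pd.DataFrame, path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index)
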