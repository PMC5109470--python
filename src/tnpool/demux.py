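"""Read demultiplexing: reduce raw pooled amplicon reads to
(insertion coordinate, pool) read-count records.

Every read pair is examined for (a) the transposon tag at the start of the
main read and (b) a pool barcode in the index read, both matched with a
Hamming tolerance (default 2 mismatches, no indels).  The genomic flank 3' of
the tag is then located on the genome, either by the built-in exact/Hamming
locator (adequate for synthetic data) or by ingesting a SAM file from an
external end-to-end aligner.  The reported coordinate is always the junction:
the genomic position of the first flank base, 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .layout import Axis, PoolId
from .simulate import reverse_complement


def match_with_mismatches(observed: str, reference: str, max_mm: int = 2) -> tuple[bool, int]:
    """Hamming comparison of equal-length strings.

    Returns (matches within ``max_mm``, mismatch count).  Mismatch counting
    stops early once the allowance is exceeded (the returned count is then
    max_mm + 1).
    """
    if len(observed) != len(reference):
        raise ValueError("sequences must have equal length for Hamming comparison")
    mm = 0
    for a, b in zip(observed, reference):
        if a != b:
            mm += 1
            if mm > max_mm:
                return False, mm
    return True, mm


class BarcodeTable:
    """Pool barcodes with ambiguity-safe fuzzy assignment.

    The table is validated at load time: barcodes must be unique, equal
    length, over ACGT, and pairwise Hamming distance strictly greater than
    2 * max_mm, which guarantees that at most one barcode can match any index
    sequence within max_mm mismatches.
    """

    def __init__(self, barcodes: Mapping[tuple[Axis, int], str], max_mm: int = 2) -> None:
        self.max_mm = max_mm
        self.by_pool = dict(barcodes)
        values = list(self.by_pool.values())
        if len(values) == 0:
            raise ValueError("empty barcode table")
        if len(set(values)) != len(values):
            raise ValueError("duplicate barcodes in table")
        lengths = {len(v) for v in values}
        if len(lengths) != 1:
            raise ValueError("barcodes must share a single length")
        self.length = lengths.pop()
        for v in values:
            if set(v) - set("ACGT"):
                raise ValueError(f"barcode {v!r} contains non-ACGT characters")
        pools = sorted(self.by_pool)
        for i in range(len(pools)):
            for j in range(i + 1, len(pools)):
                _, d = match_with_mismatches(
                    self.by_pool[pools[i]], self.by_pool[pools[j]], self.length
                )
                if d <= 2 * max_mm:
                    raise ValueError(
                        f"barcodes for {pools[i]} and {pools[j]} are only "
                        f"{d} mismatches apart; need > {2 * max_mm}"
                    )
        self._exact = {v: k for k, v in self.by_pool.items()}

    @classmethod
    def from_tsv(cls, path: str | Path, max_mm: int = 2) -> "BarcodeTable":
        df = pd.read_csv(path, sep="\t")
        barcodes = {
            (Axis(str(r.axis)), int(r.index)): str(r.barcode).upper()
            for r in df.itertuples(index=False)
        }
        return cls(barcodes, max_mm=max_mm)

    def assign(self, index_seq: str) -> PoolId | None:
        """Unique pool whose barcode matches within max_mm, else None."""
        seq = index_seq[: self.length]
        if len(seq) < self.length:
            return None
        hit = self._exact.get(seq)
        if hit is not None:
            return PoolId(hit[0], hit[1], self.by_pool[hit])
        for (axis, index), bc in self.by_pool.items():
            ok, _ = match_with_mismatches(seq, bc, self.max_mm)
            if ok:
                return PoolId(axis, index, bc)
        return None

    def barcode_of(self, axis: Axis, index: int) -> str:
        return self.by_pool[(axis, index)]


def assign_barcode(
    index_seq: str, barcode_table: BarcodeTable, max_mm: int = 2
) -> PoolId | None:
    """Functional wrapper over :meth:`BarcodeTable.assign`."""
    if max_mm != barcode_table.max_mm:
        barcode_table = BarcodeTable(barcode_table.by_pool, max_mm=max_mm)
    return barcode_table.assign(index_seq)


def extract_genomic_flank(
    main_seq: str,
    transposon_tag: str,
    max_mm: int = 2,
    tag_offsets: Iterable[int] = (0,),
    min_flank_len: int = 20,
) -> str | None:
    """Genomic flank 3' of the transposon tag, or None if the tag is absent.

    The tag is sought at each candidate 5' offset in turn (library designs
    with variable-length spacers need a small offset window); the first offset
    matching within ``max_mm`` wins.  Flanks shorter than ``min_flank_len``
    are rejected.
    """
    for off in tag_offsets:
        window = main_seq[off : off + len(transposon_tag)]
        if len(window) < len(transposon_tag):
            continue
        ok, _ = match_with_mismatches(window, transposon_tag, max_mm)
        if ok:
            flank = main_seq[off + len(transposon_tag) :]
            return flank if len(flank) >= min_flank_len else None
    return None


def _seed_codes(seq: str, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit-packed integer codes of every ``seed``-mer, plus a validity mask."""
    b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code = np.full(len(b), 4, dtype=np.int64)
    for i, base in enumerate("ACGT"):
        code[b == ord(base)] = i
    n = len(b) - seed + 1
    if n <= 0:
        return np.array([], dtype=np.int64), np.array([], dtype=bool)
    c = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for k in range(seed):
        window = code[k : k + n]
        c = (c << 2) | (window & 3)
        valid &= window < 4
    return c, valid


class GenomeIndex:
    """Seed-and-verify locator for genomic flanks (built for synthetic data).

    Exact 10-mer seeds at three query offsets (disjoint whenever the flank is
    >= 30 bases, so by pigeonhole at least one seed is error-free for up to 2
    substitutions) nominate candidate positions, which are verified by
    Hamming comparison.  Only the forward strand is indexed; reverse-strand
    hits are found by querying the flank's reverse complement.  A flank
    matching more than one genomic position equally well is discarded (None),
    mirroring unique-alignment filtering.
    """

    SEED = 10

    def __init__(self, genome: Mapping[str, str]) -> None:
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, seq in self.genome.items():
            codes, valid = _seed_codes(seq, self.SEED)
            positions = np.flatnonzero(valid)
            codes = codes[positions]
            order = np.argsort(codes, kind="stable")
            self._index[name] = (codes[order], positions[order])

    def _seed_hits(self, name: str, code: int) -> np.ndarray:
        codes, positions = self._index[name]
        lo = np.searchsorted(codes, code, side="left")
        hi = np.searchsorted(codes, code, side="right")
        return positions[lo:hi]

    def locate(self, flank: str, max_mm: int = 2) -> tuple[str, int, str] | None:
        """(replicon, junction coordinate, strand) of the unique best hit.

        The junction coordinate is the 1-based genomic position of the first
        flank base: a forward match starting at 0-based offset s gives s + 1;
        a reverse-complement match covering forward positions [s+1, s+L]
        gives s + L (the flank reads away from the junction).
        """
        flank = flank.upper()
        L = len(flank)
        if L < self.SEED:
            return None
        if L >= 3 * self.SEED:
            offsets = [0, self.SEED, 2 * self.SEED]
        else:
            offsets = sorted({0, (L - self.SEED) // 2, L - self.SEED})
        best: list[tuple[str, int, str]] = []
        best_mm = max_mm + 1
        for strand, query in (("+", flank), ("-", reverse_complement(flank))):
            seen: set[tuple[str, int]] = set()
            for off in offsets:
                kmer_codes, kmer_valid = _seed_codes(query[off : off + self.SEED], self.SEED)
                if len(kmer_codes) == 0 or not kmer_valid[0]:
                    continue
                for name, seq in self.genome.items():
                    for pos in self._seed_hits(name, int(kmer_codes[0])):
                        start = int(pos) - off
                        if start < 0 or start + L > len(seq) or (name, start) in seen:
                            continue
                        seen.add((name, start))
                        ok, mm = match_with_mismatches(query, seq[start : start + L], max_mm)
                        if not ok:
                            continue
                        junction = start + 1 if strand == "+" else start + L
                        if mm < best_mm:
                            best, best_mm = [(name, junction, strand)], mm
                        elif mm == best_mm:
                            best.append((name, junction, strand))
        if len(best) != 1:
            return None
        return best[0]


def locate_flank(
    flank: str, genome_index: GenomeIndex, max_mm: int = 2
) -> tuple[str, int, str] | None:
    """Functional wrapper over :meth:`GenomeIndex.locate`."""
    return genome_index.locate(flank, max_mm=max_mm)


def ingest_sam(sam_path: str | Path, min_mapq: int = 0) -> Iterator[tuple[str, str, int, str]]:
    """Junction coordinates from an external aligner's SAM output.

    Yields (read_id, replicon, junction, strand) for primary mapped
    alignments with MAPQ >= min_mapq.  The flank was sequenced away from the
    junction, so on the + strand the junction is the leftmost reference
    position; on the - strand it is the rightmost.
    """
    import pysam

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            if aln.is_reverse:
                junction = aln.reference_end  # 1-based inclusive end
                strand = "-"
            else:
                junction = aln.reference_start + 1
                strand = "+"
            yield aln.query_name, aln.reference_name, int(junction), strand


@dataclass
class DemuxStats:
    """Bookkeeping for a demultiplexing run."""

    total_reads: int = 0
    valid_reads: int = 0    # transposon tag and barcode both recognised
    aligned_reads: int = 0  # valid and located on the genome
    per_pool: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "total_reads": self.total_reads,
                    "valid_reads": self.valid_reads,
                    "aligned_reads": self.aligned_reads,
                    "per_pool": self.per_pool,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def iter_read_pairs(main_fastq: str | Path, index_fastq: str | Path) -> Iterator[tuple[str, str, str]]:
    """(id, main_seq, index_seq) triples from paired FASTQ files."""
    import pysam

    with pysam.FastxFile(str(main_fastq)) as fm, pysam.FastxFile(str(index_fastq)) as fi:
        for main, idx in zip(fm, fi):
            yield main.name, main.sequence.upper(), idx.sequence.upper()


def demux_reads(
    main_fastq: str | Path,
    index_fastq: str | Path,
    barcode_table: BarcodeTable,
    transposon_tag: str,
    genome_index: GenomeIndex | None = None,
    sam_coords: Mapping[str, tuple[str, int, str]] | None = None,
    max_mm: int = 2,
    tag_offsets: Iterable[int] = (0,),
    min_flank_len: int = 20,
) -> tuple[pd.DataFrame, DemuxStats]:
    """Full demultiplex: FASTQ pair -> per-pool coordinate-count table.

    Flank location comes either from the built-in locator (``genome_index``)
    or from a read-id -> (replicon, junction, strand) mapping built from an
    external aligner's SAM (``sam_coords``); exactly one must be given.
    Returns a tidy frame (replicon, position, axis, pool_index, reads) and
    run statistics.  Reads with a valid transposon tag but no assignable
    barcode count as invalid; located coordinates are cached so repeated
    flanks cost one lookup.
    """
    if (genome_index is None) == (sam_coords is None):
        raise ValueError("give exactly one of genome_index or sam_coords")
    stats = DemuxStats()
    counts: dict[tuple[str, int, Axis, int], int] = {}
    flank_cache: dict[str, tuple[str, int, str] | None] = {}
    tag_offsets = tuple(tag_offsets)
    for read_id, main, idx in iter_read_pairs(main_fastq, index_fastq):
        stats.total_reads += 1
        flank = extract_genomic_flank(
            main, transposon_tag, max_mm=max_mm,
            tag_offsets=tag_offsets, min_flank_len=min_flank_len,
        )
        if flank is None:
            continue
        pool = barcode_table.assign(idx)
        if pool is None:
            continue
        stats.valid_reads += 1
        if sam_coords is not None:
            loc = sam_coords.get(read_id)
        else:
            if flank in flank_cache:
                loc = flank_cache[flank]
            else:
                loc = genome_index.locate(flank, max_mm=max_mm)
                flank_cache[flank] = loc
        if loc is None:
            continue
        stats.aligned_reads += 1
        pool_name = PoolId(pool.axis, pool.index).name
        stats.per_pool[pool_name] = stats.per_pool.get(pool_name, 0) + 1
        key = (loc[0], loc[1], pool.axis, pool.index)
        counts[key] = counts.get(key, 0) + 1
    df = pd.DataFrame(
        [(r, p, a.value, i, c) for (r, p, a, i), c in counts.items()],
        columns=["replicon", "position", "axis", "pool_index", "reads"],
    )
    df = df.sort_values(["replicon", "position", "axis", "pool_index"]).reset_index(drop=True)
    return df, stats


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
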