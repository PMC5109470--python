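"""Synthetic data: genome, arrayed picking, and pooled amplicon sequencing.

The generator emulates the statistical structure the decoding pipeline
assumes: a replicon whose AT/TA dinucleotides are the insertion-site universe,
genes with essentiality labels, random colony picking into plates (with an
adjustable rate of the same clone landing in two wells), log-normal template
abundance per picked colony, per-pool template dilution proportional to the
number of wells feeding the pool, and multiplicative amplification noise
with Poisson read sampling.  A fully deterministic mode (all noise off,
expected counts rounded) exists for exact end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .coverage import (
    HIGH_NONESSENTIAL_LABELS,
    GenomeFeatureIndex,
    enumerate_insertion_sites,
)
from .layout import Axis, GridLayout, PoolId, WellAddress, pools_for_well

#: Default transposon tag expected at the 5' end of every main read (the last
#: bases of the inverted repeat before the genomic junction).
DEFAULT_TRANSPOSON_TAG = "ACAGGTTGGATGATAAGTCCCCGG"

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGenome:
    """Sequences plus a feature table (1-based inclusive coordinates)."""

    records: dict[str, str]
    features: pd.DataFrame  # replicon, locus_tag, start, end, strand, essentiality, insertion_free

    def write_fasta(self, path: str | Path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        recs = [SeqRecord(Seq(s), id=name, description="") for name, s in self.records.items()]
        seqio_write(recs, str(path), "fasta")

    def write_features(self, path: str | Path) -> None:
        self.features.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, fasta: str | Path, features_tsv: str | Path) -> "SyntheticGenome":
        from Bio import SeqIO

        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
        feats = pd.read_csv(features_tsv, sep="\t")
        if "insertion_free" not in feats.columns:
            feats["insertion_free"] = False
        return cls(records, feats)

    def feature_index(self) -> GenomeFeatureIndex:
        return GenomeFeatureIndex.from_features(self.records, self.features)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _site_free_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    # no T at all -> no AT or TA dinucleotide can occur
    p = np.array([1 - gc, gc / 2, gc / 2])
    return "".join(np.array(list("ACG"))[rng.choice(3, size=length, p=p)])


def generate_genome(
    n_genes: int,
    gene_len_range: tuple[int, int] = (300, 1500),
    intergenic_len_range: tuple[int, int] = (50, 300),
    essential_fraction: float = 0.1,
    gc: float = 0.5,
    seed: int | None = None,
    unknown_fraction: float = 0.1,
    insertion_free_fraction: float = 0.0,
    replicon_name: str = "chr1",
) -> SyntheticGenome:
    """Tile genes separated by intergenic gaps into one replicon.

    Every ordinary gene is guaranteed at least one AT/TA insertion site; a
    requested fraction of the non-essential genes is instead built without any
    AT/TA dinucleotide, emulating genes that can never acquire an insertion.
    ``essential_fraction`` of genes are labelled ExpectedEssential,
    ``unknown_fraction`` Unknown, the rest Dispensable.  Strands alternate
    pseudo-randomly.
    """
    for frac in (essential_fraction, unknown_fraction, insertion_free_fraction, gc):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    chunks: list[str] = []
    rows = []
    pos = 1

    def add_intergenic() -> None:
        nonlocal pos
        length = int(rng.integers(intergenic_len_range[0], intergenic_len_range[1] + 1))
        chunks.append(_random_seq(rng, length, gc))
        pos += length

    add_intergenic()
    n_essential = int(round(n_genes * essential_fraction))
    n_unknown = int(round(n_genes * unknown_fraction))
    labels = (
        ["ExpectedEssential"] * n_essential
        + ["Unknown"] * n_unknown
        + ["Dispensable"] * (n_genes - n_essential - n_unknown)
    )
    rng.shuffle(labels)
    nonessential_idx = [i for i, lab in enumerate(labels) if lab != "ExpectedEssential"]
    n_free = int(round(len(nonessential_idx) * insertion_free_fraction))
    free_set = set(rng.choice(nonessential_idx, size=n_free, replace=False)) if n_free else set()

    for i in range(n_genes):
        length = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
        if i in free_set:
            seq = _site_free_seq(rng, length, gc)
        else:
            seq = _random_seq(rng, length, gc)
            if len(enumerate_insertion_sites(seq)) == 0:
                mid = length // 2
                seq = seq[:mid] + "TA" + seq[mid + 2 :]
        chunks.append(seq)
        rows.append(
            {
                "replicon": replicon_name,
                "locus_tag": f"SG_{i + 1:04d}",
                "start": pos,
                "end": pos + length - 1,
                "strand": "+" if rng.random() < 0.5 else "-",
                "essentiality": labels[i],
                "insertion_free": i in free_set,
            }
        )
        pos += length
        add_intergenic()

    features = pd.DataFrame(
        rows,
        columns=[
            "replicon", "locus_tag", "start", "end", "strand",
            "essentiality", "insertion_free",
        ],
    )
    return SyntheticGenome({replicon_name: "".join(chunks)}, features)


# ---------------------------------------------------------------------------
# Picking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Placement:
    """One occupancy event: a clone's insertion sitting in one well."""

    clone_id: int
    replicon: str
    position: int  # junction coordinate, 1-based
    strand: str    # orientation of the transposon ('+': flank runs 3' of junction)
    well: WellAddress


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated progenitor collection."""

    genome: SyntheticGenome
    layout: GridLayout
    placements: list[Placement]
    lam: dict[int, float] = field(default_factory=dict)  # placement index -> template abundance

    def clones(self) -> dict[int, list[Placement]]:
        out: dict[int, list[Placement]] = {}
        for p in self.placements:
            out.setdefault(p.clone_id, []).append(p)
        return out

    def wells_of_clone(self, clone_id: int) -> set[WellAddress]:
        return {p.well for p in self.placements if p.clone_id == clone_id}

    def occupancy(self) -> dict[WellAddress, int]:
        occ: dict[WellAddress, int] = {}
        for p in self.placements:
            occ[p.well] = occ.get(p.well, 0) + 1
        return occ

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone_id": [p.clone_id for p in self.placements],
                "replicon": [p.replicon for p in self.placements],
                "position": [p.position for p in self.placements],
                "strand": [p.strand for p in self.placements],
                "well": [p.well.label for p in self.placements],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate_picking(
    genome: SyntheticGenome,
    layout: GridLayout,
    n_picks: int,
    duplicate_rate: float = 0.0,
    same_axis_bias: float = 0.5,
    eligible_labels: Iterable[str] = HIGH_NONESSENTIAL_LABELS,
    end_margin: int = 100,
    seed: int | None = None,
) -> SyntheticTruth:
    """Fill wells in plate order with randomly picked insertion clones.

    Each of the first ``n_picks`` usable wells receives a fresh clone with a
    distinct insertion site (drawn uniformly from the non-essential site
    universe, keeping ``end_margin`` bases clear of the replicon ends so
    junction flanks always fit).  With probability ``duplicate_rate`` the
    clone is *also* deposited into a second, already-occupied well — with
    probability ``same_axis_bias`` one in the same plate and row (the
    duplicate then shares three of four pool coordinates and decodes as an
    unambiguous multiple), otherwise anywhere (typically sharing no
    coordinate, decoding as an ambiguous line).  Second placements create
    multiply occupied wells, which is what colony purification during
    condensation has to deal with.
    """
    if not 0.0 <= duplicate_rate < 1.0:
        raise ValueError("duplicate_rate must be in [0, 1)")
    wells = list(layout.iter_wells())
    if n_picks > len(wells):
        raise ValueError(f"n_picks={n_picks} exceeds {len(wells)} usable wells")
    index = genome.feature_index()
    mask = index.eligible_site_mask(eligible_labels)
    lengths = {name: len(seq) for name, seq in genome.records.items()}
    rep_len = np.array([lengths[index.replicon_names[c]] for c in index.replicons])
    mask &= (index.positions > end_margin) & (index.positions <= rep_len - end_margin)
    pool_sites = np.flatnonzero(mask)
    if len(pool_sites) == 0:
        raise ValueError("no eligible insertion sites")
    if len(pool_sites) < n_picks:
        raise ValueError("fewer eligible insertion sites than picks")
    rng = np.random.default_rng(seed)
    site_order = pool_sites[rng.permutation(len(pool_sites))]
    placements: list[Placement] = []
    filled: list[WellAddress] = []
    by_plate_row: dict[tuple[int, int], list[WellAddress]] = {}
    for clone_id, well in enumerate(wells[:n_picks]):
        s = site_order[clone_id]
        placement = Placement(
            clone_id,
            index.replicon_names[int(index.replicons[s])],
            int(index.positions[s]),
            "+" if rng.random() < 0.5 else "-",
            well,
        )
        placements.append(placement)
        if filled and rng.random() < duplicate_rate:
            same = by_plate_row.get((well.plate, well.row), [])
            if same and rng.random() < same_axis_bias:
                target = same[rng.integers(0, len(same))]
            else:
                target = filled[rng.integers(0, len(filled))]
            placements.append(
                Placement(clone_id, placement.replicon, placement.position,
                          placement.strand, target)
            )
        filled.append(well)
        by_plate_row.setdefault((well.plate, well.row), []).append(well)
    return SyntheticTruth(genome, layout, placements)


# ---------------------------------------------------------------------------
# Pooled read counts and reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadCountModel:
    """Statistical model of per-pool read counts.

    Each clone placement carries a log-normal template abundance
    lambda ~ LogNormal(mu_abundance, sigma_abundance) (one draw per clone; a
    duplicated clone contributes its lambda once per occupied well).  Pools
    are mass-normalised before library preparation, so the expected read count
    of placement i in pool p is

        depth * lambda_i / sum_{j feeds p} lambda_j

    multiplied by a per-(placement, pool) LogNormal(0, sigma_pool)
    amplification-noise factor; integer counts are then Poisson draws.
    ``crosstalk_rate`` routes that fraction of each pool's depth to clones not
    actually present in the pool (index hopping / well cross-contamination),
    which is what makes read-count thresholding meaningful.
    """

    mu_abundance: float = 0.0
    sigma_abundance: float = 1.0
    sigma_pool: float = 0.35
    depth: float = 50_000.0
    base_error_rate: float = 0.001
    crosstalk_rate: float = 0.005
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.sigma_abundance < 0 or self.sigma_pool < 0 or self.depth < 0:
            raise ValueError("sigma_abundance, sigma_pool and depth must be >= 0")
        if not 0 <= self.base_error_rate < 1 or not 0 <= self.crosstalk_rate < 1:
            raise ValueError("rates must be in [0, 1)")

    @classmethod
    def deterministic(cls, depth: float = 50_000.0) -> "ReadCountModel":
        """All noise off; expected counts rounded to integers."""
        return cls(
            sigma_abundance=0.0,
            sigma_pool=0.0,
            depth=depth,
            base_error_rate=0.0,
            crosstalk_rate=0.0,
            poisson=False,
        )


def _assign_lambdas(
    truth: SyntheticTruth, model: ReadCountModel, rng: np.random.Generator
) -> np.ndarray:
    """One abundance per placement: each picked colony grows independently,
    so a clone occupying two wells contributes two independent templates."""
    n = len(truth.placements)
    if model.sigma_abundance == 0.0:
        lam = np.full(n, np.exp(model.mu_abundance))
    else:
        lam = rng.lognormal(model.mu_abundance, model.sigma_abundance, size=n)
    truth.lam = {i: float(v) for i, v in enumerate(lam)}
    return lam


def simulate_pool_counts(
    truth: SyntheticTruth,
    model: ReadCountModel,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-pool read counts for every insertion coordinate.

    Returns a tidy frame with columns replicon, position, strand, axis,
    pool_index, reads (reads >= 1).  Clone abundances are drawn here and
    stored on ``truth.lam``.
    """
    rng = np.random.default_rng(seed)
    lam = _assign_lambdas(truth, model, rng)
    # membership: pool -> placement indices
    members: dict[tuple[Axis, int], list[int]] = {}
    for i, p in enumerate(truth.placements):
        for pool in pools_for_well(p.well, truth.layout):
            members.setdefault((pool.axis, pool.index), []).append(i)
    lam_total = lam.sum()
    rows: dict[tuple[str, int, str, str, int], int] = {}

    def add(placement_idx: int, axis: Axis, pool_index: int, count: int) -> None:
        if count < 1:
            return
        p = truth.placements[placement_idx]
        key = (p.replicon, p.position, p.strand, axis.value, pool_index)
        rows[key] = rows.get(key, 0) + count

    for (axis, pool_index), idx_list in sorted(members.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        idx = np.array(idx_list)
        pool_lam = lam[idx]
        mean = model.depth * pool_lam / pool_lam.sum()
        if model.sigma_pool > 0:
            mean = mean * rng.lognormal(0.0, model.sigma_pool, size=len(idx))
        counts = rng.poisson(mean) if model.poisson else np.round(mean).astype(np.int64)
        for j, c in zip(idx, counts):
            add(int(j), axis, pool_index, int(c))
        if model.crosstalk_rate > 0:
            others = np.setdiff1d(np.arange(len(truth.placements)), idx, assume_unique=False)
            if len(others):
                xmean = model.crosstalk_rate * model.depth * lam[others] / lam_total
                xcounts = rng.poisson(xmean)
                for j, c in zip(others[xcounts > 0], xcounts[xcounts > 0]):
                    add(int(j), axis, pool_index, int(c))

    df = pd.DataFrame(
        [(r, pos, s, ax, pi, c) for (r, pos, s, ax, pi), c in rows.items()],
        columns=["replicon", "position", "strand", "axis", "pool_index", "reads"],
    )
    return df.sort_values(["replicon", "position", "axis", "pool_index"]).reset_index(drop=True)


def _apply_errors(
    reads: list[str], rate: float, rng: np.random.Generator
) -> list[str]:
    if rate <= 0 or not reads:
        return reads
    length = len(reads[0])
    n_err = rng.binomial(length, rate, size=len(reads))
    bases = "ACGT"
    for i in np.flatnonzero(n_err):
        s = list(reads[i])
        for pos in rng.integers(0, length, size=n_err[i]):
            s[pos] = bases[(bases.index(s[pos]) + int(rng.integers(1, 4))) % 4]
        reads[i] = "".join(s)
    return reads


def simulate_pooled_reads(
    truth: SyntheticTruth,
    model: ReadCountModel,
    barcodes: Mapping[tuple[Axis, int], str],
    main_fastq: str | Path,
    index_fastq: str | Path,
    read_len: int = 50,
    transposon_tag: str = DEFAULT_TRANSPOSON_TAG,
    seed: int | None = None,
) -> pd.DataFrame:
    """Write the main-read and index-read FASTQ files for a pooled run.

    Each main read is the transposon tag followed by the genomic flank 3' of
    the junction (for a minus-orientation insertion, the reverse complement of
    the sequence 5' of the junction); the index read is the pool barcode.
    Per-base substitution errors at ``model.base_error_rate``; constant 'I'
    qualities.  Returns the underlying true count table (see
    :func:`simulate_pool_counts`).
    """
    flank_len = read_len - len(transposon_tag)
    if flank_len < 1:
        raise ValueError("read_len must exceed the transposon tag length")
    counts = simulate_pool_counts(truth, model, seed=seed)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    genome = truth.genome.records
    flank_cache: dict[tuple[str, int, str], str] = {}

    def flank_of(replicon: str, position: int, strand: str) -> str:
        key = (replicon, position, strand)
        if key not in flank_cache:
            seq = genome[replicon]
            if strand == "+":
                if position + flank_len - 1 > len(seq):
                    raise ValueError(f"flank at {replicon}:{position}+ runs past replicon end")
                flank_cache[key] = seq[position - 1 : position - 1 + flank_len]
            else:
                if position - flank_len < 0:
                    raise ValueError(f"flank at {replicon}:{position}- runs past replicon start")
                flank_cache[key] = reverse_complement(seq[position - flank_len : position])
        return flank_cache[key]

    qual = "I" * read_len
    serial = 0
    with open(main_fastq, "w") as fm, open(index_fastq, "w") as fi:
        for row in counts.itertuples(index=False):
            barcode = barcodes[(Axis(row.axis), int(row.pool_index))]
            base_read = transposon_tag + flank_of(row.replicon, int(row.position), row.strand)
            mains = _apply_errors([base_read] * int(row.reads), model.base_error_rate, rng)
            idxs = _apply_errors([barcode] * int(row.reads), model.base_error_rate, rng)
            bq = "I" * len(barcode)
            main_buf, idx_buf = [], []
            for m, b in zip(mains, idxs):
                serial += 1
                name = f"r{serial}"
                main_buf.append(f"@{name}\n{m}\n+\n{qual}\n")
                idx_buf.append(f"@{name}\n{b}\n+\n{bq}\n")
            fm.write("".join(main_buf))
            fi.write("".join(idx_buf))
    return counts


def random_barcode_table(
    layout: GridLayout,
    length: int = 10,
    min_distance: int = 5,
    seed: int | None = None,
) -> dict[tuple[Axis, int], str]:
    """Random pool barcodes with guaranteed pairwise Hamming separation.

    ``min_distance`` must exceed twice the demultiplexer's mismatch allowance
    (default 2) for assignment to stay unambiguous.
    """
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    bases = np.array(list("ACGT"))
    arrs: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < layout.pool_count:
        cand = rng.integers(0, 4, size=length)
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not build a separated barcode set; increase length")
        if all(int((cand != prev).sum()) >= min_distance for prev in arrs):
            arrs.append(cand)
            chosen.append("".join(bases[cand]))
    pools = [
        PoolId(axis, i)
        for axis in (Axis.ROW, Axis.COL, Axis.PR, Axis.PC)
        for i in range(1, layout.axis_size(axis) + 1)
    ]
    return {(p.axis, p.index): bc for p, bc in zip(pools, chosen)}


def write_barcode_table(
    barcodes: Mapping[tuple[Axis, int], str], path: str | Path
) -> None:
    rows = [
        {"pool_id": PoolId(axis, index).name, "axis": axis.value, "index": index, "barcode": bc}
        for (axis, index), bc in sorted(barcodes.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
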