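"""Collection-size planning: Poisson coverage model, Monte Carlo picking
simulation over a genome feature index, and rarefaction from an observed
catalogue.

A mariner-family transposon inserts at AT/TA dinucleotides, approximately
uniformly across the genome, once per cell.  For a genome with ``N``
non-essential genes and a collection of ``k`` mutants, Poisson statistics give
the expected number of represented genes (genes with at least one mutant) as

    n_represented(k) = N * (1 - exp(-k / N))

so a target of about one unrepresented gene needs k = N * ln(N) picks.  The
Monte Carlo model relaxes the Poisson assumptions: insertions land on actual
AT/TA sites, intergenic insertions consume picks without representing a gene,
and genes without sites can never be represented, so the simulated curve rises
more slowly and plateaus below N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Essentiality vocabulary.  The *low* non-essential scenario counts only the
#: four Dispensable* labels as disruptable; the *high* scenario adds Unknown.
LOW_NONESSENTIAL_LABELS = frozenset(
    {"Dispensable", "SurpriseDispensable", "GuessDispensable", "DispensableUnclearInEcoli"}
)
HIGH_NONESSENTIAL_LABELS = frozenset(LOW_NONESSENTIAL_LABELS | {"Unknown"})
ESSENTIAL_LABELS = frozenset({"ExpectedEssential", "NewEssential"})
NONCODING_LABEL = "NonCoding"
ALL_LABELS = frozenset(
    LOW_NONESSENTIAL_LABELS | ESSENTIAL_LABELS | {"Unknown", NONCODING_LABEL}
)


def enumerate_insertion_sites(seq: str) -> np.ndarray:
    """1-based positions i where seq[i..i+1] is an AT or TA dinucleotide.

    Both strands see the same site set (AT/TA is its own reverse complement
    as a site class).  Dinucleotides containing N (or any non-ACGT letter)
    are excluded.  Returns a sorted int64 array; empty input gives an empty
    array.
    """
    if len(seq) < 2:
        return np.array([], dtype=np.int64)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    a, t = ord("A"), ord("T")
    first, second = arr[:-1], arr[1:]
    hits = ((first == a) & (second == t)) | ((first == t) & (second == a))
    return np.flatnonzero(hits).astype(np.int64) + 1


def poisson_represented(N: int, k: float) -> float:
    """Expected represented-gene count after k picks under the Poisson model."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return N * (1.0 - math.exp(-k / N))


def collection_size_for_coverage(N: int, target_unrepresented: float = 1.0) -> int:
    """Picks needed to leave ``target_unrepresented`` genes without a mutant.

    Inverts the Poisson model: k = N * ln(N / target), rounded to the nearest
    integer.  With the default target of one unrepresented gene, N = 3,256
    gives 26,335 picks and N = 4,184 gives 34,890.
    """
    if not 0 < target_unrepresented < N:
        raise ValueError("target_unrepresented must be in (0, N)")
    return round(N * math.log(N / target_unrepresented))


@dataclass(frozen=True)
class RarefactionCurve:
    """Represented-gene count versus number of picks, over repeated trials."""

    k: np.ndarray
    mean_represented: np.ndarray
    sd_represented: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        if not (len(self.k) == len(self.mean_represented) == len(self.sd_represented)):
            raise ValueError("curve arrays must share a length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k, "mean_represented": self.mean_represented,
             "sd_represented": self.sd_represented}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class GenomeFeatureIndex:
    """Lookup from every candidate insertion site to its locus and label.

    Sites falling outside any annotated gene are assigned to a synthetic
    non-coding locus per replicon, labelled ``NonCoding``.  A site covered by
    overlapping genes is assigned to the gene whose translation start lies
    nearest upstream of the site (strand-aware); this is a modelling choice
    and is recorded in the ``overlap_resolved`` attribute.
    """

    def __init__(
        self,
        positions: np.ndarray,
        replicons: np.ndarray,
        locus_tags: np.ndarray,
        labels: np.ndarray,
        replicon_names: Sequence[str],
        overlap_resolved: int = 0,
    ) -> None:
        self.positions = positions          # int64, 1-based site positions
        self.replicons = replicons          # int16 codes into replicon_names
        self.locus_tags = locus_tags        # object array, one per site
        self.labels = labels                # object array, one per site
        self.replicon_names = list(replicon_names)
        self.overlap_resolved = overlap_resolved

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def from_features(
        cls,
        genome: Mapping[str, str],
        features: pd.DataFrame,
        essentiality: Mapping[str, str] | None = None,
    ) -> "GenomeFeatureIndex":
        """Build the index from sequences plus a feature table.

        ``features`` needs columns replicon, locus_tag, start, end, strand and
        (optionally) essentiality; 1-based inclusive coordinates.  A separate
        ``essentiality`` mapping keyed by locus_tag overrides/supplies labels;
        genes with no label are marked Unknown.
        """
        feats = features.copy()
        if "essentiality" not in feats.columns:
            feats["essentiality"] = "Unknown"
        if essentiality:
            feats["essentiality"] = [
                essentiality.get(lt, lab)
                for lt, lab in zip(feats["locus_tag"], feats["essentiality"])
            ]
        bad = set(feats["essentiality"]) - set(ALL_LABELS)
        if bad:
            raise ValueError(f"unknown essentiality labels: {sorted(bad)}")

        replicon_names = list(genome.keys())
        all_pos, all_rep, all_locus, all_label = [], [], [], []
        overlap_resolved = 0
        for code, (name, seq) in enumerate(genome.items()):
            sites = enumerate_insertion_sites(seq)
            # a site at position L-? must fit strictly within the replicon
            sites = sites[sites <= len(seq) - 1]
            sub = feats[feats["replicon"] == name]
            locus = np.full(len(sites), f"NC_{name}", dtype=object)
            label = np.full(len(sites), NONCODING_LABEL, dtype=object)
            if len(sub):
                starts = sub["start"].to_numpy(dtype=np.int64)
                ends = sub["end"].to_numpy(dtype=np.int64)
                n_cover = np.zeros(len(sites), dtype=np.int32)
                best_dist = np.full(len(sites), np.iinfo(np.int64).max, dtype=np.int64)
                for i in range(len(sub)):
                    row = sub.iloc[i]
                    inside = (sites >= starts[i]) & (sites <= ends[i])
                    if not inside.any():
                        continue
                    # distance from translation start, strand-aware
                    if row["strand"] == "-":
                        dist = ends[i] - sites
                    else:
                        dist = sites - starts[i]
                    take = inside & (dist < best_dist)
                    locus[take] = row["locus_tag"]
                    label[take] = row["essentiality"]
                    best_dist[take] = dist[take]
                    n_cover[inside] += 1
                overlap_resolved += int((n_cover > 1).sum())
            all_pos.append(sites)
            all_rep.append(np.full(len(sites), code, dtype=np.int16))
            all_locus.append(locus)
            all_label.append(label)
        return cls(
            np.concatenate(all_pos) if all_pos else np.array([], dtype=np.int64),
            np.concatenate(all_rep) if all_rep else np.array([], dtype=np.int16),
            np.concatenate(all_locus) if all_locus else np.array([], dtype=object),
            np.concatenate(all_label) if all_label else np.array([], dtype=object),
            replicon_names,
            overlap_resolved,
        )

    @classmethod
    def from_genbank(
        cls, paths: Sequence[str | Path], essentiality: Mapping[str, str] | None = None
    ) -> "GenomeFeatureIndex":
        """Build from GenBank records (CDS/gene features with locus_tag)."""
        from Bio import SeqIO

        genome: dict[str, str] = {}
        rows = []
        for path in paths:
            for rec in SeqIO.parse(str(path), "genbank"):
                genome[rec.id] = str(rec.seq)
                for feat in rec.features:
                    if feat.type not in ("CDS", "gene"):
                        continue
                    tags = feat.qualifiers.get("locus_tag")
                    if not tags:
                        continue
                    rows.append(
                        {
                            "replicon": rec.id,
                            "locus_tag": tags[0],
                            "start": int(feat.location.start) + 1,
                            "end": int(feat.location.end),
                            "strand": "-" if feat.location.strand == -1 else "+",
                        }
                    )
        feats = pd.DataFrame(rows).drop_duplicates(subset=["replicon", "locus_tag"])
        return cls.from_features(genome, feats, essentiality)

    def locus_of(self, replicon: str, position: int) -> tuple[str, str] | None:
        """(locus_tag, label) of the site at this coordinate, or None."""
        code = self.replicon_names.index(replicon)
        mask = (self.replicons == code) & (self.positions == position)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            return None
        i = int(idx[0])
        return str(self.locus_tags[i]), str(self.labels[i])

    def eligible_site_mask(self, labels: Iterable[str]) -> np.ndarray:
        labels = set(labels) | {NONCODING_LABEL}
        return np.isin(self.labels, list(labels))

    def distinct_loci(self, labels: Iterable[str]) -> set[str]:
        """Coding loci carrying >=1 site with a label in ``labels``."""
        mask = np.isin(self.labels, list(set(labels)))
        return set(self.locus_tags[mask])


def _accumulate_first_hits(codes: np.ndarray, n_picks: int) -> np.ndarray:
    """Represented-count curve (length n_picks) from per-pick locus codes.

    ``codes`` < 0 mark picks that represent no gene (non-coding sites).
    """
    coding = codes >= 0
    if not coding.any():
        return np.zeros(n_picks, dtype=np.float64)
    _, first_idx = np.unique(codes[coding], return_index=True)
    # map back to positions in the full pick sequence
    coding_positions = np.flatnonzero(coding)
    increments = np.zeros(n_picks, dtype=np.int64)
    np.add.at(increments, coding_positions[first_idx], 1)
    return np.cumsum(increments).astype(np.float64)


def simulate_collection(
    index: GenomeFeatureIndex,
    non_essential_labels: Iterable[str],
    n_picks: int,
    n_trials: int = 1000,
    seed: int | None = None,
) -> RarefactionCurve:
    """Monte Carlo picking model over an insertion-site index.

    Each trial draws ``n_picks`` sites uniformly *with replacement* from the
    sites whose locus carries a non-essential label (non-coding sites are
    always eligible).  A pick landing in a coding non-essential locus not yet
    hit increments the represented-gene count; non-coding picks consume a pick
    without representing anything.  Returns the per-pick mean and standard
    deviation of the represented count across trials.
    """
    if n_picks < 1 or n_trials < 1:
        raise ValueError("n_picks and n_trials must be >= 1")
    labels = set(non_essential_labels)
    mask = index.eligible_site_mask(labels)
    if not mask.any():
        raise ValueError("no eligible insertion sites for the given labels")
    site_locus = index.locus_tags[mask]
    site_coding = np.isin(index.labels[mask], list(labels))
    # integer codes: coding loci 0..L-1, non-coding -> -1
    codes_by_site = np.full(len(site_locus), -1, dtype=np.int64)
    coding_tags, coding_codes = np.unique(site_locus[site_coding], return_inverse=True)
    codes_by_site[site_coding] = coding_codes
    if len(coding_tags) == 0:
        raise ValueError("no non-essential gene carries an eligible insertion site")
    rng = np.random.default_rng(seed)
    total = np.zeros(n_picks)
    total_sq = np.zeros(n_picks)
    for _ in range(n_trials):
        picks = rng.integers(0, len(codes_by_site), size=n_picks)
        curve = _accumulate_first_hits(codes_by_site[picks], n_picks)
        total += curve
        total_sq += curve * curve
    mean = total / n_trials
    var = np.maximum(total_sq / n_trials - mean**2, 0.0)
    return RarefactionCurve(
        k=np.arange(1, n_picks + 1),
        mean_represented=mean,
        sd_represented=np.sqrt(var),
        n_trials=n_trials,
    )


def rarefaction_from_catalogue(
    observed_insertions: Sequence[str],
    n_trials: int = 1000,
    seed: int | None = None,
) -> RarefactionCurve:
    """Rarefaction by sampling *without replacement* from located mutants.

    ``observed_insertions`` holds one locus tag per located mutant instance
    (so a gene hit ten times appears ten times).  Each trial shuffles the list
    and accumulates the distinct-locus count; the final mean equals the
    distinct count exactly.
    """
    if len(observed_insertions) == 0:
        raise ValueError("observed_insertions is empty")
    _, codes = np.unique(np.asarray(observed_insertions, dtype=object), return_inverse=True)
    codes = codes.astype(np.int64)
    n = len(codes)
    rng = np.random.default_rng(seed)
    total = np.zeros(n)
    total_sq = np.zeros(n)
    for _ in range(n_trials):
        perm = rng.permutation(n)
        curve = _accumulate_first_hits(codes[perm], n)
        total += curve
        total_sq += curve * curve
    mean = total / n_trials
    var = np.maximum(total_sq / n_trials - mean**2, 0.0)
    return RarefactionCurve(
        k=np.arange(1, n + 1),
        mean_represented=mean,
        sd_represented=np.sqrt(var),
        n_trials=n_trials,
    )
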