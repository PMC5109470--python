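import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnpool.coverage import (
    GenomeFeatureIndex,
    LOW_NONESSENTIAL_LABELS,
    collection_size_for_coverage,
    enumerate_insertion_sites,
    poisson_represented,
    rarefaction_from_catalogue,
    simulate_collection,
)


class TestEnumerateInsertionSites:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", [1]), ("TATA", [1, 2, 3]), ("GGCC", []), ("", []), ("A", []),
         ("ANTA", [3]), ("atgc", [1])],
    )
    def test_examples(self, seq, expected):
        assert enumerate_insertion_sites(seq).tolist() == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", max_size=60))
    def test_matches_naive_scan(self, seq):
        naive = [
            i + 1
            for i in range(len(seq) - 1)
            if seq[i : i + 2] in ("AT", "TA")
        ]
        assert enumerate_insertion_sites(seq).tolist() == naive


class TestPoissonModel:
    def test_zero_picks(self):
        assert poisson_represented(3256, 0) == 0.0

    def test_paper_collection_size_leaves_one_unrepresented(self):
        n = 3256
        k = 26335
        assert n - poisson_represented(n, k) == pytest.approx(1.0, abs=0.05)

    def test_small_case_against_direct_simulation(self, rng):
        # N=2, k=2: closed form 2(1 - e^-1); oracle simulates the insertions
        trials = 200_000
        picks = rng.integers(0, 2, size=(trials, 2))
        represented = (picks == 0).any(axis=1).astype(int) + (picks == 1).any(axis=1)
        sim_mean = represented.mean()
        se = represented.std() / math.sqrt(trials)
        # Poisson model approximates the exact binomial occupancy at small N
        exact = 2 * (1 - (1 - 0.5) ** 2)
        assert sim_mean == pytest.approx(exact, abs=3 * se)
        assert poisson_represented(2, 2) == pytest.approx(2 * (1 - math.exp(-1)))

    @pytest.mark.parametrize("N,expected", [(3256, 26335), (4184, 34890)])
    def test_collection_size_paper_values(self, N, expected):
        assert collection_size_for_coverage(N) == expected

    def test_collection_size_trivial(self):
        assert collection_size_for_coverage(1, target_unrepresented=0.5) == 1

    def test_collection_size_bad_target(self):
        with pytest.raises(ValueError):
            collection_size_for_coverage(10, target_unrepresented=0.0)
        with pytest.raises(ValueError):
            collection_size_for_coverage(10, target_unrepresented=10.0)


def _uniform_index(n_genes: int, sites_per_gene: int, n_noncoding: int = 0) -> GenomeFeatureIndex:
    """Synthetic site index: equal sites per gene, optional non-coding sites."""
    loci = [f"g{i}" for i in range(n_genes) for _ in range(sites_per_gene)]
    loci += ["NC_chr"] * n_noncoding
    n = len(loci)
    return GenomeFeatureIndex(
        positions=np.arange(1, n + 1, dtype=np.int64),
        replicons=np.zeros(n, dtype=np.int16),
        locus_tags=np.array(loci, dtype=object),
        labels=np.array(
            ["Dispensable"] * (n_genes * sites_per_gene) + ["NonCoding"] * n_noncoding,
            dtype=object,
        ),
        replicon_names=["chr"],
    )


class TestSimulateCollection:
    def test_single_gene_single_site(self):
        index = _uniform_index(1, 1)
        curve = simulate_collection(index, LOW_NONESSENTIAL_LABELS, n_picks=5, n_trials=20, seed=0)
        assert np.all(curve.mean_represented == 1.0)
        assert np.all(curve.sd_represented == 0.0)

    def test_uniform_limit_matches_poisson(self):
        # no intergenic sites, equal sites per gene -> Poisson closed form
        N, picks, trials = 50, 150, 400
        index = _uniform_index(N, 4)
        curve = simulate_collection(index, LOW_NONESSENTIAL_LABELS, picks, trials, seed=1)
        for k in (10, 50, 100, 150):
            mean = curve.mean_represented[k - 1]
            se = curve.sd_represented[k - 1] / math.sqrt(trials)
            expected = poisson_represented(N, k)
            # Poisson vs exact occupancy differ by < e^-1/2 genes; allow both
            assert abs(mean - expected) < 3 * se + 0.5

    def test_half_intergenic_thins_the_curve(self):
        # 50% non-coding sites: represented(k) ~ poisson(N, k/2)
        N, picks, trials = 40, 160, 400
        index = _uniform_index(N, 4, n_noncoding=N * 4)
        curve = simulate_collection(index, LOW_NONESSENTIAL_LABELS, picks, trials, seed=2)
        for k in (40, 80, 160):
            mean = curve.mean_represented[k - 1]
            se = curve.sd_represented[k - 1] / math.sqrt(trials)
            assert abs(mean - poisson_represented(N, k / 2)) < 3 * se + 0.5

    def test_monotone_and_bounded(self):
        index = _uniform_index(10, 3, n_noncoding=5)
        curve = simulate_collection(index, LOW_NONESSENTIAL_LABELS, 60, 50, seed=3)
        assert np.all(np.diff(curve.mean_represented) >= 0)
        assert curve.mean_represented[-1] <= 10
        # with intergenic sites present, Poisson is an upper bound on the mean
        ks = np.arange(1, 61)
        poisson = np.array([poisson_represented(10, k) for k in ks])
        assert np.all(curve.mean_represented <= poisson + 1e-9)

    def test_no_eligible_genes_raises(self):
        index = _uniform_index(2, 2)
        index.labels[:] = "ExpectedEssential"
        with pytest.raises(ValueError):
            simulate_collection(index, LOW_NONESSENTIAL_LABELS, 5, 5, seed=0)


class TestRarefaction:
    def test_tiny_catalogue_exact_tail(self):
        curve = rarefaction_from_catalogue(["g1", "g1", "g2"], n_trials=50, seed=0)
        assert curve.mean_represented[-1] == 2.0
        assert curve.sd_represented[-1] == 0.0

    def test_mid_curve_matches_permutation_oracle(self):
        # E[distinct after 2 draws w/o replacement from {g1,g1,g2}] enumerated
        # over all 6 index permutations: (2*4 + 1*2)/6
        expected = 10 / 6
        curve = rarefaction_from_catalogue(["g1", "g1", "g2"], n_trials=4000, seed=1)
        se = curve.sd_represented[1] / math.sqrt(4000)
        assert curve.mean_represented[1] == pytest.approx(expected, abs=3 * se + 1e-6)

    def test_recovers_distinct_count_of_truth_list(self, rng):
        tags = [f"g{i}" for i in rng.integers(0, 37, size=200)]
        curve = rarefaction_from_catalogue(tags, n_trials=10, seed=2)
        assert curve.mean_represented[-1] == len(set(tags))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rarefaction_from_catalogue([], n_trials=5)


class TestGenomeFeatureIndex:
    def test_sites_assigned_to_loci_and_noncoding(self):
        genome = {"chr": "GGGGATGGGG" + "CCTACC" + "GGGG"}
        #                 gene 3..8 covers the AT at pos 5; TA at 13 is intergenic
        feats = pd.DataFrame(
            [{"replicon": "chr", "locus_tag": "gA", "start": 3, "end": 8,
              "strand": "+", "essentiality": "Dispensable"}]
        )
        index = GenomeFeatureIndex.from_features(genome, feats)
        assert index.locus_of("chr", 5) == ("gA", "Dispensable")
        locus, label = index.locus_of("chr", 13)
        assert locus == "NC_chr"
        assert label == "NonCoding"

    def test_overlapping_genes_use_nearest_upstream_start(self):
        seq = "G" * 30 + "AT" + "G" * 30
        feats = pd.DataFrame(
            [
                {"replicon": "chr", "locus_tag": "early", "start": 5, "end": 40,
                 "strand": "+", "essentiality": "Dispensable"},
                {"replicon": "chr", "locus_tag": "late", "start": 25, "end": 50,
                 "strand": "+", "essentiality": "Dispensable"},
            ]
        )
        index = GenomeFeatureIndex.from_features({"chr": seq}, feats)
        # site at 31: distance 26 from "early" start, 6 from "late" start
        assert index.locus_of("chr", 31)[0] == "late"
        assert index.overlap_resolved >= 1

    def test_unknown_label_rejected(self):
        feats = pd.DataFrame(
            [{"replicon": "chr", "locus_tag": "g", "start": 1, "end": 4,
              "strand": "+", "essentiality": "Mystery"}]
        )
        with pytest.raises(ValueError, match="essentiality"):
            GenomeFeatureIndex.from_features({"chr": "ATAT"}, feats)

    def test_from_genbank_round_trip(self, tmp_path):
        from Bio.Seq import Seq
        from Bio.SeqFeature import FeatureLocation, SeqFeature
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        rec = SeqRecord(Seq("GGGGATGGGGTACCGG"), id="repA", description="")
        rec.annotations["molecule_type"] = "DNA"
        rec.features.append(
            SeqFeature(FeatureLocation(2, 8, strand=1), type="CDS",
                       qualifiers={"locus_tag": ["gbk1"]})
        )
        path = tmp_path / "mini.gbk"
        seqio_write([rec], str(path), "genbank")
        index = GenomeFeatureIndex.from_genbank([path], essentiality={"gbk1": "Dispensable"})
        assert index.locus_of("repA", 5) == ("gbk1", "Dispensable")
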