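import numpy as np
import pandas as pd
import pytest

from gtascan.genome_scan import (
    OTU,
    call_gta_clusters,
    chain_cluster,
    corrected_abundance,
    otu_group,
)
from gtascan.io import SequenceRecord
from gtascan.synthetic import plant_genome


def make_loci(starts_ends, replicon="chr1", genome="g1"):
    return [
        SequenceRecord(f"x{i}", "M", genome, replicon, s, e, "+")
        for i, (s, e) in enumerate(starts_ends)
    ]


def brute_force_chains(loci, eps, min_size):
    """All maximal contiguous windows of sorted loci with gaps <= eps."""
    out = []
    by_rep = {}
    for r in loci:
        by_rep.setdefault((r.genome_id, r.replicon_id), []).append(r)
    for members in by_rep.values():
        members = sorted(members, key=lambda r: (r.start, r.end, r.id))
        n = len(members)
        gap_ok = [
            members[i + 1].start - members[i].end - 1 <= eps for i in range(n - 1)
        ]
        for i in range(n):
            for j in range(i, n):
                if not all(gap_ok[i:j]):
                    continue
                if i > 0 and gap_ok[i - 1]:
                    continue  # extendable left
                if j < n - 1 and gap_ok[j]:
                    continue  # extendable right
                if j - i + 1 >= min_size:
                    out.append(tuple(r.id for r in members[i : j + 1]))
    return sorted(out)


class TestChainCluster:
    def test_six_genes_within_eps_form_one_cluster(self):
        loci = make_loci([(1 + i * 5000, 1000 + i * 5000) for i in range(6)])
        # adjacent gap = 5000 - 1000 - 1 = 3999 <= 8000
        clusters = chain_cluster(loci, 8000, 6)
        assert len(clusters) == 1
        assert clusters[0].n_members == 6
        assert (clusters[0].start, clusters[0].end) == (1, 26000)

    def test_one_large_gap_breaks_the_chain(self):
        coords = [(1 + i * 5000, 1000 + i * 5000) for i in range(6)]
        coords[3] = (coords[2][1] + 9002, coords[2][1] + 10001)  # gap 9001 > 8000
        coords[4] = (coords[3][1] + 1000, coords[3][1] + 1999)
        coords[5] = (coords[4][1] + 1000, coords[4][1] + 1999)
        clusters = chain_cluster(make_loci(coords), 8000, 6)
        assert clusters == []

    def test_locus_without_coordinates_rejected(self):
        with pytest.raises(ValueError, match="coordinates"):
            chain_cluster([SequenceRecord("a", "M")], 8000, 6)

    @pytest.mark.parametrize("eps,min_size", [(5000, 9), (8000, 6)])
    def test_matches_brute_force_on_random_layouts(self, eps, min_size):
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 25))
            starts = np.sort(rng.integers(1, 150_000, size=n))
            loci = [
                SequenceRecord(
                    f"x{i}", "M", "g1", "chr1",
                    int(s), int(s + rng.integers(300, 1500)), "+",
                )
                for i, s in enumerate(starts)
            ]
            got = sorted(c.member_ids for c in chain_cluster(loci, eps, min_size))
            assert got == brute_force_chains(loci, eps, min_size)

    def test_input_order_invariance(self, rng):
        loci, _ = plant_genome(8, [7, 6], rng=3)
        a = chain_cluster(loci, 8000, 6)
        shuffled = [loci[i] for i in rng.permutation(len(loci))]
        assert chain_cluster(shuffled, 8000, 6) == a

    def test_replicons_chain_independently(self):
        a = make_loci([(1 + i * 2000, 1000 + i * 2000) for i in range(4)], "chr1")
        b = [
            SequenceRecord(f"y{i}", "M", "g1", "chr2",
                           1 + i * 2000, 1000 + i * 2000, "+")
            for i in range(4)
        ]
        clusters = chain_cluster(a + b, 8000, 4)
        assert [c.replicon_id for c in clusters] == ["chr1", "chr2"]


class TestCallGtaClusters:
    def test_planted_gta_block_recovered(self):
        loci, truth = plant_genome(10, [7], rng=5)
        scores = {r.id: (-1.0 if r.id.startswith("cl") else 1.0) for r in loci}
        calls = call_gta_clusters(scores, loci)
        assert list(calls) == ["genome1"]
        (cluster,) = calls["genome1"]
        assert sorted(cluster.member_ids) == sorted(truth[0])

    def test_all_virus_predictions_yield_no_clusters(self):
        loci, _ = plant_genome(5, [7], rng=6)
        scores = {r.id: 1.0 for r in loci}
        assert call_gta_clusters(scores, loci) == {}

    def test_small_planted_cluster_not_called(self):
        loci, _ = plant_genome(0, [5], rng=7)
        scores = {r.id: -1.0 for r in loci}
        assert call_gta_clusters(scores, loci, min_size=6) == {}

    def test_duplicate_locus_ids_rejected(self):
        loci = make_loci([(1, 10), (20, 30)])
        dup = loci + [loci[0]]
        with pytest.raises(ValueError, match="duplicated"):
            call_gta_clusters({}, dup)


def union_find_components(pairs, universe, threshold):
    comps = {g: {g} for g in universe}
    for a, b, ani in pairs:
        if ani >= threshold:
            merged = comps[a] | comps[b]
            for g in merged:
                comps[g] = merged
    seen = set()
    out = []
    for g in sorted(universe):
        key = tuple(sorted(comps[g]))
        if key not in seen:
            seen.add(key)
            out.append(key)
    return sorted(out)


class TestOtuGroup:
    def test_mutual_high_ani_one_otu(self):
        ani = pd.DataFrame(
            {"genome_a": ["a", "a", "b"], "genome_b": ["b", "c", "c"],
             "ani": [96.0, 96.0, 96.0]}
        )
        (otu,) = otu_group(ani)
        assert otu.members == ("a", "b", "c")

    def test_transitive_closure_convention(self):
        ani = pd.DataFrame(
            {"genome_a": ["a", "b"], "genome_b": ["b", "c"], "ani": [96.0, 96.0]}
        )
        ani = pd.concat(
            [ani, pd.DataFrame({"genome_a": ["a"], "genome_b": ["c"], "ani": [80.0]})]
        )
        (otu,) = otu_group(ani)
        assert otu.members == ("a", "b", "c")

    def test_out_of_range_ani_rejected(self):
        ani = pd.DataFrame({"genome_a": ["a"], "genome_b": ["b"], "ani": [104.0]})
        with pytest.raises(ValueError):
            otu_group(ani)

    def test_matches_union_find_oracle_on_random_tables(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            genomes = [f"g{i}" for i in range(int(rng.integers(4, 15)))]
            pairs = []
            for _ in range(int(rng.integers(3, 25))):
                a, b = rng.choice(genomes, 2, replace=False)
                pairs.append((a, b, float(rng.uniform(80, 100))))
            ani = pd.DataFrame(pairs, columns=["genome_a", "genome_b", "ani"])
            got = sorted(o.members for o in otu_group(ani, genomes=genomes))
            assert got == union_find_components(pairs, genomes, 95.0)


class TestCorrectedAbundance:
    def test_half_weight_for_two_clusters_in_otu_of_four(self):
        otus = [OTU(("g1", "g2", "g3", "g4"))]
        groups = {g: "Rhodobacterales" for g in ("g1", "g2", "g3", "g4")}
        out = corrected_abundance(otus, {"g1": 1, "g2": 1}, groups)
        assert out == {"Rhodobacterales": pytest.approx(0.5)}

    def test_singleton_otus_leave_counts_uncorrected(self):
        otus = [OTU(("g1",)), OTU(("g2",))]
        groups = {"g1": "A", "g2": "A"}
        out = corrected_abundance(otus, {"g1": 1, "g2": 1}, groups)
        assert out == {"A": pytest.approx(2.0)}

    def test_matches_direct_summation_on_random_configs(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            genomes = [f"g{i}" for i in range(int(rng.integers(5, 20)))]
            assignment = rng.integers(0, 4, size=len(genomes))
            otus = [
                OTU(tuple(g for g, a in zip(genomes, assignment) if a == k))
                for k in range(4)
                if (assignment == k).any()
            ]
            has_cluster = {g: int(rng.random() < 0.5) for g in genomes}
            groups = {g: f"grp{rng.integers(0, 3)}" for g in genomes}
            got = corrected_abundance(otus, has_cluster, groups)
            expected = {}
            size = {g: (assignment == assignment[i]).sum()
                    for i, g in enumerate(genomes)}
            for g in genomes:
                if has_cluster[g]:
                    expected[groups[g]] = expected.get(groups[g], 0) + 1 / size[g]
            assert set(got) == set(expected)
            for k in got:
                assert got[k] == pytest.approx(expected[k])
            raw = sum(has_cluster.values())
            assert sum(got.values()) <= raw + 1e-9

    def test_unassigned_genome_rejected(self):
        with pytest.raises(ValueError, match="OTU"):
            corrected_abundance([OTU(("g1",))], {"g2": 1}, {"g2": "A"})
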