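"""Presence/pseudogene calling and clade-specific cluster census."""

import pytest

from cohesim.genecontent import (SearchHit, call_group_specific,
                                 call_presence, combination_census)
from cohesim.orthology import GeneFamilyCluster


def hit(e=1e-6, frac=0.7, ident=40.0, disrupted=False):
    return SearchHit("q", "t", e, frac, ident, disrupted)


class TestCallPresence:
    def test_loose_threshold_present(self):
        assert call_presence([hit(e=1e-6, frac=0.7, ident=40.0)]) == "present"

    def test_strict_threshold_disrupted_is_pseudogene(self):
        h = hit(e=1e-22, frac=0.35, ident=36.0, disrupted=True)
        assert call_presence([h]) == "pseudogene"

    def test_no_hits_absent(self):
        assert call_presence([]) == "absent"

    def test_subthreshold_hit_absent(self):
        assert call_presence([hit(e=1e-3, frac=0.2, ident=30.0)]) == "absent"

    def test_strict_needs_identity(self):
        assert call_presence([hit(e=1e-22, frac=0.35, ident=30.0)]) == "absent"

    def test_intact_hit_outranks_disrupted(self):
        hits = [hit(disrupted=True), hit(disrupted=False)]
        assert call_presence(hits) == "present"

    def test_monotone_in_evalue_and_coverage(self):
        # improving e-value or coverage never flips present -> absent
        base = hit(e=9e-6, frac=0.6)
        assert call_presence([base]) == "present"
        better = [hit(e=1e-30, frac=0.6), hit(e=9e-6, frac=0.99),
                  hit(e=1e-30, frac=0.99)]
        for h in better:
            assert call_presence([h]) == "present"

    def test_malformed_hit_rejected(self):
        with pytest.raises(ValueError):
            SearchHit("q", "t", -1.0, 0.5, 50.0, False)
        with pytest.raises(ValueError):
            SearchHit("q", "t", 1e-5, 1.5, 50.0, False)


GROUPS = {"wHa": "A", "wRi": "A", "wMel": "A",
          "wNo": "B", "wPip": "B", "wAlbB": "B"}
A_GENOMES = [g for g, l in GROUPS.items() if l == "A"]
B_GENOMES = [g for g, l in GROUPS.items() if l == "B"]


def cluster_over(genomes, name="x"):
    return GeneFamilyCluster([f"{g}|{name}" for g in sorted(genomes)])


class TestGroupSpecific:
    def test_all_A_absent_everywhere_else_is_specific(self):
        c = cluster_over(A_GENOMES)
        presence = {("c1", g): "absent" for g in B_GENOMES}
        calls, counts = call_group_specific([("c1", c)], presence, GROUPS)
        assert counts == {"A": 1, "B": 0}
        assert calls[0].group == "A"

    def test_intact_outside_copy_blocks_specific_call(self):
        c = cluster_over(A_GENOMES)
        presence = {("c1", g): "absent" for g in B_GENOMES}
        presence[("c1", "wNo")] = "present"
        calls, counts = call_group_specific([("c1", c)], presence, GROUPS)
        assert counts == {"A": 0, "B": 0}

    def test_pseudogene_outside_still_specific(self):
        c = cluster_over(B_GENOMES)
        presence = {("c1", g): "pseudogene" for g in A_GENOMES}
        calls, counts = call_group_specific([("c1", c)], presence, GROUPS)
        assert counts == {"A": 0, "B": 1}
        assert set(calls[0].status.values()) == {"pseudogene"}

    def test_outgroup_must_also_lack_the_gene(self):
        c = cluster_over(A_GENOMES)
        presence = {("c1", g): "absent" for g in B_GENOMES}
        presence[("c1", "wBm")] = "present"
        _, counts = call_group_specific([("c1", c)], presence, GROUPS,
                                        outgroup_genomes=["wBm"])
        assert counts == {"A": 0, "B": 0}
        presence[("c1", "wBm")] = "absent"
        _, counts = call_group_specific([("c1", c)], presence, GROUPS,
                                        outgroup_genomes=["wBm"])
        assert counts == {"A": 1, "B": 0}

    def test_symmetric_under_group_relabelling(self):
        c = cluster_over(A_GENOMES)
        presence = {("c1", g): "absent" for g in B_GENOMES}
        flipped = {g: ("B" if l == "A" else "A") for g, l in GROUPS.items()}
        _, counts1 = call_group_specific([("c1", c)], presence, GROUPS)
        _, counts2 = call_group_specific([("c1", c)], presence, flipped)
        assert counts1["A"] == counts2["B"] == 1

    def test_missing_status_is_an_error(self):
        c = cluster_over(A_GENOMES)
        with pytest.raises(KeyError):
            call_group_specific([("c1", c)], {}, GROUPS)


class TestCombinationCensus:
    GENOMES = sorted(GROUPS)

    def test_core_clusters_count_for_no_triple(self):
        clusters = [cluster_over(self.GENOMES, f"f{i}") for i in range(4)]
        counts = combination_census(clusters, self.GENOMES, k=3)
        assert all(v == 0 for v in counts.values())
        assert len(counts) == 20      # C(6,3)

    def test_exact_subset_counted_once(self):
        trio = ("wHa", "wMel", "wRi")
        clusters = [cluster_over(trio)]
        counts = combination_census(clusters, self.GENOMES, k=3)
        assert counts[trio] == 1
        assert sum(counts.values()) == 1

    def test_counts_partition_k_genome_clusters(self):
        clusters = [cluster_over(("wHa", "wMel", "wRi"), "f1"),
                    cluster_over(("wHa", "wMel", "wRi"), "f2"),
                    cluster_over(("wNo", "wPip", "wAlbB"), "f3"),
                    cluster_over(("wHa", "wNo"), "pair"),
                    cluster_over(self.GENOMES, "core")]
        counts = combination_census(clusters, self.GENOMES, k=3)
        n_k3 = sum(1 for c in clusters if len(c.per_genome_count) == 3)
        assert sum(counts.values()) == n_k3


def test_planted_truth_recovered_through_full_path():
    from cohesim.experiments import specific_recovery

    rec = specific_recovery(seed=11, n_core=10,
                            n_specific_per_group=(4, 3),
                            pseudogene_fraction=0.5)
    assert rec.exact
    assert rec.called == {"A": 4, "B": 3}
    assert rec.n_core_recovered == 10
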