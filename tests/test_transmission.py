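"""Tile matching, parent-of-origin assignment, breakpoint refinement,
transmission inference, and concordance against simulator truth."""

import numpy as np
import pytest

from gnurture import simfam, transmission
from gnurture._rng import substream
from gnurture.transmission import Tile


class TestTilePartition:
    def test_exact_multiple(self):
        tiles = transmission.tile_partition(450, 150)
        assert [(t.start, t.end) for t in tiles] == [(0, 150), (150, 300), (300, 450)]

    def test_short_remainder_merges_left(self):
        tiles = transmission.tile_partition(160, 150)
        assert [(t.start, t.end) for t in tiles] == [(0, 160)]

    def test_long_remainder_stands(self):
        tiles = transmission.tile_partition(250, 150)
        assert [(t.start, t.end) for t in tiles] == [(0, 150), (150, 250)]

    def test_single_short_chromosome(self):
        tiles = transmission.tile_partition(100, 150)
        assert [(t.start, t.end) for t in tiles] == [(0, 100)]

    def test_partition_covers_everything(self):
        for n in (2, 149, 151, 299, 300, 301, 1234):
            tiles = transmission.tile_partition(n, 150)
            assert tiles[0].start == 0 and tiles[-1].end == n
            for a, b in zip(tiles, tiles[1:]):
                assert a.end == b.start

    def test_tiny_tile_size_rejected(self):
        with pytest.raises(ValueError):
            transmission.tile_partition(100, 1)


def _rand_parent(rng, n):
    return (rng.random((2, n)) < 0.5).astype(np.int8)


class TestMatchTiles:
    def test_exact_copy_of_hap1(self):
        rng = substream(0, "mt")
        parent = _rand_parent(rng, 300)
        tiles = transmission.tile_partition(300, 150)
        tm = transmission.match_tiles(parent[0], parent, tiles)
        assert (tm.source == 1).all()
        assert (tm.mismatch1 == 0).all()

    def test_single_crossover_at_tile_boundary(self):
        rng = substream(1, "mt")
        parent = _rand_parent(rng, 300)
        off = np.concatenate([parent[0, :150], parent[1, 150:]])
        tiles = transmission.tile_partition(300, 150)
        tm = transmission.match_tiles(off, parent, tiles)
        assert list(tm.source) == [1, 2]

    def test_tie_keeps_previous_assignment(self):
        parent = np.zeros((2, 300), dtype=np.int8)
        parent[0, ::2] = 1   # heterozygous at every even marker
        parent[1, 1::2] = 1
        off = parent[0].copy()
        # make the second tile equally distant from both haplotypes
        off[150:] = 0
        tiles = transmission.tile_partition(300, 150)
        tm = transmission.match_tiles(off, parent, tiles)
        assert tm.source[0] == 1
        assert tm.source[1] == 1 and tm.tie[1]

    def test_matches_bruteforce_argmin(self):
        rng = substream(2, "mt")
        for trial in range(5):
            parent = _rand_parent(rng, 400)
            off = _rand_parent(rng, 400)[0]
            tiles = transmission.tile_partition(400, 100)
            tm = transmission.match_tiles(off, parent, tiles, min_informative=1)
            for t, tile in enumerate(tiles):
                m1 = (off[tile.start:tile.end] != parent[0, tile.start:tile.end]).sum()
                m2 = (off[tile.start:tile.end] != parent[1, tile.start:tile.end]).sum()
                assert tm.mismatch1[t] == m1 and tm.mismatch2[t] == m2
                if m1 != m2:
                    assert tm.source[t] == (1 if m1 < m2 else 2)


class TestAssignParentOfOrigin:
    def test_exact_haplotype_match(self):
        rng = substream(3, "ap")
        gmap = simfam.build_genetic_map(1, 300, 100.0)
        mother = _rand_parent(rng, 300)
        father = _rand_parent(rng, 300)
        off = np.stack([father[1], mother[0]])
        assign, margin, amb = transmission.assign_parent_of_origin(
            off, {"mother": mother, "father": father}, gmap
        )
        assert assign == {"mother": 1, "father": 0}
        assert not amb and margin > 0

    def test_identical_parents_flagged_ambiguous(self):
        rng = substream(4, "ap")
        gmap = simfam.build_genetic_map(1, 300, 100.0)
        parent = _rand_parent(rng, 300)
        off = np.stack([parent[0], parent[1]])
        _, margin, amb = transmission.assign_parent_of_origin(
            off, {"mother": parent, "father": parent.copy()}, gmap
        )
        assert amb and margin == 0.0

    def test_simulated_trios_fully_correct(self):
        """Error-free phase: inferred assignment matches truth-phase order."""
        ds = simfam.simulate_dataset(
            n_families=100, n_chromosomes=1, markers_per_chromosome=1000,
            length_cm=100.0, pair_fraction=0.0, n_offspring_per_couple=1, seed=6,
        )
        ped = ds.pedigree.set_index("individual_id")
        correct = 0
        for oid in ds.truth.source:
            fam = ped.loc[oid, "family_id"]
            sub = ds.pedigree[ds.pedigree["family_id"] == fam].set_index("role")
            parents = {
                r: ds.haps.haps[sub.loc[r, "individual_id"]]
                for r in ("mother", "father")
            }
            assign, _, amb = transmission.assign_parent_of_origin(
                ds.haps.haps[oid], parents, ds.gmap
            )
            # truth phase stores the maternal gamete as offspring haplotype 0
            correct += assign == {"mother": 0, "father": 1} and not amb
        assert correct == len(ds.truth.source)


class TestRefineBreakpoints:
    def test_midtile_crossover_recovered(self):
        """A crossover at marker 75 of a 150-marker tile (flanked by clean
        tiles) is localized within +-2 markers by the change-point scan."""
        rng = substream(5, "rb")
        checked = 0
        truth_bp = 225  # middle of the second of three tiles
        for _ in range(40):
            parent = _rand_parent(rng, 450)
            off = np.concatenate([parent[0, :truth_bp], parent[1, truth_bp:]])
            tiles = transmission.tile_partition(450, 150)
            tm = transmission.match_tiles(off, parent, tiles)
            src, bps = transmission.refine_breakpoints(tm, off, parent)
            # the refined source vector always reproduces the offspring hap
            np.testing.assert_array_equal(parent[src - 1, np.arange(450)], off)
            assert len(bps) == 1
            het = parent[0] != parent[1]
            if het[truth_bp - 2:truth_bp].any() and het[truth_bp:truth_bp + 2].any():
                assert abs(bps[0] - truth_bp) <= 2
                checked += 1
        assert checked >= 20  # the informative-flank condition mostly holds

    def test_no_change_passthrough(self):
        rng = substream(6, "rb")
        parent = _rand_parent(rng, 300)
        tiles = transmission.tile_partition(300, 150)
        tm = transmission.match_tiles(parent[1], parent, tiles)
        src, bps = transmission.refine_breakpoints(tm, parent[1], parent)
        assert bps == [] and (src == 2).all()


class TestInferTransmission:
    def test_permutation_invariant(self, small_dataset, small_tmap):
        """transmitted + non-transmitted = parental genotype, exactly, always."""
        ds = small_dataset
        ped = ds.pedigree.set_index("individual_id")
        fam_parent = {
            (r["family_id"], r["role"]): (r["individual_id"], r["genotyped"])
            for _, r in ds.pedigree[ds.pedigree["role"] != "offspring"].iterrows()
        }
        for oid, rec in small_tmap.records.items():
            fam = ped.loc[oid, "family_id"]
            for role in ("mother", "father"):
                pid, genotyped = fam_parent[(fam, role)]
                if not genotyped:
                    assert (rec.nontransmitted[role] == -1).all()
                    continue
                total = rec.transmitted[role].astype(int) + rec.nontransmitted[role]
                assert np.array_equal(total, ds.haps.dosage(pid))

    def test_clean_trio_exact_recovery(self):
        """Zero crossovers, error-free phase: inference equals truth everywhere."""
        ds = simfam.simulate_dataset(
            n_families=20, n_chromosomes=1, markers_per_chromosome=400,
            length_cm=0.0, pair_fraction=0.0, n_offspring_per_couple=1, seed=8,
        )
        tmap = transmission.infer_all(ds.haps, ds.pedigree)
        idx = np.arange(ds.gmap.n_markers)
        ped = ds.pedigree.set_index("individual_id")
        for oid, rec in tmap.records.items():
            fam = ped.loc[oid, "family_id"]
            sub = ds.pedigree[ds.pedigree["family_id"] == fam].set_index("role")
            for role in ("mother", "father"):
                pid = sub.loc[role, "individual_id"]
                src_true = ds.truth.source[oid][role]
                expect_nt = ds.haps.haps[pid][2 - src_true, idx]
                assert np.array_equal(rec.nontransmitted[role], expect_nt)

    def test_pair_consistent_with_trio(self):
        """Masking one parent preserves the genotyped parent's NT calls."""
        ds = simfam.simulate_dataset(
            n_families=40, n_chromosomes=1, markers_per_chromosome=1500,
            length_cm=100.0, pair_fraction=0.0, n_offspring_per_couple=1, seed=9,
        )
        trio_map = transmission.infer_all(ds.haps, ds.pedigree)
        ped_pair = ds.pedigree.copy()
        fathers = ped_pair["role"] == "father"
        ped_pair.loc[fathers, "genotyped"] = False
        pair_map = transmission.infer_all(ds.haps, ped_pair)
        agree = compared = 0
        for oid in trio_map.records:
            t_nt = trio_map.records[oid].nontransmitted["mother"]
            p_nt = pair_map.records[oid].nontransmitted["mother"]
            agree += int((t_nt == p_nt).sum())
            compared += len(t_nt)
        assert agree / compared >= 0.99

    def test_homozygous_markers_source_free(self, small_dataset, small_tmap):
        ds = small_dataset
        ped = ds.pedigree.set_index("individual_id")
        oid = next(iter(small_tmap.records))
        fam = ped.loc[oid, "family_id"]
        sub = ds.pedigree[ds.pedigree["family_id"] == fam].set_index("role")
        for role in ("mother", "father"):
            pid, genotyped = sub.loc[role, "individual_id"], sub.loc[role, "genotyped"]
            if not genotyped:
                continue
            hom = ds.haps.haps[pid][0] == ds.haps.haps[pid][1]
            rec = small_tmap.records[oid]
            assert np.array_equal(
                rec.transmitted[role][hom], rec.nontransmitted[role][hom]
            )


class TestConcordance:
    def test_perfect_inference(self, small_dataset, small_tmap):
        rep = transmission.concordance(
            small_tmap, small_dataset.truth, small_dataset.truth_haps,
            small_dataset.pedigree,
        )
        assert rep.rate > 0.985
        assert rep.compared > 0
        assert rep.concordant <= rep.compared
        assert np.isclose(rep.rate, rep.concordant / rep.compared)

    def test_disjoint_families_rejected(self, small_dataset, small_tmap):
        empty = simfam.TransmissionTruth()
        with pytest.raises(ValueError):
            transmission.concordance(
                small_tmap, empty, small_dataset.haps, small_dataset.pedigree
            )

    def test_degrades_with_switch_errors(self):
        """Concordance decreases monotonically (on average) in phase-error rate."""
        rates = [0.0, 0.002, 0.01]
        vals = []
        for rate in rates:
            ds = simfam.simulate_dataset(
                n_families=30, n_chromosomes=1, markers_per_chromosome=1000,
                length_cm=100.0, pair_fraction=0.0, n_offspring_per_couple=1,
                switch_error_rate=rate, seed=10,
            )
            tmap = transmission.infer_all(ds.haps, ds.pedigree)
            rep = transmission.concordance(
                tmap, ds.truth, ds.truth_haps, ds.pedigree
            )
            vals.append(rep.rate)
        assert vals[0] > vals[1] > vals[2]
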