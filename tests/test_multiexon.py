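import numpy as np
import pytest

from chemomine.multiexon import (
    GNAT3_EXON6_FWD,
    GNAT3_EXON6_REV,
    _revcomp_iupac,
    annotate_disruptions_vs_reference,
    annotate_exon_boundaries,
    compute_dotplot,
    confirm_deletion,
    detect_inversion,
    insilico_pcr,
    map_exons,
)
from chemomine.seqcore import NucSequence, revcomp
from chemomine.synthetic import MultiExonSpec, plant_multiexon, _random_dna


@pytest.fixture(scope="module")
def omacs_like():
    """13-exon reference/target pair with exons {5,9,10,11} segmentally lost."""
    return plant_multiexon(MultiExonSpec(gene_id="omacs_like", n_exons=13),
                           delete_exons={5, 9, 10, 11}, seed=7)


class TestMapExons:
    def test_self_audit_finds_every_exon_in_place(self, omacs_like):
        ref, _, model, _ = omacs_like
        pm = map_exons([ref], model, source_genome=[ref])
        assert pm.absent() == []
        for num, _seq, iv in model.exons:
            p = pm.placements[num]
            assert (p.interval.start, p.interval.end) == (iv.start, iv.end)
            assert p.strand == "+"
        orders = [pm.placements[n].order_index for n in range(1, 14)]
        assert orders == sorted(orders)

    def test_planted_losses_detected_exactly(self, omacs_like):
        ref, tgt, model, _ = omacs_like
        pm = map_exons([tgt], model, source_genome=[ref])
        assert pm.absent() == [5, 9, 10, 11]

    def test_additional_losses(self):
        ref, tgt, model, _ = plant_multiexon(
            MultiExonSpec(gene_id="omacs_like", n_exons=13),
            delete_exons={1, 2, 5, 9, 10, 11}, seed=7,
        )
        pm = map_exons([tgt], model, source_genome=[ref])
        assert pm.absent() == [1, 2, 5, 9, 10, 11]

    def test_short_exon_flagged_unmappable(self):
        from chemomine.multiexon import ExonModel
        from chemomine.seqcore import GenomicInterval

        rng = np.random.default_rng(0)
        tiny = _random_dna(rng, 12)
        big = _random_dna(rng, 200)
        model = ExonModel(gene_id="g", exons=(
            (1, NucSequence(id="e1", residues=tiny), GenomicInterval("r", 0, 12)),
            (2, NucSequence(id="e2", residues=big), GenomicInterval("r", 1000, 1200)),
        ))
        pm = map_exons([NucSequence(id="t", residues=big + _random_dna(rng, 500))], model)
        assert pm.placements[1].status == "ambiguous"
        assert pm.placements[2].status == "found"


class TestConfirmDeletion:
    def test_segmental_losses_confirmed_deleted(self, omacs_like):
        ref, tgt, model, _ = omacs_like
        pm = map_exons([tgt], model, source_genome=[ref])
        verdicts = confirm_deletion([tgt], pm, model)
        assert verdicts == {5: "deleted", 9: "deleted", 10: "deleted", 11: "deleted"}

    def test_gap_between_flanks_means_assembly_gap(self):
        ref, tgt, model, _ = plant_multiexon(
            MultiExonSpec(gene_id="g", n_exons=6), delete_exons={3}, seed=9,
        )
        # splice a 500 bp N-run into the deletion scar
        e2 = model.exon(2)[1].residues
        scar = tgt.residues.find(e2) + len(e2) + 30
        gappy = NucSequence(
            id=tgt.id, residues=tgt.residues[:scar] + "N" * 500 + tgt.residues[scar:]
        )
        pm = map_exons([gappy], model, source_genome=[ref])
        assert pm.absent() == [3]
        assert confirm_deletion([gappy], pm, model)[3] == "assembly_gap"

    def test_terminal_exon_without_flank_unresolved(self):
        ref, tgt, model, _ = plant_multiexon(
            MultiExonSpec(gene_id="g", n_exons=6), delete_exons={1}, seed=10,
        )
        # cut the target right before exon 2 so exon 1 has no upstream flank
        e2 = model.exon(2)[1].residues
        cut = tgt.residues.find(e2) - 10
        pm = map_exons([NucSequence(id="t", residues=tgt.residues[cut:])], model,
                       source_genome=[ref])
        assert 1 in pm.absent()
        assert confirm_deletion([NucSequence(id="t", residues=tgt.residues[cut:])],
                                pm, model)[1] == "unresolved"


class TestDotPlot:
    def test_self_comparison_diagonal_is_100(self):
        rng = np.random.default_rng(1)
        seq = NucSequence(id="a", residues=_random_dna(rng, 8000))
        dp = compute_dotplot(seq, seq, mesh=1000)
        assert np.allclose(np.diag(dp.grid), 100.0)

    def test_revcomp_antidiagonal(self):
        rng = np.random.default_rng(2)
        seq = NucSequence(id="a", residues=_random_dna(rng, 8000))  # multiple of mesh
        dp = compute_dotplot(seq, revcomp(seq), mesh=1000)
        n = dp.grid.shape[0]
        assert np.allclose([dp.grid[i, n - 1 - i] for i in range(n)], 100.0)

    def test_unrelated_sequences_are_dark(self):
        rng = np.random.default_rng(3)
        a = NucSequence(id="a", residues=_random_dna(rng, 6000))
        b = NucSequence(id="b", residues=_random_dna(rng, 6000))
        grid = compute_dotplot(a, b, mesh=1000).grid
        assert (grid < 50).mean() > 0.95

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(4)
        a = NucSequence(id="a", residues=_random_dna(rng, 5000))
        b = NucSequence(id="b", residues=a.residues[1500:4000] + _random_dna(rng, 2500))
        assert np.allclose(compute_dotplot(a, b, mesh=1000).grid,
                           compute_dotplot(b, a, mesh=1000).grid.T)

    def test_bad_mesh(self):
        rng = np.random.default_rng(5)
        a = NucSequence(id="a", residues=_random_dna(rng, 2000))
        with pytest.raises(ValueError):
            compute_dotplot(a, a, mesh=0)


class TestInversion:
    def test_planted_block_recovered(self):
        ref, tgt, model, _ = plant_multiexon(
            MultiExonSpec(gene_id="nqo1_like", n_exons=6), invert_exons={4, 5}, seed=8,
        )
        pm = map_exons([tgt], model, source_genome=[ref])
        events = detect_inversion(pm)
        assert [sorted(ev.exons) for ev in events] == [[4, 5]]

    def test_collinear_has_no_events(self, omacs_like):
        ref, _, model, _ = omacs_like
        pm = map_exons([ref], model, source_genome=[ref])
        assert detect_inversion(pm) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_seeded_replicates_recover_planted_blocks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        start = int(rng.integers(2, n - 2))
        block = {start, start + 1}
        ref, tgt, model, _ = plant_multiexon(
            MultiExonSpec(gene_id="g", n_exons=n), invert_exons=block, seed=100 + seed,
        )
        pm = map_exons([tgt], model, source_genome=[ref])
        events = detect_inversion(pm)
        assert [set(ev.exons) for ev in events] == [block]

    def test_single_found_exon_indeterminate(self):
        from chemomine.multiexon import ExonPlacement, ExonPresenceMap
        from chemomine.seqcore import GenomicInterval

        pm = ExonPresenceMap(gene_id="g", placements={
            1: ExonPlacement(status="found",
                             interval=GenomicInterval("t", 10, 100, "-"),
                             strand="-", order_index=0),
            2: ExonPlacement(status="absent"),
        })
        assert detect_inversion(pm) == []


class TestBoundaryRefinement:
    @staticmethod
    def _restricted(rng, n, alphabet):
        return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))

    def test_offset_boundaries_snap_to_gt_ag(self):
        # exons over {A,C,T} and intron body over {C,T}: the planted GT..AG is
        # the only candidate splice signal within reach of the perturbation
        rng = np.random.default_rng(12)
        e1 = self._restricted(rng, 100, "ACT")
        e2 = self._restricted(rng, 120, "ACT")
        e3 = self._restricted(rng, 90, "ACT")
        i1 = "GT" + self._restricted(rng, 76, "CT") + "AG"
        i2 = "GT" + self._restricted(rng, 90, "CT") + "AG"
        seq = NucSequence(id="t", residues=e1 + i1 + e2 + i2 + e3)
        true_ivs = [(1, 0, 100), (2, 180, 300), (3, 394, 484)]
        perturbed = [(1, 0, 104), (2, 176, 297), (3, 390, 484)]
        refined, flags = annotate_exon_boundaries(seq, perturbed)
        assert not flags
        assert refined == true_ivs

    def test_non_canonical_intron_flagged(self):
        rng = np.random.default_rng(13)
        e1 = self._restricted(rng, 100, "ACT")
        e2 = self._restricted(rng, 100, "ACT")
        intron = "CC" + self._restricted(rng, 96, "CT") + "TT"
        seq = NucSequence(id="t", residues=e1 + intron + e2)
        refined, flags = annotate_exon_boundaries(
            seq, [(1, 0, 100), (2, 200, 300)]
        )
        assert refined == [(1, 0, 100), (2, 200, 300)]
        assert 1 in flags and 2 in flags

    def test_single_exon_untouched(self):
        rng = np.random.default_rng(14)
        seq = NucSequence(id="t", residues=_random_dna(rng, 400))
        refined, flags = annotate_exon_boundaries(seq, [(1, 50, 350)])
        assert refined == [(1, 50, 350)] and not flags


class TestReferenceCoordinateEvents:
    @pytest.fixture(scope="class")
    @staticmethod
    def ref_cds():
        rng = np.random.default_rng(15)
        s = list(_random_dna(rng, 900))
        s[641:644] = "CAG"  # unambiguous deletion context
        return NucSequence(id="ref", residues="".join(s))

    def test_identical_target_has_no_events(self, ref_cds):
        events, _ = annotate_disruptions_vs_reference(
            [NucSequence(id="t", residues=ref_cds.residues)], ref_cds
        )
        assert events["t"] == []

    def test_shared_deletion_and_stop(self, ref_cds):
        def target(name):
            s = list(ref_cds.residues)
            s[657:660] = list("TAA")
            del s[642]
            return NucSequence(id=name, residues="".join(s))

        events, shared = annotate_disruptions_vs_reference(
            [target("w"), target("d"), NucSequence(id="c", residues=ref_cds.residues)],
            ref_cds, groups={"cet": ["w", "d"], "all": ["w", "d", "c"]},
        )
        cet = {(e.kind, e.ref_start) for e in shared["cet"]}
        assert cet == {("deletion", 643), ("premature_stop", 658)}
        assert shared["all"] == []  # the undisrupted member breaks sharing

    def test_unalignable_target_excluded(self, ref_cds):
        rng = np.random.default_rng(16)
        junk = NucSequence(id="junk", residues=_random_dna(rng, 900))
        events, _ = annotate_disruptions_vs_reference([junk], ref_cds)
        assert "junk" not in events


class TestInsilicoPcr:
    def _template(self, inner_gap, seed=17):
        rng = np.random.default_rng(seed)
        fwd_site = GNAT3_EXON6_FWD.replace("R", "A")
        rev_site = _revcomp_iupac(GNAT3_EXON6_REV)
        return NucSequence(
            id="t", residues=_random_dna(rng, 200) + fwd_site
            + _random_dna(rng, inner_gap) + rev_site + _random_dna(rng, 200),
        )

    def test_printed_primers_amplify_printed_length(self):
        inner = 299 - len(GNAT3_EXON6_FWD) - len(GNAT3_EXON6_REV)
        amps = insilico_pcr(self._template(inner), GNAT3_EXON6_FWD, GNAT3_EXON6_REV)
        assert len(amps) == 1
        assert amps[0].length == 299
        assert amps[0].fwd_mismatches == 0 and amps[0].rev_mismatches == 0

    def test_degenerate_position_matches_both_expansions(self):
        inner = 100
        for base in "AG":  # R expands to A or G
            rng = np.random.default_rng(18)
            fwd_site = GNAT3_EXON6_FWD.replace("R", base)
            t = NucSequence(
                id="t", residues=_random_dna(rng, 50) + fwd_site
                + _random_dna(rng, inner) + _revcomp_iupac(GNAT3_EXON6_REV)
                + _random_dna(rng, 50),
            )
            amps = insilico_pcr(t, GNAT3_EXON6_FWD, GNAT3_EXON6_REV)
            assert len(amps) == 1 and amps[0].fwd_mismatches == 0

    def test_missing_reverse_site_gives_nothing(self):
        rng = np.random.default_rng(19)
        t = NucSequence(
            id="t", residues=_random_dna(rng, 200)
            + GNAT3_EXON6_FWD.replace("R", "G") + _random_dna(rng, 400),
        )
        assert insilico_pcr(t, GNAT3_EXON6_FWD, GNAT3_EXON6_REV) == []

    def test_product_length_equals_planted_distance(self):
        for inner in (40, 137, 500):
            amps = insilico_pcr(self._template(inner), GNAT3_EXON6_FWD,
                                GNAT3_EXON6_REV)
            expected = inner + len(GNAT3_EXON6_FWD) + len(GNAT3_EXON6_REV)
            assert [a.length for a in amps] == [expected]
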