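import numpy as np
import pytest

from chemomine.genecall import (
    GeneCall,
    MISSING_TM_MAX_COVERAGE,
    PSEUDOGENIZING,
    call_locus,
    classify_gene,
    detect_disruptions,
    edge_context,
    reconstruct_cds,
    summarize_repertoire,
    tm_coverage,
)
from chemomine.search import CandidateLocus
from chemomine.seqcore import GenomicInterval, NucSequence

from conftest import embed_gene


def locus_on(scaf_id, start, end, strand="+", family="fam"):
    return CandidateLocus(
        interval=GenomicInterval(scaf_id, start, end, strand),
        supporting_hits=[], family=family,
    )


@pytest.fixture(scope="module")
def profile(gpcr_family):
    return gpcr_family[1]


class TestReconstruct:
    def test_full_orf_locus_zero_extension(self, profile, planted_scaffold):
        scaf, cs, ce = planted_scaffold
        model = reconstruct_cds(locus_on(scaf.id, cs, ce), profile, {scaf.id: scaf})
        assert model.start_found and model.stop_found
        assert model.ext5 == 0 and model.ext3 == 0
        assert model.cds_seq == scaf.residues[cs:ce]

    def test_hit_inside_orf_recovers_planted_start(self, profile, planted_scaffold):
        scaf, cs, ce = planted_scaffold
        model = reconstruct_cds(locus_on(scaf.id, cs + 30, ce - 30), profile,
                                {scaf.id: scaf})
        assert model.start_found and model.stop_found
        assert model.cds_seq == scaf.residues[cs:ce]
        assert model.cds_seq.startswith("ATG")

    def test_start_lost_at_scaffold_edge_flagged(self, profile, ancestor_cds):
        frag = ancestor_cds[60:]  # 5' side including the ATG removed
        rng = np.random.default_rng(9)
        scaf = NucSequence(
            id="edge", residues=frag + "".join("ACGT"[i] for i in rng.integers(4, size=2000))
        )
        model = reconstruct_cds(locus_on("edge", 0, len(frag)), profile, {"edge": scaf})
        assert not model.start_found
        assert model.edge5

    def test_minus_strand_reconstruction(self, profile, ancestor_cds):
        from chemomine.seqcore import revcomp

        scaf = revcomp(embed_gene(ancestor_cds, seed=14))
        lo = len(scaf) - (2000 + len(ancestor_cds))
        hi = len(scaf) - 2000
        model = reconstruct_cds(locus_on(scaf.id, lo, hi, "-"), profile,
                                {scaf.id: scaf})
        assert model.start_found and model.stop_found
        assert model.cds_seq == ancestor_cds


class TestDisruptions:
    def _model(self, profile, cds, seed=0):
        scaf = embed_gene(cds, seed=seed)
        return reconstruct_cds(locus_on(scaf.id, 2000, 2000 + len(cds)), profile,
                               {scaf.id: scaf})

    def test_unmutated_gene_clean(self, profile, ancestor_cds):
        model = self._model(profile, ancestor_cds)
        assert detect_disruptions(model, profile) == []

    def test_premature_stop_position(self, profile, ancestor_cds):
        c = 150  # 1-based codon index
        mutant = ancestor_cds[:3 * (c - 1)] + "TGA" + ancestor_cds[3 * c:]
        model = self._model(profile, mutant)
        stops = [d for d in detect_disruptions(model, profile) if d.kind == "premature_stop"]
        assert len(stops) == 1
        assert stops[0].cds_pos == c

    def test_one_bp_deletion_detected(self, profile, ancestor_cds):
        p = 88  # 1-based CDS position
        mutant = ancestor_cds[:p - 1] + ancestor_cds[p:]
        model = self._model(profile, mutant)
        fs = [d for d in detect_disruptions(model, profile) if d.kind == "frameshift_indel"]
        assert len(fs) == 1
        assert fs[0].detail == "1-bp deletion"
        assert abs(fs[0].cds_pos - p) <= 9  # gap placement may slide within a codon or two

    def test_two_bp_insertion_detected(self, profile, ancestor_cds):
        p = 300
        mutant = ancestor_cds[:p] + "GG" + ancestor_cds[p:]
        model = self._model(profile, mutant)
        fs = [d for d in detect_disruptions(model, profile) if d.kind == "frameshift_indel"]
        assert len(fs) == 1
        assert "insertion" in fs[0].detail


class TestTmCoverage:
    def test_intact_gene_all_segments_complete(self, profile, ancestor_cds):
        scaf = embed_gene(ancestor_cds, seed=0)
        model = reconstruct_cds(locus_on(scaf.id, 2000, 2000 + len(ancestor_cds)),
                                profile, {scaf.id: scaf})
        cov, obs = tm_coverage(model, profile)
        assert all(v == 1.0 for v in cov.values())
        assert all(obs.values())

    def test_whole_tm_deletion_is_missing(self, profile, ancestor_cds):
        s, e = profile.tm_consensus[2]  # TM3
        mutant = ancestor_cds[:3 * s] + ancestor_cds[3 * e:]
        scaf = embed_gene(mutant, seed=1)
        model = reconstruct_cds(locus_on(scaf.id, 2000, 2000 + len(mutant)),
                                profile, {scaf.id: scaf})
        cov, obs = tm_coverage(model, profile)
        assert cov["TM3"] <= MISSING_TM_MAX_COVERAGE
        assert all(cov[t] > 0.8 for t in cov if t != "TM3")
        kinds = {d.kind: d for d in detect_disruptions(model, profile)}
        assert "missing_tm" in kinds
        assert "TM3" in kinds["missing_tm"].detail

    def test_half_tm_deletion_is_not_missing(self, profile, ancestor_cds):
        s, e = profile.tm_consensus[4]  # TM5
        half = (e - s) // 2
        mutant = ancestor_cds[:3 * s] + ancestor_cds[3 * (s + half):]
        scaf = embed_gene(mutant, seed=2)
        model = reconstruct_cds(locus_on(scaf.id, 2000, 2000 + len(mutant)),
                                profile, {scaf.id: scaf})
        cov, _ = tm_coverage(model, profile)
        assert 0.3 <= cov["TM5"] <= 0.7
        assert not any(d.kind == "missing_tm"
                       for d in detect_disruptions(model, profile))


class TestClassification:
    def test_pseudogenization_dominates_edge_context(self, profile, ancestor_cds):
        """A premature stop near a scaffold edge is a pseudogene, never
        truncated: truncation is defined only for non-pseudogenized loci."""
        mutant = ancestor_cds[:450] + "TAA" + ancestor_cds[453:]
        scaf = embed_gene(mutant, left=100, right=2000, seed=5)
        call = call_locus(locus_on(scaf.id, 100, 100 + len(mutant)), profile,
                          {scaf.id: scaf})
        assert call.label == "pseudogene"
        assert any(d.kind == "premature_stop" for d in call.disruptions)

    def test_missing_start_near_edge_is_truncated(self, profile, ancestor_cds):
        frag = ancestor_cds[90:]
        rng = np.random.default_rng(6)
        scaf = NucSequence(
            id="s", residues="".join("ACGT"[i] for i in rng.integers(4, size=200))
            + frag + "".join("ACGT"[i] for i in rng.integers(4, size=2000)),
        )
        call = call_locus(locus_on("s", 200, 200 + len(frag)), profile, {"s": scaf})
        assert call.label == "truncated"
        assert {d.kind for d in call.disruptions} == {"missing_start"}

    def test_missing_start_without_edge_context_is_pseudogene(self, profile, ancestor_cds):
        frag = ancestor_cds[90:]
        scaf = embed_gene(frag, left=3000, right=3000, seed=7)
        call = call_locus(locus_on(scaf.id, 3000, 3000 + len(frag)), profile,
                          {scaf.id: scaf})
        assert call.label == "pseudogene"

    def test_intact_gene(self, profile, planted_scaffold):
        scaf, cs, ce = planted_scaffold
        call = call_locus(locus_on(scaf.id, cs, ce), profile, {scaf.id: scaf})
        assert call.label == "intact"
        assert call.disruptions == []
        assert call.cds.residues == scaf.residues[cs:ce]

    def test_adding_stop_always_pseudogenizes(self, profile, ancestor_cds):
        """Monotonicity: mutating an intact CDS with a premature stop and
        re-classifying yields pseudogene, at any interior codon."""
        for codon in (60, 150, 250):
            mutant = ancestor_cds[:3 * codon] + "TGA" + ancestor_cds[3 * codon + 3:]
            scaf = embed_gene(mutant, seed=codon)
            call = call_locus(locus_on(scaf.id, 2000, 2000 + len(mutant)), profile,
                              {scaf.id: scaf})
            assert call.label == "pseudogene"

    def test_label_invariants(self, profile, ancestor_cds):
        """Every call satisfies the label/disruption contract."""
        cases = [
            ancestor_cds,
            ancestor_cds[:450] + "TAA" + ancestor_cds[453:],
            ancestor_cds[:100] + ancestor_cds[101:],
        ]
        for i, cds in enumerate(cases):
            scaf = embed_gene(cds, seed=40 + i)
            call = call_locus(locus_on(scaf.id, 2000, 2000 + len(cds)), profile,
                              {scaf.id: scaf})
            kinds = {d.kind for d in call.disruptions}
            if call.label == "pseudogene":
                assert kinds & (PSEUDOGENIZING | {"missing_start", "missing_stop"})
            elif call.label == "truncated":
                assert kinds <= {"missing_start", "missing_stop"} and kinds
            else:
                assert not kinds


class TestEdgeContext:
    def test_distance_to_gap_and_scaffold_end(self):
        scaf = NucSequence(id="s", residues="A" * 500 + "N" * 150 + "A" * 2000)
        d = edge_context(locus_on("s", 900, 1200), {"s": scaf}, gap_min=100)
        assert d == 900 - 650  # gap run ends at 650
        d2 = edge_context(locus_on("s", 2400, 2600), {"s": scaf}, gap_min=100)
        assert d2 == 50  # scaffold end at 2650

    def test_short_n_runs_ignored(self):
        scaf = NucSequence(id="s", residues="A" * 1000 + "N" * 20 + "A" * 1000)
        d = edge_context(locus_on("s", 1100, 1200), {"s": scaf}, gap_min=100)
        assert d == 820  # only the scaffold ends count


class TestSummary:
    def test_counts_and_conservation(self, profile, ancestor_cds):
        calls = []
        for i, cds in enumerate([ancestor_cds] * 2
                                + [ancestor_cds[:450] + "TAA" + ancestor_cds[453:]]):
            scaf = embed_gene(cds, seed=60 + i, scaffold_id=f"scf{i}")
            calls.append(call_locus(locus_on(f"scf{i}", 2000, 2000 + len(cds)),
                                    profile, {f"scf{i}": scaf}))
        df = summarize_repertoire(calls)
        row = df.loc["fam"]
        assert row["intact"] == 2 and row["pseudogene"] == 1
        assert row["total"] == row["intact"] + row["truncated"] + row["pseudogene"]

    def test_empty(self):
        df = summarize_repertoire([])
        assert len(df) == 0
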