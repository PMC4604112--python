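"""Self-contained benchmark runs used by the acceptance tests and the
reproduction script: planted-truth recovery, aligner score agreement against a
full dynamic-programming reference, exon-loss/inversion worked examples,
neighbor-joining round-trips, dN/dS simulations, class I/II classification
accuracy, and the in-silico PCR / shared-disruption worked examples.

Every function takes an explicit seed and recomputes its quantities from
scratch by running the pipeline on synthetic inputs.
"""

from __future__ import annotations

import math

import numpy as np

from . import _align
from .genecall import call_locus, resolve_family_overlaps
from .multiexon import (
    GNAT3_EXON6_FWD,
    GNAT3_EXON6_REV,
    annotate_disruptions_vs_reference,
    confirm_deletion,
    detect_inversion,
    insilico_pcr,
    map_exons,
    _revcomp_iupac,
)
from .phyloclass import DistanceMatrix, build_nj, dnds_nei_gojobori, place_one_by_one
from .search import merge_hits, reciprocal_filter, translated_search
from .seqcore import CODON_TABLE, NucSequence, ProtSequence, translate_str
from .synthetic import (
    AA20,
    MultiExonSpec,
    PlantSpec,
    _back_translate,
    _mutate_protein,
    _random_dna,
    plant_genome,
    plant_multiexon,
)

DEFAULT_FAMILIES = ("OR", "TAAR", "V1R")


def _child_seed(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# planted-truth recovery


def mine_synthetic_genome(seed: int, families=DEFAULT_FAMILIES):
    """Plant a benchmark genome and run the full mining chain on it.

    Returns (truth records, matched calls) where matched calls pair each truth
    record with the GeneCall overlapping it (or None if missed).
    """
    specs = [PlantSpec(family=f, seed=i) for i, f in enumerate(families)]
    sg = plant_genome(specs, seed=seed)
    genome_by_id = sg.genome_by_id()
    proteome = [r for refs, _ in sg.families.values() for r in refs]
    loci_by_family = {
        fam: merge_hits(translated_search(sg.genome, refs), family=fam)
        for fam, (refs, _) in sg.families.items()
    }
    loci_by_family = resolve_family_overlaps(loci_by_family)
    calls = []
    for fam, (refs, profile) in sg.families.items():
        kept, _ = reciprocal_filter(
            loci_by_family[fam], sg.genome, proteome, {r.id for r in refs}
        )
        calls.extend(
            c for c in (call_locus(l, profile, genome_by_id) for l in kept) if c
        )
    matched = []
    for tr in sg.truth:
        cands = [
            c for c in calls
            if c.locus.family == tr.family and c.locus.interval.overlaps(tr.interval)
        ]
        matched.append((tr, max(cands, key=lambda c: len(c.locus.interval))
                        if cands else None))
    return matched


def planted_recovery(seed: int, n_genomes: int = 20):
    """Label-recovery rate over seeded synthetic genomes.

    Returns dict with recovery percentage, the number of planted elements, and
    the count of unmutated intact genes wrongly called pseudogene.
    """
    total = correct = false_pseudo = 0
    for g in range(n_genomes):
        for tr, call in mine_synthetic_genome(_child_seed(seed, 1, g)):
            total += 1
            if call is None:
                continue
            if call.label == tr.label:
                correct += 1
            if tr.label == "intact" and call.label == "pseudogene":
                false_pseudo += 1
    return {
        "recovery_pct": 100.0 * correct / total,
        "n": total,
        "false_pseudogene_calls": false_pseudo,
    }


# ---------------------------------------------------------------------------
# aligner score agreement vs full dynamic programming


def _full_dp_reference_score(dna: str, prot: str) -> int:
    """Independent full-DP local alignment score: best over the six frame
    translations, computed with Biopython's PairwiseAligner."""
    from Bio.Align import PairwiseAligner, substitution_matrices

    from .seqcore import revcomp_str

    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    aligner.mode = "local"
    best = 0
    for strand_seq in (dna, revcomp_str(dna)):
        for frame in range(3):
            aa = translate_str(strand_seq, frame)
            if aa:
                best = max(best, int(aligner.score(prot, aa)))
    return best


def make_planted_instance(rng):
    """Random small instance: a protein query whose (mutated) coding sequence
    is embedded in random DNA. Identity of the planted copy is ~0.85."""
    qlen = int(rng.integers(100, 450))
    prot = "M" + "".join(AA20[i] for i in rng.integers(len(AA20), size=qlen - 1))
    planted = _mutate_protein(rng, prot, 0.15)
    coding = _back_translate(rng, planted)
    extra = int(rng.integers(60, max(2000 - len(coding), 61)))
    left = int(rng.integers(0, extra))
    dna = _random_dna(rng, left) + coding + _random_dna(rng, extra - left)
    if rng.random() < 0.5:
        from .seqcore import revcomp_str

        dna = revcomp_str(dna)
    return dna, prot


def aligner_agreement(seed: int, n_instances: int = 200):
    """Fraction of random planted instances where the search engine's best raw
    score equals the full-DP local alignment score."""
    rng = np.random.default_rng(_child_seed(seed, 2))
    agree = 0
    for _ in range(n_instances):
        dna, prot = make_planted_instance(rng)
        hits = translated_search(
            [NucSequence(id="t", residues=dna)],
            [ProtSequence(id="q", residues=prot)],
            evalue_cutoff=1e9,
        )
        engine = max((h.raw_score for h in hits), default=0)
        reference = _full_dp_reference_score(dna, prot)
        agree += engine == reference
    return {"agreement_pct": 100.0 * agree / n_instances, "n": n_instances}


# ---------------------------------------------------------------------------
# exon loss / inversion worked examples


def exon_loss_worked_example(seed: int):
    """13-exon gene with exons {5,9,10,11} lost; returns the absent set and
    how many of the four carry a 'deleted' verdict."""
    ref, tgt, model, _ = plant_multiexon(
        MultiExonSpec(gene_id="omacs_like", n_exons=13),
        delete_exons={5, 9, 10, 11}, seed=_child_seed(seed, 3),
    )
    presence = map_exons([tgt], model, source_genome=[ref])
    verdicts = confirm_deletion([tgt], presence, model)
    absent = presence.absent()
    return {
        "absent_exons": absent,
        "n_absent": len(absent),
        "n_deleted_verdicts": sum(1 for v in verdicts.values() if v == "deleted"),
        "n_exons": model.n_exons,
    }


def inversion_worked_example(seed: int):
    """6-exon gene with exons {4,5} reverse-complemented in place."""
    ref, tgt, model, _ = plant_multiexon(
        MultiExonSpec(gene_id="nqo1_like", n_exons=6),
        invert_exons={4, 5}, seed=_child_seed(seed, 4),
    )
    presence = map_exons([tgt], model, source_genome=[ref])
    events = detect_inversion(presence)
    return {
        "n_events": len(events),
        "event_exons": sorted(events[0].exons) if events else [],
        "n_exons": model.n_exons,
    }


# ---------------------------------------------------------------------------
# neighbor-joining round-trip


def random_additive_tree_matrix(rng, n_taxa: int):
    """Distance matrix of a random binary tree with U(0.05,1) branch lengths,
    computed by explicit path summation (independent of the NJ code)."""
    # start from a 3-star, repeatedly attach new leaves to random edges
    # adjacency: node -> list of (node, length)
    adj: dict[int, list] = {}

    def connect(a, b, ln):
        adj.setdefault(a, []).append((b, ln))
        adj.setdefault(b, []).append((a, ln))

    leaves = [0, 1, 2]
    internal = -1
    for leaf in leaves:
        connect(leaf, internal, float(rng.uniform(0.05, 1.0)))
    edges = [(0, internal), (1, internal), (2, internal)]
    next_internal = -2
    for leaf in range(3, n_taxa):
        a, b = edges[rng.integers(len(edges))]
        ln = dict(adj[a])[b]
        adj[a] = [(x, l) for x, l in adj[a] if x != b]
        adj[b] = [(x, l) for x, l in adj[b] if x != a]
        mid = next_internal
        next_internal -= 1
        split = float(rng.uniform(0.2, 0.8)) * ln
        connect(a, mid, split)
        connect(b, mid, ln - split)
        connect(leaf, mid, float(rng.uniform(0.05, 1.0)))
        edges.remove((a, b))
        edges.extend([(a, mid), (b, mid), (leaf, mid)])

    def dist(src, dst):
        stack = [(src, None, 0.0)]
        while stack:
            node, prev, acc = stack.pop()
            if node == dst:
                return acc
            for nxt, ln in adj[node]:
                if nxt != prev:
                    stack.append((nxt, node, acc + ln))
        raise RuntimeError("disconnected tree")

    m = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            m[i, j] = m[j, i] = dist(i, j)
    return m


def nj_roundtrip(seed: int, n_trees: int = 100):
    """Max absolute deviation between input additive distances and the
    path-length matrix of the reconstructed NJ tree, over random trees."""
    rng = np.random.default_rng(_child_seed(seed, 5))
    worst = 0.0
    for _ in range(n_trees):
        n_taxa = int(rng.integers(5, 13))
        m = random_additive_tree_matrix(rng, n_taxa)
        ids = tuple(f"t{i}" for i in range(n_taxa))
        tree = build_nj(DistanceMatrix(ids=ids, matrix=m))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i in range(n_taxa):
            for j in range(i + 1, n_taxa):
                err = abs(pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]]) - m[i, j])
                worst = max(worst, err)
    return {"max_abs_error": worst, "n": n_trees}


# ---------------------------------------------------------------------------
# dN/dS


def synonymous_pair_omega():
    """omega for a constructed pair differing only by synonymous
    third-position changes (must be exactly 0)."""
    a = "GCT" * 90 + "GCC" * 10
    b = "GCT" * 100
    r = dnds_nei_gojobori(a, b)
    return {"omega": r.omega, "dn": r.dn, "ds": r.ds, "n": 100}


def _random_codons(rng, n: int) -> list:
    codons = [c for c, aa in sorted(CODON_TABLE.items()) if aa != "*"]
    return [codons[i] for i in rng.integers(len(codons), size=n)]


def _evolve(rng, codons: list, n_attempts: int, nonsyn_accept: float) -> list:
    out = list(codons)
    for _ in range(n_attempts):
        i = int(rng.integers(len(out)))
        pos = int(rng.integers(3))
        base = "ACGT"[rng.integers(4)]
        cand = out[i][:pos] + base + out[i][pos + 1:]
        if cand == out[i] or CODON_TABLE[cand] == "*":
            continue
        if CODON_TABLE[cand] == CODON_TABLE[out[i]] or rng.random() < nonsyn_accept:
            out[i] = cand
    return out


def dnds_selection_simulation(seed: int, n_replicates: int = 100,
                              n_codons: int = 300, nonsyn_accept: float = 0.1):
    """Fraction of replicate pairs evolved under purifying selection
    (nonsynonymous changes accepted at ``nonsyn_accept`` the synonymous rate)
    with omega < 1."""
    rng = np.random.default_rng(_child_seed(seed, 6))
    below = 0
    usable = 0
    for _ in range(n_replicates):
        anc = _random_codons(rng, n_codons)
        a = _evolve(rng, anc, n_codons, nonsyn_accept)
        b = _evolve(rng, anc, n_codons, nonsyn_accept)
        r = dnds_nei_gojobori("".join(a), "".join(b))
        if r.omega is None or not math.isfinite(r.omega):
            continue
        usable += 1
        below += r.omega < 1.0
    return {"omega_lt1_pct": 100.0 * below / usable, "n": usable}


def dnds_neutral_simulation(seed: int, n_codons: int = 500):
    """Mean omega under neutral evolution (expected close to 1)."""
    rng = np.random.default_rng(_child_seed(seed, 7))
    omegas = []
    for _ in range(20):
        anc = _random_codons(rng, n_codons)
        a = _evolve(rng, anc, n_codons // 2, 1.0)
        b = _evolve(rng, anc, n_codons // 2, 1.0)
        r = dnds_nei_gojobori("".join(a), "".join(b))
        if r.omega is not None and math.isfinite(r.omega):
            omegas.append(r.omega)
    return {"mean_omega": float(np.mean(omegas)), "n": len(omegas)}


# ---------------------------------------------------------------------------
# class I / class II classification


def make_class_references(rng, length_aa: int = 300, n_per_class: int = 8,
                          class_divergence: float = 0.35,
                          ref_divergence: float = 0.12):
    root = "M" + "".join(AA20[i] for i in rng.integers(len(AA20), size=length_aa - 1))
    anc = {
        "classI": _mutate_protein(rng, root, class_divergence),
        "classII": _mutate_protein(rng, root, class_divergence),
    }
    refs = []
    labels = {}
    for cls, ancestor in anc.items():
        for i in range(n_per_class):
            rid = f"{cls}_ref{i + 1}"
            refs.append(ProtSequence(id=rid,
                                     residues=_mutate_protein(rng, ancestor, ref_divergence)))
            labels[rid] = cls
    return refs, labels, anc


def classification_accuracy(seed: int, n_queries: int = 200,
                            max_divergence: float = 0.2):
    """Accuracy of class assignment for sequences simulated from labeled
    class ancestors at up to ``max_divergence`` substitutions/site."""
    rng = np.random.default_rng(_child_seed(seed, 8))
    refs, labels, anc = make_class_references(rng)
    correct = 0
    for i in range(n_queries):
        cls = "classI" if rng.random() < 0.5 else "classII"
        d = float(rng.uniform(0.05, max_divergence))
        q = ProtSequence(id=f"q{i}", residues=_mutate_protein(rng, anc[cls], d))
        a = place_one_by_one([q], refs, labels)[0]
        correct += a is not None and a.assigned_class == cls
    return {"accuracy_pct": 100.0 * correct / n_queries, "n": n_queries}


def truncated_fragment_consistency(seed: int, n_fragments: int = 20):
    """Truncated fragments of class II-derived genes: percentage assigned
    classII, identically in both processing orders."""
    rng = np.random.default_rng(_child_seed(seed, 9))
    refs, labels, anc = make_class_references(rng)
    frags = []
    for i in range(n_fragments):
        gene = _mutate_protein(rng, anc["classII"], float(rng.uniform(0.05, 0.2)))
        half = len(gene) // 2
        part = gene[:half] if i % 2 == 0 else gene[half:]
        frags.append(ProtSequence(id=f"frag{i}", residues=part))
    fwd = place_one_by_one(frags, refs, labels)
    rev = place_one_by_one(list(reversed(frags)), refs, labels)[::-1]
    ok = sum(
        1 for a, b in zip(fwd, rev)
        if a is not None and b is not None
        and a.assigned_class == "classII" and b.assigned_class == a.assigned_class
    )
    return {"class2_consistent_pct": 100.0 * ok / n_fragments, "n": n_fragments}


# ---------------------------------------------------------------------------
# in-silico PCR and shared-disruption worked examples


def pcr_worked_example(seed: int):
    """Template carrying the printed primer pair around a filler such that the
    primer-inclusive product is 299 bp; returns the computed product length."""
    rng = np.random.default_rng(_child_seed(seed, 10))
    fwd, rev = GNAT3_EXON6_FWD, GNAT3_EXON6_REV
    inner = 299 - len(fwd) - len(rev)
    fwd_site = fwd.replace("R", "AG"[rng.integers(2)])
    template = NucSequence(
        id="gnat3_exon6_synthetic",
        residues=_random_dna(rng, 180) + fwd_site + _random_dna(rng, inner)
        + _revcomp_iupac(rev) + _random_dna(rng, 180),
    )
    amplicons = insilico_pcr(template, fwd, rev)
    return {
        "n_amplicons": len(amplicons),
        "product_length_bp": amplicons[0].length if amplicons else 0,
    }


def shared_disruption_worked_example(seed: int, deletion_pos: int = 643,
                                     stop_codon_start: int = 658,
                                     cds_len: int = 1065):
    """Synthetic mirror of the shared-pseudogenization analysis: every
    'cetacean' target carries a 1-bp deletion and a stop-gain at fixed
    reference-CDS coordinates; the annotator must recover them as shared.

    The reference is a synthetic stand-in for the real reference CDS (no
    download); positions are construction inputs and the quantities returned
    are whatever the alignment-based annotator reports.
    """
    rng = np.random.default_rng(_child_seed(seed, 11))
    ref = list(_random_dna(rng, cds_len))
    # make the deleted base locally unambiguous so the alignment cannot slide
    ref[deletion_pos - 2], ref[deletion_pos - 1], ref[deletion_pos] = "C", "A", "G"
    # the reference codon at the stop-gain site: CGA (Arg), one substitution
    # away from the planted TGA stop
    ref[stop_codon_start - 1:stop_codon_start + 2] = list("CGA")
    ref_str = "".join(ref)
    reference = NucSequence(id="reference_cds_synthetic", residues=ref_str)

    def make_target(name, disrupted: bool):
        s = list(ref_str)
        if disrupted:
            s[stop_codon_start - 1:stop_codon_start + 2] = list("TGA")
            del s[deletion_pos - 1]
        return NucSequence(id=name, residues="".join(s))

    targets = [
        make_target("minke_whale", True),
        make_target("bottlenose_dolphin", True),
        make_target("cow", False),
    ]
    _events, shared = annotate_disruptions_vs_reference(
        targets, reference, groups={"cetaceans": ["minke_whale", "bottlenose_dolphin"]}
    )
    dels = [e for e in shared["cetaceans"] if e.kind == "deletion"]
    stops = [e for e in shared["cetaceans"] if e.kind == "premature_stop"]
    return {
        "shared_deletion_position": dels[0].ref_start if dels else 0,
        "shared_stop_start": stops[0].ref_start if stops else 0,
        "shared_stop_end": stops[0].ref_end if stops else 0,
        "n_shared_events": len(shared["cetaceans"]),
    }
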