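"""Synthetic genomes with planted chemosensory-receptor genes and truth tables.

The generator emulates the situations the mining pipeline must recognise in a
fragmented assembly:

* intact 7-TM GPCR genes: a full open reading frame (ATG ... stop) encoding a
  protein diverged from a simulated family ancestor;
* pseudogenes: an intact template carrying exactly one disruptive mutation
  (premature stop, 1-2 bp frameshifting indel, or an in-frame deletion of one
  whole TM segment), so truth labels map 1:1 to detected disruption kinds;
* truncated genes: an intact template cut by a scaffold boundary, with the
  retained fragment flush against the scaffold end;
* runs of N (assembly gaps) and i.i.d. uniform intergenic background;
* multi-exon reference/target locus pairs with specified exons excised
  (together with nearly all flanking intron sequence, as in a segmental loss)
  or a block of exons reverse-complemented in place (genomic inversion).

Identical specs and seeds give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .genecall import FamilyProfile, TM_NAMES
from .multiexon import ExonModel
from .seqcore import (
    CODON_TABLE,
    GenomicInterval,
    NucSequence,
    ProtSequence,
    revcomp_str,
)

logger = logging.getLogger("chemomine")

AA20 = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = "AFILMVWY"

_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    _CODONS_FOR.setdefault(_aa, []).append(_codon)

STOPS = ("TAA", "TAG", "TGA")

MUTATION_KINDS = ("premature_stop", "frameshift_1bp", "frameshift_2bp", "tm_deletion")


@dataclass(frozen=True)
class PlantSpec:
    """What to plant for one gene family."""

    family: str
    n_intact: int = 10
    n_pseudo: int = 5
    n_truncated: int = 2
    pseudo_mutation_mix: dict = field(
        default_factory=lambda: {
            "premature_stop": 0.4,
            "frameshift_1bp": 0.3,
            "frameshift_2bp": 0.15,
            "tm_deletion": 0.15,
        }
    )
    divergence: float = 0.15  # substitutions/site, planted gene vs family ancestor
    length_aa: int = 310
    n_refs: int = 6
    ref_divergence: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.divergence <= 0.5):
            raise ValueError("divergence must be in [0, 0.5]")
        total = sum(self.pseudo_mutation_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("pseudo_mutation_mix proportions must sum to 1")
        if set(self.pseudo_mutation_mix) - set(MUTATION_KINDS):
            raise ValueError(f"unknown mutation kinds in mix: "
                             f"{set(self.pseudo_mutation_mix) - set(MUTATION_KINDS)}")


@dataclass
class TruthRecord:
    family: str
    label: str  # intact | truncated | pseudogene
    interval: GenomicInterval
    residues: str  # planted sequence exactly as it appears on the + strand
    mutation: str = ""  # disruption kind for pseudogenes; cut side for truncated
    detail: str = ""


@dataclass
class SyntheticGenome:
    genome: list
    truth: list
    families: dict  # family -> (list[ProtSequence] refs, FamilyProfile)

    def genome_by_id(self):
        return {s.id: s for s in self.genome}


# ---------------------------------------------------------------------------
# protein family simulation


def _mutate_protein(rng, residues: str, divergence: float, fixed_start: bool = True) -> str:
    """Poisson substitution model: each site substituted with prob 1-exp(-d)."""
    p = 1.0 - np.exp(-divergence)
    out = list(residues)
    lo = 1 if fixed_start else 0
    for i in range(lo, len(out)):
        if rng.random() < p:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def make_gpcr_family(
    n_refs: int = 6,
    length_aa: int = 310,
    divergence: float = 0.10,
    seed: int = 0,
):
    """Simulate a 7-TM receptor family: an ancestor with designated TM
    segments (hydrophobic-biased) plus ``n_refs`` references diverged from it.

    Returns (references, profile, ancestor).
    """
    if length_aa < 250:
        raise ValueError("length_aa must be >= 250 for a 7-TM architecture")
    if n_refs < 4:
        raise ValueError("need at least 4 reference sequences")
    rng = np.random.default_rng(seed)
    tm_len = 23
    n_term = 24
    loop = 10
    tm_segments = []
    pos = n_term
    for _ in range(7):
        tm_segments.append((pos, pos + tm_len))
        pos += tm_len + loop
    pos -= loop  # no loop after TM7; remainder is the C-terminal tail
    if pos > length_aa:
        raise ValueError("length_aa too short for the 7-TM layout")
    in_tm = np.zeros(length_aa, dtype=bool)
    for s, e in tm_segments:
        in_tm[s:e] = True
    ancestor = ["M"]
    for i in range(1, length_aa):
        pool = HYDROPHOBIC if in_tm[i] and rng.random() < 0.7 else AA20
        ancestor.append(pool[rng.integers(len(pool))])
    ancestor = "".join(ancestor)
    refs = [
        ProtSequence(id=f"ref{i + 1}", residues=_mutate_protein(rng, ancestor, divergence))
        for i in range(n_refs)
    ]
    profile = FamilyProfile.from_msa("family", refs, tm_segments)
    return refs, profile, ancestor


def _back_translate(rng, protein: str) -> str:
    return "".join(
        _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in protein
    )


def _random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


# ---------------------------------------------------------------------------
# single-exon gene planting


def _make_gene_elements(spec: PlantSpec, profile: FamilyProfile, ancestor: str, rng):
    """Build the planted sequences and their truth metadata for one family."""
    elements = []  # (label, coding_strand_seq, mutation, detail, needs_terminus)

    def fresh_cds() -> str:
        protein = _mutate_protein(rng, ancestor, spec.divergence)
        return _back_translate(rng, protein) + STOPS[rng.integers(3)]

    for _ in range(spec.n_intact):
        elements.append(("intact", fresh_cds(), "", "", None))

    kinds = list(spec.pseudo_mutation_mix)
    probs = np.array([spec.pseudo_mutation_mix[k] for k in kinds])
    for _ in range(spec.n_pseudo):
        cds = fresh_cds()
        kind = kinds[rng.choice(len(kinds), p=probs)]
        ncod = len(cds) // 3 - 1  # coding codons, excluding the stop
        lo, hi = int(0.15 * ncod), int(0.85 * ncod)
        if kind == "premature_stop":
            c = int(rng.integers(lo, hi))
            mut = cds[:3 * c] + STOPS[rng.integers(3)] + cds[3 * c + 3:]
            detail = f"stop at codon {c + 1}"
        elif kind in ("frameshift_1bp", "frameshift_2bp"):
            nbp = 1 if kind == "frameshift_1bp" else 2
            p = int(rng.integers(3 * lo, 3 * hi))
            if rng.random() < 0.5:
                mut = cds[:p] + cds[p + nbp:]
                detail = f"{nbp}-bp deletion at CDS position {p + 1}"
            else:
                mut = cds[:p] + _random_dna(rng, nbp) + cds[p:]
                detail = f"{nbp}-bp insertion at CDS position {p + 1}"
        else:  # tm_deletion
            tm_idx = int(rng.integers(7))
            s, e = profile.tm_consensus[tm_idx]
            mut = cds[:3 * s] + cds[3 * e:]
            detail = f"{TM_NAMES[tm_idx]} deleted ({e - s} codons)"
        elements.append(("pseudogene", mut, kind, detail, None))

    for _ in range(spec.n_truncated):
        cds = fresh_cds()
        keep = rng.uniform(0.35, 0.6)
        ncut = 3 * int((1 - keep) * (len(cds) // 3))
        if rng.random() < 0.5:
            frag, side = cds[ncut:], "start"   # 5' lost -> at scaffold start
        else:
            frag, side = cds[:len(cds) - ncut], "end"  # 3' lost -> at scaffold end
        elements.append(("truncated", frag, "scaffold_split", f"missing {side} side", side))
    return elements


def plant_genome(
    spec,
    scaffold_lengths: tuple = tuple([12_000] * 12),
    gap_spec: dict | None = None,
    seed: int = 0,
) -> SyntheticGenome:
    """Plant one or several family specs into a synthetic assembly.

    ``spec`` may be a single PlantSpec or a list (one per family).  Intergenic
    background is i.i.d. uniform; genes are separated by 0.8-1.5 kb spacers,
    some of which carry an N-gap per ``gap_spec`` ({"per_scaffold": k,
    "length_range": (lo, hi)}).  Truncated genes sit flush against scaffold
    termini.  Raises if the planted material cannot fit.
    """
    specs = [spec] if isinstance(spec, PlantSpec) else list(spec)
    if gap_spec is None:
        gap_spec = {"per_scaffold": 1, "length_range": (120, 400)}
    rng = np.random.default_rng(seed)

    families = {}
    all_elements = []  # (family, label, seq, mutation, detail, terminus_side)
    for sp in specs:
        refs, profile, ancestor = make_gpcr_family(
            n_refs=sp.n_refs, length_aa=sp.length_aa,
            divergence=sp.ref_divergence, seed=sp.seed,
        )
        refs = [ProtSequence(id=f"{sp.family}_{r.id}", residues=r.residues)
                for r in refs]
        profile = dataclasses.replace(profile, family=sp.family)
        families[sp.family] = (refs, profile)
        fam_rng = np.random.default_rng(np.random.SeedSequence([seed, sp.seed, 7]))
        for el in _make_gene_elements(sp, profile, ancestor, fam_rng):
            all_elements.append((sp.family, *el))

    total_gene = sum(len(e[2]) for e in all_elements)
    if total_gene >= 0.8 * sum(scaffold_lengths):
        raise ValueError("planted material exceeds 80% of the genome size")

    n_scaf = len(scaffold_lengths)
    # assign truncated elements to distinct scaffold termini
    terminus_jobs = [e for e in all_elements if e[5] is not None]
    interior_jobs = [e for e in all_elements if e[5] is None]
    start_termini = list(rng.permutation(n_scaf))
    end_termini = list(rng.permutation(n_scaf))
    assigned_termini: dict[int, dict] = {}
    for job in terminus_jobs:
        pool = start_termini if job[5] == "start" else end_termini
        if not pool:
            raise ValueError("not enough scaffold termini for the truncated genes")
        si = int(pool.pop())
        assigned_termini.setdefault(si, {})[job[5]] = job

    # distribute interior genes round-robin over shuffled scaffolds
    perm = rng.permutation(len(interior_jobs))
    per_scaffold: dict[int, list] = {i: [] for i in range(n_scaf)}
    for k, idx in enumerate(perm):
        per_scaffold[k % n_scaf].append(interior_jobs[idx])

    genome = []
    truth: list[TruthRecord] = []
    for si in range(n_scaf):
        L = scaffold_lengths[si]
        sid = f"scaffold{si + 1}"
        parts: list[str] = []
        cursor = 0
        gaps_left = gap_spec.get("per_scaffold", 0)

        start_job = assigned_termini.get(si, {}).get("start")
        end_job = assigned_termini.get(si, {}).get("end")
        reserved_end = len(end_job[2]) if end_job else 0

        def place(seq: str, fam, label, mutation, detail, strand="+"):
            nonlocal cursor
            planted = seq if strand == "+" else revcomp_str(seq)
            parts.append(planted)
            iv = GenomicInterval(sid, cursor, cursor + len(planted), strand)
            truth.append(TruthRecord(family=fam, label=label, interval=iv,
                                     residues=planted, mutation=mutation,
                                     detail=detail))
            cursor += len(planted)

        if start_job:
            fam, label, seq, mutation, detail, _side = start_job
            place(seq, fam, label, mutation, detail, "+")

        for fam, label, seq, mutation, detail, _side in per_scaffold[si]:
            spacer = int(rng.integers(800, 1500))
            if gaps_left and rng.random() < 0.6:
                glo, ghi = gap_spec.get("length_range", (120, 400))
                glen = int(rng.integers(glo, ghi))
                left = int(rng.integers(200, max(spacer - glen - 200, 201)))
                block = (_random_dna(rng, left) + "N" * glen
                         + _random_dna(rng, max(spacer - glen - left, 100)))
                gaps_left -= 1
            else:
                block = _random_dna(rng, spacer)
            parts.append(block)
            cursor += len(block)
            strand = "+" if rng.random() < 0.5 else "-"
            place(seq, fam, label, mutation, detail, strand)

        tail = L - cursor - reserved_end
        if tail < 300:
            raise ValueError(
                f"scaffold {sid} too short for its planted elements "
                f"(need {cursor + reserved_end + 300}, have {L})"
            )
        parts.append(_random_dna(rng, tail))
        cursor += tail
        if end_job:
            fam, label, seq, mutation, detail, _side = end_job
            place(seq, fam, label, mutation, detail, "+")
        genome.append(NucSequence(id=sid, residues="".join(parts)))

    return SyntheticGenome(genome=genome, truth=truth, families=families)


# ---------------------------------------------------------------------------
# multi-exon locus planting


@dataclass(frozen=True)
class MultiExonSpec:
    gene_id: str = "gene"
    n_exons: int = 13
    exon_length_range: tuple = (120, 240)
    intron_length_range: tuple = (700, 1400)
    flank: int = 1500
    keep_intron_margin: int = 50  # bp of intron retained on each side of a loss
    divergence: float = 0.0       # substitutions/site applied to the target


def _mutate_dna(rng, seq: str, divergence: float) -> str:
    if divergence <= 0:
        return seq
    p = 1.0 - np.exp(-divergence)
    out = list(seq)
    for i, c in enumerate(out):
        if c != "N" and rng.random() < p:
            alt = "ACGT"[rng.integers(4)]
            while alt == c:
                alt = "ACGT"[rng.integers(4)]
            out[i] = alt
    return "".join(out)


def plant_multiexon(
    spec: MultiExonSpec,
    delete_exons: set | None = None,
    invert_exons: set | None = None,
    seed: int = 0,
):
    """Build a reference multi-exon locus and an edited target locus.

    Deleted exons are excised together with all but ``keep_intron_margin`` bp
    of the adjacent introns (segmental loss); inverted exons must form one
    consecutive block, which is reverse-complemented in place including its
    internal introns.  Returns (reference, target, model, truth).
    """
    delete_exons = set(delete_exons or ())
    invert_exons = set(invert_exons or ())
    if delete_exons & invert_exons:
        raise ValueError("an exon cannot be both deleted and inverted")
    bad = (delete_exons | invert_exons) - set(range(1, spec.n_exons + 1))
    if bad:
        raise ValueError(f"edits reference nonexistent exons {sorted(bad)}")
    if invert_exons:
        block = sorted(invert_exons)
        if block != list(range(block[0], block[-1] + 1)):
            raise ValueError("inverted exons must form one consecutive block")

    rng = np.random.default_rng(seed)
    exon_seqs = []
    intron_seqs = []
    for i in range(spec.n_exons):
        elen = int(rng.integers(*spec.exon_length_range))
        exon_seqs.append(_random_dna(rng, elen))
    for i in range(spec.n_exons - 1):
        ilen = int(rng.integers(*spec.intron_length_range))
        intron_seqs.append("GT" + _random_dna(rng, ilen - 4) + "AG")

    # reference locus
    parts = [_random_dna(rng, spec.flank)]
    exon_ivs = []
    pos = spec.flank
    for i in range(spec.n_exons):
        exon_ivs.append(GenomicInterval(f"{spec.gene_id}_ref", pos, pos + len(exon_seqs[i]), "+"))
        parts.append(exon_seqs[i])
        pos += len(exon_seqs[i])
        if i < spec.n_exons - 1:
            parts.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    parts.append(_random_dna(rng, spec.flank))
    reference = NucSequence(id=f"{spec.gene_id}_ref", residues="".join(parts))
    model = ExonModel(
        gene_id=spec.gene_id,
        exons=tuple(
            (i + 1, NucSequence(id=f"{spec.gene_id}_exon{i + 1}", residues=exon_seqs[i]), iv)
            for i, iv in enumerate(exon_ivs)
        ),
    )

    # target locus: segment list edit
    m = spec.keep_intron_margin
    segs: list[str] = [reference.residues[:spec.flank]]
    for i in range(spec.n_exons):
        deleted = (i + 1) in delete_exons
        segs.append("" if deleted else exon_seqs[i])
        if i < spec.n_exons - 1:
            intron = intron_seqs[i]
            left_del = (i + 1) in delete_exons
            right_del = (i + 2) in delete_exons
            if left_del and right_del:
                segs.append("")
            elif left_del:
                segs.append(intron[-m:])
            elif right_del:
                segs.append(intron[:m])
            else:
                segs.append(intron)
    segs.append(reference.residues[-spec.flank:])

    target_str = "".join(segs)
    if invert_exons:
        block = sorted(invert_exons)
        # recompute block coordinates on the edited target
        pos = len(segs[0])
        coords = {}
        for i in range(spec.n_exons):
            seg = segs[1 + 2 * i]
            coords[i + 1] = (pos, pos + len(seg))
            pos += len(seg)
            if i < spec.n_exons - 1:
                pos += len(segs[2 + 2 * i])
        lo = coords[block[0]][0]
        hi = coords[block[-1]][1]
        target_str = target_str[:lo] + revcomp_str(target_str[lo:hi]) + target_str[hi:]

    target_str = _mutate_dna(rng, target_str, spec.divergence)
    target = NucSequence(id=f"{spec.gene_id}_target", residues=target_str)
    truth = {
        "deleted_exons": sorted(delete_exons),
        "inverted_exons": sorted(invert_exons),
        "exon_sequences": {i + 1: exon_seqs[i] for i in range(spec.n_exons)},
    }
    return reference, target, model, truth
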