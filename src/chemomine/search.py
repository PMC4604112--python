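"""Translated (TBLASTN-like) and nucleotide (BLASTN-like) homology search.

Seed-and-extend over exact k-mer seeds (k=4 for translated protein seeds, k=11
for nucleotide seeds), gapped local alignment around each seed cluster, and
Karlin-Altschul statistics E = K*m*n*exp(-lambda*S) to convert raw scores to
e-values.  m is the total number of residues searched (all six frames for
translated search, both strands for nucleotide search) and n the total query
residues.  Overlapping same-orientation hits are merged into candidate loci,
which are then screened by a reciprocal best-hit filter against a reference
proteome: a candidate is kept only if its best reference hit belongs to the
target family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _align
from ._align import (
    BLOSUM62,
    encode_nuc,
    encode_prot,
    nuc_matrix,
    sw_align,
    ungapped_extend,
)
from .seqcore import GenomicInterval, NucSequence, ProtSequence, revcomp

logger = logging.getLogger("chemomine")

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring plus the Karlin-Altschul parameters that go with it.

    The defaults are the published gapped constants for BLOSUM62 with gap
    open 11 / extend 1 (lambda=0.267, K=0.041) and for +1/-2 nucleotide
    scoring (lambda=1.28, K=0.46).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    nuc_match: int = 1
    nuc_mismatch: int = -2

    def __post_init__(self):
        if not (self.lam > 0 and self.K > 0):
            raise ValueError("lambda and K must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must be <= gap_open")

    @classmethod
    def protein_default(cls) -> "ScoringScheme":
        return cls()

    @classmethod
    def nucleotide_default(cls) -> "ScoringScheme":
        return cls(matrix_name="nuc+1/-2", gap_open=4, gap_extend=2,
                   lam=1.28, K=0.46)

    def bitscore(self, raw: int) -> float:
        return (self.lam * raw - math.log(self.K)) / LN2

    def evalue(self, raw: int, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * raw)


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    interval: GenomicInterval
    frame: int | None
    raw_score: int
    bitscore: float
    evalue: float
    identity: float
    query_span: tuple[int, int]


@dataclass
class CandidateLocus:
    interval: GenomicInterval
    supporting_hits: list[SearchHit]
    family: str = ""

    @property
    def best_bitscore(self) -> float:
        return max(h.bitscore for h in self.supporting_hits)


# ---------------------------------------------------------------------------


def _seed_index(coded: np.ndarray, k: int) -> dict:
    idx: dict[tuple, list[int]] = {}
    key = coded.tobytes()
    for i in range(len(coded) - k + 1):
        idx.setdefault(key[i : i + k], []).append(i)
    return idx


def _cluster_seeds(seeds: list[tuple[int, int]], span: int, diag_tol: int = 6):
    """Group (tpos, qpos) seeds into diagonal clusters."""
    seeds = sorted(seeds, key=lambda s: (s[0] - s[1], s[0]))
    clusters = []
    cur = [seeds[0]]
    for s in seeds[1:]:
        prev = cur[-1]
        if abs((s[0] - s[1]) - (prev[0] - prev[1])) <= diag_tol and s[0] - prev[0] <= span:
            cur.append(s)
        else:
            clusters.append(cur)
            cur = [s]
    clusters.append(cur)
    return clusters


def _dedupe(alns: list[tuple]) -> list[tuple]:
    """Keep best-scoring alignments, dropping ones overlapping a kept one."""
    out = []
    for a in sorted(alns, key=lambda x: -x[0]):
        s, ts, te = a[0], a[3], a[4]
        clash = False
        for b in out:
            lo, hi = max(ts, b[3]), min(te, b[4])
            if hi - lo > 0.5 * min(te - ts, b[4] - b[3]):
                clash = True
                break
        if not clash:
            out.append(a)
    return out


def translated_search(
    genome: list[NucSequence],
    queries: list[ProtSequence],
    scheme: ScoringScheme | None = None,
    evalue_cutoff: float = 1e-20,
    seed_len: int = 4,
    ungapped_trigger: int = 40,
) -> list[SearchHit]:
    """Six-frame translated homology search of protein queries vs a genome.

    Exact protein k-mer seeds are grouped by diagonal, triaged with an
    ungapped X-drop extension, and clusters passing ``ungapped_trigger`` get a
    full gapped local alignment over the surrounding window.
    """
    if scheme is None:
        scheme = ScoringScheme.protein_default()
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    usable = []
    for q in queries:
        if len(q) < seed_len:
            logger.warning("query %s shorter than seed length %d; skipped", q.id, seed_len)
            continue
        usable.append(q)
    if not usable or not genome:
        return []

    n_total = sum(len(q) for q in usable)
    coded_q = [encode_prot(q.residues.replace("*", "X")) for q in usable]
    qkmers: dict[bytes, list[tuple[int, int]]] = {}
    for qi, cq in enumerate(coded_q):
        key = cq.tobytes()
        for p in range(len(cq) - seed_len + 1):
            qkmers.setdefault(key[p : p + seed_len], []).append((qi, p))

    # translations of every scaffold/strand/frame, coded
    frames = []  # (scaffold_idx, strand, frame, coded_translation, scaffold_len)
    m_total = 0
    from .seqcore import revcomp_str, translate_str

    for si, scaf in enumerate(genome):
        fwd = scaf.residues
        rev = revcomp_str(fwd)
        for strand, seqstr in (("+", fwd), ("-", rev)):
            for fr in range(3):
                aa = translate_str(seqstr, fr)
                if not aa:
                    continue
                m_total += len(aa)
                frames.append((si, strand, fr, encode_prot(aa), len(fwd)))

    hits: list[SearchHit] = []
    for si, strand, fr, taa, slen in frames:
        # collect seeds per query on this frame
        per_query: dict[int, list[tuple[int, int]]] = {}
        key = taa.tobytes()
        for t in range(len(taa) - seed_len + 1):
            lst = qkmers.get(key[t : t + seed_len])
            if lst:
                for qi, qp in lst:
                    per_query.setdefault(qi, []).append((t, qp))
        for qi, seeds in per_query.items():
            cq = coded_q[qi]
            qlen = len(cq)
            windows = []
            for cluster in _cluster_seeds(seeds, span=qlen):
                # ungapped X-drop triage before the (expensive) gapped stage
                probe = cluster if len(cluster) <= 3 else [
                    cluster[0], cluster[len(cluster) // 2], cluster[-1]
                ]
                ug = max(
                    ungapped_extend(cq, taa, qp, t, seed_len, BLOSUM62, 18)
                    for t, qp in probe
                )
                if ug < ungapped_trigger:
                    continue
                t_lo = min(t for t, _ in cluster)
                t_hi = max(t for t, _ in cluster) + seed_len
                windows.append((t_lo, t_hi))
            alns = []
            for t_lo, t_hi in windows:
                lo = max(0, t_lo - qlen - 8)
                hi = min(len(taa), t_hi + qlen + 8)
                score, qs, qe, ts, te, nid, ncol = sw_align(
                    cq, taa[lo:hi], BLOSUM62, scheme.gap_open, scheme.gap_extend
                )
                if score <= 0:
                    continue
                # if the optimum latched onto a different region of the window
                # (e.g. a nearby paralog), re-align tight around this cluster
                if lo + te <= t_lo or lo + ts >= t_hi:
                    lo = max(0, t_lo - qlen // 4)
                    hi = min(len(taa), t_hi + qlen // 4)
                    score, qs, qe, ts, te, nid, ncol = sw_align(
                        cq, taa[lo:hi], BLOSUM62, scheme.gap_open, scheme.gap_extend
                    )
                    if score <= 0:
                        continue
                alns.append((score, qs, qe, lo + ts, lo + te, nid, ncol))
            for score, qs, qe, ts, te, nid, ncol in _dedupe(alns):
                ev = scheme.evalue(score, m_total, n_total)
                if ev >= evalue_cutoff:
                    continue
                if strand == "+":
                    gs, ge = fr + 3 * ts, fr + 3 * te
                else:
                    gs, ge = slen - (fr + 3 * te), slen - (fr + 3 * ts)
                hits.append(
                    SearchHit(
                        query_id=usable[qi].id,
                        interval=GenomicInterval(genome[si].id, gs, ge, strand),
                        frame=fr,
                        raw_score=score,
                        bitscore=scheme.bitscore(score),
                        evalue=ev,
                        identity=nid / ncol if ncol else 0.0,
                        query_span=(qs, qe),
                    )
                )
    hits.sort(key=lambda h: (h.interval.seq_id, h.interval.start, h.query_id))
    return hits


def nucleotide_search(
    genome: list[NucSequence],
    queries: list[NucSequence],
    scheme: ScoringScheme | None = None,
    evalue_cutoff: float = 1e-20,
    seed_len: int = 11,
) -> list[SearchHit]:
    """Both-strand nucleotide homology search (exact 11-mer seeds by default)."""
    if scheme is None:
        scheme = ScoringScheme.nucleotide_default()
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    usable = []
    for q in queries:
        if len(q) < seed_len:
            logger.warning("query %s shorter than seed length %d; skipped", q.id, seed_len)
            continue
        usable.append(q)
    if not usable or not genome:
        return []

    sub = nuc_matrix(scheme.nuc_match, scheme.nuc_mismatch)
    n_total = sum(len(q) for q in usable)
    m_total = 2 * sum(len(s) for s in genome)

    # query k-mer index over both orientations
    variants = []  # (query_idx, strand, coded)
    qkmers: dict[bytes, list[tuple[int, int]]] = {}
    for qi, q in enumerate(usable):
        for strand, rec in (("+", q), ("-", revcomp(q))):
            vi = len(variants)
            coded = encode_nuc(rec.residues)
            variants.append((qi, strand, coded))
            key = coded.tobytes()
            for p in range(len(coded) - seed_len + 1):
                kmer = key[p : p + seed_len]
                if 4 in kmer:  # skip N-containing seeds
                    continue
                qkmers.setdefault(kmer, []).append((vi, p))

    hits: list[SearchHit] = []
    for si, scaf in enumerate(genome):
        coded_s = encode_nuc(scaf.residues)
        key = coded_s.tobytes()
        per_variant: dict[int, list[tuple[int, int]]] = {}
        for t in range(len(coded_s) - seed_len + 1):
            lst = qkmers.get(key[t : t + seed_len])
            if lst:
                for vi, qp in lst:
                    per_variant.setdefault(vi, []).append((t, qp))
        for vi, seeds in per_variant.items():
            qi, strand, cq = variants[vi]
            qlen = len(cq)
            alns = []
            for cluster in _cluster_seeds(seeds, span=qlen, diag_tol=12):
                lo = max(0, min(t for t, _ in cluster) - qlen - 20)
                hi = min(len(coded_s), max(t for t, _ in cluster) + seed_len + qlen + 20)
                score, qs, qe, ts, te, nid, ncol = sw_align(
                    cq, coded_s[lo:hi], sub, scheme.gap_open, scheme.gap_extend
                )
                if score <= 0:
                    continue
                alns.append((score, qs, qe, lo + ts, lo + te, nid, ncol))
            for score, qs, qe, ts, te, nid, ncol in _dedupe(alns):
                ev = scheme.evalue(score, m_total, n_total)
                if ev >= evalue_cutoff:
                    continue
                if strand == "-":
                    qs, qe = qlen - qe, qlen - qs
                hits.append(
                    SearchHit(
                        query_id=usable[qi].id,
                        interval=GenomicInterval(scaf.id, ts, te, strand),
                        frame=None,
                        raw_score=score,
                        bitscore=scheme.bitscore(score),
                        evalue=ev,
                        identity=nid / ncol if ncol else 0.0,
                        query_span=(qs, qe),
                    )
                )
    hits.sort(key=lambda h: (h.interval.seq_id, h.interval.start, h.query_id))
    return hits


def merge_hits(hits: list[SearchHit], family: str = "") -> list[CandidateLocus]:
    """Transitively merge overlapping same-scaffold, same-strand hits.

    Opposite strands never merge.  Idempotent and order-independent.
    """
    groups: dict[tuple[str, str], list[SearchHit]] = {}
    for h in hits:
        groups.setdefault((h.interval.seq_id, h.interval.strand), []).append(h)
    loci: list[CandidateLocus] = []
    for (sid, strand), ghits in groups.items():
        ghits = sorted(ghits, key=lambda h: (h.interval.start, h.interval.end))
        cur = [ghits[0]]
        cur_end = ghits[0].interval.end
        cur_start = ghits[0].interval.start

        def emit():
            loci.append(
                CandidateLocus(
                    interval=GenomicInterval(sid, cur_start, cur_end, strand),
                    supporting_hits=list(cur),
                    family=family,
                )
            )

        for h in ghits[1:]:
            if h.interval.start < cur_end:  # >=1 bp overlap
                cur.append(h)
                cur_end = max(cur_end, h.interval.end)
            else:
                emit()
                cur = [h]
                cur_start, cur_end = h.interval.start, h.interval.end
        emit()
    loci.sort(key=lambda l: (l.interval.seq_id, l.interval.start))
    return loci


def locus_sequence(locus: CandidateLocus, genome_by_id: dict[str, NucSequence],
                   flank: int = 0) -> NucSequence:
    scaf = genome_by_id[locus.interval.seq_id]
    lo = max(0, locus.interval.start - flank)
    hi = min(len(scaf), locus.interval.end + flank)
    res = scaf.residues[lo:hi]
    rec = NucSequence(id=f"{scaf.id}:{lo + 1}-{hi}", residues=res)
    return revcomp(rec) if locus.interval.strand == "-" else rec


def reciprocal_filter(
    loci: list[CandidateLocus],
    genome: list[NucSequence],
    reference_proteome: list[ProtSequence],
    family_member_ids: set[str],
    scheme: ScoringScheme | None = None,
):
    """Keep loci whose best reference-proteome hit is a family member.

    The candidate locus sequence is searched (translated, frame-tolerant)
    against the reference proteome; bitscore ties are resolved permissively
    (kept if ANY tied top hit is in the family).  Returns (kept, discarded)
    where discarded entries are (locus, reason).
    """
    genome_by_id = {s.id: s for s in genome}
    kept, discarded = [], []
    for locus in loci:
        lseq = locus_sequence(locus, genome_by_id)
        hits = translated_search(
            [lseq], reference_proteome, scheme=scheme, evalue_cutoff=1e6
        )
        if not hits:
            reason = "no reference hit"
            logger.info("discard %s:%d-%d: %s", locus.interval.seq_id,
                        locus.interval.start, locus.interval.end, reason)
            discarded.append((locus, reason))
            continue
        best = max(h.raw_score for h in hits)
        top_ids = {h.query_id for h in hits if h.raw_score == best}
        if top_ids & family_member_ids:
            kept.append(locus)
        else:
            reason = f"best hit {sorted(top_ids)[0]} not in family"
            logger.info("discard %s:%d-%d: %s", locus.interval.seq_id,
                        locus.interval.start, locus.interval.end, reason)
            discarded.append((locus, reason))
    return kept, discarded


# ---------------------------------------------------------------------------
# interchange


def write_hits_tsv(hits: list[SearchHit], path) -> None:
    """TSV hit table (1-based inclusive coordinates in the report layer)."""
    with open(path, "w") as fh:
        fh.write("query\tscaffold\tstart\tend\tstrand\tframe\traw_score\t"
                 "bitscore\tevalue\tidentity\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.interval.seq_id}\t{h.interval.start + 1}\t"
                f"{h.interval.end}\t{h.interval.strand}\t"
                f"{'' if h.frame is None else h.frame}\t{h.raw_score}\t"
                f"{h.bitscore:.1f}\t{h.evalue:.3g}\t{h.identity:.4f}\n"
            )


def read_tabular_hits(path, genome_lengths: dict[str, int] | None = None) -> list[SearchHit]:
    """Adapter for standard 12-column tabular search output.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore.  Raw scores are back-computed from the bitscore with
    the default protein constants; subject coordinates are 1-based inclusive
    with send < sstart meaning minus strand.
    """
    scheme = ScoringScheme.protein_default()
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"expected 12 columns, got {len(f)}")
            qid, sid = f[0], f[1]
            pident = float(f[2])
            qstart, qend = int(f[6]), int(f[7])
            sstart, send = int(f[8]), int(f[9])
            ev, bits = float(f[10]), float(f[11])
            strand = "+" if send >= sstart else "-"
            lo, hi = (sstart, send) if strand == "+" else (send, sstart)
            raw = int(round((bits * LN2 + math.log(scheme.K)) / scheme.lam))
            hits.append(
                SearchHit(
                    query_id=qid,
                    interval=GenomicInterval(sid, lo - 1, hi, strand),
                    frame=None,
                    raw_score=raw,
                    bitscore=bits,
                    evalue=ev,
                    identity=pident / 100.0,
                    query_span=(qstart - 1, qend),
                )
            )
    return hits
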