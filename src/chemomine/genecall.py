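"""Gene-model reconstruction and intact / truncated / pseudogene classification.

Each candidate locus (from the search module) is re-aligned to its family
profile with the frameshift-aware protein-to-DNA aligner, the genomic window
being extended 5'/3' when the initiation or termination codon is not inside
the original hit envelope.  Disruptions are then read off the alignment:

* premature stop codons: in-frame stops aligned strictly inside the profile
  span;
* frameshifting indels: 1-2 bp slips in the codon walk;
* completely missing transmembrane segments: profile TM segments lying inside
  the aligned span with zero aligned residues.

Any of these makes a pseudogene.  A candidate lacking a start and/or stop
codon with no such disruption is a truncated gene when its locus sits within
`edge_window` of a scaffold end or an assembly gap (a run of >= `gap_min` N),
the situation fragmented assemblies create; lacking edge context it is called
a pseudogene with the missing terminus as the disruption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._align import BLOSUM62, P2DAlignment, STOP_CODE, CODON_AA, encode_nuc, encode_prot, p2d_align
from .search import CandidateLocus
from .seqcore import (
    GenomicInterval,
    NucSequence,
    ProtSequence,
    STOP_CODONS,
    find_gap_runs,
    revcomp_str,
    translate_str,
)

logger = logging.getLogger("chemomine")

TM_NAMES = tuple(f"TM{i}" for i in range(1, 8))

# a TM segment counts as completely missing when at most this fraction of its
# columns is aligned (boundary wobble of the gap placement; a half-present
# segment is far above this and is never called missing)
MISSING_TM_MAX_COVERAGE = 0.2


@dataclass(frozen=True)
class FamilyProfile:
    """Curated family reference: aligned proteins plus 7 TM column ranges.

    ``tm_segments`` are half-open column ranges on the reference MSA; the
    profile consensus (majority residue over columns that are non-gap in at
    least half the references) is what loci are re-aligned against, and TM
    ranges are projected onto consensus coordinates.
    """

    family: str
    reference_msa: tuple[ProtSequence, ...]
    tm_segments: tuple[tuple[int, int], ...]
    consensus: str
    tm_consensus: tuple[tuple[int, int], ...]

    @classmethod
    def from_msa(cls, family: str, msa: list[ProtSequence],
                 tm_segments: list[tuple[int, int]]) -> "FamilyProfile":
        if len(tm_segments) != 7:
            raise ValueError("a GPCR profile needs exactly 7 TM segments")
        ncol = len(msa[0].residues)
        if any(len(s.residues) != ncol for s in msa):
            raise ValueError("reference sequences are not aligned (unequal lengths)")
        prev_end = 0
        for s, e in tm_segments:
            if not (prev_end <= s < e <= ncol):
                raise ValueError("TM segments must be ordered and non-overlapping")
            prev_end = e
        cols = []
        col_to_cons = np.full(ncol, -1, dtype=int)
        for c in range(ncol):
            residues = [s.residues[c] for s in msa if s.residues[c] != "-"]
            if len(residues) * 2 >= len(msa):
                vals, counts = np.unique(residues, return_counts=True)
                col_to_cons[c] = len(cols)
                cols.append(vals[np.argmax(counts)])
        tm_cons = []
        for s, e in tm_segments:
            mapped = col_to_cons[s:e]
            mapped = mapped[mapped >= 0]
            if len(mapped) == 0:
                raise ValueError("TM segment maps to no consensus column")
            tm_cons.append((int(mapped.min()), int(mapped.max()) + 1))
        return cls(
            family=family,
            reference_msa=tuple(msa),
            tm_segments=tuple(tuple(t) for t in tm_segments),
            consensus="".join(cols),
            tm_consensus=tuple(tm_cons),
        )


@dataclass(frozen=True)
class Disruption:
    kind: str  # premature_stop | frameshift_indel | missing_tm | missing_start | missing_stop | exon_loss | inversion
    genome_pos: GenomicInterval | None
    cds_pos: int | None  # 1-based within reconstructed CDS (or reference coord)
    detail: str = ""


@dataclass
class GeneCall:
    locus: CandidateLocus
    label: str  # intact | truncated | pseudogene
    disruptions: list[Disruption]
    cds: NucSequence | None
    protein: ProtSequence | None
    evidence: dict = field(default_factory=dict)


PSEUDOGENIZING = frozenset(("premature_stop", "frameshift_indel", "missing_tm"))


@dataclass
class CdsModel:
    """Intermediate reconstruction result feeding disruption detection."""

    locus: CandidateLocus
    alignment: P2DAlignment
    window_seq: str          # oriented (coding-strand) genomic window
    window_start: int        # scaffold offset of window (on + strand)
    window_end: int
    scaffold_len: int
    cds_lo: int              # CDS span within window_seq (oriented)
    cds_hi: int
    start_found: bool
    stop_found: bool
    ext5: int
    ext3: int
    edge5: bool              # window clamped at the 5' scaffold boundary
    edge3: bool

    def to_genomic(self, lo: int, hi: int) -> GenomicInterval:
        """Map an oriented window span back to scaffold coordinates."""
        strand = self.locus.interval.strand
        if strand == "+":
            return GenomicInterval(self.locus.interval.seq_id,
                                   self.window_start + lo,
                                   self.window_start + hi, "+")
        return GenomicInterval(self.locus.interval.seq_id,
                               self.window_end - hi,
                               self.window_end - lo, "-")

    @property
    def cds_seq(self) -> str:
        return self.window_seq[self.cds_lo:self.cds_hi]


def reconstruct_cds(
    locus: CandidateLocus,
    profile: FamilyProfile,
    genome_by_id: dict[str, NucSequence],
    extension_limit: int = 500,
) -> CdsModel | None:
    """Re-align a candidate locus to the family consensus and fix its ORF ends.

    The genomic window is the locus envelope extended by ``extension_limit``
    on both sides (clamped at scaffold boundaries); the initiation codon is
    searched codon-wise upstream of the aligned profile start and the
    termination codon downstream of the aligned profile end, mirroring the
    5'/3' extension step of the mining protocol.
    """
    scaf = genome_by_id[locus.interval.seq_id]
    slen = len(scaf)
    w_lo = max(0, locus.interval.start - extension_limit)
    w_hi = min(slen, locus.interval.end + extension_limit)
    window = scaf.residues[w_lo:w_hi]
    strand = locus.interval.strand
    if strand == "-":
        window = revcomp_str(window)
        edge5 = w_hi == slen and locus.interval.end + extension_limit > slen
        edge3 = w_lo == 0 and locus.interval.start - extension_limit < 0
    else:
        edge5 = w_lo == 0 and locus.interval.start - extension_limit < 0
        edge3 = w_hi == slen and locus.interval.end + extension_limit > slen

    aln = p2d_align(encode_prot(profile.consensus), encode_nuc(window))
    if aln.score <= 0 or not aln.columns:
        return None

    # --- initiation codon -------------------------------------------------
    ds = aln.d_start
    start_found = window[ds:ds + 3] == "ATG"
    ext5 = 0
    cds_lo = ds
    if not start_found:
        pos = ds - 3
        while pos >= 0 and ds - pos <= extension_limit:
            codon = window[pos:pos + 3]
            if codon in STOP_CODONS:
                break
            if codon == "ATG":
                start_found = True
                cds_lo = pos
                ext5 = ds - pos
                break
            pos -= 3

    # --- termination codon ------------------------------------------------
    de = aln.d_end
    stop_found = False
    ext3 = 0
    cds_hi = de
    pos = de
    while pos + 3 <= len(window) and pos - de <= extension_limit:
        codon = window[pos:pos + 3]
        if codon in STOP_CODONS:
            stop_found = True
            cds_hi = pos + 3
            ext3 = pos - de
            break
        pos += 3

    return CdsModel(
        locus=locus,
        alignment=aln,
        window_seq=window,
        window_start=w_lo,
        window_end=w_hi,
        scaffold_len=slen,
        cds_lo=cds_lo,
        cds_hi=cds_hi,
        start_found=start_found,
        stop_found=stop_found,
        ext5=ext5,
        ext3=ext3,
        edge5=edge5,
        edge3=edge3,
    )


_FS_DETAIL = {2: "1-bp deletion", 3: "2-bp deletion",
              4: "1-bp insertion", 5: "2-bp insertion"}


def tm_coverage(model: CdsModel, profile: FamilyProfile):
    """Per-TM-segment coverage fractions and whether each segment is observed.

    A segment is *observed* when it lies inside the profile span the alignment
    reached; segments beyond a scaffold-edge cut are unobserved, not missing
    (otherwise every truncated gene would be scored as lacking TM regions).
    """
    aln = model.alignment
    cov = np.zeros(len(profile.consensus), dtype=bool)
    for p, _d, mv in aln.columns:
        if mv in (1, 2, 3, 4, 5):
            cov[p] = True
    coverage = {}
    observed = {}
    for name, (s, e) in zip(TM_NAMES, profile.tm_consensus):
        coverage[name] = float(cov[s:e].mean())
        observed[name] = s >= aln.p_start and e <= aln.p_end
    return coverage, observed


def detect_disruptions(model: CdsModel, profile: FamilyProfile) -> list[Disruption]:
    """Read premature stops, frameshifts and missing TM segments off the alignment."""
    aln = model.alignment
    out: list[Disruption] = []
    for p, d, mv in aln.columns:
        if mv in (2, 3, 4, 5):
            out.append(Disruption(
                kind="frameshift_indel",
                genome_pos=model.to_genomic(d, d + {2: 2, 3: 1, 4: 4, 5: 5}[mv]),
                cds_pos=d - model.cds_lo + 1,
                detail=_FS_DETAIL[mv],
            ))
        if mv in (1, 4, 5):
            step = {1: 3, 4: 4, 5: 5}[mv]
            codon = model.window_seq[d + step - 3:d + step]
            if codon in STOP_CODONS and p < aln.p_end - 1:
                out.append(Disruption(
                    kind="premature_stop",
                    genome_pos=model.to_genomic(d + step - 3, d + step),
                    cds_pos=(d + step - 3 - model.cds_lo) // 3 + 1,
                    detail=f"stop codon {codon} at profile position {p + 1}",
                ))
    coverage, observed = tm_coverage(model, profile)
    for name in TM_NAMES:
        # "completely missing" with a small allowance for alignment boundary
        # wobble: a genuinely deleted segment can pick up a handful of
        # spuriously aligned columns at the gap edges
        if observed[name] and coverage[name] <= MISSING_TM_MAX_COVERAGE:
            s, e = profile.tm_consensus[TM_NAMES.index(name)]
            out.append(Disruption(
                kind="missing_tm",
                genome_pos=None,
                cds_pos=None,
                detail=f"{name} absent (profile columns {s + 1}-{e})",
            ))
    if not model.start_found:
        out.append(Disruption(
            kind="missing_start",
            genome_pos=model.to_genomic(model.cds_lo, model.cds_lo + 3),
            cds_pos=1,
            detail="no initiation codon found after 5' extension",
        ))
    if not model.stop_found:
        out.append(Disruption(
            kind="missing_stop",
            genome_pos=model.to_genomic(max(model.cds_hi - 3, 0), model.cds_hi),
            cds_pos=(model.cds_hi - model.cds_lo) // 3,
            detail="no termination codon found after 3' extension",
        ))
    return out


def edge_context(
    locus: CandidateLocus,
    genome_by_id: dict[str, NucSequence],
    gap_min: int = 100,
) -> int:
    """Distance from the locus to the nearest scaffold end or N-gap >= gap_min."""
    scaf = genome_by_id[locus.interval.seq_id]
    d = min(locus.interval.start, len(scaf) - locus.interval.end)
    for run in find_gap_runs(scaf, min_len=gap_min):
        if run.interval.end <= locus.interval.start:
            d = min(d, locus.interval.start - run.interval.end)
        elif run.interval.start >= locus.interval.end:
            d = min(d, run.interval.start - locus.interval.end)
        else:
            d = 0
    return d


def classify_gene(
    model: CdsModel | None,
    disruptions: list[Disruption],
    gap_context: int,
    edge_window: int = 1000,
) -> GeneCall:
    """Apply the label rules: pseudogenizing disruption > truncation > intact."""
    locus = model.locus
    pseudo = [d for d in disruptions if d.kind in PSEUDOGENIZING]
    missing_ends = [d for d in disruptions if d.kind in ("missing_start", "missing_stop")]
    evidence = {
        "ext5": model.ext5, "ext3": model.ext3,
        "edge_distance": gap_context,
        "scaffold_edge_5prime": model.edge5,
        "scaffold_edge_3prime": model.edge3,
    }
    if pseudo:
        label = "pseudogene"
        kept = disruptions
    elif missing_ends:
        if gap_context <= edge_window or model.edge5 or model.edge3:
            label = "truncated"
            kept = missing_ends
        else:
            # no edge context: treated as pseudogenizing loss of a terminus
            label = "pseudogene"
            kept = missing_ends
    else:
        label = "intact"
        kept = []
    cds_str = model.cds_seq
    cds = None
    protein = None
    if cds_str:
        iv = model.to_genomic(model.cds_lo, model.cds_hi)
        cds = NucSequence(
            id=f"{locus.family or 'gene'}|{iv.seq_id}:{iv.start + 1}-{iv.end}({iv.strand})",
            residues=cds_str,
        )
        aa = translate_str(cds_str)
        if aa:
            protein = ProtSequence(id=cds.id, residues=aa)
    return GeneCall(locus=locus, label=label, disruptions=list(kept),
                    cds=cds, protein=protein, evidence=evidence)


def call_locus(
    locus: CandidateLocus,
    profile: FamilyProfile,
    genome_by_id: dict[str, NucSequence],
    extension_limit: int = 500,
    edge_window: int = 1000,
    gap_min: int = 100,
) -> GeneCall | None:
    """Full reconstruct -> detect -> classify chain for one locus."""
    model = reconstruct_cds(locus, profile, genome_by_id, extension_limit)
    if model is None:
        logger.info("locus %s:%d-%d: no profile alignment",
                    locus.interval.seq_id, locus.interval.start, locus.interval.end)
        return None
    disruptions = detect_disruptions(model, profile)
    ctx = edge_context(locus, genome_by_id, gap_min=gap_min)
    call = classify_gene(model, disruptions, ctx, edge_window=edge_window)
    logger.info("locus %s:%d-%d (%s): %s %s",
                locus.interval.seq_id, locus.interval.start, locus.interval.end,
                locus.family, call.label,
                ";".join(d.kind for d in call.disruptions) or "-")
    return call


def resolve_family_overlaps(calls_by_family: dict[str, list[CandidateLocus]]):
    """Cross-family overlap resolution: higher best-bitscore family wins."""
    flat: list[tuple[str, CandidateLocus]] = []
    for fam, loci in calls_by_family.items():
        flat.extend((fam, l) for l in loci)
    keep = [True] * len(flat)
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            fi, li = flat[i]
            fj, lj = flat[j]
            if fi == fj or not li.interval.overlaps(lj.interval):
                continue
            loser = j if li.best_bitscore >= lj.best_bitscore else i
            if keep[loser]:
                keep[loser] = False
                fam, loc = flat[loser]
                logger.info("dropped %s locus %s:%d-%d (cross-family overlap)",
                            fam, loc.interval.seq_id, loc.interval.start,
                            loc.interval.end)
    out: dict[str, list[CandidateLocus]] = {fam: [] for fam in calls_by_family}
    for (fam, locus), k in zip(flat, keep):
        if k:
            out[fam].append(locus)
    return out


def summarize_repertoire(calls: list[GeneCall]):
    """Per-family intact / truncated / pseudogene counts (pandas DataFrame)."""
    import pandas as pd

    rows: dict[str, dict[str, int]] = {}
    for c in calls:
        fam = c.locus.family or "unknown"
        row = rows.setdefault(fam, {"intact": 0, "truncated": 0, "pseudogene": 0})
        row[c.label] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    for col in ("intact", "truncated", "pseudogene"):
        if col not in df.columns:
            df[col] = 0
    df = df[["intact", "truncated", "pseudogene"]]
    df["total"] = df.sum(axis=1)
    df.index.name = "family"
    return df.sort_index()


# ---------------------------------------------------------------------------
# report writers (1-based inclusive coordinates)


def write_calls_gff3(calls: list[GeneCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls, 1):
            iv = c.locus.interval
            attrs = (f"ID=gene{i};family={c.locus.family};label={c.label};"
                     f"disruptions={','.join(d.kind for d in c.disruptions) or '.'}")
            fh.write(f"{iv.seq_id}\tchemomine\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                     f"{iv.strand}\t.\t{attrs}\n")
            if c.cds is not None:
                fh.write(f"{iv.seq_id}\tchemomine\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
                         f"{iv.strand}\t0\tID=cds{i};Parent=gene{i}\n")


def write_calls_tsv(calls: list[GeneCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tscaffold\tstart\tend\tstrand\tlabel\tdisruptions\t"
                 "ext5\text3\tedge_distance\n")
        for c in calls:
            iv = c.locus.interval
            dis = ";".join(f"{d.kind}({d.detail})" for d in c.disruptions) or "."
            fh.write(f"{c.locus.family}\t{iv.seq_id}\t{iv.start + 1}\t{iv.end}\t"
                     f"{iv.strand}\t{c.label}\t{dis}\t{c.evidence.get('ext5', 0)}\t"
                     f"{c.evidence.get('ext3', 0)}\t{c.evidence.get('edge_distance', '')}\n")
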