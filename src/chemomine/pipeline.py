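"""End-to-end orchestration: config validation, repertoire mining runs and
multi-exon audits, with structured logging and fixed exit-code semantics
(0 success, 1 runtime failure, 2 invalid configuration — enforced by the CLI
layer on top of the exceptions raised here).

Default e-value cutoffs follow the two-tier convention of chemosensory
mining: 1e-20 for olfactory receptor families (OR/TAAR/V1R/V2R) and 1e-5 for
taste genes (TAS1R/TAS2R/GNAT3), overridable per family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .genecall import (
    FamilyProfile,
    call_locus,
    resolve_family_overlaps,
    summarize_repertoire,
    write_calls_gff3,
    write_calls_tsv,
)
from .multiexon import (
    ExonModel,
    compute_dotplot,
    confirm_deletion,
    detect_inversion,
    map_exons,
)
from .search import merge_hits, reciprocal_filter, translated_search, write_hits_tsv
from .seqcore import GenomicInterval, read_fasta, write_fasta

logger = logging.getLogger("chemomine")

DEFAULT_EVALUE = {"olfactory": 1e-20, "taste": 1e-5}


class ConfigError(ValueError):
    """Invalid run configuration (CLI maps this to exit code 2)."""


@dataclass
class FamilyConfig:
    name: str
    queries: str                     # protein FASTA, aligned (doubles as profile MSA)
    tm_segments: list                # seven [start, end) MSA column ranges
    gene_class: str = "olfactory"    # olfactory | taste
    evalue: float | None = None

    @property
    def evalue_cutoff(self) -> float:
        if self.evalue is not None:
            return self.evalue
        return DEFAULT_EVALUE[self.gene_class]


@dataclass
class RunConfig:
    genome: str
    out_dir: str
    families: list
    edge_window: int = 1000
    gap_min: int = 100
    extension_limit: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file {path} does not exist")
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        try:
            thresholds = raw.get("thresholds", {})
            fams = []
            for f in raw.get("families", []):
                fams.append(FamilyConfig(
                    name=f["name"],
                    queries=f["queries"],
                    tm_segments=f.get("tm_segments") or [],
                    gene_class=f.get("class", "olfactory"),
                    evalue=f.get("evalue"),
                ))
            cfg = cls(
                genome=raw["genome"],
                out_dir=raw.get("out_dir", "chemomine_out"),
                families=fams,
                edge_window=int(thresholds.get("edge_window", 1000)),
                gap_min=int(thresholds.get("gap_min", 100)),
                extension_limit=int(thresholds.get("extension_limit", 500)),
                seed=int(raw.get("seed", 0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed config: {exc}") from exc
        cfg.validate(base=path.parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        base = base or Path(".")
        genome = Path(self.genome)
        if not genome.is_absolute():
            genome = base / genome
            self.genome = str(genome)
        if not genome.exists():
            raise ConfigError(f"genome path {genome} does not exist")
        for t, v in (("edge_window", self.edge_window),
                     ("gap_min", self.gap_min),
                     ("extension_limit", self.extension_limit)):
            if v <= 0:
                raise ConfigError(f"threshold {t} must be positive")
        for f in self.families:
            q = Path(f.queries)
            if not q.is_absolute():
                q = base / q
                f.queries = str(q)
            if not q.exists():
                raise ConfigError(f"family {f.name}: query FASTA {q} does not exist")
            if f.gene_class not in DEFAULT_EVALUE:
                raise ConfigError(f"family {f.name}: unknown class {f.gene_class!r}")
            if f.evalue is not None and f.evalue <= 0:
                raise ConfigError(f"family {f.name}: e-value must be positive")
            if f.tm_segments and len(f.tm_segments) != 7:
                raise ConfigError(f"family {f.name}: need 7 TM segments")


def default_tm_segments(length_aa: int) -> list:
    """Canonical 7-TM layout used when a family config gives no TM ranges:
    24-residue N-terminal tail, 23-residue TM helices, 10-residue loops."""
    segs = []
    pos = 24
    for _ in range(7):
        if pos + 23 > length_aa:
            raise ConfigError("reference sequences too short for the default TM layout")
        segs.append([pos, pos + 23])
        pos += 33
    return segs


def run_repertoire(config: RunConfig):
    """search -> merge -> reciprocal filter -> reconstruct -> classify ->
    summarize, per family; returns (summary DataFrame, calls)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(config.genome, kind="nuc")
    genome_by_id = {s.id: s for s in genome}

    profiles = {}
    refs_by_family = {}
    for fc in config.families:
        msa = read_fasta(fc.queries, kind="prot")
        tm = fc.tm_segments or default_tm_segments(len(msa[0].residues))
        profiles[fc.name] = FamilyProfile.from_msa(
            fc.name, msa, [tuple(t) for t in tm]
        )
        refs_by_family[fc.name] = msa

    proteome = [r for refs in refs_by_family.values() for r in refs]
    loci_by_family = {}
    for fc in config.families:
        hits = translated_search(genome, refs_by_family[fc.name],
                                 evalue_cutoff=fc.evalue_cutoff)
        write_hits_tsv(hits, out / f"{fc.name}.hits.tsv")
        loci_by_family[fc.name] = merge_hits(hits, family=fc.name)
    loci_by_family = resolve_family_overlaps(loci_by_family)

    calls = []
    for fc in config.families:
        kept, discarded = reciprocal_filter(
            loci_by_family[fc.name], genome, proteome,
            {r.id for r in refs_by_family[fc.name]},
        )
        with open(out / f"{fc.name}.discarded.tsv", "w") as fh:
            fh.write("scaffold\tstart\tend\tstrand\treason\n")
            for locus, reason in discarded:
                iv = locus.interval
                fh.write(f"{iv.seq_id}\t{iv.start + 1}\t{iv.end}\t{iv.strand}\t{reason}\n")
        for locus in kept:
            call = call_locus(
                locus, profiles[fc.name], genome_by_id,
                extension_limit=config.extension_limit,
                edge_window=config.edge_window,
                gap_min=config.gap_min,
            )
            if call is not None:
                calls.append(call)

    calls.sort(key=lambda c: (c.locus.family, c.locus.interval.seq_id,
                              c.locus.interval.start))
    write_calls_tsv(calls, out / "gene_calls.tsv")
    write_calls_gff3(calls, out / "gene_calls.gff3")
    write_fasta([c.cds for c in calls if c.cds], out / "gene_calls.cds.fna")
    write_fasta([c.protein for c in calls if c.protein], out / "gene_calls.faa")
    summary = summarize_repertoire(calls)
    summary.to_csv(out / "summary.tsv", sep="\t")
    return summary, calls


def load_exon_model(exon_fasta, reference_fasta=None, gene_id="gene") -> tuple:
    """Build an ExonModel from a per-exon FASTA (ids ending in the exon
    number) plus, optionally, the reference locus for reciprocal checks.

    Exon reference intervals are located by exact match in the reference
    locus when given; otherwise laid out abstractly with 1 kb placeholders.
    """
    exon_seqs = read_fasta(exon_fasta, kind="nuc")
    reference = None
    if reference_fasta is not None:
        reference = read_fasta(reference_fasta, kind="nuc")[0]
    exons = []
    pos = 0
    for i, seq in enumerate(exon_seqs, 1):
        if reference is not None:
            at = reference.residues.find(seq.residues)
            if at < 0:
                raise ConfigError(f"exon {seq.id} not found in the reference locus")
            iv = GenomicInterval(reference.id, at, at + len(seq))
        else:
            iv = GenomicInterval("reference", pos, pos + len(seq))
        exons.append((i, seq, iv))
        pos += len(seq) + 1000
    return ExonModel(gene_id=gene_id, exons=tuple(exons)), reference


def run_multiexon_audit(
    config_out_dir,
    model: ExonModel,
    target_genome: list,
    reference: object | None = None,
    gap_min: int = 100,
    evalue_cutoff: float = 1e-20,
    mesh: int = 1000,
    write_png: bool = False,
):
    """Exon presence map, deletion verdicts, inversion events and a dot plot
    for one gene model against one target genome."""
    out = Path(config_out_dir)
    out.mkdir(parents=True, exist_ok=True)
    presence = map_exons(
        target_genome, model, evalue_cutoff=evalue_cutoff,
        source_genome=[reference] if reference is not None else None,
    )
    verdicts = confirm_deletion(target_genome, presence, model, gap_min=gap_min)
    inversions = detect_inversion(presence)

    with open(out / f"{model.gene_id}.exon_map.tsv", "w") as fh:
        fh.write("exon\tstatus\tscaffold\tstart\tend\tstrand\torder\tverdict\n")
        for num in range(1, model.n_exons + 1):
            p = presence.placements[num]
            if p.status == "found":
                iv = p.interval
                fh.write(f"{num}\t{p.status}\t{iv.seq_id}\t{iv.start + 1}\t{iv.end}"
                         f"\t{p.strand}\t{p.order_index}\t.\n")
            else:
                fh.write(f"{num}\t{p.status}\t.\t.\t.\t.\t.\t"
                         f"{verdicts.get(num, '.')}\n")
    with open(out / f"{model.gene_id}.inversions.tsv", "w") as fh:
        fh.write("exons\n")
        for ev in inversions:
            fh.write(",".join(map(str, ev.exons)) + "\n")

    if reference is not None and target_genome:
        found = presence.found()
        if found:
            sid = next(iter(found.values())).interval.seq_id
            target = next(s for s in target_genome if s.id == sid)
            if len(reference) >= mesh and len(target) >= mesh:
                dp = compute_dotplot(reference, target, mesh=mesh)
                dp.write_tsv(out / f"{model.gene_id}.dotplot.tsv")
                if write_png:
                    dp.to_png(out / f"{model.gene_id}.dotplot.png")
    return presence, verdicts, inversions
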