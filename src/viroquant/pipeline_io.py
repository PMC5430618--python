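"""On-disk formats, run configuration and pipeline orchestration.

Readers/writers for FASTQ (phred+33, fixed — no encoding auto-detection),
FASTA, BLAST tabular outfmt-6, a minimal SAM subset, lineage and grouping
TSVs; the :class:`RunConfig` tree; and :func:`run_pipeline`, which drives
every sample through the identical protocol:

    QC trim -> interlace -> subsample -> assemble -> identify candidates
    -> union across ALL samples -> remap every QC-passed read to the union
    -> split tied scores -> abundance table -> dark-matter partition
    -> diversity + reports

Samples are independent until the union step, so they may be processed in
any order (or concurrently) with identical results; determinism is anchored
by per-sample seeds derived from the run seed and the sample id.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import assembly as asm
from . import darkmatter as dm
from . import diversity as dv
from . import qc
from . import quantify as qt
from .records import (
    RANKS,
    UNKNOWN,
    Lineage,
    LineageTable,
    ReadRecord,
    SequenceRecord,
)
from .simdata import derive_seed

logger = logging.getLogger("viroquant")


class FormatError(ValueError):
    """A malformed input file (FASTQ/BLAST6/TSV...)."""


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_fastq(path, mate: int = 1) -> Iterator[ReadRecord]:
    """Stream phred+33 FASTQ records in file order.

    The mate index comes from the file's role (R1/R2), never from header
    parsing. Malformed records (base/quality length mismatch, truncation)
    raise :class:`FormatError` naming the record where possible.
    """
    try:
        with open(path) as handle:
            for title, seq, qual in FastqGeneralIterator(handle):
                read_id = title.split()[0] if title else ""
                if len(seq) != len(qual):
                    raise FormatError(
                        f"{path}: read {read_id!r} has {len(seq)} bases "
                        f"but {len(qual)} quality characters"
                    )
                yield ReadRecord(
                    read_id=read_id,
                    mate=mate,
                    bases=seq.upper(),
                    quals=[ord(c) - 33 for c in qual],
                )
    except ValueError as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            handle.write(f"@{read.read_id}/{read.mate}\n{read.bases}\n+\n{qual}\n")


def read_fasta(path) -> List[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(accession=rec.id, description=desc,
                           residues=str(rec.seq).upper())
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.accession}"
            if rec.description:
                header += f" {rec.description}"
            handle.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")


_BLAST6_COLUMNS = 12


def parse_blast6(path) -> List[qt.AlignmentHit]:
    """Parse 12-column BLAST tabular output (outfmt 6).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. Subject strand is inferred from
    sstart > send.
    """
    hits = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _BLAST6_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_BLAST6_COLUMNS} tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                s_start, s_end = int(fields[8]), int(fields[9])
                hits.append(
                    qt.AlignmentHit(
                        query_id=fields[0],
                        subject=fields[1],
                        identity=float(fields[2]),
                        aligned_length=int(fields[3]),
                        score=float(fields[11]),
                        evalue=float(fields[10]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=s_start,
                        s_end=s_end,
                        strand="-" if s_start > s_end else "+",
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def parse_sam(path) -> Dict[str, List[qt.AlignmentHit]]:
    """Ingest a minimal SAM subset as per-read hit lists.

    Score is the AS tag when present, otherwise the number of aligned bases
    from the CIGAR. Unmapped records yield an entry with no hits, so the
    read shows up as unassigned rather than missing.
    """
    hits: Dict[str, List[qt.AlignmentHit]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            hits.setdefault(rec.query_name, [])
            if rec.is_unmapped:
                continue
            if rec.has_tag("AS"):
                score = float(rec.get_tag("AS"))
            else:
                score = float(
                    sum(n for op, n in (rec.cigartuples or []) if op in (0, 7, 8))
                )
            aligned = rec.query_alignment_length or 1
            ref_start = rec.reference_start + 1
            ref_end = rec.reference_end or ref_start
            if rec.is_reverse:
                s_start, s_end, strand = ref_end, ref_start, "-"
            else:
                s_start, s_end, strand = ref_start, ref_end, "+"
            hits[rec.query_name].append(
                qt.AlignmentHit(
                    query_id=rec.query_name,
                    subject=rec.reference_name or "",
                    identity=0.0,
                    aligned_length=aligned,
                    score=score,
                    evalue=0.0,
                    q_start=1,
                    q_end=aligned,
                    s_start=s_start,
                    s_end=s_end,
                    strand=strand,
                )
            )
    return hits


def read_lineage(path) -> LineageTable:
    """accession<TAB>group<TAB>family<TAB>genus<TAB>species (header optional)."""
    table = LineageTable()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() == "accession":
                continue
            if len(fields) != 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 columns, found {len(fields)}"
                )
            table.add(
                fields[0],
                Lineage(*[f if f else UNKNOWN for f in fields[1:5]]),
            )
    return table


def write_lineage(table: LineageTable, path) -> None:
    with open(path, "w") as handle:
        handle.write("accession\tgroup\tfamily\tgenus\tspecies\n")
        for acc, lin in table.entries.items():
            handle.write(f"{acc}\t{lin.group}\t{lin.family}\t{lin.genus}\t{lin.species}\n")


def read_groups(path) -> Dict[str, str]:
    """sample_id<TAB>group mapping file."""
    groups = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns, found {len(fields)}"
                )
            groups[fields[0]] = fields[1]
    return groups


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class QCConfig:
    quality_threshold: int = qc.DEFAULT_QUALITY_THRESHOLD
    min_length: int = qc.DEFAULT_MIN_LENGTH
    max_n_fraction: float = qc.DEFAULT_MAX_N_FRACTION


@dataclass
class SubsampleConfig:
    fraction: float = qc.DEFAULT_SUBSAMPLE_FRACTION
    cap: int = qc.DEFAULT_SUBSAMPLE_CAP


@dataclass
class AssemblyConfig:
    k: int = asm.DEFAULT_K
    min_kmer_count: Optional[int] = None  # None = auto (2, or 1 on tiny input)


@dataclass
class QuantifyConfig:
    min_score: int = 60
    tie_tolerance: float = 0.0
    evalue_cutoff: float = 1e-5
    # candidate identification also demands this percent identity over the
    # aligned window: an absolute score floor alone cannot separate a long
    # contig's chance matches (~25% of its length on random sequence) from a
    # real one, since chance score grows with query length
    min_identity: float = 60.0


@dataclass
class DarkmatterConfig:
    enable_rrna: bool = True
    enable_human: bool = True


@dataclass
class RunConfig:
    """Everything a run needs; loadable from YAML (nested or dotted keys)."""

    qc: QCConfig = field(default_factory=QCConfig)
    subsample: SubsampleConfig = field(default_factory=SubsampleConfig)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    darkmatter: DarkmatterConfig = field(default_factory=DarkmatterConfig)
    cluster_identity: float = 0.97
    diversity_rank: str = "species"
    seed: int = 0
    reference_db: Optional[str] = None  # viral reference FASTA
    lineage: Optional[str] = None
    rrna_db: Optional[str] = None
    human_ref: Optional[str] = None
    groups: Optional[str] = None
    contigs: Optional[str] = None  # external assembler output (FASTA) bypass
    out_dir: Optional[str] = None

    def validate(self) -> None:
        if not 0 < self.subsample.fraction <= 1:
            raise ValueError("subsample.fraction must be in (0, 1]")
        if self.subsample.cap < 1:
            raise ValueError("subsample.cap must be >= 1")
        if not 0 < self.cluster_identity <= 1:
            raise ValueError("cluster_identity must be in (0, 1]")
        if self.diversity_rank not in RANKS:
            raise ValueError(f"diversity_rank must be one of {RANKS}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        nested: Dict[str, object] = {}
        for key, value in raw.items():
            if "." in key:  # flat-key form: qc.min_length: 50
                section, sub = key.split(".", 1)
                nested.setdefault(section, {})[sub] = value  # type: ignore[index]
            elif isinstance(value, dict):
                nested.setdefault(key, {}).update(value)  # type: ignore[union-attr]
            else:
                nested[key] = value
        config = cls()
        for section_field in dataclasses.fields(cls):
            if section_field.name not in nested:
                continue
            value = nested[section_field.name]
            current = getattr(config, section_field.name)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                for k, v in value.items():
                    if not hasattr(current, k):
                        raise ValueError(
                            f"unknown config key {section_field.name}.{k}"
                        )
                    setattr(current, k, v)
            else:
                setattr(config, section_field.name, value)
        config.validate()
        return config


@dataclass(slots=True)
class SampleSpec:
    sample_id: str
    r1: str
    r2: str


def read_manifest(path) -> List[SampleSpec]:
    """sample_id<TAB>r1_path<TAB>r2_path; relative paths resolve against the
    manifest's directory."""
    base = Path(path).parent
    samples = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns "
                    "(sample_id, r1, r2)"
                )
            r1, r2 = (str(base / f) if not Path(f).is_absolute() else f
                      for f in fields[1:3])
            samples.append(SampleSpec(sample_id=fields[0], r1=r1, r2=r2))
    return samples


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class SampleResult:
    sample_id: str
    qc_report: qc.QCReport
    candidates: List[str]
    assignments: List[qt.ReadAssignment]
    distribution: dm.ReadDistribution
    dark_reads: List[ReadRecord]
    failed: bool = False


@dataclass
class RunResult:
    """Bundle of everything a run produces."""

    abundance: qt.AbundanceTable
    union: List[str]
    per_sample_candidates: Dict[str, List[str]]
    samples: List[SampleResult]
    diversity: List[dv.DiversityRow]
    config: RunConfig


def _qc_sample(
    spec: SampleSpec, config: RunConfig
) -> Tuple[List[ReadRecord], List[ReadRecord], qc.QCReport]:
    """Trim + interlace one sample; returns (qc_passed, assembly_input, report)."""
    report = qc.QCReport(sample_id=spec.sample_id)
    survivors: List[List[ReadRecord]] = []
    for mate, path in ((1, spec.r1), (2, spec.r2)):
        kept = []
        for read in read_fastq(path, mate=mate):
            report.reads_in += 1
            trimmed = qc.trim_read(
                read,
                quality_threshold=config.qc.quality_threshold,
                min_length=config.qc.min_length,
                max_n_fraction=config.qc.max_n_fraction,
            )
            if trimmed is not None:
                kept.append(trimmed)
        survivors.append(kept)
    report.reads_after_trim = sum(len(s) for s in survivors)
    interleaved, orphans = qc.interlace(survivors[0], survivors[1])
    report.pairs_interlaced = len(interleaved) // 2
    report.orphans = len(orphans)
    qc_passed = interleaved + orphans
    assembly_input = qc.subsample(
        qc_passed,
        fraction=config.subsample.fraction,
        cap=config.subsample.cap,
        seed=derive_seed(config.seed, "subsample", spec.sample_id),
    )
    report.reads_subsampled = len(assembly_input)
    report.validate()
    return qc_passed, assembly_input, report


def _identify_candidates(
    assembly_input: Sequence[ReadRecord],
    refs: Sequence[SequenceRecord],
    config: RunConfig,
    external_contigs: Optional[Sequence[asm.Contig]] = None,
) -> List[str]:
    """Contig + singleton classification -> candidate accession set."""
    if external_contigs is not None:
        contigs = list(external_contigs)
    else:
        contigs = asm.build_unitigs(
            assembly_input, k=config.assembly.k,
            min_kmer_count=config.assembly.min_kmer_count,
        )
    singletons = asm.collect_singletons(assembly_input, contigs, k=config.assembly.k)
    min_identity = config.quantify.min_identity
    candidates: set = set()
    for contig in contigs:
        hits = qt.map_sequence(
            contig.contig_id, contig.residues, refs, config.quantify.min_score
        )
        hits = [h for h in hits if h.identity >= min_identity]
        candidates |= qt.best_hits(
            hits, config.quantify.evalue_cutoff, config.quantify.tie_tolerance
        )
    for hit_list in qt.map_reads(singletons, refs, config.quantify.min_score):
        passing = [h for h in hit_list if h.identity >= min_identity]
        candidates |= qt.best_hits(
            passing, config.quantify.evalue_cutoff, config.quantify.tie_tolerance
        )
    return sorted(candidates)


def run_pipeline(
    config: RunConfig, samples: Sequence[SampleSpec]
) -> RunResult:
    """Process every sample with identical parameters; build the candidate
    union across ALL samples before remapping any sample."""
    if not samples:
        raise ValueError("at least one sample required")
    config.validate()
    if config.reference_db is None:
        raise ValueError("config.reference_db (viral reference FASTA) is required")
    refs = read_fasta(config.reference_db)
    lineage = read_lineage(config.lineage) if config.lineage else LineageTable()
    rrna = read_fasta(config.rrna_db) if (
        config.rrna_db and config.darkmatter.enable_rrna
    ) else []
    human = read_fasta(config.human_ref) if (
        config.human_ref and config.darkmatter.enable_human
    ) else []
    groups = read_groups(config.groups) if config.groups else {}
    external_contigs = None
    if config.contigs:
        external_contigs = [
            asm.Contig(rec.accession, rec.residues, read_support=1)
            for rec in read_fasta(config.contigs)
        ]

    # stage 1: per-sample QC + assembly + candidate identification
    staged = []
    per_sample_candidates: Dict[str, List[str]] = {}
    for spec in samples:
        qc_passed, assembly_input, report = _qc_sample(spec, config)
        if not qc_passed:
            logger.warning("sample %s: no reads passed QC; flagged", spec.sample_id)
            staged.append((spec, [], report, True))
            per_sample_candidates[spec.sample_id] = []
            continue
        candidates = _identify_candidates(
            assembly_input, refs, config, external_contigs
        )
        per_sample_candidates[spec.sample_id] = candidates
        staged.append((spec, qc_passed, report, False))

    # stage 2: union, then remap every sample's full QC-passed read set
    union = qt.candidate_union(per_sample_candidates)
    union_refs = [r for r in refs if r.accession in set(union)]
    by_acc = {r.accession for r in refs}
    missing = [acc for acc in union if acc not in by_acc]
    if missing:
        raise RuntimeError(f"union references missing from database: {missing}")

    sample_results: List[SampleResult] = []
    per_sample_assignments: Dict[str, List[qt.ReadAssignment]] = {}
    for spec, qc_passed, report, failed in staged:
        hit_lists = qt.map_reads(qc_passed, union_refs, config.quantify.min_score)
        assignments = []
        unassigned: List[ReadRecord] = []
        for read, hits in zip(qc_passed, hit_lists):
            a = qt.assign_read(
                hits,
                tie_tolerance=config.quantify.tie_tolerance,
                evalue_cutoff=config.quantify.evalue_cutoff,
            )
            if not a.assigned:
                a = qt.ReadAssignment(read_id=read.read_id, weights=[])
                unassigned.append(read)
            assignments.append(a)
        ribo, hum, dark = dm.partition_reads(
            unassigned, rrna, human, config.quantify.min_score
        )
        dist = dm.distribution_report(
            spec.sample_id, len(qc_passed) - len(unassigned), ribo, hum, dark
        )
        per_sample_assignments[spec.sample_id] = assignments
        sample_results.append(
            SampleResult(
                sample_id=spec.sample_id,
                qc_report=report,
                candidates=per_sample_candidates[spec.sample_id],
                assignments=assignments,
                distribution=dist,
                dark_reads=dark,
                failed=failed,
            )
        )

    table = qt.abundance_table(
        per_sample_assignments, lineage=lineage, groups=groups, references=union
    )
    diversity_rows = (
        dv.diversity_report(table, rank=config.diversity_rank)
        if len(table.references)
        else [
            dv.DiversityRow(s.sample_id, 0.0, 0) for s in sample_results
        ]
    )
    return RunResult(
        abundance=table,
        union=union,
        per_sample_candidates=per_sample_candidates,
        samples=sample_results,
        diversity=diversity_rows,
        config=config,
    )


# ---------------------------------------------------------------------------
# output writing
# ---------------------------------------------------------------------------


def abundance_frame(table: qt.AbundanceTable) -> pd.DataFrame:
    """Abundance table as written: lineage columns first, then samples
    (OTU-table layout)."""
    lineage = table.lineage or LineageTable()
    meta = pd.DataFrame(
        [lineage.get(acc)._asdict() for acc in table.values.index],
        index=table.values.index,
    )
    return pd.concat([meta, table.values], axis=1)


def write_outputs(result: RunResult, out_dir) -> Dict[str, str]:
    """Write the TSV/JSON/FASTQ result bundle; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    abundance_path = out / "abundance.tsv"
    abundance_frame(result.abundance).to_csv(
        abundance_path, sep="\t", index_label="accession"
    )
    paths["abundance"] = str(abundance_path)

    dist_path = out / "read_distribution.tsv"
    pd.DataFrame(
        [dataclasses.asdict(s.distribution) for s in result.samples]
    ).to_csv(dist_path, sep="\t", index=False)
    paths["distribution"] = str(dist_path)

    div_path = out / "diversity.tsv"
    pd.DataFrame([dataclasses.asdict(r) for r in result.diversity]).to_csv(
        div_path, sep="\t", index=False
    )
    paths["diversity"] = str(div_path)

    dark_dir = out / "darkmatter"
    dark_dir.mkdir(exist_ok=True)
    for s in result.samples:
        dark_path = dark_dir / f"{s.sample_id}_dark.fastq"
        write_fastq(s.dark_reads, dark_path)
        paths[f"dark:{s.sample_id}"] = str(dark_path)

    assign_path = out / "read_assignments.tsv"
    with open(assign_path, "w") as handle:
        handle.write("sample\tread_id\taccession\tweight\n")
        for s in result.samples:
            for a in s.assignments:
                for acc, w in a.weights:
                    handle.write(f"{s.sample_id}\t{a.read_id}\t{acc}\t{w!r}\n")
    paths["assignments"] = str(assign_path)

    report = {
        "union": result.union,
        "per_sample_candidates": result.per_sample_candidates,
        "qc": [dataclasses.asdict(s.qc_report) for s in result.samples],
        "failed_samples": [s.sample_id for s in result.samples if s.failed],
        "config": dataclasses.asdict(result.config),
    }
    report_path = out / "run_report.json"
    with open(report_path, "w") as handle:
        json.dump(report, handle, indent=2)
    paths["report"] = str(report_path)
    return paths
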