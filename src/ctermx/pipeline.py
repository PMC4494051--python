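"""End-to-end orchestration: from per-gene families to the addition catalog.

Stages mirror the survey's funnel: input families → alignment + edge
cleanup + poly-N masking + quality filter → SCP scan → singleton exclusion
→ outgroup assessment (sister species must be monomorphic and share a stop
with some focal allele) → polarization → mutation classification and
length measurement → optional translation-evidence filter → catalog.
Every exclusion is recorded with its gene and reason, and the per-stage
retained-gene counts are emitted as a funnel report. Reruns with the same
config and seed are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .alignprep import GeneExcluded, default_aligner, align_family, clean_edges, mask_alignment_polyN, quality_filter
from .classify import assess_outgroup, classify_mutation, infer_min_events, measure_lengths, polarize
from .evidence import EvidenceCall
from .io import read_strain_fasta, write_catalog
from .model import CatalogRow, GeneAlignment, PolarizedEvent, SCPRecord, StopAllele, StrainSequence
from .scan import drop_singletons, mutation_fingerprint, partition_alleles, write_scan_report

FUNNEL_STAGES = [
    "input_genes",
    "aligned_ok",
    "scp_flagged",
    "nonsingleton_scp",
    "outgroup_usable",
    "stop_shared",
    "addition_genes",
    "catalog",
]


@dataclass
class PipelineConfig:
    focal_species: str = "scer"
    sister_species: str = "spar"
    reference_strains: dict[str, str] = field(default_factory=lambda: {"scer": "scer_ref", "spar": "spar_ref"})
    quality_threshold: float = 0.25
    quality_denominator: str = "cells"
    utr_window: int = 150
    flank_granule: int = 150
    seed: int = 0
    downstream_starts: dict[str, int] = field(default_factory=dict)
    evidence_calls: dict[str, EvidenceCall] = field(default_factory=dict)
    min_total_evidence: str = "moderate"  # applied only when evidence data present

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class GeneResult:
    gene_id: str
    stage_reached: str
    exclusion_reason: str | None = None
    record: SCPRecord | None = None
    events: list[PolarizedEvent] = field(default_factory=list)
    min_events: list[tuple[str, str]] = field(default_factory=list)
    catalog_row: CatalogRow | None = None


@dataclass
class PipelineResult:
    funnel: dict[str, int]
    catalog: list[CatalogRow]
    genes: dict[str, GeneResult]
    exclusions: dict[str, str]


def load_family_dir(path: str | Path, reference_strains: dict[str, str]) -> dict[str, list[StrainSequence]]:
    """Read every ``*.fasta`` in a cohort directory into gene families."""
    families: dict[str, list[StrainSequence]] = {}
    for fasta in sorted(Path(path).glob("*.fasta")):
        res = read_strain_fasta(fasta, gene_manifest=reference_strains)
        if res.errors:
            raise ValueError(f"{fasta}: {res.errors[0]}")
        for rec in res.records:
            families.setdefault(rec.gene_id, []).append(rec)
    return families


def _prepare_alignment(strains: list[StrainSequence], config: PipelineConfig, aligner):
    aln = align_family(strains, aligner)
    aln = clean_edges(aln, flank_source=None, aligner=aligner, seqs=strains,
                      granule=config.flank_granule)
    aln, _dropped = mask_alignment_polyN(aln)
    report = quality_filter(aln, config.quality_threshold, config.quality_denominator)
    if not report.passed:
        raise GeneExcluded(aln.gene_id, f"alignment quality {report.fraction:.4f} > {config.quality_threshold}")
    return aln


def _scan(aln: GeneAlignment) -> SCPRecord:
    record = partition_alleles(aln)
    fingerprints = {}
    for allele in record.alleles:
        for sid in allele.strains:
            fingerprints[sid] = mutation_fingerprint(aln, sid, allele.stop_col)
    return drop_singletons(record, fingerprints)


def _restrict(record: SCPRecord, strains: set[str], gene_id: str) -> SCPRecord:
    alleles = []
    for a in record.alleles:
        kept = a.strains & strains
        if kept:
            alleles.append(StopAllele(a.stop_col, frozenset(kept), a.length_codons))
    return SCPRecord(gene_id=gene_id, alleles=alleles)


def process_gene(gene_id: str, strains: list[StrainSequence], config: PipelineConfig,
                 aligner=None) -> GeneResult:
    """Run one gene through the full funnel; never raises for per-gene issues."""
    aligner = aligner or default_aligner()
    focal = [s for s in strains if s.species == config.focal_species]
    sister = [s for s in strains if s.species == config.sister_species]
    result = GeneResult(gene_id, "input_genes")
    if len(focal) < 2:
        result.exclusion_reason = "fewer than two focal-species strains"
        return result
    try:
        aln = _prepare_alignment(focal, config, aligner)
    except GeneExcluded as exc:
        result.exclusion_reason = exc.reason
        return result
    result.stage_reached = "aligned_ok"

    pre = partition_alleles(aln)
    record = _scan(aln)
    result.record = record
    if not pre.is_scp and not record.is_scp:
        return result
    result.stage_reached = "scp_flagged"
    if not record.is_scp:
        result.exclusion_reason = "only singleton evidence of SCP"
        return result
    result.stage_reached = "nonsingleton_scp"

    # outgroup: sister family must exist and be monomorphic on its own
    sister_record = None
    if sister:
        try:
            sister_aln = _prepare_alignment(sister, config, aligner)
            sister_record = _scan(sister_aln)
        except GeneExcluded:
            sister_record = None
    if sister_record is None or not sister_record.alleles:
        result.exclusion_reason = "missing_outgroup"
        return result
    if sister_record.is_scp:
        result.exclusion_reason = "polymorphic_outgroup"
        return result

    # realign retained focal strains with the monomorphic sister reference
    retained = sorted({s for a in record.alleles for s in a.strains})
    sister_ref = config.reference_strains.get(config.sister_species)
    sister_rep = next((s for s in sister if s.strain_id == sister_ref), sister[0])
    focal_ref = config.reference_strains.get(config.focal_species)
    joint_ids = set(retained) | {focal_ref}
    joint_strains = [s for s in focal if s.strain_id in joint_ids] + [sister_rep]
    try:
        joint_aln = _prepare_alignment(joint_strains, config, aligner)
    except GeneExcluded as exc:
        result.exclusion_reason = f"joint realignment failed: {exc.reason}"
        return result
    joint_record = _scan(joint_aln)
    focal_joint = _restrict(joint_record, set(retained), gene_id)
    sister_joint = _restrict(joint_record, {sister_rep.strain_id}, gene_id)
    status = assess_outgroup(focal_joint, sister_joint.alleles and sister_joint or None)
    if status.status in ("missing_outgroup", "polymorphic_outgroup"):
        result.exclusion_reason = status.status
        return result
    result.stage_reached = "outgroup_usable"
    if status.status == "stop_not_shared":
        result.exclusion_reason = "stop_not_shared"
        return result
    result.stage_reached = "stop_shared"

    polarities = polarize(focal_joint, status)
    result.min_events = infer_min_events(polarities)
    anc_allele = next(a for a in focal_joint.alleles if a.stop_col == status.outgroup_stop_col)
    anc_rep = focal_ref if focal_ref in anc_allele.strains else sorted(anc_allele.strains)[0]
    anc_seq = joint_aln.ungapped(anc_rep)
    a_start = joint_aln.ungapped_of_col(anc_rep, joint_aln.start_col) or 0
    downstream = config.downstream_starts.get(gene_id)

    addition_rows: list[tuple[int, int, str, StopAllele]] = []
    for allele in focal_joint.alleles:
        pol = polarities[allele.stop_col]
        if pol == "ancestral":
            continue
        if pol == "subtraction":
            result.events.append(PolarizedEvent(
                gene_id=gene_id, species=config.focal_species, polarity="subtraction",
                mutation_class=None, added_aa=0, new_aa=0,
                n_nonsingleton_alleles=len(focal_joint.alleles),
                outgroup_len_aa=status.outgroup_len_aa))
            continue
        der_rep = sorted(allele.strains)[0]
        der_seq = joint_aln.ungapped(der_rep)
        d_start = joint_aln.ungapped_of_col(der_rep, joint_aln.start_col) or 0
        try:
            mclass = classify_mutation(anc_seq, der_seq, a_start, d_start, downstream)
            added, new = measure_lengths(anc_seq, der_seq, a_start, d_start, downstream)
        except ValueError as exc:
            result.events.append(PolarizedEvent(
                gene_id=gene_id, species=config.focal_species, polarity="ambiguous",
                mutation_class=None, added_aa=0, new_aa=0,
                n_nonsingleton_alleles=len(focal_joint.alleles),
                outgroup_len_aa=status.outgroup_len_aa, certainty=f"unclassified: {exc}"))
            continue
        result.events.append(PolarizedEvent(
            gene_id=gene_id, species=config.focal_species, polarity="addition",
            mutation_class=mclass, added_aa=added, new_aa=new,
            n_nonsingleton_alleles=len(focal_joint.alleles),
            outgroup_len_aa=status.outgroup_len_aa))
        addition_rows.append((added, new, mclass, allele))

    if addition_rows:
        result.stage_reached = "addition_genes"
        added, new, mclass, _ = max(addition_rows, key=lambda t: t[0])
        call = config.evidence_calls.get(gene_id)
        result.catalog_row = CatalogRow(
            systematic_name=gene_id, standard_name="NA", species=config.focal_species,
            outgroup_len_aa=status.outgroup_len_aa, added_aa=added, new_aa=new,
            mutation_class=mclass, n_alleles=len(focal_joint.alleles),
            ribo_evidence=call.category if call else "none",
            total_evidence=(call.total_evidence or call.category) if call else "none",
        )
    return result


_EVIDENCE_RANK = {"none": 0, "low": 1, "moderate": 2, "strong": 3}


def run_pipeline(families: dict[str, list[StrainSequence]], config: PipelineConfig,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run every family through the funnel and assemble the catalog."""
    aligner = default_aligner()
    genes: dict[str, GeneResult] = {}
    exclusions: dict[str, str] = {}
    funnel = {stage: 0 for stage in FUNNEL_STAGES}
    order = {stage: i for i, stage in enumerate(FUNNEL_STAGES)}
    catalog: list[CatalogRow] = []
    for gene_id in sorted(families):
        res = process_gene(gene_id, families[gene_id], config, aligner)
        genes[gene_id] = res
        if res.exclusion_reason:
            exclusions[gene_id] = res.exclusion_reason
        for stage in FUNNEL_STAGES[: order[res.stage_reached] + 1]:
            funnel[stage] += 1
        if res.catalog_row is not None:
            row = res.catalog_row
            if config.evidence_calls and _EVIDENCE_RANK[row.total_evidence] < _EVIDENCE_RANK[config.min_total_evidence]:
                exclusions[gene_id] = f"insufficient translation evidence ({row.total_evidence})"
                continue
            funnel["catalog"] += 1
            catalog.append(row)
    result = PipelineResult(funnel=funnel, catalog=catalog, genes=genes, exclusions=exclusions)
    if out_dir is not None:
        write_outputs(result, out_dir, config)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path, config: PipelineConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_catalog(result.catalog, out / "catalog.tsv")
    with open(out / "funnel.tsv", "w") as fh:
        fh.write(f"# seed={config.seed}\n")
        fh.write("stage\tgenes\n")
        for stage, n in result.funnel.items():
            fh.write(f"{stage}\t{n}\n")
    records = [r.record for r in result.genes.values() if r.record is not None]
    write_scan_report(records, out / "scan.tsv")
    with open(out / "events.tsv", "w") as fh:
        fh.write("gene_id\tspecies\tpolarity\tmutation_class\tadded_aa\tnew_aa\tn_alleles\toutgroup_len_aa\tcertainty\n")
        for gene_id in sorted(result.genes):
            for e in result.genes[gene_id].events:
                fh.write(f"{e.gene_id}\t{e.species}\t{e.polarity}\t{e.mutation_class or ''}\t"
                         f"{e.added_aa}\t{e.new_aa}\t{e.n_nonsingleton_alleles}\t{e.outgroup_len_aa}\t{e.certainty}\n")
    with open(out / "exclusions.tsv", "w") as fh:
        fh.write("gene_id\treason\n")
        for gene_id, reason in sorted(result.exclusions.items()):
            fh.write(f"{gene_id}\t{reason}\n")
    with open(out / "funnel.json", "w") as fh:
        json.dump(result.funnel, fh, indent=2, sort_keys=True)
        fh.write("\n")
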