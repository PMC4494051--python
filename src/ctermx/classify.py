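"""Polarize SCPs against the sister-species outgroup and classify events.

The sister species' stop position marks the ancestral state: focal alleles
with a stop downstream of it are additions (3'-UTR converted to coding),
upstream ones subtractions. Additions are then classified by the mutation
that caused them — a point substitution destroying the stop codon, a
frameshifting indel upstream of it, or a deletion that removes the stop
plus the entire 3' flank and fuses the gene in frame to its downstream
neighbour — and measured as added amino acids (residues beyond the
ancestral stop) and new amino acids (all residues whose codon composition
the mutation altered, including frameshifted ones upstream of the old stop).
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignprep import _pairwise
from .model import GAP, SCPRecord, is_stop, translate_to_stop

OUTGROUP_STATUSES = ("usable", "polymorphic_outgroup", "missing_outgroup", "stop_not_shared")

FUSION_NOTE = (
    "deletion-mediated fusion call requires transcript-level validation; "
    "replicated assembly errors can mimic this signature"
)


@dataclass
class OutgroupStatus:
    gene_id: str
    status: str
    outgroup_stop_col: int | None = None
    outgroup_len_aa: int | None = None


@dataclass
class IndelOp:
    kind: str  # "ins" (derived gains bases) or "del" (derived loses bases)
    anc_pos: int  # ancestral coordinate where the run starts
    der_pos: int  # derived coordinate where the run starts
    length: int


@dataclass
class PairDiff:
    indels: list[IndelOp]
    stop_substituted: bool  # ancestral stop triplet replaced by a sense codon
    ancestral_len: int  # protein length, stop excluded
    derived_len: int | None


def assess_outgroup(focal: SCPRecord, sister: SCPRecord | None) -> OutgroupStatus:
    """Judge whether the sister species can polarize the focal SCP.

    Both records must come from the same (joint) alignment so stop columns
    are comparable. The outgroup is unusable when the sister gene is itself
    polymorphic, absent, or stops at a position shared by no focal allele.
    """
    gene = focal.gene_id
    if sister is None or not sister.alleles:
        return OutgroupStatus(gene, "missing_outgroup")
    if len(sister.alleles) > 1:
        return OutgroupStatus(gene, "polymorphic_outgroup")
    anc = sister.alleles[0]
    if all(a.stop_col != anc.stop_col for a in focal.alleles):
        return OutgroupStatus(gene, "stop_not_shared", outgroup_stop_col=anc.stop_col,
                              outgroup_len_aa=anc.length_codons)
    return OutgroupStatus(gene, "usable", outgroup_stop_col=anc.stop_col,
                          outgroup_len_aa=anc.length_codons)


def polarize(record: SCPRecord, outgroup: OutgroupStatus) -> dict[int, str]:
    """Per-allele polarity keyed by allele stop column.

    Downstream of the outgroup stop → addition; upstream → subtraction;
    equal → ancestral.
    """
    if outgroup.status != "usable":
        raise ValueError(f"{record.gene_id}: outgroup not usable ({outgroup.status})")
    out = {}
    for allele in record.alleles:
        if allele.stop_col > outgroup.outgroup_stop_col:
            out[allele.stop_col] = "addition"
        elif allele.stop_col < outgroup.outgroup_stop_col:
            out[allele.stop_col] = "subtraction"
        else:
            out[allele.stop_col] = "ancestral"
    return out


def infer_min_events(polarities: dict[int, str]) -> list[tuple[str, str]]:
    """Minimal event multiset explaining the allele set, with certainty labels.

    One derived allele on one side of the ancestral stop forces one certain
    event of that polarity; alleles on both sides force at least one of
    each; every further derived allele could be either an addition or a
    subtraction from a longer allele, and is labelled ambiguous. The strain
    tree is deliberately not consulted: outcrossing can make the gene tree
    disagree with the strain tree.
    """
    d = sum(1 for p in polarities.values() if p == "addition")
    u = sum(1 for p in polarities.values() if p == "subtraction")
    events: list[tuple[str, str]] = []
    if d:
        events.append(("addition", "certain"))
    if u:
        events.append(("subtraction", "certain"))
    extras = max(d - 1, 0) + max(u - 1, 0)
    events.extend([("addition_or_subtraction", "ambiguous")] * extras)
    return events


# ---------------------------------------------------------------------------
# Pairwise diff, mutation class, lengths


def diff_pair(ancestral: str, derived: str, a_start: int = 0, d_start: int = 0) -> PairDiff:
    """Align an ancestral/derived allele pair and extract causal features.

    Only indels and substitutions inside the ancestral stop triplet are
    reported; other substitutions (neutral strain-to-strain variation) are
    ignored.
    """
    la = translate_to_stop(ancestral, a_start)
    if la is None:
        raise ValueError("ancestral allele has no in-frame stop")
    stop_pos = a_start + 3 * la
    ga, gd = _pairwise(ancestral, derived)
    indels: list[IndelOp] = []
    anc_pos = der_pos = 0
    derived_stop_triplet = []
    col = 0
    n = len(ga)
    while col < n:
        a, d = ga[col], gd[col]
        if (a == GAP) != (d == GAP):
            kind = "ins" if a == GAP else "del"
            run_start_a, run_start_d = anc_pos, der_pos
            length = 0
            while col < n and (ga[col] == GAP) != (gd[col] == GAP) and \
                    (("ins" if ga[col] == GAP else "del") == kind):
                if kind == "ins":
                    der_pos += 1
                else:
                    anc_pos += 1
                length += 1
                col += 1
            indels.append(IndelOp(kind, run_start_a, run_start_d, length))
            continue
        if a != GAP:
            if stop_pos <= anc_pos < stop_pos + 3:
                derived_stop_triplet.append(d)
            anc_pos += 1
        if d != GAP:
            der_pos += 1
        col += 1
    stop_substituted = (
        len(derived_stop_triplet) == 3
        and GAP not in derived_stop_triplet
        and not is_stop("".join(derived_stop_triplet))
    )
    return PairDiff(
        indels=indels,
        stop_substituted=stop_substituted,
        ancestral_len=la,
        derived_len=translate_to_stop(derived, d_start),
    )


def _upstream_indels(diff: PairDiff, a_start: int) -> list[IndelOp]:
    stop_end = a_start + 3 * diff.ancestral_len + 3
    return [op for op in diff.indels if op.anc_pos < stop_end]


def _fusion_op(diff: PairDiff, a_start: int, d_start: int, downstream_start: int | None) -> IndelOp | None:
    """The deletion op realizing a fusion, if the diff contains one."""
    if downstream_start is None:
        return None
    stop_pos = a_start + 3 * diff.ancestral_len
    for op in diff.indels:
        if op.kind != "del":
            continue
        if op.anc_pos <= stop_pos and op.anc_pos + op.length >= downstream_start:
            # downstream ORF must land in frame with the truncated CDS
            if (op.der_pos - d_start) % 3 == 0:
                return op
    return None


def classify_mutation(ancestral: str, derived: str, a_start: int = 0, d_start: int = 0,
                      downstream_start: int | None = None) -> str:
    """Mutation class of an addition allele: point, frameshift or fusion.

    ``downstream_start`` (ancestral coordinate of the downstream gene's
    start codon) enables the deletion_fusion call; without it a fusion-like
    deletion cannot be distinguished and classification fails.
    """
    diff = diff_pair(ancestral, derived, a_start, d_start)
    if _fusion_op(diff, a_start, d_start, downstream_start) is not None:
        return "deletion_fusion"
    upstream = _upstream_indels(diff, a_start)
    if upstream:
        net = sum(op.length if op.kind == "ins" else -op.length for op in upstream)
        if net % 3 != 0:
            return "frameshift"
        raise ValueError("upstream indels preserve frame; not a stop-loss addition")
    if diff.stop_substituted:
        return "point"
    raise ValueError("derived allele shows no stop-destroying mutation (identical to ancestral?)")


def measure_lengths(ancestral: str, derived: str, a_start: int = 0, d_start: int = 0,
                    downstream_start: int | None = None) -> tuple[int, int]:
    """(added_aa, new_aa) for an addition allele.

    added = derived protein length − ancestral protein length. For point
    events new = added; for frameshifts and fusions new counts from the
    first derived codon whose composition the causal indel altered
    (an indel inside a codon attributes that codon to "new").
    """
    diff = diff_pair(ancestral, derived, a_start, d_start)
    if diff.derived_len is None:
        raise ValueError("derived allele has no in-frame stop")
    added = diff.derived_len - diff.ancestral_len
    if added < 0:
        raise ValueError(f"negative added length ({added}) for a putative addition")
    fusion = _fusion_op(diff, a_start, d_start, downstream_start)
    if fusion is not None:
        k = (fusion.der_pos - d_start) // 3
        return added, diff.derived_len - k
    upstream = _upstream_indels(diff, a_start)
    if not upstream:
        return added, added  # point event
    first = min(upstream, key=lambda op: op.anc_pos)
    k = (first.der_pos - d_start) // 3
    return added, diff.derived_len - k


def detect_fusion(ancestral: str, derived: str, downstream_start: int, a_start: int = 0,
                  d_start: int = 0) -> tuple[bool, str]:
    """Flag a deletion that removes the stop plus the whole 3' flank and
    joins the downstream ORF in frame. The note always marks the call as
    provisional pending transcript evidence."""
    diff = diff_pair(ancestral, derived, a_start, d_start)
    flagged = _fusion_op(diff, a_start, d_start, downstream_start) is not None
    return flagged, FUSION_NOTE if flagged else ""
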