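"""Alignment preparation: build and clean frame-interpretable alignments.

Families are aligned with a pluggable aligner (an external MUSCLE-compatible
tool can be hooked in; the built-in fallback is a deterministic
reference-anchored star alignment built from affine-gap pairwise
alignments). Cleanup then makes the alignment edges gap-free by extending
3' flanks and pruning, extends until every row has an in-frame stop
reachable from the annotated start, masks poly-N runs, and applies the 25%
internal-gap + ambiguity exclusion filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from Bio import Align

from .model import GAP, GeneAlignment, StrainSequence, first_stop_pos

FLANK_GRANULE = 150  # nt appended per extension round, matching the initial 3'-UTR window


class GeneExcluded(Exception):
    """A gene failed a quality rule and leaves the analysis, with a reason."""

    def __init__(self, gene_id: str, reason: str):
        self.gene_id = gene_id
        self.reason = reason
        super().__init__(f"{gene_id}: {reason}")


@dataclass
class AlignerContract:
    """A callable alignment backend.

    ``fn`` maps a list of :class:`StrainSequence` to a :class:`GeneAlignment`
    whose rows ungap back to the inputs; it must be deterministic for fixed
    inputs and parameters.
    """

    fn: Callable[[list[StrainSequence]], GeneAlignment]
    name: str = "builtin-star"
    parameters: dict = field(default_factory=dict)

    def __call__(self, seqs: list[StrainSequence]) -> GeneAlignment:
        return self.fn(seqs)


@dataclass
class QualityReport:
    n_internal_gap_chars: int
    n_ambiguous_chars: int
    n_columns: int
    n_rows: int
    fraction: float
    passed: bool


def _pairwise(ref: str, other: str, match=1.0, mismatch=-1.0, open_gap=-4.0, extend=-1.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend
    aln = aligner.align(ref, other)[0]
    return str(aln[0]), str(aln[1])


def _insertion_profile(gapped_ref: str) -> list[int]:
    """Lengths of gap runs in the reference before each ref base (and at end)."""
    profile = []
    run = 0
    for ch in gapped_ref:
        if ch == GAP:
            run += 1
        else:
            profile.append(run)
            run = 0
    profile.append(run)
    return profile


def builtin_align(seqs: list[StrainSequence], **scoring) -> GeneAlignment:
    """Reference-anchored star alignment.

    Every non-reference sequence is globally aligned to the reference with
    affine gap scoring (match +1, mismatch -1, gap open -4, gap extend -1),
    and the pairwise alignments are merged over reference coordinates, with
    insertion columns sized to the longest insertion seen at each reference
    position. Exact for the near-identical families this pipeline handles,
    and fully deterministic.
    """
    if len(seqs) < 2:
        raise ValueError("alignment needs at least two sequences")
    gene_ids = {s.gene_id for s in seqs}
    if len(gene_ids) != 1:
        raise ValueError(f"sequences from multiple genes: {sorted(gene_ids)}")
    ref = next((s for s in seqs if s.is_reference), seqs[0])
    pairs = {}
    for s in seqs:
        if s.strain_id == ref.strain_id:
            continue
        pairs[s.strain_id] = _pairwise(ref.seq, s.seq, **scoring)
    # merged insertion sizes before each reference base
    ins = [0] * (len(ref.seq) + 1)
    profiles = {}
    for sid, (gref, _) in pairs.items():
        prof = _insertion_profile(gref)
        profiles[sid] = prof
        for i, n in enumerate(prof):
            ins[i] = max(ins[i], n)

    def expand_ref() -> str:
        out = []
        for i, base in enumerate(ref.seq):
            out.append(GAP * ins[i])
            out.append(base)
        out.append(GAP * ins[len(ref.seq)])
        return "".join(out)

    def expand_other(sid: str) -> str:
        gref, gother = pairs[sid]
        prof = profiles[sid]
        out = []
        ref_i = 0
        chunk: list[str] = []
        for rch, och in zip(gref, gother):
            if rch == GAP:
                chunk.append(och)
            else:
                out.append(GAP * (ins[ref_i] - prof[ref_i]))
                out.append("".join(chunk))
                chunk = []
                out.append(och)
                ref_i += 1
        out.append(GAP * (ins[len(ref.seq)] - prof[len(ref.seq)]))
        out.append("".join(chunk))
        return "".join(out)

    rows = []
    for s in seqs:
        if s.strain_id == ref.strain_id:
            rows.append((s.strain_id, expand_ref()))
        else:
            rows.append((s.strain_id, expand_other(s.strain_id)))
    aln = GeneAlignment(gene_id=ref.gene_id, rows=rows, ref_strain=ref.strain_id)
    _annotate_anchors(aln, ref)
    return aln


def _annotate_anchors(aln: GeneAlignment, ref: StrainSequence) -> None:
    """Set start_col/stop_col from the reference annotation."""
    aln.start_col = aln.col_of_ungapped(ref.strain_id, ref.orf_start)
    stop_nt = first_stop_pos(ref.seq, ref.orf_start)
    aln.stop_col = aln.col_of_ungapped(ref.strain_id, stop_nt) if stop_nt is not None else None


def default_aligner(**scoring) -> AlignerContract:
    return AlignerContract(fn=lambda seqs: builtin_align(seqs, **scoring), name="builtin-star", parameters=scoring)


def align_family(seqs: list[StrainSequence], aligner: AlignerContract | None = None) -> GeneAlignment:
    """Align one gene family, surfacing aligner failures with the gene id."""
    if not seqs:
        raise ValueError("empty input family")
    aligner = aligner or default_aligner()
    try:
        return aligner(seqs)
    except ValueError:
        raise
    except Exception as exc:  # aligner backend failure
        raise RuntimeError(f"aligner {aligner.name!r} failed on gene {seqs[0].gene_id}: {exc}") from exc


# ---------------------------------------------------------------------------
# Edge cleanup


def _strain_start_pos(aln: GeneAlignment, strain_id: str) -> int | None:
    """Ungapped position in a strain corresponding to the start anchor column."""
    row = aln.row(strain_id)
    col = aln.start_col
    # walk forward to the first residue at or after the anchor column
    while col < len(row) and row[col] == GAP:
        col += 1
    if col >= len(row):
        return None
    return aln.ungapped_of_col(strain_id, col)


def _rows_missing_stop(aln: GeneAlignment) -> list[str]:
    missing = []
    for sid in aln.strain_ids:
        seq = aln.ungapped(sid)
        start = _strain_start_pos(aln, sid)
        if start is None or first_stop_pos(seq, start) is None:
            missing.append(sid)
    return missing


def _trim_to_support(aln: GeneAlignment) -> GeneAlignment:
    """Prune edge columns so the first and last columns are residue-only."""
    rows = aln.rows
    n = aln.n_cols
    lo = 0
    while lo < n and any(seq[lo] == GAP for _, seq in rows):
        lo += 1
    hi = n
    while hi > lo and any(seq[hi - 1] == GAP for _, seq in rows):
        hi -= 1
    if hi - lo < 3:
        raise GeneExcluded(aln.gene_id, "no common support after edge pruning")
    if lo == 0 and hi == n:
        return aln
    new_rows = [(sid, seq[lo:hi]) for sid, seq in rows]
    start_col = max(aln.start_col - lo, 0)
    stop_col = None
    if aln.stop_col is not None and lo <= aln.stop_col < hi:
        stop_col = aln.stop_col - lo
    out = GeneAlignment(aln.gene_id, new_rows, aln.ref_strain, start_col=start_col, stop_col=stop_col)
    return out


def clean_edges(
    alignment: GeneAlignment,
    flank_source: Callable[[str, int], str | None] | None = None,
    max_iter: int = 10,
    aligner: AlignerContract | None = None,
    seqs: list[StrainSequence] | None = None,
    granule: int = FLANK_GRANULE,
) -> GeneAlignment:
    """Iteratively extend and prune until edges are gap-free and every row
    has an in-frame stop reachable from the annotated start.

    Rows lacking a stop are extended 3' in ``granule``-nt steps via
    ``flank_source(strain_id, n_nt)`` and the family is realigned; when the
    flank is exhausted the gene is excluded with reason ``no in-frame stop``.
    Trailing-edge gaps are first addressed by extension, then by pruning to
    the outermost residue-only columns. Idempotent on already-clean input.
    """
    aligner = aligner or default_aligner()
    if seqs is None:
        ref_start = alignment.ungapped_of_col(alignment.ref_strain, alignment.start_col) or 0
        seqs = [
            StrainSequence(alignment.gene_id, sid, "unknown", alignment.ungapped(sid),
                           orf_start=ref_start if sid == alignment.ref_strain else 0,
                           is_reference=sid == alignment.ref_strain)
            for sid in alignment.strain_ids
        ]
    seqs = list(seqs)
    by_id = {s.strain_id: s for s in seqs}
    aln = alignment
    for _ in range(max_iter):
        missing = _rows_missing_stop(aln)
        trailing_gaps = [sid for sid, seq in aln.rows if seq.endswith(GAP)]
        needs_extension = sorted(set(missing) | set(trailing_gaps))
        extended = False
        if needs_extension and flank_source is not None:
            for sid in needs_extension:
                extra = flank_source(sid, granule)
                if extra:
                    old = by_id[sid]
                    by_id[sid] = StrainSequence(
                        old.gene_id, old.strain_id, old.species, old.seq + extra.upper(),
                        orf_start=old.orf_start, is_reference=old.is_reference,
                    )
                    extended = True
        if extended:
            aln = align_family([by_id[s.strain_id] for s in seqs], aligner)
            continue
        if missing:
            raise GeneExcluded(aln.gene_id, f"no in-frame stop for strains {missing}")
        pruned = _trim_to_support(aln)
        if _rows_missing_stop(pruned):
            raise GeneExcluded(aln.gene_id, "in-frame stop lost during edge pruning")
        return pruned
    raise GeneExcluded(alignment.gene_id, f"edge cleanup did not converge in {max_iter} iterations")


# ---------------------------------------------------------------------------
# Poly-N masking and the quality filter


def mask_polyN(row: str) -> tuple[str, int]:
    """Mask runs of two or more N and everything 5' of them.

    A run of >=2 consecutive N (gap characters do not interrupt a run) marks
    the reading frame as compromised from the 5' end through the end of that
    run; those residues become edge gaps. Single N's are retained. Returns
    the masked row and the number of residues remaining.
    """
    residues = [(i, ch) for i, ch in enumerate(row) if ch != GAP]
    last_run_end = None  # index into residues, exclusive
    run = 0
    for k, (_, ch) in enumerate(residues):
        if ch == "N":
            run += 1
            if run >= 2:
                last_run_end = k + 1
        else:
            run = 0
    if last_run_end is None:
        return row, len(residues)
    chars = list(row)
    for k in range(last_run_end):
        chars[residues[k][0]] = GAP
    remaining = len(residues) - last_run_end
    return "".join(chars), remaining


def mask_alignment_polyN(aln: GeneAlignment, min_keep: int = 3) -> tuple[GeneAlignment, dict[str, str]]:
    """Apply poly-N masking to every row; drop rows with < ``min_keep`` residues.

    Returns the masked alignment and a {strain: reason} map for dropped rows.
    The reference row is never dropped (the reference anchors the frame); a
    fully masked reference excludes the gene instead.
    """
    dropped: dict[str, str] = {}
    new_rows = []
    for sid, seq in aln.rows:
        masked, remaining = mask_polyN(seq)
        if remaining < min_keep:
            if sid == aln.ref_strain:
                raise GeneExcluded(aln.gene_id, "reference row fully masked by poly-N rule")
            dropped[sid] = "poly-N masking removed the entire row"
            continue
        new_rows.append((sid, masked))
    if len(new_rows) < 2:
        raise GeneExcluded(aln.gene_id, "fewer than two rows survive poly-N masking")
    out = GeneAlignment(aln.gene_id, new_rows, aln.ref_strain, start_col=aln.start_col, stop_col=aln.stop_col)
    return out, dropped


def _internal_gap_count(seq: str) -> int:
    stripped = seq.strip(GAP)
    return stripped.count(GAP)


def quality_filter(aln: GeneAlignment, threshold: float = 0.25, denominator: str = "cells") -> QualityReport:
    """Exclude alignments whose internal gaps plus N exceed the threshold.

    ``denominator`` selects what the raw count is divided by: total cells
    (columns x rows, the default) or columns alone. The rule is a strict
    ``>``: a fraction exactly at the threshold passes.
    """
    n_gap = sum(_internal_gap_count(seq) for _, seq in aln.rows)
    n_amb = sum(seq.count("N") for _, seq in aln.rows)
    n_rows = len(aln.rows)
    n_cols = aln.n_cols
    if denominator == "cells":
        denom = n_cols * n_rows
    elif denominator == "columns":
        denom = n_cols
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    fraction = (n_gap + n_amb) / denom if denom else 0.0
    return QualityReport(
        n_internal_gap_chars=n_gap,
        n_ambiguous_chars=n_amb,
        n_columns=n_cols,
        n_rows=n_rows,
        fraction=fraction,
        passed=fraction <= threshold,
    )
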