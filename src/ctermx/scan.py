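"""Stop-codon polymorphism detection on cleaned alignments.

A gene carries an SCP when at least one strain lacks a stop codon aligned
with the reference's annotated stop, or when any strain has a premature
in-frame stop. Strains are partitioned into alleles by their effective stop
position (the first stop in the reading frame established from the
annotated start codon); singleton alleles and "double singletons" (two
strains reaching the same stop via demonstrably independent mutations) are
excluded as likely sequencing errors or strongly deleterious variants.

Walkback runs in each strain's own ungapped coordinates, anchored at its
aligned stop; alignment columns are used only to transfer start/stop
anchors between strains, because indels make column-triplets ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .model import GAP, GeneAlignment, SCPRecord, StopAllele, ValidationError, first_stop_pos, is_stop


@dataclass
class WalkbackResult:
    strain_id: str
    premature_stop_positions: list[int]  # codons upstream of the aligned stop, walked frame
    frame_offset: int  # (start-to-stop distance) mod 3; nonzero implies a frameshift
    reached_start: bool
    effective_stop: int | None = None  # nt offset of the start-frame stop, strain coords


def stop_anchor_columns(aln: GeneAlignment) -> tuple[int, int, int]:
    """Alignment columns of the three bases of the reference stop codon."""
    if aln.stop_col is None:
        raise ValidationError(f"{aln.gene_id}: alignment has no annotated stop column")
    ref_stop_nt = aln.ungapped_of_col(aln.ref_strain, aln.stop_col)
    if ref_stop_nt is None:
        raise ValidationError(f"{aln.gene_id}: reference has a gap at its own stop column")
    cols = tuple(aln.col_of_ungapped(aln.ref_strain, ref_stop_nt + i) for i in range(3))
    ref_triplet = "".join(aln.row(aln.ref_strain)[c] for c in cols)
    if not is_stop(ref_triplet):
        raise ValidationError(
            f"{aln.gene_id}: reference spells {ref_triplet!r} at its annotated stop (annotation error)"
        )
    return cols


def start_anchor_pos(aln: GeneAlignment, strain_id: str) -> int | None:
    """Ungapped position of the start anchor in a strain, or None if masked.

    The anchor transfers through the alignment: the strain must carry a
    residue at the reference start column for its frame to be established.
    """
    return aln.ungapped_of_col(strain_id, aln.start_col)


def locate_aligned_stop(aln: GeneAlignment) -> dict[str, bool]:
    """Per strain: does it carry a stop codon at the reference stop columns?

    A gap in any of the three columns means the strain lacks an aligned
    stop; so does an insertion between them (the strain's three residues
    must be contiguous in its own sequence to form a codon).
    """
    cols = stop_anchor_columns(aln)
    out = {}
    for sid, row in aln.rows:
        triplet = "".join(row[c] for c in cols)
        if GAP in triplet or not is_stop(triplet):
            out[sid] = False
            continue
        positions = [aln.ungapped_of_col(sid, c) for c in cols]
        out[sid] = positions[1] == positions[0] + 1 and positions[2] == positions[0] + 2
    return out


def walkback(aln: GeneAlignment, strain_id: str) -> WalkbackResult:
    """Walk back one triplet at a time from the aligned stop toward the start.

    Records every stop triplet met in the stop-anchored frame of the
    strain's own ungapped sequence. The effective stop (first stop in the
    frame established from the start codon) is derived from the walk: the
    upstream-most walked stop that lies in the start frame wins; otherwise
    the aligned stop itself when it is in frame; otherwise the scan
    continues forward past the aligned stop in the start frame.
    """
    cols = stop_anchor_columns(aln)
    seq = aln.ungapped(strain_id)
    anchor = aln.ungapped_of_col(strain_id, cols[0])
    if anchor is None:
        raise ValidationError(f"{strain_id}: no aligned stop; walkback undefined")
    start = start_anchor_pos(aln, strain_id)
    reached = start is not None
    premature: list[int] = []
    if reached:
        k = 1
        while anchor - 3 * k >= start:
            t = seq[anchor - 3 * k : anchor - 3 * k + 3]
            if is_stop(t):
                premature.append(k)
            k += 1
        frame_offset = (anchor - start) % 3
    else:
        frame_offset = 0
    effective = None
    if reached:
        if frame_offset == 0:
            # walked frame == start frame: the upstream-most stop wins
            effective = anchor - 3 * max(premature) if premature else anchor
        else:
            # frameshift between start and stop: the walked frame is not the
            # coding frame, so resume a forward scan in the start frame
            effective = first_stop_pos(seq, start)
    return WalkbackResult(
        strain_id=strain_id,
        premature_stop_positions=premature,
        frame_offset=frame_offset,
        reached_start=reached,
        effective_stop=effective,
    )


def effective_stop(aln: GeneAlignment, strain_id: str) -> tuple[int | None, int | None]:
    """(nt offset, protein length in codons) of the strain's effective stop.

    Naive start-anchored translation: the first in-frame stop from the start
    anchor in the strain's own ungapped sequence. None when the start anchor
    is masked away or no stop is reachable.
    """
    start = start_anchor_pos(aln, strain_id)
    if start is None:
        return None, None
    seq = aln.ungapped(strain_id)
    pos = first_stop_pos(seq, start)
    if pos is None:
        return None, None
    return pos, (pos - start) // 3


def partition_alleles(aln: GeneAlignment, walkbacks: dict[str, WalkbackResult] | None = None) -> SCPRecord:
    """Group strains into alleles by effective stop position.

    The allele key is the alignment column of the effective stop's first
    base, so homologous stops group together across strains regardless of
    upstream indels. Strains whose frame cannot be established (masked
    start anchor, or no reachable stop) are excluded with a reason.
    Strain order does not affect the partition.
    """
    excluded: dict[str, str] = {}
    groups: dict[int, list[tuple[str, int]]] = {}
    for sid in aln.strain_ids:
        pos, length = effective_stop(aln, sid)
        if pos is None:
            excluded[sid] = "frame not established (start anchor masked or no in-frame stop)"
            continue
        col = aln.col_of_ungapped(sid, pos)
        groups.setdefault(col, []).append((sid, length))
    alleles = [
        StopAllele(stop_col=col, strains=frozenset(s for s, _ in members),
                   length_codons=members[0][1])
        for col, members in sorted(groups.items())
    ]
    return SCPRecord(gene_id=aln.gene_id, alleles=alleles, singleton_excluded=excluded)


# ---------------------------------------------------------------------------
# Mutation fingerprints and singleton exclusion


def _row_support(seq: str) -> tuple[int, int]:
    lo = len(seq) - len(seq.lstrip(GAP))
    hi = len(seq.rstrip(GAP))
    return lo, hi


def mutation_fingerprint(aln: GeneAlignment, strain_id: str, allele_stop_col: int | None = None) -> frozenset:
    """Allele-defining differences between a strain and the reference row.

    Captures (a) internal indels: maximal column runs where exactly one of
    the two rows has a gap, recorded with the inserted/deleted bases, and
    (b) substitutions at the reference stop triplet and at the strain's own
    effective stop triplet. Neutral substitutions elsewhere are ignored, so
    carriers of the same underlying mutation share a fingerprint exactly.
    """
    ref_row = aln.row(aln.ref_strain)
    row = aln.row(strain_id)
    lo = max(_row_support(ref_row)[0], _row_support(row)[0])
    hi = min(_row_support(ref_row)[1], _row_support(row)[1])
    ops = []
    col = lo
    while col < hi:
        r, s = ref_row[col], row[col]
        if (r == GAP) != (s == GAP):
            kind = "ins" if r == GAP else "del"
            run_start = col
            bases = []
            while col < hi and (ref_row[col] == GAP) != (row[col] == GAP) and \
                    (("ins" if ref_row[col] == GAP else "del") == kind):
                bases.append(row[col] if kind == "ins" else ref_row[col])
                col += 1
            ops.append((kind, run_start, col, "".join(bases)))
        else:
            col += 1
    interesting_cols = set(stop_anchor_columns(aln))
    if allele_stop_col is not None:
        # the strain's own stop triplet: three residue columns from its stop
        pos = aln.ungapped_of_col(strain_id, allele_stop_col)
        if pos is not None:
            seq_len = len(aln.ungapped(strain_id))
            for i in range(3):
                if pos + i < seq_len:
                    interesting_cols.add(aln.col_of_ungapped(strain_id, pos + i))
    for c in sorted(interesting_cols):
        if c >= len(row):
            continue
        r, s = ref_row[c], row[c]
        if r != s and r != GAP and s != GAP:
            ops.append(("sub", c, c + 1, s))
    return frozenset(ops)


def drop_singletons(record: SCPRecord, fingerprints: dict[str, frozenset]) -> SCPRecord:
    """Remove singleton alleles and double-singletons.

    An allele kept after filtering has at least two strains sharing an
    identical mutation fingerprint. Strains excluded at this step are
    recorded with reasons: ``singleton`` (one-strain allele),
    ``double-singleton`` (same stop via independent mutations), or
    ``independent singleton mutation`` (a minority fingerprint inside an
    otherwise supported allele).
    """
    excluded = dict(record.singleton_excluded)
    kept: list[StopAllele] = []
    for allele in record.alleles:
        strains = sorted(allele.strains)
        if len(strains) == 1:
            excluded[strains[0]] = "singleton"
            continue
        by_fp: dict[frozenset, list[str]] = {}
        for s in strains:
            by_fp.setdefault(fingerprints.get(s, frozenset()), []).append(s)
        supported = [grp for grp in by_fp.values() if len(grp) >= 2]
        if not supported:
            for s in strains:
                excluded[s] = "double-singleton"
            continue
        survivors = sorted(s for grp in supported for s in grp)
        for grp in by_fp.values():
            if len(grp) < 2:
                for s in grp:
                    excluded[s] = "independent singleton mutation"
        kept.append(StopAllele(stop_col=allele.stop_col, strains=frozenset(survivors),
                               length_codons=allele.length_codons))
    return SCPRecord(gene_id=record.gene_id, alleles=kept, singleton_excluded=excluded)


def write_scan_report(records: list[SCPRecord], path: str | Path) -> None:
    """Per-gene scan summary TSV."""
    with open(path, "w") as fh:
        fh.write("gene_id\tn_alleles\tallele_sizes\tn_excluded\texclusion_reasons\tis_scp\n")
        for r in records:
            sizes = ",".join(str(len(a.strains)) for a in r.alleles)
            reasons = ";".join(f"{s}:{why}" for s, why in sorted(r.singleton_excluded.items()))
            fh.write(f"{r.gene_id}\t{len(r.alleles)}\t{sizes}\t{len(r.singleton_excluded)}\t{reasons}\t{int(r.is_scp)}\n")
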