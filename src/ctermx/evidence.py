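"""Translation evidence from ribosome-footprint densities.

Footprint reads are filtered at one of two stringencies, converted to a
per-gene density (mean per-nucleotide hits over the ORF divided by mRNA
abundance), averaged across replicates, and binned into a four-level
evidence scale. Curated literature evidence can upgrade the ribosome-based
call; the combined call is the maximum of the two on the ordered scale
none < low < moderate < strong.

Also provided is the readthrough null: the number of codons a protein would
gain if its stop codon were lost and translation continued to the next
in-frame stop within the annotated 3'-UTR.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .model import EVIDENCE_LEVELS, first_stop_pos

#: Density tier boundaries (hits per nt per unit mRNA). Strong is strictly
#: above the top boundary; interior boundaries belong to the lower tier.
DENSITY_THRESHOLDS = {"strong": 0.03, "moderate": 0.015, "low": 0.005}

_LEVEL_RANK = {lvl: i for i, lvl in enumerate(EVIDENCE_LEVELS)}

_LITERATURE_TO_LEVEL = {
    "none": "none",
    "moderate_support": "moderate",
    "strong_support": "strong",
}


@dataclass
class FootprintRead:
    """One mapped ribosome-protected read with its mapping metadata."""

    position: int
    score: int
    unique: bool
    length: int


@dataclass
class FootprintProfile:
    """Per-nucleotide footprint hit counts for one gene in one replicate."""

    gene_id: str
    replicate_id: str
    hits: list[float]
    mrna_abundance: float

    def __post_init__(self) -> None:
        if self.mrna_abundance <= 0:
            raise ValueError(f"{self.gene_id}: mRNA abundance must be positive")
        if any(h < 0 for h in self.hits):
            raise ValueError(f"{self.gene_id}: negative hit count")


@dataclass
class EvidenceCall:
    gene_id: str
    density: float
    category: str
    stringency: str = "high"
    total_evidence: str | None = None


def filter_reads(reads: list[FootprintRead], stringency: str = "high") -> list[FootprintRead]:
    """Apply the mapping-quality filter for a stringency tier.

    ``high`` keeps reads with the maximum alignment score (36) that map to a
    unique location and are at least 18 nt long; ``relaxed`` keeps scores in
    [32, 36] and does not require uniqueness.
    """
    if stringency == "high":
        return [r for r in reads if r.score == 36 and r.unique and r.length >= 18]
    if stringency == "relaxed":
        return [r for r in reads if 32 <= r.score <= 36]
    raise ValueError(f"unknown stringency {stringency!r}")


def reads_to_hits(reads: list[FootprintRead], transcript_len: int) -> list[float]:
    """Accumulate filtered reads into a per-nucleotide hit track."""
    hits = [0.0] * transcript_len
    for r in reads:
        if 0 <= r.position < transcript_len:
            hits[r.position] += 1.0
    return hits


def orf_density(profile: FootprintProfile, orf_span: tuple[int, int]) -> float:
    """Mean per-nucleotide hits over the ORF, normalized by mRNA abundance."""
    lo, hi = orf_span
    if not 0 <= lo < hi <= len(profile.hits):
        raise ValueError(f"{profile.gene_id}: ORF span [{lo},{hi}) outside transcript")
    window = profile.hits[lo:hi]
    return (sum(window) / len(window)) / profile.mrna_abundance


def categorize(densities, gene_id: str = "", stringency: str = "high") -> EvidenceCall:
    """Average replicate densities and assign the four-level category."""
    densities = list(densities)
    if not densities:
        raise ValueError("need at least one replicate density")
    mean = sum(densities) / len(densities)
    if mean > DENSITY_THRESHOLDS["strong"]:
        category = "strong"
    elif mean > DENSITY_THRESHOLDS["moderate"]:
        category = "moderate"
    elif mean > DENSITY_THRESHOLDS["low"]:
        category = "low"
    else:
        category = "none"
    return EvidenceCall(gene_id=gene_id, density=mean, category=category, stringency=stringency)


def combine_total_evidence(call: EvidenceCall, literature_flag: str = "none") -> str:
    """Join ribosome-based and literature evidence on the ordered scale."""
    lit = _LITERATURE_TO_LEVEL.get(literature_flag)
    if lit is None:
        if literature_flag in EVIDENCE_LEVELS:
            lit = literature_flag
        else:
            raise ValueError(f"unknown literature flag {literature_flag!r}")
    total = max(call.category, lit, key=_LEVEL_RANK.__getitem__)
    call.total_evidence = total
    return total


def readthrough_length(seq: str, stop_pos: int, utr_boundary: int) -> int | None:
    """Hypothetical extension length if the stop at ``stop_pos`` were lost.

    Counts codons from the stop to the next in-frame stop strictly before
    ``utr_boundary`` (both stops excluded). Returns None (excluded) when no
    in-frame stop occurs before the boundary.
    """
    if utr_boundary <= stop_pos + 3:
        raise ValueError("UTR boundary at or upstream of the stop codon")
    nxt = first_stop_pos(seq[: utr_boundary], stop_pos + 3)
    if nxt is None:
        return None
    return (nxt - stop_pos) // 3 - 1


# ---------------------------------------------------------------------------
# TSV plumbing


def read_footprint_track(path: str | Path) -> dict[tuple[str, str], pd.DataFrame]:
    """Read a footprint track TSV (gene_id, replicate, transcript_pos, hits)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return {k: g.sort_values("transcript_pos") for k, g in df.groupby(["gene_id", "replicate"])}


def read_abundance(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["gene_id"], df["mrna_abundance"]))


def read_boundaries(path: str | Path) -> dict[str, int]:
    """Transcript 3'-boundary TSV (gene_id, utr_boundary)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["gene_id"], df["utr_boundary"]))


def read_literature(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["gene_id"], df["literature_flag"]))


def evidence_from_tracks(
    tracks: dict[tuple[str, str], pd.DataFrame],
    abundance: dict[str, float],
    orf_spans: dict[str, tuple[int, int]],
    literature: dict[str, str] | None = None,
) -> dict[str, EvidenceCall]:
    """Score every gene present in the track table."""
    by_gene: dict[str, list[float]] = {}
    for (gene, rep), track in tracks.items():
        if gene not in orf_spans or gene not in abundance:
            continue
        span = orf_spans[gene]
        hits = [0.0] * max(span[1], int(track["transcript_pos"].max()) + 1)
        for pos, h in zip(track["transcript_pos"], track["hits"]):
            hits[int(pos)] = float(h)
        profile = FootprintProfile(gene, rep, hits, abundance[gene])
        by_gene.setdefault(gene, []).append(orf_density(profile, span))
    calls = {}
    for gene, densities in sorted(by_gene.items()):
        call = categorize(densities, gene_id=gene)
        combine_total_evidence(call, (literature or {}).get(gene, "none"))
        calls[gene] = call
    return calls
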