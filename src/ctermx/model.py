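"""Core domain types for the stop-codon-polymorphism (SCP) pipeline.

All coordinates are 0-based, half-open, and refer to positions within the
ungapped nucleotide sequence of a strain unless a field name says ``col``
(an alignment column). Conversion to 1-based happens only when printing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NUCLEOTIDES = set("ACGTN")
GAP = "-"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Ordered evidence scale used for both ribosome-profiling and total evidence.
EVIDENCE_LEVELS = ("none", "low", "moderate", "strong")

MUTATION_CLASSES = ("point", "frameshift", "deletion_fusion")
POLARITIES = ("addition", "subtraction", "ambiguous")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass
class StrainSequence:
    """One strain's nucleotide sequence for one gene (ORF plus 3' flank).

    Parameters
    ----------
    gene_id, strain_id, species
        Identifiers; ``species`` names the species the strain belongs to.
    seq
        Nucleotide string over {A, C, G, T, N}; stored uppercase.
    orf_start
        0-based offset of the annotated start codon within ``seq``.
    is_reference
        True for the designated reference strain of its species.
    """

    gene_id: str
    strain_id: str
    species: str
    seq: str
    orf_start: int = 0
    is_reference: bool = False

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) < 3:
            raise ValidationError(
                f"{self.gene_id}/{self.strain_id}: sequence shorter than one codon"
            )
        bad = set(self.seq) - NUCLEOTIDES
        if bad:
            raise ValidationError(
                f"{self.gene_id}/{self.strain_id}: non-IUPAC characters {sorted(bad)!r} "
                "(only A, C, G, T, N accepted)"
            )
        if not 0 <= self.orf_start <= len(self.seq) - 3:
            raise ValidationError(
                f"{self.gene_id}/{self.strain_id}: orf_start {self.orf_start} "
                f"outside sequence of length {len(self.seq)}"
            )


@dataclass
class GeneAlignment:
    """Gapped multi-strain alignment for one gene.

    ``rows`` preserves input order; ``start_col``/``stop_col`` are the
    alignment columns of the first base of the reference strain's annotated
    start and stop codons (``stop_col`` may be None before edge cleanup).
    """

    gene_id: str
    rows: list[tuple[str, str]]
    ref_strain: str
    start_col: int = 0
    stop_col: int | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError(f"{self.gene_id}: alignment has no rows")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValidationError(f"{self.gene_id}: ragged alignment rows {lengths}")
        if self.ref_strain not in {s for s, _ in self.rows}:
            raise ValidationError(
                f"{self.gene_id}: reference strain {self.ref_strain!r} not in alignment"
            )
        if self.stop_col is not None and not self.start_col < self.stop_col:
            raise ValidationError(
                f"{self.gene_id}: start_col {self.start_col} not before stop_col {self.stop_col}"
            )

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def strain_ids(self) -> list[str]:
        return [s for s, _ in self.rows]

    def row(self, strain_id: str) -> str:
        for s, seq in self.rows:
            if s == strain_id:
                return seq
        raise KeyError(strain_id)

    def ungapped(self, strain_id: str) -> str:
        return self.row(strain_id).replace(GAP, "")

    def col_of_ungapped(self, strain_id: str, pos: int) -> int:
        """Alignment column holding ungapped position ``pos`` of a strain."""
        seen = -1
        for col, ch in enumerate(self.row(strain_id)):
            if ch != GAP:
                seen += 1
                if seen == pos:
                    return col
        raise IndexError(f"{strain_id}: ungapped position {pos} beyond row")

    def ungapped_of_col(self, strain_id: str, col: int) -> int | None:
        """Ungapped position of a strain at alignment column, None on gap."""
        row = self.row(strain_id)
        if row[col] == GAP:
            return None
        return col - row[:col].count(GAP)


@dataclass(frozen=True)
class StopAllele:
    """A group of strains sharing one effective stop-codon position."""

    stop_col: int
    strains: frozenset[str]
    length_codons: int

    def __post_init__(self) -> None:
        if not self.strains:
            raise ValidationError("StopAllele with empty strain set")


@dataclass
class SCPRecord:
    """Allele partition of a gene's strains by effective stop position."""

    gene_id: str
    alleles: list[StopAllele]
    singleton_excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a in self.alleles:
            overlap = seen & a.strains
            if overlap:
                raise ValidationError(
                    f"{self.gene_id}: strains {sorted(overlap)} in more than one allele"
                )
            seen |= a.strains
        positions = [a.stop_col for a in self.alleles]
        if len(set(positions)) != len(positions):
            raise ValidationError(f"{self.gene_id}: duplicate allele stop positions")

    @property
    def is_scp(self) -> bool:
        return len(self.alleles) >= 2


@dataclass
class PolarizedEvent:
    """One inferred addition/subtraction event after outgroup polarization."""

    gene_id: str
    species: str
    polarity: str
    mutation_class: str | None
    added_aa: int
    new_aa: int
    n_nonsingleton_alleles: int
    outgroup_len_aa: int
    certainty: str = "certain"

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValidationError(f"bad polarity {self.polarity!r}")
        if self.mutation_class is not None and self.mutation_class not in MUTATION_CLASSES:
            raise ValidationError(f"bad mutation class {self.mutation_class!r}")
        if not 0 <= self.added_aa <= self.new_aa:
            raise ValidationError(
                f"{self.gene_id}: new_aa {self.new_aa} < added_aa {self.added_aa} (or negative)"
            )
        if self.mutation_class == "point" and self.new_aa != self.added_aa:
            raise ValidationError(f"{self.gene_id}: point event with new_aa != added_aa")
        if self.polarity == "addition" and self.added_aa < 1:
            raise ValidationError(f"{self.gene_id}: addition with added_aa < 1")


@dataclass
class CatalogRow:
    """One catalog entry, shaped like the published per-gene addition table."""

    systematic_name: str
    standard_name: str
    species: str
    outgroup_len_aa: int
    added_aa: int
    new_aa: int
    mutation_class: str
    n_alleles: int
    ribo_evidence: str = "none"
    total_evidence: str = "none"

    def __post_init__(self) -> None:
        if self.mutation_class not in MUTATION_CLASSES:
            raise ValidationError(
                f"{self.systematic_name}: bad mutation class {self.mutation_class!r}"
            )
        if not 0 <= self.added_aa <= self.new_aa:
            raise ValidationError(
                f"{self.systematic_name}: new_aa {self.new_aa} < added_aa {self.added_aa}"
            )
        if self.mutation_class == "point" and self.added_aa != self.new_aa:
            raise ValidationError(f"{self.systematic_name}: point row with added != new")
        for level in (self.ribo_evidence, self.total_evidence):
            if level not in EVIDENCE_LEVELS:
                raise ValidationError(
                    f"{self.systematic_name}: evidence {level!r} not in {EVIDENCE_LEVELS}"
                )
        if self.n_alleles < 2:
            raise ValidationError(f"{self.systematic_name}: n_alleles < 2")


def is_stop(codon: str) -> bool:
    """True for TAA/TAG/TGA; N-containing triplets never count as stops."""
    return codon in STOP_CODONS


def translate_to_stop(seq: str, start: int = 0) -> int | None:
    """Length in codons of the ORF read from ``start`` to the first stop.

    Returns the number of sense codons before the stop (the protein length,
    stop excluded), or None if no in-frame stop is reached.
    """
    for i in range(start, len(seq) - 2, 3):
        if is_stop(seq[i : i + 3]):
            return (i - start) // 3
    return None


def first_stop_pos(seq: str, start: int = 0) -> int | None:
    """Nucleotide offset of the first in-frame stop from ``start``, or None."""
    for i in range(start, len(seq) - 2, 3):
        if is_stop(seq[i : i + 3]):
            return i
    return None
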