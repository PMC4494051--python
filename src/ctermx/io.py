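"""Readers and writers for the pipeline's external formats.

Formats: FASTA for per-strain sequences (header dialect
``gene_id|strain_id|species|orf_start``), tab-separated files for the
catalog, footprint tracks and transcript boundaries, and newick for the
strain tree. All TSVs are UTF-8 with ``#`` comment lines permitted.
"""

from __future__ import annotations

import csv
import hashlib
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO

from .model import CatalogRow, StrainSequence, ValidationError

#: sha256 of the packaged addition-gene catalog; guards against accidental edits.
_TABLE1_SHA256 = "2e40a1d6cc24b6b8c9cfd1c9d28cfad8c721bd390de766255b240c7946a1720a"

CATALOG_COLUMNS = [
    "systematic_name",
    "standard_name",
    "species",
    "outgroup_len_aa",
    "added_aa",
    "new_aa",
    "mutation_class",
    "n_alleles",
    "ribo_evidence",
    "total_evidence",
]


@dataclass
class RecordError:
    """A per-record validation failure with its file location."""

    path: str
    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}:{self.line}: {self.message}"


@dataclass
class FastaReadResult:
    records: list[StrainSequence] = field(default_factory=list)
    errors: list[RecordError] = field(default_factory=list)


def read_strain_fasta(path: str | Path, gene_manifest: dict[str, str] | None = None) -> FastaReadResult:
    """Read per-strain sequences from FASTA.

    Headers follow the dialect ``gene_id|strain_id|species|orf_start``.
    ``gene_manifest`` maps species to its designated reference strain; records
    whose strain matches are flagged ``is_reference``. Malformed records are
    collected as :class:`RecordError` rather than aborting the whole file.
    """
    path = Path(path)
    result = FastaReadResult()
    # track header line numbers for error messages
    header_lines: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                header_lines.setdefault(line[1:].strip(), lineno)
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.description.strip()
        lineno = header_lines.get(header, 0)
        parts = header.split("|")
        if len(parts) != 4 or not all(p.strip() for p in parts):
            result.errors.append(
                RecordError(str(path), lineno, f"malformed header {header!r}: expected gene|strain|species|orf_start")
            )
            continue
        gene_id, strain_id, species, orf_start_s = (p.strip() for p in parts)
        try:
            orf_start = int(orf_start_s)
        except ValueError:
            result.errors.append(RecordError(str(path), lineno, f"orf_start {orf_start_s!r} is not an integer"))
            continue
        try:
            seqrec = StrainSequence(
                gene_id=gene_id,
                strain_id=strain_id,
                species=species,
                seq=str(record.seq),
                orf_start=orf_start,
                is_reference=bool(gene_manifest) and gene_manifest.get(species) == strain_id,
            )
        except ValidationError as exc:
            result.errors.append(RecordError(str(path), lineno, str(exc)))
            continue
        result.records.append(seqrec)
    return result


def write_strain_fasta(records: list[StrainSequence], path: str | Path) -> None:
    """Write sequences in the ``gene|strain|species|orf_start`` dialect."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.gene_id}|{r.strain_id}|{r.species}|{r.orf_start}\n")
            for i in range(0, len(r.seq), 70):
                fh.write(r.seq[i : i + 70] + "\n")


def _parse_catalog_rows(lines: list[str], source: str) -> list[CatalogRow]:
    rows: list[CatalogRow] = []
    content = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(content, delimiter="\t")
    if reader.fieldnames != CATALOG_COLUMNS:
        raise ValidationError(f"{source}: catalog header {reader.fieldnames} != {CATALOG_COLUMNS}")
    for rec in reader:
        rows.append(
            CatalogRow(
                systematic_name=rec["systematic_name"],
                standard_name=rec["standard_name"],
                species=rec["species"],
                outgroup_len_aa=int(rec["outgroup_len_aa"]),
                added_aa=int(rec["added_aa"]),
                new_aa=int(rec["new_aa"]),
                mutation_class=rec["mutation_class"],
                n_alleles=int(rec["n_alleles"]),
                ribo_evidence=rec["ribo_evidence"],
                total_evidence=rec["total_evidence"],
            )
        )
    return rows


def load_table1_fixture() -> list[CatalogRow]:
    """Load the packaged 55-gene addition catalog.

    The file's sha256 is checked against the recorded digest; a mismatch is a
    hard error because every downstream summary statistic depends on it.
    """
    data = importlib.resources.files("ctermx.data").joinpath("table1.tsv").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _TABLE1_SHA256:
        raise ValidationError(f"packaged catalog checksum mismatch: {digest} != {_TABLE1_SHA256}")
    rows = _parse_catalog_rows(data.decode().splitlines(), "table1.tsv")
    if len(rows) != 55:
        raise ValidationError(f"packaged catalog has {len(rows)} rows, expected 55")
    return rows


def read_catalog(path: str | Path) -> list[CatalogRow]:
    with open(path) as fh:
        return _parse_catalog_rows(fh.read().splitlines(), str(path))


def write_catalog(rows: list[CatalogRow], path: str | Path) -> None:
    """Write catalog rows as TSV; round-trips through :func:`read_catalog`.

    Rows are validated by construction (``CatalogRow.__post_init__``); an
    invalid row can therefore not reach this writer.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        r.systematic_name,
                        r.standard_name,
                        r.species,
                        r.outgroup_len_aa,
                        r.added_aa,
                        r.new_aa,
                        r.mutation_class,
                        r.n_alleles,
                        r.ribo_evidence,
                        r.total_evidence,
                    ]
                )
                + "\n"
            )


@dataclass
class StrainTree:
    """A strain tree with an unrooted interpretation for bipartition tests."""

    tree: dendropy.Tree
    unrooted: bool = True

    @property
    def leaf_labels(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def write_newick(self, path: str | Path) -> None:
        self.tree.write(path=str(path), schema="newick", suppress_rooting=True)


def _tree_from(source: str, **kwargs) -> StrainTree:
    try:
        tree = dendropy.Tree.get(
            schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True, **kwargs,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValidationError(f"{source}: invalid newick ({exc.__class__.__name__})") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {lb for lb in labels if labels.count(lb) > 1}
    if dupes:
        raise ValidationError(f"{source}: duplicate leaf labels {sorted(dupes)}")
    return StrainTree(tree=tree)


def read_newick(path: str | Path) -> StrainTree:
    """Parse a newick strain tree; duplicate leaf labels are rejected."""
    return _tree_from(str(path), path=str(path))


def parse_newick_string(text: str) -> StrainTree:
    return _tree_from("newick string", data=text)
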