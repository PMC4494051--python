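"""Seeded simulator of multi-strain ortholog families with planted events.

Each locus is an ancestral ORF (ATG ... single in-frame stop, no internal
in-frame stop) plus a 3'-UTR window guaranteed to contain an in-frame stop,
so a readthrough length is always finite. Strains of two species carry
neutral substitutions drawn so that they never create or destroy a stop
codon in any reading frame anywhere in the locus; the planted event is
therefore the only signal a downstream scanner can see, and every carrier
of an event realizes exactly the same derived protein.

Planted event kinds mirror the mutational classes of stop-codon
polymorphisms: point stop loss, frameshifting indels, premature-stop
subtractions, a fusion-style deletion into a downstream ORF, singleton
errors, independent double-singleton pairs, and poly-N contamination.
Realized added/new amino-acid counts are measured by brute-force
translation of the constructed sequences and recorded in a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_strain_fasta
from .model import StrainSequence, first_stop_pos, is_stop, translate_to_stop

EVENT_KINDS = (
    "point_stop_loss",
    "frameshift_indel",
    "premature_stop_subtraction",
    "fusion_deletion",
    "singleton_error",
    "double_singleton",
    "polyN_run",
    "none",
)


@dataclass
class EventSpec:
    kind: str
    carrier_strains: tuple[str, ...] = ()
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class GeneTruth:
    """Expected downstream outcome for one simulated gene."""

    gene_id: str
    kind: str
    carriers: tuple[str, ...]
    polarity: str  # addition | subtraction | none
    mutation_class: str | None
    added_aa: int
    new_aa: int
    nonsingleton: bool


@dataclass
class CohortTruth:
    seed: int
    genes: list[GeneTruth]

    @property
    def nonsingleton_events(self) -> list[GeneTruth]:
        return [g for g in self.genes if g.nonsingleton and g.kind != "none"]


@dataclass
class AncestralLocus:
    gene_id: str
    seq: str
    orf_codons: int  # codons including the stop
    utr_len: int
    downstream_start: int | None = None  # ATG of a downstream ORF, fusion loci only

    @property
    def stop_pos(self) -> int:
        return 3 * (self.orf_codons - 1)

    @property
    def protein_len(self) -> int:
        return self.orf_codons - 1


@dataclass
class CohortConfig:
    """Event mix and geometry of a simulated cohort.

    Geometry defaults mirror the real survey: two species with 38 and 35
    non-reference strains plus one reference each, and a 150-nt 3'-UTR
    window. ``sub_rate`` is the per-site neutral substitution probability
    per strain.
    """

    additions: int = 0
    subtractions: int = 0
    singletons: int = 0
    double_singletons: int = 0
    fusions: int = 0
    polyN: int = 0
    clean: int = 0
    focal_species: str = "scer"
    sister_species: str = "spar"
    n_focal: int = 38
    n_sister: int = 35
    orf_codons: int = 120
    utr_len: int = 150
    gc: float = 0.40
    sub_rate: float = 0.002

    @property
    def n_genes(self) -> int:
        return (self.additions + self.subtractions + self.singletons
                + self.double_singletons + self.fusions + self.polyN + self.clean)

    @property
    def reference_strains(self) -> dict[str, str]:
        return {self.focal_species: f"{self.focal_species}_ref",
                self.sister_species: f"{self.sister_species}_ref"}


BASES = "ACGT"


def _random_bases(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def _random_sense_codon(rng, gc: float) -> str:
    while True:
        c = _random_bases(rng, 3, gc)
        if not is_stop(c):
            return c


def _make_ancestral(gene_id: str, orf_codons: int, utr_len: int, gc: float, rng,
                    downstream_codons: int = 0) -> AncestralLocus:
    if orf_codons < 10:
        raise ValueError("orf_codons must be >= 10")
    if utr_len < 9:
        raise ValueError("utr_len too short to hold an in-frame stop")
    if gc >= 0.999:
        raise ValueError("gc ~ 1.0 leaves no A/T to build stop codons")
    codons = ["ATG"] + [_random_sense_codon(rng, gc) for _ in range(orf_codons - 2)]
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    orf = "".join(codons) + stop
    utr = _random_bases(rng, utr_len, gc)
    # guarantee an in-frame stop within the UTR window (finite readthrough)
    if first_stop_pos(orf + utr, len(orf)) is None or first_stop_pos(orf + utr, len(orf)) >= len(orf) + utr_len - 2:
        slots = [i for i in range(0, utr_len - 2, 3)]
        at = slots[rng.integers(len(slots))]
        utr = utr[:at] + "TAA" + utr[at + 3:]
    seq = orf + utr
    downstream_start = None
    if downstream_codons:
        downstream_start = len(seq)
        dorf = "ATG" + "".join(_random_sense_codon(rng, gc) for _ in range(downstream_codons - 2)) + "TAA"
        seq = seq + dorf + _random_bases(rng, 30, gc)
    return AncestralLocus(gene_id, seq, orf_codons, utr_len, downstream_start)


def _stop_profile_ok(seq: str, pos: int, new_base: str) -> bool:
    """True when substituting ``new_base`` at ``pos`` leaves the stop-codon
    status of every overlapping triplet (all three frames) unchanged."""
    for start in (pos - 2, pos - 1, pos):
        if start < 0 or start + 3 > len(seq):
            continue
        old = seq[start : start + 3]
        new = old[: pos - start] + new_base + old[pos - start + 1 :]
        if is_stop(old) != is_stop(new):
            return False
    return True


def _mutate_neutral(seq: str, rng, rate: float, protected: set[int]) -> str:
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for pos in hits:
        pos = int(pos)
        if pos in protected or chars[pos] == "N":
            continue
        choices = [b for b in BASES if b != chars[pos]]
        b = choices[rng.integers(3)]
        if _stop_profile_ok("".join(chars), pos, b):
            chars[pos] = b
    return "".join(chars)


def simulate_locus(
    n_strains_per_species: dict[str, int],
    orf_codons: int,
    utr_len: int = 150,
    gc: float = 0.40,
    seed: int | np.random.Generator = 0,
    sub_rate: float = 0.002,
    gene_id: str = "g1",
    protected: set[int] | None = None,
    downstream_codons: int = 0,
    ancestral: AncestralLocus | None = None,
) -> tuple[list[StrainSequence], AncestralLocus]:
    """Simulate one ortholog family across species.

    Each species gets a ``<species>_ref`` reference strain plus numbered
    strains; all descend from the same ancestral locus with independent
    stop-structure-preserving neutral substitutions. ``protected`` positions
    receive no substitutions (used to keep planted events unambiguous).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if ancestral is None:
        ancestral = _make_ancestral(gene_id, orf_codons, utr_len, gc, rng, downstream_codons)
    protected = protected or set()
    strains: list[StrainSequence] = []
    for species, n in n_strains_per_species.items():
        names = [f"{species}_ref"] + [f"{species}_s{i:02d}" for i in range(1, n)]
        for name in names:
            seq = _mutate_neutral(ancestral.seq, rng, sub_rate, protected)
            strains.append(
                StrainSequence(gene_id, name, species, seq, orf_start=0,
                               is_reference=name.endswith("_ref"))
            )
    return strains, ancestral


# ---------------------------------------------------------------------------
# Event planting


class EventInfeasible(ValueError):
    pass


def _codon_boundaries(ancestral: AncestralLocus, margin_codons: int = 2):
    lo = 3 * margin_codons
    hi = ancestral.stop_pos - 3
    return range(lo, hi + 1, 3)


def _unambiguous_del(seq: str, p: int) -> bool:
    return 0 < p < len(seq) - 1 and seq[p] != seq[p - 1] and seq[p] != seq[p + 1]


def _unambiguous_ins(seq: str, p: int, base: str) -> bool:
    return 0 < p < len(seq) and base != seq[p - 1] and base != seq[p]


def _apply_to_carriers(strains, carriers, edit) -> None:
    for s in strains:
        if s.strain_id in carriers:
            s.seq = edit(s.seq)


def _plant_point(strains, ancestral, carriers, rng) -> tuple[int, int]:
    stop = ancestral.stop_pos
    codon = ancestral.seq[stop : stop + 3]
    options = []
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            mutated = codon[:i] + b + codon[i + 1 :]
            if not is_stop(mutated):
                options.append((i, b))
    i, b = options[rng.integers(len(options))]
    _apply_to_carriers(strains, carriers, lambda s: s[: stop + i] + b + s[stop + i + 1 :])
    la = ancestral.protein_len
    lengths = {translate_to_stop(s.seq, 0) for s in strains if s.strain_id in carriers}
    ld = lengths.pop()
    assert not lengths and ld is not None and ld > la
    return ld - la, ld - la  # added == new for point events


def _plant_frameshift(strains, ancestral, carriers, rng, want_addition=True,
                      max_tries: int = 500) -> tuple[int, int, dict]:
    la = ancestral.protein_len
    boundaries = list(_codon_boundaries(ancestral))
    for _ in range(max_tries):
        p = boundaries[rng.integers(len(boundaries))]
        if rng.random() < 0.5:
            if not _unambiguous_del(ancestral.seq, p):
                continue
            edit = lambda s, p=p: s[:p] + s[p + 1 :]
        else:
            b = BASES[rng.integers(4)]
            if not _unambiguous_ins(ancestral.seq, p, b):
                continue
            edit = lambda s, p=p, b=b: s[:p] + b + s[p:]
        derived = edit(ancestral.seq)
        ld = translate_to_stop(derived, 0)
        if ld is None:
            continue
        if want_addition and ld <= la:
            continue
        k = p // 3
        _apply_to_carriers(strains, carriers, edit)
        lengths = {translate_to_stop(s.seq, 0) for s in strains if s.strain_id in carriers}
        assert lengths == {ld}
        return ld - la, ld - k, {"pos": p}
    raise EventInfeasible(f"{ancestral.gene_id}: no feasible frameshift position found")


def _plant_subtraction(strains, ancestral, carriers, rng) -> int:
    la = ancestral.protein_len
    k = int(rng.integers(5, la - 2))
    c = 3 * k
    _apply_to_carriers(strains, carriers, lambda s: s[:c] + "TAA" + s[c + 3 :])
    return k


def _plant_fusion(strains, ancestral, carriers, rng, trim_codons: int = 9) -> tuple[int, int]:
    if ancestral.downstream_start is None:
        raise EventInfeasible(f"{ancestral.gene_id}: fusion needs a downstream ORF")
    del_start = ancestral.stop_pos - 3 * trim_codons
    del_end = ancestral.downstream_start
    edit = lambda s: s[:del_start] + s[del_end:]
    derived = edit(ancestral.seq)
    ld = translate_to_stop(derived, 0)
    la = ancestral.protein_len
    if ld is None or ld <= la:
        raise EventInfeasible(f"{ancestral.gene_id}: fusion deletion does not extend the protein")
    _apply_to_carriers(strains, carriers, edit)
    return ld - la, ld - del_start // 3


def _plant_double_singleton(strains, ancestral, carriers, rng, max_tries: int = 500):
    """Two independent 1-nt insertions in different strains, same stop."""
    s1, s2 = carriers
    boundaries = list(_codon_boundaries(ancestral))
    la = ancestral.protein_len
    for _ in range(max_tries):
        p1 = boundaries[rng.integers(len(boundaries) - 4)]
        b1 = BASES[rng.integers(4)]
        if not _unambiguous_ins(ancestral.seq, p1, b1):
            continue
        d1 = ancestral.seq[:p1] + b1 + ancestral.seq[p1:]
        l1 = translate_to_stop(d1, 0)
        if l1 is None or l1 <= la:
            continue
        stop1 = first_stop_pos(d1, 0) - 1  # ancestral coordinate of derived stop
        for p2 in range(p1 + 3, min(p1 + 30, boundaries[-1] + 1), 3):
            b2 = BASES[int(rng.integers(4))]
            if not _unambiguous_ins(ancestral.seq, p2, b2):
                continue
            d2 = ancestral.seq[:p2] + b2 + ancestral.seq[p2:]
            l2 = translate_to_stop(d2, 0)
            if l2 != l1:
                continue
            if first_stop_pos(d2, 0) - 1 != stop1:
                continue
            _apply_to_carriers(strains, [s1], lambda s: s[:p1] + b1 + s[p1:])
            _apply_to_carriers(strains, [s2], lambda s: s[:p2] + b2 + s[p2:])
            return {"positions": (p1, p2), "bases": (b1, b2)}
    raise EventInfeasible(f"{ancestral.gene_id}: no double-singleton construction found")


def _plant_polyN(strains, ancestral, carriers, rng) -> dict:
    n = int(rng.integers(2, 6))
    lo = 6
    hi = ancestral.stop_pos - n - 3
    p = int(rng.integers(lo, hi))
    _apply_to_carriers(strains, carriers, lambda s: s[:p] + "N" * n + s[p + n :])
    return {"pos": p, "len": n}


def plant_event(strains: list[StrainSequence], ancestral: AncestralLocus,
                spec: EventSpec, rng) -> GeneTruth:
    """Apply an event to its carrier strains; return the realized truth.

    Added/new counts are measured from the constructed sequences by direct
    translation, so the truth table reflects what was actually planted.
    """
    carriers = tuple(spec.carrier_strains)
    known = {s.strain_id for s in strains}
    if not set(carriers) <= known:
        raise ValueError(f"carriers {carriers} not all in cohort")
    g = ancestral.gene_id
    kind = spec.kind
    if kind == "none":
        return GeneTruth(g, kind, (), "none", None, 0, 0, False)
    if kind == "point_stop_loss":
        added, new = _plant_point(strains, ancestral, carriers, rng)
        return GeneTruth(g, kind, carriers, "addition", "point", added, new, len(carriers) >= 2)
    if kind == "frameshift_indel":
        added, new, _ = _plant_frameshift(strains, ancestral, carriers, rng)
        return GeneTruth(g, kind, carriers, "addition", "frameshift", added, new, len(carriers) >= 2)
    if kind == "premature_stop_subtraction":
        _plant_subtraction(strains, ancestral, carriers, rng)
        return GeneTruth(g, kind, carriers, "subtraction", None, 0, 0, len(carriers) >= 2)
    if kind == "fusion_deletion":
        added, new = _plant_fusion(strains, ancestral, carriers, rng)
        return GeneTruth(g, kind, carriers, "addition", "deletion_fusion", added, new, len(carriers) >= 2)
    if kind == "singleton_error":
        if len(carriers) != 1:
            raise ValueError("singleton_error must have exactly one carrier")
        if rng.random() < 0.5:
            _plant_point(strains, ancestral, carriers, rng)
        else:
            _plant_frameshift(strains, ancestral, carriers, rng, want_addition=False)
        return GeneTruth(g, kind, carriers, "none", None, 0, 0, False)
    if kind == "double_singleton":
        if len(carriers) != 2:
            raise ValueError("double_singleton needs exactly two carriers")
        _plant_double_singleton(strains, ancestral, carriers, rng)
        return GeneTruth(g, kind, carriers, "none", None, 0, 0, False)
    if kind == "polyN_run":
        _plant_polyN(strains, ancestral, carriers, rng)
        return GeneTruth(g, kind, carriers, "none", None, 0, 0, False)
    raise ValueError(kind)


# ---------------------------------------------------------------------------
# Cohorts


def _event_protection(spec_kind: str, ancestral: AncestralLocus) -> set[int]:
    """Positions shielded from neutral substitution so that the planted
    mutation stays the unambiguous, allele-defining difference."""
    protect: set[int] = set()
    stop = ancestral.stop_pos
    protect.update(range(stop - 1, stop + 4))
    if spec_kind in ("frameshift_indel", "singleton_error", "double_singleton", "fusion_deletion"):
        # indel positions are chosen later; shield the whole ORF interior so
        # local repeat structure at the chosen boundary cannot change
        protect.update(range(0, len(ancestral.seq)))
    return protect


def simulate_cohort(config: CohortConfig, seed: int) -> tuple[dict[str, list[StrainSequence]], CohortTruth]:
    """Simulate a full cohort; deterministic given (config, seed)."""
    _DOWNSTREAM_STARTS.clear()
    master = np.random.default_rng(seed)
    kinds = (
        ["point_stop_loss", "frameshift_indel"] * (config.additions // 2 + 1)
    )[: config.additions]
    kinds += ["premature_stop_subtraction"] * config.subtractions
    kinds += ["singleton_error"] * config.singletons
    kinds += ["double_singleton"] * config.double_singletons
    kinds += ["fusion_deletion"] * config.fusions
    kinds += ["polyN_run"] * config.polyN
    kinds += ["none"] * config.clean
    kinds = list(np.array(kinds)[master.permutation(len(kinds))])
    families: dict[str, list[StrainSequence]] = {}
    truths: list[GeneTruth] = []
    n_per_species = {config.focal_species: config.n_focal, config.sister_species: config.n_sister}
    focal_pool = [f"{config.focal_species}_s{i:02d}" for i in range(1, config.n_focal)]
    for idx, kind in enumerate(kinds):
        gene_id = f"g{idx:04d}"
        for attempt in range(10):
            rng = np.random.default_rng([seed, idx, attempt])
            downstream = 60 if kind == "fusion_deletion" else 0
            ancestral = _make_ancestral(gene_id, config.orf_codons, config.utr_len,
                                        config.gc, rng, downstream_codons=downstream)
            protect = _event_protection(kind, ancestral) if kind != "none" else set()
            strains, _ = simulate_locus(
                n_per_species, config.orf_codons, config.utr_len, config.gc, rng,
                sub_rate=config.sub_rate, gene_id=gene_id, protected=protect,
                ancestral=ancestral,
            )
            if kind in ("singleton_error",):
                n_carriers = 1
            elif kind == "double_singleton":
                n_carriers = 2
            elif kind == "none":
                n_carriers = 0
            else:
                n_carriers = int(rng.integers(2, 5))
            carriers = tuple(sorted(
                np.array(focal_pool)[rng.choice(len(focal_pool), size=n_carriers, replace=False)]
            )) if n_carriers else ()
            try:
                truth = plant_event(strains, ancestral, EventSpec(kind, carriers), rng)
            except EventInfeasible:
                continue
            families[gene_id] = strains
            truths.append(truth)
            if kind == "fusion_deletion":
                _DOWNSTREAM_STARTS[gene_id] = ancestral.downstream_start
            break
        else:
            raise EventInfeasible(f"{gene_id}: could not realize event kind {kind!r}")
    return families, CohortTruth(seed=seed, genes=truths)


#: downstream ORF annotations for fusion loci of the most recent cohort
_DOWNSTREAM_STARTS: dict[str, int] = {}


def downstream_annotations() -> dict[str, int]:
    return dict(_DOWNSTREAM_STARTS)


def write_cohort(families: dict[str, list[StrainSequence]], truth: CohortTruth,
                 outdir: str | Path, config: CohortConfig | None = None) -> None:
    """Write per-gene FASTA plus the truth table TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for gene_id, strains in sorted(families.items()):
        write_strain_fasta(strains, outdir / f"{gene_id}.fasta")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write(f"# seed={truth.seed}\n")
        fh.write("gene_id\tkind\tcarriers\tpolarity\tmutation_class\tadded_aa\tnew_aa\tnonsingleton\n")
        for t in truth.genes:
            fh.write(
                f"{t.gene_id}\t{t.kind}\t{','.join(t.carriers)}\t{t.polarity}\t"
                f"{t.mutation_class or ''}\t{t.added_aa}\t{t.new_aa}\t{int(t.nonsingleton)}\n"
            )
    if _DOWNSTREAM_STARTS:
        with open(outdir / "downstream.tsv", "w") as fh:
            fh.write("gene_id\tdownstream_start\n")
            for g, pos in sorted(_DOWNSTREAM_STARTS.items()):
                if g in families:
                    fh.write(f"{g}\t{pos}\n")
    if config is not None:
        with open(outdir / "cohort.cfg", "w") as fh:
            for k, v in config.__dict__.items():
                fh.write(f"{k}: {v}\n")


def read_truth(path: str | Path) -> CohortTruth:
    seed = 0
    genes: list[GeneTruth] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# seed="):
                seed = int(line.split("=", 1)[1])
                continue
            if line.startswith("gene_id") or not line.strip():
                continue
            g, kind, carriers, pol, cls, added, new, nonsing = line.split("\t")
            genes.append(GeneTruth(g, kind, tuple(carriers.split(",")) if carriers else (),
                                   pol, cls or None, int(added), int(new), bool(int(nonsing))))
    return CohortTruth(seed=seed, genes=genes)


# ---------------------------------------------------------------------------
# Catalog-shaped pair synthesis (classifier round-trip)


def pair_from_catalog_row(outgroup_len_aa: int, added_aa: int, new_aa: int,
                          mutation_class: str, rng) -> tuple[str, str, int | None]:
    """Construct an (ancestral, derived) sequence pair realizing a catalog row.

    The ancestral ORF has ``outgroup_len_aa`` sense codons plus a stop; the
    derived allele realizes exactly (added, new) under the stated mutation
    class. Construction is exact, not sampled: outside the mutation the
    sequence is drawn from {A, C, G} (no stop codon can occur in any frame
    without a T), and the required in-frame and shifted-frame stops are
    placed at positions computed from the lengths. Returns
    (ancestral, derived, downstream_start) where downstream_start is the
    in-frame fusion ORF start for deletion rows, else None.
    """
    la = outgroup_len_aa
    if not 1 <= added_aa <= new_aa or new_aa > la + added_aa:
        raise ValueError("inconsistent (outgroup_len, added, new)")
    ld = la + added_aa

    def fill(n: int) -> str:
        return "".join("ACG"[i] for i in rng.integers(0, 3, size=n))

    if mutation_class == "point":
        if new_aa != added_aa:
            raise ValueError("point rows must have added == new")
        # the substituted stop becomes a sense codon and contributes one
        # residue, so added-1 sense codons precede the next in-frame stop
        body = "ATG" + fill(3 * (la - 1))
        utr_codons = fill(3 * (added_aa - 1))
        ancestral = body + "TAA" + utr_codons + "TAA" + fill(12)
        derived = body + "CAA" + utr_codons + "TAA" + fill(12)
        return ancestral, derived, None

    if mutation_class == "frameshift":
        # 1-nt deletion at codon boundary k shifts the frame; the derived
        # allele then reads S[3j+1 : 3j+4] as codon j for j >= k.
        k = la + added_aa - new_aa
        if not 1 <= k <= la:
            raise ValueError("frameshift row with infeasible new_aa")
        total = 3 * ld + 10
        body = list("ATG" + fill(total - 3))
        body[3 * la : 3 * la + 3] = "TAA"      # ancestral in-frame stop
        body[3 * ld + 1 : 3 * ld + 4] = "TAA"  # derived-frame stop after the deletion
        if k < la:
            # pin the deleted base's neighbourhood so gap placement is unique
            body[3 * k] = "A"
            body[3 * k + 1] = "G"
            if 3 * k - 1 > 2:
                body[3 * k - 1] = "C"
        ancestral = "".join(body)
        derived = ancestral[: 3 * k] + ancestral[3 * k + 1 :]
        return ancestral, derived, None

    if mutation_class == "deletion_fusion":
        # deletion from codon k through the whole 3' flank into a downstream
        # ORF that begins in frame with the truncated coding sequence
        k = la + added_aa - new_aa
        if not 0 <= k <= la:
            raise ValueError("deletion row with infeasible new_aa")
        body = "ATG" + fill(3 * (la - 1)) + "TAA"
        utr = fill(45) + "TAA" + fill(45)  # flank with its own in-frame stop
        downstream_codons = ld - k
        dorf = "ATG" + fill(3 * (downstream_codons - 1)) + "TAA"
        ancestral = body + utr + dorf + fill(9)
        downstream_start = len(body) + len(utr)
        derived = ancestral[: 3 * k] + ancestral[downstream_start:]
        return ancestral, derived, downstream_start

    raise ValueError(f"unknown mutation class {mutation_class!r}")
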