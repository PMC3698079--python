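"""Codon-level alignment model and FASTA / domain-table IO.

The central container is :class:`CodonAlignment`: an in-frame, gap-aware
alignment of coding sequences whose columns are whole codons, carrying
named domain annotations (e.g. the DUF3594 and PHD-finger regions of a
two-domain transcription-factor family).  All downstream stages — domain
trees, co-evolution, selection tests, codon-usage statistics and the
conversion scan — consume this container.

Coordinates in files are 1-based inclusive codon columns (the convention
of biologists' domain tables) and converted to 0-based half-open slices
exactly once, here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codata import CODON_TO_AA, GAP, STOP_CODONS
from .errors import (
    AlignmentError,
    AnnotationError,
    FrameError,
    LookupError_,
    ValidationError,
)

_VALID_CHARS = frozenset("ACGTN" + GAP)


@dataclass(frozen=True)
class CodingSequence:
    """An aligned coding sequence: codon-unit gaps, no internal stop codons."""

    id: str
    cds: str
    species: str = ""

    def __post_init__(self):
        cds = self.cds.upper().replace("U", "T")
        object.__setattr__(self, "cds", cds)
        if len(cds) % 3 != 0:
            raise FrameError(f"{self.id}: length {len(cds)} is not a multiple of 3")
        bad = set(cds) - _VALID_CHARS
        if bad:
            raise ValidationError(f"{self.id}: invalid characters {sorted(bad)}")
        codons = self.codons()
        last_nongap = max(
            (k for k, c in enumerate(codons) if c != GAP * 3), default=-1
        )
        for k, codon in enumerate(codons):
            if GAP in codon and codon != GAP * 3:
                raise FrameError(
                    f"{self.id}: gap run not aligned to codon boundary at codon {k + 1}"
                )
            if codon in STOP_CODONS and k < last_nongap:
                raise ValidationError(f"{self.id}: internal stop codon {codon} at codon {k + 1}")

    def codons(self) -> list[str]:
        return [self.cds[i: i + 3] for i in range(0, len(self.cds), 3)]

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def ungapped(self) -> str:
        return "".join(c for c in self.codons() if c != GAP * 3)


@dataclass(frozen=True)
class DomainAnnotation:
    """A named codon-column interval, 1-based inclusive."""

    name: str
    start_codon: int
    end_codon: int

    def __post_init__(self):
        if self.start_codon < 1:
            raise AnnotationError(f"domain {self.name}: start_codon must be >= 1")
        if self.start_codon > self.end_codon:
            raise AnnotationError(
                f"domain {self.name}: start {self.start_codon} > end {self.end_codon}"
            )

    @property
    def n_codons(self) -> int:
        return self.end_codon - self.start_codon + 1


@dataclass(frozen=True)
class CodonAlignment:
    """Equal-length aligned coding sequences with domain annotations."""

    rows: tuple[CodingSequence, ...]
    domains: tuple[DomainAnnotation, ...] = field(default_factory=tuple)

    def __post_init__(self):
        rows = tuple(self.rows)
        domains = tuple(self.domains)
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "domains", domains)
        if not rows:
            raise AlignmentError("alignment has no rows")
        lengths = {len(r.cds) for r in rows}
        if len(lengths) != 1:
            raise AlignmentError(f"rows differ in aligned length: {sorted(lengths)}")
        ids = [r.id for r in rows]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate sequence ids in alignment")
        n = self.n_codon_columns
        for d in domains:
            if d.end_codon > n:
                raise AnnotationError(
                    f"domain {d.name} [{d.start_codon},{d.end_codon}] exceeds {n} codon columns"
                )
        for a, b in zip(sorted(domains, key=lambda d: d.start_codon)[:-1],
                        sorted(domains, key=lambda d: d.start_codon)[1:]):
            if b.start_codon <= a.end_codon:
                raise AnnotationError(f"domains {a.name} and {b.name} overlap")

    @property
    def n_codon_columns(self) -> int:
        return self.rows[0].n_codons

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, seq_id: str) -> CodingSequence:
        for r in self.rows:
            if r.id == seq_id:
                return r
        raise LookupError_(f"no sequence named {seq_id!r}")

    def domain(self, name: str) -> DomainAnnotation:
        for d in self.domains:
            if d.name == name:
                return d
        raise LookupError_(f"no domain named {name!r}; have {[d.name for d in self.domains]}")


def translate(cds: str) -> str:
    """Translate an in-frame CDS under the standard genetic code.

    Codon-unit gaps map to ``-``; codons containing N map to ``X``; a
    terminal stop maps to ``*``; an internal stop raises
    :class:`~famevol.errors.ValidationError` (via CodingSequence validation
    when called on raw strings, or directly here).
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise FrameError(f"length {len(cds)} is not a multiple of 3")
    out = []
    n = len(cds) // 3
    codons = [cds[3 * k: 3 * k + 3] for k in range(n)]
    last_nongap = max((k for k, c in enumerate(codons) if c != GAP * 3), default=-1)
    for k, codon in enumerate(codons):
        if codon == GAP * 3:
            out.append(GAP)
        elif GAP in codon:
            raise FrameError(f"gap run not aligned to codon boundary at codon {k + 1}")
        elif codon in STOP_CODONS:
            if k < last_nongap:
                raise ValidationError(f"internal stop codon {codon} at codon {k + 1}")
            out.append("*")
        elif codon in CODON_TO_AA:
            out.append(CODON_TO_AA[codon])
        else:
            out.append("X")
    return "".join(out)


def translate_alignment(aln: CodonAlignment) -> list[tuple[str, str]]:
    """Translate every row; returns (id, protein) pairs in row order."""
    return [(r.id, translate(r.cds)) for r in aln.rows]


def slice_domain(aln: CodonAlignment, name: str) -> CodonAlignment:
    """Sub-alignment of exactly one annotated domain's codon columns."""
    d = aln.domain(name)
    lo, hi = 3 * (d.start_codon - 1), 3 * d.end_codon
    rows = tuple(replace(r, cds=r.cds[lo:hi]) for r in aln.rows)
    return CodonAlignment(rows=rows, domains=(DomainAnnotation(name, 1, d.n_codons),))


def _species_from_id(seq_id: str) -> str:
    return seq_id.split("_", 1)[0] if "_" in seq_id else ""


def read_domain_table(path: str | Path) -> tuple[DomainAnnotation, ...]:
    """Read a domain table: whitespace/tab-separated ``[set] name start end`` rows.

    A header line (non-numeric start column) is skipped; a leading gene-set
    column is tolerated and ignored.
    """
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise AnnotationError(f"domain table row has fewer than 3 fields: {line!r}")
        name, start, end = fields[-3], fields[-2], fields[-1]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            if not out:  # header
                continue
            raise AnnotationError(f"non-integer codon coordinates in row: {line!r}")
        out.append(DomainAnnotation(name=name, start_codon=start_i, end_codon=end_i))
    return tuple(out)


def write_domain_table(domains, path: str | Path) -> None:
    lines = ["domain\tstart_codon\tend_codon"]
    lines += [f"{d.name}\t{d.start_codon}\t{d.end_codon}" for d in domains]
    Path(path).write_text("\n".join(lines) + "\n")


def read_alignment(path: str | Path, domain_table: str | Path | None = None) -> CodonAlignment:
    """Read an aligned in-frame CDS FASTA (optionally with a domain table).

    A final codon column consisting solely of stop codons and gaps is
    stripped (codon models operate on the 61 sense codons).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentError(f"{path}: sequences have unequal lengths {sorted(lengths)}")
    (length,) = lengths
    if length % 3 != 0:
        raise FrameError(f"{path}: aligned length {length} is not a multiple of 3")
    seqs = [str(r.seq).upper().replace("U", "T") for r in records]
    last = [s[-3:] for s in seqs]
    if all(c in STOP_CODONS or c == GAP * 3 for c in last) and any(c in STOP_CODONS for c in last):
        seqs = [s[:-3] for s in seqs]
    rows = tuple(
        CodingSequence(id=r.id, cds=s, species=_species_from_id(r.id))
        for r, s in zip(records, seqs)
    )
    domains = read_domain_table(domain_table) if domain_table is not None else ()
    return CodonAlignment(rows=rows, domains=domains)


def write_alignment(aln: CodonAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(r.cds), id=r.id, description="") for r in aln.rows]
    SeqIO.write(records, str(path), "fasta")


def read_protein_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA as (id, sequence) pairs."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return [(r.id, str(r.seq).upper()) for r in records]


def write_protein_fasta(pairs, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in pairs]
    SeqIO.write(records, str(path), "fasta")
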