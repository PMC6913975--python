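"""Codon counting under a declared genetic code.

Reads CDS FASTA files, validates reading frames, tallies frame-0 codons
and aggregates per-genome tables.  All downstream metrics consume the
:class:`CodonCountTable` produced here.

Conventions: lower-case and RNA (U) input are normalised to upper-case DNA;
the terminal stop codon is trimmed before counting so every metric shares one
denominator; codon indices are 1-based (codon *i* covers nucleotides
``3i-2..3i``).  Alternative start codons (GTG, TTG) are counted as their
literal triplet, not recoded to ATG.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

#: the 64 codons in lexicographic (A<C<G<T) order
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
)

LIFESTYLES = ("P", "NP", "unknown")
GRAM_CLASSES = ("positive", "negative", "variable", "unknown")


class FrameError(ValueError):
    """CDS length is not a whole number of codons."""


class DuplicateIdError(ValueError):
    """Two FASTA records share a sequence id."""


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code with synonymous-family and degeneracy-class structure.

    Parameters
    ----------
    table_id
        NCBI translation table number (11 = bacterial/archaeal/plastid).
    codon_to_aa
        Mapping of all 64 codons to one-letter amino acids, with ``*`` for
        stop codons.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    families: Mapping[str, tuple[str, ...]] = field(init=False)
    degeneracy_classes: Mapping[int, tuple[str, ...]] = field(init=False)
    sense_codons: tuple[str, ...] = field(init=False)
    stop_codons: tuple[str, ...] = field(init=False)
    start_codons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            aa = self.codon_to_aa[codon]
            if aa == "*":
                continue
            fams.setdefault(aa, []).append(codon)
        families = {aa: tuple(sorted(cs)) for aa, cs in fams.items()}
        classes: dict[int, list[str]] = {}
        for aa, cs in families.items():
            classes.setdefault(len(cs), []).append(aa)
        object.__setattr__(self, "families", families)
        object.__setattr__(
            self,
            "degeneracy_classes",
            {k: tuple(sorted(v)) for k, v in classes.items()},
        )
        object.__setattr__(
            self,
            "sense_codons",
            tuple(c for c in ALL_CODONS if self.codon_to_aa[c] != "*"),
        )
        object.__setattr__(
            self,
            "stop_codons",
            tuple(c for c in ALL_CODONS if self.codon_to_aa[c] == "*"),
        )

    @classmethod
    def from_ncbi_table(cls, table_id: int = 11) -> "GeneticCode":
        """Build from Biopython's NCBI codon tables (default: table 11)."""
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(tbl.forward_table)
        for stop in tbl.stop_codons:
            mapping[stop] = "*"
        return cls(
            table_id=table_id,
            codon_to_aa=mapping,
            start_codons=tuple(tbl.start_codons),
        )

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]


#: module-level default: the bacterial code
BACTERIAL_CODE = GeneticCode.from_ncbi_table(11)


def normalize_nucleotides(seq: str) -> str:
    """Upper-case and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


@dataclass
class CodingSequence:
    """One CDS with optional species metadata.

    ``lifestyle`` is P (pathogenic) / NP (non-pathogenic) / unknown;
    ``gram`` is positive / negative / variable / unknown.
    """

    seq_id: str
    nucleotides: str
    species: str = ""
    lifestyle: str = "unknown"
    gram: str = "unknown"

    def __post_init__(self) -> None:
        self.nucleotides = normalize_nucleotides(self.nucleotides)
        bad = set(self.nucleotides) - set("ACGTN")
        if bad:
            raise ValueError(
                f"{self.seq_id}: illegal nucleotide symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass
class CodonCountTable:
    """Per-sequence counts over the 64 codons.

    ``n_codons`` is the total number of sense codons counted; codons
    containing N are excluded from ``counts`` and tallied in ``skipped``.
    """

    seq_id: str
    counts: dict[str, int]
    n_codons: int = 0
    skipped: int = 0
    internal_stops: int = 0
    species: str = ""
    lifestyle: str = "unknown"
    gram: str = "unknown"

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        for codon, n in self.counts.items():
            if codon not in full:
                raise ValueError(f"{self.seq_id}: unknown codon {codon!r}")
            if n < 0:
                raise ValueError(f"{self.seq_id}: negative count for {codon}")
            full[codon] = int(n)
        self.counts = full
        if self.n_codons == 0:
            self.n_codons = sum(
                full[c] for c in ALL_CODONS if BACTERIAL_CODE.codon_to_aa[c] != "*"
            )

    def __getitem__(self, codon: str) -> int:
        return self.counts[codon]

    def family_counts(self, amino_acid: str, code: GeneticCode) -> dict[str, int]:
        return {c: self.counts[c] for c in code.families[amino_acid]}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"seq_id": self.seq_id, "codon": list(ALL_CODONS),
             "count": [self.counts[c] for c in ALL_CODONS]}
        )


def read_cds_fasta(
    path: str | Path,
    metadata: pd.DataFrame | None = None,
) -> list[CodingSequence]:
    """Read a CDS FASTA, joining per-species metadata when provided.

    ``metadata`` is keyed by ``seq_id`` or ``species`` and may carry
    ``lifestyle`` and ``gram`` columns; missing fields default to "unknown".
    Duplicate record ids raise :class:`DuplicateIdError`.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        logger.warning("no FASTA records found in %s", path)
        return []
    seen: set[str] = set()
    meta_by_key: dict[str, dict] = {}
    if metadata is not None:
        key = "seq_id" if "seq_id" in metadata.columns else "species"
        meta_by_key = {
            str(row[key]): row.to_dict() for _, row in metadata.iterrows()
        }
    out: list[CodingSequence] = []
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        row = meta_by_key.get(rec.id, {})
        out.append(
            CodingSequence(
                seq_id=rec.id,
                nucleotides=str(rec.seq),
                species=str(row.get("species", rec.id)),
                lifestyle=str(row.get("lifestyle", "unknown")),
                gram=str(row.get("gram", "unknown")),
            )
        )
    return out


def count_codons(
    seq: CodingSequence,
    code: GeneticCode = BACTERIAL_CODE,
    trim_terminal_stop: bool = True,
) -> CodonCountTable:
    """Tally frame-0 non-overlapping codons of one CDS.

    The terminal stop is removed before counting (when present and
    ``trim_terminal_stop`` is set).  Internal stop codons are counted but
    reported in a warning; codons containing N are skipped and tallied in
    ``skipped``.
    """
    nt = seq.nucleotides
    if len(nt) % 3 != 0:
        raise FrameError(
            f"{seq.seq_id}: length {len(nt)} is not divisible by 3"
        )
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    if trim_terminal_stop and codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]
    counts: dict[str, int] = {}
    skipped = 0
    internal_stops = 0
    n_sense = 0
    for codon in codons:
        if "N" in codon:
            skipped += 1
            continue
        counts[codon] = counts.get(codon, 0) + 1
        if codon in code.stop_codons:
            internal_stops += 1
        else:
            n_sense += 1
    if internal_stops:
        logger.warning(
            "%s: %d internal stop codon(s) encountered", seq.seq_id, internal_stops
        )
    return CodonCountTable(
        seq_id=seq.seq_id,
        counts=counts,
        n_codons=n_sense,
        skipped=skipped,
        internal_stops=internal_stops,
        species=seq.species,
        lifestyle=seq.lifestyle,
        gram=seq.gram,
    )


def aggregate_counts(
    tables: Sequence[CodonCountTable], genome_id: str = "aggregate"
) -> CodonCountTable:
    """Element-wise sum of codon count tables (e.g. a whole genome)."""
    if not tables:
        raise ValueError("aggregate_counts requires a non-empty list")
    counts = {c: 0 for c in ALL_CODONS}
    for t in tables:
        for c in ALL_CODONS:
            counts[c] += t.counts[c]
    return CodonCountTable(
        seq_id=genome_id,
        counts=counts,
        n_codons=sum(t.n_codons for t in tables),
        skipped=sum(t.skipped for t in tables),
        internal_stops=sum(t.internal_stops for t in tables),
    )


@dataclass
class GenomeCodonSet:
    """All per-CDS count tables of one genome plus their aggregate."""

    genome_id: str
    gene_tables: list[CodonCountTable]
    aggregate: CodonCountTable = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.aggregate is None:
            self.aggregate = aggregate_counts(self.gene_tables, self.genome_id)


# ---------------------------------------------------------------------------
# TSV round-trip

def write_counts_tsv(tables: Iterable[CodonCountTable], path: str | Path) -> None:
    """Write count tables in long format (seq_id, codon, count)."""
    df = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    with open(path, "w") as fh:
        fh.write("# codon counts: seq_id, codon, count (all 64 codons per sequence)\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> list[CodonCountTable]:
    """Inverse of :func:`write_counts_tsv`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for seq_id, grp in df.groupby("seq_id", sort=False):
        counts = dict(zip(grp["codon"], grp["count"]))
        out.append(CodonCountTable(seq_id=str(seq_id), counts=counts))
    return out


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read the species metadata table (species, lifestyle {P,NP}, gram)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("lifestyle", "gram"):
        if col not in df.columns:
            df[col] = "unknown"
    return df
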