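"""Codon usage stratified by protein secondary structure.

Aligns a CDS codon-by-codon with its protein sequence and a three-class
secondary-structure markup string (H = alpha helix, E = strand, C = all
other elements, one symbol per residue, produced by an external predictor),
then splits the codon counts by class and computes per-class RSCU and a
codon presence/absence matrix.  Structure prediction itself is out of
scope: the markup is consumed as input, and any alphabet beyond {H, E, C}
is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .codons import BACTERIAL_CODE, CodingSequence, CodonCountTable, GeneticCode
from .metrics import RscuTable, rscu

SSE_CLASSES = ("H", "E", "C")


@dataclass
class SseMarkup:
    """Per-residue three-class secondary-structure string."""

    seq_id: str
    classes: str

    def __post_init__(self) -> None:
        bad = set(self.classes) - set(SSE_CLASSES)
        if bad:
            raise ValueError(
                f"{self.seq_id}: illegal SSE symbols {sorted(bad)}; "
                f"only H/E/C are accepted"
            )

    def __len__(self) -> int:
        return len(self.classes)


@dataclass
class CodonResidueRecord:
    """One residue of the CDS/protein/SSE triple alignment (1-based position)."""

    position: int
    codon: str
    amino_acid: str
    sse_class: str


@dataclass
class StratifiedCounts:
    """Per-class codon count tables; their sum equals the whole-CDS table."""

    seq_id: str
    per_class: dict[str, CodonCountTable]
    species: str = ""


def read_markup_fasta(path: str | Path) -> list[SseMarkup]:
    """Read FASTA-like records of H/E/C markup (one record per protein)."""
    return [
        SseMarkup(seq_id=rec.id, classes=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def align_cds_protein_sse(
    cds: CodingSequence,
    protein: str,
    markup: SseMarkup,
    code: GeneticCode = BACTERIAL_CODE,
) -> list[CodonResidueRecord]:
    """Triple alignment CDS codons <-> protein residues <-> SSE classes.

    The terminal stop is trimmed first (it has no residue).  Translation is
    verified at every position; position 1 accepts the table's alternative
    initiation codons (e.g. GTG, TTG) when the protein shows M.
    """
    nt = cds.nucleotides
    if len(nt) % 3 != 0:
        raise ValueError(f"{cds.seq_id}: CDS length {len(nt)} not divisible by 3")
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    if codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]
    protein = protein.upper()
    if len(codons) != len(protein):
        raise ValueError(
            f"{cds.seq_id}: CDS has {len(codons)} codons but protein has "
            f"{len(protein)} residues"
        )
    if len(markup) != len(protein):
        raise ValueError(
            f"{cds.seq_id}: markup length {len(markup)} != protein length "
            f"{len(protein)}"
        )
    records = []
    for i, (codon, aa, cls) in enumerate(zip(codons, protein, markup.classes), start=1):
        if "N" in codon:
            translated = aa  # untranslatable; trust the protein
        else:
            translated = code.codon_to_aa[codon]
        if translated != aa:
            if i == 1 and aa == "M" and codon in code.start_codons:
                translated = "M"
            else:
                raise ValueError(
                    f"{cds.seq_id}: translation mismatch at position {i}: "
                    f"codon {codon} -> {translated}, protein says {aa}"
                )
        records.append(
            CodonResidueRecord(position=i, codon=codon, amino_acid=aa, sse_class=cls)
        )
    return records


def stratify_counts(
    records: list[CodonResidueRecord], seq_id: str = "", species: str = ""
) -> StratifiedCounts:
    """Split codon tallies by SSE class; class sums reproduce the whole CDS."""
    if not records:
        raise ValueError("no records to stratify")
    per_class: dict[str, dict[str, int]] = {c: {} for c in SSE_CLASSES}
    for rec in records:
        if "N" in rec.codon:
            continue
        d = per_class[rec.sse_class]
        d[rec.codon] = d.get(rec.codon, 0) + 1
    tables = {
        cls: CodonCountTable(seq_id=f"{seq_id or 'cds'}|{cls}", counts=counts,
                             species=species)
        for cls, counts in per_class.items()
    }
    return StratifiedCounts(seq_id=seq_id or "cds", per_class=tables, species=species)


def rscu_by_sse(
    strat: StratifiedCounts, code: GeneticCode = BACTERIAL_CODE
) -> list[RscuTable]:
    """Per-class RSCU tables (stratum labels H/E/C); unused families flagged."""
    return [
        rscu(strat.per_class[cls], code, stratum=cls) for cls in SSE_CLASSES
    ]


def presence_matrix(
    strata: list[StratifiedCounts], code: GeneticCode = BACTERIAL_CODE
) -> pd.DataFrame:
    """Used/unused flags per (species, class) x sense codon.

    Supports qualitative claims of the form "codon X is totally absent from
    the helix region of species Y".
    """
    if not strata:
        raise ValueError("need at least one species")
    rows = []
    index = []
    for st in strata:
        for cls in SSE_CLASSES:
            counts = st.per_class[cls].counts
            rows.append([counts[c] >= 1 for c in code.sense_codons])
            index.append((st.species or st.seq_id, cls))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["species", "sse_class"]),
        columns=list(code.sense_codons),
    )
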