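"""Synthetic multi-species cohorts with controllable codon-usage structure.

Two codon-choice regimes are available per gene:

* **mutational** — the third codon position is G/C with probability ``s``
  (uniform between G and C and between A and T), with the first two
  positions fixed by the amino acid.  Six-fold families are handled as
  their two-fold + four-fold first-two-base blocks (block chosen with
  probability proportional to block size); the three-codon Ile family is
  renormalised over its legal third letters.  This is the null regime of
  the Nc-plot: synonymous GC reflects composition alone, and synonymous
  GC3 converges to ``s``.
* **selected** — per-family codon probabilities are drawn once per gene
  from a symmetric Dirichlet(``alpha``); small ``alpha`` concentrates usage
  on few codons (strong bias, low Nc), ``alpha = None`` means the uniform
  limit.  An optional ``preferred`` codon per amino acid receives an extra
  multiplicative weight ``w >= 1`` shared across genes, planting a
  cohort-wide "core" codon.

A cohort crosses two categorical factors — lifestyle (P / NP) and Gram
nature (positive / negative / variable) — over the species, and can inject
multiplicative frequency effects tied to a factor level, targeting either
an amino acid (composition shift) or a codon (within-family weight shift).
Everything is driven by one integer seed through numpy SeedSequence
spawning, so per-species streams are independent and reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .codons import BACTERIAL_CODE, CodingSequence, GeneticCode
from .sse import SseMarkup

AA20 = tuple(sorted(BACTERIAL_CODE.families))  # the 20 standard amino acids


@dataclass(frozen=True)
class UsageModel:
    """Codon-choice regime for one class of genes (see module docstring)."""

    mode: str = "mutational"  # or "selected"
    s: float = 0.5  # third-position GC probability (mutational)
    alpha: float | None = None  # Dirichlet concentration (selected); None = uniform
    preferred: dict[str, str] = field(default_factory=dict)
    preferred_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("mutational", "selected"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "mutational" and not 0.0 <= self.s <= 1.0:
            raise ValueError("s must lie in [0, 1]")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.preferred_weight < 1.0:
            raise ValueError("preferred-codon weight must be >= 1")
        for aa, codon in self.preferred.items():
            if aa not in BACTERIAL_CODE.families:
                raise ValueError(f"unknown amino acid {aa!r}")
            if codon not in BACTERIAL_CODE.families[aa]:
                raise ValueError(f"{codon!r} does not encode {aa!r}")


@dataclass(frozen=True)
class Effect:
    """Multiplicative frequency shift tied to one factor level.

    ``target`` is a one-letter amino acid (shifts its compositional
    frequency) or a codon (shifts its within-family weight).
    """

    factor: str  # "lifestyle" or "gram"
    level: str
    target: str
    shift: float

    def __post_init__(self) -> None:
        if self.factor not in ("lifestyle", "gram"):
            raise ValueError(f"unknown factor {self.factor!r}")
        if self.shift <= 0:
            raise ValueError("shift must be positive")
        t = self.target
        if len(t) == 1:
            if t not in BACTERIAL_CODE.families:
                raise ValueError(f"unknown amino acid {t!r}")
        elif len(t) == 3:
            if BACTERIAL_CODE.codon_to_aa.get(t, "*") == "*":
                raise ValueError(f"{t!r} is not a sense codon")
        else:
            raise ValueError(f"target must be an amino acid or codon, got {t!r}")


@dataclass
class CohortSpec:
    """Full parameterisation of a synthetic multi-species dataset.

    Defaults emulate a bacterial comparative study: ~143 species with a
    ~50:50 pathogenic split and a 43:99:1 Gram split, modest genomes of
    heterogeneous mutational bias, and a focal gene under stronger
    selection-like bias than its genome.
    """

    n_species: int = 143
    genes_per_genome: int = 40
    gene_length_codons: int = 300
    usage: UsageModel = field(default_factory=UsageModel)
    focal_gene_usage: UsageModel = field(
        default_factory=lambda: UsageModel(mode="selected", alpha=0.3)
    )
    #: the housekeeping reference gene (rpoB analogue) is slightly more
    #: biased than the focal gene by default, as expected of a core gene
    reference_gene_usage: UsageModel = field(
        default_factory=lambda: UsageModel(mode="selected", alpha=0.25)
    )
    lifestyle_proportions: dict[str, float] = field(
        default_factory=lambda: {"NP": 75 / 143, "P": 68 / 143}
    )
    gram_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "positive": 43 / 143, "negative": 99 / 143, "variable": 1 / 143,
        }
    )
    #: per-species spread of mutational s (genome heterogeneity); the
    #: genome model's s is the centre, +/- this half-width, clipped to [0,1]
    s_halfwidth: float = 0.15
    #: per-gene jitter of s around the species value (mutational genomes)
    s_gene_sd: float = 0.05
    #: fraction of genome genes under selection-like (Dirichlet) usage,
    #: emulating the biased tail of highly expressed genes; 0 disables
    genome_selected_fraction: float = 0.25
    genome_selected_alpha: float = 0.5
    effects: list[Effect] = field(default_factory=list)
    aa_composition: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for props in (self.lifestyle_proportions, self.gram_proportions):
            total = sum(props.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError("factor proportions must sum to 1")


@dataclass
class SyntheticCohort:
    """Generated cohort: per-species genomes, focal/reference genes, truth."""

    metadata: pd.DataFrame  # species, lifestyle, gram
    genomes: dict[str, list[CodingSequence]]
    focal: dict[str, CodingSequence]
    reference: dict[str, CodingSequence]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "genomes").mkdir(parents=True, exist_ok=True)
        for sp, genes in self.genomes.items():
            _write_fasta(outdir / "genomes" / f"{sp}.fasta", genes)
        # one gene per species: key the FASTA records by species so the
        # metadata table joins directly
        _write_fasta(outdir / "focal.fasta", list(self.focal.values()), by_species=True)
        _write_fasta(
            outdir / "reference.fasta", list(self.reference.values()), by_species=True
        )
        with open(outdir / "metadata.tsv", "w") as fh:
            fh.write("# species metadata: lifestyle {P,NP}, gram {positive,negative,variable}\n")
            self.metadata.to_csv(fh, sep="\t", index=False)
        with open(outdir / "truth.txt", "w") as fh:
            for key, val in sorted(self.truth.items()):
                fh.write(f"{key}={val}\n")


def _write_fasta(
    path: Path, seqs: list[CodingSequence], by_species: bool = False
) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.species if by_species and s.species else s.seq_id}\n")
            for i in range(0, len(s.nucleotides), 70):
                fh.write(s.nucleotides[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# per-gene generation

def _blocks(codons: Sequence[str]) -> list[list[str]]:
    """Group a family's codons by their first two bases."""
    by_prefix: dict[str, list[str]] = {}
    for c in codons:
        by_prefix.setdefault(c[:2], []).append(c)
    return list(by_prefix.values())


def _mutational_family_probs(codons: Sequence[str], s: float) -> np.ndarray:
    """Codon probabilities within one family under the third-position GC rule."""
    probs = {c: 0.0 for c in codons}
    blocks = _blocks(codons)
    k = len(codons)
    for block in blocks:
        p_block = len(block) / k
        weights = np.array(
            [s / 2.0 if c[2] in "GC" else (1.0 - s) / 2.0 for c in block]
        )
        total = weights.sum()
        if total == 0:  # s at 0 or 1 with only-GC/only-AT block
            weights = np.ones(len(block))
            total = weights.sum()
        for c, w in zip(block, weights):
            probs[c] += p_block * w / total
    return np.array([probs[c] for c in codons])


def _family_probs(
    aa: str,
    model: UsageModel,
    rng: np.random.Generator,
    code: GeneticCode,
    codon_weight: dict[str, float] | None = None,
) -> np.ndarray:
    codons = code.families[aa]
    if model.mode == "mutational":
        p = _mutational_family_probs(codons, model.s)
    else:
        k = len(codons)
        if model.alpha is None:
            p = np.full(k, 1.0 / k)
        else:
            p = rng.dirichlet(np.full(k, model.alpha))
    w = np.ones(len(codons))
    pref = model.preferred.get(aa)
    for i, c in enumerate(codons):
        if c == pref:
            w[i] *= model.preferred_weight
        if codon_weight and c in codon_weight:
            w[i] *= codon_weight[c]
    p = p * w
    total = p.sum()
    if total <= 0:
        p = np.full(len(codons), 1.0 / len(codons))
    else:
        p = p / total
    return p


def generate_gene(
    length: int,
    model: UsageModel,
    rng: np.random.Generator,
    code: GeneticCode = BACTERIAL_CODE,
    aa_composition: dict[str, float] | None = None,
    codon_weight: dict[str, float] | None = None,
    seq_id: str = "gene",
    species: str = "",
) -> CodingSequence:
    """Generate one CDS of ``length`` codons (plus a terminal TAA stop).

    Amino acids are drawn i.i.d. from ``aa_composition`` (default uniform
    over the 20); the codon within each family follows ``model``.
    """
    if length < 1:
        raise ValueError("gene length must be >= 1 codon")
    if aa_composition is None:
        comp = np.full(len(AA20), 1.0 / len(AA20))
    else:
        comp = np.array([aa_composition.get(aa, 0.0) for aa in AA20], float)
        comp = comp / comp.sum()
    aa_idx = rng.choice(len(AA20), size=length, p=comp)
    codon_of = np.empty(length, dtype=object)
    for j, aa in enumerate(AA20):
        pos = np.nonzero(aa_idx == j)[0]
        if pos.size == 0:
            continue
        codons = code.families[aa]
        p = _family_probs(aa, model, rng, code, codon_weight)
        picks = rng.choice(len(codons), size=pos.size, p=p)
        for where, pick in zip(pos, picks):
            codon_of[where] = codons[pick]
    nt = "".join(codon_of) + "TAA"
    return CodingSequence(seq_id=seq_id, nucleotides=nt, species=species)


# ---------------------------------------------------------------------------
# cohort generation

def _assign_levels(
    proportions: dict[str, float], n: int, rng: np.random.Generator
) -> list[str]:
    """Deterministic level counts (largest-remainder), then shuffled."""
    levels = sorted(proportions)
    raw = {lv: proportions[lv] * n for lv in levels}
    counts = {lv: int(math.floor(raw[lv])) for lv in levels}
    short = n - sum(counts.values())
    for lv in sorted(levels, key=lambda l: raw[l] - counts[l], reverse=True)[:short]:
        counts[lv] += 1
    out = [lv for lv in levels for _ in range(counts[lv])]
    rng.shuffle(out)
    return out


def _apply_effects(
    spec: CohortSpec, lifestyle: str, gram: str
) -> tuple[dict[str, float], dict[str, float]]:
    """Resolve this species' amino-acid composition and codon-weight shifts."""
    comp = dict(
        spec.aa_composition
        if spec.aa_composition is not None
        else {aa: 1.0 / len(AA20) for aa in AA20}
    )
    codon_weight: dict[str, float] = {}
    level_of = {"lifestyle": lifestyle, "gram": gram}
    for eff in spec.effects:
        if level_of[eff.factor] != eff.level:
            continue
        if len(eff.target) == 1:
            comp[eff.target] = comp.get(eff.target, 0.0) * eff.shift
        else:
            codon_weight[eff.target] = codon_weight.get(eff.target, 1.0) * eff.shift
    total = sum(comp.values())
    comp = {aa: v / total for aa, v in comp.items()}
    return comp, codon_weight


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full cohort described by ``spec`` (seed-deterministic)."""
    root = np.random.SeedSequence(spec.seed)
    master = np.random.default_rng(root.spawn(1)[0])
    lifestyles = _assign_levels(spec.lifestyle_proportions, spec.n_species, master)
    grams = _assign_levels(spec.gram_proportions, spec.n_species, master)
    species_seeds = root.spawn(spec.n_species)

    genomes: dict[str, list[CodingSequence]] = {}
    focal: dict[str, CodingSequence] = {}
    reference: dict[str, CodingSequence] = {}
    meta_rows = []
    truth: dict = {
        "seed": spec.seed,
        "n_species": spec.n_species,
        "genes_per_genome": spec.genes_per_genome,
        "gene_length_codons": spec.gene_length_codons,
        "genome_mode": spec.usage.mode,
        "genome_s": spec.usage.s,
        "focal_mode": spec.focal_gene_usage.mode,
        "focal_alpha": spec.focal_gene_usage.alpha,
        "n_effects": len(spec.effects),
    }
    for i, eff in enumerate(spec.effects):
        truth[f"effect_{i}"] = f"{eff.factor}={eff.level}:{eff.target}x{eff.shift}"

    for i in range(spec.n_species):
        sp = f"sp{i:03d}"
        rng = np.random.default_rng(species_seeds[i])
        comp, codon_weight = _apply_effects(spec, lifestyles[i], grams[i])
        genome_model = spec.usage
        if genome_model.mode == "mutational" and spec.s_halfwidth > 0:
            s_i = float(
                np.clip(
                    genome_model.s + rng.uniform(-spec.s_halfwidth, spec.s_halfwidth),
                    0.0, 1.0,
                )
            )
            genome_model = replace(genome_model, s=s_i)
            truth[f"s_{sp}"] = s_i
        genes = []
        for j in range(spec.genes_per_genome):
            gene_model = genome_model
            if gene_model.mode == "mutational":
                if (
                    spec.genome_selected_fraction > 0
                    and rng.uniform() < spec.genome_selected_fraction
                ):
                    gene_model = UsageModel(
                        mode="selected", alpha=spec.genome_selected_alpha
                    )
                elif spec.s_gene_sd > 0:
                    gene_model = replace(
                        gene_model,
                        s=float(
                            np.clip(
                                gene_model.s + rng.normal(0.0, spec.s_gene_sd),
                                0.0, 1.0,
                            )
                        ),
                    )
            genes.append(
                generate_gene(
                    spec.gene_length_codons, gene_model, rng,
                    aa_composition=comp, codon_weight=codon_weight,
                    seq_id=f"{sp}_g{j:04d}", species=sp,
                )
            )
        genomes[sp] = genes
        focal[sp] = generate_gene(
            spec.gene_length_codons, spec.focal_gene_usage, rng,
            aa_composition=comp, codon_weight=codon_weight,
            seq_id=f"{sp}_focal", species=sp,
        )
        reference[sp] = generate_gene(
            spec.gene_length_codons, spec.reference_gene_usage, rng,
            aa_composition=comp, codon_weight=codon_weight,
            seq_id=f"{sp}_ref", species=sp,
        )
        meta_rows.append(
            {"species": sp, "lifestyle": lifestyles[i], "gram": grams[i]}
        )
    metadata = pd.DataFrame(meta_rows)
    return SyntheticCohort(
        metadata=metadata, genomes=genomes, focal=focal,
        reference=reference, truth=truth,
    )


def generate_sse_markup(
    length: int,
    mean_segment: float,
    class_weights: Sequence[float],
    rng: np.random.Generator,
) -> SseMarkup:
    """Run-length H/E/C markup with geometric segment lengths.

    Segments' classes are drawn by ``class_weights`` (H, E, C order) with no
    two adjacent segments sharing a class.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    w = np.asarray(class_weights, float)
    if w.size != 3 or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("class_weights must be 3 non-negative reals, not all 0")
    if mean_segment < 1:
        raise ValueError("mean segment length must be >= 1")
    p_stop = 1.0 / mean_segment
    classes = np.array(["H", "E", "C"])
    out: list[str] = []
    prev: str | None = None
    while len(out) < length:
        weights = w.copy()
        if prev is not None and np.count_nonzero(w) > 1:
            weights[classes == prev] = 0.0
        probs = weights / weights.sum()
        cls = str(rng.choice(classes, p=probs))
        seg = int(rng.geometric(p_stop)) if p_stop < 1 else 1
        out.extend([cls] * seg)
        prev = cls
    return SseMarkup(seq_id=f"markup{length}", classes="".join(out[:length]))
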