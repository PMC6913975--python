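"""End-to-end pipeline: counting -> metrics -> comparison -> statistics -> SSE.

All tables are written as tab-separated UTF-8 with '#'-prefixed comment
headers.  Identical configuration and inputs produce byte-identical
outputs.  Each stage failure raises :class:`StageError` naming the stage.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .codons import (
    BACTERIAL_CODE,
    GeneticCode,
    aggregate_counts,
    count_codons,
    read_cds_fasta,
    read_counts_tsv,
    read_metadata_tsv,
    write_counts_tsv,
)
from .compare import neutrality_fit, ncplot_table, percent_genes_below, spearman, zscore
from .metrics import compute_metrics, metrics_frame
from .sse import (
    align_cds_protein_sse,
    presence_matrix,
    read_markup_fasta,
    rscu_by_sse,
    stratify_counts,
)
from .stats import core_codon_scan, two_way_anova
from Bio import SeqIO

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, switches and output location of one pipeline run."""

    focal_cds: str = ""
    reference_cds: str = ""
    genome_dir: str = ""  # per-species FASTA files <species>.fasta
    genome_metrics: str = ""  # or precomputed TSV: species, seq_id, nc, gc3, gc
    metadata: str = ""
    protein_fasta: str = ""
    markup: str = ""
    genetic_code: int = 11
    rank_test_mode: str = "counts"  # or "frequencies"
    exclude_gram_variable: bool = True
    alpha_core: float = 0.001
    alpha_anova: float = 0.01
    outdir: str = "cubkit_out"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat key=value config file; '#' starts a comment."""
        values: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {line!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            values[key] = val
        kwargs = {}
        for f in fields(cls):
            if f.name not in values:
                continue
            raw = values.pop(f.name)
            if f.type == "bool":
                kwargs[f.name] = raw.lower() in ("1", "true", "yes")
            elif f.type == "int":
                kwargs[f.name] = int(raw)
            elif f.type == "float":
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = raw
        if values:
            raise ValueError(f"unknown config keys: {sorted(values)}")
        return cls(**kwargs)


def _write_tsv(df: pd.DataFrame, path: Path, comment: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage the configuration enables; return output paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    code = GeneticCode.from_ncbi_table(config.genetic_code)

    # ---- load inputs -----------------------------------------------------
    stage = "load"
    try:
        meta = read_metadata_tsv(config.metadata) if config.metadata else None
        if not config.focal_cds:
            raise ValueError("focal CDS FASTA is required")
        focal = read_cds_fasta(config.focal_cds, meta)
        reference = (
            read_cds_fasta(config.reference_cds, meta) if config.reference_cds else []
        )
    except Exception as exc:  # noqa: BLE001 - stage-named abort contract
        raise StageError(stage, str(exc)) from exc

    # ---- counting + metrics ---------------------------------------------
    stage = "metrics"
    try:
        focal_counts = [count_codons(s, code) for s in focal]
        ref_counts = [count_codons(s, code) for s in reference]
        focal_metrics = [compute_metrics(c, code) for c in focal_counts]
        ref_metrics = [compute_metrics(c, code) for c in ref_counts]
        mf = metrics_frame(focal_metrics)
        mf.insert(0, "gene", "focal")
        if ref_metrics:
            rf = metrics_frame(ref_metrics)
            rf.insert(0, "gene", "reference")
            mf = pd.concat([mf, rf], ignore_index=True)
        outputs["metrics"] = outdir / "metrics.tsv"
        _write_tsv(
            mf, outputs["metrics"],
            "per-CDS codon-usage metrics: Nc (20=max bias..61=none), "
            "GC fractions by codon position, gc3s = synonymous GC3",
        )
        write_counts_tsv(focal_counts, outdir / "counts.tsv")
        outputs["counts"] = outdir / "counts.tsv"
        if ref_counts:
            write_counts_tsv(ref_counts, outdir / "counts_reference.tsv")
            outputs["counts_reference"] = outdir / "counts_reference.tsv"
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- genome comparison ----------------------------------------------
    stage = "compare"
    try:
        genome_metrics = _load_genome_metrics(config, code)
        if genome_metrics is not None:
            comp = _compare_table(focal_metrics, ref_metrics, genome_metrics)
            outputs["compare"] = outdir / "compare.tsv"
            _write_tsv(
                comp, outputs["compare"],
                "per-species genic vs genome comparison: z = (x-mu)/delta "
                "(population sd), pct_below = % genome genes strictly below",
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- Nc-plot and neutrality plot ------------------------------------
    stage = "ncplot"
    try:
        nc_tbl = ncplot_table(focal_metrics)
        outputs["ncplot"] = outdir / "ncplot.tsv"
        _write_tsv(
            nc_tbl, outputs["ncplot"],
            "Nc-plot data: expected = 2 + s + 29/(s^2+(1-s)^2) (mutation-only null)",
        )
        valid = [
            m for m in focal_metrics if not (math.isnan(m.nc) or math.isnan(m.gc3))
        ]
        if len(valid) >= 4:
            fit = neutrality_fit(
                [m.gc1 for m in valid], [m.gc2 for m in valid], [m.gc3 for m in valid]
            )
            rho = spearman([m.gc3s for m in valid], [m.nc for m in valid])
            neut = pd.DataFrame(
                {
                    "species": [m.species for m in valid],
                    "seq_id": [m.seq_id for m in valid],
                    "gc12": [(m.gc1 + m.gc2) / 2 for m in valid],
                    "gc3": [m.gc3 for m in valid],
                }
            )
            outputs["neutrality"] = outdir / "neutrality.tsv"
            _write_tsv(
                neut, outputs["neutrality"],
                f"neutrality plot GC12 vs GC3; slope={fit.coefficients[1]:.4f} "
                f"intercept={fit.coefficients[0]:.4f} r2={fit.r_squared:.4f}; "
                f"spearman(nc,gc3s) rho={rho.rho:.3f} p={rho.p_value:.3g}",
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- core-codon rank tests ------------------------------------------
    stage = "famstats"
    try:
        if len(focal_counts) >= 3:
            fam = core_codon_scan(
                focal_counts, code, mode=config.rank_test_mode,
                alpha=config.alpha_core,
            )
            outputs["famstats"] = outdir / "famstats.tsv"
            _write_tsv(
                fam, outputs["famstats"],
                f"core-codon rank tests per amino-acid family "
                f"(mode={config.rank_test_mode}, alpha={config.alpha_core}); "
                "U = min(U1,U2); H tie-corrected",
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- two-way ANOVA ---------------------------------------------------
    stage = "anova"
    try:
        if meta is not None and len(focal_counts) >= 8:
            anova_tbl = _anova_table(focal_counts, config, code)
            if anova_tbl is not None:
                outputs["anova"] = outdir / "anova.tsv"
                _write_tsv(
                    anova_tbl, outputs["anova"],
                    "two-way (lifestyle x Gram) Type II ANOVA per codon and "
                    "per amino acid on per-1000-codon frequencies",
                )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- SSE stratification ----------------------------------------------
    stage = "sse"
    try:
        if config.protein_fasta or config.markup:
            if not (config.protein_fasta and config.markup):
                raise ValueError("SSE stage needs both protein FASTA and markup file")
            sse_rscu_tbl, sse_presence_tbl = _sse_tables(focal, config, code)
            outputs["sse_rscu"] = outdir / "sse_rscu.tsv"
            _write_tsv(
                sse_rscu_tbl, outputs["sse_rscu"],
                "RSCU per secondary-structure class (H=helix, E=strand, C=other)",
            )
            outputs["sse_presence"] = outdir / "sse_presence.tsv"
            _write_tsv(
                sse_presence_tbl, outputs["sse_presence"],
                "codon used (True) / unused (False) per species x SSE class",
                index=True,
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- manifest ---------------------------------------------------------
    manifest = outdir / "run_manifest.txt"
    with open(manifest, "w") as fh:
        fh.write(f"cubkit_version={__version__}\n")
        fh.write(f"python={sys.version.split()[0]}\n")
        for f in fields(PipelineConfig):
            fh.write(f"{f.name}={getattr(config, f.name)}\n")
        for name, path in sorted(outputs.items()):
            fh.write(f"output_{name}={path.name}\n")
    outputs["manifest"] = manifest
    return outputs


def _load_genome_metrics(config: PipelineConfig, code: GeneticCode):
    """Per-species per-gene genome metrics from a FASTA dir or a TSV."""
    if config.genome_metrics:
        df = pd.read_csv(config.genome_metrics, sep="\t", comment="#")
        need = {"species", "nc", "gc3"}
        if not need <= set(df.columns):
            raise ValueError(f"genome metrics TSV needs columns {sorted(need)}")
        return df
    if config.genome_dir:
        rows = []
        gdir = Path(config.genome_dir)
        for fa in sorted(gdir.glob("*.fasta")):
            species = fa.stem
            for seq in read_cds_fasta(fa):
                counts = count_codons(seq, code)
                m = compute_metrics(counts, code)
                rows.append(
                    {"species": species, "seq_id": m.seq_id, "nc": m.nc,
                     "gc3": m.gc3, "gc3s": m.gc3s, "gc": m.gc}
                )
        if not rows:
            raise ValueError(f"no genome FASTA files under {gdir}")
        return pd.DataFrame(rows)
    return None


def _compare_table(focal_metrics, ref_metrics, genome_df: pd.DataFrame) -> pd.DataFrame:
    ref_by_species = {m.species: m for m in ref_metrics}
    rows = []
    for m in focal_metrics:
        gdf = genome_df[genome_df["species"] == m.species]
        if gdf.empty:
            logger.warning("%s: no genome metrics, skipped from compare", m.species)
            continue
        nc_vals = gdf["nc"].dropna().to_numpy()
        gc3_vals = gdf["gc3"].dropna().to_numpy()
        row = {
            "species": m.species,
            "lifestyle": m.lifestyle,
            "gram": m.gram,
            "focal_nc": m.nc,
            "focal_gc3": m.gc3,
            "focal_gc": m.gc,
            "genome_mean_nc": float(np.mean(nc_vals)),
            "genome_mean_gc3": float(np.mean(gc3_vals)),
            "focal_nc_z": zscore(m.nc, nc_vals, m.species, "nc").z,
            "focal_gc3_z": zscore(m.gc3, gc3_vals, m.species, "gc3").z,
            "focal_nc_pct_below": percent_genes_below(nc_vals, m.nc),
            "focal_gc3_pct_below": percent_genes_below(gc3_vals, m.gc3),
        }
        ref = ref_by_species.get(m.species)
        if ref is not None:
            row.update(
                {
                    "ref_nc": ref.nc,
                    "ref_gc3": ref.gc3,
                    "ref_nc_z": zscore(ref.nc, nc_vals, m.species, "nc").z,
                    "ref_gc3_z": zscore(ref.gc3, gc3_vals, m.species, "gc3").z,
                    "ref_nc_pct_below": percent_genes_below(nc_vals, ref.nc),
                    "ref_gc3_pct_below": percent_genes_below(gc3_vals, ref.gc3),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _anova_table(focal_counts, config: PipelineConfig, code: GeneticCode):
    tables = list(focal_counts)
    if config.exclude_gram_variable:
        tables = [t for t in tables if t.gram != "variable"]
    lifestyles = [t.lifestyle for t in tables]
    grams = [t.gram for t in tables]
    if len(set(lifestyles)) < 2 or len(set(grams)) < 2:
        logger.warning("fewer than 2 levels per factor: ANOVA stage skipped")
        return None
    rows = []
    responses: list[tuple[str, str, list[float]]] = []
    for codon in code.sense_codons:
        responses.append(
            (
                "codon", codon,
                [1000.0 * t.counts[codon] / t.n_codons for t in tables],
            )
        )
    for aa in sorted(code.families):
        responses.append(
            (
                "amino_acid", aa,
                [
                    1000.0 * sum(t.counts[c] for c in code.families[aa]) / t.n_codons
                    for t in tables
                ],
            )
        )
    for kind, name, vals in responses:
        res = two_way_anova(vals, lifestyles, grams)
        for term in ("factor_A", "factor_B", "interaction", "residual"):
            if term not in res.terms.index:
                continue
            rec = res.terms.loc[term]
            rows.append(
                {
                    "response_type": kind,
                    "response": name,
                    "term": {"factor_A": "lifestyle", "factor_B": "gram"}.get(
                        term, term
                    ),
                    "sum_of_squares": rec["sum_of_squares"],
                    "df": rec["df"],
                    "F": rec["F"],
                    "p_value": rec["p_value"],
                    "significant": (
                        term != "residual" and rec["p_value"] < config.alpha_anova
                    ),
                }
            )
    return pd.DataFrame(rows)


def _sse_tables(focal, config: PipelineConfig, code: GeneticCode):
    proteins = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(config.protein_fasta, "fasta")
    }
    markups = {m.seq_id: m for m in read_markup_fasta(config.markup)}
    strata = []
    rscu_rows = []
    for seq in focal:
        if seq.seq_id not in proteins or seq.seq_id not in markups:
            continue
        records = align_cds_protein_sse(
            seq, proteins[seq.seq_id], markups[seq.seq_id], code
        )
        st = stratify_counts(records, seq_id=seq.seq_id, species=seq.species or seq.seq_id)
        strata.append(st)
        for tbl in rscu_by_sse(st, code):
            counts = st.per_class[tbl.stratum].counts
            for codon in code.sense_codons:
                rscu_rows.append(
                    {
                        "species": st.species,
                        "sse_class": tbl.stratum,
                        "codon": codon,
                        "amino_acid": code.codon_to_aa[codon],
                        "count": counts[codon],
                        "rscu": tbl.rscu[codon],
                    }
                )
    if not strata:
        raise ValueError("no focal CDS matched the protein/markup records")
    return pd.DataFrame(rscu_rows), presence_matrix(strata, code)
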