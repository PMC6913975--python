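"""Triple alignment CDS/protein/SSE and structure-stratified codon usage."""

import numpy as np
import pytest
from Bio.Seq import Seq

from cubkit.codons import ALL_CODONS, BACTERIAL_CODE, CodingSequence, count_codons
from cubkit.metrics import rscu
from cubkit.simulate import UsageModel, generate_gene, generate_sse_markup
from cubkit.sse import (
    SseMarkup,
    align_cds_protein_sse,
    presence_matrix,
    rscu_by_sse,
    stratify_counts,
)


def make_gene_with_markup(rng, length=120):
    gene = generate_gene(length, UsageModel(mode="selected", alpha=None), rng,
                         seq_id="g", species="sp")
    protein = str(Seq(gene.nucleotides[:-3]).translate(table=11))
    markup = generate_sse_markup(length, 6.0, (1, 1, 1), rng)
    return gene, protein, markup


class TestMarkup:
    def test_alphabet_enforced(self):
        with pytest.raises(ValueError, match="H/E/C"):
            SseMarkup("x", "HHEX")

    def test_valid(self):
        assert len(SseMarkup("x", "HEC")) == 3


class TestAlign:
    def test_direct_mapping_with_stop_trim(self):
        cds = CodingSequence("x", "ATGGGTTAA")
        recs = align_cds_protein_sse(cds, "MG", SseMarkup("x", "CH"))
        assert [(r.position, r.codon, r.amino_acid, r.sse_class) for r in recs] == [
            (1, "ATG", "M", "C"), (2, "GGT", "G", "H"),
        ]

    def test_translation_mismatch_reports_position(self):
        cds = CodingSequence("x", "ATGGGTTAA")
        with pytest.raises(ValueError, match="position 2"):
            align_cds_protein_sse(cds, "MA", SseMarkup("x", "CH"))

    def test_markup_length_mismatch(self):
        cds = CodingSequence("x", "ATGGGTTAA")
        with pytest.raises(ValueError, match="markup"):
            align_cds_protein_sse(cds, "MG", SseMarkup("x", "CHH"))

    def test_cds_protein_length_mismatch(self):
        cds = CodingSequence("x", "ATGGGTGCTTAA")
        with pytest.raises(ValueError, match="codons"):
            align_cds_protein_sse(cds, "MG", SseMarkup("x", "CH"))

    def test_alternative_start_accepted_as_met(self):
        cds = CodingSequence("x", "GTGGGTTAA")  # GTG start, protein shows M
        recs = align_cds_protein_sse(cds, "MG", SseMarkup("x", "CC"))
        assert recs[0].codon == "GTG" and recs[0].amino_acid == "M"

    def test_internal_gtg_is_valine_not_met(self):
        cds = CodingSequence("x", "ATGGTGTAA")
        with pytest.raises(ValueError, match="position 2"):
            align_cds_protein_sse(cds, "MM", SseMarkup("x", "CC"))


class TestStratify:
    def test_trivial_split(self):
        cds = CodingSequence("x", "ATGGGTTAA")
        recs = align_cds_protein_sse(cds, "MG", SseMarkup("x", "CH"))
        st = stratify_counts(recs, seq_id="x")
        assert st.per_class["H"].counts["GGT"] == 1
        assert st.per_class["C"].counts["ATG"] == 1
        assert st.per_class["E"].n_codons == 0

    def test_degenerate_all_h_equals_full_table(self, rng):
        gene, protein, _ = make_gene_with_markup(rng)
        markup = SseMarkup("g", "H" * len(protein))
        recs = align_cds_protein_sse(gene, protein, markup)
        st = stratify_counts(recs, seq_id="g")
        full = count_codons(gene)
        assert st.per_class["H"].counts == full.counts
        assert st.per_class["E"].n_codons == 0 and st.per_class["C"].n_codons == 0

    def test_class_sums_reproduce_full_counts(self, rng):
        for _ in range(20):
            gene, protein, markup = make_gene_with_markup(rng)
            recs = align_cds_protein_sse(gene, protein, markup)
            st = stratify_counts(recs, seq_id="g")
            full = count_codons(gene)
            for codon in ALL_CODONS:
                total = sum(
                    st.per_class[c].counts[codon] for c in ("H", "E", "C")
                )
                assert total == full.counts[codon]

    def test_empty_error(self):
        with pytest.raises(ValueError):
            stratify_counts([])


class TestRscuBySse:
    def test_single_class_markup_equals_plain_rscu(self, rng):
        gene, protein, _ = make_gene_with_markup(rng)
        markup = SseMarkup("g", "E" * len(protein))
        recs = align_cds_protein_sse(gene, protein, markup)
        st = stratify_counts(recs, seq_id="g")
        tables = {t.stratum: t for t in rscu_by_sse(st)}
        plain = rscu(count_codons(gene))
        assert tables["E"].rscu == pytest.approx(plain.rscu)

    def test_single_codon_glycine_class(self):
        cds = CodingSequence("x", "GGTGGTTAA")
        recs = align_cds_protein_sse(cds, "GG", SseMarkup("x", "EE"))
        st = stratify_counts(recs, seq_id="x")
        tables = {t.stratum: t for t in rscu_by_sse(st)}
        assert tables["E"].rscu["GGT"] == pytest.approx(4.0)

    def test_unused_family_flagged_not_zero_biased(self, rng):
        cds = CodingSequence("x", "ATGGGTTAA")
        recs = align_cds_protein_sse(cds, "MG", SseMarkup("x", "CH"))
        st = stratify_counts(recs, seq_id="x")
        tables = {t.stratum: t for t in rscu_by_sse(st)}
        assert "G" in tables["E"].unused_families  # Gly absent from strands

    def test_matches_direct_recount_oracle(self, rng):
        # per-class RSCU equals RSCU recomputed from scratch on the subset
        for _ in range(5):
            gene, protein, markup = make_gene_with_markup(rng, length=200)
            recs = align_cds_protein_sse(gene, protein, markup)
            st = stratify_counts(recs, seq_id="g")
            tables = {t.stratum: t for t in rscu_by_sse(st)}
            for cls in ("H", "E", "C"):
                subset = [r.codon for r in recs if r.sse_class == cls]
                counts = {}
                for c in subset:
                    counts[c] = counts.get(c, 0) + 1
                from cubkit.codons import CodonCountTable

                oracle = rscu(CodonCountTable("o", counts))
                assert tables[cls].rscu == pytest.approx(oracle.rscu)


class TestPresenceMatrix:
    def _strata(self, rng, n=3):
        out = []
        for i in range(n):
            gene, protein, markup = make_gene_with_markup(rng)
            gene.species = f"sp{i}"
            recs = align_cds_protein_sse(gene, protein, markup)
            out.append(stratify_counts(recs, seq_id=f"g{i}", species=f"sp{i}"))
        return out

    def test_flags_match_counts(self, rng):
        strata = self._strata(rng)
        mat = presence_matrix(strata)
        for st in strata:
            for cls in ("H", "E", "C"):
                for codon in BACTERIAL_CODE.sense_codons:
                    assert mat.loc[(st.species, cls), codon] == (
                        st.per_class[cls].counts[codon] >= 1
                    )

    def test_planted_absent_codon(self, rng):
        # force a markup where Leu codon CTA never lands in helix
        cds = CodingSequence("x", "CTACTGTAA")
        recs = align_cds_protein_sse(cds, "LL", SseMarkup("x", "CH"))
        st = stratify_counts(recs, seq_id="x", species="spx")
        mat = presence_matrix([st])
        assert not mat.loc[("spx", "H"), "CTA"]
        assert mat.loc[("spx", "H"), "CTG"]

    def test_monotone_under_added_data(self, rng):
        strata = self._strata(rng, n=1)
        mat1 = presence_matrix(strata)
        # add a second gene's records into the same species' strata
        gene, protein, markup = make_gene_with_markup(rng)
        recs = align_cds_protein_sse(gene, protein, markup)
        merged = strata[0]
        for r in recs:
            merged.per_class[r.sse_class].counts[r.codon] += 1
        mat2 = presence_matrix([merged])
        assert ((mat1 <= mat2) | ~mat1).all().all()

    def test_empty_error(self):
        with pytest.raises(ValueError):
            presence_matrix([])
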