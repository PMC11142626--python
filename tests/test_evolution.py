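"""Conservation degrees and evolutionary-origin classification."""

import math

import numpy as np
import pytest

import axesbio as ab
from axesbio.asfa import ASFA
from axesbio.evolution import categorize_degree

# printed taxon lists of three published human-axis fixtures: a
# telomere/Cajal-body axis (15 taxa), a GABA-signalling synapse axis
# whose taxa include E. coli (13 taxa), and a cranial-nerve development
# axis restricted to vertebrates
TELOMERE_AXIS_TAXA = {3702, 4896, 6239, 7227, 7955, 9031, 9606, 9615,
                      9823, 9913, 10090, 10116, 352472, 511145, 559292}
SYNAPSE_AXIS_TAXA = {4896, 10116, 9606, 9031, 511145, 10090, 9615, 7955,
                     3702, 352472, 7227, 559292, 6239}
CRANIAL_AXIS_TAXA = {7955, 9031, 9606, 10090, 10116}


def table_with_taxa(taxa_by_term):
    terms = sorted(taxa_by_term)
    M = np.ones((len(terms), 4))
    return ab.AnnotationTable(terms, [f"g{i}" for i in range(4)], M,
                              term_taxa={t: set(s) for t, s
                                         in taxa_by_term.items()})


class TestCatalog:
    def test_twenty_taxa_each_classified(self):
        cat = ab.TaxonCatalog.default()
        assert cat.total_taxa == 20
        assert set(cat.clade.values()) <= {"prokaryote", "eukaryote",
                                           "vertebrate"}

    def test_known_clades(self):
        cat = ab.TaxonCatalog.default()
        assert cat.clade[511145] == "prokaryote"
        assert cat.clade[9606] == "vertebrate"
        assert cat.clade[559292] == "eukaryote"


class TestConservationDegree:
    def test_single_taxon(self):
        t = table_with_taxa({"a": {9606}})
        assert ab.conservation_degree("a", t) == 1

    def test_all_catalogued_taxa(self):
        cat = ab.TaxonCatalog.default()
        t = table_with_taxa({"a": set(cat.clade)})
        assert ab.conservation_degree("a", t) == 20

    def test_telomere_axis_fixture(self):
        t = table_with_taxa({"a": TELOMERE_AXIS_TAXA})
        assert ab.conservation_degree("a", t) == 15

    def test_empty_taxa_is_error(self):
        t = table_with_taxa({"a": set()})
        with pytest.raises(ValueError):
            ab.conservation_degree("a", t)


class TestSpecificityCorrelations:
    def test_degree_equals_gene_count(self):
        """Terms whose taxon spread equals their gene count correlate +1."""
        terms = [f"t{i}" for i in range(5)]
        M = np.zeros((5, 10))
        taxa = {}
        levels = {}
        for i in range(5):
            M[i, :i + 4] = 1         # gene counts 4..8
            taxa[terms[i]] = set(range(i + 4))
            levels[terms[i]] = 1
        table = ab.AnnotationTable(terms, [f"g{j}" for j in range(10)], M,
                                   term_taxa=taxa)

        class Dag:
            level = {t: 5 - i for i, t in enumerate(terms)}

        r_genes, r_level = ab.specificity_correlations(table, Dag())
        assert r_genes == pytest.approx(1.0)
        assert r_level == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        terms = [f"t{i}" for i in range(8)]
        M = (rng.random((8, 12)) < 0.5).astype(float)
        taxa = {t: set(rng.choice(20, size=int(rng.integers(1, 20)),
                                  replace=False).tolist())
                for t in terms}
        table = ab.AnnotationTable(terms, [f"g{j}" for j in range(12)], M,
                                   term_taxa=taxa)

        class Dag:
            level = {t: int(rng.integers(1, 9)) for t in terms}

        dag = Dag()
        r_genes, r_level = ab.specificity_correlations(table, dag)
        deg = np.array([len(taxa[t]) for t in terms])
        cnt = M.sum(axis=1)
        lev = np.array([dag.level[t] for t in terms])

        def pearson_oracle(x, y):
            x, y = x - x.mean(), y - y.mean()
            return float((x * y).sum()
                         / math.sqrt((x * x).sum() * (y * y).sum()))

        assert r_genes == pytest.approx(pearson_oracle(deg, cnt),
                                        abs=1e-12)
        assert r_level == pytest.approx(pearson_oracle(deg, lev),
                                        abs=1e-12)


class TestDistanceVsConservation:
    def test_identical_embeddings_degenerate(self):
        t = table_with_taxa({"a": {1}, "b": {1, 2}})
        U = np.ones((2, 3))
        out = ab.distance_vs_conservation(U, t)
        assert math.isnan(out["spearman"])

    def test_degree_ranks_distance(self):
        taxa = {f"t{i}": set(range(i + 1)) for i in range(6)}
        t = table_with_taxa(taxa)
        # orthogonal rows with growing norms: mean distance to the rest
        # strictly increases with the degree
        U = np.diag(np.arange(6, dtype=float))
        out = ab.distance_vs_conservation(U, t)
        assert out["spearman"] == pytest.approx(1.0)

    def test_planted_jump_detected(self):
        # degrees 14..17; terms at degree >= 17 sit far away
        taxa = {f"t{i}": set(range(14 + i)) for i in range(4)}
        t = table_with_taxa(taxa)
        U = np.zeros((4, 2))
        U[3, 0] = 50.0                  # the degree-17 term is isolated
        out = ab.distance_vs_conservation(U, t)
        assert out["jump_degree"] == 17

    def test_categories(self):
        assert categorize_degree(1) == "generic"
        assert categorize_degree(4) == "generic"
        assert categorize_degree(5) == "background"
        assert categorize_degree(16) == "background"
        assert categorize_degree(17) == "specific"
        assert categorize_degree(20) == "specific"


class TestASFAConservation:
    def test_single_term_union(self):
        t = table_with_taxa({"a": {9606, 10090}})
        asfa = ASFA(0, {}, "go_terms", item_ids=["a"])
        assert ab.asfa_conservation(asfa, t) == {9606, 10090}

    def test_disjoint_taxa_sum(self):
        t = table_with_taxa({"a": {1, 2}, "b": {3}})
        asfa = ASFA(0, {}, "go_terms", item_ids=["a", "b"])
        assert len(ab.asfa_conservation(asfa, t)) == 3

    def test_synapse_axis_degree_thirteen(self):
        t = table_with_taxa({"a": SYNAPSE_AXIS_TAXA})
        asfa = ASFA(144, {}, "go_terms", item_ids=["a"])
        assert len(ab.asfa_conservation(asfa, t)) == 13

    def test_union_dominates_members(self, annotated, planted):
        asfas = ab.build_asfas(annotated, planted["texts"])
        table = planted["table"]
        for a in asfas:
            union = ab.asfa_conservation(a, table)
            per_term = max(len(table.term_taxa.get(t, set()))
                           for t in a.item_ids)
            assert len(union) >= per_term

    def test_axis_without_terms_is_error(self):
        t = table_with_taxa({"a": {1}})
        asfa = ASFA(0, {}, "go_terms", item_ids=[])
        with pytest.raises(ValueError):
            ab.asfa_conservation(asfa, t)


class TestClassifyEvolution:
    def test_prokaryote_member_dominates(self):
        assert ab.classify_evolution(SYNAPSE_AXIS_TAXA) == "prokaryotes"

    def test_all_vertebrates(self):
        assert ab.classify_evolution(CRANIAL_AXIS_TAXA) == "vertebrates"

    def test_invertebrate_eukaryotes(self):
        assert ab.classify_evolution({7227, 559292}) == "eukaryotes"

    def test_partition_of_outcomes(self):
        cat = ab.TaxonCatalog.default()
        rng = np.random.default_rng(0)
        taxa = sorted(cat.clade)
        for _ in range(100):
            union = set(rng.choice(taxa, size=int(rng.integers(1, 10)),
                                   replace=False).tolist())
            cls = ab.classify_evolution(union, cat)
            assert cls in ("prokaryotes", "eukaryotes", "vertebrates")
            has_pro = any(cat.clade[t] == "prokaryote" for t in union)
            has_ver = any(cat.clade[t] == "vertebrate" for t in union)
            if has_pro:
                assert cls == "prokaryotes"
            elif has_ver:
                assert cls == "vertebrates"
            else:
                assert cls == "eukaryotes"

    def test_empty_union_is_error(self):
        with pytest.raises(ValueError):
            ab.classify_evolution(set())

    def test_unknown_taxon_is_error(self):
        with pytest.raises(KeyError):
            ab.classify_evolution({42})
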