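"""The synthetic study generator: determinism, planted-count exactness and
self-certifying ground truth (every truth field is verifiable from the
emitted tables alone)."""

import filecmp
from pathlib import Path

import pytest

from phytonet.enrichment import ora
from phytonet.mass_annotation import MassPeak, fit_formulas
from phytonet.network_core import (
    build_compound_target_network,
    build_ppi_network,
    hub_genes,
    screen_main_ingredients,
    summarize,
)
from phytonet.synthetic_data import (
    InfeasibleConfig,
    PeakSpec,
    StudyConfig,
    generate_peaks,
    generate_study,
)
from phytonet.target_assembly import (
    GeneSet,
    intersect_targets,
    merge_sources,
    screen_disease_targets,
    screen_predictions,
)

CHNO_BOUNDS = {"C": (0, 30), "H": (0, 60), "N": (0, 6), "O": (0, 17)}


def acquisition_adducts(polarity):
    """The generator's adduct pool (no formate) restricted to one polarity."""
    return [a for a in PeakSpec().adducts
            if ("+" if polarity == "positive" else "-") == a[-1]]


def assemble(study):
    per, union, pred_report = screen_predictions(study.predictions)
    per_source, _ = screen_disease_targets(study.disease)
    disease_union = merge_sources(per_source)
    therapeutic = intersect_targets(union, disease_union)
    return per, union, pred_report, per_source, disease_union, therapeutic


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_study(StudyConfig.small(5)).write(a)
        generate_study(StudyConfig.small(5)).write(b)
        names = sorted(p.name for p in a.iterdir())
        assert names == sorted(p.name for p in b.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
        assert mismatch == [] and errors == []

    def test_different_seed_same_marginal_counts(self):
        s1 = generate_study(StudyConfig.small(1))
        s2 = generate_study(StudyConfig.small(2))
        assert len(s1.predictions) == len(s2.predictions)
        assert len(s1.disease) == len(s2.disease)
        assert len(s1.annotations.terms) == len(s2.annotations.terms)
        assert s1.truth["planted_intersection"] != s2.truth["planted_intersection"] \
            or s1.truth["planted_ingredients"] != s2.truth["planted_ingredients"]


class TestPlantedCounts:
    def test_assembly_chain(self, small_study):
        cfg = small_study.config
        per, union, pred_report, per_source, disease_union, therapeutic = \
            assemble(small_study)
        assert pred_report.counts["kept"] == cfg.n_prediction_rows
        assert len(union) == cfg.intersection_size + cfg.n_compound_only_genes
        for src in cfg.sources:
            assert len(per_source[src.name]) == src.n_screened
        assert len(disease_union) == cfg.disease_union_size
        assert len(therapeutic) == cfg.intersection_size
        assert set(therapeutic.genes) == set(small_study.truth["planted_intersection"])

    def test_network_counts(self, small_study):
        cfg = small_study.config
        per, *_, therapeutic = assemble(small_study)
        ct = build_compound_target_network(per, therapeutic)
        s = summarize(ct)
        assert s.role_counts["compound"] == cfg.n_connected_compounds
        assert s.n_edges == cfg.n_ct_edges
        assert sorted(ct.nodes("compound")) == small_study.truth["connected_compounds"]
        ppi = build_ppi_network(small_study.ppi, therapeutic,
                                cfg.ppi.score_threshold)
        assert ppi.n_nodes == cfg.ppi.n_connected
        assert ppi.n_edges == cfg.ppi.n_edges
        free = set(small_study.truth["ppi_free_genes"])
        assert free & set(ppi.nodes()) == set()
        assert len(free) == cfg.intersection_size - cfg.ppi.n_connected

    def test_planted_recovery_fixed_seed(self, small_study):
        cfg = small_study.config
        per, *_, therapeutic = assemble(small_study)
        ct = build_compound_target_network(per, therapeutic)
        ingredients, *_ = screen_main_ingredients(ct)
        assert sorted(ingredients) == small_study.truth["planted_ingredients"]
        ppi = build_ppi_network(small_study.ppi, therapeutic)
        top, overflow = hub_genes(ppi, cfg.ppi.n_planted_hubs)
        assert sorted(g for g, _ in top) == small_study.truth["planted_hubs"]
        assert overflow == []

    def test_planted_terms_significant_and_first(self, small_study):
        query = GeneSet.from_iterable("q", small_study.truth["planted_intersection"])
        rows, _ = ora(query, small_study.annotations, alpha=0.01)
        planted = set(small_study.truth["planted_terms"])
        significant = {r.term_id for r in rows}
        assert planted <= significant
        by_cat = {}
        for r in rows:  # rows sorted by p ascending
            by_cat.setdefault(r.category, r.term_id)
        for cat, first in by_cat.items():
            assert first in planted, f"non-planted term ranked first in {cat}"

    def test_ctp_structure(self, small_study):
        cfg = small_study.config
        truth = small_study.truth
        kegg_planted = [t for t in small_study.annotations.terms
                        if t.category == "KEGG" and t.term_id in truth["planted_terms"]]
        covered = set()
        for t in kegg_planted:
            covered |= t.genes & set(truth["planted_intersection"])
        assert sorted(covered) == truth["ctp_targets"]
        assert len(covered) == cfg.n_ctp_targets


class TestPeaks:
    def test_zero_noise_rank_one_recovery(self):
        cfg = StudyConfig.small(3)
        cfg = StudyConfig(**{**cfg.__dict__,
                             "peaks": PeakSpec(n_peaks=8, noise_ppm=1e-9,
                                               fraction_outside=0.0)})
        table, truth = generate_peaks(cfg)
        assert truth["peaks_outside_tolerance"] == []
        for _, row in table.iterrows():
            peak = MassPeak(row["peak_id"], row["rt_min"], row["observed_mz"],
                            row["polarity"])
            hits = fit_formulas(peak, adducts=acquisition_adducts(peak.polarity),
                                bounds=CHNO_BOUNDS, tolerance_ppm=5)
            assert hits and hits[0].composition.hill_formula() == row["known_formula"]

    def test_all_outside_never_recovers_truth(self):
        cfg = StudyConfig.small(4)
        cfg = StudyConfig(**{**cfg.__dict__,
                             "peaks": PeakSpec(n_peaks=8, fraction_outside=1.0)})
        table, truth = generate_peaks(cfg)
        assert len(truth["peaks_outside_tolerance"]) == 8
        for _, row in table.iterrows():
            peak = MassPeak(row["peak_id"], row["rt_min"], row["observed_mz"],
                            row["polarity"])
            hits = fit_formulas(peak, adducts=acquisition_adducts(peak.polarity),
                                bounds=CHNO_BOUNDS, tolerance_ppm=5)
            assert row["known_formula"] not in [
                c.composition.hill_formula() for c in hits]


class TestFeasibility:
    def test_infeasible_intersection_rejected(self):
        cfg = StudyConfig.small(0)
        bad = StudyConfig(**{**cfg.__dict__, "intersection_size": 200})
        with pytest.raises(InfeasibleConfig):
            generate_study(bad)

    def test_error_names_the_constraint(self):
        cfg = StudyConfig.small(0)
        bad = StudyConfig(**{**cfg.__dict__, "targets_per_compound": (10, 20)})
        with pytest.raises(InfeasibleConfig, match="mean degree"):
            generate_study(bad)

    def test_roundtrip_through_readers(self, tmp_path, small_study):
        from phytonet.enrichment import read_gmt
        from phytonet.mass_annotation import read_peak_table
        from phytonet.network_core import read_ppi_edges
        from phytonet.target_assembly import read_disease_targets, read_predictions
        small_study.write(tmp_path)
        assert len(read_peak_table(tmp_path / "peaks.tsv")) == len(small_study.peaks)
        preds = read_predictions(tmp_path / "predictions.tsv")
        _, union, _ = screen_predictions(preds)
        assert len(union) == small_study.config.intersection_size + \
            small_study.config.n_compound_only_genes
        per_source, _ = screen_disease_targets(
            read_disease_targets(tmp_path / "disease.tsv"))
        for src in small_study.config.sources:
            assert len(per_source[src.name]) == src.n_screened
        assert len(read_ppi_edges(tmp_path / "ppi.tsv")) == len(small_study.ppi)
        db = read_gmt(tmp_path / "annotations.gmt")
        assert len(db.terms) == len(small_study.annotations.terms)
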