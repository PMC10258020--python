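"""Generator determinism, planted structure, and fixture validity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from granuleseq import annotation as ann
from granuleseq import partition as part
from granuleseq import peaks as pk
from granuleseq import synthetic as syn


class TestDeterminism:
    def test_byte_identical_fixture_set(self, small_config, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            study = syn.simulate_study(small_config, with_sequences=True)
            syn.write_study(study, d)
        for p1 in sorted(d1.rglob("*")):
            if p1.is_file():
                p2 = d2 / p1.relative_to(d1)
                assert p1.read_bytes() == p2.read_bytes(), p1.name

    def test_seed_changes_output(self, small_config):
        import dataclasses

        a = syn.generate_features(small_config)
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        b = syn.generate_features(other)
        assert not a["length_total"].equals(b["length_total"])

    def test_sequences_do_not_perturb_other_stages(self, small_config):
        with_seq = syn.simulate_study(small_config, with_sequences=True)
        without = syn.simulate_study(small_config, with_sequences=False)
        assert with_seq.expression.equals(without.expression)
        assert with_seq.peaks.keys() == without.peaks.keys()
        for key in with_seq.peaks:
            assert with_seq.peaks[key].equals(without.peaks[key])


class TestGenerateAnnotation:
    def test_all_lncrna_config_has_no_cds(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, lncrna_fraction=1.0)
        models, features = syn.generate_annotation(cfg)
        assert all(m.cds == [] for m in models)
        assert (features["biotype"] == ann.LNCRNA).all()
        assert (features["length_total"] > 0).all()

    def test_region_lengths_sum_and_intervals_valid(self, small_config):
        models, features = syn.generate_annotation(small_config)
        for m in models:
            assert all(s < e for s, e in m.exons)
            widths = {
                "utr5": sum(e - s for s, e in m.utr5),
                "cds": sum(e - s for s, e in m.cds),
                "utr3": sum(e - s for s, e in m.utr3),
                "exon": sum(e - s for s, e in m.exons),
            }
            if m.biotype == ann.PROTEIN_CODING:
                assert widths["utr5"] + widths["cds"] + widths["utr3"] == widths["exon"]

    def test_realized_gc_concentrates_on_drawn_gc(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(
            small_config, gc_alpha=1e9, gc_beta=1e9, seed=9
        )  # degenerate at 0.5
        models, features = syn.generate_annotation(cfg)
        chroms = syn.generate_sequences(models, features, cfg)
        long_models = [m for m in models if m.exonic_length() >= 2000]
        assert long_models, "fixture needs some >=2 kb transcripts"
        for m in long_models:
            gc = ann.compute_features(m, chroms).gc_fraction
            assert abs(gc - 0.5) < 0.03


class TestGeneratePeaks:
    def test_null_coefficients_homogeneous_counts(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(
            small_config, peak_b_length=0.0, peak_b_at=0.0, peak_intercept=np.log(2.0)
        )
        models, features = syn.generate_annotation(cfg)
        tracks = syn.generate_peaks(models, features, cfg, proteins=("G3BP1",), conditions=("Ctrl",))
        counts = tracks[("G3BP1", "Ctrl", 1)].groupby(
            tracks[("G3BP1", "Ctrl", 1)]["chrom"]
        ).size()
        # no length/AT coupling: per-gene counts carry no length correlation
        rep1 = tracks[("G3BP1", "Ctrl", 1)]
        assigned = pk.assign_peaks(rep1, models)
        per_gene = assigned.groupby("gene_id").size()
        merged = features.set_index("gene_id").join(per_gene.rename("k")).fillna(0)
        r = np.corrcoef(np.log(merged["length_total"]), merged["k"])[0, 1]
        assert abs(r) < 0.2

    def test_planted_length_effect_recovered(self, small_config):
        models, features = syn.generate_annotation(small_config)
        tracks = syn.generate_peaks(models, features, small_config,
                                    proteins=("G3BP1",), conditions=("Ctrl",))
        assigned = pk.assign_peaks(tracks[("G3BP1", "Ctrl", 1)], models)
        per_gene = assigned.groupby("gene_id").size()
        merged = features.set_index("gene_id").join(per_gene.rename("k")).fillna(0)
        r = np.corrcoef(np.log(merged["length_total"]), merged["k"])[0, 1]
        assert r > 0.2

    def test_full_utr3_weight_places_all_coding_peaks_in_utr3(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, utr3_weight=1.0, lncrna_fraction=0.0)
        models, features = syn.generate_annotation(cfg)
        tracks = syn.generate_peaks(models, features, cfg, proteins=("G3BP1",), conditions=("Ctrl",))
        assigned = pk.assign_peaks(tracks[("G3BP1", "Ctrl", 1)], models)
        assert (assigned["region"] == "3UTR").all()

    def test_replicates_mostly_overlap(self, small_config):
        models, features = syn.generate_annotation(small_config)
        tracks = syn.generate_peaks(models, features, small_config,
                                    proteins=("G3BP1",), conditions=("Ctrl",))
        rep1, rep2 = tracks[("G3BP1", "Ctrl", 1)], tracks[("G3BP1", "Ctrl", 2)]
        common = pk.intersect_replicates(rep1, rep2)
        assert len(rep2) < len(rep1)
        assert len(common) >= 0.8 * len(rep2)


class TestGenerateExpression:
    def test_null_model_yields_no_enrichment_calls(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(
            small_config, sg_b_length=0.0, sg_b_at=0.0, sg_b_abundance=0.0, sg_noise_sd=0.0
        )
        features = syn.generate_features(cfg)
        _, truth = syn.generate_expression(features, cfg, with_counts=False)
        classes = part.classify_sg(truth["sg_tpm"], truth["total_tpm"])
        assert set(classes["sg_class"]) <= {"neither", "low"}
        assert np.allclose(truth["log_ratio"], 0.0)

    def test_planted_length_effect_gives_longer_enriched_class(self, small_config):
        features = syn.generate_features(small_config)
        _, truth = syn.generate_expression(features, small_config, with_counts=False)
        classes = part.classify_sg(truth["sg_tpm"], truth["total_tpm"])
        merged = classes.merge(features, on="gene_id")
        enr = merged.loc[merged["sg_class"] == "enriched", "length_total"]
        dep = merged.loc[merged["sg_class"] == "depleted", "length_total"]
        assert enr.median() > dep.median()
        assert sps.mannwhitneyu(enr, dep).pvalue < 0.01

    def test_counts_recover_planted_tpm_with_depth(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, depth=20_000_000)
        features = syn.generate_features(cfg)
        expression, truth = syn.generate_expression(features, cfg)
        tpm_hat = part.tpm_from_expression(expression, "Total")
        true = truth["total_tpm"]
        # Poisson concentration: relative error shrinks with depth; compare
        # on well-expressed genes
        big = true[true > 50]
        rel = (tpm_hat[big.index] - big).abs() / big
        assert rel.median() < 0.05

    def test_expression_table_layout(self, small_config):
        expression, _ = syn.generate_expression(
            syn.generate_features(small_config), small_config
        )
        assert set(expression["sample"]) == {"SG", "Total", "Ctrl", "siG3BP1", "siG3BP2", "AS"}
        assert not expression.duplicated(subset=["gene_id", "sample"]).any()
        assert (expression["count"] >= 0).all()


class TestGenerateDisease:
    def test_disease_genes_longer(self, small_config):
        features = syn.generate_features(small_config)
        disease = syn.generate_disease(features, small_config)
        mask = features["gene_id"].isin(disease)
        assert 0 < mask.sum() < len(features)
        assert (
            features.loc[mask, "length_total"].median()
            > features.loc[~mask, "length_total"].median()
        )


class TestGenerateProteomicsErrors:
    def test_unknown_planted_module_rejected(self, small_config):
        import dataclasses

        plan = dataclasses.replace(
            small_config.proteomics,
            planted_effects=(syn.PlantedModuleEffect("M99", "enriched", (0, 0, 1)),),
        )
        cfg = dataclasses.replace(small_config, proteomics=plan)
        features = syn.generate_features(cfg)
        _, truth = syn.generate_expression(features, cfg, with_counts=False)
        classes = part.classify_sg(truth["sg_tpm"], truth["total_tpm"])
        with pytest.raises(ValueError, match="unknown module"):
            syn.generate_proteomics(classes, cfg)

    def test_insufficient_class_pool_rejected(self):
        plan = syn.ProteomicsPlan(
            n_control=5, n_asymad=5, n_ad=5, n_modules=40,
            proteins_per_class=10, planted_effects=(),
        )
        cfg = syn.SyntheticConfig(seed=1, n_genes=100, proteomics=plan)
        features = syn.generate_features(cfg)
        _, truth = syn.generate_expression(features, cfg, with_counts=False)
        classes = part.classify_sg(truth["sg_tpm"], truth["total_tpm"])
        with pytest.raises(ValueError, match="not enough"):
            syn.generate_proteomics(classes, cfg)


def test_config_yaml_round_trip(tmp_path, planted_small_config):
    path = tmp_path / "config.yaml"
    planted_small_config.to_yaml(path)
    back = syn.SyntheticConfig.from_yaml(path)
    assert back == planted_small_config
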