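"""Generator contracts: determinism, geometry, planted effects and peaks."""

import numpy as np
import pandas as pd
import pytest

from coreg_ir.synthetic_data import (
    SimulationConfig,
    design_table,
    generate_annotation,
    generate_truth,
    plant_motifs,
    simulate_all,
    simulate_counts,
    simulate_peaks,
    write_narrowpeak,
)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"n_replicates": 1},
        {"nb_dispersion": 0.0},
        {"silencing_efficiency": 0.0},
        {"silencing_efficiency": 1.0},
        {"n_genes": 0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestAnnotation:
    def test_single_gene_window_inside_contig(self):
        cfg = SimulationConfig(n_genes=1, seed=3)
        ann, genome = generate_annotation(cfg)
        assert len(ann) == 1
        tss = int(ann["tss"].iloc[0])
        assert tss - 3000 >= 0
        assert tss + 3000 <= len(genome["chr1"])

    def test_windows_disjoint_by_brute_force(self, small_config, small_annotation):
        """All 200 +/-3000 bp windows are pairwise non-overlapping."""
        ann, _ = small_annotation
        windows = sorted((t - 3000, t + 3000) for t in ann["tss"])
        overlaps = sum(1 for (s1, e1), (s2, e2) in zip(windows, windows[1:])
                       if s2 < e1)
        assert overlaps == 0

    def test_both_strands_represented(self, small_annotation):
        ann, _ = small_annotation
        assert set(ann["strand"]) == {"+", "-"}

    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(n_genes=30, seed=11)
        ann1, g1 = generate_annotation(cfg)
        ann2, g2 = generate_annotation(cfg)
        pd.testing.assert_frame_equal(ann1, ann2)
        assert g1["chr1"].tobytes() == g2["chr1"].tobytes()


class TestTruth:
    def test_null_genes_have_no_effects_or_binding(self, small_truth):
        null = small_truth[small_truth["reg_class"] == "null"]
        assert (null["ir_log2fc_4gy"] == 0).all()
        assert (null["ir_log2fc_10gy"] == 0).all()
        for col in ("bound_p53_2h", "bound_p53_4h", "bound_rela_2h", "bound_rela_4h"):
            assert not null[col].any()

    def test_dual_classes_bind_both_factors(self, small_truth):
        dual = small_truth[small_truth["reg_class"].isin(
            ["coactivated", "antagonistic_nfkb_act_p53_rep",
             "antagonistic_p53_act_nfkb_rep"])]
        assert len(dual) > 0
        assert (dual["bound_p53_2h"] | dual["bound_p53_4h"]).all()
        assert (dual["bound_rela_2h"] | dual["bound_rela_4h"]).all()

    def test_effect_sign_pattern_matches_class(self, small_truth):
        """Per class, the sign of (p53 component, NF-kB component) is fixed."""
        signs = {
            "p53_activated": (1, 0), "nfkb_activated": (0, 1),
            "coactivated": (1, 1),
            "antagonistic_nfkb_act_p53_rep": (-1, 1),
            "antagonistic_p53_act_nfkb_rep": (1, -1),
            "null": (0, 0),
        }
        for cls, (sp, sn) in signs.items():
            sub = small_truth[small_truth["reg_class"] == cls]
            assert (np.sign(sub["c_p53_10gy"]) == sp).all(), cls
            assert (np.sign(sub["c_nfkb_10gy"]) == sn).all(), cls


class TestPlantMotifs:
    def test_bound_genes_carry_sites_null_genes_do_not(self, small_config):
        truth = generate_truth(small_config)
        ann, genome = generate_annotation(small_config)
        planted = plant_motifs(genome, ann, truth, small_config)
        ann_i = ann.set_index("gene_id")
        seq = genome["chr1"].tobytes().decode()
        for row in planted.itertuples(index=False):
            assert seq[row.start:row.end] == row.site
            tss = int(ann_i.at[row.gene_id, "tss"])
            assert tss - 3000 <= row.start and row.end <= tss + 3000
        null_genes = set(truth.loc[truth["reg_class"] == "null", "gene_id"])
        assert not (set(planted["gene_id"]) & null_genes)
        coact = truth[truth["reg_class"] == "coactivated"]["gene_id"]
        by_gene = planted.groupby("gene_id")["tf"].apply(set)
        for g in coact:
            assert by_gene[g] == {"RelA", "p53"}


class TestCounts:
    def test_null_truth_mean_log2fc_near_zero(self):
        cfg = SimulationConfig(n_genes=500, n_replicates=3, frac_per_class=0.0, seed=21)
        truth = generate_truth(cfg)
        counts = simulate_counts(truth, cfg)
        ctrl = [c for c in counts if c.startswith("control_siCTR")]
        ir = [c for c in counts if c.startswith("IR10_siCTR")]
        lfc = np.log2(counts[ir].mean(axis=1) + 0.5) - np.log2(counts[ctrl].mean(axis=1) + 0.5)
        se = lfc.std() / np.sqrt(len(lfc))
        assert abs(lfc.mean()) < 3 * se + 1e-3

    def test_planted_effect_recovered_at_large_n(self):
        """log2 fold change of 1.5 estimated within +/-0.2 with 50 replicates."""
        cfg = SimulationConfig(n_genes=10, n_replicates=50, frac_per_class=0.0, seed=5)
        truth = generate_truth(cfg)
        truth.loc[:, ["c_p53_10gy"]] = 1.5
        truth.loc[:, ["c_nfkb_10gy"]] = 0.0
        counts = simulate_counts(truth, cfg)
        ctrl = [c for c in counts if c.startswith("control_siCTR")]
        ir = [c for c in counts if c.startswith("IR10_siCTR")]
        lfc = np.log2(counts[ir].mean(axis=1)) - np.log2(counts[ctrl].mean(axis=1))
        assert (np.abs(lfc - 1.5) < 0.2).all()

    def test_silenced_arm_reduces_tf_driven_component(self):
        cfg = SimulationConfig(n_genes=40, n_replicates=50, seed=9)
        truth = generate_truth(cfg)
        counts = simulate_counts(truth, cfg)
        sirela = [c for c in counts if c.startswith("IR10_siRELA")]
        sictr = [c for c in counts if c.startswith("IR10_siCTR")]
        ratio = counts[sirela].mean(axis=1) / counts[sictr].mean(axis=1)
        coact = truth["reg_class"] == "coactivated"
        assert (ratio[coact.to_numpy()] < 1).all()

    def test_design_covers_full_grid(self, small_config):
        design = design_table(small_config)
        assert len(design) == 3 * 3 * small_config.n_replicates
        assert set(design["condition"]) == {"control", "IR4", "IR10"}
        assert set(design["arm"]) == {"siCTR", "siRELA", "siTP53"}


class TestPeaks:
    def test_bound_at_4h_only_absent_at_2h(self, small_annotation):
        cfg = SimulationConfig(n_genes=200, seed=7, background_peak_rate=0.0)
        truth = generate_truth(cfg)
        only_4h = truth[truth["bound_p53_4h"] & ~truth["bound_p53_2h"]]
        assert len(only_4h) > 0
        ann, _ = small_annotation
        regions = simulate_peaks(truth, ann, cfg)
        p53 = regions[regions["tf"] == "p53"]
        for g in only_4h["gene_id"]:
            assert g in set(p53.loc[p53["timepoint"] == "4h", "peak_id"].str[-6:])
            assert g not in set(p53.loc[p53["timepoint"] == "2h", "peak_id"].str[-6:])

    def test_peak_summits_inside_windows(self, small_truth, small_annotation):
        cfg = SimulationConfig(n_genes=200, seed=7)
        ann, _ = small_annotation
        regions = simulate_peaks(small_truth, ann, cfg)
        tss = ann.set_index("gene_id")["tss"]
        gene = regions["peak_id"].str.rsplit("_", n=1).str[-1]
        offsets = regions["summit"].to_numpy() - tss.loc[gene].to_numpy()
        assert (np.abs(offsets) <= 3000).all()

    def test_narrowpeak_bytes_deterministic(self, tmp_path, small_truth, small_annotation):
        cfg = SimulationConfig(n_genes=200, seed=7)
        ann, _ = small_annotation
        paths = {}
        for tag in ("a", "b"):
            regions = simulate_peaks(small_truth, ann, cfg)
            out = tmp_path / tag
            paths[tag] = write_narrowpeak(regions, out)
        for pa, pb in zip(paths["a"], paths["b"]):
            assert open(pa, "rb").read() == open(pb, "rb").read()


def test_simulate_all_bundle_roundtrip(tmp_path):
    cfg = SimulationConfig(n_genes=20, seed=2)
    out = simulate_all(cfg, out_dir=tmp_path)
    assert set(out) >= {"truth", "annotation", "genome", "counts", "regions", "design"}
    assert (tmp_path / "genome.fa").exists()
    counts = pd.read_csv(tmp_path / "counts.tsv", sep="\t", index_col=0)
    assert counts.shape == (20, 27)
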