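"""Tests for the ground-truthed synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from ovatome import (
    InvalidConfigError,
    SimulationConfig,
    deduplicate,
    generate_ct_table,
    generate_expression_pair,
    generate_go_world,
    generate_ovary_section,
    generate_read_set,
    is_pcr_duplicate,
    parse_obo,
    quantify,
)
from ovatome.dedup import read_fastq, write_fastq
from ovatome.enrichment import propagate_annotations, term_frequency
from ovatome.morphometry import classify_stage, summarize_section
from ovatome.synthetic import write_obo


class TestConfig:
    def test_defaults_validate(self):
        SimulationConfig().validate()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"read_length": 10},
            {"duplicate_rate": 1.5},
            {"planted_fold": 1.0},
            {"n_up_mutant": 300, "n_up_wildtype": 300, "n_genes": 500},
            {"dag_depth": 2},
            {"section_area_mm2": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(**kwargs).validate()


class TestReadSet:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(seed=11, n_unique_reads=40, duplicate_rate=0.5)
        r1, t1 = generate_read_set(cfg)
        r2, t2 = generate_read_set(cfg)
        assert [x.sequence for x in r1] == [x.sequence for x in r2]
        assert t1.equals(t2)

    def test_zero_duplicate_rate_gives_singletons(self):
        cfg = SimulationConfig(seed=2, n_unique_reads=30, duplicate_rate=0.0)
        reads, truth = generate_read_set(cfg)
        assert len(reads) == 30
        assert truth["cluster"].value_counts().max() == 1

    def test_planted_duplicates_satisfy_the_rule(self):
        cfg = SimulationConfig(seed=1, n_unique_reads=50, duplicate_rate=0.5)
        reads, truth = generate_read_set(cfg)
        by_id = {r.read_id: r for r in reads}
        seeds = truth[truth.role == "seed"].set_index("cluster")["read_id"]
        dups = truth[truth.role == "duplicate"]
        assert len(dups) > 0
        for row in dups.itertuples():
            assert is_pcr_duplicate(by_id[row.read_id], by_id[seeds[row.cluster]])

    def test_near_misses_violate_exactly_one_condition(self):
        cfg = SimulationConfig(seed=4, n_unique_reads=80, duplicate_rate=0.6)
        reads, truth = generate_read_set(cfg)
        by_id = {r.read_id: r for r in reads}
        seeds = truth[truth.role == "seed"].set_index("cluster")["read_id"]
        near = truth[truth.role.str.startswith("near_miss")]
        assert len(near) > 0
        for row in near.itertuples():
            nm = by_id[row.read_id]
            seed_read = by_id[seeds[row.cluster.removesuffix("nm")]]
            assert not is_pcr_duplicate(nm, seed_read)
            from ovatome import similarity

            same_prefix = nm.sequence[:10] == seed_read.sequence[:10]
            sim = similarity(nm, seed_read)
            if row.role == "near_miss_prefix":
                assert not same_prefix and sim > 0.90
            else:
                assert same_prefix and sim <= 0.90

    def test_truth_matches_dedup(self):
        cfg = SimulationConfig(seed=5, n_unique_reads=60, duplicate_rate=0.5)
        reads, truth = generate_read_set(cfg)
        kept, report = deduplicate(reads)
        assert report.n_kept == truth["cluster"].nunique()

    def test_duplicate_fraction_converges_to_rate(self):
        """Fraction of reads in clusters of size >= 2 approaches duplicate_rate."""
        rate = 0.4
        fracs = []
        for seed in range(8):
            cfg = SimulationConfig(seed=seed, n_unique_reads=400, duplicate_rate=rate)
            _, truth = generate_read_set(cfg)
            sizes = truth[~truth.role.str.startswith("near_miss")][
                "cluster"
            ].value_counts()
            n_multi = sizes[sizes >= 2].sum()
            fracs.append(n_multi / sizes.sum())
        mean = np.mean(fracs)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(mean - rate) < 3 * se + 0.01

    def test_short_read_length_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_read_set(SimulationConfig(read_length=10))

    def test_fastq_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=6, n_unique_reads=10, duplicate_rate=0.3)
        reads, _ = generate_read_set(cfg)
        path = tmp_path / "r.fastq"
        write_fastq(reads, path)
        back = read_fastq(path)
        assert [(r.read_id, r.sequence) for r in back] == [
            (r.read_id, r.sequence) for r in reads
        ]


class TestExpressionPair:
    def test_no_planting_means_no_up_labels(self):
        cfg = SimulationConfig(seed=3, n_genes=100, n_up_mutant=0, n_up_wildtype=0)
        _, truth = generate_expression_pair(cfg)
        assert set(truth["label"]) <= {"unchanged", "not_expressed"}

    def test_truth_ratio_honours_planted_fold(self):
        cfg = SimulationConfig(seed=7, n_genes=200, n_up_mutant=20, planted_fold=4)
        _, truth = generate_expression_pair(cfg)
        up = truth[truth.label == "up_in_mutant"]
        assert len(up) == 20
        assert (up.true_fpkm_mut / up.true_fpkm_wt >= 4).all()
        assert (up.true_fpkm_wt > 5).all()

    def test_below_threshold_genes_labelled_not_expressed(self):
        cfg = SimulationConfig(seed=8, n_genes=300, n_up_mutant=0, n_up_wildtype=0)
        _, truth = generate_expression_pair(cfg)
        low = truth[(truth.true_fpkm_mut <= 5) & (truth.true_fpkm_wt <= 5)]
        assert len(low) > 0
        assert (low.label == "not_expressed").all()
        # the threshold is exercised on both sides
        assert (truth.true_fpkm_mut > 5).any() and (truth.true_fpkm_mut <= 5).any()

    def test_counts_are_non_negative_integers(self):
        cfg = SimulationConfig(seed=9, n_genes=100)
        counts, _ = generate_expression_pair(cfg)
        assert (counts[["count_mut", "count_wt"]] >= 0).all().all()
        assert counts["count_mut"].dtype.kind in "iu"

    def test_recovery_of_planted_genes(self):
        cfg = SimulationConfig(seed=7, n_genes=500, n_up_mutant=40, planted_fold=4)
        counts, truth = generate_expression_pair(cfg)
        merged = quantify(counts).merge(truth, on="gene_id")
        planted = merged[merged.label == "up_in_mutant"]
        assert (planted.call == "up_in_mutant").mean() >= 0.90

    def test_invalid_fold_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_expression_pair(SimulationConfig(planted_fold=0.8))


class TestGoWorld:
    def test_dag_is_acyclic_and_single_rooted(self):
        import networkx as nx

        dag, *_ = generate_go_world(SimulationConfig(seed=3))
        assert nx.is_directed_acyclic_graph(dag.graph)
        assert len(dag.roots) == 1

    def test_uniform_annotations_give_near_zero_scores(self):
        from ovatome import compute_enrichment

        cfg = SimulationConfig(seed=3, planted_terms={})
        dag, ann, sa, sb, planted = generate_go_world(cfg)
        assert planted == {}
        results = compute_enrichment(dag, ann, sa, sb)
        mean_abs = np.mean([abs(r.score) for r in results])
        assert mean_abs < 0.5

    def test_planted_term_frequencies_carry_the_margin(self):
        cfg = SimulationConfig(seed=3)
        dag, ann, sa, sb, planted = generate_go_world(cfg)
        closed = propagate_annotations(dag, ann)
        assert planted
        for term, direction in planted.items():
            fa = term_frequency(sa, term, closed)
            fb = term_frequency(sb, term, closed)
            hi, lo = (fa, fb) if direction == "up_in_A" else (fb, fa)
            assert hi >= 0.25 and lo <= 0.15

    def test_obo_round_trip_counts(self, tmp_path):
        dag, *_ = generate_go_world(SimulationConfig(seed=5))
        path = tmp_path / "synthetic.obo"
        write_obo(dag, path)
        back = parse_obo(str(path))
        assert back.terms == dag.terms
        assert back.graph.number_of_edges() == dag.graph.number_of_edges()

    def test_shallow_planted_term_rejected(self):
        # the root sits at level 0: planting it would be masked by display
        cfg = SimulationConfig(seed=3, planted_terms={"GO:0000001": "up_in_A"})
        with pytest.raises(InvalidConfigError, match="level"):
            generate_go_world(cfg)


class TestOvarySection:
    def test_zero_cv_classifies_perfectly(self):
        cfg = SimulationConfig(
            seed=5, diameter_cv=0.0,
            n_follicles_per_stage={"I": 10, "II": 10, "III": 10},
        )
        follicles, truth = generate_ovary_section(cfg)
        for f, row in zip(follicles, truth.itertuples()):
            assert classify_stage(f.diameter_um) == row.true_stage

    def test_density_from_counts(self):
        cfg = SimulationConfig(
            seed=5, n_follicles_per_stage={"I": 200, "II": 150, "III": 30},
            section_area_mm2=5.0,
        )
        follicles, _ = generate_ovary_section(cfg)
        s = summarize_section(follicles, cfg.section_area_mm2)
        assert s.density_total == pytest.approx((200 + 150 + 30) / 5.0)

    def test_empty_section(self):
        cfg = SimulationConfig(
            seed=5, n_follicles_per_stage={"I": 0, "II": 0, "III": 0}
        )
        follicles, truth = generate_ovary_section(cfg)
        assert follicles == [] and truth.empty
        s = summarize_section(follicles, cfg.section_area_mm2)
        assert s.density_total == 0.0 and s.prop_stage3 is None

    def test_overlapping_stages_warn_not_error(self):
        cfg = SimulationConfig(
            seed=5, diameter_cv=0.5,
            n_follicles_per_stage={"I": 100, "II": 100, "III": 100},
        )
        with pytest.warns(UserWarning, match="overlap"):
            generate_ovary_section(cfg)

    def test_stage_recovery_at_low_cv(self):
        cfg = SimulationConfig(seed=12, diameter_cv=0.05)
        follicles, truth = generate_ovary_section(cfg)
        hits = [
            classify_stage(f.diameter_um) == row.true_stage
            for f, row in zip(follicles, truth.itertuples())
        ]
        assert np.mean(hits) >= 0.99


class TestCtTable:
    def test_known_ground_truth_recoverable(self):
        from ovatome import CtTable, delta_delta_ct

        cfg = SimulationConfig(seed=13)
        table, truth = generate_ct_table(cfg, true_ddct={"X": 1.0}, noise_sd=0.0)
        r = delta_delta_ct(CtTable(table), "X", "Ci-GAPDH", "wildtype", "mutant")
        assert r.ddct == pytest.approx(1.0)
        assert r.relative_expression == pytest.approx(0.5)

    def test_replicate_structure(self):
        cfg = SimulationConfig(seed=13)
        table, truth = generate_ct_table(cfg, n_replicates=3)
        counts = table.groupby(["sample", "gene"]).size()
        assert (counts == 3).all()
        assert set(truth) == set(table["gene"]) - {"Ci-GAPDH"}
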