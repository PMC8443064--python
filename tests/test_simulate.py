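"""Determinism, calibration and recoverability of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from epm.classify import classify_regions
from epm.hic import link_by_interactions
from epm.model import assemble_dataset, evaluate, fit_linear_model
from epm.simulate import (
    SyntheticTruth,
    default_transition_probs,
    gen_biased_samples,
    gen_expression_trajectories,
    gen_reads,
    gen_regions_and_interactions,
    gen_segmentation,
    gen_signal_expression,
    segmentation_from_candidates,
    write_bundle,
)
from epm.states import coalesce, merge_state_groups, transition_matrix


class TestSegmentation:
    def test_deterministic(self, truth):
        a = gen_segmentation(truth, seed=4)
        b = gen_segmentation(truth, seed=4)
        assert a.segments == b.segments

    def test_tiles_without_overlap(self, truth):
        track = gen_segmentation(truth, seed=1)
        for chrom, segs in track.by_chromosome().items():
            assert segs[0].start == 0
            for x, y in zip(segs, segs[1:]):
                assert x.end == y.start

    def test_coalesced_by_construction(self, truth):
        track = gen_segmentation(truth, seed=2)
        assert len(coalesce(track)) == len(track)

    def test_empirical_transitions_match_generator(self, truth):
        """Conditional transition frequencies of a large track agree with
        the generating matrix within 3 binomial standard errors."""
        probs = default_transition_probs()
        track = gen_segmentation(truth, n_segments=100_000, seed=3)
        tm = transition_matrix(track, coalesce_first=False)
        idx = {s: i for i, s in enumerate(tm.states)}
        outside = 0
        for x in range(1, 10):
            row = tm.observed[idx[x]]
            n_x = row.sum()
            if n_x < 100:
                continue
            for y in range(1, 10):
                p = probs[x - 1, y - 1]
                se = np.sqrt(max(p * (1 - p) / n_x, 1e-12))
                if abs(row[idx[y]] / n_x - p) > 3 * se + 1e-9:
                    outside += 1
        # 3-sigma misses should be rare across the 72 off-diagonal cells
        assert outside <= 2


class TestRegionWorld:
    def test_round_trip_recovers_planted_classes(self, truth):
        world = gen_regions_and_interactions(truth, seed=5)
        track = segmentation_from_candidates(world.candidates, world.genome)
        candidates = merge_state_groups(track)
        regions = classify_regions(candidates, world.tss, world.p300)
        got = sorted((r.id, r.region_class, r.interval.start) for r in regions)
        planted = sorted((r.id, r.region_class, r.interval.start) for r in world.regions)
        assert got == planted

    def test_linking_recovers_planted_associations(self, truth):
        world = gen_regions_and_interactions(truth, seed=6)
        table = link_by_interactions(
            world.regions_of("AE", "PE"),
            world.regions_of("AP", "BP"),
            world.gene_map,
            world.interactions,
        )
        pd.testing.assert_frame_equal(
            table.reset_index(drop=True), world.associations.reset_index(drop=True)
        )

    def test_deterministic(self, truth):
        a = gen_regions_and_interactions(truth, seed=7)
        b = gen_regions_and_interactions(truth, seed=7)
        assert a.interactions == b.interactions
        pd.testing.assert_frame_equal(a.associations, b.associations)


class TestSignalExpression:
    def test_noiseless_limit_recovers_beta(self):
        truth = SyntheticTruth(seed=1, sigma=0.0)
        sim = gen_signal_expression(truth, n_genes=400, seed=2)["c0"]
        ds = assemble_dataset(sim.expression, sim.signal, sim.associations, truth.marks)
        model = fit_linear_model(ds)
        np.testing.assert_allclose(
            model.params[truth.marks].to_numpy(), truth.beta_vector, atol=1e-6
        )
        assert evaluate(model, ds).r == pytest.approx(1.0, abs=1e-9)

    def test_fpkm_nonnegative_and_deterministic(self, truth):
        a = gen_signal_expression(truth, n_genes=200, seed=3)["c0"]
        b = gen_signal_expression(truth, n_genes=200, seed=3)["c0"]
        assert (a.expression >= 0).all()
        pd.testing.assert_series_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.signal, b.signal)

    def test_enhancer_duplication_mode(self, truth):
        sims = gen_signal_expression(
            truth, n_genes=100, enhancers_per_gene="poisson", seed=4
        )
        assoc = sims["c0"].associations
        assert (assoc.groupby("gene_id").size() >= 1).all()
        assert len(assoc) > 100  # some genes have several enhancers

    def test_bivalent_trend_monotone(self):
        truth = SyntheticTruth(seed=2, sigma=0.3)
        sims = gen_signal_expression(truth, n_genes=500, contexts=("t0", "t1", "t2"), seed=8)
        classes = sims["t0"].gene_classes
        biv = classes[classes == "bivalent"].index
        logs = np.column_stack(
            [np.log2(sims[c].expression.loc[biv] + 0.1) for c in ("t0", "t1", "t2")]
        )
        # activated bivalent genes push the group mean upward over contexts
        assert logs.mean(axis=0)[2] > logs.mean(axis=0)[0] + 0.5


class TestBiasedSamples:
    def test_no_bias_no_noise_identity(self):
        base = pd.Series([1.0, 2.0, 4.0])
        out = gen_biased_samples(base, [0.0, 0.0], noise_sd=0.0)
        np.testing.assert_allclose(out["s1"], base)
        np.testing.assert_allclose(out["s2"], base)

    def test_constant_bias_shift(self):
        base = pd.Series([1.0, 2.0, 4.0])
        out = gen_biased_samples(base, [0.0, 2.0], noise_sd=0.0)
        np.testing.assert_allclose(out["s2"], 4.0 * base)


class TestTrajectories:
    def test_info_matches_table(self):
        table, info = gen_expression_trajectories(n_genes=500, seed=0)
        assert len(table) == 500 and (table.to_numpy() > 0).all()
        assert info["activated"].sum() > 0
        assert (info.loc[info["activated"], "slope"] > 0).all()
        assert (info.loc[~info["activated"], "slope"] == 0).all()


class TestReads:
    def test_reads_fall_inside_regions(self, truth, rng):
        from conftest import iv

        regions = [iv("chr1", 1000, 2000), iv("chr1", 5000, 6000)]
        reads = gen_reads(regions, [5.0, 5.0], 100_000, truth.genome, seed=0)
        assert reads
        for r in reads:
            assert any(r.start >= q.start and r.start < q.end for q in regions)


class TestBundle:
    def test_bundle_files_written(self, tmp_path):
        manifest = write_bundle(tmp_path / "b", preset="small", seed=1)
        out = tmp_path / "b"
        for name in (
            "chrom.sizes",
            "segmentation.bed",
            "tss.tsv",
            "p300.bed",
            "interactions.bedpe",
            "candidates.bed",
            "regions_truth.bed",
            "gene_map.tsv",
            "associations_truth.tsv",
            "library_sizes.json",
            "truth.json",
        ):
            assert (out / name).exists(), name
        assert (out / "expression" / "ESC.tsv").exists()
        assert (out / "signal" / "ESC.tsv").exists()
        assert manifest["preset"] == "small"
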