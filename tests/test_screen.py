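"""Jack-knife neighbour screen: sampling, extraction, coverage arithmetic
and scaffold concatenation."""

from __future__ import annotations

import numpy as np
import pytest

from mitoscreen.homology import OrthologDataset
from mitoscreen.screen import (
    ScaffoldMap,
    ScreenConfig,
    extract_mito_neighbours,
    jackknife_sample,
    register_backend,
    run_screen,
    scaffold_concat,
    unsampled_fraction,
)
from mitoscreen.simulate import SimConfig, evaluate_screen, simulate_dataset
from mitoscreen.trees import (
    ENVIRONMENTAL,
    MITOCHONDRIAL,
    OUTGROUP,
    parse_newick,
    reference,
)


def screen_tree():
    """Hand-built rooted tree: outgroup, a SAR11-like reference clade with a
    nested environmental leaf, a Rickettsiales-like clade with an
    environmental leaf, mitochondria, and an environmental lineage on the
    stem above the Rickettsiales+mitochondria pair."""
    t = parse_newick(
        "(((( (R1:1,R2:1):1,(M1:1,(M2:1,Ge:0.5):0.5):1):1,Gs:1.5):1,"
        "((S1:1,(S2:1,Gn:0.4):0.6):1,S3:1):1):1,O1:3);".replace(" ", "")
    )
    t.categories = {
        "R1": reference("Rickettsiales"),
        "R2": reference("Rickettsiales"),
        "S1": reference("SAR11"),
        "S2": reference("SAR11"),
        "S3": reference("SAR11"),
        "M1": MITOCHONDRIAL,
        "M2": MITOCHONDRIAL,
        "Ge": ENVIRONMENTAL,  # inside the mitochondrial clade
        "Gs": ENVIRONMENTAL,  # on the stem above Rickettsiales+mitochondria
        "Gn": ENVIRONMENTAL,  # nested in the SAR11 reference clade
        "O1": OUTGROUP,
    }
    return t


class TestJackknife:
    def test_single_item_pool(self, rng):
        assert jackknife_sample(["x"], 1, rng) == ["x"]

    def test_seed_reproducibility(self):
        pool = [f"g{i}" for i in range(50)]
        a = jackknife_sample(pool, 100, np.random.default_rng(5))
        b = jackknife_sample(pool, 100, np.random.default_rng(5))
        assert a == b

    def test_empty_pool_errors(self, rng):
        with pytest.raises(ValueError):
            jackknife_sample([], 3, rng)

    def test_inclusion_frequency_matches_closed_form(self):
        """Per-id inclusion probability is 1-(1-1/N)^m for draws with
        replacement; checked by Monte Carlo within 3 binomial SE."""
        pool = [f"g{i}" for i in range(50)]
        m, reps = 100, 3000
        rng = np.random.default_rng(42)
        target = "g7"
        hits = sum(
            target in set(jackknife_sample(pool, m, rng)) for _ in range(reps)
        )
        p = 1 - (1 - 1 / 50) ** m
        se = np.sqrt(p * (1 - p) / reps)
        assert abs(hits / reps - p) < 3 * se


class TestUnsampledFraction:
    @pytest.mark.parametrize(
        "n,m,r,expected",
        [(1, 1, 1, 0.0), (2, 1, 1, 0.5), (1040, 100, 100, 6.6e-5)],
    )
    def test_closed_form(self, n, m, r, expected):
        assert unsampled_fraction(n, m, r) == pytest.approx(expected, rel=0.02)

    def test_invalid_pool_errors(self):
        with pytest.raises(ValueError):
            unsampled_fraction(0, 1, 1)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(3)
        for n_pool, m, r in [(10, 10, 1), (100, 10, 10), (1000, 100, 1)]:
            draws = m * r
            trials = 200_000
            counts = rng.binomial(draws, 1.0 / n_pool, size=trials)
            p_mc = float(np.mean(counts == 0))
            p = unsampled_fraction(n_pool, m, r)
            se = np.sqrt(max(p * (1 - p), 1e-12) / trials)
            assert abs(p_mc - p) <= 3 * se + 1e-9


class TestNeighbourExtraction:
    def test_inside_mito_clade_always_flagged(self):
        t = screen_tree()
        assert "Ge" in extract_mito_neighbours(t, "INSIDE_ONLY")
        assert "Ge" in extract_mito_neighbours(t, "INSIDE_PLUS_SISTER")

    def test_stem_lineage_only_in_sister_mode(self):
        t = screen_tree()
        assert "Gs" not in extract_mito_neighbours(t, "INSIDE_ONLY")
        assert "Gs" in extract_mito_neighbours(t, "INSIDE_PLUS_SISTER")

    def test_env_leaf_in_mito_sister_clade_flagged(self):
        # env leaf nested in the Rickettsiales (the mito MRCA's sister)
        t = parse_newick("((((R1:1,Gx:1):1,(M1:1,M2:1):1):1,S1:2):1,O1:3);")
        t.categories = {
            "R1": reference("Rickettsiales"),
            "S1": reference("SAR11"),
            "M1": MITOCHONDRIAL,
            "M2": MITOCHONDRIAL,
            "Gx": ENVIRONMENTAL,
            "O1": OUTGROUP,
        }
        assert "Gx" not in extract_mito_neighbours(t, "INSIDE_ONLY")
        assert "Gx" in extract_mito_neighbours(t, "INSIDE_PLUS_SISTER")

    def test_reference_nested_env_never_flagged(self):
        t = screen_tree()
        for mode in ("INSIDE_ONLY", "INSIDE_PLUS_SISTER"):
            assert "Gn" not in extract_mito_neighbours(t, mode)

    def test_polytomy_sister_is_union_of_siblings(self):
        t = parse_newick("(((M1:1,M2:1):1,Ga:1,Gb:1):1,(S1:1,O1:1):1);")
        t.categories = {
            "M1": MITOCHONDRIAL,
            "M2": MITOCHONDRIAL,
            "Ga": ENVIRONMENTAL,
            "Gb": ENVIRONMENTAL,
            "S1": reference("SAR11"),
            "O1": OUTGROUP,
        }
        flagged = extract_mito_neighbours(t, "INSIDE_PLUS_SISTER")
        assert flagged == {"Ga", "Gb"}

    def test_no_mitochondrial_leaf_errors(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t.categories = {l: ENVIRONMENTAL for l in t.leaf_labels}
        with pytest.raises(ValueError, match="mitochondrial"):
            extract_mito_neighbours(t)

    def test_unrooted_errors(self):
        t = parse_newick("(M1:1,M2:1,G1:1);", rooted=False)
        t.categories = {
            "M1": MITOCHONDRIAL,
            "M2": MITOCHONDRIAL,
            "G1": ENVIRONMENTAL,
        }
        with pytest.raises(ValueError, match="rooted"):
            extract_mito_neighbours(t)


class TestRunScreen:
    def _datasets(self):
        ref = OrthologDataset(
            "m",
            members={"M1": "mitochondrial", "M2": "mitochondrial",
                     "R1": "reference:Rickettsiales", "S1": "reference:SAR11",
                     "O1": "outgroup"},
            sequences={k: "A" * 4 for k in ("M1", "M2", "R1", "S1", "O1")},
            alignment={k: "A" * 4 for k in ("M1", "M2", "R1", "S1", "O1")},
        )
        env = OrthologDataset(
            "m",
            members={"G1": "environmental"},
            sequences={"G1": "AAAA"},
            alignment={"G1": "AAAA"},
        )
        return env, ref

    def test_fixed_backend_flags_planted_neighbour(self):
        fixed = parse_newick(
            "(((M1:1,(M2:1,G1:1):1):1,R1:1):1,(S1:1,O1:1):1);", rooted=False
        )

        def backend(aln, cats):
            t = fixed.copy()
            t.categories = dict(cats)
            return t

        register_backend("fixed-test", backend)
        env, ref = self._datasets()
        res = run_screen(env, ref, ScreenConfig(sample_size=1, replicates=1,
                                                backend="fixed-test"))
        assert res.flagged == {"G1"}
        assert res.times_flagged["G1"] == 1
        assert res.times_sampled["G1"] == 1

    def test_flag_counts_bounded_by_sampling_counts(self):
        sim = simulate_dataset(SimConfig(rng_seed=5, env_pool_size=80))
        env = sim.environmental_dataset("COX1")
        ref = sim.reference_dataset("COX1")
        res = run_screen(env, ref, ScreenConfig(sample_size=30, replicates=5,
                                                rng_seed=5))
        for sid, flags in res.times_flagged.items():
            assert flags <= res.times_sampled[sid]

    def test_bit_identical_under_fixed_seed(self):
        sim = simulate_dataset(SimConfig(rng_seed=5, env_pool_size=60))
        env = sim.environmental_dataset("COB")
        ref = sim.reference_dataset("COB")
        cfg = ScreenConfig(sample_size=20, replicates=3, rng_seed=9)
        a = run_screen(env, ref, cfg)
        b = run_screen(env, ref, cfg)
        assert a.times_sampled == b.times_sampled
        assert a.times_flagged == b.times_flagged
        assert a.flagged == b.flagged

    def test_negative_control_no_planted_clade(self):
        """Without relatives of the mitochondrial clade in the pool (no
        planted clade, no environmental Rickettsiales), the flagged set
        stays empty."""
        profile = {"SAR11": 0.825, "Rhodobacterales": 0.095,
                   "Rhodospirillales": 0.074, "Rhizobiales": 0.006}
        for seed in (1, 2, 3):
            sim = simulate_dataset(
                SimConfig(rng_seed=seed, env_pool_size=80, planted_fraction=0.0,
                          env_order_profile=profile)
            )
            env = sim.environmental_dataset("COX1")
            ref = sim.reference_dataset("COX1")
            res = run_screen(env, ref, ScreenConfig(sample_size=40, replicates=5,
                                                    rng_seed=seed))
            assert res.flagged == frozenset()

    def test_planted_clade_recovered(self):
        sim = simulate_dataset(SimConfig(rng_seed=7, env_pool_size=150))
        flagged = set()
        for marker in sim.config.markers:
            env = sim.environmental_dataset(marker)
            ref = sim.reference_dataset(marker)
            res = run_screen(env, ref, ScreenConfig(sample_size=40, replicates=8,
                                                    rng_seed=7))
            flagged |= res.flagged
        precision, recall = evaluate_screen(flagged, sim)
        assert recall >= 0.9
        assert precision >= 0.8


class TestScaffoldMap:
    def test_sequence_on_two_scaffolds_rejected(self):
        with pytest.raises(ValueError, match="appears on scaffolds"):
            ScaffoldMap({"s1": [("COX1", "g1")], "s2": [("COB", "g1")]})

    def test_tsv_roundtrip(self):
        smap = ScaffoldMap({"s1": [("COX1", "g1"), ("COX2", "g2")],
                            "s2": [("COB", "g3")]})
        import io

        back = ScaffoldMap.read_tsv(io.StringIO(smap.to_tsv()))
        assert back.scaffolds == smap.scaffolds
        assert back.scaffold_of("g3") == "s2"


class TestScaffoldConcat:
    ALN = {
        "COX1": {"g1": "AAAA", "g3": "CCCC", "Ref1": "GGGG"},
        "COX2": {"g2": "TTT", "Ref1": "AAA"},
        "COB": {"g4": "DD", "Ref1": "EE"},
    }

    def test_single_gene_scaffold_dropped(self):
        smap = ScaffoldMap({"s1": [("COX1", "g3")]})
        concat, parts = scaffold_concat({"g3"}, smap, self.ALN)
        assert concat == {} and parts == []

    def test_two_gene_concatenation_conserves_residues(self):
        smap = ScaffoldMap({"s1": [("COX1", "g1"), ("COX2", "g2")]})
        concat, parts = scaffold_concat({"g1"}, smap, self.ALN,
                                        reference_taxa={"Ref1": {
                                            "COX1": "GGGG", "COX2": "AAA"}})
        assert concat["s1"] == "AAAA" + "TTT"
        assert concat["Ref1"] == "GGGG" + "AAA"
        assert parts == [("COX1", 1, 4), ("COX2", 5, 7)]

    def test_three_marker_scaffold_allowed(self):
        smap = ScaffoldMap({"s1": [("COX1", "g1"), ("COX2", "g2"), ("COB", "g4")]})
        concat, parts = scaffold_concat({"g1"}, smap, self.ALN)
        assert len(concat["s1"]) == 4 + 3 + 2
        assert [p[0] for p in parts] == ["COB", "COX1", "COX2"]

    def test_duplicate_marker_paralogy_error(self):
        smap = ScaffoldMap({"s1": [("COX1", "g1"), ("COX1", "g3")]})
        with pytest.raises(ValueError, match="paralogy"):
            scaffold_concat({"g1"}, smap, self.ALN)

    def test_flagged_id_missing_from_map_errors(self):
        smap = ScaffoldMap({"s1": [("COX1", "g1")]})
        with pytest.raises(KeyError, match="absent"):
            scaffold_concat({"zz"}, smap, self.ALN)
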