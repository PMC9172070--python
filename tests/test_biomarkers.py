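import numpy as np
import pandas as pd
import pytest

from lne.biomarkers import (
    LneGeneSet,
    classify_biomarkers,
    common_lne_genes,
    dark_genes,
    export_dnb_subnetwork,
    lne_genes,
)
from lne.entropy import LocalEntropyProfile, SampleScore
from lne.survival import SurvivalRecord


def make_score(sid, stage, gene_scores):
    """gene_scores: gene -> local score; encoded as dE = score, dSD = 1."""
    profiles = [
        LocalEntropyProfile(gene=g, E_ref=0.0, E_mixed=v, dE=v, dSD=1.0)
        for g, v in gene_scores.items()
    ]
    total = float(np.mean([v for v in gene_scores.values()]))
    return SampleScore(sample_id=sid, stage=stage, global_dE=total, profiles=profiles)


class TestLneGenes:
    def test_round_five_percent(self):
        scores = {f"g{i:03d}": float(i) for i in range(100)}
        gs = lne_genes(make_score("s", "I", scores), fraction=0.05)
        assert len(gs.genes) == 5
        assert gs.genes == {"g099", "g098", "g097", "g096", "g095"}

    def test_fraction_one_takes_all(self):
        scores = {f"g{i}": float(i) for i in range(7)}
        gs = lne_genes(make_score("s", "I", scores), fraction=1.0)
        assert len(gs.genes) == 7

    def test_ceiling_rule(self):
        scores = {f"g{i}": float(i) for i in range(10)}
        gs = lne_genes(make_score("s", "I", scores), fraction=0.05)
        assert len(gs.genes) == 1  # ceil(0.5)

    def test_tie_break_lexicographic(self):
        scores = {"b": 1.0, "a": 1.0, "c": 1.0}
        gs = lne_genes(make_score("s", "I", scores), fraction=0.3)
        assert gs.genes == {"a"}

    def test_scale_invariance(self):
        raw = {f"g{i}": float(i + 1) for i in range(20)}
        s1 = lne_genes(make_score("s", "I", raw), fraction=0.2)
        s2 = lne_genes(make_score("s", "I", {g: 17.3 * v for g, v in raw.items()}), fraction=0.2)
        assert s1.genes == s2.genes

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            lne_genes(make_score("s", "I", {"a": 1.0}), fraction=0.0)
        with pytest.raises(ValueError):
            lne_genes(make_score("s", "I", {"a": 1.0}), fraction=1.5)


class TestCommonGenes:
    def _sets(self, *gene_lists, stage="III"):
        return [
            LneGeneSet(f"s{i}", stage, frozenset(gl), 0.05)
            for i, gl in enumerate(gene_lists)
        ]

    def test_intersection(self):
        common = common_lne_genes(self._sets({"A", "B", "C"}, {"B", "C", "D"}), "III")
        assert common == {"B", "C"}

    def test_single_sample_is_own_set(self):
        common = common_lne_genes(self._sets({"A", "B"}), "III")
        assert common == {"A", "B"}

    def test_disjoint_empty_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            common = common_lne_genes(self._sets({"A"}, {"B"}), "III")
        assert common == frozenset()
        assert "empty" in caplog.text

    def test_wrong_stage_errors(self):
        with pytest.raises(ValueError, match="IV"):
            common_lne_genes(self._sets({"A"}), "IV")

    def test_min_fraction_relaxation(self):
        sets = self._sets({"A", "B"}, {"A", "C"}, {"A", "D"}, {"B", "C"})
        assert common_lne_genes(sets, "III", min_fraction=0.75) == {"A"}
        assert common_lne_genes(sets, "III", min_fraction=0.5) == {"A", "B", "C"}


class TestClassifyBiomarkers:
    def _clinical(self, times, events):
        return [SurvivalRecord(f"s{i}", t, e) for i, (t, e) in enumerate(zip(times, events))]

    def _sets(self, memberships, stage="III"):
        return [
            LneGeneSet(f"s{i}", stage, frozenset(gs), 0.05) for i, gs in enumerate(memberships)
        ]

    def test_dominant_with_group_is_optimistic(self):
        sets = self._sets([{"G"}] * 5 + [set()] * 5)
        clinical = self._clinical([20, 21, 22, 23, 24, 1, 2, 3, 4, 5], [1] * 10)
        calls = classify_biomarkers(sets, clinical, candidates={"G"})
        assert calls[0].klass == "O-LNE"
        assert calls[0].direction == "longer"

    def test_short_lived_with_group_is_pessimistic(self):
        sets = self._sets([{"G"}] * 5 + [set()] * 5)
        clinical = self._clinical([1, 2, 3, 4, 5, 20, 21, 22, 23, 24], [1] * 10)
        calls = classify_biomarkers(sets, clinical, candidates={"G"})
        assert calls[0].klass == "P-LNE"
        assert calls[0].direction == "shorter"

    def test_identical_survival_is_neither(self):
        sets = self._sets([{"G"}] * 4 + [set()] * 4)
        clinical = self._clinical([5, 6, 7, 8, 5, 6, 7, 8], [1] * 8)
        calls = classify_biomarkers(sets, clinical, candidates={"G"})
        assert calls[0].klass == "neither"

    def test_empty_group_reported_neutral(self):
        sets = self._sets([{"G"}] * 4)
        clinical = self._clinical([5, 6, 7, 8], [1] * 4)
        calls = classify_biomarkers(sets, clinical, candidates={"G", "ABSENT"})
        by_gene = {c.gene: c for c in calls}
        assert by_gene["ABSENT"].klass == "neither"
        assert by_gene["ABSENT"].direction == "none"
        assert by_gene["ABSENT"].logrank_p == 1.0

    def test_sample_order_stability(self, rng):
        memberships = [{"G"} if rng.random() < 0.5 else set() for _ in range(20)]
        sets = self._sets(memberships)
        times = list(rng.exponential(5, 20) + 0.1)
        clinical = self._clinical(times, [1] * 20)
        calls1 = classify_biomarkers(sets, clinical, candidates={"G"})
        perm = list(rng.permutation(20))
        calls2 = classify_biomarkers([sets[i] for i in perm], clinical, candidates={"G"})
        assert calls1 == calls2

    def test_default_candidates_is_union(self):
        sets = self._sets([{"A", "B"}, {"B", "C"}, set(), set()])
        clinical = self._clinical([1, 2, 3, 4], [1] * 4)
        calls = classify_biomarkers(sets, clinical)
        assert {c.gene for c in calls} == {"A", "B", "C"}


class TestDarkGenes:
    def test_planted_dark_gene_flagged(self):
        # constant-median scale change: DE rank-sum blind, local score shifts
        from lne.entropy import score_cohort
        from lne.synthetic import SimConfig, simulate_network, simulate_study

        cfg = SimConfig(seed=3, sd_crit=2.5, n_per_stage=30,
                        post_trajectory="plateau", anchor_sd_boost=1.0)
        net = simulate_network(cfg)
        study, truth = simulate_study(cfg)
        scores = score_cohort(study, net)
        dark = dark_genes(study, scores, truth.critical_stage, cfg.stages)
        assert dark & set(truth.module_genes)

    def test_differential_expression_not_flagged(self, rng):
        from lne.expression import ExpressionStudy

        genes = ["up", "flat"]
        n_ref, n_case = 10, 10
        ref = rng.normal(0, 1, size=(2, n_ref))
        case = rng.normal(0, 1, size=(2, n_case))
        case[0] += 10.0  # strong expression shift for "up"
        expr = pd.DataFrame(
            np.hstack([ref, case]), index=genes,
            columns=[f"r{i}" for i in range(n_ref)] + [f"s{i}" for i in range(n_case)],
        )
        groups = {f"r{i}": "reference" for i in range(n_ref)} | {f"s{i}": "case" for i in range(n_case)}
        stages = {f"s{i}": "I" if i < 5 else "II" for i in range(n_case)}
        study = ExpressionStudy(expr, groups, stages)
        # strong local-score shift for both genes
        scores = [
            make_score(f"s{i}", stages[f"s{i}"], {"up": 0.1 + (i >= 5), "flat": 0.1 + (i >= 5)})
            for i in range(n_case)
        ]
        dark = dark_genes(study, scores, "II", ["I", "II"])
        assert "up" not in dark

    def test_no_signal_not_flagged(self, rng):
        from lne.expression import ExpressionStudy

        genes = ["a", "b"]
        cols = {f"r{i}": rng.normal(size=2) for i in range(5)}
        cols |= {f"s{i}": rng.normal(size=2) for i in range(6)}
        expr = pd.DataFrame(cols, index=genes)
        groups = {f"r{i}": "reference" for i in range(5)} | {f"s{i}": "case" for i in range(6)}
        stages = {f"s{i}": "I" if i < 3 else "II" for i in range(6)}
        study = ExpressionStudy(expr, groups, stages)
        scores = [
            make_score(f"s{i}", stages[f"s{i}"], {"a": rng.random(), "b": rng.random()})
            for i in range(6)
        ]
        dark = dark_genes(study, scores, "II", ["I", "II"])
        assert dark == frozenset()

    def test_insufficient_samples(self, tiny_study):
        with pytest.raises(ValueError, match=">= 3"):
            dark_genes(tiny_study, [], "late", ["early", "late"])


class TestDnbExport:
    def test_export_attrs(self, tmp_path, rng):
        import networkx as nx

        from lne.network import GeneNetwork

        net = GeneNetwork([("A", "B"), ("B", "C"), ("C", "D")])
        expr = pd.DataFrame(rng.normal(size=(4, 6)), index=["A", "B", "C", "D"])
        scores = [make_score("s1", "III", {"A": 1.0, "B": 2.0, "C": 3.0, "D": 0.5})]
        sub = export_dnb_subnetwork(
            net, {"A", "B", "C"}, scores, expr,
            tmp_path / "dnb.sif", tmp_path / "dnb.graphml",
        )
        assert sub.nodes == {"A", "B", "C"}
        g = nx.read_graphml(tmp_path / "dnb.graphml")
        assert g.nodes["B"]["mean_local_score"] == 2.0
        assert 0.0 <= g.edges["A", "B"]["abs_pcc"] <= 1.0
        assert (tmp_path / "dnb.sif").read_text().splitlines() == ["A\tpp\tB", "B\tpp\tC"]
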