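"""Synthetic trees, alignments, rules, assays, and the full study bundle."""

import filecmp

import numpy as np
import pytest
from scipy.linalg import expm

import tpsevo as t
from tpsevo.simulate import (ANCESTRAL_RESIDUES, CLASS_RESIDUES, SITE_CONTROL,
                             SITE_LETHAL, SITE_NEIGHBOR, SITE_SWITCH)


def scripted_sequence(cls="basal", overrides=None, L=850):
    seq = ["A"] * L
    for pos, res in ANCESTRAL_RESIDUES.items():
        seq[pos - 1] = res
    for pos, res in CLASS_RESIDUES[cls].items():
        seq[pos - 1] = res
    for pos, res in (overrides or {}).items():
        seq[pos - 1] = res
    return "".join(seq)


class TestSimulateTree:
    def test_two_tips_is_a_cherry(self):
        tree = t.simulate_tree(2, seed=0)
        assert len(tree.leaf_nodes()) == 2
        assert len(tree.internal_nodes()) == 1

    def test_sixteen_tips_fifteen_internal_nodes(self):
        tree = t.simulate_tree(16, seed=1)
        assert len(tree.leaf_nodes()) == 16
        assert len(tree.internal_nodes()) == 15

    def test_deterministic_newick(self):
        nwk = lambda s: t.simulate_tree(8, seed=s).as_string(schema="newick")
        assert nwk(42) == nwk(42)
        assert nwk(42) != nwk(43)

    def test_branch_lengths_in_range(self):
        tree = t.simulate_tree(10, branch_range=(0.05, 0.2), seed=3)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert 0.05 <= edge.length <= 0.2


class TestSimulateAlignment:
    def test_zero_branches_copy_the_root(self, jtt):
        tree = t.simulate_tree(4, branch_range=(0.0, 0.0), seed=0)
        sim = t.simulate_alignment(tree, jtt, 30, seed=1)
        seqs = set(sim.alignment.values()) | set(sim.ancestors.values())
        assert len(seqs) == 1

    def test_deterministic(self, jtt):
        tree = t.simulate_tree(5, seed=2)
        a = t.simulate_alignment(tree, jtt, 40, seed=9)
        b = t.simulate_alignment(tree, jtt, 40, seed=9)
        assert a.alignment == b.alignment and a.ancestors == b.ancestors

    def test_substitution_counts_match_transition_probabilities(self):
        # long single branch: empirical A->X counts vs the matrix exponential
        model = t.SubstitutionModel.jtt(K=1)
        tree = t.simulate_tree(2, branch_range=(0.5, 0.5), seed=0)
        L = 4000
        sim = t.simulate_alignment(tree, model, L, seed=4)
        root = sim.ancestors[tree.seed_node.label]
        tip = sim.alignment[tree.leaf_nodes()[0].taxon.label]
        P = expm(model.rate_matrix * 0.5)
        i_a = t.ALPHABET.index("A")
        sites = [s for s in range(L) if root[s] == "A"]
        stayed = sum(tip[s] == "A" for s in sites)
        p = P[i_a, i_a]
        se = np.sqrt(p * (1 - p) * len(sites))
        assert abs(stayed - p * len(sites)) <= 3 * se


class TestRules:
    rules = t.default_rules()

    def test_default_background_is_abietane_dominant(self):
        comp = t.phenotype_from_genotype(scripted_sequence("basal"), self.rules)
        assert comp["levopimaradiene"] == pytest.approx(0.8)

    def test_723_switch_is_iso_dominant_in_derived_class(self):
        seq = scripted_sequence("genus", {SITE_SWITCH: "T"})
        comp = t.phenotype_from_genotype(seq, self.rules)
        assert comp["isopimaradiene"] == pytest.approx(0.9)

    def test_723_switch_is_weak_in_basal_class(self):
        seq = scripted_sequence("basal", {SITE_SWITCH: "T"})
        comp = t.phenotype_from_genotype(seq, self.rules)
        assert comp["isopimaradiene"] < 0.2

    def test_833_lethal_without_724_and_rescued_with_it(self):
        lethal = scripted_sequence("basal", {SITE_LETHAL: "Y"})
        assert t.phenotype_from_genotype(lethal, self.rules) is None
        rescued = scripted_sequence("basal", {SITE_LETHAL: "Y",
                                                SITE_NEIGHBOR: "G"})
        assert t.phenotype_from_genotype(rescued, self.rules) is not None

    def test_control_shift_is_identical_across_classes(self):
        deltas = {}
        for cls in ("basal", "pinaceae", "genus"):
            bg = t.phenotype_from_genotype(scripted_sequence(cls), self.rules)
            mut = t.phenotype_from_genotype(
                scripted_sequence(cls, {SITE_CONTROL: "V"}), self.rules)
            vocab = set(bg) | set(mut)
            deltas[cls] = {p: mut.get(p, 0) - bg.get(p, 0) for p in vocab
                           if mut.get(p, 0) != bg.get(p, 0)}
        assert deltas["basal"] == deltas["pinaceae"] == deltas["genus"]

    def test_first_matching_rule_wins(self):
        # 833Y + 724L matches the lethal rule before any other
        seq = scripted_sequence("genus", {SITE_LETHAL: "Y", SITE_SWITCH: "T"})
        assert t.phenotype_from_genotype(seq, self.rules) is None


class TestSimulateAssays:
    def test_huge_kappa_recovers_base_composition(self):
        base = {"isopimaradiene": 0.9, "sandaracopimaradiene": 0.1}
        noise = t.AssayNoiseModel(kappa=1e9)
        table = t.simulate_assays(base, n_replicates=3, noise=noise, seed=0)
        for comp in t.relative_abundances(table):
            for prod, frac in base.items():
                assert comp.as_dict()[prod] == pytest.approx(frac, abs=1e-3)

    def test_inactive_round_trip(self):
        table = t.simulate_assays(None, n_replicates=3, seed=0)
        comps = t.relative_abundances(table)
        assert all(not c.active for c in comps)

    def test_replicate_means_near_base_at_study_noise(self):
        # Dirichlet moment check: kappa=200, n=3 replicate means stay close
        base = {"isopimaradiene": 0.45, "sandaracopimaradiene": 0.34,
                "isopimara-8,15-diene": 0.21}
        noise = t.AssayNoiseModel(kappa=200.0)
        errs = []
        for trial in range(100):
            table = t.simulate_assays(base, n_replicates=3, noise=noise,
                                      seed=trial)
            prof = t.replicate_summary(t.relative_abundances(table))
            errs.append(max(abs(prof.as_dict()[p] - base[p]) for p in base))
        assert np.mean(errs) <= 0.05

    def test_zero_base_products_stay_zero(self):
        base = {"isopimaradiene": 1.0}
        table = t.simulate_assays(base, n_replicates=2, seed=1)
        comp = t.relative_abundances(table)[0]
        assert comp.as_dict()["sandaracopimaradiene"] == 0.0


class TestMakeStudy:
    def test_trajectory_on_true_values_reproduces_manifest(self, study):
        mask = study.config.alpha_mask
        ancestors = [(a, study.ancestors[a]) for a in study.manifest["ancestors"]]
        for suffix in ("1", "2"):
            profs = {}
            for i, (anc, _) in enumerate(ancestors):
                comp = study.manifest["true_compositions"][f"M{i + 1}-{suffix}"]
                if comp is not None:
                    vocab = tuple(comp)
                    mean = np.array([comp[p] for p in vocab])
                    profs[anc] = t.ProductProfile(anc, vocab, mean / mean.sum(),
                                                  np.zeros(len(vocab)), 3, True)
            pts = t.iso_trajectory(ancestors, profs, site_mask=mask,
                                   numbering=study.numbering)
            truth = study.manifest["trajectories"][suffix]
            assert [p.x for p in pts] == [q["x"] for q in truth]
            for p, q in zip(pts, truth):
                assert p.mean == pytest.approx(q["true_focal"])

    def test_planted_fold_changes_at_the_switch(self, study):
        truth = study.manifest["trajectories"]
        basal_last, switch = 3, 4  # Anc4 (basal) -> Anc5 (intermediate)
        fold_t = truth["1"][switch]["true_focal"] / truth["1"][basal_last]["true_focal"]
        fold_s = truth["2"][switch]["true_focal"] / truth["2"][basal_last]["true_focal"]
        assert fold_t == pytest.approx(2.0)
        assert fold_s == pytest.approx(1.8)

    def test_hamming_intervals_match_manifest(self, study):
        ids = study.manifest["ancestors"]
        mask = study.config.alpha_mask
        got = [t.hamming_distance(study.ancestors[a], study.ancestors[b],
                                  site_mask=mask, numbering=study.numbering)
               for a, b in zip(ids, ids[1:])]
        assert got == study.manifest["intervals"]
        assert t.hamming_distance(study.ancestors[ids[0]],
                                  study.ancestors[ids[3]], site_mask=mask,
                                  numbering=study.numbering) == 113

    def test_bundle_is_byte_identical_given_seed(self, tmp_path):
        for name in ("one", "two"):
            t.make_study(seed=5).write(tmp_path / name)
        files = ["tree.nwk", "tips.fasta", "ancestors.fasta", "variants.fasta",
                 "variants.json", "regions.json", "peaks.csv", "manifest.json"]
        match, mismatch, errors = filecmp.cmpfiles(tmp_path / "one",
                                                   tmp_path / "two", files,
                                                   shallow=False)
        assert mismatch == [] and errors == []

    def test_planted_mutation_has_top_divergence_rank(self, study):
        # across the backgrounds straddling the class switch, the planted
        # 723 switch outranks every other comparable mutation
        profiles = t.profiles_from_table(study.peak_table)
        scores = {}
        for suffix, _ in study.config.mutation_sets:
            effs = []
            for bg_i in (4, 5):  # Anc4 and Anc5
                bg = profiles[f"Anc{bg_i}"]
                mut = profiles[f"M{bg_i}-{suffix}"]
                if not mut.active:
                    break
                effs.append(t.mutation_effect(bg, mut, code=suffix))
            if len(effs) == 2:
                scores[suffix] = t.effect_divergence(*effs)
        assert max(scores, key=scores.get) in ("1", "2")
        assert scores["1"] > scores["6"]  # planted beats the additive control

    def test_pipeline_tree_is_valid_phylo_instance(self, study):
        inst = t.PhyloInstance.from_strings(
            study.newick, "".join(f">{k}\n{v}\n"
                                  for k, v in study.tip_alignment.items()))
        assert inst.L == study.config.L

    def test_chimera_full_swap_equals_donor_phenotype(self, study):
        full = study.variant_sequences[f"M{study.config.n_ancestors - 1}-9"]
        donor = study.ancestors[study.manifest["ancestors"][-1]]
        assert t.phenotype_from_genotype(full, study.rules, study.numbering) \
            == t.phenotype_from_genotype(donor, study.rules, study.numbering)


class TestPlantedEpistasisExperiment:
    def test_planted_outranks_control_with_noise(self):
        exp = t.planted_epistasis_experiment(n_replicates=25, seed=3)
        assert exp.success_rate >= 0.95
        assert np.median(exp.planted_divergences) > np.median(
            exp.control_divergences)
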