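"""Signature decomposition, set formation, consensus and the combine loop."""

import itertools

import numpy as np
import pandas as pd
import pytest

import pancansig as ps
from pancansig.combiner import (COSINE_THRESHOLD, ExtractedSignature,
                                ReferenceSet, admit_next, build_sets,
                                combine_all, combine_set, composability_audit,
                                decompose)
from pancansig.extraction import cosine_similarity


def make_reference(profiles: dict[str, np.ndarray]) -> ReferenceSet:
    return ReferenceSet(pd.DataFrame(profiles))


@pytest.fixture
def orthogonal_reference():
    return make_reference({
        "R1": np.array([1.0, 0.0, 0.0, 0.0]),
        "R2": np.array([0.0, 1.0, 0.0, 0.0]),
    })


class TestDecompose:
    def test_reference_member_reconstructs_itself(self, orthogonal_reference):
        dec = decompose(np.array([1.0, 0.0, 0.0, 0.0]), orthogonal_reference)
        assert dec.cosine == pytest.approx(1.0)
        assert dec.decomposable
        assert dec.weights["R1"] == pytest.approx(1.0, abs=1e-9)
        assert dec.weights["R2"] == pytest.approx(0.0, abs=1e-9)

    def test_mixture_of_two_members(self, orthogonal_reference):
        dec = decompose(np.array([0.5, 0.5, 0.0, 0.0]), orthogonal_reference)
        assert dec.cosine > 0.999
        assert dec.weights["R1"] == pytest.approx(0.5, abs=1e-9)
        assert dec.weights["R2"] == pytest.approx(0.5, abs=1e-9)

    def test_disjoint_support_not_decomposable(self, orthogonal_reference):
        dec = decompose(np.array([0.0, 0.0, 0.5, 0.5]), orthogonal_reference)
        assert dec.cosine < COSINE_THRESHOLD
        assert not dec.decomposable

    def test_empty_reference(self):
        empty = ReferenceSet(pd.DataFrame(index=range(4)))
        dec = decompose(np.array([0.25] * 4), empty)
        assert dec.cosine == 0.0 and not dec.decomposable


def _sig(name, cohort, profile, var=None):
    return ExtractedSignature(name, cohort, np.asarray(profile, dtype=float),
                              None if var is None else np.asarray(var, dtype=float))


def brute_force_sets(signatures):
    """Independent re-implementation of the pairing rules by direct scan."""
    pairs = []
    for i, j in itertools.combinations(range(len(signatures)), 2):
        sim = cosine_similarity(signatures[i].profile, signatures[j].profile)
        pairs.append((sim, i, j))
    pairs.sort(key=lambda t: (-t[0],
                              (signatures[t[1]].cohort, signatures[t[1]].name),
                              (signatures[t[2]].cohort, signatures[t[2]].name)))
    sets, assigned = [], {}
    for sim, i, j in pairs:
        if sim <= 0.8:
            continue
        if i not in assigned and j not in assigned:
            if signatures[i].cohort != signatures[j].cohort:
                sets.append([i, j])
                assigned[i] = assigned[j] = len(sets) - 1
        elif (i in assigned) != (j in assigned):
            a, f = (i, j) if i in assigned else (j, i)
            members = sets[assigned[a]]
            ok = all(cosine_similarity(signatures[f].profile,
                                       signatures[m].profile) > 0.8
                     for m in members)
            ok = ok and all(signatures[m].cohort != signatures[f].cohort
                            for m in members)
            if ok:
                members.append(f)
                assigned[f] = assigned[a]
    return [{(signatures[m].cohort, signatures[m].name) for m in s} for s in sets]


class TestBuildSets:
    def test_cross_cohort_pair_forms_a_set(self):
        p = np.array([0.7, 0.3, 0.0])
        sets = build_sets([_sig("a", "breast", p), _sig("b", "lung", p + 0.01)])
        assert len(sets) == 1 and len(sets[0]) == 2

    def test_same_cohort_pair_forms_no_set(self):
        p = np.array([0.7, 0.3, 0.0])
        sets = build_sets([_sig("a", "breast", p), _sig("b", "breast", p + 0.01)])
        assert sets == []

    def test_three_cohorts_one_set_matches_brute_force(self):
        p = np.array([0.6, 0.3, 0.1])
        sigs = [_sig("a", "breast", p), _sig("b", "lung", p * [1.02, 0.98, 1.0]),
                _sig("c", "colon", p * [0.98, 1.03, 1.0])]
        sets = build_sets(sigs)
        assert len(sets) == 1 and len(sets[0]) == 3
        assert brute_force_sets(sigs) == [
            {(m.cohort, m.name) for m in s} for s in sets]

    def test_random_fixtures_match_brute_force(self):
        rng = np.random.default_rng(77)
        cohorts = ["breast", "lung", "colon", "ovary"]
        for trial in range(10):
            sigs = []
            base_profiles = rng.dirichlet(np.full(6, 0.3), size=3)
            for c, cohort in enumerate(cohorts):
                for b in range(rng.integers(1, 3)):
                    base = base_profiles[rng.integers(0, 3)]
                    prof = base + rng.uniform(0, 0.05, 6)
                    sigs.append(_sig(f"s{trial}_{c}_{b}", cohort, prof))
            assert brute_force_sets(sigs) == [
                {(m.cohort, m.name) for m in s} for s in build_sets(sigs)]


class TestCombineSet:
    def test_identical_members(self):
        p = np.array([0.6, 0.4])
        out = combine_set([_sig("a", "x", p), _sig("b", "y", p)])
        np.testing.assert_allclose(out, p, atol=1e-12)

    def test_equal_variances_give_arithmetic_mean(self):
        out = combine_set([_sig("a", "x", [0.8, 0.2], [0.01, 0.01]),
                           _sig("b", "y", [0.6, 0.4], [0.01, 0.01])])
        np.testing.assert_allclose(out, [0.7, 0.3], atol=1e-12)

    def test_inverse_variance_hand_arithmetic(self):
        """(0.8,0.2)@var0.01 with (0.6,0.4)@var0.04 -> weights 100 vs 25 ->
        channelwise (0.76, 0.24), already normalized."""
        out = combine_set([_sig("a", "x", [0.8, 0.2], [0.01, 0.01]),
                           _sig("b", "y", [0.6, 0.4], [0.04, 0.04])])
        np.testing.assert_allclose(out, [0.76, 0.24], atol=1e-12)

    def test_zero_variance_floor(self):
        out = combine_set([_sig("a", "x", [0.9, 0.1], [0.0, 0.0]),
                           _sig("b", "y", [0.5, 0.5], [0.0, 0.0])])
        np.testing.assert_allclose(out.sum(), 1.0)


class TestAdmitNext:
    def test_least_similar_set_admitted(self, orthogonal_reference):
        near = [_sig("a", "x", [0.9, 0.1, 0.0, 0.0]),
                _sig("b", "y", [0.88, 0.12, 0.0, 0.0])]       # close to R1
        far = [_sig("c", "x", [0.0, 0.0, 0.5, 0.5]),
               _sig("d", "y", [0.0, 0.0, 0.52, 0.48])]        # orthogonal to both
        ref = admit_next([near, far], orthogonal_reference, "NEW1")
        new = ref.signatures["NEW1"].to_numpy()
        assert new[2] > 0.4 and new[0] == pytest.approx(0.0, abs=1e-9)
        assert ref.provenance["NEW1"] == "new"
        # admitted signature decomposes against the updated reference exactly
        assert decompose(new, ref).cosine == pytest.approx(1.0)


class TestCombineAll:
    def test_already_decomposable_reference_unchanged(self, orthogonal_reference):
        sigs = {"breast": [_sig("a", "breast", [0.95, 0.05, 0.0, 0.0])]}
        res = combine_all(sigs, orthogonal_reference)
        assert res.admitted == []
        assert res.reference.names == orthogonal_reference.names

    def test_planted_novel_signature_recovered_once(self):
        rng = np.random.default_rng(5)
        ref_df = ps.gen_reference_signatures(24, 5, 0.1, seed=31, prefix="R")
        reference = ReferenceSet(ref_df)
        novel = ps.gen_reference_signatures(24, 1, 0.1, seed=901).to_numpy()[:, 0]
        while decompose(novel, reference).decomposable:  # pragma: no cover
            novel = rng.dirichlet(np.full(24, 0.1))
        cohorts = {}
        for cohort in ("breast", "lung", "colon"):
            noisy = novel + rng.uniform(0, 0.003, 24)
            cohorts[cohort] = [
                _sig(f"{cohort}_novel", cohort, noisy),
                _sig(f"{cohort}_known", cohort,
                     ref_df.iloc[:, 0].to_numpy() + rng.uniform(0, 0.001, 24)),
            ]
        res = combine_all(cohorts, reference)
        assert len(res.admitted) == 1
        recovered = res.reference.signatures[res.admitted[0]].to_numpy()
        assert cosine_similarity(recovered, novel) > 0.95
        assert all(d.decomposable for d in res.decompositions.values())
        # idempotence: rerunning on the final reference admits nothing
        res2 = combine_all(cohorts, res.reference)
        assert res2.admitted == []

    def test_singleton_admitted_directly(self, orthogonal_reference):
        lone = _sig("only", "breast", [0.0, 0.0, 0.0, 1.0])
        res = combine_all({"breast": [lone]}, orthogonal_reference)
        assert len(res.admitted) == 1
        assert all(d.decomposable for d in res.decompositions.values())

    def test_termination_bound(self):
        """Iterations never exceed initially-non-decomposable count + 1."""
        reference = ReferenceSet(pd.DataFrame(
            {"R1": np.eye(6)[0], "R2": np.eye(6)[1]}))
        cohorts = {
            "a": [_sig("a1", "a", np.eye(6)[2]), _sig("a2", "a", np.eye(6)[3])],
            "b": [_sig("b1", "b", np.eye(6)[4])],
        }
        res = combine_all(cohorts, reference)
        assert res.iterations <= 3 + 1
        assert all(d.decomposable for d in res.decompositions.values())

    def test_planted_recovery_across_seeds(self):
        """Novel-signature recovery succeeds in >= 90% of seeded replicates."""
        successes = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            reference = ReferenceSet(
                ps.gen_reference_signatures(24, 5, 0.1, seed=200 + seed, prefix="R"))
            novel = rng.dirichlet(np.full(24, 0.1))
            if decompose(novel, reference).decomposable:
                successes += 1  # nothing to recover; trivially consistent
                continue
            cohorts = {c: [_sig(f"{c}_n", c, novel + rng.uniform(0, 0.003, 24))]
                       for c in ("x", "y")}
            res = combine_all(cohorts, reference)
            if len(res.admitted) == 1:
                rec = res.reference.signatures[res.admitted[0]].to_numpy()
                if cosine_similarity(rec, novel) > 0.95:
                    successes += 1
        assert successes >= 18


class TestComposabilityAudit:
    def test_orthogonal_signatures_not_composable(self, orthogonal_reference):
        audit = composability_audit(orthogonal_reference)
        assert not audit["composable"].any()

    def test_mixture_is_composable(self):
        ref = make_reference({
            "A": np.array([0.9, 0.1, 0.0, 0.0]),
            "B": np.array([0.0, 0.0, 0.1, 0.9]),
            "mix": np.array([0.45, 0.05, 0.05, 0.45]),
        })
        audit = composability_audit(ref)
        assert audit.loc["mix", "composable"]
        assert audit.loc["mix", "cosine"] > 0.999

    def test_duplicate_is_composable_with_cosine_one(self):
        p = np.array([0.3, 0.3, 0.4, 0.0])
        audit = composability_audit(make_reference({"A": p, "Adup": p.copy(),
                                                    "B": np.eye(4)[3]}))
        assert audit.loc["A", "cosine"] == pytest.approx(1.0)
        assert audit.loc["Adup", "composable"]

    def test_requires_two_signatures(self):
        with pytest.raises(ValueError):
            composability_audit(make_reference({"A": np.array([0.5, 0.5])}))
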