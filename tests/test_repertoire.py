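"""Duration-balanced ensembles, chance-corrected similarity, families, consensus."""

import numpy as np
import pytest

from slnets import (
    NetworkState,
    StateEnsemble,
    build_ensembles,
    consensus_families,
    detect_families,
    significant_similarity,
)

from .oracles import brute_force_best_modularity, newman_girvan_q


def make_state(rep, dur=100.0, subject="s0", cluster=0):
    return NetworkState(
        cluster=cluster,
        start=0,
        end=int(dur // 2) - 1,
        duration_ms=dur,
        representative=np.asarray(rep, dtype=float),
        subject=subject,
    )


def sparse_vec(support, n=45, value=0.6, seed=None):
    v = np.zeros(n)
    v[list(support)] = value
    if seed is not None:
        v += 0.02 * np.random.default_rng(seed).random(n)
    return v


@pytest.fixture
def three_family_states():
    """Three planted topographies across 3 subjects, several states each."""
    protos = [range(0, 10), range(15, 25), range(30, 40)]
    states_by_subject = {}
    idx = 0
    for subj in ("s0", "s1", "s2"):
        states = []
        for fam in range(3):
            for rep in range(4):
                states.append(
                    make_state(
                        sparse_vec(protos[fam], seed=idx),
                        dur=80.0 + 10 * rep,
                        subject=subj,
                        cluster=fam,
                    )
                )
                idx += 1
        states_by_subject[subj] = states
    return states_by_subject


class TestBuildEnsembles:
    def test_target_time_is_min_total_over_four(self):
        sbs = {
            "a": [make_state(sparse_vec([0]), dur=1000.0)],
            "b": [make_state(sparse_vec([1]), dur=2000.0)],
            "c": [make_state(sparse_vec([2]), dur=4000.0)],
        }
        ens = build_ensembles(sbs, n_ensembles=3, seed=0)
        assert ens[0].target_time == 250.0

    def test_single_large_state_contributes_exactly_once(self):
        sbs = {
            "a": [make_state(sparse_vec([0]), dur=300.0, subject="a")],
            "b": [make_state(sparse_vec([1]), dur=1000.0, subject="b")],
        }
        (e,) = build_ensembles(sbs, n_ensembles=1, seed=0)
        a_states = [s for s in e.states if s.subject == "a"]
        assert len(a_states) == 1

    def test_sampled_totals_exceed_target_everywhere(self, three_family_states):
        ensembles = build_ensembles(three_family_states, n_ensembles=100, seed=1)
        for e in ensembles:
            for subj, tot in e.sampled_totals.items():
                assert tot > e.target_time

    def test_zero_duration_subject_excluded_with_warning(self):
        sbs = {
            "a": [make_state(sparse_vec([0]), dur=100.0)],
            "b": [make_state(sparse_vec([1]), dur=100.0)],
            "z": [],
        }
        with pytest.warns(UserWarning, match="excluding"):
            ens = build_ensembles(sbs, n_ensembles=1, seed=0)
        assert "z" not in ens[0].subjects

    def test_bounded_overshoot(self, three_family_states):
        ensembles = build_ensembles(three_family_states, n_ensembles=20, seed=2)
        for e in ensembles:
            max_single = max(s.duration_ms for subj in three_family_states
                             for s in three_family_states[subj])
            for tot in e.sampled_totals.values():
                assert tot <= e.target_time + max_single


class TestSignificantSimilarity:
    def _ensemble(self, reps):
        states = [make_state(r) for r in reps]
        return StateEnsemble(
            states=states,
            subjects=["s0"],
            sampled_totals={"s0": 100.0 * len(reps)},
            target_time=50.0,
        )

    def test_identical_sparse_vectors_significant(self):
        v = sparse_vec(range(5), seed=1)
        ens = self._ensemble([v, v.copy()])
        binary = significant_similarity(ens, n_perm=1000, alpha=1e-6, seed=0)
        assert binary[0, 1] == 1

    def test_disjoint_supports_not_significant(self):
        ens = self._ensemble(
            [sparse_vec(range(5), seed=1), sparse_vec(range(20, 25), seed=2)]
        )
        binary = significant_similarity(ens, n_perm=500, alpha=1e-6, seed=0)
        assert binary[0, 1] == 0

    def test_constant_vectors_never_significant(self):
        with pytest.warns(UserWarning, match="constant"):
            binary = significant_similarity(
                self._ensemble([np.full(45, 0.3), np.full(45, 0.3)]),
                n_perm=200,
                alpha=1e-6,
                seed=0,
            )
        assert binary[0, 1] == 0


class TestDetectFamilies:
    def test_three_blocks_recovered(self):
        n = 9
        binary = np.zeros((n, n), dtype=int)
        for b in range(3):
            sl = slice(3 * b, 3 * b + 3)
            binary[sl, sl] = 1
        np.fill_diagonal(binary, 0)
        part = detect_families(binary, seed=0)
        assert part.n_families == 3
        for b in range(3):
            assert len(set(part.labels[3 * b : 3 * b + 3])) == 1

    def test_complete_graph_single_family(self):
        binary = 1 - np.eye(6, dtype=int)
        part = detect_families(binary, seed=0)
        assert part.n_families == 1

    def test_empty_graph_singletons_flagged(self):
        part = detect_families(np.zeros((5, 5), dtype=int), seed=0)
        assert part.flagged_empty
        assert part.n_families == 5

    def test_matches_exhaustive_modularity_on_8_states(self, rng):
        binary = np.zeros((8, 8), dtype=int)
        for block in (range(4), range(4, 8)):
            for a in block:
                for b in block:
                    if a != b:
                        binary[a, b] = 1
        binary[0, 4] = binary[4, 0] = 1
        part = detect_families(binary, seed=0)
        _, best_q = brute_force_best_modularity(binary.astype(float))
        q = newman_girvan_q(binary.astype(float), part.labels)
        assert q == pytest.approx(best_q, abs=1e-9)


class TestConsensusFamilies:
    def _family_partition(self, topos, sizes):
        from slnets.repertoire import FamilyPartition

        labels = np.concatenate(
            [np.full(s, i) for i, s in enumerate(sizes)]
        )
        return FamilyPartition(labels=labels, topographies=np.stack(topos))

    def test_three_planted_families_across_ensembles(self):
        protos = [sparse_vec(range(0, 10)), sparse_vec(range(15, 25)),
                  sparse_vec(range(30, 40))]
        partitions = [
            self._family_partition(
                [p + 0.01 * np.random.default_rng(e * 3 + i).random(45)
                 for i, p in enumerate(protos)],
                [4, 4, 4],
            )
            for e in range(3)
        ]
        consensus = consensus_families(partitions, seed=0)
        assert consensus.n_meta == 3
        # each meta-family contains exactly one family per ensemble
        for m in range(3):
            sel = consensus.meta_of_family == m
            assert sorted(consensus.family_ensemble[sel].tolist()) == [0, 1, 2]

    def test_identical_topographies_single_meta_family(self):
        proto = sparse_vec(range(5))
        partitions = [
            self._family_partition([proto.copy(), proto.copy()], [3, 3])
            for _ in range(2)
        ]
        consensus = consensus_families(partitions, seed=0)
        assert consensus.n_meta == 1

    def test_orthogonal_topographies_no_merging(self):
        partitions = [
            self._family_partition([sparse_vec([0, 1])], [5]),
            self._family_partition([sparse_vec([10, 11])], [5]),
        ]
        consensus = consensus_families(partitions, seed=0)
        assert consensus.n_meta == 2

    def test_single_ensemble_identity(self):
        part = self._family_partition(
            [sparse_vec([0]), sparse_vec([5])], [2, 2]
        )
        consensus = consensus_families([part], seed=0)
        assert consensus.n_meta == 2
        assert consensus.state_fraction.sum() == pytest.approx(1.0)
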