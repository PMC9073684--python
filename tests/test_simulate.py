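import dataclasses

import numpy as np
import pytest

from sirescan import (SimParams, scan_alignment, simulate_duplication_noise,
                      simulate_families, simulate_family, to_newick)
from sirescan.spectrum import bin_variants, pool_bins, vnvs_curve

SMALL = SimParams(max_elements=40, turnover_generations=20, seed=7)


class TestDeterminismAndGenealogy:
    def test_fixed_seed_reproduces_bit_identical_output(self):
        a = simulate_family(SMALL)
        b = simulate_family(SMALL)
        assert np.array_equal(a.alignment.codes, b.alignment.codes)
        assert a.alignment.ids == b.alignment.ids
        assert a.mutations.equals(b.mutations)

    def test_different_seed_differs(self):
        a = simulate_family(SMALL)
        b = simulate_family(dataclasses.replace(SMALL, seed=8))
        assert not np.array_equal(a.alignment.codes, b.alignment.codes)

    def test_genealogy_is_a_valid_tree(self):
        res = simulate_family(SMALL)
        assert res.parents[0] == -1
        for child in range(1, len(res.parents)):
            parent = res.parents[child]
            assert 0 <= parent < child
            assert res.birth_generation[parent] < \
                res.birth_generation[child]

    def test_final_population_size(self):
        res = simulate_family(SMALL)
        assert res.alignment.n_sequences == SMALL.max_elements

    def test_newick_export_parses(self):
        import io

        from Bio import Phylo

        res = simulate_family(dataclasses.replace(
            SMALL, max_elements=12, turnover_generations=4))
        tree = Phylo.read(io.StringIO(to_newick(res)), "newick")
        leaves = {leaf.name for leaf in tree.get_terminals()}
        assert leaves == set(res.ids)

    def test_mutation_truth_table_consistent_with_loads(self):
        res = simulate_family(SMALL)
        per_element = res.mutations[
            res.mutations["status"] == "deleterious"
        ].groupby("element_id").size()
        for idx, eid in enumerate(res.ids):
            own = int(per_element.get(eid, 0))
            parent = res.parents[idx]
            inherited = 0 if parent < 0 else res.n_deleterious[parent]
            assert res.n_deleterious[idx] == inherited + own


class TestParams:
    @pytest.mark.parametrize("bad", [
        {"f": 1.5}, {"s": -0.1}, {"u": 0}, {"L": 10}, {"mode": "both"},
        {"growth": "magic"}, {"base_rate": 0}, {"loss_rate": 1.0},
        {"turnover_generations": -1},
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            dataclasses.replace(SMALL, **bad)

    def test_ancestral_sequence_respected(self):
        anc = tuple(["TTT"] * 500)
        res = simulate_family(dataclasses.replace(
            SMALL, ancestral_sequence=anc, u=1e-6,
            turnover_generations=0))
        assert res.alignment.column(0) == ["TTT"] * res.alignment.n_sequences

    def test_ancestral_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            simulate_family(dataclasses.replace(
                SMALL, ancestral_sequence=("TTT",) * 3))


class TestBranchingMode:
    def test_cap_truncation_flagged(self):
        res = simulate_family(SimParams(
            growth="branching", base_rate=2.0, max_elements=30,
            turnover_generations=0, seed=3))
        assert res.truncated
        assert res.alignment.n_sequences == 30

    def test_stalled_population_flagged_extinct(self):
        res = simulate_family(SimParams(
            growth="branching", base_rate=1e-6, n_generations=3,
            turnover_generations=0, seed=1))
        assert res.extinct
        assert res.alignment is None


class TestSelectionMachinery:
    def test_synonymous_count_scales_linearly_with_u(self):
        def syn_total(u, seed):
            res = simulate_family(SimParams(
                u=u, f=1.0, max_elements=60, turnover_generations=30,
                seed=seed))
            recs = scan_alignment(res.alignment)
            return sum(r.variant_class == "synonymous" for r in recs)

        lo = np.mean([syn_total(1e-3, s) for s in range(8)])
        hi = np.mean([syn_total(2e-3, s) for s in range(8)])
        assert hi / lo == pytest.approx(2.0, rel=0.25)

    def test_neutral_family_has_flat_unit_ratio(self):
        results = simulate_families(SimParams(f=1.0, seed=11), 12)
        curve = pool_bins([
            vnvs_curve(bin_variants(scan_alignment(r.alignment)))
            for r in results
        ])
        for b in curve.bins:
            if b.vN + b.vS >= 100:
                assert 0.8 < b.vN / b.vS < 1.25

    def test_lethal_class_confines_deleterious_to_singletons(self):
        res = simulate_family(SimParams(s=1.0, f=0.0, seed=5,
                                        max_elements=60,
                                        turnover_generations=30))
        # all parents of surviving elements must be load-free
        for idx in res.alive:
            parent = res.parents[idx]
            if parent >= 0:
                assert res.n_deleterious[parent] == 0

    def test_trans_mode_ignores_load_in_parent_choice(self):
        cis = simulate_family(SMALL)
        trans = simulate_family(dataclasses.replace(SMALL, mode="trans"))
        # under trans, heavily loaded elements keep reproducing, so the
        # final mean load exceeds the cis mean load
        assert trans.n_deleterious[trans.alive].mean() > \
            cis.n_deleterious[cis.alive].mean()


class TestDuplicationNoise:
    def test_zero_rate_is_identity(self):
        res = simulate_family(SMALL)
        assert simulate_duplication_noise(res.alignment, 0.0) is res.alignment

    def test_duplication_count_and_ids(self):
        res = simulate_family(dataclasses.replace(SMALL, max_elements=100))
        noisy = simulate_duplication_noise(res.alignment, 0.5, seed=2)
        added = noisy.n_sequences - 100
        assert 30 <= added <= 70  # Binomial(100, 0.5) well inside 5 sigma
        assert all(i.endswith("_dup") for i in noisy.ids[100:])

    def test_duplicating_everyone_doubles_private_variants(self):
        res = simulate_family(SMALL)
        # rate ~1: every sequence duplicated, frequencies preserved, so
        # every minor count doubles
        noisy = simulate_duplication_noise(res.alignment, 0.999999, seed=0)
        assert noisy.n_sequences == 2 * res.alignment.n_sequences
        before = {(r.column, r.set_name, r.position_in_codon): r.minor_count
                  for r in scan_alignment(res.alignment)}
        after = {(r.column, r.set_name, r.position_in_codon): r.minor_count
                 for r in scan_alignment(noisy)}
        assert set(before) == set(after)
        assert all(after[k] == 2 * before[k] for k in before)

    def test_invalid_rate(self):
        res = simulate_family(SMALL)
        with pytest.raises(ValueError):
            simulate_duplication_noise(res.alignment, 1.0)
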