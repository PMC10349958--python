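from datetime import date

import numpy as np
import pytest

from abag_eval.benchmark_curation import (BenchmarkEntry, CurationConfig,
                                          CurationDecision, basic_filters,
                                          curate, length_filters,
                                          percent_identity, sequence_redundant,
                                          structural_redundant)
from abag_eval.synthetic_data import build_toy_complex

RNG = np.random.default_rng(77)
AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_seq(n, rng=RNG):
    return "".join(rng.choice(AA, n))


def mutated(seq, fraction, rng=RNG):
    seq = list(seq)
    k = int(round(len(seq) * fraction))
    for pos in rng.choice(len(seq), k, replace=False):
        seq[pos] = AA[(AA.index(seq[pos]) + 7) % 20]
    return "".join(seq)


def make_entry(entry_id, heavy, antigen, light=None, release=date(2019, 6, 1),
               resolution=2.0, **kw):
    return BenchmarkEntry(
        entry_id=entry_id, release_date=release, resolution=resolution,
        heavy_variable=heavy, light_variable=light,
        antigen_sequences=[antigen],
        antigen_seqres_lengths=[len(antigen)],
        antigen_resolved_lengths=[len(antigen)], **kw)


@pytest.fixture(scope="module")
def base_pair():
    heavy = random_seq(120)
    antigen = random_seq(150)
    return heavy, antigen


class TestSequenceRedundancy:
    def test_identical_entries_redundant(self, base_pair):
        heavy, antigen = base_pair
        a = make_entry("a", heavy, antigen)
        b = make_entry("b", heavy, antigen)
        assert sequence_redundant(a, b)

    def test_high_heavy_identity_with_antigen_match(self, base_pair):
        heavy, antigen = base_pair
        a = make_entry("a", heavy, antigen)
        b = make_entry("b", mutated(heavy, 0.05), mutated(antigen, 0.10))
        assert sequence_redundant(a, b)

    def test_low_identity_not_redundant(self, base_pair):
        heavy, antigen = base_pair
        a = make_entry("a", heavy, antigen)
        b = make_entry("b", mutated(heavy, 0.15), antigen)
        assert not sequence_redundant(a, b)

    def test_no_antigen_match_not_redundant(self, base_pair):
        heavy, antigen = base_pair
        a = make_entry("a", heavy, antigen)
        b = make_entry("b", heavy, random_seq(150))
        assert not sequence_redundant(a, b)

    def test_symmetric_for_equal_lengths(self, base_pair):
        heavy, antigen = base_pair
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = make_entry("a", mutated(heavy, rng.uniform(0, 0.2, 1)[0], rng), antigen)
            b = make_entry("b", mutated(heavy, rng.uniform(0, 0.2, 1)[0], rng), antigen)
            assert sequence_redundant(a, b) == sequence_redundant(b, a)

    def test_empty_sequence_rejected(self, base_pair):
        heavy, antigen = base_pair
        with pytest.raises(ValueError):
            percent_identity("", heavy)


class TestStructuralRedundancy:
    def entry_with_structure(self, entry_id, cx, heavy_seq, **kw):
        return make_entry(entry_id, heavy_seq, cx.reference.sequence("A"),
                          structure=cx.reference, partition=cx.partition, **kw)

    def test_same_structure_redundant(self):
        cx = build_toy_complex(seed=31)
        heavy = cx.reference.sequence("H")
        a = self.entry_with_structure("a", cx, heavy)
        b = self.entry_with_structure("b", cx, heavy)
        assert structural_redundant(a, b)

    def test_displaced_antibody_not_redundant(self):
        """Same antibody sequence, antibody moved 20 A on the antigen."""
        cx = build_toy_complex(seed=31)
        heavy = cx.reference.sequence("H")
        moved = cx.reference.copy()
        for res in moved.chains["H"]:
            for atom in res.atoms:
                atom.position = atom.position + np.array([0.0, 20.0, 0.0])
        a = make_entry("a", heavy, cx.reference.sequence("A"),
                       structure=moved, partition=cx.partition)
        b = self.entry_with_structure("b", cx, heavy)
        assert not structural_redundant(a, b)

    def test_low_identity_overrides_rmsd(self):
        cx = build_toy_complex(seed=31)
        heavy = cx.reference.sequence("H")
        a = self.entry_with_structure("a", cx, heavy)
        # same geometry but claimed heavy sequence with < 70% identity
        b = self.entry_with_structure("b", cx, mutated(heavy, 0.5))
        assert not structural_redundant(a, b)

    def test_missing_structure_keeps(self, base_pair):
        heavy, antigen = base_pair
        a = make_entry("a", heavy, antigen)
        b = make_entry("b", heavy, antigen)
        assert not structural_redundant(a, b)


class TestLengthFilters:
    def test_fully_resolved_kept(self, base_pair):
        heavy, antigen = base_pair
        assert length_filters(make_entry("a", heavy, antigen)).verdict == "keep"

    def test_mostly_unresolved_removed(self, base_pair):
        heavy, _ = base_pair
        entry = make_entry("a", heavy, "X")
        entry.antigen_seqres_lengths = [1000]
        entry.antigen_resolved_lengths = [250]
        decision = length_filters(entry)
        assert decision.verdict == "remove"
        assert decision.rule_fired == "length_unresolved_70"

    def test_large_partially_unresolved_removed(self, base_pair):
        heavy, _ = base_pair
        entry = make_entry("a", heavy, "X")
        entry.antigen_seqres_lengths = [900]
        entry.antigen_resolved_lengths = [540]
        decision = length_filters(entry)
        assert decision.verdict == "remove"
        assert decision.rule_fired == "length_unresolved_35_large"

    def test_small_partially_unresolved_kept(self, base_pair):
        heavy, _ = base_pair
        entry = make_entry("a", heavy, "X")
        entry.antigen_seqres_lengths = [400]
        entry.antigen_resolved_lengths = [240]  # 0.40 unresolved but only 240 aa
        assert length_filters(entry).verdict == "keep"

    def test_zero_seqres_rejected(self, base_pair):
        heavy, _ = base_pair
        entry = make_entry("a", heavy, "X")
        entry.antigen_seqres_lengths = [0]
        entry.antigen_resolved_lengths = [0]
        with pytest.raises(ValueError, match="seqres"):
            length_filters(entry)


class TestBasicFilters:
    def test_good_entry_kept(self, base_pair):
        heavy, antigen = base_pair
        entry = make_entry("a", heavy, antigen, release=date(2019, 1, 1),
                           resolution=2.5)
        assert basic_filters(entry).verdict == "keep"

    def test_low_resolution_removed(self, base_pair):
        heavy, antigen = base_pair
        entry = make_entry("a", heavy, antigen, resolution=3.2)
        decision = basic_filters(entry)
        assert (decision.verdict, decision.rule_fired) == ("remove", "resolution")

    def test_boundary_resolution_kept(self, base_pair):
        heavy, antigen = base_pair
        entry = make_entry("a", heavy, antigen, resolution=3.0)
        assert basic_filters(entry).verdict == "keep"

    def test_early_release_removed(self, base_pair):
        heavy, antigen = base_pair
        entry = make_entry("a", heavy, antigen, release=date(2017, 1, 1))
        assert basic_filters(entry).rule_fired == "release_date"

    def test_missing_date_rejected(self, base_pair):
        heavy, antigen = base_pair
        entry = make_entry("a", heavy, antigen)
        entry.release_date = None
        with pytest.raises(ValueError, match="date"):
            basic_filters(entry)


class TestCurate:
    def cohort(self, n_unique=4, n_dups=2, seed=9):
        rng = np.random.default_rng(seed)
        entries = []
        for i in range(n_unique):
            heavy = random_seq(120, rng)
            antigen = random_seq(150, rng)
            entries.append(make_entry(f"u{i}", heavy, antigen,
                                      release=date(2019, 1, 1 + i)))
            if i < n_dups:
                entries.append(make_entry(
                    f"d{i}", mutated(heavy, 0.03, rng), mutated(antigen, 0.05, rng),
                    release=date(2020, 1, 1 + i)))
        return entries

    def test_planted_duplicates_removed(self):
        entries = self.cohort(n_unique=4, n_dups=2)
        decisions, survivors = curate(entries)
        removed = [d for d in decisions if d.verdict == "remove"]
        assert len(removed) == 2
        assert all(d.rule_fired == "sequence_redundant" for d in removed)
        assert sorted(d.entry_id for d in removed) == ["d0", "d1"]
        assert len(survivors) == 4

    def test_idempotent(self):
        entries = self.cohort()
        _, survivors = curate(entries)
        decisions2, survivors2 = curate(survivors)
        assert [e.entry_id for e in survivors2] == [e.entry_id for e in survivors]
        assert all(d.verdict == "keep" for d in decisions2)

    def test_order_invariant(self):
        entries = self.cohort()
        _, survivors_a = curate(entries)
        rng = np.random.default_rng(0)
        shuffled = list(entries)
        rng.shuffle(shuffled)
        _, survivors_b = curate(shuffled)
        assert {e.entry_id for e in survivors_a} == {e.entry_id for e in survivors_b}

    def test_priors_only_filters(self, base_pair):
        heavy, antigen = base_pair
        cand = make_entry("c", heavy, antigen)
        prior = make_entry("p", heavy, antigen, release=date(2015, 1, 1))
        decisions, survivors = curate([cand], priors=[prior])
        assert survivors == []
        assert decisions[0].rule_fired == "sequence_redundant"

    def test_exclusion_list(self, base_pair):
        heavy, antigen = base_pair
        cand = make_entry("c", heavy, antigen)
        decisions, survivors = curate(
            [cand], config=CurationConfig(exclusions={"c"}))
        assert survivors == []
        assert decisions[0].rule_fired == "manual_exclusion"

    def test_every_removal_cites_one_rule(self):
        entries = self.cohort()
        entries.append(make_entry("bad_res", random_seq(120), random_seq(150),
                                  resolution=3.5))
        decisions, _ = curate(entries)
        for d in decisions:
            if d.verdict == "remove":
                assert d.rule_fired
            else:
                assert d.rule_fired == ""

    def test_removal_requires_rule(self):
        with pytest.raises(ValueError):
            CurationDecision("x", "remove", rule_fired="")
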