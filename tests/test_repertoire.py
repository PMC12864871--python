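import math
from collections import defaultdict

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shmkit import motifs as mg
from shmkit import repertoire as rep
from shmkit import simulate as sim
from shmkit.errors import DataError
from shmkit.stats import pearson, two_sample_t


def make_record(record_id, germline, observed, regions=()):
    return rep.AnnotatedSequenceRecord(record_id, germline, observed, tuple(regions))


GERMLINE = "A" * 10 + "TACGGTAGTAGCTACTTTGACT" + "A" * 10  # AGCT target C at 22


class TestRecordValidation:
    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError, match="rec1"):
            make_record("rec1", "ACGT", "ACG")

    def test_n_rejected(self):
        with pytest.raises(DataError):
            make_record("rec1", "ACNT", "ACGT")

    def test_bad_regions_rejected(self):
        with pytest.raises(DataError):
            make_record("r", "ACGTACGT", "ACGTACGT", [("FWR1", 1, 9)])
        with pytest.raises(DataError):
            make_record("r", "ACGTACGT", "ACGTACGT", [("FWR1", 1, 4), ("CDR1", 3, 6)])


class TestCallMutations:
    def test_no_mutations(self):
        assert rep.call_mutations(make_record("r", "ACGT", "ACGT")) == []

    def test_single_substitution(self):
        germ = "A" * 11 + "C" + "A" * 11
        obs = "A" * 11 + "T" + "A" * 11
        calls = rep.call_mutations(make_record("r", germ, obs))
        assert calls == [rep.MutationCall(12, "C", "T")]

    def test_multiple(self):
        calls = rep.call_mutations(make_record("r", "AACC", "ATCA"))
        assert {(c.position, c.from_base, c.to_base) for c in calls} == {
            (2, "A", "T"),
            (4, "C", "A"),
        }


def brute_force_groups(records, k=15):
    """Independent regrouping oracle keyed by germline k-mer string."""
    coverage = defaultdict(int)
    mutated = defaultdict(int)
    half = k // 2
    for record in records:
        for i, base in enumerate(record.germline):
            if base != "C":
                continue
            lo, hi = i - half, i + half + 1
            if lo < 0 or hi > len(record.germline):
                continue
            kmer = record.germline[lo:hi]
            coverage[kmer] += 1
            if record.observed[i] != record.germline[i]:
                mutated[kmer] += 1
    return dict(coverage), dict(mutated)


class TestContextGroups:
    def test_coverage_and_frequency(self):
        records = [
            make_record(f"r{i}", GERMLINE, GERMLINE) for i in range(36)
        ]
        mutated = GERMLINE[:21] + "T" + GERMLINE[22:]
        records += [make_record(f"m{i}", GERMLINE, mutated) for i in range(4)]
        groups = {g.kmer: g for g in rep.build_context_groups(records)}
        target = mg.extract_context(GERMLINE, 22).kmer
        assert groups[target].coverage == 40
        assert groups[target].central_mutated == 4
        assert groups[target].central_mutation_frequency == pytest.approx(0.1)

    def test_pooling_across_genes_matches_oracle(self):
        rng = np.random.default_rng(7)
        core = "TACGGTAGTAGCTACTTTGACT"
        genes = ["".join(rng.choice(list("ACGT"), 8)) + core +
                 "".join(rng.choice(list("ACGT"), 8)) for _ in range(3)]
        records = []
        for gi, gene in enumerate(genes):
            for i in range(5):
                obs = list(gene)
                if i % 2 == 0:  # mutate the shared central C (core C12, index 19)
                    obs[19] = "T"
                records.append(make_record(f"g{gi}r{i}", gene, "".join(obs)))
        groups = {g.kmer: g for g in rep.build_context_groups(records)}
        cov_oracle, mut_oracle = brute_force_groups(records)
        assert {k: g.coverage for k, g in groups.items()} == cov_oracle
        for kmer, group in groups.items():
            assert group.central_mutated == mut_oracle.get(kmer, 0)

    def test_conservation_of_mutation_tallies(self):
        rng = np.random.default_rng(3)
        records = []
        for i in range(30):
            obs = list(GERMLINE)
            for j in range(len(obs)):
                if GERMLINE[j] == "C" and rng.random() < 0.2:
                    obs[j] = "T"
            records.append(make_record(f"r{i}", GERMLINE, "".join(obs)))
        groups = rep.build_context_groups(records)
        eligible = {
            i + 1
            for i, b in enumerate(GERMLINE)
            if b == "C" and mg.extract_context(GERMLINE, i + 1) is not None
        }
        total_calls = sum(
            1
            for r in records
            for c in rep.call_mutations(r)
            if c.from_base == "C" and c.position in eligible
        )
        assert sum(g.central_mutated for g in groups) == total_calls

    def test_wrch_only_filters_non_motif_windows(self):
        records = [make_record("r", GERMLINE, GERMLINE)]
        all_groups = rep.build_context_groups(records, wrch_only=False)
        wrch_groups = rep.build_context_groups(records, wrch_only=True)
        assert all(g.motif for g in wrch_groups)
        assert len(wrch_groups) <= len(all_groups)


class TestFilterCoverage:
    def _groups(self, coverages):
        return [rep.ContextGroup(f"kmer{i}", None, coverage=c) for i, c in enumerate(coverages)]

    def test_boundary(self):
        kept = rep.filter_coverage(self._groups([29, 30, 31]))
        assert [g.coverage for g in kept] == [30, 31]

    def test_empty(self):
        assert rep.filter_coverage([]) == []

    def test_idempotent(self):
        groups = self._groups([10, 40, 29, 30, 100])
        once = rep.filter_coverage(groups)
        assert rep.filter_coverage(once) == once

    def test_monotone_in_threshold(self):
        groups = self._groups(list(range(60)))
        sizes = [len(rep.filter_coverage(groups, t)) for t in (1, 10, 30, 50)]
        assert sizes == sorted(sizes, reverse=True)


class TestPearson:
    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=3,
            max_size=40,
        )
    )
    @settings(max_examples=100)
    def test_matches_two_pass_oracle(self, points):
        x = np.array([p[0] for p in points])
        y = np.array([p[1] for p in points])
        # textbook two-pass formula
        mx, my = x.mean(), y.mean()
        sxy = ((x - mx) * (y - my)).sum()
        sxx = ((x - mx) ** 2).sum()
        syy = ((y - my) ** 2).sum()
        r, note = pearson(x, y)
        if sxx == 0 or syy == 0:
            assert note == "degenerate" and math.isnan(r)
        else:
            assert note == "ok"
            assert r == pytest.approx(sxy / math.sqrt(sxx * syy), abs=1e-12)

    def test_weighted_equals_repetition(self):
        x, y, w = [0, 1, 2, 3], [1.0, 0.9, 2.1, 2.9], [1, 3, 2, 1]
        r_w, _ = pearson(x, y, w)
        x_rep = [xi for xi, wi in zip(x, w) for _ in range(wi)]
        y_rep = [yi for yi, wi in zip(y, w) for _ in range(wi)]
        r_rep, _ = pearson(x_rep, y_rep)
        assert r_w == pytest.approx(r_rep, abs=1e-12)


class TestMutabilityByPypy:
    def _group(self, kmer, pypy, mutated, coverage=50):
        return rep.ContextGroup(kmer, "AGCT", coverage=coverage, central_mutated=mutated, pypy=pypy)

    def test_degenerate_all_mutated(self):
        groups = [self._group(f"k{i}", i % 3, 5) for i in range(9)]
        table, corr = rep.mutability_by_pypy(groups)
        assert (table["fraction_mutated"] == 1.0).all()
        assert corr.note == "degenerate" and math.isnan(corr.r)

    def test_perfect_linear(self):
        groups = []
        for level in range(5):
            for j in range(10):
                groups.append(self._group(f"k{level}_{j}", level, 1 if j < level else 0))
        table, corr = rep.mutability_by_pypy(groups)
        assert list(table["fraction_mutated"]) == pytest.approx(
            [0.0, 0.1, 0.2, 0.3, 0.4]
        )
        assert corr.r == pytest.approx(1.0)
        assert corr.r_squared == pytest.approx(1.0)

    def test_single_level_flagged(self):
        _, corr = rep.mutability_by_pypy([self._group("k", 2, 1)])
        assert corr.note in ("insufficient", "degenerate")

    def test_mixed_motifs_rejected(self):
        groups = [
            rep.ContextGroup("a", "AGCT", 10, 0, 0),
            rep.ContextGroup("b", "AACT", 10, 0, 0),
        ]
        with pytest.raises(DataError):
            rep.mutability_by_pypy(groups)

    def test_planted_positive_pypy_effect_recovered(self):
        """Context-dependent rates produce a positive mutability correlation."""
        rng = np.random.default_rng(0)
        germ = "".join(rng.choice(list("ACGT"), 8000))
        model = sim.MutationModel(
            base_rate={"AGCT": 0.0005},
            context_multiplier={p: 2.0**p for p in range(10)},
        )
        positives = 0
        n_seeds = 20
        for seed in range(n_seeds):
            records = sim.simulate_repertoire(germ, model, 300, seed=seed)
            groups = [
                g
                for g in rep.build_context_groups(records, wrch_only=True)
                if g.motif == "AGCT"
            ]
            _, corr = rep.mutability_by_pypy(groups)
            if corr.note == "ok" and corr.r > 0:
                positives += 1
        assert positives >= int(0.95 * n_seeds)


class TestFrequencyByPypy:
    def test_single_group_per_level(self):
        groups = [
            rep.ContextGroup("a", "AGCT", 100, 10, 1),
            rep.ContextGroup("b", "AGCT", 100, 30, 3),
        ]
        out = rep.frequency_by_pypy(groups)
        assert out[1]["median"] == pytest.approx(0.1)
        assert out[3]["median"] == pytest.approx(0.3)
        assert out[1]["q1"] == out[1]["q3"] == pytest.approx(0.1)

    def test_unmutated_excluded_by_default(self):
        groups = [
            rep.ContextGroup("a", "AGCT", 100, 0, 2),
            rep.ContextGroup("b", "AGCT", 100, 5, 2),
        ]
        out = rep.frequency_by_pypy(groups)
        assert out[2]["n"] == 1

    def test_empty_level_omitted(self):
        groups = [rep.ContextGroup("a", "AGCT", 100, 2, 4)]
        out = rep.frequency_by_pypy(groups)
        assert set(out) == {4}

    def test_flat_rates_give_similar_medians(self):
        # identical planted frequency at every level: medians within
        # binomial noise of each other (3 SE at the configured coverage)
        rng = np.random.default_rng(5)
        p, coverage = 0.2, 400
        groups = []
        for level in range(4):
            for j in range(25):
                muts = rng.binomial(coverage, p)
                groups.append(
                    rep.ContextGroup(f"k{level}_{j}", "AGCT", coverage, muts, level)
                )
        out = rep.frequency_by_pypy(groups, mutated_only=False)
        se = math.sqrt(p * (1 - p) / coverage)
        for level in range(4):
            assert abs(out[level]["median"] - p) < 3 * se


class TestSubregionSummary:
    REGIONS = (("FWR1", 1, 14), ("CDR1", 15, 24), ("FWR2", 25, 42))

    def test_mutations_only_in_one_region(self):
        germ = "AAAAAGCTAAAAAA" + "AAAAAGCTAA" + "AAAAAGCTAAAAAAAAAA"
        assert len(germ) == 42
        obs = list(germ)
        obs[20] = "T"  # the CDR1 AGCT target C (position 21)
        records = [
            rep.AnnotatedSequenceRecord("r", germ, "".join(obs), self.REGIONS)
        ]
        table = rep.subregion_summary(records, wrch_only=True)
        mutated = table[table["mutated"] > 0]
        assert set(mutated["region"]) == {"CDR1"}
        assert set(mutated["motif"]) == {"AGCT"}

    def test_absent_motif_rows_are_explicit_zeros(self):
        germ = "AAAAAGCTAAAAAA" + "A" * 28
        records = [
            rep.AnnotatedSequenceRecord("r", germ, germ, self.REGIONS)
        ]
        table = rep.subregion_summary(records, wrch_only=True)
        row = table[(table["region"] == "CDR1") & (table["motif"] == "TGCA")]
        assert len(row) == 1
        assert int(row["n_sites"].iloc[0]) == 0

    def test_unassigned_positions_warned(self):
        germ = "AAAAAGCTAAAAAA" + "A" * 28
        records = [
            rep.AnnotatedSequenceRecord("r", germ, germ, (("FWR1", 1, 4),))
        ]
        with pytest.warns(UserWarning, match="unassigned"):
            table = rep.subregion_summary(records, wrch_only=True)
        assert "unassigned" in set(table["region"])

    def test_uniform_rate_tracks_site_counts(self):
        rng = np.random.default_rng(11)
        germ = "AAAAAGCTAAAAAA" + "AAAAAGCTAA" + "AAAAAGCTAAAAAAAAAA"
        p = 0.3
        records = []
        for i in range(400):
            obs = list(germ)
            for pos in (6, 20, 30):  # the three AGCT target Cs (0-based)
                if rng.random() < p:
                    obs[pos] = "T"
            records.append(
                rep.AnnotatedSequenceRecord(f"r{i}", germ, "".join(obs), self.REGIONS)
            )
        table = rep.subregion_summary(records, wrch_only=True)
        agct = table[(table["motif"] == "AGCT") & (table["n_sites"] > 0)]
        se = math.sqrt(p * (1 - p) / 400)
        for freq in agct["frequency"]:
            assert abs(freq - p) < 4 * se


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p, note = two_sample_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (t, p) == (0.0, 1.0) and note == "degenerate"

    def test_separated_groups(self):
        a = [0.0, 0.001, 0.0, 0.001]
        b = [1.0, 1.001, 1.0, 1.001]
        _, p, _ = two_sample_t(a, b)
        assert p < 1e-6
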