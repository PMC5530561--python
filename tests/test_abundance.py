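"""Unique/multi read-partition abundance estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quantmeta import abundance, synthetic
from quantmeta.abundance import (gene_abundance, normalize_relative,
                                 species_abundance)

from conftest import make_hits, paired_genome_hits


class TestSpeciesAbundance:
    def test_unique_only_reads_per_bp(self):
        records = []
        for i in range(10):
            records += paired_genome_hits(f"r{i}", "G", span=200)
        ab = species_abundance(make_hits(records), {"G": 1000.0})
        assert ab["G"] == pytest.approx(0.01)

    def test_worked_unique_multi_partition(self, two_genome_hits):
        """4 unique on A (l=100), 2 on B (l=200), 3 multi-reads:
        Co_A = 0.8, Co_B = 0.2, Ab_A = 0.064, Ab_B = 0.013."""
        hits, lengths = two_genome_hits
        ab = species_abundance(hits, lengths)
        assert ab["A"] == pytest.approx(0.064)
        assert ab["B"] == pytest.approx(0.013)

    def test_zero_unique_candidate_gets_zero_weight(self):
        # C has no unique reads: the multi-read splits between A and B only
        records = []
        records += paired_genome_hits("uA", "A", span=100)
        records += paired_genome_hits("uB", "B", span=100)
        for t in "ABC":
            records += paired_genome_hits("m0", t, span=100)
        lengths = {"A": 100.0, "B": 100.0, "C": 100.0}
        ab = species_abundance(make_hits(records), lengths)
        assert ab["C"] == 0.0
        assert ab["A"] == ab["B"] == pytest.approx(1 / 100 + 0.5 / 100)

    def test_all_zero_unique_read_dropped_and_logged(self):
        records = []
        for t in "AB":
            records += paired_genome_hits("m0", t, span=100)
        ab, diag = species_abundance(make_hits(records), {"A": 100.0, "B": 100.0},
                                     return_diagnostics=True)
        assert (ab == 0).all()
        assert diag.n_dropped_reads == 1
        assert diag.dropped_reads == ["m0"]

    def test_unpaired_and_gene_records_excluded(self, two_genome_hits):
        hits, lengths = two_genome_hits
        extra = make_hits([("x", 1, "A", "genome", 0, 100, 0),
                           ("y", 1, "A", "gene", 0, 100, 1)])
        ab = species_abundance(pd.concat([hits, extra]), lengths)
        assert ab["A"] == pytest.approx(0.064)

    def test_linearity_doubling_reads(self, two_genome_hits):
        hits, lengths = two_genome_hits
        doubled = hits.copy()
        doubled["read_id"] = doubled["read_id"] + "_copy"
        ab2 = species_abundance(pd.concat([hits, doubled]), lengths)
        assert np.allclose(ab2, 2 * species_abundance(hits, lengths))

    def test_no_multi_equals_naive_estimator(self):
        rng = np.random.default_rng(0)
        lengths = pd.Series({f"G{i}": float(rng.integers(500, 2000)) for i in range(5)})
        records, counts = [], {g: 0 for g in lengths.index}
        for i in range(200):
            g = rng.choice(lengths.index)
            counts[g] += 1
            records += paired_genome_hits(f"r{i}", g, span=200)
        ab = species_abundance(make_hits(records), lengths)
        naive = pd.Series(counts) / lengths
        assert np.allclose(ab, naive)

    def test_co_weights_sum_to_one_per_multi_read(self):
        """Each multi-read's total contribution, re-scaled by target
        lengths, must be exactly one read."""
        rng = np.random.default_rng(1)
        lengths = pd.Series({f"G{i}": float(rng.integers(500, 2000)) for i in range(6)})
        records = []
        for i in range(50):
            records += paired_genome_hits(f"u{i}", rng.choice(lengths.index), span=200)
        base = species_abundance(make_hits(records), lengths)
        for j in range(20):
            cands = rng.choice(lengths.index, size=rng.integers(2, 5), replace=False)
            multi = []
            for t in cands:
                multi += paired_genome_hits(f"m{j}", t, span=200)
            with_multi = species_abundance(make_hits(records + multi), lengths)
            added_reads = ((with_multi - base) * lengths).sum()
            assert added_reads == pytest.approx(1.0)


class TestGeneAbundance:
    def test_fully_internal_pairs(self):
        records = []
        for i in range(5):
            records += [(f"r{i}", 1, "g1", "gene", 0, 100, 1),
                        (f"r{i}", 2, "g1", "gene", 300, 400, 1)]
        ab = gene_abundance(make_hits(records), {"g1": 500.0})
        assert ab["g1"] == pytest.approx(0.01)

    def test_single_end_with_mate_beyond_gene_counts(self):
        # one end at 400..500 in a 500 bp gene; mate implied 800 bp on is
        # past the gene end, so the pair qualifies
        records = [("r0", 1, "g1", "gene", 400, 500, 0)]
        ab = gene_abundance(make_hits(records), {"g1": 500.0})
        assert ab["g1"] == pytest.approx(1 / 500)

    def test_single_end_with_mate_inside_long_gene_skipped(self):
        # 2000 bp gene, end at 900..1000: both implied mate placements are
        # inside the gene, so a lone end does not qualify the pair
        records = [("r0", 1, "g1", "gene", 900, 1000, 0)]
        ab = gene_abundance(make_hits(records), {"g1": 2000.0})
        assert ab["g1"] == 0.0

    def test_matches_brute_force_qualifier(self):
        """Independent per-read re-evaluation of the boundary rule and the
        Co partition reproduces gene_abundance exactly."""
        rng = np.random.default_rng(7)
        lengths = {f"g{i}": float(rng.integers(200, 2500)) for i in range(8)}
        records = []
        for i in range(300):
            read = f"r{i}"
            for g in rng.choice(list(lengths), size=rng.integers(1, 3), replace=False):
                L = int(lengths[g])
                if rng.random() < 0.5:  # both ends inside
                    s = int(rng.integers(0, max(L - 100, 1)))
                    records += [(read, 1, g, "gene", s, min(s + 100, L), 1),
                                (read, 2, g, "gene", max(L - 100, 0), L, 1)]
                else:
                    s = int(rng.integers(0, max(L - 100, 1)))
                    records.append((read, 1, g, "gene", s, min(s + 100, L), 0))
        hits = make_hits(records)
        ab = gene_abundance(hits, lengths, insert_size=800)

        # ---- naive oracle -------------------------------------------
        qualified = {}
        for (read, gene), grp in hits.groupby(["read_id", "target_id"]):
            L = lengths[gene]
            if grp["end"].nunique() >= 2:
                ok = True
            else:
                rec = grp.iloc[0]
                ok = rec["start"] + 800 > L or rec["stop"] - 800 < 0
            if ok:
                qualified.setdefault(read, set()).add(gene)
        unique_counts = {g: 0.0 for g in lengths}
        for read, genes in qualified.items():
            if len(genes) == 1:
                unique_counts[next(iter(genes))] += 1
        ab_u = {g: unique_counts[g] / lengths[g] for g in lengths}
        expected = dict(ab_u)
        for read, genes in qualified.items():
            if len(genes) < 2:
                continue
            total = sum(ab_u[g] for g in genes)
            if total == 0:
                continue
            for g in genes:
                expected[g] += (ab_u[g] / total) / lengths[g]
        for g in lengths:
            assert ab[g] == pytest.approx(expected[g]), g


class TestNormalize:
    def test_worked_example(self):
        v = pd.Series({"A": 0.064, "B": 0.013})
        rel = normalize_relative(v)
        assert rel["A"] == pytest.approx(0.064 / 0.077)
        assert rel["B"] == pytest.approx(0.013 / 0.077)

    def test_idempotent_and_sums_to_one(self):
        v = normalize_relative(pd.Series([0.3, 1.2, 0.01, 4.0]))
        assert v.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(normalize_relative(v), v, atol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_relative(pd.Series([0.0, 0.0]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=1, max_size=30)
           .filter(lambda xs: sum(xs) > 0))
    def test_property_sum_one(self, xs):
        assert normalize_relative(pd.Series(xs)).sum() == pytest.approx(1.0, abs=1e-9)
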