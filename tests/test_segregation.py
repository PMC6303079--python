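"""Genotype tables, penetrance, allele frequency and exact segregation
tests."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wgva.containers import CohortDesign, GenotypeMatrix
from wgva.segregation import (allele_frequency, fisher_exact, genotype_counts,
                              penetrance, segregation_test)


class TestPenetrance:
    @pytest.mark.parametrize("present,absent,pct,display", [
        (20, 24, 100 * 20 / 44, 45.5),
        (7, 0, 100.0, 100.0),
        (42, 0, 100.0, 100.0),
        (0, 5, 0.0, 0.0),
    ])
    def test_worked_examples(self, present, absent, pct, display):
        est = penetrance(present, absent)
        assert est.penetrance_pct == pytest.approx(pct)
        assert est.display == display

    def test_truncating_publication_convention_documented(self):
        """47/51 homozygotes = 92.16%; round-half-up displays 92.2 (some
        published tables truncate to 92.1, which is why the raw fraction is
        the field of record)."""
        est = penetrance(47, 4)
        assert est.penetrance_pct == pytest.approx(92.1568627, abs=1e-6)
        assert est.display == 92.2

    def test_scale_invariance(self):
        assert penetrance(20, 24).display == penetrance(60, 72).display

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            penetrance(0, 0)


class TestAlleleFrequency:
    def test_high_frequency_breed_rounds_to_094(self):
        f = allele_frequency(2, 4, 59)
        assert f == pytest.approx(122 / 130)
        assert round(f, 2) == 0.94

    def test_boundaries(self):
        assert allele_frequency(7, 0, 0) == 0.0
        assert allele_frequency(0, 0, 9) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            allele_frequency(0, 0, 0)


class TestGenotypeCounts:
    def _cohort(self, counts_by_breed):
        """Build a one-variant cohort from {breed: (hom_ref, het, hom_alt)}."""
        ids, breed_of, dosage = [], {}, []
        for breed, (r, h, a) in counts_by_breed.items():
            for g, n in ((0, r), (1, h), (2, a)):
                for k in range(n):
                    sid = f"{breed}_{g}_{k}"
                    ids.append(sid)
                    breed_of[sid] = breed
                    dosage.append(g)
        status_of = {s: "control" for s in ids}
        design = CohortDesign(ids, breed_of, status_of)
        variants = pd.DataFrame({"CHROM": ["chr5"], "POS": [100], "REF": ["AC"],
                                 "ALT": ["A"], "IS_INDEL": [True]})
        matrix = GenotypeMatrix(np.array([dosage], dtype=np.int8), variants, ids)
        return matrix, design

    def test_counts_and_frequency_reconstruct_known_row(self):
        matrix, design = self._cohort({"breedA": (2, 4, 59)})
        out = genotype_counts(matrix, design, 0)
        row = out.iloc[0]
        assert (row["HOM_REF"], row["HET"], row["HOM_ALT"]) == (2, 4, 59)
        assert round(row["ALT_FREQ"], 2) == 0.94

    def test_totals_conserved_per_breed(self):
        matrix, design = self._cohort({"x": (3, 2, 1), "y": (0, 5, 5)})
        out = genotype_counts(matrix, design, 0)
        totals = out[["HOM_REF", "HET", "HOM_ALT"]].sum(axis=1)
        sizes = pd.Series([6, 10], index=totals.index)
        assert (totals == sizes).all()

    def test_all_missing_breed_warns(self, caplog):
        matrix, design = self._cohort({"x": (1, 1, 1), "y": (2, 0, 0)})
        matrix.dosages[0, [3, 4]] = -1  # knock out breed y entirely
        with caplog.at_level("WARNING"):
            out = genotype_counts(matrix, design, 0)
        assert out.set_index("BREED").loc["y", ["HOM_REF", "HET", "HOM_ALT"]].sum() == 0
        assert any("no genotyped sample" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# Fisher's exact test vs independent enumeration
# ---------------------------------------------------------------------------

def hypergeom_oracle(a, b, c, d, alternative="two-sided"):
    """Float enumeration via scipy's hypergeometric pmf with the standard
    point-probability tie rule (1e-12 relative tolerance)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(k, n, r1, c1)
    obs = stats.hypergeom.pmf(a, n, r1, c1)
    if alternative == "two-sided":
        return pmf[pmf <= obs * (1 + 1e-12)].sum()
    if alternative == "greater":
        return pmf[k >= a].sum()
    return pmf[k <= a].sum()


class TestFisherExact:
    def test_flat_table_is_one(self):
        assert fisher_exact(1, 1, 1, 1) == 1.0

    def test_small_diagonal_table_exact_value(self):
        # margins (3,3)x(3,3): only the two extreme tables are as improbable
        assert fisher_exact(3, 0, 0, 3) == pytest.approx(0.1, abs=1e-15)

    def test_perfect_segregation_point_mass(self):
        p = fisher_exact(16, 0, 0, 22, alternative="greater")
        assert p == pytest.approx(1 / comb(38, 16), rel=1e-12)

    def test_matches_scipy_on_exhaustive_small_grid(self):
        """All 2x2 tables with total <= 16 agree with scipy.stats.fisher_exact
        in every alternative."""
        for n in range(1, 17):
            for a, b, c in itertools.product(range(n + 1), repeat=3):
                d = n - a - b - c
                if d < 0:
                    continue
                for alt, scipy_alt in (("two-sided", "two-sided"),
                                       ("greater", "greater"),
                                       ("less", "less")):
                    mine = fisher_exact(a, b, c, d, alternative=alt)
                    ref = stats.fisher_exact([[a, b], [c, d]],
                                             alternative=scipy_alt).pvalue
                    assert mine == pytest.approx(ref, rel=1e-9), (a, b, c, d, alt)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(-1, 0, 0, 1)


class TestSegregationTest:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["BREED", "GENOTYPE", "AFFECTED",
                                           "UNAFFECTED"])

    def test_recessive_pooling_across_breeds(self):
        """Pooling fully penetrant recessive counts across breeds yields the
        [[16,0],[0,22]] table and its exact point-mass p-value."""
        table = self._table([
            ("b1", "HOM_REF", 0, 1), ("b1", "HET", 0, 2), ("b1", "HOM_ALT", 12, 0),
            ("b2", "HOM_REF", 0, 8), ("b2", "HET", 0, 1),
            ("b3", "HOM_REF", 0, 7), ("b3", "HET", 0, 3), ("b3", "HOM_ALT", 4, 0),
        ])
        p = segregation_test(table, collapse="recessive")
        assert p == pytest.approx(fisher_exact(16, 0, 0, 22), rel=1e-12)
        assert p == pytest.approx(1 / comb(38, 16), rel=1e-9)

    def test_independent_table_uninformative(self):
        table = self._table([
            ("b", "HOM_REF", 5, 5), ("b", "HET", 5, 5), ("b", "HOM_ALT", 5, 5),
        ])
        assert segregation_test(table, collapse="recessive") == 1.0

    def test_p_shrinks_with_sample_size_at_fixed_structure(self):
        ps = []
        for n in (5, 10, 20):
            table = self._table([("b", "HOM_ALT", n, 0), ("b", "HOM_REF", 0, n)])
            ps.append(segregation_test(table, collapse="recessive"))
        assert ps[0] > ps[1] > ps[2]

    def test_empty_phenotype_margin_warns_and_returns_one(self, caplog):
        table = self._table([("b", "HOM_ALT", 3, 0), ("b", "HOM_REF", 2, 0)])
        with caplog.at_level("WARNING"):
            assert segregation_test(table) == 1.0

    def test_genotypic_mode_matches_brute_force_enumeration(self):
        """The 3x2 exact test equals a from-scratch enumeration over all
        tables with the observed margins."""
        rows = [(4, 1), (2, 3), (0, 5)]
        table = self._table([("b", g, a, u) for (a, u), g in
                             zip(rows, ("HOM_REF", "HET", "HOM_ALT"))])
        p = segregation_test(table, collapse="genotypic")

        row_totals = [a + u for a, u in rows]
        col1 = sum(a for a, _ in rows)
        n = sum(row_totals)
        obs_w = np.prod([comb(rt, a) for (a, _), rt in zip(rows, row_totals)])
        total = 0
        for x0 in range(row_totals[0] + 1):
            for x1 in range(row_totals[1] + 1):
                x2 = col1 - x0 - x1
                if not 0 <= x2 <= row_totals[2]:
                    continue
                w = comb(row_totals[0], x0) * comb(row_totals[1], x1) \
                    * comb(row_totals[2], x2)
                if w <= obs_w:
                    total += w
        assert p == pytest.approx(total / comb(n, col1), rel=1e-12)

    def test_two_class_genotypic_reduces_to_fisher(self):
        table = self._table([("b", "HOM_ALT", 3, 0), ("b", "HOM_REF", 0, 3)])
        assert segregation_test(table, collapse="genotypic") == \
            pytest.approx(fisher_exact(3, 0, 0, 3), rel=1e-12)
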