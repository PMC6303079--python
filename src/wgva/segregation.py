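"""Genotype-phenotype tables: per-breed genotype counts, allele frequencies,
penetrance, and exact segregation tests.

Fisher's exact test is computed by direct enumeration over the hypergeometric
support in exact integer arithmetic (binomial coefficients and a single
rational division at the end), so two-sided tie handling -- include every
table whose point probability is at most the observed table's -- involves no
floating-point comparisons at all.  The r x 2 "genotypic" test enumerates all
tables with the observed margins the same way; at segregation-table counts
this is a few thousand tables at most.

Penetrance is the fraction of homozygotes expressing the phenotype; the full-
precision fraction is retained alongside a one-decimal round-half-up display
value (published tables occasionally truncate instead -- e.g. 47/51 = 92.16%
shown as 92.1 -- which is why the raw fraction is the field of record).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from .containers import MISSING, CohortDesign, GenotypeMatrix

log = logging.getLogger(__name__)

GENOTYPE_LABELS = ("HOM_REF", "HET", "HOM_ALT")


@dataclass(frozen=True)
class PenetranceEstimate:
    present: int
    absent: int

    @property
    def fraction(self) -> float:
        return self.present / (self.present + self.absent)

    @property
    def penetrance_pct(self) -> float:
        return 100.0 * self.fraction

    @property
    def display(self) -> float:
        """One-decimal percentage, round half up."""
        pct = Decimal(self.present * 100) / Decimal(self.present + self.absent)
        return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))

    def __post_init__(self):
        if self.present < 0 or self.absent < 0:
            raise ValueError("counts must be non-negative")
        if self.present + self.absent == 0:
            raise ValueError("penetrance undefined for an empty genotype class")


def penetrance(present: int, absent: int) -> PenetranceEstimate:
    """Penetrance estimate from phenotype-present/absent counts among
    homozygotes."""
    return PenetranceEstimate(present=present, absent=absent)


def allele_frequency(hom_ref: int, het: int, hom_alt: int) -> float:
    """Alternate-allele frequency from genotype counts."""
    total = hom_ref + het + hom_alt
    if total == 0:
        raise ValueError("no genotyped samples")
    return (het + 2 * hom_alt) / (2 * total)


def genotype_counts(matrix: GenotypeMatrix, design: CohortDesign,
                    variant_index: int) -> pd.DataFrame:
    """Per-breed (hom-ref, het, hom-alt) counts at one bi-allelic variant,
    over non-missing samples.  Breeds fully missing at the site are reported
    as zeros with a warning."""
    g = matrix.dosages[variant_index]
    breeds = [design.breed_of[s] for s in matrix.samples]
    order = list(dict.fromkeys(breeds))
    rows = []
    for b in order:
        mask = np.fromiter((x == b for x in breeds), dtype=bool, count=len(breeds))
        gb = g[mask]
        gb = gb[gb != MISSING]
        if gb.size == 0:
            log.warning("breed %s has no genotyped sample at variant %d", b, variant_index)
        rows.append({
            "BREED": b,
            "HOM_REF": int((gb == 0).sum()),
            "HET": int((gb == 1).sum()),
            "HOM_ALT": int((gb == 2).sum()),
        })
    df = pd.DataFrame(rows)
    df["ALT_FREQ"] = [
        allele_frequency(r.HOM_REF, r.HET, r.HOM_ALT)
        if (r.HOM_REF + r.HET + r.HOM_ALT) else np.nan
        for r in df.itertuples()
    ]
    return df


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact(a: int, b: int, c: int, d: int,
                 alternative: str = "two-sided") -> float:
    """Exact hypergeometric p-value for the 2x2 table [[a, b], [c, d]].

    ``two-sided`` sums all tables with the observed margins whose point
    probability does not exceed the observed table's; ``greater``/``less``
    are the upper/lower tails in ``a``.  Integer-exact throughout.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("empty table")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    obs = weights[a]
    if alternative == "two-sided":
        num = sum(w for w in weights.values() if w <= obs)
    elif alternative == "greater":
        num = sum(w for k, w in weights.items() if k >= a)
    elif alternative == "less":
        num = sum(w for k, w in weights.items() if k <= a)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(Fraction(num, comb(n, c1)))


def _rx2_exact(rows: list[tuple[int, int]]) -> float:
    """Exact test for an r x 2 table by full enumeration with fixed margins.

    Point-probability ordering, integer-exact.  Probability of a table with
    first-column entries x_i is prod_i C(row_i, x_i) / C(N, col1).
    """
    row_totals = [y + nn for y, nn in rows]
    col1 = sum(y for y, _ in rows)
    n = sum(row_totals)
    obs_w = 1
    for (y, _), rt in zip(rows, row_totals):
        obs_w *= comb(rt, y)

    total = 0
    r = len(rows)

    def rec(i: int, remaining: int, w: int):
        nonlocal total
        if i == r - 1:
            if 0 <= remaining <= row_totals[i]:
                w2 = w * comb(row_totals[i], remaining)
                if w2 <= obs_w:
                    total += w2
            return
        lo = max(0, remaining - sum(row_totals[i + 1:]))
        hi = min(row_totals[i], remaining)
        for x in range(lo, hi + 1):
            rec(i + 1, remaining - x, w * comb(row_totals[i], x))

    rec(0, col1, 1)
    return float(Fraction(total, comb(n, col1)))


def segregation_test(table: pd.DataFrame, collapse: str = "recessive",
                     alternative: str = "two-sided") -> float:
    """Exact segregation p-value from a genotype-phenotype table.

    ``table`` has one row per (breed, genotype) with ``AFFECTED`` and
    ``UNAFFECTED`` counts and a ``GENOTYPE`` column in {HOM_REF, HET,
    HOM_ALT}.  ``recessive`` pools hom-alt vs (het + hom-ref) across breeds
    into a 2x2 Fisher test; ``genotypic`` pools across breeds by genotype and
    runs the exact 3x2 enumeration.  An empty margin returns p = 1 with a
    warning.
    """
    if not len(table):
        raise ValueError("empty segregation table")
    hom = table["GENOTYPE"] == "HOM_ALT"
    aff = table["AFFECTED"].to_numpy()
    un = table["UNAFFECTED"].to_numpy()
    if aff.sum() == 0 or un.sum() == 0 or aff.sum() + un.sum() == 0:
        log.warning("segregation table has an empty phenotype margin; p = 1")
        return 1.0
    if collapse == "recessive":
        a = int(aff[hom].sum())
        b = int(un[hom].sum())
        c = int(aff[~hom].sum())
        d = int(un[~hom].sum())
        if (a + b) == 0 or (c + d) == 0:
            log.warning("segregation table has an empty genotype margin; p = 1")
            return 1.0
        return fisher_exact(a, b, c, d, alternative=alternative)
    if collapse == "genotypic":
        rows = []
        for g in GENOTYPE_LABELS:
            m = table["GENOTYPE"] == g
            ra, ru = int(aff[m].sum()), int(un[m].sum())
            if ra + ru > 0:
                rows.append((ra, ru))
        if len(rows) < 2:
            log.warning("fewer than two genotype classes present; p = 1")
            return 1.0
        return _rx2_exact(rows)
    raise ValueError(f"unknown collapse mode {collapse!r}")
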