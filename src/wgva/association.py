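"""Case/control allelic association with genomic control.

Each bi-allelic variant contributes a 2x2 table of allele counts
(case alt ``a``, case ref ``b``, control alt ``c``, control ref ``d``; missing
genotypes drop two alleles from their group).  The test statistic is the
1-df Pearson allelic chi-square

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),   N = a+b+c+d,

whose upper tail gives the raw p-value.  A perfectly separated table
(b = c = 0) attains chi2 = N exactly.  Tables with a zero margin are
uninformative and score chi2 = 0, p = 1.

Population stratification inflates these statistics; genomic control divides
every statistic by an inflation factor lambda estimated from the genome-wide
distribution -- either the mean of the statistics (the expectation of a null
1-df chi-square is 1) or the median divided by the 1-df chi-square median
(~0.4549).  Corrected p-values are Bonferroni-adjusted for a configurable
number of tests, by default the size of the LD-pruned variant set standing in
for the number of independent haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, CohortDesign, GenotypeMatrix

#: Median of the 1-df chi-square distribution.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass(frozen=True)
class GCModel:
    lambda_: float
    mode: str = "mean"
    floor: bool = True

    @property
    def effective_lambda(self) -> float:
        return max(self.lambda_, 1.0) if self.floor else self.lambda_


@dataclass(frozen=True)
class AssocConfig:
    gc_mode: str = "mean"
    lambda_floor: bool = True
    n_tests: int | None = None   # None -> number of variants tested
    alpha: float = 0.05


def allele_table(dosages_row: np.ndarray, case_mask: np.ndarray,
                 control_mask: np.ndarray, name: str = "variant"
                 ) -> tuple[int, int, int, int]:
    """(case_alt, case_ref, control_alt, control_ref) allele counts over
    non-missing genotypes.  Errors if either group is entirely missing."""
    out = []
    for label, mask in (("case", case_mask), ("control", control_mask)):
        g = dosages_row[mask]
        ok = g != MISSING
        if not ok.any():
            raise ValueError(f"all {label} genotypes missing at {name}")
        alt = int(g[ok].sum())
        out.extend([alt, int(2 * ok.sum()) - alt])
    return tuple(out)  # type: ignore[return-value]


def allelic_chisq(a, b, c, d) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 1-df allelic chi-square and upper-tail p for 2x2 allele
    counts; any zero margin yields chi2 = 0, p = 1."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    p = stats.chi2.sf(chi2, 1)
    p = np.where(denom > 0, p, 1.0)
    return chi2, p


def estimate_lambda(chi2_values, mode: str = "mean", floor: bool = True) -> GCModel:
    """Genomic inflation factor from a vector of 1-df statistics."""
    x = np.asarray(chi2_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite statistics to estimate lambda from")
    if mode == "mean":
        lam = float(np.mean(x))
    elif mode == "median":
        lam = float(np.median(x) / CHI2_1DF_MEDIAN)
    else:
        raise ValueError(f"unknown lambda mode {mode!r}")
    return GCModel(lambda_=lam, mode=mode, floor=floor)


def gc_correct(chi2_values, model: GCModel) -> tuple[np.ndarray, np.ndarray]:
    """Divide statistics by the (floored) inflation factor; p from the 1-df
    upper tail.  Monotone, so the variant ordering by p is preserved."""
    lam = model.effective_lambda
    chi2_gc = np.asarray(chi2_values, dtype=float) / lam
    return chi2_gc, stats.chi2.sf(chi2_gc, 1)


def bonferroni(p_values, n_tests: int) -> np.ndarray:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return np.minimum(1.0, np.asarray(p_values, dtype=float) * n_tests)


def significance_threshold(alpha: float, n_tests: int, model: GCModel) -> float:
    """Raw p-value at which a variant attains a Bonferroni-corrected p of
    ``alpha`` after genomic control:

        t = SF_chi2_1( lambda * Q_chi2_1(1 - alpha / n_tests) ).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    lam = model.effective_lambda
    q = stats.chi2.isf(alpha / n_tests, 1)
    return float(stats.chi2.sf(lam * q, 1))


def qq_table(p_values: np.ndarray) -> pd.DataFrame:
    """Observed vs expected -log10 p order statistics for a QQ plot."""
    p = np.sort(np.asarray(p_values, dtype=float))
    n = len(p)
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({
        "EXPECTED_LOG10P": -np.log10(expected),
        "OBSERVED_LOG10P": -np.log10(np.clip(p, 1e-300, None)),
    })


def run_association(matrix: GenotypeMatrix, design: CohortDesign,
                    config: AssocConfig | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GCModel]:
    """Allelic association across all variants of an (already filtered)
    matrix.  Trio offspring are excluded; returns the per-variant result
    table (sorted by chromosome/position, i.e. input order), the QQ table of
    GC-corrected p-values, and the fitted GC model.
    """
    cfg = config or AssocConfig()
    analysis = set(design.analysis_ids)
    case_mask = np.fromiter(
        (s in analysis and design.status_of[s] == "case" for s in matrix.samples),
        dtype=bool, count=matrix.n_samples)
    control_mask = np.fromiter(
        (s in analysis and design.status_of[s] == "control" for s in matrix.samples),
        dtype=bool, count=matrix.n_samples)
    if not case_mask.any():
        raise ValueError("empty case set")
    if not control_mask.any():
        raise ValueError("empty control set")

    D = matrix.dosages
    ok = D != MISSING
    case_ok = ok[:, case_mask]
    ctrl_ok = ok[:, control_mask]
    a = np.where(case_ok, D[:, case_mask], 0).sum(axis=1)
    b = 2 * case_ok.sum(axis=1) - a
    c = np.where(ctrl_ok, D[:, control_mask], 0).sum(axis=1)
    d = 2 * ctrl_ok.sum(axis=1) - c

    chi2, p_raw = allelic_chisq(a, b, c, d)
    model = estimate_lambda(chi2, mode=cfg.gc_mode, floor=cfg.lambda_floor)
    chi2_gc, p_gc = gc_correct(chi2, model)
    n_tests = cfg.n_tests if cfg.n_tests is not None else matrix.n_variants
    p_bonf = bonferroni(p_gc, n_tests)

    with np.errstate(invalid="ignore", divide="ignore"):
        f_case = np.divide(a, a + b, out=np.zeros_like(chi2), where=(a + b) > 0)
        f_ctrl = np.divide(c, c + d, out=np.zeros_like(chi2), where=(c + d) > 0)

    results = pd.DataFrame({
        "CHR": matrix.variants["CHROM"].to_numpy(),
        "POS": matrix.variants["POS"].to_numpy(),
        "REF": matrix.variants["REF"].to_numpy(),
        "ALT": matrix.variants["ALT"].to_numpy(),
        "A_CASE": a, "U_CASE": b, "A_CTRL": c, "U_CTRL": d,
        "F_CASE": f_case, "F_CTRL": f_ctrl,
        "CHISQ": chi2, "P": p_raw,
        "CHISQ_GC": chi2_gc, "P_GC": p_gc, "P_BONF": p_bonf,
        "ALLELIC_DIFF": np.abs(f_case - f_ctrl),
    })
    return results, qq_table(p_gc), model
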