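"""Fixation-difference candidate scan.

Breed-defining recessive variants are expected to be (nearly) fixed in
affected breeds and (nearly) absent elsewhere, so candidate variants are
those whose case/control alternate-allele frequency difference exceeds a
cutoff (strictly more than 90% by default).  Passing variants that sit close
together on one chromosome are chained into candidate regions; short chains
are discarded and the survivors ranked by physical span, which prioritizes
long fixed haplotypes consistent with identity-by-descent inheritance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REGION_COLUMNS = ["CHROM", "START", "END", "N_VARIANTS",
                  "MEAN_ALLELIC_DIFF", "CASE_FIXED_FRACTION", "SPAN"]


def fixation_filter(results: pd.DataFrame, min_diff: float = 0.9) -> pd.DataFrame:
    """Rows of an association table with allelic difference strictly above
    ``min_diff``."""
    return results[results["ALLELIC_DIFF"] > min_diff].copy()


def build_regions(passing: pd.DataFrame, max_gap: int = 1_000_000,
                  min_variants: int = 10) -> pd.DataFrame:
    """Chain consecutive passing variants into candidate regions.

    Variants on the same chromosome merge while the gap to the previous
    passing variant is at most ``max_gap``; chains with fewer than
    ``min_variants`` members are dropped.  Coordinates are 1-based inclusive.
    """
    regions = []
    if len(passing):
        df = passing.sort_values(["CHR", "POS"], kind="stable")
        chrom = df["CHR"].to_numpy()
        pos = df["POS"].to_numpy()
        new_chain = np.r_[True, (chrom[1:] != chrom[:-1]) | (np.diff(pos) > max_gap)]
        chain_id = np.cumsum(new_chain)
        for _, grp in df.groupby(chain_id, sort=False):
            if len(grp) < min_variants:
                continue
            regions.append({
                "CHROM": grp["CHR"].iloc[0],
                "START": int(grp["POS"].min()),
                "END": int(grp["POS"].max()),
                "N_VARIANTS": len(grp),
                "MEAN_ALLELIC_DIFF": float(grp["ALLELIC_DIFF"].mean()),
                "CASE_FIXED_FRACTION": float((grp["F_CASE"] == 1.0).mean()),
            })
    out = pd.DataFrame(regions, columns=REGION_COLUMNS[:-1])
    out["SPAN"] = (out["END"] - out["START"] + 1) if len(out) else pd.Series(dtype=int)
    return out


def rank_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Order regions by span (desc), breaking ties by variant count then mean
    allelic difference."""
    if not len(regions):
        return regions.copy()
    return regions.sort_values(
        ["SPAN", "N_VARIANTS", "MEAN_ALLELIC_DIFF"],
        ascending=[False, False, False], kind="stable",
    ).reset_index(drop=True)


def regions_to_bed(regions: pd.DataFrame) -> str:
    """BED text (0-based half-open) for the candidate regions."""
    lines = [
        f"{r.CHROM}\t{r.START - 1}\t{r.END}\tregion{i + 1}\t{r.N_VARIANTS}"
        for i, r in enumerate(regions.itertuples())
    ]
    return "\n".join(lines) + ("\n" if lines else "")
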