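"""Site-level hard filters and allele recoding.

A joint-genotyped call set arrives with per-site annotations (QD, FS, SOR,
ReadPosRankSum, DP, MQ, MQRankSum, InbreedingCoeff).  Sites failing any of the
standard hard-filter inequalities are flagged; mapping-quality criteria apply
to SNVs only and the inbreeding-coefficient criterion to indels only, with the
depth cap applied to both classes.  All inequalities are strict, so a site
sitting exactly at a threshold passes.  A missing annotation skips that
criterion (with a logged warning) rather than failing the site.

Association treats SNVs and indels uniformly, so bi-allelic indel alleles are
recoded to single characters (REF -> "A", ALT -> "T"); any fixed injective
assignment preserves the ref/alt distinction, and the original alleles are
kept in sidecar columns for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    qd_min: float = 2.0
    fs_max: float = 60.0
    sor_max: float = 4.0
    readpos_ranksum_min: float = -8.0
    dp_max: float = 3105.0
    mq_min: float = 40.0                 # SNVs only
    mq_ranksum_min: float = -12.5        # SNVs only
    inbreeding_coeff_min: float = -0.8   # indels only

    def __post_init__(self):
        for f in self.__dataclass_fields__:
            if not np.isfinite(getattr(self, f)):
                raise ValueError(f"threshold {f} must be finite")


def _criteria(t: FilterThresholds):
    """(field, fail predicate, label, applies-to) for every criterion."""
    return [
        ("QD", lambda v: v < t.qd_min, f"QD<{t.qd_min}", "both"),
        ("FS", lambda v: v > t.fs_max, f"FS>{t.fs_max}", "both"),
        ("SOR", lambda v: v > t.sor_max, f"SOR>{t.sor_max}", "both"),
        ("ReadPosRankSum", lambda v: v < t.readpos_ranksum_min,
         f"ReadPosRankSum<{t.readpos_ranksum_min}", "both"),
        ("DP", lambda v: v > t.dp_max, f"DP>{t.dp_max:g}", "both"),
        ("MQ", lambda v: v < t.mq_min, f"MQ<{t.mq_min}", "snp"),
        ("MQRankSum", lambda v: v < t.mq_ranksum_min,
         f"MQRankSum<{t.mq_ranksum_min}", "snp"),
        ("InbreedingCoeff", lambda v: v < t.inbreeding_coeff_min,
         f"InbreedingCoeff<{t.inbreeding_coeff_min}", "indel"),
    ]


def apply_hard_filters(variants: pd.DataFrame,
                       thresholds: FilterThresholds | None = None
                       ) -> tuple[np.ndarray, pd.Series]:
    """Flag each site against the hard-filter inequalities.

    Returns ``(pass_mask, filter_labels)`` where ``filter_labels`` holds
    "PASS" or the semicolon-joined labels of every failed criterion, ready for
    a VCF FILTER column.  Requires an ``IS_INDEL`` column.
    """
    t = thresholds or FilterThresholds()
    n = len(variants)
    is_indel = variants["IS_INDEL"].to_numpy(dtype=bool)
    reasons = [[] for _ in range(n)]
    skipped: dict[str, int] = {}
    for field, fails, label, applies in _criteria(t):
        if field not in variants.columns:
            skipped[field] = n
            continue
        values = variants[field].to_numpy(dtype=float)
        absent = np.isnan(values)
        if absent.any():
            skipped[field] = int(absent.sum())
        scope = np.ones(n, dtype=bool)
        if applies == "snp":
            scope = ~is_indel
        elif applies == "indel":
            scope = is_indel
        with np.errstate(invalid="ignore"):
            fail = scope & ~absent & fails(values)
        for i in np.flatnonzero(fail):
            reasons[i].append(label)
    for field, count in skipped.items():
        log.warning("annotation %s absent for %d site(s); criterion skipped", field, count)
    labels = pd.Series([";".join(r) if r else "PASS" for r in reasons], index=variants.index)
    pass_mask = np.array([not r for r in reasons])
    return pass_mask, labels


def select_biallelic(variants: pd.DataFrame) -> np.ndarray:
    """Indices of sites with exactly one alternate allele."""
    alt = variants["ALT"].astype(str)
    ok = ~alt.str.contains(",") & (alt != ".") & (alt != "")
    return np.flatnonzero(ok.to_numpy())


def drop_unplaced(variants: pd.DataFrame, characterized_chromosomes) -> np.ndarray:
    """Indices of sites on characterized (named) chromosomes."""
    keep = variants["CHROM"].isin(set(characterized_chromosomes))
    return np.flatnonzero(keep.to_numpy())


def recode_indels(variants: pd.DataFrame) -> pd.DataFrame:
    """Recode multi-character alleles to REF="A"/ALT="T" (idempotent).

    SNV rows are untouched; recoded rows keep their original alleles in
    ``REF_ORIG``/``ALT_ORIG``.  Positions never change.
    """
    out = variants.copy()
    multi = (out["REF"].str.len() > 1) | (out["ALT"].str.len() > 1)
    if "REF_ORIG" not in out.columns:
        out["REF_ORIG"] = out["REF"]
        out["ALT_ORIG"] = out["ALT"]
    out.loc[multi, "REF"] = "A"
    out.loc[multi, "ALT"] = "T"
    return out
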