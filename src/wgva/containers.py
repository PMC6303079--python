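"""In-memory carriers for cohort genotype data.

The whole pipeline operates on a single dense representation: a variants x
samples matrix of alternate-allele dosages (0, 1, 2, with -1 for a missing
genotype call) plus a variant table (chromosome, position, alleles, GATK-style
site annotations) and a cohort design (breed labels, case/control status and
parent-offspring trios).  At the scale this package targets (hundreds of
samples, tens of thousands to millions of sites) a dense int8 matrix is both
the simplest and the fastest container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: INFO fields emitted by joint-genotyping callers that the hard filters consume.
ANNOTATION_FIELDS = (
    "QD",
    "FS",
    "SOR",
    "ReadPosRankSum",
    "DP",
    "MQ",
    "MQRankSum",
    "InbreedingCoeff",
)


@dataclass
class CohortDesign:
    """Sample bookkeeping: who is in the cohort and how samples relate.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers; the column order of the genotype matrix.
    breed_of
        Sample id -> breed label.
    status_of
        Sample id -> ``"case"`` or ``"control"``.  Cases are exactly the
        members of the case breeds: affection status is the breed-defining
        trait itself, not an individual phenotype.
    trios
        ``(offspring, sire, dam)`` id triples; every member must be a cohort
        sample.
    """

    sample_ids: list[str]
    breed_of: dict[str, str]
    status_of: dict[str, str]
    trios: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = set(self.sample_ids)
        if len(ids) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        for s in self.sample_ids:
            if self.status_of.get(s) not in ("case", "control"):
                raise ValueError(f"sample {s!r} lacks a case/control status")
        for trio in self.trios:
            for member in trio:
                if member not in ids:
                    raise ValueError(f"trio member {member!r} not in cohort")
        case_breeds = {self.breed_of[s] for s in self.sample_ids if self.status_of[s] == "case"}
        for s in self.sample_ids:
            expected = "case" if self.breed_of[s] in case_breeds else "control"
            if self.status_of[s] != expected:
                raise ValueError(
                    f"sample {s!r}: status {self.status_of[s]!r} inconsistent with "
                    f"breed {self.breed_of[s]!r} (cases must be exactly the case breeds)"
                )

    # -- convenience views -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def index_of(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    @property
    def case_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.status_of[s] == "case"]

    @property
    def control_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.status_of[s] == "control"]

    @property
    def offspring_ids(self) -> list[str]:
        return [t[0] for t in self.trios]

    @property
    def analysis_ids(self) -> list[str]:
        """Samples used for association: trio offspring are excluded so that
        each independent chromosome is counted once."""
        off = set(self.offspring_ids)
        return [s for s in self.sample_ids if s not in off]

    def mask(self, ids: list[str]) -> np.ndarray:
        wanted = set(ids)
        return np.fromiter((s in wanted for s in self.sample_ids), dtype=bool, count=self.n_samples)

    def trio_indices(self) -> list[tuple[int, int, int]]:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return [(pos[o], pos[s], pos[d]) for o, s, d in self.trios]


@dataclass
class GenotypeMatrix:
    """Variants x samples alternate-allele dosage matrix.

    ``dosages`` is int8 with entries in {0, 1, 2, MISSING}; rows follow
    ``variants`` (a DataFrame with at least CHROM, POS, REF, ALT, IS_INDEL and
    the site annotation columns) and columns follow ``samples``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (variants x samples)")
        nv, ns = self.dosages.shape
        if len(self.variants) != nv:
            raise ValueError("variant table length does not match dosage rows")
        if len(self.samples) != ns:
            raise ValueError("sample list length does not match dosage columns")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or MISSING (-1)")

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
        )

    def alt_freqs(self) -> np.ndarray:
        """Per-variant alternate-allele frequency over non-missing genotypes
        (NaN where every genotype is missing)."""
        d = self.dosages
        ok = d != MISSING
        alt = np.where(ok, d, 0).sum(axis=1)
        denom = 2 * ok.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, alt / np.maximum(denom, 1), np.nan)
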