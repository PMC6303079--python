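"""Breed-structured synthetic cohort generator.

Emulates a whole-genome-sequenced dog cohort: ~100 samples drawn from ~21
discrete pure breeds with strong stratification, a handful of
parent-parent-offspring trios, per-cell genotype missingness, GATK-style site
annotation fields, and an implanted breed-defining recessive deletion that is
homozygous in the "case" breeds and (nearly) absent elsewhere, sitting on a
long fixed flanking haplotype the way an identical-by-descent sweep region
would in closely related breeds.

Population structure follows the Balding-Nichols model: for a variant with
ancestral allele frequency ``p`` and divergence ``F`` (an FST-like parameter),
each breed's frequency is an independent draw from

    Beta(p (1-F)/F, (1-p)(1-F)/F)

which has mean ``p`` and variance ``F p (1-p)``.  Genotypes are then
Hardy-Weinberg within breed.  Linkage disequilibrium is emulated by tiling
variants into blocks that share a latent "core" genotype: each cell copies the
block core with probability ``ld_rho`` and is redrawn independently otherwise.
This is deliberately minimal -- enough LD to exercise VIF pruning and a
pruned-count Bonferroni, with no recombination-map realism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ANNOTATION_FIELDS, MISSING, CohortDesign, GenotypeMatrix

log = logging.getLogger(__name__)

_BASES = np.array(["A", "C", "G", "T"])

#: Default breed sizes: three case breeds (5+3+2 = 10 cases) and eighteen
#: control breeds (12x5 + 6x4 = 84 controls); trio offspring come on top.
DEFAULT_BREED_SIZES = (5, 3, 2) + (5,) * 12 + (4,) * 6


@dataclass
class CausalSpec:
    """How the breed-defining recessive variant is implanted.

    The focal variant is a 1-bp deletion made homozygous in every case-breed
    sample (``case_alt_freq`` = 1) and carried at ``control_alt_freq`` in
    controls.  ``flank_variants`` sites on each side are fixed for the
    alternate allele in case breeds and segregate at
    ``flank_control_alt_freq`` in controls, emulating the long shared
    haplotype around a variant that is identical by descent across related
    breeds.
    """

    variant_index: int | None = None
    case_alt_freq: float = 1.0
    control_alt_freq: float = 0.0
    flank_variants: int = 20
    flank_control_alt_freq: float = 0.05

    def __post_init__(self) -> None:
        for name in ("case_alt_freq", "control_alt_freq", "flank_control_alt_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.flank_variants < 0:
            raise ValueError("flank_variants must be >= 0")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the cohort this generator stands in for: 21 breeds, 10
    case samples in 3 case breeds vs 84 controls, 6 trios, ~6.4% missing
    genotype cells and moderate breed divergence (F = 0.2), which yields the
    strongly inflated association statistics (lambda of a few) that motivate
    genomic control.
    """

    n_breeds: int = 21
    breed_sizes: tuple[int, ...] = DEFAULT_BREED_SIZES
    breed_fst: float = 0.2
    n_variants: int = 20_000
    case_breeds: tuple[int, ...] = (0, 1, 2)
    causal: CausalSpec | None = field(default_factory=CausalSpec)
    missing_rate: float = 0.064
    n_trios: int = 6
    genotype_error_rate: float = 0.05
    annotation_fail_rate: float = 0.02
    seed: int = 0
    # physical layout / nuisance structure
    n_chromosomes: int = 38
    variant_spacing: int = 3_000
    indel_fraction: float = 0.35
    ld_block_size: int = 5
    ld_rho: float = 0.8
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    breed_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.breed_sizes) != self.n_breeds:
            raise ValueError("breed_sizes length must equal n_breeds")
        if any(s < 1 for s in self.breed_sizes):
            raise ValueError("every breed must have at least one sample")
        if not 0.0 <= self.breed_fst < 1.0:
            raise ValueError("breed_fst must be in [0,1)")
        for name in ("missing_rate", "genotype_error_rate", "annotation_fail_rate",
                     "indel_fraction", "ld_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not self.case_breeds:
            raise ValueError("case_breeds must be non-empty")
        if not set(self.case_breeds) < set(range(self.n_breeds)):
            raise ValueError("case_breeds must be a strict subset of breeds")
        if self.ld_block_size < 1 or self.n_variants < 1 or self.n_chromosomes < 1:
            raise ValueError("counts must be positive")
        if not 0.0 < self.ancestral_low <= self.ancestral_high < 1.0:
            raise ValueError("ancestral frequency range must satisfy 0 < low <= high < 1")
        if self.breed_names is not None and len(self.breed_names) != self.n_breeds:
            raise ValueError("breed_names length must equal n_breeds")

    @property
    def names(self) -> tuple[str, ...]:
        if self.breed_names is not None:
            return self.breed_names
        return tuple(f"breed{i + 1:02d}" for i in range(self.n_breeds))


def breed_frequencies(ancestral_freq: float, fst: float, n_breeds: int, rng) -> np.ndarray:
    """Per-breed allele frequencies under the Balding-Nichols model.

    Zero divergence (or a fixed ancestral allele) returns the ancestral
    frequency for every breed without consuming random draws.
    """
    if not 0.0 <= ancestral_freq <= 1.0:
        raise ValueError("ancestral_freq must be in [0,1]")
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must be in [0,1)")
    if fst == 0.0 or ancestral_freq in (0.0, 1.0):
        return np.full(n_breeds, ancestral_freq)
    scale = (1.0 - fst) / fst
    return rng.beta(ancestral_freq * scale, (1.0 - ancestral_freq) * scale, size=n_breeds)


def _balding_nichols_matrix(p: np.ndarray, fst: float, n_breeds: int, rng) -> np.ndarray:
    """Vectorized Balding-Nichols draws: (len(p), n_breeds) frequencies."""
    p = np.asarray(p, dtype=float)
    if fst == 0.0:
        return np.repeat(p[:, None], n_breeds, axis=1)
    scale = (1.0 - fst) / fst
    return rng.beta(p[:, None] * scale, (1.0 - p)[:, None] * scale, size=(len(p), n_breeds))


def _variant_table(cfg: SimulationConfig, rng) -> pd.DataFrame:
    """Physical layout plus alleles and GATK-style annotations.

    Variants are placed at fixed spacing along ``n_chromosomes`` autosome-like
    chromosomes.  Annotation fields are drawn from unit-scale distributions
    centred well inside each filter's pass region; an ``annotation_fail_rate``
    fraction of sites per field is pushed beyond the corresponding threshold.
    """
    n = cfg.n_variants
    per_chrom = int(np.ceil(n / cfg.n_chromosomes))
    chrom_idx = np.arange(n) // per_chrom
    chrom = np.array([f"chr{i + 1}" for i in chrom_idx])
    pos = (np.arange(n) % per_chrom + 1) * cfg.variant_spacing

    is_indel = rng.random(n) < cfg.indel_fraction
    ref_base = _BASES[rng.integers(0, 4, size=n)]
    alt_shift = rng.integers(1, 4, size=n)
    alt_base = _BASES[(np.char.find("ACGT", ref_base.astype("U1")) + alt_shift) % 4]
    ext = _BASES[rng.integers(0, 4, size=n)]
    ref = np.where(is_indel, np.char.add(ref_base, ext), ref_base)
    alt = np.where(is_indel, ref_base, alt_base)  # deletions: REF 2bp, ALT 1bp

    df = pd.DataFrame(
        {"CHROM": chrom, "POS": pos.astype(np.int64), "REF": ref, "ALT": alt,
         "IS_INDEL": is_indel}
    )

    # (pass-region sampler, fail-region sampler) per annotation field
    def norm(mu, sd):
        return lambda size: rng.normal(mu, sd, size)

    draw = {
        "QD": (lambda s: np.clip(rng.normal(20.0, 6.0, s), 2.5, None),
               lambda s: rng.uniform(0.0, 1.9, s)),
        "FS": (lambda s: rng.exponential(5.0, s).clip(max=55.0),
               lambda s: rng.uniform(61.0, 200.0, s)),
        "SOR": (lambda s: np.clip(rng.normal(1.5, 0.6, s), 0.05, 3.9),
                lambda s: rng.uniform(4.1, 9.0, s)),
        "ReadPosRankSum": (lambda s: np.clip(norm(0.0, 1.5)(s), -7.5, None),
                           lambda s: rng.uniform(-15.0, -8.2, s)),
        "DP": (lambda s: np.clip(rng.normal(2000.0, 350.0, s), 100.0, 3100.0),
               lambda s: rng.uniform(3110.0, 6000.0, s)),
        "MQ": (lambda s: np.clip(rng.normal(59.0, 2.5, s), 41.0, None),
               lambda s: rng.uniform(10.0, 39.5, s)),
        "MQRankSum": (lambda s: np.clip(norm(0.0, 2.0)(s), -12.0, None),
                      lambda s: rng.uniform(-20.0, -12.8, s)),
        "InbreedingCoeff": (lambda s: np.clip(norm(0.1, 0.2)(s), -0.75, 1.0),
                            lambda s: rng.uniform(-1.0, -0.82, s)),
    }
    for name in ANNOTATION_FIELDS:
        ok, bad = draw[name]
        values = ok(n)
        fail = rng.random(n) < cfg.annotation_fail_rate
        values = np.where(fail, bad(n), values)
        if name == "DP":
            df[name] = np.round(values).astype(np.int64)
        else:
            # materialize at single precision: VCF Float INFO is float32
            df[name] = np.float32(values).astype(np.float64)
    return df


def _hwe_genotypes(freqs: np.ndarray, rng) -> np.ndarray:
    """Binomial(2, f) draws; ``freqs`` broadcast to the output shape."""
    return rng.binomial(2, freqs).astype(np.int8)


def implant_causal_variant(matrix: GenotypeMatrix, design: CohortDesign,
                           causal: CausalSpec, rng=None) -> int:
    """Overwrite one variant (plus its flanking haplotype) with the
    breed-defining recessive pattern.  Returns the causal variant index.

    Case-breed samples become homozygous alternate at the focal site and
    across the flank; controls carry the alternate allele at the configured
    low frequencies (Hardy-Weinberg draws).  The focal site's alleles are
    rewritten as a deletion so the consequence caller has something real to
    chew on downstream.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n = matrix.n_variants
    idx = causal.variant_index if causal.variant_index is not None else n // 2
    if not 0 <= idx < n:
        raise IndexError(f"causal variant index {idx} out of range [0, {n})")

    case = np.fromiter(
        (design.status_of[s] == "case" for s in matrix.samples), dtype=bool, count=matrix.n_samples
    )
    control = ~case

    lo = max(0, idx - causal.flank_variants)
    hi = min(n, idx + causal.flank_variants + 1)
    chrom = matrix.variants["CHROM"].to_numpy()
    same_chrom = chrom[lo:hi] == chrom[idx]
    region = np.arange(lo, hi)[same_chrom]

    for j in region:
        row = matrix.dosages[j]
        if j == idx:
            f_case, f_ctrl = causal.case_alt_freq, causal.control_alt_freq
        else:
            f_case, f_ctrl = 1.0, causal.flank_control_alt_freq
        row[case] = 2 if f_case == 1.0 else _hwe_genotypes(np.full(case.sum(), f_case), rng)
        row[control] = 0 if f_ctrl == 0.0 else _hwe_genotypes(np.full(control.sum(), f_ctrl), rng)

    matrix.variants.loc[idx, ["REF", "ALT", "IS_INDEL"]] = ["AC", "A", True]
    matrix.variants["CAUSAL"] = False
    matrix.variants.loc[idx, "CAUSAL"] = True
    # the scenario being emulated is a causal variant that survived site
    # filtering, so the implanted region carries nominal passing annotations
    nominal = {"QD": 20.0, "FS": 3.0, "SOR": 1.5, "ReadPosRankSum": 0.0,
               "DP": 2000, "MQ": 60.0, "MQRankSum": 0.0, "InbreedingCoeff": 0.1}
    for field_name, value in nominal.items():
        if field_name in matrix.variants.columns:
            if field_name != "DP":
                value = float(np.float32(value))  # match VCF single precision
            matrix.variants.loc[region, field_name] = value
    return idx


def simulate_trios(matrix: GenotypeMatrix, design: CohortDesign, n_trios: int,
                   genotype_error_rate: float, rng) -> tuple[GenotypeMatrix, CohortDesign]:
    """Append trio offspring formed by Mendelian transmission from sampled
    parent pairs, then corrupt offspring cells at ``genotype_error_rate``
    (uniform substitution to a different dosage).  Parents are paired within
    breed so offspring have a well-defined breed label.
    """
    if n_trios == 0:
        return matrix, design
    by_breed: dict[str, list[str]] = {}
    for s in design.sample_ids:
        by_breed.setdefault(design.breed_of[s], []).append(s)
    eligible = [b for b, members in by_breed.items() if len(members) >= 2]
    if 2 * n_trios > sum(len(by_breed[b]) // 2 * 2 for b in eligible):
        raise ValueError("not enough parent candidates for the requested trios")
    breeds = list(rng.permutation(eligible))
    # cycle breeds, taking a fresh parent pair each time
    taken: dict[str, int] = {b: 0 for b in eligible}
    trios: list[tuple[str, str, str]] = []
    offspring_cols = []
    b_i = 0
    while len(trios) < n_trios:
        b = breeds[b_i % len(breeds)]
        b_i += 1
        members = by_breed[b]
        if taken[b] + 2 > len(members):
            continue
        sire, dam = members[taken[b]], members[taken[b] + 1]
        taken[b] += 2
        child = f"{b}_trio{len(trios) + 1}"
        gs = matrix.dosages[:, matrix.samples.index(sire)].astype(np.int16)
        gd = matrix.dosages[:, matrix.samples.index(dam)].astype(np.int16)
        t1 = rng.binomial(1, gs / 2.0)
        t2 = rng.binomial(1, gd / 2.0)
        g = (t1 + t2).astype(np.int8)
        if genotype_error_rate > 0:
            err = rng.random(matrix.n_variants) < genotype_error_rate
            shift = rng.integers(1, 3, size=matrix.n_variants)
            g = np.where(err, (g + shift) % 3, g).astype(np.int8)
        offspring_cols.append(g)
        trios.append((child, sire, dam))

    dosages = np.column_stack([matrix.dosages] + [c[:, None] for c in offspring_cols])
    samples = list(matrix.samples) + [t[0] for t in trios]
    breed_of = dict(design.breed_of)
    status_of = dict(design.status_of)
    case_breeds = {design.breed_of[s] for s in design.case_ids}
    for child, sire, _ in trios:
        breed_of[child] = breed_of[sire]
        status_of[child] = "case" if breed_of[sire] in case_breeds else "control"
    new_design = CohortDesign(
        sample_ids=samples, breed_of=breed_of, status_of=status_of,
        trios=design.trios + trios,
    )
    new_matrix = GenotypeMatrix(dosages=dosages, variants=matrix.variants, samples=samples)
    return new_matrix, new_design


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeMatrix, CohortDesign]:
    """Generate a full cohort under the configured study conditions.

    Order of operations: per-breed frequencies and Hardy-Weinberg genotypes
    (with LD blocks) -> implant the causal variant and its fixed flank ->
    form trio offspring by Mendelian transmission (so an error rate of zero
    yields a Mendel-clean cohort) -> apply per-cell missingness -> attach the
    site annotation table.  Everything is driven by one seeded generator, so
    equal seeds give identical cohorts.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    names = cfg.names
    case_breed_names = {names[i] for i in cfg.case_breeds}

    sample_ids: list[str] = []
    breed_of: dict[str, str] = {}
    status_of: dict[str, str] = {}
    for b, size in enumerate(cfg.breed_sizes):
        for k in range(size):
            sid = f"{names[b]}_{k + 1}"
            sample_ids.append(sid)
            breed_of[sid] = names[b]
            status_of[sid] = "case" if names[b] in case_breed_names else "control"
    design = CohortDesign(sample_ids=sample_ids, breed_of=breed_of, status_of=status_of)

    variants = _variant_table(cfg, rng)

    n_blocks = int(np.ceil(cfg.n_variants / cfg.ld_block_size))
    p_anc = rng.uniform(cfg.ancestral_low, cfg.ancestral_high, size=n_blocks)
    freq = _balding_nichols_matrix(p_anc, cfg.breed_fst, cfg.n_breeds, rng)  # blocks x breeds

    breed_idx = np.concatenate(
        [np.full(size, b) for b, size in enumerate(cfg.breed_sizes)]
    )
    block_of = np.arange(cfg.n_variants) // cfg.ld_block_size
    f_sample_block = freq[:, breed_idx]                       # blocks x samples
    core = _hwe_genotypes(f_sample_block, rng)                # blocks x samples
    f_cells = f_sample_block[block_of]                        # variants x samples
    indep = _hwe_genotypes(f_cells, rng)
    copy_core = rng.random(indep.shape) < cfg.ld_rho
    dosages = np.where(copy_core, core[block_of], indep).astype(np.int8)

    matrix = GenotypeMatrix(dosages=dosages, variants=variants, samples=sample_ids)

    causal_idx = None
    if cfg.causal is not None:
        causal_idx = implant_causal_variant(matrix, design, cfg.causal, rng)

    matrix, design = simulate_trios(matrix, design, cfg.n_trios,
                                    cfg.genotype_error_rate, rng)

    if cfg.missing_rate > 0:
        miss = rng.random(matrix.dosages.shape) < cfg.missing_rate
        if causal_idx is not None:
            # the emulated scenario is a causal site genotyped in every
            # sample; missingness elsewhere is untouched
            miss[causal_idx, :] = False
        matrix.dosages[miss] = MISSING

    log.info("simulated cohort: %d variants x %d samples (%d cases, %d trios)",
             matrix.n_variants, matrix.n_samples, len(design.case_ids), len(design.trios))
    return matrix, design
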