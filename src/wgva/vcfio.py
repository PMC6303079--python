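"""VCF 4.2 and pedigree serialization.

Writing is a deterministic text emitter (GT-only FORMAT, annotations in INFO,
filter labels in FILTER); reading goes through cyvcf2/htslib.  Float INFO
fields are stored by htslib at single precision, so the generator materializes
annotation values as float32 and the writer prints them with ``%.9g`` -- nine
significant digits uniquely identify a float32, making the write -> read round
trip exact.

The pedigree file is the classic six-column whitespace-delimited layout
(family, individual, sire, dam, sex, phenotype) with "0" for an unknown parent
and phenotype coded 2 = case / 1 = control; breed labels travel in a sidecar
two-column TSV since the six-column format has nowhere to put them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import ANNOTATION_FIELDS, MISSING, CohortDesign, GenotypeMatrix

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

_INFO_TYPES = {name: ("Integer" if name == "DP" else "Float") for name in ANNOTATION_FIELDS}


def _info_string(row) -> str:
    parts = []
    for name in ANNOTATION_FIELDS:
        if name not in row or pd.isna(row[name]):
            continue
        if _INFO_TYPES[name] == "Integer":
            parts.append(f"{name}={int(row[name])}")
        else:
            parts.append(f"{name}={row[name]:.9g}")
    return ";".join(parts) if parts else "."


def write_vcf(matrix: GenotypeMatrix, path: str, design: CohortDesign | None = None) -> None:
    """Write the matrix as an uncompressed VCF 4.2 file.

    The FILTER column carries semicolon-joined fail labels from the hard
    filters when a ``FILTER`` column is present in the variant table, and
    ``.`` otherwise.
    """
    variants = matrix.variants
    chroms = list(dict.fromkeys(variants["CHROM"]))
    filters: set[str] = set()
    if "FILTER" in variants.columns:
        for lab in variants["FILTER"]:
            if lab and lab not in (".", "PASS"):
                filters.update(lab.split(";"))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=wgva\n")
        for c in chroms:
            sub = variants.loc[variants["CHROM"] == c, "POS"]
            fh.write(f"##contig=<ID={c},length={int(sub.max()) + 1000}>\n")
        for name in ANNOTATION_FIELDS:
            fh.write(
                f"##INFO=<ID={name},Number=1,Type={_INFO_TYPES[name]},"
                f'Description="Site annotation">\n'
            )
        for lab in sorted(filters):
            fh.write(f'##FILTER=<ID={lab},Description="Hard-filter fail">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        filt_col = variants["FILTER"] if "FILTER" in variants.columns else None
        for i in range(matrix.n_variants):
            row = variants.iloc[i]
            filt = filt_col.iloc[i] if filt_col is not None else "."
            gts = "\t".join(_GT[int(g)] for g in matrix.dosages[i])
            fh.write(
                f"{row['CHROM']}\t{int(row['POS'])}\t.\t{row['REF']}\t{row['ALT']}"
                f"\t.\t{filt}\t{_info_string(row)}\tGT\t{gts}\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (bi-allelic dosage = count of
    non-reference alleles; any allele missing makes the genotype missing)."""
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, records = [], []
    for v in vcf:
        alt = ",".join(v.ALT) if v.ALT else "."
        rec = {
            "CHROM": v.CHROM,
            "POS": v.POS,
            "REF": v.REF,
            "ALT": alt,
            "IS_INDEL": bool(v.is_indel),
            "FILTER": v.FILTER if v.FILTER is not None else "PASS",
        }
        for name in ANNOTATION_FIELDS:
            val = v.INFO.get(name)
            if val is not None:
                rec[name] = float(val) if name != "DP" else int(val)
            else:
                rec[name] = np.nan if name != "DP" else np.nan
        records.append(rec)
        dos = np.empty(len(samples), dtype=np.int8)
        for j, gt in enumerate(v.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                dos[j] = MISSING
            else:
                dos[j] = (a != 0) + (b != 0)
        rows.append(dos)
    variants = pd.DataFrame(records)
    dosages = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


def write_pedigree(design: CohortDesign, path: str, breed_path: str | None = None) -> None:
    """Write the six-column pedigree file plus the breed sidecar TSV."""
    sire_of = {o: s for o, s, _ in design.trios}
    dam_of = {o: d for o, _, d in design.trios}
    sires = set(sire_of.values())
    dams = set(dam_of.values())
    with open(path, "w") as fh:
        for s in design.sample_ids:
            sex = 1 if s in sires else 2 if s in dams else 0
            pheno = 2 if design.status_of[s] == "case" else 1
            fh.write(f"{design.breed_of[s]} {s} {sire_of.get(s, 0)} "
                     f"{dam_of.get(s, 0)} {sex} {pheno}\n")
    if breed_path is None:
        breed_path = path + ".breeds.tsv"
    with open(breed_path, "w") as fh:
        fh.write("sample\tbreed\n")
        for s in design.sample_ids:
            fh.write(f"{s}\t{design.breed_of[s]}\n")


def read_pedigree(path: str, breed_path: str | None = None) -> CohortDesign:
    """Reconstruct a CohortDesign from the pedigree file (and sidecar)."""
    ped = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["fid", "iid", "sire", "dam", "sex", "pheno"],
                      dtype=str)
    if breed_path is None:
        breed_path = path + ".breeds.tsv"
    try:
        breeds = pd.read_csv(breed_path, sep="\t").set_index("sample")["breed"].to_dict()
    except FileNotFoundError:
        breeds = dict(zip(ped["iid"], ped["fid"]))
    sample_ids = list(ped["iid"])
    status_of = {r.iid: ("case" if r.pheno == "2" else "control") for r in ped.itertuples()}
    trios = [(r.iid, r.sire, r.dam) for r in ped.itertuples()
             if r.sire != "0" and r.dam != "0"]
    return CohortDesign(
        sample_ids=sample_ids,
        breed_of={s: breeds.get(s, "unknown") for s in sample_ids},
        status_of=status_of,
        trios=trios,
    )
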