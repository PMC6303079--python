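"""Protein-level consequence prediction for small coding indels.

Given a transcript model (CDS plus 3'UTR) and a CDS-internal variant in
c.-coordinates, the caller translates the wild-type CDS and the mutant
sequence from the start codon onward -- running past the wild-type stop into
the UTR if the frame shift has eliminated it -- and compares the two proteins
residue by residue.  An indel whose length is not a multiple of three shifts
the reading frame, producing a run of novel residues that ends at the first
downstream stop codon; the structured call records where the proteins first
diverge, how many novel residues precede the new stop, and the net length
change (positive = truncation, negative = extension).

Notation: two renderings are provided.  The HGVS convention counts the stop
itself -- p.<Wt><pos><New>fsTer<k> with k = novel residues + 1 -- while the
older fsX style writes the count of altered residues.  A frameshift whose
very first novel codon is a stop is rendered p.(<Wt><pos>Ter).  The
structured fields, not the strings, are the source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.SeqUtils import seq3

_TABLE = unambiguous_dna_by_id[1]
_CODON = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as sequence + CDS coordinates (1-based, inclusive).

    The CDS must have length divisible by three, start with ATG and end with
    a stop codon; sequence past ``cds_end`` is treated as 3'UTR available to
    frameshifted translation.
    """

    id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not 1 <= self.cds_start < self.cds_end <= len(seq):
            raise ValueError("CDS coordinates outside the sequence")
        cds = self.cds
        if len(cds) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if not cds.startswith("ATG"):
            raise ValueError("CDS must begin with ATG")
        if cds[-3:] not in _STOPS:
            raise ValueError("CDS must end with a stop codon")

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start - 1:self.cds_end]

    @property
    def utr3(self) -> str:
        return self.sequence[self.cds_end:]


@dataclass(frozen=True)
class FrameshiftCall:
    """Structured description of an indel's protein consequence.

    ``n_altered`` counts novel residues after the divergence point,
    excluding the stop; when a stop was found the lengths satisfy
    ``mutant_length = fs_position - 1 + n_altered``.
    """

    is_frameshift: bool
    fs_position: int | None
    wt_residue: str | None
    new_residue: str | None
    n_altered: int | None
    wt_length: int
    mutant_length: int | None
    truncation: int | None
    no_stop: bool = False

    def __post_init__(self):
        if (self.is_frameshift and not self.no_stop
                and self.fs_position is not None and self.mutant_length is not None
                and self.mutant_length != self.fs_position - 1 + self.n_altered):
            raise ValueError(
                "inconsistent call: mutant_length must equal fs_position - 1 + n_altered")


def apply_variant(t: TranscriptModel, pos: int, ref: str, alt: str) -> str:
    """Mutant full-length sequence after replacing ``ref`` with ``alt`` at
    CDS coordinate ``pos`` (c.1 = the A of the start codon)."""
    ref, alt = ref.upper(), alt.upper()
    idx = t.cds_start - 1 + pos - 1
    if pos < 1 or idx + len(ref) > len(t.sequence):
        raise ValueError(f"variant at c.{pos} outside the transcript")
    observed = t.sequence[idx:idx + len(ref)]
    if observed != ref:
        raise ValueError(
            f"reference mismatch at c.{pos}: expected {ref!r}, transcript has {observed!r}")
    return t.sequence[:idx] + alt + t.sequence[idx + len(ref):]


def translate(seq: str) -> tuple[str, bool]:
    """Translate in frame from the first base, stopping at the first stop
    codon.  Returns ``(protein, stop_found)``; a trailing partial codon is
    ignored.
    """
    seq = seq.upper()
    protein = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        if codon in _STOPS:
            return "".join(protein), True
        protein.append(_CODON.get(codon, "X"))
    return "".join(protein), False


def call_consequence(t: TranscriptModel, pos: int, ref: str, alt: str) -> FrameshiftCall:
    """Call the protein-level consequence of a CDS-internal indel or
    substitution."""
    cds_len = t.cds_end - t.cds_start + 1
    if not 1 <= pos <= cds_len:
        raise ValueError(f"c.{pos} is outside the CDS (length {cds_len})")
    wt_protein, _ = translate(t.cds)
    mutant = apply_variant(t, pos, ref, alt)
    # translate the mutant from the start codon through the 3'UTR: the new
    # stop of a frameshift may lie beyond the wild-type stop
    mut_protein, stop_found = translate(mutant[t.cds_start - 1:])

    indel_delta = len(alt) - len(ref)
    is_fs = indel_delta % 3 != 0

    wt_len = len(wt_protein)
    # first differing residue (1-based); positions beyond a protein's end
    # compare as differences (stop/absence vs residue)
    fs_position = None
    limit = max(wt_len, len(mut_protein))
    for i in range(limit):
        wt_r = wt_protein[i] if i < wt_len else None
        mu_r = mut_protein[i] if i < len(mut_protein) else None
        if wt_r != mu_r:
            fs_position = i + 1
            break

    if fs_position is None:
        # silent at the protein level
        return FrameshiftCall(
            is_frameshift=is_fs, fs_position=None, wt_residue=None,
            new_residue=None, n_altered=0 if stop_found else None,
            wt_length=wt_len,
            mutant_length=len(mut_protein) if stop_found else None,
            truncation=wt_len - len(mut_protein) if stop_found else None,
            no_stop=not stop_found)

    wt_residue = wt_protein[fs_position - 1] if fs_position <= wt_len else "Ter"
    if not stop_found:
        return FrameshiftCall(
            is_frameshift=is_fs, fs_position=fs_position, wt_residue=wt_residue,
            new_residue=(mut_protein[fs_position - 1]
                         if fs_position <= len(mut_protein) else None),
            n_altered=None, wt_length=wt_len, mutant_length=None,
            truncation=None, no_stop=True)

    mut_len = len(mut_protein)
    if fs_position > mut_len:
        # the first novel codon is a stop: protein is a clean truncation
        new_residue = "Ter"
        n_altered = 0
    else:
        new_residue = mut_protein[fs_position - 1]
        n_altered = mut_len - (fs_position - 1)
    return FrameshiftCall(
        is_frameshift=is_fs, fs_position=fs_position, wt_residue=wt_residue,
        new_residue=new_residue, n_altered=n_altered, wt_length=wt_len,
        mutant_length=mut_len if fs_position <= mut_len else fs_position - 1,
        truncation=wt_len - (mut_len if fs_position <= mut_len else fs_position - 1),
        no_stop=False)


def render_notation(call: FrameshiftCall, convention: str = "hgvs") -> str:
    """Protein notation string for a call.

    ``hgvs``: p.<Wt3><pos><New3>fsTer<k>, k = n_altered + 1 (stop included in
    the count).  ``legacy``: p.<Wt3><pos><New3>fsX<n_altered> (count of
    altered residues only).  Immediate stops render p.(<Wt3><pos>Ter); calls
    without a downstream stop render an explicit marker.
    """
    if convention not in ("hgvs", "legacy"):
        raise ValueError(f"unknown convention {convention!r}")
    if call.fs_position is None:
        return "p.(=)"
    wt3 = seq3(call.wt_residue) if call.wt_residue != "Ter" else "Ter"
    if call.no_stop:
        new3 = seq3(call.new_residue) if call.new_residue else "?"
        return f"p.{wt3}{call.fs_position}{new3}fs (no stop found)"
    if call.new_residue == "Ter":
        return f"p.({wt3}{call.fs_position}Ter)"
    new3 = seq3(call.new_residue)
    if not call.is_frameshift:
        return f"p.{wt3}{call.fs_position}{new3}"
    if convention == "hgvs":
        return f"p.{wt3}{call.fs_position}{new3}fsTer{call.n_altered + 1}"
    return f"p.{wt3}{call.fs_position}{new3}fsX{call.n_altered}"
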