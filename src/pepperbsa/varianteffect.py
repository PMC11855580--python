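"""CDS-level consequence annotation for candidate-gene variants.

Classifies single-base substitutions in coding sequences as synonymous,
missense, stop-gained, stop-lost or start-lost, reporting the affected
codon, the truncated protein length for premature stops, and whether the
codon falls inside an annotated protein domain.

Positions count from the A of the start codon ATG as 1, so base ``p``
falls in codon ``ceil(p / 3)`` at within-codon position
``((p - 1) mod 3) + 1``.  Under this convention a G->A change at CDS
position 1428 hits the third base of codon 476; if that codon is TGG the
change creates the stop TGA, truncating a 586-residue protein to 475
amino acids.

Frameshift annotation for indels is limited to reporting the first
affected codon; no downstream stop scanning is attempted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio import SeqIO

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # {TAA, TAG, TGA}


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; ``*`` for a stop."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    return standard_dna_table.forward_table[codon]


@dataclass(frozen=True)
class CodingSequence:
    """A validated CDS: ATG ... in-frame sense codons ... stop codon.

    ``domains`` are (name, aa_start, aa_end) in 1-based amino-acid
    coordinates, inclusive on both ends.
    """

    id: str
    bases: str
    domains: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        b = self.bases.upper()
        object.__setattr__(self, "bases", b)
        if len(b) % 3 != 0:
            raise ValueError(f"{self.id}: CDS length {len(b)} not divisible by 3")
        if not b.startswith("ATG"):
            raise ValueError(f"{self.id}: CDS does not begin with ATG")
        if b[-3:] not in STOP_CODONS:
            raise ValueError(f"{self.id}: CDS does not end with a stop codon")
        for k in range(0, len(b) - 3, 3):
            if b[k:k + 3] in STOP_CODONS:
                raise ValueError(
                    f"{self.id}: internal stop codon at codon {k // 3 + 1}"
                )
        if any(c not in "ACGT" for c in b):
            raise ValueError(f"{self.id}: non-ACGT base in CDS")

    @property
    def n_codons(self) -> int:
        return len(self.bases) // 3

    @property
    def protein_length(self) -> int:
        """Residues in the full-length protein (terminal stop excluded)."""
        return self.n_codons - 1

    def codon(self, index: int) -> str:
        """1-based codon lookup."""
        if not 1 <= index <= self.n_codons:
            raise IndexError(f"codon index {index} out of 1..{self.n_codons}")
        return self.bases[(index - 1) * 3: index * 3]

    def protein(self) -> str:
        """Full translation (no stop), via the standard genetic code."""
        return str(Seq(self.bases).translate(to_stop=True))


@dataclass(frozen=True)
class CdsVariant:
    """A substitution at a 1-based offset from the A of the start codon."""

    cds_id: str
    pos: int
    ref_base: str
    alt_base: str


@dataclass(frozen=True)
class EffectCall:
    """Consequence of one CDS variant."""

    cds_id: str
    consequence: str  # synonymous | missense | stop_gained | stop_lost | start_lost
    codon_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    truncated_protein_length: int | None
    full_protein_length: int
    in_domain: bool


def annotate_cds_variant(cds: CodingSequence, v: CdsVariant) -> EffectCall:
    """Classify a single-base CDS substitution.

    Raises ``ValueError`` when the variant's stated reference base does
    not match the CDS at that position, or the position is out of range.
    """
    if not 1 <= v.pos <= len(cds.bases):
        raise ValueError(
            f"{cds.id}: variant position {v.pos} outside CDS of length "
            f"{len(cds.bases)}"
        )
    observed = cds.bases[v.pos - 1]
    if observed != v.ref_base.upper():
        raise ValueError(
            f"{cds.id}: reference mismatch at position {v.pos}: variant says "
            f"{v.ref_base}, CDS has {observed}"
        )
    codon_index = (v.pos + 2) // 3  # ceil(pos / 3)
    offset = (v.pos - 1) % 3
    ref_codon = cds.codon(codon_index)
    alt_codon = ref_codon[:offset] + v.alt_base.upper() + ref_codon[offset + 1:]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)

    if ref_aa == "*" and alt_aa != "*":
        consequence = "stop_lost"
    elif alt_aa == "*" and ref_aa != "*":
        consequence = "stop_gained"
    elif codon_index == 1 and alt_codon != "ATG":
        consequence = "start_lost"
    elif ref_aa == alt_aa:
        consequence = "synonymous"
    else:
        consequence = "missense"

    in_domain = any(start <= codon_index <= end
                    for _, start, end in cds.domains)
    return EffectCall(
        cds_id=cds.id,
        consequence=consequence,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        truncated_protein_length=(codon_index - 1
                                  if consequence == "stop_gained" else None),
        full_protein_length=cds.protein_length,
        in_domain=in_domain,
    )


def truncation_summary(calls: Iterable[EffectCall]) -> pd.DataFrame:
    """One row per call; stop-gains carry the truncated/full length ratio."""
    rows = []
    for c in calls:
        frac = (c.truncated_protein_length / c.full_protein_length
                if c.consequence == "stop_gained" else None)
        rows.append({
            "gene": c.cds_id,
            "consequence": c.consequence,
            "codon_index": c.codon_index,
            "aa_change": f"{c.ref_aa}{c.codon_index}{c.alt_aa}",
            "truncated_length": c.truncated_protein_length,
            "full_length": c.full_protein_length,
            "truncation_fraction": frac,
            "in_domain": c.in_domain,
        })
    return pd.DataFrame(rows, columns=[
        "gene", "consequence", "codon_index", "aa_change",
        "truncated_length", "full_length", "truncation_fraction", "in_domain",
    ])


# ---------------------------------------------------------------------------
# synthetic fixture construction
# ---------------------------------------------------------------------------

_SENSE_CODONS = tuple(
    sorted(set(standard_dna_table.forward_table) - {"ATG"})
)


def make_synthetic_cds(n_codons: int,
                       codon_overrides: dict[int, str] | None = None,
                       cds_id: str = "synthetic",
                       domains: Sequence[tuple[str, int, int]] = (),
                       seed: int = 0) -> CodingSequence:
    """Engineer a synthetic CDS carrying chosen codons at chosen positions.

    ``n_codons`` counts sense codons plus the terminal stop; interior
    codons are drawn from the sense codons of the standard code, with
    ``codon_overrides`` (1-based codon index -> codon string) applied on
    top.  Useful for reproducing published codon-level variants without
    the real gene sequence.
    """
    import numpy as np

    if n_codons < 2:
        raise ValueError("need at least a start and a stop codon")
    rng = np.random.default_rng(seed)
    codons = ["ATG"]
    codons += [ _SENSE_CODONS[i]
                for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2) ]
    codons.append("TAA")
    for index, codon in (codon_overrides or {}).items():
        if not 1 <= index <= n_codons:
            raise ValueError(f"override codon index {index} out of range")
        if index < n_codons and codon.upper() in STOP_CODONS:
            raise ValueError("cannot place an internal stop codon")
        codons[index - 1] = codon.upper()
    return CodingSequence(cds_id, "".join(codons), tuple(domains))


# ---------------------------------------------------------------------------
# file interfaces
# ---------------------------------------------------------------------------

def read_cds_fasta(path: str | Path,
                   domains_path: str | Path | None = None
                   ) -> dict[str, CodingSequence]:
    """Load coding sequences from FASTA, with an optional domain side-car.

    The side-car is a TSV of cds_id, name, aa_start, aa_end.
    """
    domain_map: dict[str, list[tuple[str, int, int]]] = {}
    if domains_path is not None:
        with open(domains_path, encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                cds_id, name, start, end = row[:4]
                domain_map.setdefault(cds_id, []).append(
                    (name, int(start), int(end)))
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = CodingSequence(
            rec.id, str(rec.seq), tuple(domain_map.get(rec.id, ())))
    return out


def read_cds_variants(path: str | Path) -> list[CdsVariant]:
    """Variants as a 4-column TSV: cds_id, pos, ref, alt."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 4:
                raise ValueError(f"line {lineno}: expected 4 columns")
            out.append(CdsVariant(row[0], int(row[1]), row[2], row[3]))
    return out


def write_effect_table(calls: Iterable[EffectCall], path: str | Path) -> None:
    truncation_summary(calls).to_csv(path, sep="\t", index=False,
                                     lineterminator="\n")
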