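"""Variant/allele-depth tables for bulked-segregant analysis.

The scan's substrate is a table of biallelic sites with per-sample read
depths for four samples: the green parent (P1), the yellow parent (P2),
the extreme-yellow bulk (D1) and the extreme-green bulk (D2).  Two input
dialects are supported: a native tab-separated format and VCF 4.x with
AD-style per-sample allele depths.

Coordinates are 1-based and inclusive (VCF convention); genomic windows
elsewhere in the package use half-open base-pair intervals [start, end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SAMPLES = ("P1", "P2", "D1", "D2")

#: header of the native TSV dialect (bit-exact)
TSV_HEADER = "#chrom\tpos\tref\talt\tvtype\tP1\tP2\tD1\tD2"


class VariantFormatError(ValueError):
    """Raised for malformed variant-table input; messages carry line numbers."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP or small indel at a 1-based genomic position."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantFormatError(
                f"position must be >= 1, got {self.pos} at {self.chrom}"
            )
        if self.ref_allele == self.alt_allele:
            raise VariantFormatError(
                f"ref and alt alleles identical ({self.ref_allele}) at "
                f"{self.chrom}:{self.pos}"
            )

    @property
    def vtype(self) -> str:
        """``"SNP"`` if both alleles are single bases, else ``"InDel"``."""
        return "SNP" if len(self.ref_allele) == len(self.alt_allele) == 1 else "InDel"


@dataclass(frozen=True)
class SampleDepths:
    """Per-allele read counts for the four samples at one site.

    Each mapping goes allele string -> non-negative read count.
    """

    p1: Mapping[str, int]
    p2: Mapping[str, int]
    d1: Mapping[str, int]
    d2: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, depths in zip(SAMPLES, (self.p1, self.p2, self.d1, self.d2)):
            for allele, count in depths.items():
                if count < 0:
                    raise VariantFormatError(
                        f"negative depth {count} for allele {allele} in {name}"
                    )

    def sample(self, name: str) -> Mapping[str, int]:
        try:
            return {"P1": self.p1, "P2": self.p2, "D1": self.d1, "D2": self.d2}[name]
        except KeyError:
            raise KeyError(f"unknown sample {name!r}; expected one of {SAMPLES}")

    def total(self, name: str) -> int:
        return sum(self.sample(name).values())


@dataclass
class VariantTable:
    """Ordered variant sites with per-sample depths and chromosome lengths.

    ``yellow_allele`` is populated by :func:`filter_parental_informative`:
    for each retained site it names the allele carried by the yellow
    parent (P2).
    """

    sites: list[VariantSite]
    depths: list[SampleDepths]
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    yellow_allele: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.depths):
            raise ValueError("sites and depths must have equal length")
        if self.yellow_allele is not None and len(self.yellow_allele) != len(self.sites):
            raise ValueError("yellow_allele must align with sites")
        if not self._is_sorted():
            logger.warning("variant table not sorted by (chrom, pos); sorting")
            self.sort()
        self._check_duplicates()
        if not self.chrom_lengths:
            # fall back to the last observed position per chromosome
            for s in self.sites:
                if s.pos > self.chrom_lengths.get(s.chrom, 0):
                    self.chrom_lengths[s.chrom] = s.pos

    def _is_sorted(self) -> bool:
        keys = [(s.chrom, s.pos) for s in self.sites]
        return all(a <= b for a, b in zip(keys, keys[1:]))

    def _check_duplicates(self) -> None:
        seen = set()
        for s in self.sites:
            key = (s.chrom, s.pos, s.alt_allele)
            if key in seen:
                raise VariantFormatError(f"duplicate site {key}")
            seen.add(key)

    def sort(self) -> None:
        order = sorted(range(len(self.sites)),
                       key=lambda i: (self.sites[i].chrom, self.sites[i].pos))
        self.sites = [self.sites[i] for i in order]
        self.depths = [self.depths[i] for i in order]
        if self.yellow_allele is not None:
            self.yellow_allele = [self.yellow_allele[i] for i in order]

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[tuple[VariantSite, SampleDepths]]:
        return iter(zip(self.sites, self.depths))

    def to_dataframe(self) -> pd.DataFrame:
        """Flatten to a DataFrame (one row per site, depth cells as dicts)."""
        rows = []
        for i, (s, d) in enumerate(self):
            row = {
                "chrom": s.chrom, "pos": s.pos,
                "ref": s.ref_allele, "alt": s.alt_allele, "vtype": s.vtype,
                "P1": dict(d.p1), "P2": dict(d.p2),
                "D1": dict(d.d1), "D2": dict(d.d2),
            }
            if self.yellow_allele is not None:
                row["yellow_allele"] = self.yellow_allele[i]
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# native TSV dialect
# ---------------------------------------------------------------------------

def _format_depths(depths: Mapping[str, int]) -> str:
    return ";".join(f"{a}:{c}" for a, c in depths.items())


def _parse_depths(cell: str, lineno: int) -> dict[str, int]:
    out: dict[str, int] = {}
    for part in cell.split(";"):
        try:
            allele, count = part.split(":")
            out[allele] = int(count)
        except ValueError:
            raise VariantFormatError(
                f"line {lineno}: malformed depth cell {cell!r}"
            )
    return out


def write_variant_table(table: VariantTable, path: str | Path) -> None:
    """Write the native TSV dialect (UTF-8, LF line endings)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for chrom, length in table.chrom_lengths.items():
            fh.write(f"##contig={chrom}:{length}\n")
        fh.write(TSV_HEADER + "\n")
        for s, d in table:
            cells = [s.chrom, str(s.pos), s.ref_allele, s.alt_allele, s.vtype]
            cells += [_format_depths(d.sample(name)) for name in SAMPLES]
            fh.write("\t".join(cells) + "\n")


def _read_tsv(path: Path) -> VariantTable:
    sites: list[VariantSite] = []
    depths: list[SampleDepths] = []
    chrom_lengths: dict[str, int] = {}
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##contig="):
                chrom, _, length = line[len("##contig="):].partition(":")
                chrom_lengths[chrom] = int(length)
                continue
            if line.startswith("#chrom"):
                if line != TSV_HEADER:
                    raise VariantFormatError(
                        f"line {lineno}: unexpected header {line!r}"
                    )
                header_seen = True
                continue
            if not header_seen:
                raise VariantFormatError(f"line {lineno}: data before header")
            fields = line.split("\t")
            if len(fields) != 9:
                raise VariantFormatError(
                    f"line {lineno}: expected 9 columns, got {len(fields)}"
                )
            chrom, pos_s, ref, alt, vtype = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError:
                raise VariantFormatError(f"line {lineno}: bad position {pos_s!r}")
            try:
                site = VariantSite(chrom, pos, ref, alt)
            except VariantFormatError as exc:
                raise VariantFormatError(f"line {lineno}: {exc}") from None
            if vtype != site.vtype:
                raise VariantFormatError(
                    f"line {lineno}: declared vtype {vtype!r} inconsistent with "
                    f"alleles {ref}/{alt}"
                )
            cells = [_parse_depths(c, lineno) for c in fields[5:9]]
            sites.append(site)
            depths.append(SampleDepths(*cells))
    return VariantTable(sites, depths, chrom_lengths)


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def _read_vcf(path: Path) -> VariantTable:
    import pysam

    sites: list[VariantSite] = []
    depths: list[SampleDepths] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        missing = [s for s in SAMPLES if s not in samples]
        if missing:
            raise VariantFormatError(
                f"VCF is missing required sample columns: {missing}"
            )
        chrom_lengths = {
            c: vcf.header.contigs[c].length
            for c in vcf.header.contigs
            if vcf.header.contigs[c].length
        }
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                logger.warning(
                    "skipping non-biallelic record at %s:%s", rec.chrom, rec.pos
                )
                continue
            alleles = (rec.ref, rec.alts[0])
            per_sample = []
            for name in SAMPLES:
                ad = rec.samples[name].get("AD")
                if ad is None or any(x is None for x in ad):
                    raise VariantFormatError(
                        f"missing AD for sample {name} at {rec.chrom}:{rec.pos}"
                    )
                per_sample.append(dict(zip(alleles, (int(x) for x in ad))))
            sites.append(VariantSite(rec.chrom, rec.pos, *alleles))
            depths.append(SampleDepths(*per_sample))
    return VariantTable(sites, depths, chrom_lengths)


def read_variant_table(path: str | Path, format: str | None = None) -> VariantTable:
    """Read a variant table from the native TSV dialect or a VCF.

    Parameters
    ----------
    path
        Input file.  Must exist.
    format
        ``"tsv"``, ``"vcf"``, or ``None`` to guess from the extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in {".vcf", ".bcf", ".gz"} else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# parental-informativeness filter
# ---------------------------------------------------------------------------

def _called_homozygous(
    depths: Mapping[str, int], min_depth: int, max_minor_fraction: float
) -> str | None:
    """Return the called allele if the sample looks homozygous, else None.

    A sample is called homozygous when total depth >= ``min_depth`` and the
    combined fraction of reads on non-majority alleles is at most
    ``max_minor_fraction``.
    """
    total = sum(depths.values())
    if total < min_depth or not depths:
        return None
    allele = max(depths, key=lambda a: (depths[a], a))
    if (total - depths[allele]) / total > max_minor_fraction:
        return None
    return allele


def filter_parental_informative(
    table: VariantTable,
    min_parent_depth: int = 10,
    max_minor_fraction: float = 0.05,
) -> VariantTable:
    """Keep sites homozygous in both parents for different alleles.

    This is the marker filter of a BSA scan: only sites where the two
    parents are confidently homozygous for different alleles carry
    information about bulk ancestry.  Each retained site is annotated
    with the yellow-parent (P2) allele, which downstream SNP-index
    computations use as the reference orientation.
    """
    sites: list[VariantSite] = []
    depths: list[SampleDepths] = []
    yellow: list[str] = []
    for s, d in table:
        a1 = _called_homozygous(d.p1, min_parent_depth, max_minor_fraction)
        a2 = _called_homozygous(d.p2, min_parent_depth, max_minor_fraction)
        if a1 is None or a2 is None or a1 == a2:
            continue
        sites.append(s)
        depths.append(d)
        yellow.append(a2)
    logger.info(
        "parental-informative filter: retained %d of %d sites",
        len(sites), len(table),
    )
    return VariantTable(sites, depths, dict(table.chrom_lengths), yellow)
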