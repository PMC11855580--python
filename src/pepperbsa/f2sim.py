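"""Forward simulation of an F2 pepper cross for BSA-seq validation.

Emulates the study design the scan assumes: two fully homozygous parents
(green-fruited P1 and yellow-fruited P2) crossed to a uniformly
heterozygous F1, selfed to an F2 of 423 plants; a two-locus color model
(major locus on chr10, minor on chr1) with dominant + additive effects
on a continuous green score binned into six grades; extreme bulks of 13
yellow and 20 green individuals; and pooled short-read sequencing
modelled as Poisson total depth with binomial allele sampling.

Genetic map: uniform cM/Mb, Poisson crossover counts with uniform
placement (Haldane model, no interference).

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; independent streams for meiosis, allele
labels and read sampling are spawned in a fixed documented order
(children 0, 1, 2 of the root sequence), so partial re-runs are
reproducible.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .variantio import SampleDepths, VariantSite, VariantTable

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class GenomeModel:
    """Marker scaffold: chromosome lengths, marker density, map scaling."""

    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 50_000_000),
        ("chr10", 50_000_000),
    )
    marker_density: float = 50.0  # markers per Mb
    cm_per_mb: float = 2.0

    def __post_init__(self) -> None:
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.marker_density <= 0:
            raise ValueError("marker_density must be positive")

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)


@dataclass(frozen=True)
class CausalLocus:
    """One causal locus: genomic position, effect weight and dominance.

    ``weight`` is the locus's share of the full green score; ``dominance``
    (h) is the heterozygote's effect as a fraction of the homozygous-green
    effect (h=1 fully dominant, h=0.5 additive).
    """

    chrom: str
    pos: int
    weight: float
    dominance: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.dominance <= 1.0:
            raise ValueError("dominance must lie in [0, 1]")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")


@dataclass(frozen=True)
class ColorModel:
    """Genotype -> green score -> grade mapping.

    Defaults model a major CaGLK2-like locus (weight 0.7) and a minor
    CaAPRR2-like locus (weight 0.3), both partially dominant (h = 0.6),
    with Gaussian environmental noise and five grade cuts chosen so a
    423-plant draw yields a middle-heavy six-grade histogram.
    """

    loci: tuple[CausalLocus, ...] = (
        CausalLocus("chr10", 16_450_000, weight=0.7, dominance=0.6),
        CausalLocus("chr1", 17_650_000, weight=0.3, dominance=0.6),
    )
    noise_sd: float = 0.08
    grade_cuts: tuple[float, ...] = (0.09, 0.26, 0.50, 0.66, 0.93)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if list(self.grade_cuts) != sorted(set(self.grade_cuts)):
            raise ValueError("grade_cuts must be strictly ascending")
        if self.loci and abs(sum(l.weight for l in self.loci) - 1.0) > 1e-9:
            raise ValueError("locus weights must sum to 1")

    def grade(self, score: float) -> int:
        """Grade 1 (yellow) .. len(grade_cuts)+1 (green)."""
        return int(np.searchsorted(self.grade_cuts, score, side="right")) + 1


@dataclass(frozen=True)
class BulkDesign:
    """Extreme-bulk sizes and pooled-sequencing depth."""

    n_yellow: int = 13
    n_green: int = 20
    mean_depth: float = 40.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.n_yellow < 1 or self.n_green < 1:
            raise ValueError("bulk sizes must be positive")


@dataclass
class F2Individual:
    """One simulated F2 plant.

    ``genotype`` holds, per marker, the dosage of the green-parent allele
    (0, 1 or 2), aligned with the population's marker arrays.
    """

    id: int
    genotype: np.ndarray
    green_score: float
    grade: int
    rgb: tuple[int, int, int]


@dataclass
class F2Population:
    """Marker map plus the genotype matrix and phenotypes of an F2 draw."""

    marker_chrom: np.ndarray  # str per marker
    marker_pos: np.ndarray    # int bp per marker
    dosage: np.ndarray        # (n, m) green-parent allele dosage in {0,1,2}
    green_score: np.ndarray   # (n,)
    grade: np.ndarray         # (n,) in 1..6
    rgb: np.ndarray           # (n, 3) uint8-ish ints
    causal_index: dict[tuple[str, int], int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def individuals(self) -> list[F2Individual]:
        return [
            F2Individual(i, self.dosage[i], float(self.green_score[i]),
                         int(self.grade[i]), tuple(int(c) for c in self.rgb[i]))
            for i in range(self.n)
        ]

    def marker_index(self, chrom: str, pos: int) -> int:
        hits = np.flatnonzero((self.marker_chrom == chrom) & (self.marker_pos == pos))
        if hits.size == 0:
            raise KeyError(f"no marker at {chrom}:{pos}")
        return int(hits[0])


# ---------------------------------------------------------------------------
# map function and marker placement
# ---------------------------------------------------------------------------

def haldane_recombination_fraction(d: float) -> float:
    """Recombination fraction for genetic distance ``d`` in cM (Haldane).

    r = (1 - exp(-2 d / 100)) / 2; no interference.
    """
    if d < 0:
        raise ValueError("genetic distance must be non-negative")
    return (1.0 - math.exp(-2.0 * d / 100.0)) / 2.0


def marker_positions(genome: GenomeModel, model: ColorModel | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced marker grid, with causal positions inserted.

    Returns (chrom array, pos array), sorted by (chromosome order in the
    genome model, position).
    """
    chroms: list[str] = []
    poss: list[int] = []
    spacing = int(round(1_000_000 / genome.marker_density))
    causal = {}
    if model is not None:
        for locus in model.loci:
            causal.setdefault(locus.chrom, set()).add(locus.pos)
    for name, length in genome.chromosomes:
        grid = set(range(1, length + 1, spacing))
        grid |= causal.get(name, set())
        for pos in sorted(grid):
            chroms.append(name)
            poss.append(pos)
    return np.array(chroms), np.array(poss, dtype=np.int64)


# ---------------------------------------------------------------------------
# meiosis and the F2 draw
# ---------------------------------------------------------------------------

def _gametes(length_bp: int, positions: np.ndarray, n_gametes: int,
             cm_per_mb: float, rng: np.random.Generator) -> np.ndarray:
    """Draw gametes from a fully heterozygous F1 for one chromosome.

    Crossover count per gamete is Poisson(map length in Morgans) with
    uniform placement; the starting phase is a fair coin.  Returns a
    (n_gametes, n_markers) 0/1 array (1 = green-parent allele).
    """
    morgans = length_bp / 1e6 * cm_per_mb / 100.0
    n_xo = rng.poisson(morgans, size=n_gametes)
    out = np.empty((n_gametes, positions.size), dtype=np.int8)
    start_phase = rng.integers(0, 2, size=n_gametes)
    for g in range(n_gametes):
        if n_xo[g] == 0:
            out[g] = start_phase[g]
            continue
        breaks = np.sort(rng.uniform(0, length_bp, size=n_xo[g]))
        crossings = np.searchsorted(breaks, positions)
        out[g] = (start_phase[g] + crossings) % 2
    return out


def simulate_f2(genome: GenomeModel, model: ColorModel, n: int,
                seed: int | np.random.Generator) -> F2Population:
    """Simulate ``n`` F2 individuals with genotypes, scores and grades."""
    if n <= 0:
        raise ValueError("population size must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms, poss = marker_positions(genome, model)
    dosage = np.empty((n, poss.size), dtype=np.int8)
    for name, length in genome.chromosomes:
        idx = np.flatnonzero(chroms == name)
        gam = _gametes(length, poss[idx], 2 * n, genome.cm_per_mb, rng)
        dosage[:, idx] = gam[:n] + gam[n:]

    causal_index = {(l.chrom, l.pos): 0 for l in model.loci}
    for key in causal_index:
        causal_index[key] = int(
            np.flatnonzero((chroms == key[0]) & (poss == key[1]))[0]
        )
    effect = np.array([0.0, 0.0, 1.0])
    score = np.zeros(n)
    for locus in model.loci:
        d = dosage[:, causal_index[(locus.chrom, locus.pos)]]
        effect[1] = locus.dominance
        score += locus.weight * effect[d]
    if model.noise_sd > 0:
        score = score + rng.normal(0.0, model.noise_sd, size=n)

    grade = np.searchsorted(model.grade_cuts, score, side="right").astype(np.int16) + 1
    rgb = np.array([assign_rgb(s) for s in score], dtype=np.int64)
    return F2Population(chroms, poss, dosage, score, grade, rgb, causal_index)


def assign_rgb(green_score: float,
               base: tuple[int, int, int] = (120, 80, 90),
               gain: float = 100.0) -> tuple[int, int, int]:
    """Map a green score to an RGB triplet.

    R and B stay at the base values; G = base_G + gain * score, so the
    green index 2G - R - B is a strictly increasing affine function of
    the score (before clipping to [0, 255]).
    """
    r, g, b = base
    g = int(round(g + gain * green_score))
    clip = lambda c: max(0, min(255, int(c)))
    return (clip(r), clip(g), clip(b))


def select_bulks(pop: F2Population, design: BulkDesign
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pick the extreme bulks: lowest scores = yellow, highest = green.

    Returns (yellow ids, green ids), disjoint, ties broken by id.
    """
    if design.n_yellow + design.n_green > pop.n:
        raise ValueError(
            f"bulks of {design.n_yellow}+{design.n_green} exceed population "
            f"size {pop.n}"
        )
    order = np.lexsort((np.arange(pop.n), pop.green_score))
    yellow = np.sort(order[: design.n_yellow])
    green = np.sort(order[pop.n - design.n_green:])
    return yellow, green


# ---------------------------------------------------------------------------
# pooled sequencing of the bulks
# ---------------------------------------------------------------------------

def sample_bulk_depths(pop: F2Population,
                       bulks: tuple[np.ndarray, np.ndarray],
                       genome: GenomeModel,
                       design: BulkDesign,
                       seed: int | np.random.Generator | None = None,
                       indel_fraction: float = 0.05) -> VariantTable:
    """Emit a variant table of pooled read depths for parents and bulks.

    For each marker the bulk frequency of the yellow-parent allele is the
    mean yellow-allele dosage over bulk members divided by 2; total read
    depth is Poisson(mean_depth) and the yellow-allele count binomial.
    Parents are emitted as pure homozygotes at ``mean_depth`` so the
    table passes the parental-informativeness filter unchanged.

    Allele labels (which nucleotides, and whether ref or alt is the
    yellow-parent allele) are randomized per site; a small fraction of
    sites are emitted as indels (ref base vs ref base + insertion).
    """
    if seed is None:
        seed = design.seed if design.seed is not None else 0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    yellow_ids, green_ids = bulks
    m = pop.n_markers
    depth = int(round(design.mean_depth))

    # yellow-parent allele frequency per bulk (dosage counts green alleles)
    f_d1 = 1.0 - pop.dosage[yellow_ids].mean(axis=0) / 2.0
    f_d2 = 1.0 - pop.dosage[green_ids].mean(axis=0) / 2.0
    tot_d1 = rng.poisson(design.mean_depth, size=m)
    tot_d2 = rng.poisson(design.mean_depth, size=m)
    y_d1 = rng.binomial(tot_d1, f_d1)
    y_d2 = rng.binomial(tot_d2, f_d2)

    ref_idx = rng.integers(0, 4, size=m)
    alt_shift = rng.integers(1, 4, size=m)
    yellow_is_ref = rng.integers(0, 2, size=m).astype(bool)
    is_indel = rng.random(m) < indel_fraction

    sites: list[VariantSite] = []
    depths: list[SampleDepths] = []
    for i in range(m):
        ref = NUCLEOTIDES[ref_idx[i]]
        if is_indel[i]:
            alt = ref + NUCLEOTIDES[(ref_idx[i] + alt_shift[i]) % 4]
        else:
            alt = NUCLEOTIDES[(ref_idx[i] + alt_shift[i]) % 4]
        yellow, green = (ref, alt) if yellow_is_ref[i] else (alt, ref)
        sites.append(VariantSite(str(pop.marker_chrom[i]),
                                 int(pop.marker_pos[i]), ref, alt))
        depths.append(SampleDepths(
            p1={green: depth, yellow: 0},
            p2={yellow: depth, green: 0},
            d1={yellow: int(y_d1[i]), green: int(tot_d1[i] - y_d1[i])},
            d2={yellow: int(y_d2[i]), green: int(tot_d2[i] - y_d2[i])},
        ))
    lengths = {name: length for name, length in genome.chromosomes}
    return VariantTable(sites, depths, lengths)


# ---------------------------------------------------------------------------
# chlorophyll assay simulation
# ---------------------------------------------------------------------------

#: coefficient matrix of the spectrophotometric equations:
#: [Ca, Cb] = M @ [D649, D665]
_CHL_MATRIX = np.array([[-6.8, 13.95], [24.96, -7.32]])


def simulate_absorbance(true_chl_per_g: float,
                        volume_l: float = 0.05,
                        dilution: float = 1.0,
                        fresh_weight_g: float = 0.1,
                        ab_ratio: float = 3.0,
                        noise_sd: float = 0.0,
                        seed: int | np.random.Generator | None = None
                        ) -> tuple[float, float]:
    """Invert the chlorophyll equations to synthesize an absorbance pair.

    Given a true pigment content (mg per g fresh weight), the cuvette
    concentration is Ct = content * W / (V * D) mg/L, split into
    chlorophyll a and b at ``ab_ratio`` : 1, and the two-equation linear
    system is solved for (D649, D665).  Optional Gaussian noise on the
    absorbances models spectrophotometer error.  With zero noise, the
    phenostats chlorophyll/pigment-content formulas recover the input
    exactly.
    """
    if true_chl_per_g < 0 or volume_l <= 0 or dilution <= 0 or fresh_weight_g <= 0:
        raise ValueError("extraction parameters must be positive")
    ct = true_chl_per_g * fresh_weight_g / (volume_l * dilution)
    ca = ct * ab_ratio / (1.0 + ab_ratio)
    cb = ct / (1.0 + ab_ratio)
    d649, d665 = np.linalg.solve(_CHL_MATRIX, [ca, cb])
    if noise_sd > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        d649 += rng.normal(0.0, noise_sd)
        d665 += rng.normal(0.0, noise_sd)
    return float(d649), float(d665)


# ---------------------------------------------------------------------------
# dataset assembly and on-disk outputs
# ---------------------------------------------------------------------------

def genotype_code(dosage: int) -> str:
    """Green-parent allele dosage -> YY / GY / GG code."""
    return {0: "YY", 1: "GY", 2: "GG"}[int(dosage)]


def simulate_dataset(genome: GenomeModel | None = None,
                     model: ColorModel | None = None,
                     n: int = 423,
                     design: BulkDesign | None = None,
                     seed: int = 0,
                     indel_fraction: float = 0.05):
    """One full synthetic study: population, bulks and sequenced table.

    The root seed is split into independent streams (0: meiosis and
    phenotype noise, 1: read sampling and allele labels) via
    ``SeedSequence.spawn``.

    Returns ``(pop, (yellow_ids, green_ids), table)``.
    """
    genome = genome or GenomeModel()
    model = model or ColorModel()
    design = design or BulkDesign()
    ss = np.random.SeedSequence(seed)
    child_f2, child_reads = ss.spawn(2)
    pop = simulate_f2(genome, model, n, np.random.default_rng(child_f2))
    bulks = select_bulks(pop, design)
    table = sample_bulk_depths(pop, bulks, genome, design,
                               np.random.default_rng(child_reads),
                               indel_fraction=indel_fraction)
    return pop, bulks, table


def write_phenotypes_csv(pop: F2Population, model: ColorModel,
                         path: str | Path) -> None:
    """Phenotype CSV: id, score, grade, RGB, causal-locus genotype codes."""
    loci = [(l, pop.causal_index[(l.chrom, l.pos)]) for l in model.loci]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        header = ["id", "green_score", "grade", "R", "G", "B"]
        header += [f"geno_{l.chrom}_{l.pos}" for l, _ in loci]
        writer.writerow(header)
        for i in range(pop.n):
            row = [i, f"{pop.green_score[i]:.6f}", int(pop.grade[i]),
                   int(pop.rgb[i][0]), int(pop.rgb[i][1]), int(pop.rgb[i][2])]
            row += [genotype_code(pop.dosage[i, j]) for _, j in loci]
            writer.writerow(row)


def write_truth_manifest(genome: GenomeModel, model: ColorModel,
                         design: BulkDesign, n: int, seed: int,
                         bulks: tuple[np.ndarray, np.ndarray],
                         path: str | Path) -> None:
    """Structured echo of the simulation config, seed and causal truth."""
    manifest = {
        "seed": seed,
        "n": n,
        "genome": {
            "chromosomes": [[c, int(l)] for c, l in genome.chromosomes],
            "marker_density": genome.marker_density,
            "cm_per_mb": genome.cm_per_mb,
        },
        "color_model": {
            "loci": [
                {"chrom": l.chrom, "pos": l.pos, "weight": l.weight,
                 "dominance": l.dominance}
                for l in model.loci
            ],
            "noise_sd": model.noise_sd,
            "grade_cuts": list(model.grade_cuts),
        },
        "bulks": {
            "n_yellow": design.n_yellow,
            "n_green": design.n_green,
            "mean_depth": design.mean_depth,
            "yellow_ids": [int(i) for i in bulks[0]],
            "green_ids": [int(i) for i in bulks[1]],
        },
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
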