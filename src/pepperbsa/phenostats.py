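"""Phenotype quantification and population statistics.

Covers the non-sequencing side of the study: the RGB green index
(2G - R - B), spectrophotometric chlorophyll quantification, a
normality report (mean, sample SD, adjusted skewness/kurtosis,
Shapiro-Wilk), genotype-by-grade contingency tables, Mendelian
segregation tests, and case/control association of candidate-gene
mutations in an accession panel (odds ratio + Fisher exact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

GRADE_NAMES = ("yellow", "yellow-green", "light green",
               "tender green", "grass green", "green")


def green_index(r: int, g: int, b: int) -> int:
    """Greenness of an RGB triplet: 2G - R - B (may be negative).

    Higher values indicate greener color; a grey pixel scores 0.
    """
    for name, c in (("r", r), ("g", g), ("b", b)):
        if not 0 <= c <= 255:
            raise ValueError(f"channel {name}={c} outside 0..255")
    return 2 * g - r - b


# ---------------------------------------------------------------------------
# chlorophyll
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbsorbancePair:
    """Absorbance readings at 649 nm and 665 nm (unitless)."""

    d649: float
    d665: float

    def __post_init__(self) -> None:
        if self.d649 < 0 or self.d665 < 0:
            raise ValueError("absorbances must be non-negative")


@dataclass(frozen=True)
class ExtractionParams:
    """Extraction geometry: volume (L), dilution factor, fresh weight (g)."""

    volume_l: float
    dilution: float
    fresh_weight_g: float

    def __post_init__(self) -> None:
        if self.volume_l <= 0 or self.dilution <= 0 or self.fresh_weight_g <= 0:
            raise ValueError("V, D and W must all be positive")


@dataclass(frozen=True)
class ChlorophyllResult:
    """Chlorophyll a, b and total concentrations in the cuvette (mg/L).

    ``ct_direct`` is the total recomputed from the direct coefficients
    (18.16 D649 + 6.63 D665); it agrees with ca + cb to machine
    precision because the coefficient pairs are arithmetic combinations
    of the a and b equations.  ``negative_flagged`` marks out-of-model
    absorbances that yield a negative concentration.
    """

    ca: float
    cb: float
    ct: float
    ct_direct: float
    negative_flagged: bool


def chlorophyll(a: AbsorbancePair) -> ChlorophyllResult:
    """Chlorophyll a/b/total from a 649/665 nm absorbance pair.

    Ca = 13.95 D665 - 6.8 D649
    Cb = 24.96 D649 - 7.32 D665
    Ct = Ca + Cb = 18.16 D649 + 6.63 D665
    """
    ca = 13.95 * a.d665 - 6.8 * a.d649
    cb = 24.96 * a.d649 - 7.32 * a.d665
    ct_direct = 18.16 * a.d649 + 6.63 * a.d665
    return ChlorophyllResult(
        ca=ca, cb=cb, ct=ca + cb, ct_direct=ct_direct,
        negative_flagged=(ca < 0 or cb < 0),
    )


def pigment_content(ct_mg_per_l: float, p: ExtractionParams) -> float:
    """Pigment per gram fresh weight: C * V * D / W (mg/g)."""
    return ct_mg_per_l * p.volume_l * p.dilution / p.fresh_weight_g


# ---------------------------------------------------------------------------
# normality report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalityReport:
    """Summary statistics and Shapiro-Wilk normality test for one sample.

    Skewness is the adjusted Fisher-Pearson estimator G1 and kurtosis
    the adjusted excess estimator G2 (both sample-size corrected); the
    SD uses the n-1 denominator.  ``w`` and ``p_value`` are None for
    degenerate (constant) input, where the test is undefined.
    """

    n: int
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    w: float | None
    p_value: float | None


def normality_report(values: Sequence[float]) -> NormalityReport:
    """Mean, SD, G1 skewness, G2 excess kurtosis and Shapiro-Wilk W/p."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return NormalityReport(n, mean, 0.0, float("nan"), float("nan"),
                               None, None)
    skew = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    w, p = stats.shapiro(x)
    return NormalityReport(n, mean, sd, skew, kurt, float(w), float(p))


# ---------------------------------------------------------------------------
# genotype / grade tables and tests
# ---------------------------------------------------------------------------

GENOTYPE_CODES = ("GG", "GY", "YY")


def grade_table(genotypes: Sequence[str], grades: Sequence[int],
                margins: bool = True) -> pd.DataFrame:
    """Genotype x color-grade contingency table with optional totals."""
    if len(genotypes) != len(grades):
        raise ValueError("genotypes and grades must have equal length")
    for g in genotypes:
        if g not in GENOTYPE_CODES:
            raise ValueError(f"unknown genotype code {g!r}; "
                             f"expected one of {GENOTYPE_CODES}")
    geno = pd.Categorical(genotypes, categories=GENOTYPE_CODES)
    grade = pd.Categorical(grades, categories=range(1, 7))
    table = pd.crosstab(geno, grade, dropna=False)
    table.index.name = "genotype"
    table.columns.name = "grade"
    if margins:
        table["total"] = table.sum(axis=1)
        table.loc["total"] = table.sum(axis=0)
    return table


def segregation_test(counts: Sequence[int],
                     ratio: Sequence[float] = (1, 2, 1)
                     ) -> tuple[float, int, float]:
    """Pearson chi-square goodness of fit against a segregation ratio.

    ``counts`` are observed genotype counts (e.g. GG, GY, YY); the
    default 1:2:1 is the Mendelian F2 expectation.  Returns
    (chi-square, df, p).
    """
    obs = np.asarray(counts, dtype=float)
    if obs.sum() <= 0:
        raise ValueError("total count must be positive")
    ratio = np.asarray(ratio, dtype=float)
    expected = ratio / ratio.sum() * obs.sum()
    chi2, p = stats.chisquare(obs, expected)
    return float(chi2), obs.size - 1, float(p)


@dataclass(frozen=True)
class AssociationResult:
    """2x2 mutation-by-phenotype association in an accession panel."""

    odds_ratio: float
    corrected: bool  # Haldane-Anscombe +0.5 applied (a zero cell)
    p_value: float   # two-sided Fisher exact


def accession_association(table: Sequence[Sequence[int]]) -> AssociationResult:
    """Odds ratio and Fisher exact p for a 2x2 count table.

    Layout: rows = mutation present/absent, columns = yellow/green (any
    consistent orientation; the Fisher p is invariant under transposes).
    With a zero cell the odds ratio uses the Haldane-Anscombe +0.5
    correction; the Fisher test always uses the raw counts.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    a, b, c, d = t.ravel()
    corrected = (t == 0).any()
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return AssociationResult(float(odds), bool(corrected), float(p))


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def grade_distribution(grades: Sequence[int]) -> pd.Series:
    """Counts per grade 1..6 (yellow ... green)."""
    counts = pd.Series(grades).value_counts().reindex(range(1, 7), fill_value=0)
    counts.index = GRADE_NAMES
    return counts


def render_report(dist: pd.Series, report: NormalityReport) -> str:
    """Human-readable text summary of the grade distribution and normality."""
    lines = ["Grade distribution:"]
    for name, count in dist.items():
        lines.append(f"  {name:<14} {int(count):>5}")
    lines.append(f"  {'total':<14} {int(dist.sum()):>5}")
    lines.append("")
    lines.append("Normality of the grade counts:")
    lines.append(f"  n         {report.n}")
    lines.append(f"  mean      {report.mean:.3f}")
    lines.append(f"  sd        {report.sd:.3f}")
    lines.append(f"  skewness  {report.skewness:.3f}")
    lines.append(f"  kurtosis  {report.kurtosis:.3f}")
    if report.w is None:
        lines.append("  Shapiro-Wilk W undefined (constant input)")
    else:
        lines.append(f"  Shapiro-Wilk W {report.w:.3f} (p = {report.p_value:.3f})")
    return "\n".join(lines) + "\n"
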