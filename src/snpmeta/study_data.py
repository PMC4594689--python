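"""Study-level data model for case-control SNP association studies.

The central object is a :class:`StudyOutcome`: one SNP examined in one
case-control study, carrying either genotype counts (major homozygote /
heterozygote / minor homozygote) or a published odds ratio with its 95%
confidence interval, or both.  From either representation an
:class:`EffectEstimate` — a log odds ratio with standard error — is
derived, which is the unit of all downstream pooling.

Conventions
-----------
* Genotype count strings follow the ``a/b/c`` order major-hom / het /
  minor-hom.
* Odds ratios contrast the minor allele against the major allele unless
  an outcome's ``effect_allele_orientation`` says otherwise.
* The normal quantile used to convert between confidence intervals and
  standard errors defaults to 1.96 (the conventional rounded value for a
  95% interval), configurable everywhere it appears.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Z_DEFAULT",
    "GenotypeCounts",
    "StudyOutcome",
    "EffectEstimate",
    "HweResult",
    "StudyTableError",
    "minor_allele_frequency",
    "hwe_test",
    "allele_table",
    "effect_from_counts",
    "effect_from_ci",
    "effect_for_outcome",
    "parse_study_table",
    "write_study_table",
    "load_il2ra_t1d",
]

#: Normal quantile for a 95% confidence interval.  The rounded 1.96 is
#: used rather than ``norm.ppf(0.975)`` because published intervals are
#: almost always constructed with it.
Z_DEFAULT = 1.96

ANCESTRIES = ("European", "Asian", "other")
DESIGNS = ("case_control", "gwas")
ORIENTATIONS = ("minor", "major")

#: Control-HWE significance threshold per study design.  Genome-wide
#: scans tolerate much smaller HWE p-values than candidate-gene
#: case-control studies before a control sample is considered suspect.
HWE_THRESHOLDS = {"case_control": 0.05, "gwas": 1e-5}


class StudyTableError(ValueError):
    """Raised when a study table or one of its rows fails validation."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one sample: major-hom, het, minor-hom."""

    n_major_hom: int
    n_het: int
    n_minor_hom: int

    def __post_init__(self) -> None:
        for name in ("n_major_hom", "n_het", "n_minor_hom"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise StudyTableError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.n_major_hom + self.n_het + self.n_minor_hom

    @property
    def n_minor_alleles(self) -> int:
        return self.n_het + 2 * self.n_minor_hom

    @property
    def n_major_alleles(self) -> int:
        return 2 * self.n_major_hom + self.n_het

    @classmethod
    def from_string(cls, s: str) -> "GenotypeCounts":
        """Parse the ``a/b/c`` = major-hom/het/minor-hom convention."""
        parts = s.strip().split("/")
        if len(parts) != 3:
            raise StudyTableError(f"genotype counts must be 'a/b/c', got {s!r}")
        return cls(*(int(p) for p in parts))

    def __str__(self) -> str:
        return f"{self.n_major_hom}/{self.n_het}/{self.n_minor_hom}"


@dataclass(frozen=True)
class EffectEstimate:
    """A log odds ratio with its standard error.

    ``source`` records whether the estimate came from genotype counts
    (Woolf allele-table method) or from a published OR and confidence
    interval.  ``ci_low``/``ci_high`` are always consistent with
    ``log_or`` ± z·``se_log_or`` at the z used to build the estimate.
    """

    log_or: float
    se_log_or: float
    source: Literal["counts", "reported_ci"]
    or_point: float
    ci_low: float
    ci_high: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.se_log_or) and self.se_log_or > 0):
            raise StudyTableError(f"se_log_or must be finite and > 0, got {self.se_log_or}")

    @property
    def variance(self) -> float:
        return self.se_log_or ** 2


@dataclass(frozen=True)
class HweResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions."""

    chi_square: float
    p_value: float
    passes: bool


@dataclass(frozen=True)
class StudyOutcome:
    """One SNP examined in one study: the unit row of the study table."""

    study_id: str
    author_year: str
    year: int
    country: str
    ancestry: str
    snp: str
    design: str = "case_control"
    case_counts: Optional[GenotypeCounts] = None
    control_counts: Optional[GenotypeCounts] = None
    reported_or: Optional[float] = None
    reported_ci_low: Optional[float] = None
    reported_ci_high: Optional[float] = None
    effect_allele_orientation: str = "minor"
    n_cases: int = 0
    n_controls: int = 0
    maf_cases: Optional[float] = None
    maf_controls: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ancestry not in ANCESTRIES:
            raise StudyTableError(f"ancestry must be one of {ANCESTRIES}, got {self.ancestry!r}")
        if self.design not in DESIGNS:
            raise StudyTableError(f"design must be one of {DESIGNS}, got {self.design!r}")
        if self.effect_allele_orientation not in ORIENTATIONS:
            raise StudyTableError(
                f"orientation must be one of {ORIENTATIONS}, got {self.effect_allele_orientation!r}"
            )
        has_counts = self.case_counts is not None and self.control_counts is not None
        has_reported = (
            self.reported_or is not None
            and self.reported_ci_low is not None
            and self.reported_ci_high is not None
        )
        if not has_counts and not has_reported:
            raise StudyTableError(
                f"{self.study_id}/{self.snp}: needs genotype counts for both groups "
                "or a reported OR with both CI bounds"
            )
        if has_counts and (self.case_counts.total == 0 or self.control_counts.total == 0):
            raise StudyTableError(f"{self.study_id}/{self.snp}: zero genotype total")
        if has_reported:
            if not (0 < self.reported_ci_low < self.reported_or < self.reported_ci_high):
                raise StudyTableError(
                    f"{self.study_id}/{self.snp}: reported CI must satisfy "
                    f"0 < low < OR < high, got {self.reported_or} "
                    f"({self.reported_ci_low}-{self.reported_ci_high})"
                )
        if self.effect_allele_orientation == "major" and not has_counts:
            raise StudyTableError(
                f"{self.study_id}/{self.snp}: major-allele orientation requires genotype counts"
            )

    @property
    def has_counts(self) -> bool:
        return self.case_counts is not None and self.control_counts is not None

    @property
    def has_reported(self) -> bool:
        return self.reported_or is not None


def minor_allele_frequency(counts: GenotypeCounts) -> float:
    """Frequency of the minor allele: (het + 2·minor-hom) / (2·total)."""
    if counts.total == 0:
        raise StudyTableError("cannot compute allele frequency from a zero genotype total")
    return counts.n_minor_alleles / (2 * counts.total)


def hwe_test(counts: GenotypeCounts, design: str = "case_control") -> HweResult:
    """Pearson chi-square (1 df) test of Hardy-Weinberg proportions.

    Expected genotype counts are n·(q², 2pq, p²) at the sample minor
    allele frequency p.  A monomorphic sample carries no information
    about HWE and is returned as chi-square 0, p = 1.

    The pass/fail threshold depends on the study design: p ≥ 0.05 for
    candidate-gene case-control studies, p ≥ 1e-5 for GWAS.
    """
    if design not in HWE_THRESHOLDS:
        raise StudyTableError(f"design must be one of {DESIGNS}, got {design!r}")
    threshold = HWE_THRESHOLDS[design]
    n = counts.total
    if n == 0:
        raise StudyTableError("cannot test HWE on a zero genotype total")
    p = minor_allele_frequency(counts)
    if p in (0.0, 1.0):
        return HweResult(chi_square=0.0, p_value=1.0, passes=True)
    q = 1.0 - p
    expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
    observed = np.array([counts.n_major_hom, counts.n_het, counts.n_minor_hom], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi_square=chi2, p_value=p_value, passes=p_value >= threshold)


def allele_table(
    case: GenotypeCounts, control: GenotypeCounts, orientation: str = "minor"
) -> tuple[int, int, int, int]:
    """Allele-level 2×2 table ``(a, b, c, d)``.

    a = effect alleles in cases, b = reference alleles in cases,
    c = effect alleles in controls, d = reference alleles in controls.
    The effect allele is the minor allele unless ``orientation='major'``.
    """
    if orientation not in ORIENTATIONS:
        raise StudyTableError(f"orientation must be one of {ORIENTATIONS}")
    a, b = case.n_minor_alleles, case.n_major_alleles
    c, d = control.n_minor_alleles, control.n_major_alleles
    if orientation == "major":
        a, b, c, d = b, a, d, c
    return a, b, c, d


def effect_from_counts(
    case: GenotypeCounts,
    control: GenotypeCounts,
    orientation: str = "minor",
    z: float = Z_DEFAULT,
    label: str = "",
) -> EffectEstimate:
    """Allelic odds ratio and Woolf standard error from genotype counts.

    The 2N alleles of each group are cross-tabulated against case status
    and OR = (a·d)/(b·c) with se = sqrt(1/a + 1/b + 1/c + 1/d).  If
    exactly one cell is zero, 0.5 is added to all four cells (Haldane-
    Anscombe continuity correction); with two or more zero cells the
    effect is not estimable and an error is raised.
    """
    if case.total == 0 or control.total == 0:
        raise StudyTableError("both genotype totals must be positive")
    cells = allele_table(case, control, orientation)
    n_zero = sum(1 for x in cells if x == 0)
    if n_zero >= 2:
        raise StudyTableError(
            f"allele table {cells} has {n_zero} zero cells; odds ratio not estimable"
        )
    if n_zero == 1:
        cells = tuple(x + 0.5 for x in cells)
    a, b, c, d = cells
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        log_or=log_or,
        se_log_or=se,
        source="counts",
        or_point=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        label=label,
    )


def effect_from_ci(
    or_point: float,
    ci_low: float,
    ci_high: float,
    level: float = 0.95,
    z: Optional[float] = None,
    label: str = "",
) -> EffectEstimate:
    """Recover a log-OR and its standard error from a published CI.

    se = (ln high − ln low) / (2·z).  For the default 95% level the
    rounded z = 1.96 is used, matching how published intervals are
    constructed; any other level uses the exact normal quantile.
    """
    if not 0 < level < 1:
        raise StudyTableError(f"confidence level must be in (0, 1), got {level}")
    if not 0 < ci_low < ci_high:
        raise StudyTableError(f"require 0 < ci_low < ci_high, got ({ci_low}, {ci_high})")
    if not ci_low <= or_point <= ci_high:
        raise StudyTableError(
            f"point estimate {or_point} outside its interval ({ci_low}, {ci_high})"
        )
    if z is None:
        z = Z_DEFAULT if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2))
    log_or = math.log(or_point)
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * z)
    return EffectEstimate(
        log_or=log_or,
        se_log_or=se,
        source="reported_ci",
        or_point=or_point,
        ci_low=ci_low,
        ci_high=ci_high,
        label=label,
    )


def effect_for_outcome(
    outcome: StudyOutcome,
    source: Literal["reported", "counts"] = "reported",
    z: float = Z_DEFAULT,
) -> EffectEstimate:
    """Extract the effect estimate for one study outcome.

    ``source='reported'`` prefers the published OR and CI when present
    (published estimates may carry covariate adjustment the raw counts
    cannot reproduce) and falls back to genotype counts; ``'counts'``
    does the reverse.
    """
    if source not in ("reported", "counts"):
        raise StudyTableError(f"effect source must be 'reported' or 'counts', got {source!r}")
    label = f"{outcome.study_id}:{outcome.snp}"
    use_reported = outcome.has_reported if source == "reported" else not outcome.has_counts
    if use_reported:
        return effect_from_ci(
            outcome.reported_or,
            outcome.reported_ci_low,
            outcome.reported_ci_high,
            z=z,
            label=label,
        )
    return effect_from_counts(
        outcome.case_counts,
        outcome.control_counts,
        orientation=outcome.effect_allele_orientation,
        z=z,
        label=label,
    )


# ---------------------------------------------------------------------------
# Table I/O

_REQUIRED_COLUMNS = [
    "study_id", "year", "country", "ancestry", "snp", "design",
    "case_counts", "control_counts", "reported_or", "ci_low", "ci_high",
    "orientation", "n_cases", "n_controls",
]
_MISSING_TOKENS = {"", "NA", "ND", "NAN", "NONE"}


def _missing(value) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return True
    return str(value).strip().upper() in _MISSING_TOKENS


def _row_to_outcome(row: pd.Series, row_number: int) -> StudyOutcome:
    def opt_float(col):
        return None if _missing(row.get(col)) else float(row[col])

    def opt_counts(col):
        return None if _missing(row.get(col)) else GenotypeCounts.from_string(str(row[col]))

    try:
        outcome = StudyOutcome(
            study_id=str(row["study_id"]),
            author_year=str(row["label"]) if not _missing(row.get("label"))
            else f"{row['study_id']} ({row['year']})",
            year=int(row["year"]),
            country=str(row["country"]),
            ancestry=str(row["ancestry"]),
            snp=str(row["snp"]),
            design=str(row["design"]),
            case_counts=opt_counts("case_counts"),
            control_counts=opt_counts("control_counts"),
            reported_or=opt_float("reported_or"),
            reported_ci_low=opt_float("ci_low"),
            reported_ci_high=opt_float("ci_high"),
            effect_allele_orientation=str(row["orientation"]) if not _missing(row.get("orientation")) else "minor",
            n_cases=int(row["n_cases"]),
            n_controls=int(row["n_controls"]),
            maf_cases=opt_float("maf_cases"),
            maf_controls=opt_float("maf_controls"),
        )
    except (StudyTableError, ValueError) as exc:
        raise StudyTableError(f"row {row_number}: {exc}") from exc

    # Printed MAFs are cross-checked against the counts, not trusted blindly;
    # a mismatch beyond rounding is reported but does not reject the row.
    # Published tables sometimes divide allele counts by the full sample total
    # rather than the genotype-complete total, so both denominators are tried.
    for printed, counts, n_total, group in (
        (outcome.maf_cases, outcome.case_counts, outcome.n_cases, "cases"),
        (outcome.maf_controls, outcome.control_counts, outcome.n_controls, "controls"),
    ):
        if printed is not None and counts is not None:
            candidates = [minor_allele_frequency(counts)]
            if n_total > 0:
                candidates.append(counts.n_minor_alleles / (2 * n_total))
            ndp = len(str(printed).split(".")[-1])
            tol = 1.5 * 10 ** -ndp  # allow a one-ulp slip in the printed digit
            if all(abs(c - printed) > tol for c in candidates):
                warnings.warn(
                    f"row {row_number} ({outcome.study_id}/{outcome.snp}): printed "
                    f"{group} MAF {printed} disagrees with counts-derived "
                    f"{candidates[0]:.3f}",
                    stacklevel=2,
                )
    return outcome


def parse_study_table(path: str | Path, sep: Optional[str] = None) -> list[StudyOutcome]:
    """Read and validate a delimited study table.

    The delimiter is sniffed (tab or comma) unless given.  Every row
    must satisfy the :class:`StudyOutcome` invariants; the first failing
    row aborts the parse with a row-numbered diagnostic and no partial
    output is returned.
    """
    path = Path(path)
    if not path.exists():
        raise StudyTableError(f"study table not found: {path}")
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise StudyTableError(f"{path}: empty study table") from None
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise StudyTableError(f"{path}: missing required columns {missing_cols}")
    if len(df) == 0:
        raise StudyTableError(f"{path}: study table has a header but no rows")
    return [_row_to_outcome(row, i + 2) for i, row in df.iterrows()]


def write_study_table(outcomes: Sequence[StudyOutcome], path: str | Path, sep: str = "\t") -> None:
    """Write outcomes back to the normalized delimited format."""
    rows = []
    for o in outcomes:
        rows.append({
            "study_id": o.study_id,
            "label": o.author_year,
            "year": o.year,
            "country": o.country,
            "ancestry": o.ancestry,
            "snp": o.snp,
            "design": o.design,
            "case_counts": str(o.case_counts) if o.case_counts else "ND",
            "control_counts": str(o.control_counts) if o.control_counts else "ND",
            "maf_cases": "ND" if o.maf_cases is None else o.maf_cases,
            "maf_controls": "ND" if o.maf_controls is None else o.maf_controls,
            "reported_or": "ND" if o.reported_or is None else o.reported_or,
            "ci_low": "ND" if o.reported_ci_low is None else o.reported_ci_low,
            "ci_high": "ND" if o.reported_ci_high is None else o.reported_ci_high,
            "orientation": o.effect_allele_orientation,
            "n_cases": o.n_cases,
            "n_controls": o.n_controls,
        })
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def bundled_study_table() -> Path:
    """Path to the packaged IL2RA / type-1-diabetes study table."""
    return Path(resources.files("snpmeta") / "data" / "il2ra_t1d_studies.tsv")


def load_il2ra_t1d() -> list[StudyOutcome]:
    """Load the packaged IL2RA / type-1-diabetes study outcomes (21 rows)."""
    return parse_study_table(bundled_study_table())
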