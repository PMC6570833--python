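"""Case-control allelic association statistics and SNP quality control.

Implements the classical GWAS single-marker toolkit on coded genotype
matrices: the 1-df Pearson chi-square allelic test on the 2x2 table of
allele counts (minor vs major, affected vs unaffected), the allelic odds
ratio with a log-scale normal 95% CI, the Hardy-Weinberg exact test used
as a genotyping-error filter, and the per-SNP QC gate (missing rate,
minor-allele frequency, HWE in controls).

Degenerate tables follow the literal cross-product convention: a zero
numerator yields OR 0, a zero denominator +inf, and the CI is undefined
(NaN) whenever any cell is empty. A Haldane-Anscombe 0.5 correction is
available by flag but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix, SnpMeta

__all__ = [
    "AlleleCount2x2",
    "AssociationResult",
    "QcThresholds",
    "DegenerateInputError",
    "count_alleles",
    "allelic_chi2",
    "chi2_sf",
    "odds_ratio",
    "odds_ratio_from_freqs",
    "hwe_exact",
    "qc_filter",
    "run_association",
]


class DegenerateInputError(ValueError):
    """A statistic is undefined on the given table (e.g. empty margin)."""


@dataclass(frozen=True)
class AlleleCount2x2:
    """Allele-count contingency table: rows affected/unaffected, columns a1/a2."""

    a: int  # allele 1 in affected
    b: int  # allele 2 in affected
    c: int  # allele 1 in unaffected
    d: int  # allele 2 in unaffected

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def f_A(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def f_U(self) -> float:
        return self.c / (self.c + self.d)


@dataclass(frozen=True)
class AssociationResult:
    """Per-SNP allelic association summary (the per-row output of the scan)."""

    snp: SnpMeta
    f_A: float
    f_U: float
    chi2: float
    df: int
    p: float
    or_: float
    ci_low: float
    ci_high: float

    def as_row(self) -> dict:
        return {
            "snp": self.snp.snp_id,
            "locus": self.snp.locus,
            "chrom": self.snp.chrom,
            "a1": self.snp.a1,
            "a2": self.snp.a2,
            "f_A": self.f_A,
            "f_U": self.f_U,
            "chi2": self.chi2,
            "p": self.p,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


@dataclass(frozen=True)
class QcThresholds:
    """SNP inclusion gates: missing rate, MAF floor, HWE p floor (controls)."""

    max_snp_missing_rate: float = 0.05
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("max_snp_missing_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def count_alleles(
    matrix: GenotypeMatrix,
    snp: str | int,
    affected_group: str,
    unaffected_group: str,
) -> AlleleCount2x2:
    """Tally the 2x2 allele-count table for one SNP, excluding missing calls."""
    j = matrix.snp_index(snp) if isinstance(snp, str) else int(snp)
    labels = matrix.group_labels()
    for g in (affected_group, unaffected_group):
        if g not in labels:
            raise KeyError(f"group label {g!r} not present in matrix")
    col = matrix.calls[:, j]
    out = []
    for g in (affected_group, unaffected_group):
        calls = col[matrix.group_mask(g)]
        calls = calls[calls != MISSING]
        if calls.size == 0:
            raise DegenerateInputError(
                f"no called genotypes for group {g!r} at SNP index {j}"
            )
        a1 = int(calls.sum())
        out.append((a1, 2 * calls.size - a1))
    (a, b), (c, d) = out
    return AlleleCount2x2(a=a, b=b, c=c, d=d)


def allelic_chi2(t: AlleleCount2x2) -> tuple[float, int]:
    """Pearson 1-df chi-square on the allele-count table, no continuity correction.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if 0 in margins:
        raise DegenerateInputError(f"zero margin in table {t}; statistic undefined")
    n = t.n
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(chi2), 1


def chi2_sf(x: float, df: int = 1) -> float:
    """Upper-tail probability of the chi-square distribution (asymptotic p)."""
    if x < 0:
        raise ValueError(f"statistic must be non-negative, got {x}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(stats.chi2.sf(x, df))


def odds_ratio(
    t: AlleleCount2x2, haldane: bool = False, z: float = 1.959963984540054
) -> tuple[float, float, float]:
    """Allelic odds ratio (a1 vs a2) with log-scale normal 95% CI.

    With ``haldane=True`` 0.5 is added to every cell before computing.
    Without it, zero cells follow the literal quotient: 0 numerator -> 0.0,
    0 denominator -> +inf, 0/0 -> NaN; the CI is NaN whenever a cell is 0.
    """
    a, b, c, d = (x + 0.5 for x in (t.a, t.b, t.c, t.d)) if haldane else (
        float(t.a), float(t.b), float(t.c), float(t.d)
    )
    num, den = a * d, b * c
    if den == 0.0:
        or_ = math.nan if num == 0.0 else math.inf
    else:
        or_ = num / den
    if min(a, b, c, d) == 0.0:
        return or_, math.nan, math.nan
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    return or_, math.exp(log_or - z * se), math.exp(log_or + z * se)


def odds_ratio_from_freqs(f_A: float, f_U: float) -> float:
    """OR from allele-1 frequencies alone (scale-invariant cross product)."""
    if not (0 <= f_A <= 1 and 0 <= f_U <= 1):
        raise ValueError("frequencies must be in [0, 1]")
    num, den = f_A * (1 - f_U), f_U * (1 - f_A)
    if den == 0.0:
        return math.nan if num == 0.0 else math.inf
    return num / den


def hwe_exact(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value on genotype counts.

    Conditional on the observed allele counts, sums the probabilities of
    every heterozygote count whose probability does not exceed that of the
    observed configuration (the standard exact HWE test). Runs in O(n)
    using the heterozygote-count recurrence in log space.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise DegenerateInputError("all genotype counts are zero")
    n1 = 2 * n_hom1 + n_het  # copies of allele 1
    rare = min(n1, 2 * n - n1)
    if rare == 0:
        return 1.0
    # feasible het counts share parity with `rare`
    hets = list(range(rare % 2, rare + 1, 2))
    lg = math.lgamma
    logprobs = []
    for h in hets:
        # hom counts for the configuration with h heterozygotes
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        lp = (
            lg(n + 1) - lg(hom_rare + 1) - lg(h + 1) - lg(hom_common + 1)
            + h * math.log(2)
            + lg(n1 + 1) + lg(2 * n - n1 + 1) - lg(2 * n + 1)
        )
        logprobs.append(lp)
    m = max(logprobs)
    probs = np.exp(np.array(logprobs) - m)
    probs /= probs.sum()
    obs = hets.index(n_het) if n_het in hets else None
    if obs is None:
        raise ValueError(
            f"genotype counts ({n_hom1},{n_het},{n_hom2}) inconsistent with allele totals"
        )
    p_obs = probs[obs]
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return min(1.0, p)


def qc_filter(
    matrix: GenotypeMatrix,
    thresholds: QcThresholds,
    control_group: str = "HC",
) -> tuple[list[str], pd.DataFrame]:
    """Apply per-SNP QC; returns kept SNP ids and a per-SNP report.

    A SNP is kept iff its missing rate is at or below the cap, its
    minor-allele frequency over all samples is at or above the floor, and
    the HWE exact p in the control group is at or above the floor. The
    report records each value and the first failing criterion.
    """
    ctrl_mask = matrix.group_mask(control_group)
    rows = []
    kept: list[str] = []
    for j, meta in enumerate(matrix.snps):
        col = matrix.calls[:, j]
        n_missing = int((col == MISSING).sum())
        missing_rate = n_missing / matrix.n_samples
        called = col[col != MISSING]
        if called.size:
            f1 = called.sum() / (2 * called.size)
            maf = float(min(f1, 1 - f1))
        else:
            maf = 0.0
        ctrl = col[ctrl_mask]
        ctrl = ctrl[ctrl != MISSING]
        if ctrl.size:
            hwe_p = hwe_exact(
                int((ctrl == 2).sum()), int((ctrl == 1).sum()), int((ctrl == 0).sum())
            )
        else:
            hwe_p = float("nan")
        reason = ""
        if missing_rate > thresholds.max_snp_missing_rate:
            reason = "missing"
        elif maf < thresholds.min_maf:
            reason = "maf"
        elif not (hwe_p >= thresholds.min_hwe_p):
            reason = "hwe"
        if not reason:
            kept.append(meta.snp_id)
        rows.append(
            {
                "snp": meta.snp_id,
                "missing_rate": missing_rate,
                "maf": maf,
                "hwe_p": hwe_p,
                "kept": not reason,
                "fail_reason": reason,
            }
        )
    return kept, pd.DataFrame(rows)


def run_association(
    matrix: GenotypeMatrix,
    affected_group: str,
    unaffected_group: str,
    alpha: float = 0.05,
    snp_ids: list[str] | None = None,
) -> list[AssociationResult]:
    """Allelic scan of one case/control contrast, filtered at p <= alpha.

    Results are sorted by ascending p, ties broken by rsID. SNPs whose
    table has a zero margin (monomorphic in both groups combined) are
    skipped. ``snp_ids`` restricts the scan to a QC-kept subset.
    """
    labels = matrix.group_labels()
    for g in (affected_group, unaffected_group):
        if g not in labels:
            raise KeyError(f"group label {g!r} not present in matrix")
    wanted = set(snp_ids) if snp_ids is not None else None
    results = []
    for j, meta in enumerate(matrix.snps):
        if wanted is not None and meta.snp_id not in wanted:
            continue
        try:
            t = count_alleles(matrix, j, affected_group, unaffected_group)
            chi2, df = allelic_chi2(t)
        except DegenerateInputError:
            continue
        p = chi2_sf(chi2, df)
        or_, lo, hi = odds_ratio(t)
        results.append(
            AssociationResult(
                snp=meta, f_A=t.f_A, f_U=t.f_U, chi2=chi2, df=df, p=p,
                or_=or_, ci_low=lo, ci_high=hi,
            )
        )
    results = [r for r in results if r.p <= alpha]
    results.sort(key=lambda r: (r.p, r.snp.snp_id))
    return results


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabulate results (mirrors the risk-SNP panel columns) with a BH column.

    The BH-adjusted p-values are informational; selection happens on raw p.
    """
    df = pd.DataFrame([r.as_row() for r in results])
    if len(df):
        from statsmodels.stats.multitest import multipletests

        df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
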