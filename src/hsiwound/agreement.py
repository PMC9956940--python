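"""Method-agreement statistics for the 30-case wound-area comparison.

Three measurement conventions are compared pairwise: the nurse's ruler LW
area, the machine LW area, and the machine morphology (planimetric) area.
For each pairing the suite reports Pearson's r, Spearman's rho (midranks),
two single-measure ICC forms — one-way random ICC(1,1) and two-way
absolute-agreement ICC(A,1) — and Cohen's kappa, unweighted and weighted,
on pooled-quintile area bins, with large-sample 95% confidence intervals.

The study's 30-case table (NPUAP stage, the three area columns, and the
seven flagged outlier cases whose wound location was judged inconsistently
between methods) is bundled as a CSV fixture and loaded by
:func:`load_study_cases`; the full with/without-outlier comparison grid is
produced by :func:`reproduce_table4`.

The binning behind the kappa statistics deserves emphasis: kappa is defined
for categories, so continuous areas must be binned, and the choice of bins
is part of the statistic. The default here is five pooled-quantile bins
over the union of the two compared columns, recorded in every report.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, StatisticsError

NPUAP_STAGES = ("1", "2", "3", "4", "unstageable")

#: The three pairwise comparisons reported by the study.
METHOD_PAIRINGS = (
    ("nurse_lw_cm2", "machine_lw_cm2"),
    ("nurse_lw_cm2", "machine_morph_cm2"),
    ("machine_lw_cm2", "machine_morph_cm2"),
)


@dataclass(frozen=True)
class CaseRecord:
    """One patient row: stage, the three area measurements, outlier flag."""

    case_id: str
    stage: str
    nurse_lw_cm2: float
    machine_lw_cm2: float
    machine_morph_cm2: float
    outlier: bool = False

    def __post_init__(self):
        if self.stage not in NPUAP_STAGES:
            raise ParameterError(
                f"stage {self.stage!r} not in NPUAP set {NPUAP_STAGES}"
            )
        for name in ("nurse_lw_cm2", "machine_lw_cm2", "machine_morph_cm2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


def load_study_cases(path: str | Path | None = None) -> list[CaseRecord]:
    """Load the bundled 30-case study table (or a compatible CSV)."""
    if path is None:
        src = resources.files("hsiwound.data").joinpath("cases.csv")
        df = pd.read_csv(src.open())
    else:
        df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CaseRecord(
                case_id=str(row.case_id),
                stage=str(row.stage),
                nurse_lw_cm2=float(row.nurse_lw_cm2),
                machine_lw_cm2=float(row.machine_lw_cm2),
                machine_morph_cm2=float(row.machine_morph_cm2),
                outlier=bool(row.outlier),
            )
        )
    return records


def records_to_frame(records: list[CaseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "case_id": [r.case_id for r in records],
            "stage": [r.stage for r in records],
            "nurse_lw_cm2": [r.nurse_lw_cm2 for r in records],
            "machine_lw_cm2": [r.machine_lw_cm2 for r in records],
            "machine_morph_cm2": [r.machine_morph_cm2 for r in records],
            "outlier": [r.outlier for r in records],
        }
    )


def stage_summary(records: list[CaseRecord]) -> pd.DataFrame:
    """NPUAP stage counts and percentages over the record list."""
    n = len(records)
    counts = {s: 0 for s in NPUAP_STAGES}
    for r in records:
        counts[r.stage] += 1
    return pd.DataFrame(
        {
            "stage": list(counts),
            "count": list(counts.values()),
            "percent": [100.0 * c / n if n else 0.0 for c in counts.values()],
        }
    )


def exclude_outliers(
    records: list[CaseRecord], ids: list[str] | None = None
) -> list[CaseRecord]:
    """Drop the given case ids (default: the flagged outliers), preserving
    order; unknown ids raise."""
    if ids is None:
        ids = [r.case_id for r in records if r.outlier]
    known = {r.case_id for r in records}
    unknown = [i for i in ids if i not in known]
    if unknown:
        raise ParameterError(f"unknown case id(s): {unknown}")
    drop = set(ids)
    return [r for r in records if r.case_id not in drop]


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def _check_pair(x, y, min_n=3):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D sequences")
    if x.size < min_n:
        raise ParameterError(f"need at least {min_n} pairs, got {x.size}")
    return x, y


def pearson_r(x, y) -> float:
    """Product-moment correlation (undefined for zero variance).

    Computed from centred sums, sum(dx dy) / sqrt(sum dx^2 sum dy^2),
    which keeps perfect agreement at exactly 1.0.
    """
    x, y = _check_pair(x, y)
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0 or syy == 0:
        raise StatisticsError("Pearson r undefined for zero-variance input")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


def spearman_rho(x, y) -> float:
    """Pearson correlation of midranks (ties get average ranks)."""
    x, y = _check_pair(x, y)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise StatisticsError("Spearman rho undefined for constant input")
    return pearson_r(stats.rankdata(x), stats.rankdata(y))


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

def icc_single(x, y, form: str = "oneway") -> float:
    """Single-measure ICC of two raters from ANOVA mean squares.

    ``oneway`` is ICC(1,1) from the one-way random-effects model;
    ``twoway_agreement`` is ICC(A,1), the two-way absolute-agreement form
    that additionally charges systematic rater offsets to disagreement.
    """
    x, y = _check_pair(x, y)
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)

    ss_total = ((data - grand) ** 2).sum()
    ss_subject = k * ((subj_means - grand) ** 2).sum()
    ss_rater = n * ((rater_means - grand) ** 2).sum()

    msr = ss_subject / (n - 1)                     # between-subject
    if form == "oneway":
        msw = (ss_total - ss_subject) / (n * (k - 1))
        denom = msr + (k - 1) * msw
        if denom == 0:
            raise StatisticsError("ICC undefined: no variance in the data")
        return float((msr - msw) / denom)
    if form == "twoway_agreement":
        mse = (ss_total - ss_subject - ss_rater) / ((n - 1) * (k - 1))
        msc = ss_rater / (k - 1)
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        if denom == 0:
            raise StatisticsError("ICC undefined: no variance in the data")
        return float((msr - mse) / denom)
    raise ParameterError(f"unknown ICC form {form!r}")


def icc_mixed(replicates: pd.DataFrame) -> float:
    """Variance-components ICC from replicated measurements.

    ``replicates`` is a long table with columns ``subject`` and ``value``
    (a ``replicate`` column may be present but is not used: the model is
    one-way). The one-way random-effects model value_ij = mu + s_i + e_ij
    is estimated by the ANOVA method of moments; the ICC is
    sigma^2_subject / (sigma^2_subject + sigma^2_residual), with a negative
    between-subject component truncated at zero. Handles unbalanced designs
    via the standard n0 coefficient.
    """
    if not {"subject", "value"}.issubset(replicates.columns):
        raise ParameterError("replicates needs 'subject' and 'value' columns")
    groups = replicates.groupby("subject")["value"]
    sizes = groups.size().to_numpy(dtype=np.float64)
    a = sizes.size
    if a < 2:
        raise StatisticsError("need at least 2 subjects")
    if (sizes < 2).all():
        raise StatisticsError("need at least one subject with >= 2 replicates")
    values = replicates["value"].to_numpy(dtype=np.float64)
    N = values.size
    grand = values.mean()
    means = groups.mean().to_numpy(dtype=np.float64)

    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(
        ((values - replicates.groupby("subject")["value"].transform("mean")
          .to_numpy()) ** 2).sum()
    )
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a)
    n0 = (N - (sizes**2).sum() / N) / (a - 1)
    sigma2_s = max(0.0, (ms_between - ms_within) / n0)
    denom = sigma2_s + ms_within
    if denom == 0:
        raise StatisticsError("ICC undefined: zero total variance")
    return float(sigma2_s / denom)


# ---------------------------------------------------------------------------
# Binning and kappa
# ---------------------------------------------------------------------------

def quantile_edges(values, n_bins: int = 5) -> np.ndarray:
    """Interior cut points splitting ``values`` into n_bins quantile bins."""
    values = np.asarray(values, dtype=np.float64)
    if np.unique(values).size < n_bins:
        raise ParameterError(
            f"quantile binning needs >= {n_bins} distinct values"
        )
    qs = np.arange(1, n_bins) / n_bins
    return np.quantile(values, qs)


def bin_areas(values, scheme: str = "quintile", edges=None) -> np.ndarray:
    """Assign each area to an ordinal category.

    ``quintile``: five quantile bins over ``values`` itself (for a pooled
    two-method binning, pass precomputed pooled edges with ``fixed_edges``).
    ``fixed_edges``: user cut points; intervals are right-open, i.e. a value
    lands in bin i when edges[i-1] <= v < edges[i].
    """
    values = np.asarray(values, dtype=np.float64)
    if scheme == "quintile":
        cut = quantile_edges(values, 5)
    elif scheme == "fixed_edges":
        if edges is None:
            raise ParameterError("fixed_edges scheme requires edges")
        cut = np.asarray(edges, dtype=np.float64)
        if cut.ndim != 1 or cut.size == 0:
            raise ParameterError("edges must be a non-empty 1-D sequence")
        if np.any(np.diff(cut) <= 0):
            raise ParameterError("edges must be strictly increasing")
    else:
        raise ParameterError(f"unknown binning scheme {scheme!r}")
    return np.searchsorted(cut, values, side="right")


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    weights: str

    def __float__(self):
        return self.kappa


def _kappa_weight_matrix(n_cat: int, weights: str) -> np.ndarray:
    """Agreement weights: 1 on the diagonal, decaying off it."""
    if n_cat == 1:
        return np.ones((1, 1))
    i, j = np.meshgrid(np.arange(n_cat), np.arange(n_cat), indexing="ij")
    if weights == "none":
        return (i == j).astype(np.float64)
    if weights == "linear":
        return 1.0 - np.abs(i - j) / (n_cat - 1)
    if weights == "quadratic":
        return 1.0 - ((i - j) ** 2) / (n_cat - 1) ** 2
    raise ParameterError(f"unknown kappa weights {weights!r}")


def cohen_kappa(a, b, weights: str = "none") -> KappaResult:
    """Cohen's kappa with optional linear/quadratic weights and the
    large-sample 95% CI (Fleiss-Cohen-Everitt variance).

    kappa = (po - pe) / (1 - pe) on the chosen agreement-weight scheme;
    raises when both raters use a single category (pe = 1).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("category lists must be equal-length 1-D")
    cats = np.unique(np.concatenate([a, b]))
    n_cat = cats.size
    if n_cat < 2:
        raise StatisticsError("kappa undefined: a single category observed")
    idx = {c: i for i, c in enumerate(cats)}
    n = a.size
    p = np.zeros((n_cat, n_cat))
    for ai, bi in zip(a, b):
        p[idx[ai], idx[bi]] += 1.0
    p /= n

    w = _kappa_weight_matrix(n_cat, weights)
    p_row = p.sum(axis=1)
    p_col = p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(p_row, p_col)).sum())
    if pe >= 1.0:
        raise StatisticsError("kappa undefined: expected agreement is 1")
    kappa = (po - pe) / (1.0 - pe)

    # large-sample variance (agreement-weight formulation)
    w_row = w @ p_col          # mean weight of row i against rater-B marginal
    w_col = w.T @ p_row        # mean weight of col j against rater-A marginal
    term = (w - (w_row[:, None] + w_col[None, :]) * (1.0 - kappa)) ** 2
    var = ((p * term).sum() - (kappa - pe * (1.0 - kappa)) ** 2) / (
        n * (1.0 - pe) ** 2
    )
    se = float(np.sqrt(max(var, 0.0)))
    lo = max(-1.0, kappa - 1.959963984540054 * se)
    hi = min(1.0, kappa + 1.959963984540054 * se)
    return KappaResult(float(kappa), se, float(lo), float(hi), weights)


# ---------------------------------------------------------------------------
# Full comparison reports
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """All agreement statistics for one method pairing on one case subset."""

    method_x: str
    method_y: str
    n: int
    excluded: list[str]
    pearson_r: float
    spearman_rho: float
    icc_oneway: float
    icc_agreement: float
    kappa_unweighted: KappaResult
    kappa_weighted: KappaResult
    binning: str
    kappa_weights: str = "quadratic"

    def __post_init__(self):
        for name in ("pearson_r", "spearman_rho", "icc_oneway", "icc_agreement"):
            v = getattr(self, name)
            if not (-1.0 - 1e-9 <= v <= 1.0 + 1e-9):
                raise StatisticsError(f"{name}={v} outside [-1, 1]")

    def to_dict(self, round_to: int | None = None) -> dict:
        def r(v):
            return round(v, round_to) if round_to is not None else v

        return {
            "method_x": self.method_x,
            "method_y": self.method_y,
            "n": self.n,
            "excluded": list(self.excluded),
            "pearson_r": r(self.pearson_r),
            "spearman_rho": r(self.spearman_rho),
            "icc_oneway": r(self.icc_oneway),
            "icc_agreement": r(self.icc_agreement),
            "kappa_unweighted": r(self.kappa_unweighted.kappa),
            "kappa_unweighted_ci": [
                r(self.kappa_unweighted.ci_low), r(self.kappa_unweighted.ci_high)
            ],
            "kappa_weighted": r(self.kappa_weighted.kappa),
            "kappa_weighted_ci": [
                r(self.kappa_weighted.ci_low), r(self.kappa_weighted.ci_high)
            ],
            "kappa_weights": self.kappa_weights,
            "binning": self.binning,
        }


def compare_methods(
    records: list[CaseRecord],
    column_x: str,
    column_y: str,
    excluded: list[str] | None = None,
    binning: str = "quintile",
    edges=None,
    kappa_weights: str = "quadratic",
) -> AgreementReport:
    """Compute the full agreement suite for one pair of area columns.

    Kappa uses pooled binning: cut points are derived from the union of the
    two columns (quintile scheme) or supplied as fixed edges, then applied
    to each column separately so both raters share one category alphabet.
    """
    x = np.array([getattr(r, column_x) for r in records])
    y = np.array([getattr(r, column_y) for r in records])
    if binning == "quintile":
        cut = quantile_edges(np.concatenate([x, y]), 5)
        scheme_desc = "pooled-quintile"
    else:
        if edges is None:
            raise ParameterError("fixed_edges binning requires edges")
        cut = np.asarray(edges, dtype=np.float64)
        scheme_desc = f"fixed_edges={list(cut)}"
    cat_x = bin_areas(x, "fixed_edges", edges=cut)
    cat_y = bin_areas(y, "fixed_edges", edges=cut)

    return AgreementReport(
        method_x=column_x,
        method_y=column_y,
        n=len(records),
        excluded=list(excluded or []),
        pearson_r=pearson_r(x, y),
        spearman_rho=spearman_rho(x, y),
        icc_oneway=icc_single(x, y, "oneway"),
        icc_agreement=icc_single(x, y, "twoway_agreement"),
        kappa_unweighted=cohen_kappa(cat_x, cat_y, "none"),
        kappa_weighted=cohen_kappa(cat_x, cat_y, kappa_weights),
        binning=scheme_desc,
        kappa_weights=kappa_weights,
    )


def reproduce_table4(
    records: list[CaseRecord] | None = None,
    binning: str = "quintile",
    edges=None,
) -> dict[str, AgreementReport]:
    """The full with/without-outliers comparison grid of the study.

    Returns six reports keyed ``<x>__vs__<y>[__no_outliers]`` covering the
    three method pairings, first on all cases and then with the flagged
    outlier cases removed.
    """
    if records is None:
        records = load_study_cases()
    outlier_ids = [r.case_id for r in records if r.outlier]
    kept = exclude_outliers(records, outlier_ids)

    reports: dict[str, AgreementReport] = {}
    for cx, cy in METHOD_PAIRINGS:
        key = f"{cx[:-4]}__vs__{cy[:-4]}"
        reports[key] = compare_methods(
            records, cx, cy, excluded=[], binning=binning, edges=edges
        )
        reports[key + "__no_outliers"] = compare_methods(
            kept, cx, cy, excluded=outlier_ids, binning=binning, edges=edges
        )
    return reports


def reports_to_frame(reports: dict[str, AgreementReport],
                     round_to: int | None = 2) -> pd.DataFrame:
    """Flatten a report dict to a printable table (2-decimal by default;
    full precision is preserved in the JSON path)."""
    rows = []
    for key, rep in reports.items():
        d = rep.to_dict(round_to=round_to)
        d["comparison"] = key
        rows.append(d)
    return pd.DataFrame(rows).set_index("comparison")
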