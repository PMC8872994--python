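"""Longitudinal cohort statistics.

Rank-based k-group testing (Kruskal-Wallis with Dunn's pairwise post hoc and
Sidak or Benjamini-Hochberg adjustment), repeated-measures correlation with
subject-level bootstrap confidence intervals, distributional diagnostics, and
a report runner that mirrors the usual layout of a longitudinal biomarker
study: medians per timepoint, baseline-vs-follow-up pairwise p-values, and a
serum-vs-tissue correlation matrix.

The repeated-measures correlation is exposed statsmodels-style: a
:class:`RepeatedMeasuresCorrelation` model is built from a long-format table
and ``fit()`` returns a :class:`RmcorrResults` object carrying the estimate,
its degrees of freedom, p-value, optional bootstrap CI and a ``summary()``
table.  The estimator is the common within-subject correlation from the
ANCOVA with subject as a categorical factor and a common slope; it is
computed by subject-centering both variables, which is algebraically
identical to the subject-dummy ANCOVA:

    r = sum(xc * yc) / sqrt(sum(xc^2) * sum(yc^2)),   df = N - k - 1

with ``xc, yc`` the within-subject centered variables, ``N`` complete
observations and ``k`` subjects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
    SchemaError,
    UndefinedCorrelationError,
)

# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


@dataclass
class KWResult:
    """Tie-corrected Kruskal-Wallis H with its chi-square p-value."""

    H: float
    df: int
    p: float
    group_n: dict = field(default_factory=dict)


def _split_groups(values, groups) -> dict:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise InvalidInputError("values and groups must have equal length")
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    out = {g: values[groups == g] for g in pd.unique(groups)}
    if any(len(v) == 0 for v in out.values()):
        raise InvalidInputError("every group needs at least one observation")
    return out


def kruskal_wallis(values, groups) -> KWResult:
    """Kruskal-Wallis rank test across groups.

    H is tie-corrected; p comes from the chi-square distribution with k-1
    degrees of freedom.  All-identical values give H = 0, p = 1 (no signal,
    not an error).
    """
    by_group = _split_groups(values, groups)
    k = len(by_group)
    if k < 2:
        raise InvalidInputError("need at least 2 groups")
    n_total = sum(len(v) for v in by_group.values())
    if n_total < 3:
        raise InvalidInputError("need at least 3 observations in total")
    group_n = {g: len(v) for g, v in by_group.items()}
    pooled = np.concatenate(list(by_group.values()))
    if np.ptp(pooled) == 0:  # scipy raises on all-identical input
        return KWResult(H=0.0, df=k - 1, p=1.0, group_n=group_n)
    H, p = sps.kruskal(*by_group.values())
    return KWResult(H=float(H), df=k - 1, p=float(p), group_n=group_n)


# ---------------------------------------------------------------------------
# Dunn's post hoc
# ---------------------------------------------------------------------------


@dataclass
class DunnResult:
    """Pairwise Dunn z statistics with raw and adjusted p-values."""

    pairs: pd.DataFrame  # columns: group_a, group_b, z, p_raw, p_adj
    method: str


def sidak_adjust(p_raw: np.ndarray, m: int | None = None) -> np.ndarray:
    """Sidak family-wise adjustment: ``1 - (1 - p)^m``."""
    p = np.asarray(p_raw, dtype=float)
    m = len(p) if m is None else m
    return 1.0 - (1.0 - p) ** m


def dunn_posthoc(values, groups, adjust: str = "sidak") -> DunnResult:
    """Dunn's pairwise post hoc for a preceding Kruskal-Wallis test.

    For each pair (i, j) of groups the statistic is

        z = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)]

    with pooled mean ranks Rbar, total N and tie term T = sum(t^3 - t).
    Raw p-values are two-sided normal; adjustment is Sidak (default) or
    Benjamini-Hochberg over the m = k(k-1)/2 pairs.
    """
    if adjust not in ("sidak", "bh"):
        raise InvalidParameterError(f"adjust must be 'sidak' or 'bh', got {adjust!r}")
    by_group = _split_groups(values, groups)
    labels = list(by_group)
    if len(labels) < 2:
        raise InvalidInputError("need at least 2 groups")
    pooled = np.concatenate([by_group[g] for g in labels])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_rank, offset = {}, 0
    for g in labels:
        n_g = len(by_group[g])
        mean_rank[g] = ranks[offset : offset + n_g].mean()
        offset += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    rows = []
    for ga, gb in itertools.combinations(labels, 2):
        na, nb = len(by_group[ga]), len(by_group[gb])
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_rank[ga] - mean_rank[gb]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": ga, "group_b": gb, "z": z, "p_raw": p_raw})
    df = pd.DataFrame(rows)
    if adjust == "sidak":
        df["p_adj"] = sidak_adjust(df["p_raw"].to_numpy())
    else:
        df["p_adj"] = sps.false_discovery_control(df["p_raw"].to_numpy(), method="bh")
    df["p_adj"] = np.clip(np.maximum(df["p_adj"], df["p_raw"]), 0.0, 1.0)
    return DunnResult(pairs=df, method=adjust)


# ---------------------------------------------------------------------------
# Repeated-measures correlation (statsmodels-style model / results pair)
# ---------------------------------------------------------------------------


@dataclass
class RmcorrResults:
    """Results of a repeated-measures correlation fit."""

    r: float
    df: int
    pvalue: float
    slope: float
    n_obs: int
    n_subjects: int
    x: str
    y: str
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    seed: int | None = None
    boot_r: np.ndarray | None = None
    n_boot_dropped: int = 0

    def summary(self) -> str:
        lines = [
            "Repeated-Measures Correlation",
            "=" * 46,
            f"{'x':<22}{self.x}",
            f"{'y':<22}{self.y}",
            f"{'n observations':<22}{self.n_obs}",
            f"{'n subjects':<22}{self.n_subjects}",
            f"{'r':<22}{self.r:.4f}",
            f"{'df':<22}{self.df}",
            f"{'p-value':<22}{self.pvalue:.4g}",
            f"{'common slope':<22}{self.slope:.4g}",
        ]
        if self.ci_low is not None:
            lines.append(
                f"{'95% bootstrap CI':<22}[{self.ci_low:.4f}, {self.ci_high:.4f}]"
                f"  (n_boot={self.n_boot}, seed={self.seed})"
            )
        lines.append("=" * 46)
        return "\n".join(lines)


class RepeatedMeasuresCorrelation:
    """Common within-subject correlation between two repeatedly measured variables.

    Parameters
    ----------
    data : DataFrame
        Long-format table, one row per subject x visit.
    x, y : str
        Column names of the two variables.
    subject : str
        Column identifying the subject (the repeated-measures unit).

    Rows with a missing x or y are dropped (complete-case); subjects retain
    all their remaining visits.
    """

    def __init__(self, data: pd.DataFrame, x: str, y: str, subject: str = "subject_id"):
        missing = [c for c in (x, y, subject) if c not in data.columns]
        if missing:
            raise SchemaError(f"table lacks required columns: {missing}")
        sub = data[[subject, x, y]].dropna()
        self.x, self.y, self.subject = x, y, subject
        self._xv = sub[x].to_numpy(dtype=float)
        self._yv = sub[y].to_numpy(dtype=float)
        codes, uniques = pd.factorize(sub[subject].to_numpy())
        self._codes = codes
        self._k = len(uniques)
        self._n = len(sub)
        # per-subject row indices, for the subject-level bootstrap
        order = np.argsort(codes, kind="stable")
        bounds = np.searchsorted(codes[order], np.arange(self._k + 1))
        self._subject_rows = [order[bounds[i] : bounds[i + 1]] for i in range(self._k)]

    @staticmethod
    def _fit_arrays(xv: np.ndarray, yv: np.ndarray, codes: np.ndarray, k: int):
        """Core estimator on raw arrays; returns (r, slope, n, k) or raises."""
        counts = np.bincount(codes, minlength=k).astype(float)
        xm = np.bincount(codes, xv, k) / counts
        ym = np.bincount(codes, yv, k) / counts
        xc = xv - xm[codes]
        yc = yv - ym[codes]
        ssx = float(xc @ xc)
        if ssx <= 0:
            raise UndefinedCorrelationError("no within-subject variance in x")
        ssy = float(yc @ yc)
        sxy = float(xc @ yc)
        if ssy <= 0:
            return 0.0, 0.0
        return sxy / np.sqrt(ssx * ssy), sxy / ssx

    def fit(self) -> RmcorrResults:
        if self._k < 2:
            raise InsufficientDataError("need at least 2 subjects with complete pairs")
        df = self._n - self._k - 1
        if df < 1:
            raise InsufficientDataError(f"df = N - k - 1 = {df} < 1")
        r, slope = self._fit_arrays(self._xv, self._yv, self._codes, self._k)
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
            p = float(2.0 * sps.t.sf(abs(t), df))
        return RmcorrResults(
            r=float(r), df=int(df), pvalue=p, slope=float(slope),
            n_obs=self._n, n_subjects=self._k, x=self.x, y=self.y,
        )

    def fit_bootstrap(self, n_boot: int = 1000, seed: int | None = None) -> RmcorrResults:
        """Fit plus a subject-level (cluster) bootstrap percentile CI.

        Subjects are resampled with replacement; a resampled subject keeps
        all its visits and duplicated subjects receive distinct identities.
        Replicates on which the correlation is undefined (df < 1 or no
        within-subject x variance) are redrawn up to 10 times, then dropped.
        Deterministic for a fixed seed.
        """
        if n_boot < 1:
            raise InvalidParameterError("n_boot must be >= 1")
        res = self.fit()
        rng = np.random.default_rng(seed)
        rows = self._subject_rows
        k = self._k
        boot_r = np.empty(n_boot)
        n_valid = 0
        n_dropped = 0
        for _ in range(n_boot):
            for _retry in range(11):
                chosen = rng.integers(0, k, k)
                idx = np.concatenate([rows[c] for c in chosen])
                codes = np.repeat(np.arange(k), [len(rows[c]) for c in chosen])
                if len(idx) - k - 1 < 1:
                    continue
                try:
                    r_b, _ = self._fit_arrays(self._xv[idx], self._yv[idx], codes, k)
                except UndefinedCorrelationError:
                    continue
                boot_r[n_valid] = r_b
                n_valid += 1
                break
            else:
                n_dropped += 1
        boot_r = boot_r[:n_valid]
        if n_valid == 0:
            raise InsufficientDataError("all bootstrap replicates were degenerate")
        lo, hi = np.percentile(boot_r, [2.5, 97.5])
        res.ci_low, res.ci_high = float(lo), float(hi)
        res.n_boot, res.seed = n_boot, seed
        res.boot_r, res.n_boot_dropped = boot_r, n_dropped
        return res


def rmcorr(table: pd.DataFrame, x: str, y: str, subject: str = "subject_id") -> RmcorrResults:
    """Functional wrapper: fit a repeated-measures correlation."""
    return RepeatedMeasuresCorrelation(table, x, y, subject).fit()


def bootstrap_rmcorr(
    table: pd.DataFrame,
    x: str,
    y: str,
    n_boot: int = 1000,
    seed: int | None = None,
    subject: str = "subject_id",
) -> RmcorrResults:
    """Functional wrapper: rmcorr with a subject-bootstrap percentile CI."""
    return RepeatedMeasuresCorrelation(table, x, y, subject).fit_bootstrap(n_boot, seed)


# ---------------------------------------------------------------------------
# Distribution diagnostics
# ---------------------------------------------------------------------------


@dataclass
class DiagnosticsReport:
    """Normality/variance diagnostics for one variable (optionally by group)."""

    shapiro_p: float | None
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    bartlett: tuple[float, float] | None
    levene: tuple[float, float] | None
    fligner: tuple[float, float] | None
    boxcox_lambda: float | None
    boxcox_normality_p: float | None
    boxcox_suitable: bool | None
    notes: list[str] = field(default_factory=list)


def distribution_diagnostics(values, groups=None) -> DiagnosticsReport:
    """Normality and homoscedasticity diagnostics.

    Emits QQ-plot data (theoretical vs. sample normal quantiles), a Shapiro
    normality p, Bartlett / median-centered Levene / Fligner-Killeen variance
    tests across groups (each group needs >= 3 observations; otherwise the
    variance tests are marked not-computable and the rest still run), and a
    Box-Cox suitability flag: true iff the MLE lambda makes the transformed
    values pass Shapiro at p > 0.05.  Box-Cox requires strictly positive
    values.
    """
    vals = np.asarray(values, dtype=float)
    keep = np.isfinite(vals)
    vals = vals[keep]
    notes: list[str] = []
    if vals.size < 3:
        raise InvalidInputError("need at least 3 observations")

    (osm, osr), _ = sps.probplot(vals, dist="norm", fit=True)
    shapiro_p = float(sps.shapiro(vals).pvalue) if np.ptp(vals) > 0 else None
    if shapiro_p is None:
        notes.append("constant variable: normality test not computable")

    bartlett = levene = fligner = None
    if groups is not None:
        g = np.asarray(groups)[keep]
        by_group = [vals[g == lab] for lab in pd.unique(g)]
        if len(by_group) >= 2 and all(len(v) >= 3 for v in by_group):
            if all(np.ptp(v) > 0 for v in by_group):
                b = sps.bartlett(*by_group)
                bartlett = (float(b.statistic), float(b.pvalue))
                lv = sps.levene(*by_group, center="median")
                levene = (float(lv.statistic), float(lv.pvalue))
                fk = sps.fligner(*by_group, center="median")
                fligner = (float(fk.statistic), float(fk.pvalue))
            else:
                notes.append("a group is constant: variance tests not computable")
        else:
            notes.append("variance tests need >= 2 groups with >= 3 observations each")

    boxcox_lambda = boxcox_p = suitable = None
    if np.all(vals > 0) and np.ptp(vals) > 0:
        try:
            boxcox_lambda = float(sps.boxcox_normmax(vals, method="mle"))
            transformed = sps.boxcox(vals, boxcox_lambda)
            boxcox_p = float(sps.shapiro(transformed).pvalue)
            suitable = boxcox_p > 0.05
        except Exception as exc:  # pathological profiles: flag, do not fail
            notes.append(f"Box-Cox fit failed: {exc}")
    else:
        notes.append("Box-Cox requires strictly positive, non-constant values")

    return DiagnosticsReport(
        shapiro_p=shapiro_p,
        qq_theoretical=np.asarray(osm),
        qq_sample=np.asarray(osr),
        bartlett=bartlett,
        levene=levene,
        fligner=fligner,
        boxcox_lambda=boxcox_lambda,
        boxcox_normality_p=boxcox_p,
        boxcox_suitable=suitable,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Longitudinal report
# ---------------------------------------------------------------------------

ID_COLUMNS = ("subject_id", "intervention", "timepoint")


@dataclass
class LongitudinalReport:
    """Bundle of report tables from :func:`run_longitudinal_report`."""

    medians: pd.DataFrame       # variable x timepoint medians
    kruskal: pd.DataFrame       # variable, H, df, p
    dunn: pd.DataFrame          # variable, group_a, group_b, z, p_raw, p_adj, baseline_pair, significant
    rmcorr: pd.DataFrame | None  # x, y, r, df, p, ci_low, ci_high
    alpha: float

    def to_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.medians.to_csv(out / "medians_by_timepoint.csv")
        self.kruskal.to_csv(out / "kruskal_wallis.csv", index=False)
        self.dunn.to_csv(out / "dunn_pairwise.csv", index=False)
        if self.rmcorr is not None:
            self.rmcorr.to_csv(out / "rmcorr_pairs.csv", index=False)


def run_longitudinal_report(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    adjust: str = "sidak",
    n_boot: int = 0,
    seed: int | None = None,
    variables: list[str] | None = None,
) -> LongitudinalReport:
    """Run the full longitudinal analysis over a cohort table.

    Per variable: medians per timepoint, Kruskal-Wallis across timepoints and
    Dunn's adjusted post hoc (baseline-vs-follow-up pairs flagged).  Per
    (x, y) pair: repeated-measures correlation, bootstrapped when
    ``n_boot > 0``.  ``pairs=None`` or an empty list yields a report with the
    medians/KW/Dunn section only.
    """
    required = ["subject_id", "timepoint"]
    missing = [c for c in required if c not in table.columns]
    if pairs:
        missing += [c for xy in pairs for c in xy if c not in table.columns]
    if variables:
        missing += [c for c in variables if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table lacks required columns: {sorted(set(missing))}")

    if variables is None:
        variables = [
            c for c in table.columns
            if c not in ID_COLUMNS and pd.api.types.is_numeric_dtype(table[c])
        ]

    tps = sorted(pd.unique(table["timepoint"]))
    baseline = tps[0]
    medians = pd.DataFrame(
        {t: table.loc[table["timepoint"] == t, variables].median() for t in tps}
    )
    medians.index.name = "variable"

    kw_rows, dunn_rows = [], []
    for var in variables:
        sub = table[["timepoint", var]].dropna()
        kw = kruskal_wallis(sub[var], sub["timepoint"])
        kw_rows.append({"variable": var, "H": kw.H, "df": kw.df, "p": kw.p,
                        "significant": kw.p < alpha})
        dn = dunn_posthoc(sub[var], sub["timepoint"], adjust=adjust)
        d = dn.pairs.copy()
        d.insert(0, "variable", var)
        d["baseline_pair"] = (d["group_a"] == baseline) | (d["group_b"] == baseline)
        d["significant"] = d["p_adj"] < alpha
        dunn_rows.append(d)
    kw_df = pd.DataFrame(kw_rows)
    dunn_df = pd.concat(dunn_rows, ignore_index=True)

    rm_df = None
    if pairs:
        rows = []
        for i, (x, y) in enumerate(pairs):
            model = RepeatedMeasuresCorrelation(table, x, y)
            if n_boot > 0:
                pair_seed = None if seed is None else seed + i  # distinct, reproducible
                res = model.fit_bootstrap(n_boot=n_boot, seed=pair_seed)
            else:
                res = model.fit()
            rows.append({
                "x": x, "y": y, "r": res.r, "df": res.df, "p": res.pvalue,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "significant": res.pvalue < alpha,
            })
        rm_df = pd.DataFrame(rows)

    return LongitudinalReport(medians=medians, kruskal=kw_df, dunn=dunn_df,
                              rmcorr=rm_df, alpha=alpha)
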