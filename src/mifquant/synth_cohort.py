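"""Synthetic longitudinal cohort with programmed effect structure.

Emulates a 43-subject weight-loss cohort (37 bariatric surgery, 6 low-calorie
diet) sampled at 0, 2 and 12 months, with serum inflammatory markers (CRP,
IL-6, TNF-alpha) and tissue immune-cell fractions (CD56, CD68, CD3, CD8,
FOXP3, PD-1).  The generator is median-calibrated: at every timepoint the
sample median of each marker equals the configured median exactly (markers
are multiplicative log-normal around the median, and the per-time median of
the stochastic part is subtracted on the log scale).

Within-subject association is programmed explicitly.  For each marker a
latent log-scale signal is built as

    log y_it = log med(t) + b_i + beta * u_it + sigma_e * z_it

where ``u`` is the standardized within-subject weight deviation, ``b_i`` a
subject random intercept and ``z`` independent noise with the configured
coefficient of variation.  The weight-coupling coefficient ``beta`` is
solved numerically so that the expected within-subject (subject-centered)
correlation between log y and weight equals the configured ``rho_within`` —
this accounts for the correlation already implied by the configured median
time-trends, so a marker with rho 0 is decorrelated from weight even when
its medians drift, and a marker whose trend over-implies the target is
partially decoupled.  On the raw scale the correlation is attenuated
slightly by the log-normal transform (about 2-3% at the default noise
level).

Weight trajectories interpolate each subject's baseline to their 12-month
loss through the 2-month anchor, with log-normal subject effects on baseline
weight and on total loss; BMI is weight / height^2 with per-subject heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import InvalidParameterError

SERUM_MARKERS = ("crp", "il6", "tnfa")
TISSUE_MARKERS = ("cd56", "cd68", "cd3", "cd8", "foxp3", "pd1")


def _default_serum_medians() -> dict[str, dict[int, float]]:
    return {
        "crp": {0: 5.9, 2: 4.2, 12: 1.7},     # ug/ml
        "il6": {0: 4.8, 2: 1.7, 12: 1.2},     # pg/ml
        "tnfa": {0: 29.1, 2: 31.4, 12: 25.2},  # pg/ml
    }


def _default_tissue_medians() -> dict[str, dict[int, float]]:
    # fraction of segmented cells positive per marker
    return {
        "cd56": {0: 0.0071, 2: 0.0069, 12: 0.0116},
        "cd68": {0: 0.0019, 2: 0.0012, 12: 0.0008},
        "cd3": {0: 0.0019, 2: 0.0009, 12: 0.0013},
        "cd8": {0: 0.0037, 2: 0.0038, 12: 0.0056},
        "foxp3": {0: 0.00069, 2: 0.00069, 12: 0.00066},
        "pd1": {0: 0.0011, 2: 0.0008, 12: 0.0012},
    }


def _default_rho() -> dict[str, float]:
    # correlation of each marker with weight, within subject:
    # inflammatory markers fall with weight (positive), CD8 rises (negative)
    return {
        "crp": 0.57,
        "il6": 0.46,
        "tnfa": 0.0,
        "cd56": 0.0,
        "cd68": 0.0,
        "cd3": 0.0,
        "cd8": -0.32,
        "foxp3": 0.0,
        "pd1": 0.0,
    }


@dataclass
class CohortSimParams:
    """Generator configuration; defaults are the cohort's study conditions."""

    n_subjects: int = 43
    n_surgery: int = 37
    n_diet: int = 6
    timepoints: tuple[int, ...] = (0, 2, 12)  # months
    baseline_weight_median: float = 140.0  # kg (median BMI 52 at ~1.64 m)
    baseline_bmi_median: float = 52.0  # kg/m^2
    weight_loss_2m: dict[str, float] = field(
        default_factory=lambda: {"surgery": 15.1, "diet": 1.7}
    )
    weight_loss_12m: dict[str, float] = field(
        default_factory=lambda: {"surgery": 63.3, "diet": 13.0}
    )
    serum_medians: dict[str, dict[int, float]] = field(default_factory=_default_serum_medians)
    tissue_medians: dict[str, dict[int, float]] = field(default_factory=_default_tissue_medians)
    rho_within: dict[str, float] = field(default_factory=_default_rho)
    noise_cv: float = 0.25  # multiplicative (log-normal) marker noise
    subject_sd: float = 0.4  # log-scale between-subject marker intercept SD
    weight_subject_cv: float = 0.12  # log-normal spread of baseline weight
    loss_subject_cv: float = 0.25  # log-normal spread of per-subject total loss
    weight_visit_cv: float = 0.015  # visit-to-visit weight fluctuation (~2 kg)
    height_mean: float = 1.64  # m
    height_sd: float = 0.055  # m
    subject_effects: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_surgery + self.n_diet != self.n_subjects:
            problems.append(
                f"n_surgery + n_diet = {self.n_surgery + self.n_diet} != n_subjects = {self.n_subjects}"
            )
        if self.n_subjects < 2:
            problems.append("need at least 2 subjects")
        if len(self.timepoints) < 2:
            problems.append("need at least 2 timepoints")
        for name, med in self.all_medians().items():
            if any(v <= 0 for v in med.values()):
                problems.append(f"non-positive median configured for {name}")
            if set(med) != set(self.timepoints):
                problems.append(f"medians for {name} must cover timepoints {self.timepoints}")
        for arm in ("surgery", "diet"):
            if self.weight_loss_12m[arm] <= 0:
                problems.append(f"weight_loss_12m[{arm}] must be > 0")
        if self.baseline_weight_median <= 0 or self.baseline_bmi_median <= 0:
            problems.append("baseline medians must be > 0")
        for name, rho in self.rho_within.items():
            if abs(rho) > 1:
                problems.append(f"|rho_within[{name}]| must be <= 1")
        if self.noise_cv < 0:
            problems.append("noise_cv must be >= 0")
        if problems:
            raise InvalidParameterError("; ".join(problems))

    def all_medians(self) -> dict[str, dict[int, float]]:
        return {**self.serum_medians, **self.tissue_medians}

    @classmethod
    def null(cls, **overrides) -> "CohortSimParams":
        """A no-effect cohort: flat marker medians, all rho_within = 0,
        near-stationary weights.

        Marker trajectories carry no time trend and no association with
        weight, and weight itself only fluctuates around each subject's
        set-point (nominal 1 kg drift, visit-to-visit wobble).  Used for
        type-I-error checks of the longitudinal report and as the clean
        testbed for programmed-correlation recovery, where any association
        must come from subject-level variation rather than a shared time
        course.
        """
        base = cls()
        flat_serum = {k: {t: v[0] for t in base.timepoints} for k, v in base.serum_medians.items()}
        flat_tissue = {k: {t: v[0] for t in base.timepoints} for k, v in base.tissue_medians.items()}
        rho0 = {k: 0.0 for k in base.rho_within}
        return replace(
            base,
            serum_medians=flat_serum,
            tissue_medians=flat_tissue,
            rho_within=rho0,
            weight_loss_2m={"surgery": 0.3, "diet": 0.3},
            weight_loss_12m={"surgery": 1.0, "diet": 1.0},
            weight_visit_cv=0.02,
            **overrides,
        )


def _subject_center(a: np.ndarray, n_tp: int) -> np.ndarray:
    """Center a (subjects x timepoints)-shaped flat array within subject."""
    m = a.reshape(-1, n_tp)
    return (m - m.mean(axis=1, keepdims=True)).ravel()


def simulate_cohort(
    params: CohortSimParams | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Generate the long-format cohort table and the truth-effects record.

    Returns ``(table, truth)``: one row per subject x timepoint with columns
    ``subject_id, intervention, timepoint, weight, bmi`` plus the serum and
    tissue markers, and a truth dictionary recording, per marker, the target
    within-subject correlation, the solved mixing coefficient and the
    realized log-scale within-subject correlation.  Fully deterministic for
    a fixed (params, seed).
    """
    if params is None:
        params = CohortSimParams()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    n = params.n_subjects
    tps = np.asarray(params.timepoints, dtype=float)
    n_tp = len(tps)
    arms = np.array(["surgery"] * params.n_surgery + ["diet"] * params.n_diet)
    subject_ids = np.array([f"S{i + 1:03d}" for i in range(n)])

    # --- weight trajectories -------------------------------------------------
    if params.subject_effects:
        sig_w = np.sqrt(np.log1p(params.weight_subject_cv**2))
        sig_l = np.sqrt(np.log1p(params.loss_subject_cv**2))
        baseline = params.baseline_weight_median * np.exp(sig_w * rng.standard_normal(n))
        loss_jit = np.exp(sig_l * rng.standard_normal(n))
        heights = params.height_mean + params.height_sd * rng.standard_normal(n)
    else:
        baseline = np.full(n, params.baseline_weight_median)
        loss_jit = np.ones(n)
        heights = np.full(n, params.height_mean)
    loss12 = np.array([params.weight_loss_12m[a] for a in arms]) * loss_jit
    loss12 = np.minimum(loss12, 0.75 * baseline)  # keep weights physical
    if params.subject_effects and params.weight_visit_cv > 0:
        sig_v = np.sqrt(np.log1p(params.weight_visit_cv**2))
        visit_wobble = np.exp(sig_v * rng.standard_normal((n, n_tp)))
    else:
        visit_wobble = np.ones((n, n_tp))
    frac2 = np.array(
        [params.weight_loss_2m[a] / params.weight_loss_12m[a] for a in arms]
    )
    # loss fraction at each timepoint, linear between the 0/2/12-month anchors
    frac = np.empty((n, n_tp))
    for i in range(n):
        frac[i] = np.interp(tps, [0.0, 2.0, 12.0], [0.0, frac2[i], 1.0])
    weight = (baseline[:, None] - loss12[:, None] * frac) * visit_wobble  # (n, n_tp)
    bmi = weight / (heights**2)[:, None]

    w_flat = weight.ravel()
    u_raw = _subject_center(w_flat, n_tp)
    s_u = u_raw.std()
    u = u_raw / s_u if s_u > 0 else np.zeros_like(u_raw)

    sigma_e = np.sqrt(np.log1p(params.noise_cv**2))
    b_sd = params.subject_sd if params.subject_effects else 0.0

    table = pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, n_tp),
            "intervention": np.repeat(arms, n_tp),
            "timepoint": np.tile(params.timepoints, n),
            "weight": w_flat,
            "bmi": bmi.ravel(),
        }
    )

    truth: dict[str, dict] = {"seed": seed, "markers": {}}
    for name, med in params.all_medians().items():
        log_med = np.log([med[t] for t in params.timepoints])
        log_med_flat = np.tile(log_med, n)
        rho = params.rho_within.get(name, 0.0)
        b = b_sd * rng.standard_normal(n) if b_sd > 0 else np.zeros(n)
        z = rng.standard_normal(n * n_tp)

        if (sigma_e == 0.0 and not params.subject_effects) or s_u == 0:
            # fully deterministic cohort: medians are reproduced exactly and
            # no correlation structure can (or need) be embedded
            stoch = np.repeat(b, n_tp)
            beta, clamped = 0.0, rho != 0.0
        else:
            beta, clamped = _solve_beta(log_med_flat, u, sigma_e, rho, n_tp)
            stoch = np.repeat(b, n_tp) + beta * u + sigma_e * z
        # exact median calibration: subtract the per-time median of the
        # stochastic part so sample medians hit the configured values
        stoch_m = stoch.reshape(-1, n_tp)
        stoch_m = stoch_m - np.median(stoch_m, axis=0, keepdims=True)
        log_y = log_med_flat + stoch_m.ravel()
        table[name] = np.exp(np.clip(log_y, -600.0, 600.0))

        wc = _subject_center(log_y, n_tp)
        denom = np.sqrt((wc**2).sum() * (u_raw**2).sum())
        achieved = float((wc * u_raw).sum() / denom) if denom > 0 else 0.0
        truth["markers"][name] = {
            "rho_target": rho,
            "beta": float(beta),
            "achieved_log_within_corr": achieved,
            "clamped": bool(clamped),
        }
    return table, truth


def _solve_beta(
    log_med_flat: np.ndarray,
    u: np.ndarray,
    sigma_e: float,
    rho: float,
    n_tp: int,
) -> tuple[float, bool]:
    """Solve the weight-coupling coefficient so that the *expected*
    within-subject correlation between the log marker and weight equals
    ``rho``, conditional on the realized weight trajectories.

    The expectation accounts for the configured median time-trend and for
    the per-time median recalibration (whose systematic part is the
    per-time median profile of the weight deviations scaled by beta), so
    trends neither inflate nor deflate the programmed correlation.  The
    noise realization is drawn independently afterwards, so the realized
    correlation fluctuates around the target with ordinary sampling noise.

    Because median pinning makes the expected correlation saturate as
    |beta| grows, the function is not monotone; the solver scans a signed
    grid for bracketing intervals and returns the root closest to zero (the
    least distortion of the marker's variance).  If no beta attains the
    target the best grid point is used and the marker is flagged as
    clamped."""
    n_obs = len(u)
    n_subj = n_obs // n_tp
    d0c = _subject_center(log_med_flat, n_tp)
    # systematic part of the median recalibration: per-time median of u
    ghat = np.median(u.reshape(-1, n_tp), axis=0)
    ugc = _subject_center(u - np.tile(ghat, n_subj), n_tp)
    ssu = float(u @ u)
    noise_ss = sigma_e**2 * (n_obs - n_subj)  # E sum of centered-noise squares

    def achieved(beta: float) -> float:
        vc = d0c + beta * ugc
        cov = float(vc @ u)
        var = float(vc @ vc) + noise_ss
        return cov / np.sqrt(var * ssu) if var > 0 else 0.0

    scale = sigma_e + float(np.std(d0c)) + 0.1
    mags = np.geomspace(1e-3 * scale, 40.0 * scale, 80)
    grid = np.concatenate([-mags[::-1], [0.0], mags])
    f = np.array([achieved(b) - rho for b in grid])
    roots = []
    for i in np.flatnonzero(np.sign(f[:-1]) * np.sign(f[1:]) <= 0):
        if f[i] == 0.0:
            roots.append(float(grid[i]))
        else:
            roots.append(float(brentq(lambda b: achieved(b) - rho,
                                      grid[i], grid[i + 1], xtol=1e-12)))
    if roots:
        return min(roots, key=abs), False
    best = grid[int(np.argmin(np.abs(f)))]
    return float(best), True
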