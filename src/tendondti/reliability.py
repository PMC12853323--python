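"""Reliability statistics: mixed-model ICCs, bootstrap CIs, SEM.

The intraclass correlation used throughout is the *consistency* form from
a linear mixed model

    value = intercept + rating (fixed) [+ limb type (fixed)]
            + participant (random intercept) + residual,

fit by REML, with ``ICC = σ²_participant / (σ²_participant + σ²_residual)``.
The rating factor (rater or scan session) enters the mean structure only,
so systematic offsets between ratings do not count against agreement.  On
balanced two-rating data this equals the classical two-way mean-squares
consistency ICC, ICC(C,1) = (MS_between − MS_error)/(MS_between + MS_error).

Confidence intervals resample participants with replacement (keeping all
their ratings) and take percentile bounds over successful refits.  The
standard error of measurement is SEM = SD·sqrt(1 − ICC) with SD pooled
over all observations in the stratum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

__all__ = [
    "VarianceComponents",
    "ICCResult",
    "fit_icc_lmm",
    "bootstrap_ci",
    "sem",
    "classify_icc",
    "icc_battery",
    "pooled_icc_with_limbtype",
    "outlier_sensitivity",
    "sample_size_icc",
]

_FACTOR_COLUMN = {"rater": "rater", "session": "session"}


@dataclass(frozen=True)
class VarianceComponents:
    """REML variance components and fixed effects of the ICC model."""

    sigma2_participant: float
    sigma2_residual: float
    fixed_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma2_participant < 0 or self.sigma2_residual < 0:
            raise ValueError("variance components must be non-negative")


@dataclass
class ICCResult:
    """Point estimate, bootstrap CI, SEM and qualitative class of one ICC."""

    icc: float
    ci_low: float
    ci_high: float
    n_boot: int
    sem: float
    sd_pooled: float
    classification: str
    n_subjects: int
    factor: str
    components: VarianceComponents | None = None
    n_boot_failed: int = 0
    warnings: list[str] = field(default_factory=list)


def _rating_column(table: pd.DataFrame, factor: str) -> str:
    if "rating" in table.columns:
        return "rating"
    try:
        return _FACTOR_COLUMN[factor]
    except KeyError:
        raise ValueError(f"unknown factor {factor!r}; expected 'rater' or "
                         "'session'") from None


def _validate(table: pd.DataFrame, factor: str) -> pd.DataFrame:
    col = _rating_column(table, factor)
    df = table.loc[:, ["participant_id", col, "value"]].copy()
    df.columns = ["participant_id", "rating", "value"]
    if "limb_type" in table.columns:
        df["limb_type"] = table["limb_type"].to_numpy()
    if "missing" in table.columns:
        df = df[~table["missing"].to_numpy(dtype=bool)]
    if len(df) < 2:
        raise ValueError("fewer than 2 ratings: cannot estimate an ICC")
    if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite values in the measurement table")
    multi = (df.groupby("participant_id")["rating"].nunique() >= 2).sum()
    if multi < 3:
        raise ValueError(
            "need at least 3 participants with at least 2 ratings each "
            f"(got {int(multi)})"
        )
    return df


def _design(df: pd.DataFrame, limb_type_fixed: bool):
    """Intercept + treatment-coded rating (and limb-type) dummies."""
    cols = ["rating", "limb_type"] if limb_type_fixed else ["rating"]
    names = ["intercept"]
    parts = [np.ones(len(df))]
    for c in cols:
        levels = sorted(df[c].astype(str).unique())
        for lev in levels[1:]:
            parts.append((df[c].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{c}[{lev}]")
    return np.column_stack(parts), names


def fit_icc_lmm(table: pd.DataFrame, factor: str, *,
                limb_type_fixed: bool = False, polish: bool = True):
    """REML mixed-model fit returning (VarianceComponents, icc).

    The rating factor is fixed, participants are random intercepts;
    ``limb_type_fixed=True`` adds limb type to the mean structure (the
    pooled model).  Degenerate data where the additive fixed-effect
    structure fits exactly (zero residual) short-circuits to ICC 1 when
    participants differ, avoiding a boundary REML fit.  ``polish``
    refines the REML optimum along the profiled variance ratio; bootstrap
    refits skip it for speed.
    """
    df = _validate(table, factor)
    y = df["value"].to_numpy(dtype=float)
    X, names = _design(df, limb_type_fixed)
    _, group_idx = np.unique(df["participant_id"].to_numpy(), return_inverse=True)
    return _fit_arrays(y, X, group_idx, names, polish=polish)


def _fit_arrays(y: np.ndarray, X: np.ndarray, group_idx: np.ndarray,
                names: list[str], *, polish: bool,
                warn_undefined: bool = True):
    n_groups = int(group_idx.max()) + 1
    # exact-fit degeneracy: residual of OLS on participant + fixed effects
    G = np.zeros((len(y), n_groups))
    G[np.arange(len(y)), group_idx] = 1.0
    full = np.column_stack([X, G[:, 1:]])
    beta, *_ = np.linalg.lstsq(full, y, rcond=None)
    resid = y - full @ beta
    scale = max(float(np.abs(y).max()), 1e-300)
    if np.abs(resid).max() <= 1e-10 * scale:
        adj = y - X[:, 1:] @ beta[1:len(names)] if X.shape[1] > 1 else y
        pm = np.bincount(group_idx, weights=adj) / np.bincount(group_idx)
        s2p = float(np.var(pm, ddof=1)) if len(pm) > 1 else 0.0
        fe = dict(zip(names, beta[:len(names)]))
        if s2p <= (1e-10 * scale) ** 2:
            if warn_undefined:
                warnings.warn("all observations identical: ICC is undefined",
                              stacklevel=2)
            return VarianceComponents(0.0, 0.0, fe), float("nan")
        return VarianceComponents(s2p, 0.0, fe), 1.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=group_idx)
        res = model.fit(reml=True)
        s2p = max(float(np.asarray(res.cov_re).ravel()[0]), 0.0)
        s2e = float(res.scale)
        fe = np.asarray(res.fe_params, dtype=float)
        if polish:
            s2p, s2e, fe = _polish_reml(model, X.shape[1], s2p, s2e)
    comps = VarianceComponents(s2p, s2e, dict(zip(names, fe)))
    icc = s2p / (s2p + s2e) if (s2p + s2e) > 0 else 0.0
    return comps, float(min(max(icc, 0.0), 1.0))


def _polish_reml(model: MixedLM, k_fe: int, s2p: float, s2e: float):
    """Refine the REML optimum along the profiled variance ratio.

    The one-random-intercept REML criterion is smooth in the ratio
    vr = σ²_participant/σ²_residual with the scale and fixed effects
    profiled out; a 1-D Brent refinement of statsmodels' own objective
    tightens the optimizer's default tolerance by several orders of
    magnitude (the ANOVA-equivalence property on balanced data holds to
    ~1e-8 after polishing).
    """
    from scipy.optimize import minimize_scalar

    def nll(u: float) -> float:
        pm = MixedLMParams.from_components(
            fe_params=np.zeros(k_fe), cov_re=np.array([[math.exp(u)]]))
        return -model.loglike(pm, profile_fe=True)

    u0 = math.log(max(s2p / max(s2e, 1e-300), 1e-8))
    try:
        opt = minimize_scalar(nll, bracket=(u0 - 1.0, u0, u0 + 1.0),
                              method="brent", options={"xtol": 1e-12})
    except ValueError:
        opt = minimize_scalar(nll, bounds=(math.log(1e-10), math.log(1e8)),
                              method="bounded", options={"xatol": 1e-12})
    vr = math.exp(opt.x)
    if nll(math.log(1e-12)) < opt.fun:          # boundary σ²_participant → 0
        vr = 0.0
    cov_re = np.array([[vr]])
    vcomp = np.empty(0)
    fe, _sing = model.get_fe_params(cov_re, vcomp)
    s2e = float(model.get_scale(fe, cov_re, vcomp))
    return vr * s2e, s2e, np.asarray(fe, dtype=float)


def bootstrap_ci(table: pd.DataFrame, factor: str, n_boot: int = 1000,
                 seed: int = 0, *, limb_type_fixed: bool = False,
                 alpha: float = 0.05):
    """Percentile bootstrap CI for the ICC, resampling participants.

    Each resample draws participants with replacement (keeping all their
    ratings, relabelled uniquely), refits the mixed model and records the
    ICC; the CI is the (α/2, 1−α/2) percentile pair over successful
    refits.  Returns ``(ci_low, ci_high, n_failed, warning_messages)``.
    """
    df = _validate(table, factor)
    rng = np.random.default_rng(seed)
    y_all = df["value"].to_numpy(dtype=float)
    X_all, names = _design(df, limb_type_fixed)
    pid = df["participant_id"].astype(str).to_numpy()
    ids = np.array(sorted(np.unique(pid)))
    row_idx = [np.flatnonzero(pid == p) for p in ids]
    iccs: list[float] = []
    n_failed = 0
    for _ in range(n_boot):
        draw = rng.integers(0, len(ids), size=len(ids))
        take = np.concatenate([row_idx[j] for j in draw])
        groups = np.repeat(np.arange(len(ids)),
                           [len(row_idx[j]) for j in draw])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, icc = _fit_arrays(y_all[take], X_all[take], groups, names,
                                     polish=False, warn_undefined=False)
        except Exception:
            n_failed += 1
            continue
        if math.isnan(icc):
            n_failed += 1
            continue
        iccs.append(icc)
    msgs: list[str] = []
    if not iccs:
        msgs.append("all bootstrap refits failed")
        return float("nan"), float("nan"), n_failed, msgs
    if n_failed > 0.2 * n_boot:
        msgs.append(f"{n_failed}/{n_boot} bootstrap refits failed")
    lo, hi = np.percentile(iccs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi), n_failed, msgs


def sem(sd_pooled: float, icc: float) -> float:
    """Standard error of measurement, SD·sqrt(1 − ICC)."""
    if sd_pooled < 0:
        raise ValueError("sd must be non-negative")
    if not 0 <= icc <= 1:
        raise ValueError("icc must lie in [0, 1]")
    return float(sd_pooled * math.sqrt(1.0 - icc))


def classify_icc(icc: float) -> str:
    """Qualitative agreement class.

    poor < 0.50 ≤ moderate < 0.75 ≤ good < 0.90 ≤ excellent; the bins are
    left-closed, so 0.50 is moderate, 0.75 is good, and 0.90 is excellent.
    """
    if not math.isfinite(icc):
        raise ValueError("icc must be finite")
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.90:
        return "good"
    return "excellent"


def icc_battery(table: pd.DataFrame, factor: str, *, n_boot: int = 1000,
                seed: int = 0, limb_type_fixed: bool = False) -> ICCResult:
    """Point estimate, bootstrap CI, SEM and class in one result object."""
    comps, icc = fit_icc_lmm(table, factor, limb_type_fixed=limb_type_fixed)
    lo, hi, n_failed, msgs = bootstrap_ci(
        table, factor, n_boot=n_boot, seed=seed,
        limb_type_fixed=limb_type_fixed)
    df = _validate(table, factor)
    sd_pooled = float(np.std(df["value"].to_numpy(dtype=float), ddof=1))
    return ICCResult(
        icc=icc, ci_low=lo, ci_high=hi, n_boot=n_boot,
        sem=sem(sd_pooled, icc) if math.isfinite(icc) else float("nan"),
        sd_pooled=sd_pooled,
        classification=classify_icc(icc) if math.isfinite(icc) else "undefined",
        n_subjects=int(df["participant_id"].nunique()), factor=factor,
        components=comps, n_boot_failed=n_failed, warnings=msgs,
    )


def pooled_icc_with_limbtype(table: pd.DataFrame, factor: str, *,
                             n_boot: int = 1000, seed: int = 0) -> ICCResult:
    """ICC pooled across limb types, with limb type as a fixed effect.

    With a single limb type present this falls back to the plain model
    (with a warning) — the fixed effect would be inestimable.
    """
    if "limb_type" not in table.columns or table["limb_type"].nunique() < 2:
        warnings.warn("single limb type present: falling back to the plain "
                      "ICC model", stacklevel=2)
        return icc_battery(table, factor, n_boot=n_boot, seed=seed)
    return icc_battery(table, factor, n_boot=n_boot, seed=seed,
                       limb_type_fixed=True)


def outlier_sensitivity(table: pd.DataFrame, drop_participant_id: str,
                        factor: str, *, n_boot: int = 1000, seed: int = 0,
                        limb_type_fixed: bool = False) -> ICCResult:
    """Recompute the full ICC battery with one participant removed."""
    ids = set(table["participant_id"].astype(str))
    if str(drop_participant_id) not in ids:
        raise ValueError(f"participant {drop_participant_id!r} not in table")
    if len(ids) - 1 < 3:
        raise ValueError("dropping this participant leaves fewer than 3; "
                         "the ICC model is not estimable")
    kept = table[table["participant_id"].astype(str) != str(drop_participant_id)]
    return icc_battery(kept, factor, n_boot=n_boot, seed=seed,
                       limb_type_fixed=limb_type_fixed)


def sample_size_icc(rho_null: float, rho_alt: float, k_ratings: int = 2,
                    alpha_two_sided: float = 0.05, power: float = 0.80) -> int:
    """Participants needed to distinguish ICC ρ1 from ρ0 with k ratings.

    Walter–Eliasziw–Donner approximation:

        n = ceil(1 + 2k (z_{α/2} + z_β)² / ((k − 1) (ln C₀)²)),
        C₀ = (1 + k ρ₀/(1 − ρ₀)) / (1 + k ρ₁/(1 − ρ₁)).

    With ρ₀ = 0, ρ₁ = 0.75, k = 2, two-sided α = 0.05 and power 0.80 this
    gives n = 10.
    """
    if not (0 <= rho_null < rho_alt < 1):
        raise ValueError("require 0 <= rho_null < rho_alt < 1")
    if k_ratings < 2:
        raise ValueError("need at least 2 ratings per participant")
    if not (0 < alpha_two_sided < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    z_a = stats.norm.ppf(1.0 - alpha_two_sided / 2.0)
    z_b = stats.norm.ppf(power)
    k = float(k_ratings)
    c0 = (1.0 + k * rho_null / (1.0 - rho_null)) / \
         (1.0 + k * rho_alt / (1.0 - rho_alt))
    n = 1.0 + 2.0 * k * (z_a + z_b) ** 2 / ((k - 1.0) * math.log(c0) ** 2)
    return int(math.ceil(n - 1e-12))
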