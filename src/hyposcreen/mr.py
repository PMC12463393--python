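"""Bidirectional two-sample Mendelian randomization screening.

Instruments are SNPs associated with the exposure (p < 1e-5), mutually
independent (greedy clumping at r² < 0.001 when LD information is
supplied) and strong (F = (β/se)² ≥ 10).  After harmonizing outcome
effects to the exposure effect allele, five estimators are fitted to the
per-SNP Wald ratios: inverse-variance weighting (multiplicative
random-effects), MR-Egger, weighted median, and simple/weighted mode.
A direction *passes* the screen when all five estimates share a sign
(equivalently all odds ratios are simultaneously > 1 or < 1) and the IVW
p-value is below 0.05; Cochran's Q heterogeneity and the Egger-intercept
pleiotropy test annotate but do not gate the decision.  Running both
directions classifies a trait pair as forward-only, reverse-only,
bidirectional or none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig, MRThresholds

log = logging.getLogger(__name__)

METHODS = ("IVW", "Egger", "Weighted median", "Simple mode", "Weighted mode")

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ------------------------------------------------------------ instruments
def select_instruments(
    exposure: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    cfg: MRThresholds | None = None,
) -> pd.DataFrame:
    """SNPs with exposure p below the instrument threshold, greedily
    clumped in ascending-p order against the supplied pairwise r² table.

    Without LD information SNPs are assumed independent (logged) and the
    selection reduces to the p-value filter.  May return an empty frame —
    the screen is then not estimable.
    """
    cfg = cfg or MRThresholds()
    cand = exposure[exposure["pval"] < cfg.instrument_p].sort_values(
        ["pval", "snp"], kind="mergesort"
    )
    if ld is None:
        log.info("no LD table supplied; SNPs assumed independent")
        return cand.reset_index(drop=True)
    r2: dict = {}
    for row in ld.itertuples(index=False):
        r2[frozenset((row.snp_a, row.snp_b))] = row.r2
    kept: list = []
    for row in cand.itertuples(index=False):
        if all(
            r2.get(frozenset((row.snp, k)), 0.0) < cfg.clump_r2 for k in kept
        ):
            kept.append(row.snp)
    return cand[cand["snp"].isin(kept)].reset_index(drop=True)


def compute_f(instruments: pd.DataFrame, cfg: MRThresholds | None = None) -> pd.DataFrame:
    """Attach F = (β/se)² and drop weak instruments (F strictly below the
    threshold is discarded; F exactly at it is retained)."""
    cfg = cfg or MRThresholds()
    if (instruments["se"] <= 0).any():
        bad = instruments.loc[instruments["se"] <= 0, "snp"].iloc[0]
        raise ValueError(f"non-positive se at SNP {bad!r}")
    out = instruments.copy()
    out["F"] = (out["beta"] / out["se"]) ** 2
    n_weak = int((out["F"] < cfg.min_f).sum())
    if n_weak:
        log.info("discarding %d weak instruments (F < %g)", n_weak, cfg.min_f)
    return out[out["F"] >= cfg.min_f].reset_index(drop=True)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    cfg: MRThresholds | None = None,
) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele.

    Sign-flips outcome betas when the allele pair is swapped (directly or
    on the opposite strand); drops palindromic SNPs whose effect-allele
    frequency is too close to 0.5 to orient, SNPs absent from the
    outcome, and SNPs with irreconcilable alleles (logged).
    """
    cfg = cfg or MRThresholds()
    out_by_snp = outcome.set_index("snp")
    rows = []
    for row in exposure.itertuples(index=False):
        if row.snp not in out_by_snp.index:
            log.info("SNP %s absent from outcome; dropped", row.snp)
            continue
        o = out_by_snp.loc[row.snp]
        ea, oa = row.effect_allele, row.other_allele
        pal = frozenset((ea, oa)) in _PALINDROMIC
        if pal and abs(row.eaf - 0.5) < cfg.palindromic_eaf_tol:
            log.info("palindromic SNP %s with eaf %.3f dropped", row.snp, row.eaf)
            continue
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        flip_ea, flip_oa = _COMPLEMENT.get(o_ea), _COMPLEMENT.get(o_oa)
        if (o_ea, o_oa) == (ea, oa) or (flip_ea, flip_oa) == (ea, oa):
            sign = 1.0
        elif (o_ea, o_oa) == (oa, ea) or (flip_ea, flip_oa) == (oa, ea):
            sign = -1.0
        else:
            log.info("SNP %s alleles irreconcilable (%s/%s vs %s/%s); dropped",
                     row.snp, ea, oa, o_ea, o_oa)
            continue
        rows.append(
            {"snp": row.snp, "effect_allele": ea, "other_allele": oa,
             "beta_exp": row.beta, "se_exp": row.se, "pval_exp": row.pval,
             "beta_out": sign * o["beta"], "se_out": o["se"],
             "pval_out": o["pval"], "eaf": row.eaf,
             "F": getattr(row, "F", (row.beta / row.se) ** 2)}
        )
    return pd.DataFrame(
        rows,
        columns=["snp", "effect_allele", "other_allele", "beta_exp", "se_exp",
                 "pval_exp", "beta_out", "se_out", "pval_out", "eaf", "F"],
    )


def wald_ratios(s: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP causal ratio β_out/β_exp with first-order standard error
    se_out/|β_exp|; SNPs with zero exposure beta are dropped."""
    s = s[s["beta_exp"] != 0].copy()
    s["ratio"] = s["beta_out"] / s["beta_exp"]
    s["ratio_se"] = s["se_out"] / s["beta_exp"].abs()
    return s


# -------------------------------------------------------------- estimators
@dataclass
class MRFit:
    method: str
    estimate: float
    se: float
    p: float
    n_snps: int

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))


def _norm_p(est: float, se: float) -> float:
    if se <= 0 or not np.isfinite(se):
        return float("nan")
    return float(min(2.0 * stats.norm.sf(abs(est / se)), 1.0))


def _ivw(ratio: np.ndarray, ratio_se: np.ndarray, random_effects: bool = True):
    w = 1.0 / ratio_se**2
    est = float(np.sum(w * ratio) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (ratio - est) ** 2))
    k = ratio.size
    if random_effects and k > 1:
        se *= max(1.0, np.sqrt(q / (k - 1)))
    return est, se, q


def _egger(b_exp, se_exp, b_out, se_out):
    """Weighted regression of outcome betas on exposure betas with
    intercept (weights 1/se_out²), exposure effects oriented positive.
    Returns (slope, slope_se, slope_p, intercept, intercept_se,
    intercept_p) with multiplicative random-effects scaling (sigma
    floored at 1) and t-distribution p-values on k−2 df."""
    flip = np.sign(b_exp)
    flip[flip == 0] = 1.0
    x = b_exp * flip
    y = b_out * flip
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError(
            "exposure effects have zero spread; Egger slope unidentifiable"
        )
    w = 1.0 / se_out**2
    X = np.column_stack([np.ones_like(x), x])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ coef
    k = x.size
    dof = k - 2
    sigma2 = float(np.sum(w * resid**2) / dof) if dof > 0 else np.nan
    XtWX_inv = np.linalg.inv(X.T @ (X * w[:, None]))
    base_se = np.sqrt(np.diag(XtWX_inv))
    scale = max(1.0, np.sqrt(sigma2)) if dof > 0 else np.nan
    ses = base_se * scale
    ps = [2.0 * stats.t.sf(abs(c / s), dof) if dof > 0 else np.nan
          for c, s in zip(coef, ses)]
    return coef[1], ses[1], ps[1], coef[0], ses[0], ps[0]


def _weighted_median(ratio: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratio, kind="mergesort")
    r = ratio[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def _mode_estimate(ratio: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Mode of the (weighted) kernel-smoothed ratio density with the
    modified-Silverman bandwidth phi·0.9·min(sd, mad)·k^(−1/5)."""
    k = ratio.size
    if k == 1:
        return float(ratio[0])
    sd = float(np.std(ratio, ddof=1))
    mad = float(stats.median_abs_deviation(ratio, scale="normal"))
    s = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    h = phi * 0.9 * s * k ** (-1.0 / 5.0)
    if h == 0:
        return float(np.average(ratio, weights=weights))
    lo, hi = ratio.min() - 3 * h, ratio.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = np.sum(
        weights[:, None] / weights.sum()
        * np.exp(-0.5 * ((grid[None, :] - ratio[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def _bootstrap_se(estimator, ratio, ratio_se, n_boot: int, rng) -> float:
    """Parametric bootstrap se; ``n_boot=0`` disables it (se reported as
    NaN — enough for sign-concordance screening, where only the
    estimates and the IVW p enter the decision)."""
    if n_boot == 0:
        return float("nan")
    draws = rng.normal(ratio, ratio_se, size=(n_boot, ratio.size))
    vals = np.array([estimator(row) for row in draws])
    return float(vals.std(ddof=1))


def fit_five_methods(
    s: pd.DataFrame,
    cfg: MRThresholds | None = None,
    seed: int = 0,
) -> dict:
    """Fit IVW, MR-Egger, weighted median and the two mode estimators on
    a harmonized instrument set.

    With fewer than 3 instruments only IVW and the weighted median are
    estimable (Egger and the modes need ≥ 3); with fewer than 2, nothing
    is.  Bootstrap standard errors (weighted median and modes) use the
    given seed.  Returns ``{method: MRFit}``.
    """
    cfg = cfg or MRThresholds()
    s = wald_ratios(s)
    k = len(s)
    if k < 2:
        raise ValueError("need at least 2 instruments")
    ratio = s["ratio"].to_numpy()
    ratio_se = s["ratio_se"].to_numpy()
    w = 1.0 / ratio_se**2
    rng = np.random.default_rng(seed)
    fits: dict = {}

    est, se, _q = _ivw(ratio, ratio_se)
    fits["IVW"] = MRFit("IVW", est, se, _norm_p(est, se), k)

    degenerate = np.allclose(ratio, ratio[0])
    wm = _weighted_median(ratio, w)
    wm_se = (
        0.0 if degenerate
        else _bootstrap_se(lambda r: _weighted_median(r, w), ratio, ratio_se,
                           cfg.n_boot, rng)
    )
    fits["Weighted median"] = MRFit("Weighted median", wm, wm_se, _norm_p(wm, wm_se), k)

    if k >= 3:
        try:
            slope, sse, sp, *_ = _egger(
                s["beta_exp"].to_numpy(), s["se_exp"].to_numpy(),
                s["beta_out"].to_numpy(), s["se_out"].to_numpy(),
            )
            fits["Egger"] = MRFit("Egger", float(slope), float(sse), float(sp), k)
        except np.linalg.LinAlgError as exc:
            log.warning("Egger not fitted: %s", exc)
        phi = cfg.mode_bandwidth_factor
        ones = np.ones(k)
        sm = _mode_estimate(ratio, ones, phi)
        wmod = _mode_estimate(ratio, w, phi)
        sm_se = 0.0 if degenerate else _bootstrap_se(
            lambda r: _mode_estimate(r, ones, phi), ratio, ratio_se, cfg.n_boot, rng
        )
        wmod_se = 0.0 if degenerate else _bootstrap_se(
            lambda r: _mode_estimate(r, w, phi), ratio, ratio_se, cfg.n_boot, rng
        )
        fits["Simple mode"] = MRFit("Simple mode", sm, sm_se, _norm_p(sm, sm_se), k)
        fits["Weighted mode"] = MRFit("Weighted mode", wmod, wmod_se,
                                      _norm_p(wmod, wmod_se), k)
    else:
        log.info("only %d instruments: Egger and mode estimators not fitted", k)
    # degenerate agreement: every estimator returns the common ratio with p=0 convention
    if degenerate:
        for f in fits.values():
            if f.se == 0:
                f.p = 0.0 if f.estimate != 0 else 1.0
    return fits


def heterogeneity_q(s: pd.DataFrame) -> dict:
    """Cochran's Q of the Wald ratios about the (fixed-effect) IVW mean,
    with k−1 df and its chi-square p-value."""
    s = wald_ratios(s)
    if len(s) < 2:
        raise ValueError("need at least 2 instruments")
    ratio = s["ratio"].to_numpy()
    ratio_se = s["ratio_se"].to_numpy()
    est, _se, q = _ivw(ratio, ratio_se, random_effects=False)
    df = len(s) - 1
    return {"Q": q, "df": df, "p": float(stats.chi2.sf(q, df))}


def egger_intercept(s: pd.DataFrame) -> dict:
    """MR-Egger intercept (directional pleiotropy test)."""
    s = wald_ratios(s)
    if len(s) < 3:
        raise ValueError("Egger needs at least 3 instruments")
    *_, ic, ic_se, ic_p = _egger(
        s["beta_exp"].to_numpy(), s["se_exp"].to_numpy(),
        s["beta_out"].to_numpy(), s["se_out"].to_numpy(),
    )
    return {"intercept": float(ic), "se": float(ic_se), "p": float(ic_p)}


# ---------------------------------------------------------------- screen
@dataclass
class MRScreenResult:
    exposure: str
    outcome: str
    direction: str                     # "forward" | "reverse"
    estimable: bool
    concordant: bool = False
    ivw_p: float = float("nan")
    ivw_estimate: float = float("nan")
    passed: bool = False
    heterogeneity: bool = False
    pleiotropy: bool = False
    reason: str = ""
    fits: dict = field(default_factory=dict)


def apply_screen_rule(fits: dict, cfg: MRThresholds | None = None) -> tuple:
    """The concordance pass rule on a full set of five fits: returns
    (concordant, ivw_p, passed).  Concordance means all five estimates
    share one sign — equivalently every odds ratio is on the same side
    of 1; a zero estimate breaks concordance."""
    cfg = cfg or MRThresholds()
    signs = np.sign([f.estimate for f in fits.values()])
    concordant = bool(np.all(signs > 0) or np.all(signs < 0))
    ivw_p = fits["IVW"].p
    return concordant, ivw_p, bool(concordant and ivw_p < cfg.ivw_p)


def screen(
    s: pd.DataFrame,
    exposure: str = "exposure",
    outcome: str = "outcome",
    direction: str = "forward",
    cfg: MRThresholds | None = None,
    seed: int = 0,
) -> MRScreenResult:
    """Apply the concordance screening rule to one direction.

    Pass ⇔ the five estimates all share one sign (all odds ratios > 1 or
    all < 1) *and* IVW p < 0.05.  Heterogeneity (Q p < 0.05) and
    pleiotropy (Egger intercept p < 0.05) flags annotate the result but
    never gate it.  Fewer than 5 estimable methods fails with reason
    "insufficient instruments".
    """
    cfg = cfg or MRThresholds()
    res = MRScreenResult(exposure, outcome, direction, estimable=False)
    s = wald_ratios(s)
    if len(s) < 3:
        res.reason = "insufficient instruments"
        return res
    fits = fit_five_methods(s, cfg, seed=seed)
    res.fits = fits
    if len(fits) < 5:
        res.reason = "insufficient instruments"
        return res
    res.estimable = True
    res.concordant, res.ivw_p, res.passed = apply_screen_rule(fits, cfg)
    res.ivw_estimate = fits["IVW"].estimate
    het = heterogeneity_q(s)
    res.heterogeneity = bool(het["p"] < 0.05)
    ple = egger_intercept(s)
    res.pleiotropy = bool(ple["p"] < 0.05)
    if not res.passed:
        res.reason = "discordant signs" if not res.concordant else "IVW not significant"
    return res


def bidirectional_classify(forward: MRScreenResult, reverse: MRScreenResult) -> str:
    """Combine the two directions: forward-only, reverse-only,
    bidirectional, or none."""
    f, r = forward.passed, reverse.passed
    if f and r:
        return "bidirectional"
    if f:
        return "forward-only"
    if r:
        return "reverse-only"
    return "none"


# ------------------------------------------------------------- pipeline
def run_mr(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    ld: pd.DataFrame | None = None,
    cfg: AnalysisConfig | None = None,
    bidirectional: bool = True,
) -> dict:
    """End-to-end screen of one trait pair.

    Forward: instruments from the exposure table, effects read off the
    outcome.  Reverse (optional): roles swapped.  Returns the screen
    results per direction, the bidirectional class, and the harmonized
    instrument sets.
    """
    cfg = cfg or AnalysisConfig()

    def one_direction(exp_df, out_df, exp_name, out_name, direction):
        inst = select_instruments(exp_df, ld, cfg.mr)
        if inst.empty:
            res = MRScreenResult(exp_name, out_name, direction, estimable=False,
                                 reason="no instruments passed selection")
            return res, pd.DataFrame()
        inst = compute_f(inst, cfg.mr)
        if inst.empty:
            res = MRScreenResult(exp_name, out_name, direction, estimable=False,
                                 reason="all instruments weak (F below threshold)")
            return res, pd.DataFrame()
        harm = harmonize(inst, out_df, cfg.mr)
        if harm.empty:
            res = MRScreenResult(exp_name, out_name, direction, estimable=False,
                                 reason="no harmonizable instruments")
            return res, harm
        return screen(harm, exp_name, out_name, direction, cfg.mr, seed=cfg.seed), harm

    fwd, fwd_harm = one_direction(exposure, outcome, exposure_name, outcome_name, "forward")
    result = {"forward": fwd, "forward_instruments": fwd_harm}
    if bidirectional:
        rev, rev_harm = one_direction(outcome, exposure, outcome_name, exposure_name, "reverse")
        result["reverse"] = rev
        result["reverse_instruments"] = rev_harm
        result["class"] = bidirectional_classify(fwd, rev)
    return result
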