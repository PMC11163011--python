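"""Behavioral statistics: intelligibility/quality mixed models, estimated
marginal means, pairwise contrasts, and stepwise AIC over demographics.

The data layout mirrors a within-participant listening experiment: each
participant contributes one percent-correct score per masker x SNR x
processing cell (plus a quiet reference) and quality ratings for a subset of
conditions, with participant-level demographics.  Percent-correct scores are
modeled on the raw % scale with a participant random intercept:

    percent_correct ~ processing + snr + masker + processing:masker + (1 | participant)

and quality as ``quality ~ processing * masker + (1 | participant)``.

EMMs are model predictions on a balanced reference grid with delta-method
standard errors from the fixed-effect covariance; the identity
"balanced-design EMM = cell mean" holds exactly when the fitted model is
saturated in the grid factors.  Inferential denominator degrees of freedom
use a containment-style rule, n_obs - n_participants (a Satterthwaite
approximation is deliberately not attempted; see docs/methods.md).

A seeded generator (:func:`simulate_behavioral`) produces score tables from
specified cell means with participant random intercepts, so every routine is
testable without access to any deposited dataset.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats as scs
import statsmodels.formula.api as smf

from .types import InvalidArgumentError, require

__all__ = [
    "DEFAULT_CELL_MEANS",
    "DEFAULT_QUIET_MEAN",
    "DEFAULT_QUALITY_MEANS",
    "simulate_behavioral",
    "FittedLMM",
    "fit_intelligibility_model",
    "fit_quality_model",
    "emm",
    "pairwise_contrasts",
    "improvement_table",
    "stepwise_aic",
]

MASKERS = ("ccitt", "ttb")
SNRS_DB = (5.0, 10.0)
PROCESSINGS = ("unprocessed", "rnn", "sepformer")

#: Default intelligibility cell means (percent correct) for the 12 noise
#: cells, matching the magnitudes reported for adult CI users on sentence
#: recognition: mid-50s overall, a ~15-point SNR effect, and algorithm gains
#: of roughly 12-21 points that are largest in two-talker babble.
DEFAULT_CELL_MEANS: dict = {
    ("ccitt", 5.0, "unprocessed"): 42.1,
    ("ccitt", 5.0, "rnn"): 54.0,
    ("ccitt", 5.0, "sepformer"): 63.0,
    ("ccitt", 10.0, "unprocessed"): 57.3,
    ("ccitt", 10.0, "rnn"): 69.3,
    ("ccitt", 10.0, "sepformer"): 78.2,
    ("ttb", 5.0, "unprocessed"): 33.1,
    ("ttb", 5.0, "rnn"): 53.8,
    ("ttb", 5.0, "sepformer"): 59.5,
    ("ttb", 10.0, "unprocessed"): 48.3,
    ("ttb", 10.0, "rnn"): 69.0,
    ("ttb", 10.0, "sepformer"): 74.7,
}

#: Quiet-condition mean (percent correct), in the range CI users score on
#: sentences without masking.
DEFAULT_QUIET_MEAN = 79.8

#: Default quality (MOS 1-5) means per processing x masker cell.
DEFAULT_QUALITY_MEANS: dict = {
    ("quiet", "ccitt"): 4.20, ("quiet", "ttb"): 4.20,
    ("rnn", "ccitt"): 4.17, ("rnn", "ttb"): 3.78,
    ("sepformer", "ccitt"): 4.36, ("sepformer", "ttb"): 4.31,
}

#: Default variance components (percent-correct scale): chosen so the
#: implied EMM standard error at 13 participants is ~5.3 points.
DEFAULT_SD_PARTICIPANT = 15.0
DEFAULT_SD_RESIDUAL = 12.0

STRATEGIES = ("FS4", "FS4-p", "FSP")


@dataclass(frozen=True)
class BehavioralRecord:
    """One score row; ``percent_correct`` or ``quality`` may be absent (NaN)."""

    participant: str
    masker: str  # 'ccitt', 'ttb', or 'none'
    snr_db: float  # NaN when not applicable
    processing: str  # 'unprocessed', 'rnn', 'sepformer', 'quiet'
    percent_correct: float = np.nan
    quality: float = np.nan
    gender: str = "F"
    age_at_test: float = np.nan
    age_at_onset: float = np.nan
    duration_ci: float = np.nan
    n_electrodes: int = 12
    strategy: str = "FS4"


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([vars(r) if not isinstance(r, dict) else r for r in records])


def simulate_behavioral(
    n_participants: int = 13,
    cell_means: Mapping | None = None,
    quiet_mean: float = DEFAULT_QUIET_MEAN,
    quality_means: Mapping | None = None,
    sd_participant: float = DEFAULT_SD_PARTICIPANT,
    sd_residual: float = DEFAULT_SD_RESIDUAL,
    sd_participant_quality: float = 0.45,
    sd_residual_quality: float = 0.35,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a behavioral score table with participant random intercepts.

    score(p, cell) = cell_mean + b_p + eps, with b_p ~ N(0, sd_participant^2)
    and eps ~ N(0, sd_residual^2), truncated to [0, 100] (quality to [1, 5]).
    One intelligibility record per participant per noise cell plus quiet, and
    one quality record per participant per quality cell.  Fully seeded.
    """
    require(n_participants >= 1, "need at least one participant")
    cell_means = dict(cell_means) if cell_means is not None else dict(DEFAULT_CELL_MEANS)
    quality_means = (
        dict(quality_means) if quality_means is not None else dict(DEFAULT_QUALITY_MEANS)
    )
    expected = {
        (m, s, p) for m in MASKERS for s in SNRS_DB for p in PROCESSINGS
    }
    missing = expected - set(cell_means)
    if missing:
        raise InvalidArgumentError(f"missing cells in cell_means: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        pid = f"P{i:03d}"
        b = rng.normal(0.0, sd_participant)
        b_q = rng.normal(0.0, sd_participant_quality)
        demo = {
            "gender": "M" if rng.random() < 7 / 13 else "F",
            "age_at_test": float(np.clip(rng.normal(58.6, 14.7), 20, 85)),
            "age_at_onset": float(np.clip(rng.normal(25.0, 18.0), 0, 70)),
            "duration_ci": float(np.clip(rng.normal(78.0, 60.0), 6, 300)),
            "n_electrodes": int(rng.integers(8, 13)),
            "strategy": STRATEGIES[int(rng.integers(0, len(STRATEGIES)))],
        }
        for (m, s, p), mu in sorted(cell_means.items()):
            score = np.clip(mu + b + rng.normal(0.0, sd_residual), 0.0, 100.0)
            rows.append(
                dict(participant=pid, masker=m, snr_db=s, processing=p,
                     percent_correct=float(score), quality=np.nan, **demo)
            )
        quiet = np.clip(quiet_mean + b + rng.normal(0.0, sd_residual), 0.0, 100.0)
        rows.append(
            dict(participant=pid, masker="none", snr_db=np.nan, processing="quiet",
                 percent_correct=float(quiet), quality=np.nan, **demo)
        )
        for (p, m), mu in sorted(quality_means.items()):
            q = np.clip(mu + b_q + rng.normal(0.0, sd_residual_quality), 1.0, 5.0)
            rows.append(
                dict(participant=pid, masker=m, snr_db=np.nan, processing=p,
                     percent_correct=np.nan, quality=float(q), **demo)
            )
    return pd.DataFrame(rows)


INTELLIGIBILITY_FORMULA = (
    "percent_correct ~ C(processing, Sum) + C(snr_db, Sum) + C(masker, Sum)"
    " + C(processing, Sum):C(masker, Sum)"
)
SATURATED_INTELLIGIBILITY_FORMULA = (
    "percent_correct ~ C(processing, Sum) * C(masker, Sum) * C(snr_db, Sum)"
)
QUALITY_FORMULA = "quality ~ C(processing, Sum) * C(masker, Sum)"


@dataclass
class FittedLMM:
    """A fitted linear mixed model with its Type-III Wald F table."""

    result: object  # statsmodels MixedLMResults
    formula: str
    data: pd.DataFrame
    response: str

    @property
    def ddf(self) -> int:
        """Containment-style denominator df for within-participant inference
        (contrasts, Type-III F): n_obs - n_participants."""
        return int(len(self.data) - self.data["participant"].nunique())

    @property
    def ddf_between(self) -> int:
        """df for between-participant quantities such as EMMs, whose variance
        is dominated by the participant-intercept component: n_participants - 1."""
        return int(self.data["participant"].nunique() - 1)

    @property
    def fixed_effects(self) -> pd.Series:
        return self.result.fe_params

    @property
    def variance_components(self) -> dict:
        return {
            "participant_var": float(np.asarray(self.result.cov_re).ravel()[0]),
            "residual_var": float(self.result.scale),
        }

    def type_iii_table(self) -> pd.DataFrame:
        """Joint Wald F test per model term (sum-coded, so marginal/Type III)."""
        res = self.result
        names = list(res.fe_params.index)
        V = np.asarray(res.cov_params())[: len(names), : len(names)]
        beta = np.asarray(res.fe_params)
        design_info = res.model.data.design_info
        rows = []
        for term, sl in design_info.term_name_slices.items():
            if term == "Intercept":
                continue
            idx = list(range(sl.start, sl.stop))
            L = np.zeros((len(idx), len(names)))
            for r, c in enumerate(idx):
                L[r, c] = 1.0
            lb = L @ beta
            w = float(lb @ np.linalg.solve(L @ V @ L.T, lb))
            q = len(idx)
            f = w / q
            p = float(scs.f.sf(f, q, self.ddf))
            rows.append({"term": term, "df_num": q, "df_den": self.ddf,
                         "F": f, "p_value": p})
        return pd.DataFrame(rows)

    def predict_fixed(self, newdata: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Fixed-effect predictions and delta-method SEs for new factor rows."""
        design_info = self.result.model.data.design_info
        X = np.asarray(patsy.build_design_matrices([design_info], newdata)[0])
        beta = np.asarray(self.result.fe_params)
        V = np.asarray(self.result.cov_params())[: len(beta), : len(beta)]
        pred = X @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, V, X))
        return pred, se


def _robust_fit(model, reml: bool):
    """Fit a MixedLM, falling back to a gradient-free optimizer when the
    variance estimate hits the zero boundary (where the score blows up)."""
    try:
        return model.fit(reml=reml)
    except np.linalg.LinAlgError:
        pass
    try:
        return model.fit(reml=reml, method="powell", maxiter=2000)
    except np.linalg.LinAlgError as exc:
        raise InvalidArgumentError(f"singular design: {exc}") from exc


def _fit_lmm(data: pd.DataFrame, formula: str, response: str) -> FittedLMM:
    require(data["participant"].nunique() >= 2, "need at least 2 participants")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data["participant"])
        result = _robust_fit(model, reml=True)
    return FittedLMM(result=result, formula=formula, data=data, response=response)


def fit_intelligibility_model(records, formula: str = INTELLIGIBILITY_FORMULA) -> FittedLMM:
    """REML mixed model of percent correct over the noise cells.

    Quiet rows are excluded (their masker/SNR factors are undefined).
    """
    df = _as_frame(records)
    df = df[df["percent_correct"].notna() & (df["processing"] != "quiet")].copy()
    if df.empty:
        raise InvalidArgumentError("no intelligibility records in noise cells")
    return _fit_lmm(df, formula, "percent_correct")


def fit_quality_model(records, formula: str = QUALITY_FORMULA) -> FittedLMM:
    """REML mixed model of quality ratings (quiet included as a level)."""
    df = _as_frame(records)
    df = df[df["quality"].notna()].copy()
    if df.empty:
        raise InvalidArgumentError("no quality records")
    return _fit_lmm(df, formula, "quality")


def emm(fitted: FittedLMM, grid: pd.DataFrame | None = None,
        level: float = 0.95) -> pd.DataFrame:
    """Estimated marginal means over a balanced reference grid.

    ``grid`` rows name focal-factor combinations (columns must be model
    factors); missing model factors are averaged over a balanced set of
    their observed levels.  SEs by the delta method on the fixed-effect
    covariance; CIs at ``level`` using t with the containment ddf.
    """
    data = fitted.data
    factor_cols = [c for c in ("processing", "masker", "snr_db") if c in fitted.formula]
    if grid is None:
        combos = sorted(set(map(tuple, data[factor_cols].itertuples(index=False))))
        grid = pd.DataFrame(combos, columns=factor_cols)
    missing = [c for c in grid.columns if c not in factor_cols]
    if missing:
        raise InvalidArgumentError(f"factors absent from the model: {missing}")
    rows = []
    tcrit = scs.t.ppf(0.5 + level / 2.0, fitted.ddf_between)
    averaged = [c for c in factor_cols if c not in grid.columns]
    for _, focal in grid.iterrows():
        if averaged:
            levels = [sorted(data[c].unique()) for c in averaged]
            ref = pd.DataFrame(
                [dict(zip(averaged, combo), **focal.to_dict())
                 for combo in itertools.product(*levels)]
            )
        else:
            ref = pd.DataFrame([focal.to_dict()])
        for lvl_col in factor_cols:  # factor levels absent -> error
            bad = set(ref[lvl_col]) - set(data[lvl_col])
            if bad:
                raise InvalidArgumentError(
                    f"level(s) {sorted(bad)} of {lvl_col!r} absent from the fit"
                )
        preds, _ = fitted.predict_fixed(ref)
        # SE of the average prediction: average the design rows first
        design_info = fitted.result.model.data.design_info
        X = np.asarray(patsy.build_design_matrices([design_info], ref)[0])
        xbar = X.mean(axis=0)
        beta = np.asarray(fitted.result.fe_params)
        V = np.asarray(fitted.result.cov_params())[: len(beta), : len(beta)]
        se = float(np.sqrt(xbar @ V @ xbar))
        mean = float(xbar @ beta)
        row = focal.to_dict()
        row.update(emm=mean, se=se, ci_lo=mean - tcrit * se, ci_hi=mean + tcrit * se)
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_contrasts(
    fitted: FittedLMM,
    factor: str = "processing",
    strata: Sequence[str] = ("masker", "snr_db"),
    adjust: str = "tukey",
) -> pd.DataFrame:
    """All pairwise EMM differences of ``factor`` within each stratum.

    p-values use the fixed-effect covariance with a Tukey (studentized
    range) family adjustment by default; 'none' and 'bh' are available.
    """
    data = fitted.data
    strata = [s for s in strata if s in fitted.formula]
    levels = sorted(data[factor].unique())
    k = len(levels)
    require(k >= 2, "need at least two factor levels")
    design_info = fitted.result.model.data.design_info
    beta = np.asarray(fitted.result.fe_params)
    V = np.asarray(fitted.result.cov_params())[: len(beta), : len(beta)]
    strat_combos = (
        sorted(set(map(tuple, data[strata].itertuples(index=False))))
        if strata else [()]
    )
    rows = []
    for combo in strat_combos:
        base = dict(zip(strata, combo))
        for i in range(k):
            for j in range(i + 1, k):
                ra = pd.DataFrame([dict(base, **{factor: levels[i]})])
                rb = pd.DataFrame([dict(base, **{factor: levels[j]})])
                xa = np.asarray(patsy.build_design_matrices([design_info], ra)[0])[0]
                xb = np.asarray(patsy.build_design_matrices([design_info], rb)[0])[0]
                c = xa - xb
                diff = float(c @ beta)
                se = float(np.sqrt(c @ V @ c))
                t = diff / se
                if adjust == "tukey":
                    p = float(scs.studentized_range.sf(abs(t) * np.sqrt(2.0), k,
                                                       fitted.ddf))
                else:
                    p = float(2.0 * scs.t.sf(abs(t), fitted.ddf))
                rows.append(dict(base, level_a=levels[i], level_b=levels[j],
                                 diff=diff, se=se, t=t, p_value=p))
    out = pd.DataFrame(rows)
    if adjust == "bh" and not out.empty:
        from .evalgrid import fdr_adjust

        out["p_value"] = fdr_adjust(out["p_value"])
    return out


def improvement_table(records) -> pd.DataFrame:
    """Per participant x masker x SNR x algorithm change in percent correct
    relative to the unprocessed condition."""
    df = _as_frame(records)
    df = df[df["percent_correct"].notna() & (df["processing"] != "quiet")]
    demo_cols = ["gender", "age_at_test", "age_at_onset", "duration_ci",
                 "n_electrodes", "strategy"]
    demo_cols = [c for c in demo_cols if c in df.columns]
    base = df[df["processing"] == "unprocessed"].set_index(
        ["participant", "masker", "snr_db"]
    )["percent_correct"]
    rows = []
    for _, r in df[df["processing"] != "unprocessed"].iterrows():
        key = (r["participant"], r["masker"], r["snr_db"])
        rows.append(
            dict(participant=r["participant"], masker=r["masker"],
                 snr_db=r["snr_db"], algorithm=r["processing"],
                 delta=float(r["percent_correct"] - base.loc[key]),
                 **{c: r[c] for c in demo_cols})
        )
    return pd.DataFrame(rows)


def _ml_aic(data: pd.DataFrame, terms: Sequence[str]) -> float:
    rhs = " + ".join(terms) if terms else "1"
    formula = f"delta ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data["participant"])
        result = _robust_fit(model, reml=False)
    k = len(result.fe_params) + 2  # + random-intercept variance + residual
    return float(-2.0 * result.llf + 2.0 * k)


DEFAULT_DEMOGRAPHIC_TERMS = (
    "gender", "age_at_test", "age_at_onset", "duration_ci",
    "n_electrodes", "strategy",
)


def stepwise_aic(
    records_with_deltas: pd.DataFrame,
    demographic_factors: Sequence[str] = DEFAULT_DEMOGRAPHIC_TERMS,
    base_terms: Sequence[str] = ("masker", "algorithm"),
) -> dict:
    """Bidirectional stepwise AIC search over demographic terms.

    The response is the improvement over unprocessed (``delta``); the search
    starts from the full model (base + demographics), repeatedly applying the
    single add/drop move that lowers AIC most; the participant random
    intercept is retained throughout and all fits use maximum likelihood.

    Returns {"selected_terms", "aic", "trace"} where the trace lists
    (terms, aic) along accepted steps (non-increasing by construction).
    """
    data = records_with_deltas.copy()
    require("delta" in data.columns, "expected an improvement table with 'delta'")
    base = list(base_terms)
    candidates = list(demographic_factors)
    current = base + candidates  # full model
    current_aic = _ml_aic(data, current)
    trace = [(tuple(current), current_aic)]
    while True:
        moves = []
        for term in candidates:
            if term in current:
                moves.append([t for t in current if t != term])
            else:
                moves.append(current + [term])
        best_terms, best_aic = None, current_aic
        for terms in moves:
            aic = _ml_aic(data, terms)
            if aic < best_aic - 1e-9:
                best_terms, best_aic = terms, aic
        if best_terms is None:
            break
        current, current_aic = best_terms, best_aic
        trace.append((tuple(current), current_aic))
    return {"selected_terms": tuple(current), "aic": current_aic, "trace": trace}
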