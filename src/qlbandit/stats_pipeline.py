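"""Group-level inference and end-to-end pipeline orchestration.

The animal is always the statistical unit: session-level measures are
averaged within animal before any test.  The central design is a 2 x 2 mixed
ANOVA — mouse line (between subjects) x drug (within subjects) — whose
line x drug interaction carries the double-dissociation logic: inactivation
is expected to lower the action-selection gain beta in one line and the
learning rate alpha in the other.

With two within-subject levels the mixed ANOVA reduces exactly to two
orthogonal one-way problems: the between effect is an ANOVA on subject
means, and the drug and interaction effects are tests on within-subject
difference scores.  That closed form (Type III, unweighted group means for
the unbalanced 20/19 design) is implemented directly in numpy so that the
100-permutation control — eight ANOVAs per permutation — stays cheap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .behavior_analysis import (
    MEASURES,
    animal_measure_table,
    exclude_duration_outliers,
    match_durations,
    qvalue_block_profile,
)
from .core_io import Session, SessionSet
from .fitting import FitConfig, fit_cohort
from .rl_models import MODELS
from .synthetic_data import CohortConfig, DurationModel, TabTaskConfig, generate_cohort

__all__ = [
    "AnovaResult",
    "Comparison",
    "PermutationResult",
    "RecoveryReport",
    "mixed_anova_2x2",
    "between_anova_2x3",
    "bonferroni_posthoc",
    "permutation_interaction_count",
    "parameter_fit_table",
    "CohortAnalysis",
    "analyze_cohort",
    "paired_sign_test",
    "run_pipeline",
    "recovery_simulation",
    "parameter_recovery_experiment",
]


@dataclass
class AnovaResult:
    """F-table of one ANOVA; ``effects`` maps effect name to a row dict with
    ss, df1, df2, F, p."""

    design: str
    effects: dict[str, dict[str, float]]

    def p(self, effect: str) -> float:
        return self.effects[effect]["p"]

    def F(self, effect: str) -> float:
        return self.effects[effect]["F"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.effects, orient="index")


def _f_p(ss: float, df1: int, rss: float, df2: int) -> tuple[float, float]:
    if df2 <= 0 or rss <= 0:
        return float("nan"), float("nan")
    f = (ss / df1) / (rss / df2)
    return float(f), float(sps.f.sf(f, df1, df2))


def mixed_anova_2x2(
    table: pd.DataFrame,
    dv: str = "value",
    between: str = "line",
    within: str = "treatment",
    subject: str = "mouse_id",
    within_order: tuple[str, str] = ("DMSO", "CNO"),
) -> AnovaResult:
    """Two-way mixed-design ANOVA: one between factor (2 levels), one
    within factor (2 levels).

    Expects one value per subject per within level.  Returns effects
    ``between``, ``within`` and ``interaction``, each on df (1, n - 2).
    Degenerate inputs (zero error variance) yield NaN F rather than raising.
    """
    wide = table.pivot_table(
        index=[subject, between], columns=within, values=dv, aggfunc="first"
    )
    for lev in within_order:
        if lev not in wide.columns:
            raise ValueError(f"missing within level {lev!r}")
    incomplete = wide[list(within_order)].isna().any(axis=1)
    if incomplete.any():
        bad = [idx[0] for idx in wide.index[incomplete]]
        raise ValueError(f"missing within-subject cell for animal(s): {bad}")
    groups = wide.index.get_level_values(between)
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"between factor must have 2 levels, got {levels}")
    g = np.asarray(groups == levels[0])
    y1 = wide[within_order[0]].to_numpy(float)
    y2 = wide[within_order[1]].to_numpy(float)
    s = (y1 + y2) / 2.0  # subject means
    d = y2 - y1  # within-subject difference scores
    n = s.shape[0]

    def one_way(y):
        """Classical one-way decomposition over the two groups."""
        grand = y.mean()
        ss_total_mean = y.shape[0] * grand**2
        ss_groups = sum(
            y[m].shape[0] * (y[m].mean() - grand) ** 2 for m in (g, ~g)
        )
        rss = sum(float(((y[m] - y[m].mean()) ** 2).sum()) for m in (g, ~g))
        return ss_total_mean, ss_groups, rss

    _, ss_s_groups, rss_s = one_way(s)
    ss_d_mean, ss_d_groups, rss_d = one_way(d)

    # convert to sums of squares on the original response scale:
    # subject-mean SS scale by the 2 within levels; difference-score SS halve
    ss_between = 2.0 * ss_s_groups
    ss_err_between = 2.0 * rss_s
    ss_within = ss_d_mean / 2.0
    ss_inter = ss_d_groups / 2.0
    ss_err_within = rss_d / 2.0
    df2 = n - 2

    effects = {}
    for name, ss, rss in (
        ("between", ss_between, ss_err_between),
        ("within", ss_within, ss_err_within),
        ("interaction", ss_inter, ss_err_within),
    ):
        f, p = _f_p(ss, 1, rss, df2)
        effects[name] = {"ss": float(ss), "df1": 1, "df2": df2, "F": f, "p": p}
    return AnovaResult(design="mixed 2x2", effects=effects)


def between_anova_2x3(
    table: pd.DataFrame,
    dv: str = "value",
    factor_a: str = "line",
    factor_b: str = "group",
) -> AnovaResult:
    """Two-way between-groups factorial ANOVA with Type-II sums of squares
    (robust to the mildly unbalanced cells of real cohorts)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.rename(columns={dv: "_y", factor_a: "_a", factor_b: "_b"})
    for col in ("_a", "_b"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col} needs >= 2 levels")
    counts = df.groupby(["_a", "_b"]).size()
    if (counts < 1).any() or len(counts) < df["_a"].nunique() * df["_b"].nunique():
        raise ValueError("empty cell in the factorial design")
    fit = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    resid_df = float(aov.loc["Residual", "df"])
    resid_ss = float(aov.loc["Residual", "sum_sq"])
    mapping = {
        "C(_a)": factor_a,
        "C(_b)": factor_b,
        "C(_a):C(_b)": "interaction",
    }
    effects = {}
    for row, name in mapping.items():
        effects[name] = {
            "ss": float(aov.loc[row, "sum_sq"]),
            "df1": int(aov.loc[row, "df"]),
            "df2": int(resid_df),
            "F": float(aov.loc[row, "F"]),
            "p": float(aov.loc[row, "PR(>F)"]),
        }
    effects["residual"] = {
        "ss": resid_ss,
        "df1": int(resid_df),
        "df2": int(resid_df),
        "F": float("nan"),
        "p": float("nan"),
    }
    return AnovaResult(design="between 2x3", effects=effects)


@dataclass(frozen=True)
class Comparison:
    """One post-hoc contrast: rows matching ``a`` vs rows matching ``b``.

    ``paired_by`` names the column to pair on (e.g. mouse_id for a
    within-animal drug contrast); None gives an unpaired test.
    """

    name: str
    a: Mapping[str, object]
    b: Mapping[str, object]
    paired_by: str | None = None


def _select(table: pd.DataFrame, flt: Mapping[str, object]) -> pd.DataFrame:
    m = pd.Series(True, index=table.index)
    for col, val in flt.items():
        m &= table[col] == val
    return table[m]


def _t_p(x: np.ndarray, y: np.ndarray, paired: bool) -> tuple[float, float]:
    if paired:
        diff = x - y
        if np.allclose(diff.std(ddof=1), 0.0):
            return (0.0, 1.0) if np.allclose(diff.mean(), 0.0) else (np.inf, 0.0)
        t, p = sps.ttest_rel(x, y)
    else:
        if np.allclose(np.std(x, ddof=1), 0) and np.allclose(np.std(y, ddof=1), 0):
            return (0.0, 1.0) if np.allclose(x.mean(), y.mean()) else (np.inf, 0.0)
        t, p = sps.ttest_ind(x, y)
    return float(t), float(p)


def bonferroni_posthoc(
    table: pd.DataFrame,
    comparisons: Sequence[Comparison],
    dv: str = "value",
) -> pd.DataFrame:
    """Pairwise post-hoc tests with Bonferroni correction.

    Raw p-values are multiplied by the family size (the number of
    comparisons passed in) and capped at 1.  Cells with fewer than 2
    observations skip the comparison with a warning.
    """
    m = len(comparisons)
    rows = []
    for cmp_ in comparisons:
        a = _select(table, cmp_.a)
        b = _select(table, cmp_.b)
        if cmp_.paired_by is not None:
            merged = a.merge(b, on=cmp_.paired_by, suffixes=("_a", "_b"))
            xa = merged[f"{dv}_a"].to_numpy(float)
            xb = merged[f"{dv}_b"].to_numpy(float)
        else:
            xa = a[dv].to_numpy(float)
            xb = b[dv].to_numpy(float)
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(
                f"comparison {cmp_.name!r} skipped: fewer than 2 observations",
                stacklevel=2,
            )
            rows.append(
                {
                    "name": cmp_.name,
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "mean_a": np.nan,
                    "mean_b": np.nan,
                    "t": np.nan,
                    "p_raw": np.nan,
                    "p_corrected": np.nan,
                    "skipped": True,
                }
            )
            continue
        t, p = _t_p(xa, xb, cmp_.paired_by is not None)
        rows.append(
            {
                "name": cmp_.name,
                "n_a": len(xa),
                "n_b": len(xb),
                "mean_a": float(np.mean(xa)),
                "mean_b": float(np.mean(xb)),
                "t": t,
                "p_raw": p,
                "p_corrected": min(1.0, m * p),
                "skipped": False,
            }
        )
    return pd.DataFrame(rows)


def drug_contrasts_by_line(measure_filter: Mapping[str, object] | None = None):
    """The standard post-hoc family: CNO vs DMSO within each line (m = 2)."""
    extra = dict(measure_filter or {})
    return [
        Comparison(
            name=f"CNO-vs-DMSO:{line}",
            a={"line": line, "treatment": "CNO", **extra},
            b={"line": line, "treatment": "DMSO", **extra},
            paired_by="mouse_id",
        )
        for line in ("D1R", "D2R")
    ]


@dataclass
class PermutationResult:
    observed_count: int
    counts: np.ndarray
    n_perm: int
    alpha: float

    def n_with_at_least(self, k: int = 3) -> int:
        return int(np.sum(self.counts >= k))


def permutation_interaction_count(
    table: pd.DataFrame,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
    measures: Sequence[str] = MEASURES,
    scopes: Sequence[str] = ("dynamic", "steady"),
) -> PermutationResult:
    """Chance control for multiple significant interactions.

    Animals are randomly reassigned to two pseudo-lines (original group
    sizes preserved, sampling without replacement); the eight mixed ANOVAs
    (4 measures x 2 states) are rerun per permutation and the number of
    significant line x drug interactions counted.  Returns the count
    distribution, the observed (true-label) count, and — via
    :meth:`PermutationResult.n_with_at_least` — how many permutations reach
    three or more.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cells = [(m, s) for s in scopes for m in measures]
    animals = (
        table[["mouse_id", "line"]]
        .drop_duplicates()
        .sort_values("mouse_id")
        .reset_index(drop=True)
    )
    labels = animals["line"].to_numpy()

    def count_significant(label_map: Mapping[str, str]) -> int:
        c = 0
        for measure, scope in cells:
            sub = table[(table["measure"] == measure) & (table["scope"] == scope)]
            sub = sub.assign(line=sub["mouse_id"].map(label_map))
            res = mixed_anova_2x2(sub)
            if res.p("interaction") < alpha:
                c += 1
        return c

    observed = count_significant(dict(zip(animals["mouse_id"], labels)))
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        perm = rng.permutation(labels)
        counts[i] = count_significant(dict(zip(animals["mouse_id"], perm)))
    return PermutationResult(
        observed_count=observed, counts=counts, n_perm=n_perm, alpha=alpha
    )


# ---------------------------------------------------------------------------
# pipeline


def parameter_fit_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Reshape a fit table to the long measure layout used by the ANOVAs.

    Emits measures ``alpha`` (= alpha_pos; equal to alpha_neg for tied
    models) and ``beta`` with scope ``param``.
    """
    rows = []
    for _, r in fits.iterrows():
        for measure, value in (("alpha", r["alpha_pos"]), ("beta", r["beta"])):
            rows.append(
                (r["mouse_id"], r["line"], r["treatment"], measure, "param", value)
            )
    return pd.DataFrame(
        rows, columns=["mouse_id", "line", "treatment", "measure", "scope", "value"]
    )


def _interaction_analysis(measure_table: pd.DataFrame, measure: str, scope: str):
    sub = measure_table[
        (measure_table["measure"] == measure) & (measure_table["scope"] == scope)
    ]
    aov = mixed_anova_2x2(sub)
    post = bonferroni_posthoc(sub, drug_contrasts_by_line())
    return aov, post


def _cohort_config_from_dict(d: Mapping) -> CohortConfig:
    kwargs = dict(d)
    if "effects" in kwargs:
        kwargs["effects"] = {
            tuple(k.split(":")) if isinstance(k, str) else tuple(k): dict(v)
            for k, v in kwargs["effects"].items()
        }
    if "baseline" in kwargs:
        kwargs["baseline"] = {k: tuple(v) for k, v in kwargs["baseline"].items()}
    if "n_per_line" in kwargs:
        kwargs["n_per_line"] = tuple(kwargs["n_per_line"])
    if "task" in kwargs:
        kwargs["task"] = TabTaskConfig(**kwargs["task"])
    if "duration_model" in kwargs:
        kwargs["duration_model"] = DurationModel(**kwargs["duration_model"])
    return CohortConfig(**kwargs)


def run_pipeline(
    config: Mapping | str | Path,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis chain on generated (or loaded) sessions.

    Stages: generate/load -> exclude duration outliers -> match durations
    (per line) -> fit the Q-learning model per animal x condition -> segment
    states & compute choice metrics -> fitted-value block profiles -> mixed
    ANOVAs with Bonferroni post-hocs on fitted alpha/beta and on the 8
    measure x state cells -> permutation control.  Returns a report dict;
    when ``out_dir`` is given, also writes tidy CSVs, ``summary.json`` and a
    log of every exclusion/removal decision.
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    config = dict(config)
    root = np.random.SeedSequence(seed)
    gen_seed, fit_seed, perm_seed = root.spawn(3)

    log: list[str] = []
    if config.get("input"):
        from .core_io import read_sessions

        data = read_sessions(config["input"])
        truth = None
        log.append(f"loaded {len(data)} sessions from {config['input']}")
    else:
        cohort_cfg = _cohort_config_from_dict(config.get("cohort", {}))
        data, truth = generate_cohort(cohort_cfg, gen_seed)
        log.append(f"generated {len(data)} sessions ({cohort_cfg.n_per_line} animals)")

    kept, excluded = exclude_duration_outliers(
        data.sessions, k=float(config.get("outlier_sd", 3.0))
    )
    log.extend(f"excluded outlier session {s.key}" for s in excluded)

    match_cfg = config.get("match_durations", {})
    matched: list[Session] = []
    for line in ("D1R", "D2R"):
        cno = [s for s in kept if s.line == line and s.treatment == "CNO"]
        dmso = [s for s in kept if s.line == line and s.treatment == "DMSO"]
        if not cno or not dmso:
            matched.extend(cno + dmso)
            continue
        mc, md, mlog = match_durations(
            cno,
            dmso,
            tolerance=float(match_cfg.get("tolerance", 0.5)),
            max_fraction_removed=float(match_cfg.get("max_fraction_removed", 0.2)),
        )
        matched.extend(mc + md)
        log.extend(
            f"duration matching removed {e['group']} session {e['session_key']}"
            for e in mlog
        )
    clean = SessionSet(matched, provenance=data.provenance)

    model_id = int(config.get("model_id", 1))
    fit_cfg = FitConfig(
        n_restarts=int(config.get("fit", {}).get("n_restarts", 20)),
        seed=int(
            config.get("fit", {}).get(
                "seed", int(fit_seed.generate_state(1)[0] % 2**31)
            )
        ),
    )
    fits = fit_cohort(clean, MODELS[model_id], fit_cfg)

    measures = animal_measure_table(clean)
    param_table = parameter_fit_table(fits)

    anova_rows = []
    posthoc_frames = []
    summary: dict = {"seed": seed, "n_sessions": len(clean), "model_id": model_id}
    for measure, scope in [("alpha", "param"), ("beta", "param")] + [
        (m, s) for s in ("all", "dynamic", "steady") for m in MEASURES
    ]:
        aov, post = _interaction_analysis(
            param_table if scope == "param" else measures, measure, scope
        )
        for eff, row in aov.effects.items():
            anova_rows.append({"measure": measure, "scope": scope, "effect": eff, **row})
        post.insert(0, "scope", scope)
        post.insert(0, "measure", measure)
        posthoc_frames.append(post)
    anova = pd.DataFrame(anova_rows)
    posthoc = pd.concat(posthoc_frames, ignore_index=True)

    def _p(measure, scope, effect="interaction"):
        row = anova[
            (anova["measure"] == measure)
            & (anova["scope"] == scope)
            & (anova["effect"] == effect)
        ]
        return float(row["p"].iloc[0])

    def _post_p(measure, scope, line):
        row = posthoc[
            (posthoc["measure"] == measure)
            & (posthoc["scope"] == scope)
            & (posthoc["name"] == f"CNO-vs-DMSO:{line}")
        ]
        return float(row["p_corrected"].iloc[0])

    alpha_sig = bool(_p("alpha", "param") < 0.05)
    beta_sig = bool(_p("beta", "param") < 0.05)
    summary["alpha_interaction_p"] = _p("alpha", "param")
    summary["beta_interaction_p"] = _p("beta", "param")
    summary["alpha_interaction_significant"] = alpha_sig
    summary["beta_interaction_significant"] = beta_sig
    summary["beta_localized_to_D1R"] = bool(
        _post_p("beta", "param", "D1R") < 0.05
        and _post_p("beta", "param", "D2R") >= 0.05
    )
    summary["alpha_localized_to_D2R"] = bool(
        _post_p("alpha", "param", "D2R") < 0.05
        and _post_p("alpha", "param", "D1R") >= 0.05
    )
    summary["double_dissociation_detected"] = bool(
        alpha_sig
        and beta_sig
        and summary["beta_localized_to_D1R"]
        and summary["alpha_localized_to_D2R"]
    )

    perm_cfg = config.get("permutation", {})
    perm = permutation_interaction_count(
        measures,
        n_perm=int(perm_cfg.get("n_perm", 100)),
        alpha=float(perm_cfg.get("alpha", 0.05)),
        seed=int(perm_seed.generate_state(1)[0] % 2**31),
    )
    summary["permutation_observed_count"] = perm.observed_count
    summary["permutation_max_count"] = int(perm.counts.max())
    summary["permutation_n_ge3"] = perm.n_with_at_least(3)

    from .rl_models import ParamSet

    fit_map = {
        (r["mouse_id"], r["treatment"]): ParamSet(
            **{k: r[k] for k in (
                "alpha_pos", "alpha_neg", "beta", "bias",
                "gamma_win", "gamma_lose", "epsilon", "rho",
            )}
        )
        for _, r in fits.iterrows()
    }
    qprofile = qvalue_block_profile(clean.sessions, fit_map)

    report = {
        "summary": summary,
        "sessions": clean,
        "truth": truth,
        "fits": fits,
        "measures": measures,
        "param_table": param_table,
        "anova": anova,
        "posthoc": posthoc,
        "permutation": perm,
        "qprofile": qprofile,
        "log": log,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fits.to_csv(out / "fits.csv", index=False)
        measures.to_csv(out / "measures.csv", index=False)
        anova.to_csv(out / "anova.csv", index=False)
        posthoc.to_csv(out / "posthoc.csv", index=False)
        pd.DataFrame({"count": perm.counts}).to_csv(
            out / "permutation.csv", index=False
        )
        qprofile.aligned.to_csv(out / "qprofile_aligned.csv", index=False)
        qprofile.state_means.to_csv(out / "qprofile_state_means.csv", index=False)
        if truth is not None:
            truth.to_csv(out / "truth.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        (out / "run.log").write_text("\n".join(log) + "\n")
    return report


@dataclass
class CohortAnalysis:
    """One synthetic cohort taken through fitting and group inference."""

    truth: pd.DataFrame
    fits: pd.DataFrame
    measures: pd.DataFrame  # animal-level choice metrics, long layout
    interaction_p: dict[str, float]  # fitted alpha / beta line x drug p
    posthoc_p: dict[tuple[str, str], float]  # (param, line) -> corrected p
    aligned_q: pd.DataFrame  # transition-aligned q_high/q_low + line column
    state_q: pd.DataFrame  # dynamic/steady-state q means + line column


def analyze_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    fit_config: FitConfig | None = None,
) -> CohortAnalysis:
    """Generate one cohort, fit every animal x condition, and run the
    line x drug inference on the fitted parameters.

    This is the single-cohort unit of the double-dissociation experiment:
    the returned interaction and post-hoc p-values carry the test of whether
    the drug effect on beta is confined to one line and the effect on alpha
    to the other.
    """
    config = config or CohortConfig()
    data, truth = generate_cohort(config, seed)
    cfg = fit_config or FitConfig(
        seed=int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31)
    )
    fits = fit_cohort(data, MODELS[config.model_id], cfg)
    ptable = parameter_fit_table(fits)
    interaction_p = {}
    posthoc_p = {}
    for measure in ("alpha", "beta"):
        aov, post = _interaction_analysis(ptable, measure, "param")
        interaction_p[measure] = aov.p("interaction")
        for line in ("D1R", "D2R"):
            posthoc_p[(measure, line)] = float(
                post.loc[post["name"] == f"CNO-vs-DMSO:{line}", "p_corrected"].iloc[0]
            )
    measures = animal_measure_table(data)
    from .rl_models import ParamSet

    fit_map = {
        (r["mouse_id"], r["treatment"]): ParamSet(
            **{
                k: r[k]
                for k in (
                    "alpha_pos",
                    "alpha_neg",
                    "beta",
                    "bias",
                    "gamma_win",
                    "gamma_lose",
                    "epsilon",
                    "rho",
                )
            }
        )
        for _, r in fits.iterrows()
    }
    qprof = qvalue_block_profile(data.sessions, fit_map)
    lines = truth[["mouse_id", "line"]].drop_duplicates()
    return CohortAnalysis(
        truth=truth,
        fits=fits,
        measures=measures,
        interaction_p=interaction_p,
        posthoc_p=posthoc_p,
        aligned_q=qprof.aligned.merge(lines, on="mouse_id"),
        state_q=qprof.state_means.merge(lines, on="mouse_id"),
    )


def paired_sign_test(
    table: pd.DataFrame,
    value: str = "value",
    subject: str = "mouse_id",
    within: str = "treatment",
    order: tuple[str, str] = ("CNO", "DMSO"),
    alternative: str = "less",
) -> tuple[float, int, int]:
    """Paired sign test of ``order[0]`` vs ``order[1]`` across subjects.

    Returns (p, n_in_direction, n_nonzero): with ``alternative='less'`` the
    direction counted is order[0] < order[1] (e.g. CNO below DMSO).
    """
    wide = table.pivot_table(index=subject, columns=within, values=value,
                             aggfunc="first")
    diff = (wide[order[0]] - wide[order[1]]).dropna()
    nonzero = diff[diff != 0]
    k = int((nonzero < 0).sum()) if alternative == "less" else int(
        (nonzero > 0).sum()
    )
    n = int(len(nonzero))
    if n == 0:
        return 1.0, 0, 0
    p = float(sps.binomtest(k, n, alternative="greater").pvalue)
    return p, k, n


# ---------------------------------------------------------------------------
# recovery experiments


def recovery_simulation(
    n_agents: int = 50,
    alpha_range: tuple[float, float] = (0.2, 0.8),
    beta_range: tuple[float, float] = (1.0, 5.0),
    n_sessions: int = 10,
    model_id: int = 1,
    seed: int = 0,
    fit_config: FitConfig | None = None,
) -> pd.DataFrame:
    """Simulate independent agents and refit them (parameter recovery).

    Each agent runs ``n_sessions`` TAB sessions (~155 trials each, the
    per-condition data size of the within-subject design).  Returns one row
    per agent with true and fitted alpha/beta plus the fitted and
    true-parameter negative log-likelihoods.
    """
    from .fitting import fit_mle
    from .rl_models import session_loglik
    from .synthetic_data import simulate_tab_session

    model = MODELS[model_id]
    root = np.random.SeedSequence(seed)
    agent_seeds = root.spawn(n_agents)
    rows = []
    for i in range(n_agents):
        rng = np.random.default_rng(agent_seeds[i])
        alpha = float(rng.uniform(*alpha_range))
        beta = float(rng.uniform(*beta_range))
        truth = model.paramset_from_vector([alpha, beta])
        sess_seeds = agent_seeds[i].spawn(n_sessions)
        sessions = [
            simulate_tab_session(
                truth, model, seed=sess_seeds[j], mouse_id=f"a{i}", day=j + 1
            )
            for j in range(n_sessions)
        ]
        cfg = fit_config or FitConfig(seed=i)
        fit = fit_mle(sessions, model, cfg)
        rows.append(
            {
                "agent": i,
                "true_alpha": alpha,
                "true_beta": beta,
                "fit_alpha": fit.params.alpha_pos,
                "fit_beta": fit.params.beta,
                "nll_fit": fit.nll,
                "nll_truth": -session_loglik(sessions, truth),
                "n_trials": fit.n_trials,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RecoveryReport:
    """Truth-vs-fit agreement and dissociation detection per cohort replicate."""

    param_stats: pd.DataFrame  # replicate, parameter, r, mae, bias
    per_replicate: pd.DataFrame  # replicate, interaction ps, localization flags
    joined: pd.DataFrame  # truth-vs-fit table across all replicates


def parameter_recovery_experiment(
    config: CohortConfig | Mapping | None = None,
    seed: int = 0,
    n_replicates: int = 1,
    fit_config: FitConfig | None = None,
) -> RecoveryReport:
    """Simulate full cohorts, refit, and score recovery + dissociation.

    Computed strictly from the generator's ground-truth table and the fit
    table (sessions are not consulted).  Per parameter: truth-vs-fit
    Pearson r, median absolute error, mean signed bias.  Per replicate:
    line x drug interaction p on fitted alpha and beta, and whether the
    Bonferroni post-hocs localize the beta effect to D1R and the alpha
    effect to D2R.
    """
    if config is None:
        config = CohortConfig()
    elif isinstance(config, Mapping):
        config = _cohort_config_from_dict(config)
    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(n_replicates)
    stats_rows = []
    rep_rows = []
    joined_frames = []
    for r in range(n_replicates):
        data, truth = generate_cohort(config, rep_seeds[r])
        cfg = fit_config or FitConfig(
            seed=int(rep_seeds[r].generate_state(1)[0] % 2**31)
        )
        fits = fit_cohort(data, MODELS[config.model_id], cfg)
        joined = truth.merge(
            fits, on=["mouse_id", "line", "treatment"], suffixes=("_true", "_fit")
        )
        joined.insert(0, "replicate", r)
        joined_frames.append(joined)
        for pname in ("alpha_pos", "beta"):
            t = joined[f"{pname}_true"].to_numpy(float)
            f = joined[f"{pname}_fit"].to_numpy(float)
            stats_rows.append(
                {
                    "replicate": r,
                    "parameter": "alpha" if pname == "alpha_pos" else pname,
                    "r": float(np.corrcoef(t, f)[0, 1]),
                    "mae": float(np.median(np.abs(f - t))),
                    "bias": float(np.mean(f - t)),
                }
            )
        ptable = parameter_fit_table(fits)
        rep = {"replicate": r}
        for measure in ("alpha", "beta"):
            aov, post = _interaction_analysis(ptable, measure, "param")
            rep[f"{measure}_interaction_p"] = aov.p("interaction")
            p_d1 = float(
                post.loc[post["name"] == "CNO-vs-DMSO:D1R", "p_corrected"].iloc[0]
            )
            p_d2 = float(
                post.loc[post["name"] == "CNO-vs-DMSO:D2R", "p_corrected"].iloc[0]
            )
            rep[f"{measure}_posthoc_D1R_p"] = p_d1
            rep[f"{measure}_posthoc_D2R_p"] = p_d2
        rep["beta_localized_to_D1R"] = bool(
            rep["beta_posthoc_D1R_p"] < 0.05 and rep["beta_posthoc_D2R_p"] >= 0.05
        )
        rep["alpha_localized_to_D2R"] = bool(
            rep["alpha_posthoc_D2R_p"] < 0.05 and rep["alpha_posthoc_D1R_p"] >= 0.05
        )
        rep_rows.append(rep)
    return RecoveryReport(
        param_stats=pd.DataFrame(stats_rows),
        per_replicate=pd.DataFrame(rep_rows),
        joined=pd.concat(joined_frames, ignore_index=True),
    )
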