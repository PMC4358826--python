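"""Statistics for the two-group ratio-report experiment.

Subjects in two between-subject groups (EW: expected weight, PV:
perceived volume) verbally report ratios of object pairs relative to a
reference value of 10.  All analysis happens on natural-log ratios in
the canonical small/large orientation, collapsed per subject over
presentation order.

Main machinery: the 2 (condition, between) x 3 (object set) x 6 (pair)
split-plot ANOVA and the per-pair 2 x 3 post-hoc ANOVAs, each effect
tested against its own subject-level error stratum; Lilliefors normality
checks with a seeded Monte-Carlo null; Benjamini-Hochberg FDR; Cohen's d;
and per-object-set ratio-line fits comparable to the environmental lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .pair_ratios import STIMULUS_PAIRS, RatioLine

GROUPS = ("EW", "PV")
OBJECT_SETS = ("Blobs", "Greebles", "Cubes")
ORDERS = ("S-L", "L-S")
REFERENCE_UNITS = 10.0

TRIAL_COLUMNS = ["subject", "group", "object_set", "pair", "order", "report"]


@dataclass(frozen=True)
class ResponseTrial:
    """One raw verbal ratio report."""

    subject: str
    group: str
    object_set: str
    pair: str
    order: str
    report: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.object_set not in OBJECT_SETS:
            raise ValueError(f"unknown object_set {self.object_set!r}")
        if self.pair not in STIMULUS_PAIRS:
            raise ValueError(f"unknown pair {self.pair!r}")
        if self.order not in ORDERS:
            raise ValueError(f"unknown order {self.order!r}")
        if self.report <= 0:
            raise ValueError(f"report must be > 0, got {self.report}")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    label: str
    df: float | None = None


@dataclass(frozen=True)
class AnovaRow:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    ss: float = float("nan")
    ss_error: float = float("nan")


@dataclass
class AnovaTable:
    rows: list[AnovaRow] = field(default_factory=list)

    def __getitem__(self, effect: str) -> AnovaRow:
        for row in self.rows:
            if row.effect == effect:
                return row
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"effect": r.effect, "F": r.F, "df_num": r.df_num,
                 "df_den": r.df_den, "p": r.p}
                for r in self.rows
            ]
        )


# ---------------------------------------------------------------------------
# normalization and collapsing

def normalize_response(order: str, report: float) -> float:
    """Canonical natural-log small/large ratio of one report.

    The left object carries the reference value of 10 units.  With the
    small object on the left (order ``"S-L"``) the report describes the
    large object, so the small/large ratio is 10/report; with the large
    object on the left it is report/10.
    """
    if order not in ORDERS:
        raise ValueError(f"unknown order {order!r}")
    if report <= 0:
        raise ValueError(f"report must be > 0, got {report}")
    if order == "S-L":
        return math.log(REFERENCE_UNITS / report)
    return math.log(report / REFERENCE_UNITS)


def trials_to_frame(trials: list[ResponseTrial]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"subject": t.subject, "group": t.group, "object_set": t.object_set,
             "pair": t.pair, "order": t.order, "report": t.report}
            for t in trials
        ],
        columns=TRIAL_COLUMNS,
    )


def load_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial CSV and validate the schema and value domains."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV missing column(s) {missing}")
    for col, allowed in (
        ("group", GROUPS), ("object_set", OBJECT_SETS),
        ("pair", STIMULUS_PAIRS), ("order", ORDERS),
    ):
        bad = set(df[col].unique()) - set(allowed)
        if bad:
            raise ValueError(f"trial CSV column {col!r} has unknown values {sorted(bad)}")
    if (df["report"] <= 0).any():
        raise ValueError("trial CSV contains non-positive reports")
    return df


def subject_pair_means(trials: pd.DataFrame | list[ResponseTrial]) -> pd.DataFrame:
    """Per subject x object_set x pair mean of canonical log ratios,
    collapsed over presentation order.

    Returns columns subject, group, object_set, pair, mean_log_ratio,
    n_trials.
    """
    if isinstance(trials, list):
        trials = trials_to_frame(trials)
    df = trials.copy()
    df["log_ratio"] = [
        normalize_response(o, r) for o, r in zip(df["order"], df["report"])
    ]
    out = (
        df.groupby(["subject", "group", "object_set", "pair"], observed=True)
        .agg(mean_log_ratio=("log_ratio", "mean"), n_trials=("log_ratio", "size"))
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# scalar tests

def lilliefors_test(sample, n_reps: int = 10_000, seed: int = 0) -> TestResult:
    """Lilliefors normality test with a seeded Monte-Carlo null.

    D is the KS distance between the empirical CDF and a normal CDF with
    mean and SD estimated from the sample; the null distribution of D is
    resampled from standard normals of the same n.
    """
    x = np.asarray(sample, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError(f"need at least 5 observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    d_obs = _lilliefors_d(x)
    rng = np.random.default_rng(seed)
    null = rng.standard_normal((n_reps, n))
    d_null = np.array([_lilliefors_d(row) for row in null])
    p = (1.0 + np.count_nonzero(d_null >= d_obs)) / (n_reps + 1.0)
    return TestResult(statistic=d_obs, p=float(p), df=float(n),
                      label="Lilliefors D")


def _lilliefors_d(x: np.ndarray) -> float:
    n = len(x)
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = stats.norm.cdf(z)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def one_sample_t(sample, mu0: float = 0.0, label: str = "t") -> TestResult:
    """Two-sided one-sample t-test with n-1 degrees of freedom."""
    x = np.asarray(sample, dtype=float)
    if len(x) < 2:
        raise ValueError(f"need at least 2 observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance sample")
    res = stats.ttest_1samp(x, popmean=mu0)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      df=float(len(x) - 1), label=label)


def cohens_d(group_a, group_b, label: str = "Cohen's d") -> TestResult:
    """(mean_a - mean_b) / pooled SD with n-1 denominators.

    ``p`` is reported as 1.0 — the statistic is descriptive.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    pooled_var = (
        (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    ) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    d = (a.mean() - b.mean()) / math.sqrt(pooled_var)
    return TestResult(statistic=float(d), p=1.0, label=label)


def fdr_correct(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted q-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


# ---------------------------------------------------------------------------
# split-plot ANOVAs

def _balanced_array(summaries: pd.DataFrame, within: list[str],
                    within_levels: list[tuple[str, ...]]) -> tuple[np.ndarray, list[str]]:
    """Pivot the summary table into Y[group, subject, w1, (w2)].

    Raises on any unbalanced or incomplete design.
    """
    df = summaries.copy()
    groups = sorted(df["group"].unique(), key=GROUPS.index)
    if len(groups) < 2:
        raise ValueError("need both EW and PV groups")
    subj_by_group = {
        g: sorted(df.loc[df["group"] == g, "subject"].unique()) for g in groups
    }
    ns = {g: len(s) for g, s in subj_by_group.items()}
    if len(set(ns.values())) != 1:
        raise ValueError(f"unbalanced groups: {ns} subjects per group")
    n = next(iter(ns.values()))
    shape = [len(groups), n] + [len(lv) for lv in within_levels]
    y = np.full(shape, np.nan)
    idx = {
        (row.subject, *(getattr(row, w) for w in within)): row.mean_log_ratio
        for row in df.itertuples()
    }
    for gi, g in enumerate(groups):
        for si, subj in enumerate(subj_by_group[g]):
            for cell in np.ndindex(*shape[2:]):
                key = (subj, *(within_levels[k][cell[k]] for k in range(len(within))))
                if key not in idx:
                    raise ValueError(
                        f"incomplete design: subject {subj!r} missing cell "
                        f"{key[1:]}"
                    )
                y[(gi, si, *cell)] = idx[key]
    return y, groups


def mixed_anova(summaries: pd.DataFrame) -> AnovaTable:
    """2 (condition, between) x 3 (object set) x 6 (pair) split-plot ANOVA.

    ``summaries`` is the output of :func:`subject_pair_means`.  Each
    effect is tested against its own error stratum: the between-subjects
    effect against subjects-within-groups; each within effect (and its
    interaction with condition) against the corresponding
    factor-by-subjects-within-groups term.  No sphericity correction is
    applied.
    """
    y, _ = _balanced_array(
        summaries, ["object_set", "pair"], [OBJECT_SETS, STIMULUS_PAIRS]
    )
    return _split_plot_two_within(
        y, names=("condition", "object_set", "pair")
    )


def _split_plot_two_within(y: np.ndarray,
                           names: tuple[str, str, str]) -> AnovaTable:
    """Balanced split-plot decomposition for Y[g, s, a, b]."""
    cond, aname, bname = names
    G, n, p, q = y.shape
    grand = y.mean()

    def ss_dev(mean_over_axes, scale):
        m = y.mean(axis=mean_over_axes)
        return scale * float(((m - grand) ** 2).sum())

    # between-subjects strata
    ss_cells_gs = ss_dev((2, 3), p * q)             # subjects x groups cells
    ss_cond = ss_dev((1, 2, 3), n * p * q)
    ss_subj = ss_cells_gs - ss_cond

    # factor A stratum
    ss_a = ss_dev((0, 1, 3), G * n * q)
    ss_ga = ss_dev((1, 3), n * q) - ss_a - ss_cond
    ss_a_err = ss_dev((3,), q) - ss_cells_gs - ss_a - ss_ga

    # factor B stratum
    ss_b = ss_dev((0, 1, 2), G * n * p)
    ss_gb = ss_dev((1, 2), n * p) - ss_b - ss_cond
    ss_b_err = ss_dev((2,), p) - ss_cells_gs - ss_b - ss_gb

    # A x B stratum
    ss_ab = ss_dev((0, 1), G * n) - ss_a - ss_b
    ss_gab = (
        ss_dev((1,), n)
        - ss_cond - ss_a - ss_b - ss_ga - ss_gb - ss_ab
    )
    ss_total = float(((y - grand) ** 2).sum())
    ss_ab_err = (
        ss_total
        - ss_cells_gs - ss_a - ss_ga - ss_a_err
        - ss_b - ss_gb - ss_b_err - ss_ab - ss_gab
    )

    df_subj = G * (n - 1)
    specs = [
        (cond, ss_cond, G - 1, ss_subj, df_subj),
        (aname, ss_a, p - 1, ss_a_err, (p - 1) * df_subj),
        (f"{aname} x {cond}", ss_ga, (G - 1) * (p - 1), ss_a_err, (p - 1) * df_subj),
        (bname, ss_b, q - 1, ss_b_err, (q - 1) * df_subj),
        (f"{bname} x {cond}", ss_gb, (G - 1) * (q - 1), ss_b_err, (q - 1) * df_subj),
        (f"{aname} x {bname}", ss_ab, (p - 1) * (q - 1), ss_ab_err,
         (p - 1) * (q - 1) * df_subj),
        (f"{aname} x {bname} x {cond}", ss_gab, (G - 1) * (p - 1) * (q - 1),
         ss_ab_err, (p - 1) * (q - 1) * df_subj),
    ]
    return AnovaTable([_f_row(*s) for s in specs])


def _f_row(effect: str, ss: float, df: int, ss_err: float, df_err: int) -> AnovaRow:
    ms = ss / df
    ms_err = ss_err / df_err
    f = ms / ms_err if ms_err > 0 else (0.0 if ms == 0 else math.inf)
    pval = float(stats.f.sf(f, df, df_err)) if math.isfinite(f) else 0.0
    return AnovaRow(effect=effect, F=float(f), df_num=df, df_den=df_err,
                    p=pval, ss=ss, ss_error=ss_err)


def mixed_anova_one_within(summaries: pd.DataFrame, within: str = "object_set",
                           within_levels: tuple[str, ...] = OBJECT_SETS) -> AnovaTable:
    """2 (condition, between) x k (within) split-plot ANOVA."""
    y, _ = _balanced_array(summaries, [within], [within_levels])
    G, n, p = y.shape
    grand = y.mean()
    ss_cells_gs = p * float(((y.mean(axis=2) - grand) ** 2).sum())
    ss_cond = n * p * float(((y.mean(axis=(1, 2)) - grand) ** 2).sum())
    ss_subj = ss_cells_gs - ss_cond
    ss_a = G * n * float(((y.mean(axis=(0, 1)) - grand) ** 2).sum())
    ss_ga = n * float(((y.mean(axis=1) - grand) ** 2).sum()) - ss_a - ss_cond
    ss_total = float(((y - grand) ** 2).sum())
    ss_a_err = ss_total - ss_cells_gs - ss_a - ss_ga
    df_subj = G * (n - 1)
    specs = [
        ("condition", ss_cond, G - 1, ss_subj, df_subj),
        (within, ss_a, p - 1, ss_a_err, (p - 1) * df_subj),
        (f"{within} x condition", ss_ga, (G - 1) * (p - 1), ss_a_err,
         (p - 1) * df_subj),
    ]
    return AnovaTable([_f_row(*s) for s in specs])


def posthoc_pair_anovas(summaries: pd.DataFrame) -> dict[str, AnovaTable]:
    """Six per-pair 2 (condition) x 3 (object set) split-plot ANOVAs."""
    out = {}
    for pair in STIMULUS_PAIRS:
        sub = summaries[summaries["pair"] == pair]
        if sub.empty:
            raise ValueError(f"no summaries for pair {pair!r}")
        out[pair] = mixed_anova_one_within(sub)
    return out


def posthoc_report(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-pair condition F/p with BH q-values (post-hoc table layout)."""
    tables = posthoc_pair_anovas(summaries)
    rows = [
        {"pair": pair, "F_condition": t["condition"].F, "p": t["condition"].p}
        for pair, t in tables.items()
    ]
    df = pd.DataFrame(rows)
    df["q_bh"] = fdr_correct(df["p"].tolist())
    return df


def pair_effect_sizes(summaries: pd.DataFrame) -> dict[str, TestResult]:
    """Cohen's d (EW vs PV) per pair, collapsing across object set."""
    out = {}
    collapsed = (
        summaries.groupby(["subject", "group", "pair"], observed=True)["mean_log_ratio"]
        .mean()
        .reset_index()
    )
    for pair in STIMULUS_PAIRS:
        sub = collapsed[collapsed["pair"] == pair]
        ew = sub.loc[sub["group"] == "EW", "mean_log_ratio"].to_numpy()
        pv = sub.loc[sub["group"] == "PV", "mean_log_ratio"].to_numpy()
        out[pair] = cohens_d(ew, pv, label=f"d {pair}")
    return out


def set_effect_sizes(summaries: pd.DataFrame) -> dict[str, TestResult]:
    """Cohen's d (EW vs PV) per object set, collapsing across pair."""
    out = {}
    collapsed = (
        summaries.groupby(["subject", "group", "object_set"], observed=True)["mean_log_ratio"]
        .mean()
        .reset_index()
    )
    for oset in OBJECT_SETS:
        sub = collapsed[collapsed["object_set"] == oset]
        ew = sub.loc[sub["group"] == "EW", "mean_log_ratio"].to_numpy()
        pv = sub.loc[sub["group"] == "PV", "mean_log_ratio"].to_numpy()
        out[oset] = cohens_d(ew, pv, label=f"d {oset}")
    return out


def volume_error_ttests(summaries: pd.DataFrame,
                        volume_ratios: dict[str, dict[str, float]],
                        group: str = "PV") -> dict[str, TestResult]:
    """Per-object-set t-tests of log(report ratio / true volume ratio) vs 0.

    For each subject in ``group`` the per-pair log error
    mean_log_ratio - ln(true volume ratio) is averaged across pairs; the
    per-subject means are tested against zero.
    """
    out = {}
    sub = summaries[summaries["group"] == group].copy()
    for oset in OBJECT_SETS:
        if oset not in volume_ratios:
            raise ValueError(f"no volume ratios for object set {oset!r}")
        s = sub[sub["object_set"] == oset].copy()
        s["log_error"] = [
            row.mean_log_ratio - math.log(volume_ratios[oset][row.pair])
            for row in s.itertuples()
        ]
        per_subject = s.groupby("subject", observed=True)["log_error"].mean()
        out[oset] = one_sample_t(per_subject.to_numpy(), 0.0, label=f"t {oset}")
    return out


def fit_perceptual_lines(summaries: pd.DataFrame,
                         volume_ratios: dict[str, dict[str, float]],
                         group: str = "EW") -> dict[str, dict[str, RatioLine]]:
    """Per-object-set OLS of mean log report ratio on true log volume ratio.

    Uses the pooled (across-subject) mean per pair, six points per set.
    The density line follows from the ratio identity: slope minus one,
    identical intercept.
    """
    out = {}
    sub = summaries[summaries["group"] == group]
    if sub.empty:
        raise ValueError(f"no summaries for group {group!r}")
    for oset in OBJECT_SETS:
        s = sub[sub["object_set"] == oset]
        means = s.groupby("pair", observed=True)["mean_log_ratio"].mean()
        missing = set(STIMULUS_PAIRS) - set(means.index)
        if missing:
            raise ValueError(f"{oset}: missing pairs {sorted(missing)}")
        x = np.array([math.log(volume_ratios[oset][p]) for p in STIMULUS_PAIRS])
        ykind = np.array([means[p] for p in STIMULUS_PAIRS])
        slope, intercept = np.polyfit(x, ykind, 1)
        weight_line = RatioLine(float(slope), float(intercept), "weight",
                                n_pairs=len(STIMULUS_PAIRS))
        out[oset] = {"weight": weight_line,
                     "density": weight_line.to_density_line()}
    return out


def convert_sav_to_trials(path: str | Path, out_csv: str | Path) -> None:
    """Convert an SPSS .sav trial file to the trial CSV schema.

    Requires the optional ``pyreadstat`` dependency; columns must match
    the trial schema after lower-casing.
    """
    try:
        import pyreadstat
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "SAV conversion needs the optional 'pyreadstat' package"
        ) from exc
    df, _ = pyreadstat.read_sav(str(path))
    df.columns = [c.lower() for c in df.columns]
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SAV file missing column(s) {missing}")
    df[TRIAL_COLUMNS].to_csv(out_csv, index=False)
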