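"""Group statistics for spectral profiles.

The battery applied to normalized hyperspectral profiles: Kolmogorov-
Smirnov normality screening, Grubbs outlier detection, a mixed-design
(repeated-measures two-way) ANOVA with Greenhouse-Geisser sphericity
correction — genotype/preparation as the between-subject factor,
wavelength as the within-subject factor — and per-wavelength post-hoc
t-tests with the adaptive two-stage linear step-up false-discovery-rate
procedure of Benjamini, Krieger & Yekutieli (2006).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaEffect", "AnovaResult", "build_long_table", "ks_normality",
    "grubbs_test", "rm_two_way_anova", "fdr_two_stage",
    "per_wavelength_posthoc", "significant_bands", "grubbs_screen_subjects",
]


# ------------------------------------------------------------- long table

def build_long_table(groups: dict[str, list]) -> pd.DataFrame:
    """Stack per-subject spectral profiles into a long table.

    ``groups`` maps group name -> list of SpectralProfile; subjects are
    labelled ``<group>:<index>``. Columns: subject_id, group,
    wavelength_nm, value.
    """
    rows = []
    for gname, profiles in groups.items():
        for i, p in enumerate(profiles):
            sid = f"{gname}:{i}"
            for wl, v in zip(p.grid.wavelengths_nm, p.values):
                rows.append((sid, gname, float(wl), float(v)))
    return pd.DataFrame(rows, columns=["subject_id", "group",
                                       "wavelength_nm", "value"])


def _validate_long(table: pd.DataFrame) -> None:
    required = {"subject_id", "group", "wavelength_nm", "value"}
    if not required <= set(table.columns):
        raise ValueError(f"long table needs columns {sorted(required)}")
    counts = table.groupby("subject_id")["wavelength_nm"].nunique()
    per_subj = table.groupby("subject_id").size()
    if not (counts == counts.iloc[0]).all() or not (per_subj == counts.iloc[0]).all():
        raise ValueError("each subject needs exactly one value per wavelength")


# ---------------------------------------------------------- normality etc.

def ks_normality(sample, method: str = "ks") -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test with estimated mean and SD.

    Returns (D, p). The default uses the plain KS null distribution, whose
    p-values are markedly conservative when the null parameters come from
    the same sample; ``method="lilliefors"`` applies the Lilliefors
    correction (via statsmodels) for a calibrated test.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("KS normality needs at least 5 observations")
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors
        d, p = lilliefors(x, dist="norm")
        return float(d), float(p)
    if method != "ks":
        raise ValueError("method must be 'ks' or 'lilliefors'")
    res = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GrubbsResult:
    statistic: float
    critical: float
    outlier_index: int | None


def grubbs_test(sample, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided Grubbs test for a single outlier.

    G = max|x_i - mean| / s; the critical value is the usual t-based bound
    at level ``alpha``. The most extreme point is flagged iff G exceeds it.
    Location/scale invariant.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 observations")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("Grubbs test undefined for zero-variance sample")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / s)
    t2 = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    crit = float((n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2)))
    return GrubbsResult(g, crit, idx if g > crit else None)


def grubbs_screen_subjects(table: pd.DataFrame, alpha: float = 0.05
                           ) -> tuple[pd.DataFrame, list[str]]:
    """Exclude subjects whose whole-profile mean is a Grubbs outlier within
    their group (one pass per group). Profile-level screening preserves the
    repeated-measures structure. Returns (filtered table, excluded ids)."""
    _validate_long(table)
    excluded: list[str] = []
    means = (table.groupby(["group", "subject_id"])["value"]
             .mean().reset_index())
    for g, sub in means.groupby("group"):
        if len(sub) < 3:
            continue
        res = grubbs_test(sub["value"].to_numpy(), alpha)
        if res.outlier_index is not None:
            excluded.append(str(sub["subject_id"].iloc[res.outlier_index]))
    return table[~table["subject_id"].isin(excluded)].copy(), excluded


# ----------------------------------------------------------------- ANOVA

@dataclass(frozen=True)
class AnovaEffect:
    name: str
    ss: float
    df1: float
    df2: float
    F: float
    p: float
    p_gg: float
    eps: float | None  # Greenhouse-Geisser epsilon (within effects only)


@dataclass(frozen=True)
class AnovaResult:
    group: AnovaEffect
    wavelength: AnovaEffect
    interaction: AnovaEffect
    eps: float

    def as_frame(self) -> pd.DataFrame:
        rows = [self.group, self.wavelength, self.interaction]
        return pd.DataFrame([{
            "effect": e.name, "SS": e.ss, "df1": e.df1, "df2": e.df2,
            "F": e.F, "p": e.p, "p_gg": e.p_gg, "eps": e.eps,
        } for e in rows])


def _gg_epsilon(table: pd.DataFrame) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance
    of the repeated measures (group means centred out)."""
    wide = table.pivot_table(index=["group", "subject_id"],
                             columns="wavelength_nm", values="value")
    k = wide.shape[1]
    pooled = np.zeros((k, k))
    dof = 0
    for _, sub in wide.groupby(level="group"):
        x = sub.to_numpy()
        if x.shape[0] < 2:
            continue
        pooled += (x.shape[0] - 1) * np.cov(x, rowvar=False)
        dof += x.shape[0] - 1
    if dof == 0:
        raise ValueError("need at least two subjects in some group")
    s = pooled / dof
    h = np.eye(k) - np.full((k, k), 1.0 / k)
    sc = h @ s @ h
    lam = np.linalg.eigvalsh(sc)
    lam = np.clip(lam, 0.0, None)
    denom = (k - 1) * float((lam ** 2).sum())
    if denom == 0:
        return 1.0
    eps = float(lam.sum() ** 2 / denom)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_two_way_anova(table: pd.DataFrame) -> AnovaResult:
    """Mixed-design two-way ANOVA on a long spectral table.

    Group (genotype/preparation) is the between-subject factor and
    wavelength the within-subject (repeated) factor; the design must be
    complete (every subject measured at every wavelength). The
    Greenhouse-Geisser epsilon computed from the pooled within-group
    covariance rescales the degrees of freedom of the within-subject
    effects (wavelength and interaction), since sphericity is not assumed;
    the between-subject effect needs no correction.
    """
    import pingouin as pg

    _validate_long(table)
    groups = table["group"].unique()
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n_per = table.groupby("group")["subject_id"].nunique()
    if (n_per < 2).any():
        raise ValueError("need at least two subjects per group")
    if table["wavelength_nm"].nunique() < 2:
        raise ValueError("need at least two wavelengths")

    aov = pg.mixed_anova(data=table, dv="value", within="wavelength_nm",
                         subject="subject_id", between="group",
                         correction=False)
    aov = aov.set_index("Source")
    eps = _gg_epsilon(table)

    def effect(source: str, name: str, within: bool) -> AnovaEffect:
        row = aov.loc[source]
        f = float(row["F"])
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        p = float(row["p_unc"])
        if within:
            p_gg = float(sps.f.sf(f, eps * df1, eps * df2))
            return AnovaEffect(name, float(row["SS"]), df1, df2, f, p,
                               max(p_gg, p), eps)
        return AnovaEffect(name, float(row["SS"]), df1, df2, f, p, p, None)

    return AnovaResult(
        group=effect("group", "group", within=False),
        wavelength=effect("wavelength_nm", "wavelength", within=True),
        interaction=effect("Interaction", "interaction", within=True),
        eps=eps,
    )


# ------------------------------------------------------------------- FDR

def _bh_reject_count(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the linear step-up (BH) procedure at
    ``level`` for ascending-sorted p-values."""
    m = p_sorted.size
    thresh = level * np.arange(1, m + 1) / m
    passing = np.nonzero(p_sorted <= thresh)[0]
    return 0 if passing.size == 0 else int(passing[-1]) + 1


def fdr_two_stage(pvalues, alpha: float = 0.05
                  ) -> tuple[np.ndarray, np.ndarray, int]:
    """Two-stage linear step-up FDR (Benjamini-Krieger-Yekutieli 2006).

    Stage 1 runs the linear step-up procedure at alpha' = alpha/(1+alpha)
    and estimates the number of true nulls as m0 = m - r1; if r1 = 0
    nothing is rejected, if r1 = m everything is; otherwise stage 2 re-runs
    the step-up at level alpha' * m / m0. Returns (reject flags, q-values,
    m0) in the input order; flags are exactly ``q <= alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    alpha1 = alpha / (1.0 + alpha)
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    r1 = _bh_reject_count(p_sorted, alpha1)
    m0 = m - r1

    # q-values: step-up-adjusted p with the m0 estimate, rescaled so that
    # rejection at the two-stage criterion reads q <= alpha
    ranks = np.arange(1, m + 1)
    adj = np.minimum.accumulate((p_sorted * m0 / ranks)[::-1])[::-1]
    q_sorted = np.clip(adj * (1.0 + alpha), 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted

    if r1 == 0:
        reject = np.zeros(m, dtype=bool)
    elif m0 == 0:
        reject = np.ones(m, dtype=bool)
    else:
        r2 = _bh_reject_count(p_sorted, alpha1 * m / m0)
        reject = np.zeros(m, dtype=bool)
        reject[order[:r2]] = True
    return reject, q, int(m0)


def per_wavelength_posthoc(table: pd.DataFrame, alpha: float = 0.05
                           ) -> pd.DataFrame:
    """Per-wavelength two-sample t-tests (equal variance) between the two
    groups, corrected across wavelengths with the two-stage step-up FDR.

    Returns a table with columns wavelength_nm, t, p, q, significant.
    Wavelengths where both groups are constant and equal (e.g. the
    normalization anchor bands) get t = 0, p = 1.
    """
    _validate_long(table)
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError("post-hoc contrast needs exactly two groups")
    ga, gb = groups
    rows = []
    for wl, sub in table.groupby("wavelength_nm"):
        a = sub.loc[sub["group"] == ga, "value"].to_numpy()
        b = sub.loc[sub["group"] == gb, "value"].to_numpy()
        if a.size < 2 or b.size < 2:
            raise ValueError("need at least two subjects per group per band")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            diff = a.mean() - b.mean()
            t, p = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
        else:
            t, p = sps.ttest_ind(a, b, equal_var=True)
        rows.append((float(wl), float(t), float(p)))
    out = pd.DataFrame(rows, columns=["wavelength_nm", "t", "p"])
    reject, qvals, _ = fdr_two_stage(out["p"].to_numpy(), alpha)
    out["q"] = qvals
    out["significant"] = reject
    return out


def significant_bands(posthoc: pd.DataFrame) -> list[tuple[float, float]]:
    """Contiguous runs of significant wavelengths as (lo, hi) nm pairs."""
    df = posthoc.sort_values("wavelength_nm")
    bands: list[tuple[float, float]] = []
    start = prev = None
    for wl, sig in zip(df["wavelength_nm"], df["significant"]):
        if sig:
            if start is None:
                start = wl
            prev = wl
        elif start is not None:
            bands.append((float(start), float(prev)))
            start = None
    if start is not None:
        bands.append((float(start), float(prev)))
    return bands
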