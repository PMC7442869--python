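"""Within-subject inferential battery.

Formula-level implementations of the paired t-test, fully within-subject
repeated-measures ANOVA (1-3 factors, classical sums of squares, each
effect tested against its effect-by-subject interaction), and Spearman
rank correlation with midranks.

No sphericity correction is applied by default (Greenhouse-Geisser is
available behind a flag) and no multiple-testing adjustment is performed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, IncompleteDesignError


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    n: int
    mean_diff: float
    undefined: bool = False  # zero variance of differences


@dataclass
class AnovaEffect:
    effect: str
    ss: float
    ss_error: float
    df_num: int
    df_den: int
    f: float
    p: float
    undefined: bool = False
    gg_epsilon: float | None = None


@dataclass
class AnovaResult:
    effects: dict[str, AnovaEffect]
    n_subjects: int

    def __getitem__(self, effect: str) -> AnovaEffect:
        return self.effects[effect]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects.values()])


@dataclass
class CorrelationResult:
    rs: float
    n: int
    p: float
    method: str = "t-approx"
    undefined: bool = False


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Two-sided paired t-test on per-subject value pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("paired_t needs two equal-length 1-d arrays")
    n = len(x)
    if n < 3:
        raise DomainError(f"paired_t needs n >= 3, got {n}")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedTResult(
            t=0.0, df=n - 1, p=1.0, n=n, mean_diff=float(d.mean()), undefined=True
        )
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return PairedTResult(t=t, df=n - 1, p=p, n=n, mean_diff=float(d.mean()))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------


def _uncorrected_ss(df: pd.DataFrame, cols: tuple[str, ...], dv: str) -> float:
    """U-term: sum over cells of (cell sum)^2 / cell count."""
    if not cols:
        return float(df[dv].sum() ** 2 / len(df))
    g = df.groupby(list(cols), observed=True)[dv]
    return float((g.sum() ** 2 / g.size()).sum())


def _interaction_ss(df: pd.DataFrame, factors: tuple[str, ...], dv: str) -> float:
    """Classical SS of the full interaction of ``factors`` by inclusion-exclusion."""
    ss = 0.0
    for r in range(len(factors) + 1):
        for sub in itertools.combinations(factors, r):
            ss += (-1) ** (len(factors) - r) * _uncorrected_ss(df, sub, dv)
    return ss


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1, k) orthonormal contrast rows, each orthogonal to the constant."""
    c = np.zeros((k - 1, k))
    for i in range(1, k):
        c[i - 1, :i] = 1.0
        c[i - 1, i] = -float(i)
        c[i - 1] /= np.linalg.norm(c[i - 1])
    return c


def _gg_epsilon(
    df: pd.DataFrame, subject: str, factors: list[str],
    levels: dict[str, list], dv: str,
) -> float:
    """Greenhouse-Geisser epsilon on the effect's contrast covariance.

    The contrast matrix is the Kronecker product of per-factor orthonormal
    contrasts, so interaction effects get their own (double-centered)
    epsilon rather than the epsilon of the flattened cell factor.
    """
    wide = df.pivot_table(index=subject, columns=factors, values=dv,
                          observed=True)
    # lexicographic cell order matches the Kronecker contrast ordering
    wide = wide.sort_index(axis=1)
    s = np.cov(wide.to_numpy(), rowvar=False, ddof=1)
    c = _orthonormal_contrasts(len(levels[factors[0]]))
    for f in factors[1:]:
        c = np.kron(c, _orthonormal_contrasts(len(levels[f])))
    sc = c @ s @ c.T
    d = sc.shape[0]
    denom = d * float(np.sum(sc * sc))
    if denom <= 0:
        return 1.0
    eps = float(np.trace(sc)) ** 2 / denom
    return float(min(1.0, max(eps, 1.0 / d)))


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    subject: str = "subject_id",
    within: Sequence[str] = (),
    sphericity_correction: str = "none",
) -> AnovaResult:
    """Fully within-subject repeated-measures ANOVA (1-3 factors).

    Classical sums-of-squares decomposition on a complete balanced
    crossing; every effect is tested against its interaction with the
    subject factor, giving df_den = df_num * (n_subjects - 1).

    Parameters
    ----------
    sphericity_correction : "none" (default, matches integer dfs) or "gg"
        for Greenhouse-Geisser corrected p-values on multi-df effects.
    """
    within = tuple(within)
    if not 1 <= len(within) <= 3:
        raise DomainError("rm_anova supports 1 to 3 within-subject factors")
    if sphericity_correction not in ("none", "gg"):
        raise DomainError(f"unknown sphericity_correction {sphericity_correction!r}")
    df = table[[subject, *within, dv]].copy()
    if df[dv].isna().any():
        raise IncompleteDesignError("dependent variable contains missing values")

    subjects = df[subject].unique()
    n_subj = len(subjects)
    levels = {f: sorted(df[f].unique()) for f in within}
    sizes = df.groupby([subject, *within], observed=True).size()
    expected = {
        (s, *cell) if within else (s,)
        for s in subjects
        for cell in itertools.product(*(levels[f] for f in within))
    }
    got = set(sizes.index)
    missing = sorted(expected - got)
    if missing:
        raise IncompleteDesignError(
            f"missing within-subject cells: {missing[:10]}"
            + (" ..." if len(missing) > 10 else "")
        )
    if (sizes != 1).any():
        dup = sizes[sizes > 1].index.tolist()
        raise IncompleteDesignError(
            f"duplicated within-subject cells: {dup[:10]}"
            + (" ..." if len(dup) > 10 else "")
        )
    if n_subj < 2:
        raise DomainError("rm_anova needs at least 2 subjects")

    effects: dict[str, AnovaEffect] = {}
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            name = "*".join(combo)
            ss_eff = max(_interaction_ss(df, combo, dv), 0.0)
            ss_err = max(_interaction_ss(df, (subject, *combo), dv), 0.0)
            df_num = int(np.prod([len(levels[f]) - 1 for f in combo]))
            df_den = df_num * (n_subj - 1)
            eps: float | None = None
            if ss_err == 0.0 or df_den == 0:
                effects[name] = AnovaEffect(
                    effect=name, ss=ss_eff, ss_error=ss_err, df_num=df_num,
                    df_den=df_den, f=0.0 if ss_eff == 0 else math.inf,
                    p=math.nan, undefined=True,
                )
                continue
            f_stat = (ss_eff / df_num) / (ss_err / df_den)
            if sphericity_correction == "gg" and df_num > 1:
                eps = _gg_epsilon(df, subject, list(combo), levels, dv)
                p = float(stats.f.sf(f_stat, eps * df_num, eps * df_den))
            else:
                p = float(stats.f.sf(f_stat, df_num, df_den))
            effects[name] = AnovaEffect(
                effect=name, ss=float(ss_eff), ss_error=float(ss_err),
                df_num=df_num, df_den=df_den, f=float(f_stat), p=p,
                gg_epsilon=eps,
            )
    return AnovaResult(effects=effects, n_subjects=n_subj)


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    den = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / den if den > 0 else math.nan


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    rng: np.random.Generator | None = None,
) -> CorrelationResult:
    """Spearman correlation: Pearson on midranks.

    Two-sided p-value: exact permutation enumeration for n < 8,
    t approximation ``t = rs * sqrt((n-2)/(1-rs^2))`` for n >= 10, and a
    seeded Monte-Carlo permutation estimate in between.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("spearman needs two equal-length 1-d arrays")
    n = len(x)
    if n < 4:
        raise DomainError(f"spearman needs n >= 4, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rs = _rank_corr(rx, ry)
    if math.isnan(rs):
        return CorrelationResult(rs=math.nan, n=n, p=math.nan,
                                 method="undefined", undefined=True)
    if n < 8:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            rs_p = _rank_corr(rx, ry[list(perm)])
            if abs(rs_p) >= abs(rs) - 1e-12:
                count += 1
            total += 1
        return CorrelationResult(rs=rs, n=n, p=count / total, method="exact")
    if n >= 10:
        denom = max(1.0 - rs * rs, 1e-15)
        t = rs * math.sqrt((n - 2) / denom)
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
        return CorrelationResult(rs=rs, n=n, p=min(p, 1.0), method="t-approx")
    if rng is None:
        rng = np.random.default_rng(0)
    n_mc = 20000
    hits = 1
    for _ in range(n_mc):
        rs_p = _rank_corr(rx, rng.permutation(ry))
        if abs(rs_p) >= abs(rs) - 1e-12:
            hits += 1
    return CorrelationResult(rs=rs, n=n, p=hits / (n_mc + 1), method="monte-carlo")


def anisotropy_change_correlation(
    behavioral: Mapping[str, float] | pd.Series,
    bold: Mapping[str, float] | pd.Series,
) -> CorrelationResult:
    """Spearman correlation between per-subject behavioral and BOLD
    anisotropy-index changes (post - pre), after z-standardization.

    Standardization does not affect the rank correlation; it is applied so
    reported scatter values match the standardized-change convention.
    """
    b = pd.Series(dict(behavioral) if not isinstance(behavioral, pd.Series) else behavioral)
    f = pd.Series(dict(bold) if not isinstance(bold, pd.Series) else bold)
    if set(b.index) != set(f.index):
        only_b = sorted(set(b.index) - set(f.index))
        only_f = sorted(set(f.index) - set(b.index))
        raise DomainError(
            f"subject mismatch between behavioral and BOLD changes: "
            f"behavioral-only={only_b}, bold-only={only_f}"
        )
    order = sorted(b.index)
    bv = b.loc[order].to_numpy(dtype=float)
    fv = f.loc[order].to_numpy(dtype=float)
    bv = (bv - bv.mean()) / bv.std(ddof=1) if bv.std(ddof=1) > 0 else bv
    fv = (fv - fv.mean()) / fv.std(ddof=1) if fv.std(ddof=1) > 0 else fv
    return spearman(bv, fv)
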