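"""Two-way fully within-subject repeated-measures ANOVA.

For a complete subjects x A x B table the classical decomposition
splits the total sum of squares into the two main effects, the A x B
interaction, and their subject-interaction error terms.  The statistic
of interest here is the seed-by-target interaction

    F = MS_AB / MS_ABxSubject,   df = ((a-1)(b-1), (a-1)(b-1)(n-1)).

Sphericity of the interaction contrasts is rarely credible for
connectivity data, so the Greenhouse-Geisser epsilon (from the
covariance of the orthonormalized interaction contrasts) and the
Huynh-Feldt epsilon

    eps_HF = (n d eps_GG - 2) / (d (n - 1 - d eps_GG)),  d = (a-1)(b-1)

(capped at 1) are always reported, together with unadjusted and
adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError


@dataclass
class RmAnovaResult:
    """Result of the two-way within-subject ANOVA."""

    ss_table: pd.DataFrame
    F_interaction: float
    df1: int
    df2: int
    epsilon_gg: float
    epsilon_hf: float
    p_unadjusted: float
    p_gg: float
    p_hf: float
    n_subjects: int
    n_dropped: int = 0
    sphericity_flag: bool = False  # True when eps_HF < 0.75

    @property
    def df1_adj(self) -> float:
        return self.epsilon_hf * self.df1

    @property
    def df2_adj(self) -> float:
        return self.epsilon_hf * self.df2

    @property
    def p_adjusted(self) -> float:
        return self.p_hf


def interaction_dof(a: int, b: int, n: int) -> tuple[int, int]:
    """Unadjusted degrees of freedom of the A x B interaction.

    df1 = (a-1)(b-1), df2 = (a-1)(b-1)(n-1).
    """
    if a < 2 or b < 2 or n < 2:
        raise ValidationError("need a >= 2, b >= 2, n >= 2")
    df1 = (a - 1) * (b - 1)
    return df1, df1 * (n - 1)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows sum to zero)."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
        helmert[i] /= np.linalg.norm(helmert[i])
    return helmert


def _epsilons(data: np.ndarray) -> tuple[float, float]:
    """Greenhouse-Geisser and Huynh-Feldt epsilons for the interaction.

    Computed from the covariance of the orthonormalized interaction
    contrast scores; with S = Cov(Y C'), eps_GG = tr(S)^2 / (d tr(S^2)).
    """
    n, a, b = data.shape
    d = (a - 1) * (b - 1)
    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    c = np.kron(ca, cb)  # d x (a*b)
    y = data.reshape(n, a * b) @ c.T  # n x d
    s = np.cov(y, rowvar=False, ddof=1).reshape(d, d)
    tr = np.trace(s)
    tr2 = np.trace(s @ s)
    if tr2 <= 0:
        raise DegenerateDataError("zero contrast covariance")
    eps_gg = tr**2 / (d * tr2)
    denom = d * (n - 1 - d * eps_gg)
    if denom <= 0:
        eps_hf = 1.0
    else:
        eps_hf = (n * d * eps_gg - 2.0) / denom
    eps_hf = min(max(eps_hf, eps_gg), 1.0)
    return float(eps_gg), float(eps_hf)


def two_way_rm_anova(data: np.ndarray) -> RmAnovaResult:
    """Two-way fully within-subject ANOVA on a subjects x a x b array.

    Subjects with any NaN cell are dropped listwise (with a warning).
    Raises :class:`DegenerateDataError` when the interaction error mean
    square is zero.  When n <= (a-1)(b-1) the epsilons cannot be
    estimated; they are set to NaN and the unadjusted p is reported as
    the adjusted one, with a warning.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValidationError("data must be subjects x a x b")
    n_raw = data.shape[0]
    complete = np.all(np.isfinite(data), axis=(1, 2))
    n_dropped = int(n_raw - complete.sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} subject(s) with incomplete cells", stacklevel=2
        )
        data = data[complete]
    n, a, b = data.shape
    if n < 2 or a < 2 or b < 2:
        raise ValidationError(f"need n, a, b >= 2 after dropping; got {(n, a, b)}")

    grand = data.mean()
    subj = data.mean(axis=(1, 2))  # n
    ma = data.mean(axis=(0, 2))  # a
    mb = data.mean(axis=(0, 1))  # b
    mab = data.mean(axis=0)  # a x b
    mas = data.mean(axis=2)  # n x a
    mbs = data.mean(axis=1)  # n x b

    ss_subj = a * b * np.sum((subj - grand) ** 2)
    ss_a = n * b * np.sum((ma - grand) ** 2)
    ss_b = n * a * np.sum((mb - grand) ** 2)
    ss_ab = n * np.sum((mab - ma[:, None] - mb[None, :] + grand) ** 2)
    ss_as = b * np.sum((mas - ma[None, :] - subj[:, None] + grand) ** 2)
    ss_bs = a * np.sum((mbs - mb[None, :] - subj[:, None] + grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    df_a, df_as = a - 1, (a - 1) * (n - 1)
    df_b, df_bs = b - 1, (b - 1) * (n - 1)
    df_ab, df_abs = interaction_dof(a, b, n)

    ms_ab = ss_ab / df_ab
    ms_abs = ss_abs / df_abs
    if ms_abs <= 0:
        raise DegenerateDataError("interaction error mean square is zero")
    f_int = ms_ab / ms_abs
    p_unadj = float(stats.f.sf(f_int, df_ab, df_abs))

    d = df_ab
    if n <= d:
        warnings.warn(
            f"n={n} too small to estimate sphericity for d={d} contrasts; "
            "reporting unadjusted p only",
            stacklevel=2,
        )
        eps_gg = eps_hf = np.nan
        p_gg = p_hf = p_unadj
    else:
        eps_gg, eps_hf = _epsilons(data)
        p_gg = float(stats.f.sf(f_int, eps_gg * df_ab, eps_gg * df_abs))
        p_hf = float(stats.f.sf(f_int, eps_hf * df_ab, eps_hf * df_abs))

    rows = [
        ("subject", ss_subj, n - 1, ss_subj / (n - 1)),
        ("A", ss_a, df_a, ss_a / df_a),
        ("A x subject", ss_as, df_as, ss_as / df_as),
        ("B", ss_b, df_b, ss_b / df_b),
        ("B x subject", ss_bs, df_bs, ss_bs / df_bs),
        ("A x B", ss_ab, df_ab, ms_ab),
        ("A x B x subject", ss_abs, df_abs, ms_abs),
        ("total", ss_total, n * a * b - 1, np.nan),
    ]
    table = pd.DataFrame(rows, columns=["effect", "SS", "df", "MS"])

    return RmAnovaResult(
        ss_table=table,
        F_interaction=float(f_int),
        df1=df_ab,
        df2=df_abs,
        epsilon_gg=eps_gg,
        epsilon_hf=eps_hf,
        p_unadjusted=p_unadj,
        p_gg=p_gg,
        p_hf=p_hf,
        n_subjects=n,
        n_dropped=n_dropped,
        sphericity_flag=bool(np.isfinite(eps_hf) and eps_hf < 0.75),
    )


def anova_from_long(df: pd.DataFrame) -> RmAnovaResult:
    """Run the ANOVA from a long table (subject, seed, target, r)."""
    required = {"subject", "seed", "target", "r"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"long table missing columns: {sorted(missing)}")
    wide = df.pivot_table(
        index="subject", columns=["seed", "target"], values="r", dropna=False
    )
    subjects = wide.index
    seeds = sorted(df["seed"].unique())
    targets = sorted(df["target"].unique())
    arr = np.full((len(subjects), len(seeds), len(targets)), np.nan)
    for i_s, s in enumerate(seeds):
        for i_t, t in enumerate(targets):
            arr[:, i_s, i_t] = wide[(s, t)].to_numpy()
    return two_way_rm_anova(arr)
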