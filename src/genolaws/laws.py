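"""Per-genome conformity to the three composition laws.

Law 1 (base pairing): P(A)=P(T) and P(G)=P(C) on a single strand.
Law 2 (base equality): purine content P(R) = pyrimidine content P(Y) = 1/2.
Law 3 (independence factorization): S/W status and R/Y status of a base are
statistically independent, so

    P(A) = P(W)·P(R),  P(T) = P(W)·P(Y),
    P(G) = P(S)·P(R),  P(C) = P(S)·P(Y),

with W = Sᶜ and Y = Rᶜ.  :func:`estimate_profile` evaluates these products;
:func:`independence_test` tests the factorization on the 2×2 contingency
table {S, W}×{R, Y} whose cells are the raw base counts (G, C / A, T).  The
expected counts of that table under independence are exactly the law-3
estimates times the sequence length, which is why the expected cells here
are computed through :func:`estimate_profile` rather than the generic
margins formula (the two are algebraically identical).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from scipy import stats

from genolaws.composition import BaseCounts, CompositionProfile, profile_from_counts

__all__ = [
    "DegenerateTableError",
    "LawReport",
    "estimate_profile",
    "evaluate_genome",
    "evaluate_profile",
    "independence_test",
    "law1_deviation",
    "law2_deviation",
    "law3_residuals",
]


class DegenerateTableError(ValueError):
    """Raised when a contingency-table margin is empty (e.g. no purines)."""


def estimate_profile(p_s: float, p_r: float) -> CompositionProfile:
    """Base proportions implied by GC content ``p_s`` and purine content
    ``p_r`` under the independence factorization.

    The four products ``(1-s)r, (1-s)(1-r), sr, s(1-r)`` sum to 1 for any
    inputs in the unit square, and the output's own GC and purine contents
    reproduce the inputs.
    """
    if not 0.0 <= p_s <= 1.0:
        raise ValueError(f"p_s={p_s} outside [0, 1]")
    if not 0.0 <= p_r <= 1.0:
        raise ValueError(f"p_r={p_r} outside [0, 1]")
    p_w = 1.0 - p_s
    p_y = 1.0 - p_r
    return CompositionProfile(
        p_a=p_w * p_r,
        p_t=p_w * p_y,
        p_g=p_s * p_r,
        p_c=p_s * p_y,
    )


def law1_deviation(profile: CompositionProfile) -> tuple[float, float]:
    """Absolute pairing deviations ``(|p_a - p_t|, |p_g - p_c|)``."""
    return abs(profile.p_a - profile.p_t), abs(profile.p_g - profile.p_c)


def law2_deviation(profile: CompositionProfile) -> float:
    """Absolute deviation of purine content from 1/2, ``|p_r - 0.5|``."""
    return abs(profile.p_r - 0.5)


def law3_residuals(observed: CompositionProfile) -> tuple[dict[str, float], float]:
    """Signed residuals observed − estimated for each base.

    The estimate is the independence factorization evaluated at the
    observed genome's own GC and purine contents.  Returns the residual
    mapping (keys ``a t g c``) and the maximum absolute residual.  The four
    residuals sum to zero because both profiles sum to one.
    """
    est = estimate_profile(observed.p_s, observed.p_r)
    residuals = {
        "a": observed.p_a - est.p_a,
        "t": observed.p_t - est.p_t,
        "g": observed.p_g - est.p_g,
        "c": observed.p_c - est.p_c,
    }
    return residuals, max(abs(v) for v in residuals.values())


def independence_test(counts: BaseCounts, method: str = "chi2"):
    """Test S ⟂ R on the 2×2 table rows {S, W} × columns {R, Y}.

    The table cells are (G, C / A, T).  ``method='chi2'`` is the Pearson
    statistic without continuity correction (at genome scale the Yates
    correction is negligible); ``method='g'`` is the likelihood-ratio
    G statistic, preferable for small toy tables.  Both have df = 1.

    Returns ``(statistic, df, p_value, odds_ratio)`` where the odds ratio
    is ``n_g·n_t / (n_a·n_c)``, reported as ``inf`` when the denominator is
    zero and the numerator positive.

    Raises :class:`DegenerateTableError` when a margin is empty, since
    every expected cell in that row/column would be zero.
    """
    if method not in ("chi2", "g"):
        raise ValueError(f"unknown method {method!r}")
    n = counts.n_unambiguous
    if n < 1:
        raise ValueError("no unambiguous bases to test")
    margins = {
        "S (G+C)": counts.n_g + counts.n_c,
        "W (A+T)": counts.n_a + counts.n_t,
        "R (A+G)": counts.n_a + counts.n_g,
        "Y (T+C)": counts.n_t + counts.n_c,
    }
    empty = [name for name, m in margins.items() if m == 0]
    if empty:
        raise DegenerateTableError(f"empty margin(s): {', '.join(empty)}")

    profile = profile_from_counts(counts)
    est = estimate_profile(profile.p_s, profile.p_r)
    observed = {"a": counts.n_a, "t": counts.n_t, "g": counts.n_g, "c": counts.n_c}
    expected = {"a": n * est.p_a, "t": n * est.p_t, "g": n * est.p_g, "c": n * est.p_c}

    if method == "chi2":
        statistic = sum((observed[b] - expected[b]) ** 2 / expected[b] for b in observed)
    else:
        statistic = 2.0 * sum(
            observed[b] * math.log(observed[b] / expected[b])
            for b in observed
            if observed[b] > 0
        )
    df = 1
    p_value = float(stats.chi2.sf(statistic, df))

    numerator = counts.n_g * counts.n_t
    denominator = counts.n_a * counts.n_c
    if denominator == 0:
        odds_ratio = math.inf if numerator > 0 else math.nan
    else:
        odds_ratio = numerator / denominator
    return statistic, df, p_value, odds_ratio


@dataclass(frozen=True)
class LawReport:
    """Per-genome conformity record across all three laws.

    ``chi2``, ``chi2_p`` and ``odds_ratio`` are ``None`` when the genome
    was supplied as proportions only (integer counts unavailable).
    ``outlier_score`` is the larger of the two law-1 pairing deviations —
    a size-free disparity measure, unlike the chi-square statistic which
    grows with genome length.
    """

    genome_id: str
    observed: CompositionProfile
    estimated: CompositionProfile
    law1_delta_at: float
    law1_delta_gc: float
    law2_delta: float
    residuals: dict[str, float]
    max_abs_residual: float
    chi2: float | None
    chi2_df: int | None
    chi2_p: float | None
    odds_ratio: float | None
    outlier_score: float

    def as_dict(self, decimals: int | None = None) -> dict:
        def f(x):
            if x is None:
                return None
            return round(x, decimals) if decimals is not None else x

        # observed-profile fields keep their plain names so an emitted
        # cohort TSV can be read back as a composition table
        d = {"genome_id": self.genome_id}
        d.update(self.observed.as_dict(decimals))
        est = self.estimated.as_dict(decimals)
        d.update({f"est_p_{b}": est[f"p_{b}"] for b in "atgc"})
        d.update(
            {
                "law1_delta_at": f(self.law1_delta_at),
                "law1_delta_gc": f(self.law1_delta_gc),
                "law2_delta": f(self.law2_delta),
                "resid_a": f(self.residuals["a"]),
                "resid_t": f(self.residuals["t"]),
                "resid_g": f(self.residuals["g"]),
                "resid_c": f(self.residuals["c"]),
                "max_abs_residual": f(self.max_abs_residual),
                "chi2": self.chi2,
                "chi2_df": self.chi2_df,
                "chi2_p": self.chi2_p,
                "odds_ratio": self.odds_ratio,
                "outlier_score": f(self.outlier_score),
            }
        )
        return d

    def to_json(self) -> str:
        """Full-precision JSON serialization."""
        return json.dumps(self.as_dict(), allow_nan=True)


def evaluate_profile(genome_id: str, profile: CompositionProfile) -> LawReport:
    """Law report for a genome known only through its proportions.

    The contingency test needs integer counts, so its fields are ``None``.
    """
    d_at, d_gc = law1_deviation(profile)
    residuals, max_resid = law3_residuals(profile)
    return LawReport(
        genome_id=genome_id,
        observed=profile,
        estimated=estimate_profile(profile.p_s, profile.p_r),
        law1_delta_at=d_at,
        law1_delta_gc=d_gc,
        law2_delta=law2_deviation(profile),
        residuals=residuals,
        max_abs_residual=max_resid,
        chi2=None,
        chi2_df=None,
        chi2_p=None,
        odds_ratio=None,
        outlier_score=max(d_at, d_gc),
    )


def evaluate_genome(genome_id: str, counts: BaseCounts, method: str = "chi2") -> LawReport:
    """Full law report from integer tallies, including the 2×2 test."""
    profile = profile_from_counts(counts)
    base = evaluate_profile(genome_id, profile)
    chi2, df, p, odds = independence_test(counts, method=method)
    return LawReport(
        genome_id=genome_id,
        observed=profile,
        estimated=base.estimated,
        law1_delta_at=base.law1_delta_at,
        law1_delta_gc=base.law1_delta_gc,
        law2_delta=base.law2_delta,
        residuals=base.residuals,
        max_abs_residual=base.max_abs_residual,
        chi2=chi2,
        chi2_df=df,
        chi2_p=p,
        odds_ratio=odds,
        outlier_score=base.outlier_score,
    )
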