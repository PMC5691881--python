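"""Nonparametric group comparisons and the study-level report.

The three curve types (NS major, IS main, IS compensatory) are compared
pairwise with the Mann-Whitney U test; with three comparisons per variable
family the Bonferroni-adjusted significance level is 0.05 / 3 ~ 0.017.  Age
is compared between the two patient groups at 0.05.

:class:`ScoliosisStudy` is the model object (built from tidy DataFrames or a
synthetic :class:`~vertmorph.synthetic.Cohort`); :meth:`ScoliosisStudy.fit`
returns a :class:`StudyResults` carrying per-curve summaries, all pairwise
comparisons and a formatted ``summary()`` table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "mann_whitney_u",
    "bonferroni_threshold",
    "ComparisonResult",
    "ScoliosisStudy",
    "StudyResults",
    "CURVE_GROUPS",
]

CURVE_GROUPS = ("NS_major", "IS_main", "IS_comp")

#: Combined-sample-size cutoff below which the exact null distribution of U
#: is enumerated (untied samples only).
EXACT_ENUMERATION_LIMIT = 12


def _exact_two_sided_p(u_min: float, n1: int, n2: int) -> float:
    """Exact two-sided p by enumerating all rank assignments (no ties)."""
    import math

    N = n1 + n2
    const = n1 * (n1 + 1) // 2
    count = 0
    total = math.comb(N, n1)
    for positions in itertools.combinations(range(N), n1):
        u1 = sum(positions) + n1 - const
        if min(u1, n1 * n2 - u1) <= u_min + 1e-9:
            count += 1
    return count / total


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with ``U = min(U1, U2)`` from midrank rank sums.  The
    p-value is exact (full enumeration of rank assignments) when the combined
    sample size is at most 12 and the pooled sample is untied, otherwise a
    normal approximation with tie and continuity corrections is used.  A
    pooled sample with all values identical gives p = 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()
    if (tie_counts == n1 + n2).any():
        return u, 1.0

    if n1 + n2 <= EXACT_ENUMERATION_LIMIT and not has_ties:
        return u, _exact_two_sided_p(u, n1, n2)

    N = n1 + n2
    tie_term = float(((tie_counts**3) - tie_counts).sum()) / (N * (N - 1))
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (u - n1 * n2 / 2.0 + 0.5) / np.sqrt(sigma2)
    return u, float(min(1.0, 2.0 * norm.cdf(z)))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-comparison significance level alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be at least 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def format_p(p: float, ndigits: int = 3) -> str:
    """Display rounding for p-values: 3 decimals, '<0.001' below that."""
    return "<0.001" if p < 10 ** (-ndigits) / 2 else f"{p:.{ndigits}f}"


@dataclass
class ComparisonResult:
    variable: str
    group1: str
    group2: str
    n1: int
    n2: int
    U: float
    p: float
    alpha: float
    significant: bool


# variable -> (frame, pretty label).  VHR and HU live on vertebra / curve
# rows respectively; Cobb and FI on curve rows; age on patient rows.
_VARIABLE_PLAN = (
    ("cobb_erect", "curves", "Cobb angle erect (deg)"),
    ("cobb_bending", "curves", "Cobb angle bending (deg)"),
    ("fi_percent", "curves", "Flexibility index (%)"),
    ("hu", "curves", "Hounsfield unit (HU)"),
    ("vhr_ant", "vertebrae", "VHR anterior"),
    ("vhr_mid", "vertebrae", "VHR middle"),
    ("vhr_post", "vertebrae", "VHR posterior"),
)


class ScoliosisStudy:
    """Group-comparison study over measured scoliosis cohorts.

    Parameters
    ----------
    vertebrae : DataFrame
        One row per vertebra with at least ``patient``, ``curve`` (one of
        ``NS_major``/``IS_main``/``IS_comp``) and ``vhr_ant``, ``vhr_mid``,
        ``vhr_post``; an optional ``hu`` column.
    curves : DataFrame, optional
        One row per curve with ``cobb_erect``, ``cobb_bending``,
        ``fi_percent`` and curve-level ``hu``.
    patients : DataFrame, optional
        One row per patient with ``group`` ('NS'/'IS') and ``age``.
    """

    def __init__(self, vertebrae: pd.DataFrame, curves: pd.DataFrame | None = None,
                 patients: pd.DataFrame | None = None):
        vertebrae = pd.DataFrame(vertebrae)
        required = {"patient", "curve", "vhr_ant", "vhr_mid", "vhr_post"}
        missing = required - set(vertebrae.columns)
        if missing:
            raise ValueError(f"vertebra table is missing columns: {sorted(missing)}")
        self.vertebrae = vertebrae
        self.curves = None if curves is None else pd.DataFrame(curves)
        self.patients = None if patients is None else pd.DataFrame(patients)

    @classmethod
    def from_frames(cls, frames: dict) -> "ScoliosisStudy":
        return cls(
            frames["vertebrae"], frames.get("curves"), frames.get("patients")
        )

    @classmethod
    def from_cohort(cls, cohort, source: str = "realized") -> "ScoliosisStudy":
        return cls.from_frames(cohort.to_frames(source=source))

    # -- fitting -----------------------------------------------------------

    def _frame_for(self, which: str) -> pd.DataFrame | None:
        return {"vertebrae": self.vertebrae, "curves": self.curves}[which]

    def fit(self, alpha: float = 0.05, n_comparisons: int = 3,
            unit: str = "vertebra") -> "StudyResults":
        """Run all pairwise curve comparisons and per-curve summaries.

        ``unit`` selects the unit of analysis for vertebra-level variables:
        ``"vertebra"`` (each vertebra one observation) or ``"patient_mean"``
        (per patient-curve means).
        """
        if unit not in ("vertebra", "patient_mean"):
            raise ValueError("unit must be 'vertebra' or 'patient_mean'")
        present = set(self.vertebrae["curve"].unique())
        missing = set(CURVE_GROUPS) - present
        if missing:
            raise ValueError(f"missing curve groups: {sorted(missing)}")

        adj_alpha = bonferroni_threshold(alpha, n_comparisons)
        comparisons: list[ComparisonResult] = []
        summaries: list[dict] = []

        for var, frame_name, label in _VARIABLE_PLAN:
            frame = self._frame_for(frame_name)
            if frame is None or var not in frame.columns:
                continue
            work = frame
            if frame_name == "vertebrae" and unit == "patient_mean":
                work = (
                    frame.groupby(["patient", "curve"], as_index=False)[var].mean()
                )
            samples = {
                g: work.loc[work["curve"] == g, var].to_numpy(dtype=float)
                for g in CURVE_GROUPS
            }
            for g, s in samples.items():
                summaries.append(
                    {
                        "variable": var,
                        "label": label,
                        "curve": g,
                        "mean": float(s.mean()),
                        "sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
                        "n": len(s),
                    }
                )
            for g1, g2 in itertools.combinations(CURVE_GROUPS, 2):
                U, p = mann_whitney_u(samples[g1], samples[g2])
                comparisons.append(
                    ComparisonResult(
                        var, g1, g2, len(samples[g1]), len(samples[g2]),
                        U, p, adj_alpha, p < adj_alpha,
                    )
                )

        if self.patients is not None and "age" in self.patients.columns:
            ns = self.patients.loc[self.patients["group"] == "NS", "age"].to_numpy()
            is_ = self.patients.loc[self.patients["group"] == "IS", "age"].to_numpy()
            if len(ns) and len(is_):
                U, p = mann_whitney_u(ns, is_)
                comparisons.append(
                    ComparisonResult(
                        "age", "NS", "IS", len(ns), len(is_), U, p, alpha, p < alpha
                    )
                )
                for name, s in (("NS", ns), ("IS", is_)):
                    summaries.append(
                        {
                            "variable": "age", "label": "Age (years)", "curve": name,
                            "mean": float(s.mean()),
                            "sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
                            "n": len(s),
                        }
                    )

        return StudyResults(
            comparisons=pd.DataFrame([c.__dict__ for c in comparisons]),
            summaries=pd.DataFrame(summaries),
            alpha=alpha,
            adjusted_alpha=adj_alpha,
            unit=unit,
        )


@dataclass
class StudyResults:
    """Fitted study: per-curve summaries and all pairwise comparisons."""

    comparisons: pd.DataFrame
    summaries: pd.DataFrame
    alpha: float
    adjusted_alpha: float
    unit: str = "vertebra"
    metadata: dict = field(default_factory=dict)

    def vhr_table(self) -> pd.DataFrame:
        """Per-curve mean +/- SD of the three VHR parts (report shape)."""
        sub = self.summaries[self.summaries["variable"].str.startswith("vhr_")]
        piv = sub.pivot(index="curve", columns="variable", values=["mean", "sd"])
        return piv.reindex(list(CURVE_GROUPS))

    def summary(self) -> str:
        lines = [
            "Scoliosis curve comparison study",
            "=" * 72,
            f"unit of analysis: {self.unit};  alpha {self.alpha:.3f} "
            f"(curve variables at Bonferroni-adjusted "
            f"{round(self.adjusted_alpha, 3):.3f})",
            "",
            f"{'variable':<22}{'curve':<12}{'mean':>10}{'SD':>9}{'n':>5}",
            "-" * 58,
        ]
        for _, row in self.summaries.iterrows():
            lines.append(
                f"{row['variable']:<22}{row['curve']:<12}"
                f"{row['mean']:>10.3f}{row['sd']:>9.3f}{row['n']:>5d}"
            )
        lines += [
            "",
            f"{'variable':<14}{'comparison':<22}{'U':>8}{'p':>9}{'sig':>5}",
            "-" * 58,
        ]
        for _, row in self.comparisons.iterrows():
            lines.append(
                f"{row['variable']:<14}{row['group1'] + ' vs ' + row['group2']:<22}"
                f"{row['U']:>8.1f}{format_p(row['p']):>9}"
                f"{'*' if row['significant'] else '':>5}"
            )
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "alpha": self.alpha,
            "adjusted_alpha": round(self.adjusted_alpha, 3),
            "unit": self.unit,
            "summaries": self.summaries.to_dict(orient="records"),
            "comparisons": self.comparisons.to_dict(orient="records"),
            **({"metadata": self.metadata} if self.metadata else {}),
        }

    def plot_vhr(self, ax=None):
        """Box plots of vertebra-level VHR summaries are not reconstructible
        from summaries alone; this plots mean +/- SD per curve and part."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        sub = self.summaries[self.summaries["variable"].str.startswith("vhr_")]
        parts = ["vhr_ant", "vhr_mid", "vhr_post"]
        width = 0.25
        xs = np.arange(len(parts))
        for k, curve in enumerate(CURVE_GROUPS):
            rows = sub[sub["curve"] == curve].set_index("variable").reindex(parts)
            ax.errorbar(
                xs + (k - 1) * width, rows["mean"], yerr=rows["sd"],
                fmt="o", capsize=3, label=curve,
            )
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_xticks(xs, ["anterior", "middle", "posterior"])
        ax.set_ylabel("VHR (concave / convex)")
        ax.legend()
        return ax


def run_study(frames: dict, alpha: float = 0.05, unit: str = "vertebra") -> StudyResults:
    """Functional wrapper: build the study from tidy frames and fit it."""
    return ScoliosisStudy.from_frames(frames).fit(alpha=alpha, unit=unit)
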