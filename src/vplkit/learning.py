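"""Power-law learning curves fitted jointly across groups, with nested-model
comparison by F-test.

The learning curve is ``C(t) = C0 * t**(-rho)`` per group. A candidate joint
model is a pair of set partitions of the group labels: groups in the same
block of the C0 partition share one initial threshold, groups in the same
block of the rho partition share one learning rate. The fully free model has
one (C0, rho) per group (k = 2G parameters); the fully shared model has a
single pair (k = 2). Models are fitted by bounded multi-start nonlinear least
squares on the pooled residuals, and a reduced model is compared with the
full model by

    F(df1, df2) = [(r2_full - r2_reduced) / df1] / [(1 - r2_full) / df2]

with ``df1 = k_full - k_reduced`` and ``df2 = N - k_full``, N the number of
data points. The best model is the smallest (fewest-parameter) reduced model
that is statistically indistinguishable from the full model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sympy.utilities.iterables import multiset_partitions

__all__ = [
    "CurveData",
    "ModelSpec",
    "ModelComparison",
    "LearningCurveResults",
    "JointLearningCurveModel",
    "ModelSelectionResult",
    "fit_power_law",
    "fit_joint",
    "enumerate_models",
    "nested_f_test",
    "select_best_model",
]

C0_BOUNDS = (1e-8, 1.5)
RHO_BOUNDS = (0.0, 3.0)
_RHO_STARTS = (0.1, 0.5, 1.0)
# Relative RSS below which a fit is treated as exact (r2 = 1, infinite F).
_PERFECT_RTOL = 1e-10


@dataclass(frozen=True)
class CurveData:
    """Mean thresholds of one group over sessions (t is 1-based, increasing)."""

    group: str
    t: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("t and y must be 1-D and of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("session indices must be strictly increasing")
        if np.any(t < 1):
            raise ValueError("session indices must be >= 1")
        if np.any(y <= 0):
            raise ValueError("thresholds must be positive")

    @staticmethod
    def from_dataframe(df: pd.DataFrame) -> list["CurveData"]:
        """Build per-group curve data from long-format (group, session, threshold)."""
        out = []
        for group, sub in df.groupby("group", sort=False):
            sub = sub.sort_values("session")
            out.append(
                CurveData(
                    group=str(group),
                    t=tuple(sub["session"].astype(float)),
                    y=tuple(sub["threshold"].astype(float)),
                )
            )
        return out


def _canonical_partition(
    blocks: Iterable[Iterable[str]], groups: Sequence[str]
) -> tuple[tuple[str, ...], ...]:
    """Sort blocks and members into a canonical, hashable form and validate cover."""
    blocks = tuple(tuple(sorted(set(b))) for b in blocks)
    members = [g for b in blocks for g in b]
    if sorted(members) != sorted(set(members)):
        raise ValueError("partition blocks must be disjoint")
    if set(members) != set(groups):
        raise ValueError("partition must cover exactly the group set")
    return tuple(sorted(blocks))


@dataclass(frozen=True)
class ModelSpec:
    """A parameter-sharing pattern: set partitions of groups for C0 and rho."""

    c0_partition: tuple[tuple[str, ...], ...]
    rho_partition: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        groups = self.groups
        object.__setattr__(
            self, "c0_partition", _canonical_partition(self.c0_partition, groups)
        )
        object.__setattr__(
            self, "rho_partition", _canonical_partition(self.rho_partition, groups)
        )

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted({g for b in self.c0_partition for g in b}))

    @property
    def k(self) -> int:
        """Number of free parameters: one C0 per C0-block, one rho per rho-block."""
        return len(self.c0_partition) + len(self.rho_partition)

    @classmethod
    def full(cls, groups: Sequence[str]) -> "ModelSpec":
        """Fully free model: every group has its own C0 and rho (k = 2G)."""
        singletons = tuple((g,) for g in groups)
        return cls(singletons, singletons)

    @classmethod
    def fully_shared(cls, groups: Sequence[str]) -> "ModelSpec":
        """One C0 and one rho shared by all groups (k = 2)."""
        whole = (tuple(groups),)
        return cls(whole, whole)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        """True when this model is a constrained version of ``other``.

        Requires every block of the finer (``other``) partition to be
        contained in a block of this model's coarser partition, for both
        parameter families.
        """
        if set(self.groups) != set(other.groups):
            return False

        def refines(fine, coarse):
            return all(
                any(set(fb) <= set(cb) for cb in coarse) for fb in fine
            )

        return refines(other.c0_partition, self.c0_partition) and refines(
            other.rho_partition, self.rho_partition
        )

    def label(self) -> str:
        def fmt(p):
            return "|".join("+".join(b) for b in p)

        return f"C0[{fmt(self.c0_partition)}] rho[{fmt(self.rho_partition)}]"


@dataclass(frozen=True)
class ModelComparison:
    """Nested F-test between a full and a reduced joint fit."""

    f_stat: float
    df1: int
    df2: int
    p: float
    r2_full: float
    r2_reduced: float


class JointLearningCurveModel:
    """Joint power-law learning-curve model for one or more groups.

    Parameters
    ----------
    data : sequence of CurveData
        Per-group session/threshold series.
    spec : ModelSpec, optional
        Parameter-sharing pattern; defaults to the fully free model.
    """

    def __init__(
        self, data: Sequence[CurveData], spec: ModelSpec | None = None
    ) -> None:
        data = list(data)
        if not data:
            raise ValueError("no curve data supplied")
        groups = [d.group for d in data]
        if len(set(groups)) != len(groups):
            raise ValueError("duplicate group labels in curve data")
        if spec is None:
            spec = ModelSpec.full(groups)
        if set(spec.groups) != set(groups):
            raise ValueError("spec groups do not match the data")
        self.data = data
        self.spec = spec
        self.n_points = sum(len(d.t) for d in data)
        if self.n_points < spec.k:
            raise ValueError(
                f"underdetermined: {self.n_points} points for {spec.k} parameters"
            )
        # index of the C0/rho parameter used by each group
        self._c0_idx = {g: i for i, b in enumerate(spec.c0_partition) for g in b}
        self._rho_idx = {g: j for j, b in enumerate(spec.rho_partition) for g in b}
        self._t = [np.asarray(d.t, dtype=float) for d in data]
        self._y = [np.asarray(d.y, dtype=float) for d in data]
        self._y_all = np.concatenate(self._y)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, spec: ModelSpec | None = None
    ) -> "JointLearningCurveModel":
        """Build from a long-format table with columns group, session, threshold."""
        return cls(CurveData.from_dataframe(df), spec)

    # -- fitting ---------------------------------------------------------

    def _split(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n_c0 = len(self.spec.c0_partition)
        return params[:n_c0], params[n_c0:]

    def _residuals(self, params: np.ndarray) -> np.ndarray:
        c0s, rhos = self._split(params)
        res = [
            y - c0s[self._c0_idx[d.group]] * t ** (-rhos[self._rho_idx[d.group]])
            for d, t, y in zip(self.data, self._t, self._y)
        ]
        return np.concatenate(res)

    def _jacobian(self, params: np.ndarray) -> np.ndarray:
        c0s, rhos = self._split(params)
        n_c0 = len(c0s)
        jac = np.zeros((self.n_points, self.spec.k))
        row = 0
        for d, t in zip(self.data, self._t):
            i, j = self._c0_idx[d.group], self._rho_idx[d.group]
            pred = c0s[i] * t ** (-rhos[j])
            sl = slice(row, row + len(t))
            jac[sl, i] = -(t ** (-rhos[j]))
            jac[sl, n_c0 + j] = pred * np.log(t)
            row += len(t)
        return jac

    def fit(self, rho_starts: Sequence[float] = _RHO_STARTS) -> "LearningCurveResults":
        """Multi-start bounded nonlinear least squares on the pooled residuals."""
        n_c0, n_rho = len(self.spec.c0_partition), len(self.spec.rho_partition)
        # start C0 at the mean of each block's earliest thresholds
        first_y = {d.group: d.y[0] for d in self.data}
        c0_start = np.array(
            [
                np.clip(np.mean([first_y[g] for g in block]), 0.01, C0_BOUNDS[1])
                for block in self.spec.c0_partition
            ]
        )
        lower = np.r_[np.full(n_c0, C0_BOUNDS[0]), np.full(n_rho, RHO_BOUNDS[0])]
        upper = np.r_[np.full(n_c0, C0_BOUNDS[1]), np.full(n_rho, RHO_BOUNDS[1])]
        best = None
        for rho0 in rho_starts:
            x0 = np.r_[c0_start, np.full(n_rho, rho0)]
            sol = optimize.least_squares(
                self._residuals,
                x0,
                jac=self._jacobian,
                bounds=(lower, upper),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            rss = float(2.0 * sol.cost)
            if best is None or rss < best[0] - 1e-15:
                best = (rss, sol)
        rss, sol = best
        if not sol.success and sol.status <= 0:
            raise RuntimeError(f"joint fit failed to converge: {sol.message}")
        c0s, rhos = self._split(sol.x)
        return LearningCurveResults(model=self, c0_values=c0s, rho_values=rhos, rss=rss)


def _r_squared(rss: float, y: np.ndarray) -> float:
    """1 - RSS/TSS with TSS about the mean of the measured values."""
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return 1.0 if rss <= 1e-15 else float("nan")
    return 1.0 - rss / tss


class LearningCurveResults:
    """Fitted joint power-law model: estimates, fit quality, comparisons."""

    def __init__(
        self,
        model: JointLearningCurveModel,
        c0_values: np.ndarray,
        rho_values: np.ndarray,
        rss: float,
    ) -> None:
        self.model = model
        self.spec = model.spec
        self.c0_values = np.asarray(c0_values, dtype=float)
        self.rho_values = np.asarray(rho_values, dtype=float)
        self.rss = float(rss)
        self.n_points = model.n_points
        self.r2 = _r_squared(self.rss, model._y_all)

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def c0_by_group(self) -> dict[str, float]:
        return {g: float(self.c0_values[i]) for g, i in self.model._c0_idx.items()}

    @property
    def rho_by_group(self) -> dict[str, float]:
        return {g: float(self.rho_values[j]) for g, j in self.model._rho_idx.items()}

    def predict(self, group: str, t: Sequence[float] | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.c0_by_group[group] * t ** (-self.rho_by_group[group])

    def compare(self, reduced: "LearningCurveResults") -> ModelComparison:
        """Nested F-test of this (full) fit against a reduced fit."""
        return nested_f_test(self, reduced)

    def summary(self) -> str:
        lines = [
            "Joint power-law learning-curve fit",
            "=" * 44,
            f"model: {self.spec.label()}",
            f"k = {self.k} free parameters, N = {self.n_points} points",
            f"RSS = {self.rss:.6g}   r2 = {self.r2:.4f}",
            "-" * 44,
            f"{'group':<14}{'C0':>10}{'rho':>10}",
        ]
        for d in self.model.data:
            g = d.group
            lines.append(
                f"{g:<14}{self.c0_by_group[g]:>10.4f}{self.rho_by_group[g]:>10.4f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data points and fitted curves per group (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for d in self.model.data:
            t = np.asarray(d.t)
            pts = ax.plot(t, d.y, "o", label=d.group)
            tt = np.linspace(t.min(), t.max(), 200)
            ax.plot(tt, self.predict(d.group, tt), "-", color=pts[0].get_color())
        ax.set_xlabel("session")
        ax.set_ylabel("coherence threshold")
        ax.legend()
        return ax


def fit_power_law(
    t: Sequence[float], y: Sequence[float], group: str = "group"
) -> LearningCurveResults:
    """Fit a single power-law curve C0 * t**(-rho) to one series (k = 2)."""
    data = [CurveData(group=group, t=tuple(t), y=tuple(y))]
    if len(data[0].t) < 3:
        raise ValueError("need at least 3 data points to fit a power law")
    return JointLearningCurveModel(data).fit()


def fit_joint(data: Sequence[CurveData], spec: ModelSpec) -> LearningCurveResults:
    """Fit a joint model under the given parameter-sharing pattern."""
    return JointLearningCurveModel(data, spec).fit()


def enumerate_models(groups: Sequence[str]) -> list[ModelSpec]:
    """All parameter-sharing patterns: pairs of set partitions of the groups.

    For G groups this is Bell(G)**2 specs (G=4 -> 225), ordered by increasing
    parameter count k, and always contains the fully free and fully shared
    models.
    """
    groups = list(groups)
    if not 2 <= len(groups) <= 6:
        raise ValueError("model enumeration supports 2..6 groups")
    partitions = [
        tuple(tuple(b) for b in p) for p in multiset_partitions(sorted(groups))
    ]
    specs = [
        ModelSpec(c0_p, rho_p)
        for c0_p, rho_p in itertools.product(partitions, partitions)
    ]
    specs.sort(key=lambda s: (s.k, s.label()))
    return specs


def nested_f_test(
    full: LearningCurveResults, reduced: LearningCurveResults
) -> ModelComparison:
    """Compare a reduced (more-shared) fit with the full fit it is nested in.

    Degenerate cases: a numerically perfect full fit gives infinite F and
    p = 0, unless the reduced fit is also perfect, in which case F = 0 and
    p = 1 (the models are indistinguishable on these data).
    """
    if not reduced.spec.is_nested_in(full.spec):
        raise ValueError("reduced model is not nested in the full model")
    if full.n_points != reduced.n_points:
        raise ValueError("full and reduced fits must use the same data")
    df1 = full.k - reduced.k
    df2 = full.n_points - full.k
    if df1 < 1:
        raise ValueError("full model must have more parameters than the reduced model")
    if df2 < 1:
        raise ValueError("no residual degrees of freedom for the full model")
    tss = float(np.sum((full.model._y_all - full.model._y_all.mean()) ** 2))
    perfect_full = full.rss <= _PERFECT_RTOL * max(tss, 1e-30)
    perfect_reduced = reduced.rss <= _PERFECT_RTOL * max(tss, 1e-30)
    if perfect_full:
        if perfect_reduced:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
    else:
        f_stat = ((full.r2 - reduced.r2) / df1) / ((1.0 - full.r2) / df2)
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, df1, df2))
    return ModelComparison(
        f_stat=f_stat, df1=df1, df2=df2, p=p, r2_full=full.r2, r2_reduced=reduced.r2
    )


@dataclass
class ModelSelectionResult:
    """Winner of the nested-model search plus the full comparison table."""

    best_spec: ModelSpec
    best_fit: LearningCurveResults
    table: pd.DataFrame
    full_fit: LearningCurveResults
    no_candidate: bool = False

    def summary(self) -> str:
        head = "Model selection over parameter-sharing patterns"
        note = (
            " (no reduced model matched the full model; full model returned)"
            if self.no_candidate
            else ""
        )
        return (
            f"{head}\n{'=' * len(head)}\n"
            f"{len(self.table)} candidate models, best: {self.best_spec.label()} "
            f"(k={self.best_spec.k}, r2={self.best_fit.r2:.4f}){note}\n\n"
            + self.best_fit.summary()
        )


def select_best_model(
    data: Sequence[CurveData],
    specs: Sequence[ModelSpec] | None = None,
    alpha: float = 0.05,
) -> ModelSelectionResult:
    """Pick the most parsimonious model statistically equal to the full model.

    Every spec is fitted and compared with the fully free model by nested
    F-test. Candidates are the specs whose p exceeds ``alpha`` (they fit as
    well as the full model); the winner is the candidate with the fewest
    parameters, ties broken by larger r2, then by partition label. If no
    reduced model survives, the full model is returned with a warning flag.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    groups = [d.group for d in data]
    if specs is None:
        specs = enumerate_models(groups)
    full_spec = ModelSpec.full(groups)
    if full_spec not in specs:
        raise ValueError("spec list must include the fully free model")
    fits = {spec: JointLearningCurveModel(data, spec).fit() for spec in specs}
    full_fit = fits[full_spec]
    rows = []
    candidates = []
    for spec in specs:
        fit = fits[spec]
        if spec == full_spec:
            cmp = ModelComparison(0.0, 1, full_fit.n_points - full_fit.k, 1.0,
                                  full_fit.r2, full_fit.r2)
        else:
            cmp = nested_f_test(full_fit, fits[spec])
        rows.append(
            {
                "spec_id": spec.label(),
                "c0_partition": "|".join("+".join(b) for b in spec.c0_partition),
                "rho_partition": "|".join("+".join(b) for b in spec.rho_partition),
                "k": spec.k,
                "rss": fit.rss,
                "r2": fit.r2,
                "F_vs_full": cmp.f_stat if spec != full_spec else 0.0,
                "df1": cmp.df1,
                "df2": cmp.df2,
                "p": cmp.p,
            }
        )
        if cmp.p > alpha:
            candidates.append(spec)
    table = pd.DataFrame(rows)
    no_candidate = not candidates
    if no_candidate:
        best = full_spec
    else:
        best = min(candidates, key=lambda s: (s.k, -fits[s].r2, s.label()))
    return ModelSelectionResult(
        best_spec=best,
        best_fit=fits[best],
        table=table,
        full_fit=full_fit,
        no_candidate=no_candidate,
    )
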