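"""Panel-level correlation and regression analysis of lobe scores.

Across a panel of split inteins the N2 score correlates positively with the
overall Int^N score and negatively with the N1 score — the signature of
aggregation propensity being redistributed between the two lobes. This
module computes Spearman rank correlations (with t-approximation or exact /
Monte-Carlo permutation p-values), ordinary least-squares fits, and a
combined per-panel report including classification-vs-label agreement.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lobes import LobeScores

EXACT_PERMUTATION_MAX_N = 8


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average (mid-rank) tie handling: Pearson
    correlation of the rank vectors."""
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    p_mode: str = "t_approx",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    ``t_approx`` uses the t-distribution approximation; ``permutation`` is
    exact (all n! orderings) for n <= 8 and seeded Monte-Carlo above.
    Constant input vectors leave rho undefined and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman rho undefined")
    rho = _spearman_rho(x, y)
    if p_mode == "t_approx":
        res = stats.spearmanr(x, y)
        return rho, float(res.pvalue)
    if p_mode != "permutation":
        raise ValueError(f"unknown p_mode {p_mode!r}")
    target = abs(rho) - 1e-12
    if n <= EXACT_PERMUTATION_MAX_N:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_spearman_rho(x, y[list(perm)])) >= target:
                count += 1
        return rho, count / total
    rng = np.random.default_rng(seed)
    count = sum(
        abs(_spearman_rho(x, rng.permutation(y))) >= target
        for _ in range(n_permutations)
    )
    # add-one smoothing keeps the Monte-Carlo p-value away from 0
    return rho, (count + 1) / (n_permutations + 1)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least-squares line y = slope*x + intercept; returns
    (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 paired observations")
    if np.all(x == x[0]):
        raise ValueError("constant x: slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


@dataclass(frozen=True)
class PanelResult:
    """Scores table plus the two panel correlations and regression fits."""

    table: pd.DataFrame
    rho_n2_vs_total: Optional[float]
    p_n2_vs_total: Optional[float]
    rho_n2_vs_n1: Optional[float]
    p_n2_vs_n1: Optional[float]
    fit_n2_vs_total: Optional[tuple[float, float]]
    fit_n2_vs_n1: Optional[tuple[float, float]]
    confusion: Optional[dict] = None

    def to_dict(self) -> dict:
        d = {
            "table": self.table.to_dict(orient="records"),
            "rho_n2_vs_total": self.rho_n2_vs_total,
            "p_n2_vs_total": self.p_n2_vs_total,
            "rho_n2_vs_n1": self.rho_n2_vs_n1,
            "p_n2_vs_n1": self.p_n2_vs_n1,
            "fit_n2_vs_total": self.fit_n2_vs_total,
            "fit_n2_vs_n1": self.fit_n2_vs_n1,
        }
        if self.confusion is not None:
            d["confusion"] = self.confusion
        return d


def panel_report(
    scores: Sequence[tuple[str, LobeScores]],
    labels: Optional[dict[str, str]] = None,
    p_mode: str = "t_approx",
    seed: int = 0,
) -> PanelResult:
    """Aggregate (name, LobeScores) pairs into the panel analysis.

    Computes Spearman rho and OLS fits for N2-vs-total and N2-vs-N1. With
    fewer than 3 rows the correlations are omitted with a warning and only
    the table is returned. When efficiency labels ({efficient | inefficient |
    unknown}) are supplied, classification-vs-label confusion counts are
    included. The report is invariant to the input row order (rows are
    sorted by name in the output table).
    """
    rows = []
    for name, sc in scores:
        rows.append(
            {
                "name": name,
                "s_n1": sc.s_n1,
                "s_n2": sc.s_n2,
                "s_total": sc.s_total,
                "ratio": sc.ratio,
                "classification": sc.classification,
                "label": (labels or {}).get(name, "unknown"),
            }
        )
    table = pd.DataFrame(rows).sort_values("name").reset_index(drop=True)
    rho_t = p_t = rho_n1 = p_n1 = None
    fit_t = fit_n1 = None
    if len(table) >= 3:
        s_n1 = table["s_n1"].to_numpy()
        s_n2 = table["s_n2"].to_numpy()
        s_tot = table["s_total"].to_numpy()

        def _safe(func, *args):
            # a constant score vector leaves rho / the slope undefined;
            # report None for that pair instead of failing the whole panel
            try:
                return func(*args)
            except ValueError as exc:
                warnings.warn(f"panel correlation omitted: {exc}", stacklevel=3)
                return None

        if (pair := _safe(spearman, s_tot, s_n2, p_mode, 10_000, seed)) is not None:
            rho_t, p_t = pair
        if (pair := _safe(spearman, s_n1, s_n2, p_mode, 10_000, seed)) is not None:
            rho_n1, p_n1 = pair
        if (fit := _safe(linear_fit, s_tot, s_n2)) is not None:
            fit_t = fit[:2]
        if (fit := _safe(linear_fit, s_n1, s_n2)) is not None:
            fit_n1 = fit[:2]
    else:
        warnings.warn(
            "fewer than 3 scored inteins: correlations omitted", stacklevel=2
        )
    confusion = None
    if labels:
        confusion = {
            "efficient_predicted_and_efficient": 0,
            "efficient_predicted_and_inefficient": 0,
            "aggregation_prone_predicted_and_efficient": 0,
            "aggregation_prone_predicted_and_inefficient": 0,
            "indeterminate_or_unlabelled": 0,
        }
        for _, r in table.iterrows():
            pred, lab = r["classification"], r["label"]
            if lab in ("efficient", "inefficient") and pred in (
                "efficient_predicted",
                "aggregation_prone_predicted",
            ):
                confusion[f"{pred}_and_{lab}"] += 1
            else:
                confusion["indeterminate_or_unlabelled"] += 1
    return PanelResult(
        table=table,
        rho_n2_vs_total=rho_t,
        p_n2_vs_total=p_t,
        rho_n2_vs_n1=rho_n1,
        p_n2_vs_n1=p_n1,
        fit_n2_vs_total=fit_t,
        fit_n2_vs_n1=fit_n1,
        confusion=confusion,
    )


def plot_panel(result: PanelResult, out_prefix: str) -> list[str]:
    """Scatter plots of N2 vs total and N2 vs N1 with the identity line
    (solid) and the OLS fit (dashed red). Returns written file paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    specs = [
        ("s_total", result.fit_n2_vs_total, result.rho_n2_vs_total, "n2_vs_total"),
        ("s_n1", result.fit_n2_vs_n1, result.rho_n2_vs_n1, "n2_vs_n1"),
    ]
    for xcol, fit, rho, tag in specs:
        fig, ax = plt.subplots(figsize=(4, 4))
        x = result.table[xcol].to_numpy()
        y = result.table["s_n2"].to_numpy()
        ax.scatter(x, y, color="k", zorder=3)
        lim = [0, max(1e-9, x.max(), y.max()) * 1.1]
        ax.plot(lim, lim, "-", color="grey", lw=1, label="1:1")
        if fit is not None:
            xs = np.linspace(lim[0], lim[1], 50)
            ax.plot(xs, fit[0] * xs + fit[1], "r--", lw=1.2, label="OLS fit")
        ax.set_xlabel(f"{xcol} (per residue)")
        ax.set_ylabel("s_n2 (per residue)")
        if rho is not None:
            ax.set_title(f"Spearman rho = {rho:.2f}")
        ax.legend(frameon=False)
        path = f"{out_prefix}_{tag}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
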