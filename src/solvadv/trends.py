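"""Class-split linear trend analysis.

Mono- and dicarboxylic coformers follow different structural mechanisms
of cocrystal formation, so every correlation (solubility advantage vs
complex exponent, vs melting-point shift, vs relative hydration) is
fitted separately per acid class.  Fits are ordinary least squares of
y on x; R² is the squared Pearson correlation, identical to the OLS
coefficient of determination for a simple linear fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["TrendFit", "fit_class_trends", "sign_diagnostic", "plot_class_trends"]


def _normalize(name: str) -> str:
    return name.strip().casefold()


@dataclass(frozen=True)
class TrendFit:
    """One per-class simple linear fit.

    ``defined`` is False when fewer than two points (or no x variance)
    remained after exclusions; ``degenerate`` flags a constant-y fit,
    reported with slope 0 and R² 0.
    """

    class_label: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    excluded: tuple = ()
    stderr: float = float("nan")
    defined: bool = True
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "class": self.class_label,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
            "excluded": list(self.excluded),
            "stderr": self.stderr,
            "defined": self.defined,
            "degenerate": self.degenerate,
        }


def _undefined_fit(label: str, n: int, excluded: tuple, reason: str) -> TrendFit:
    warnings.warn(
        f"trend fit for class {label!r} undefined: {reason}",
        RuntimeWarning,
        stacklevel=3,
    )
    nan = float("nan")
    return TrendFit(
        class_label=label,
        slope=nan,
        intercept=nan,
        r_squared=nan,
        n=n,
        excluded=excluded,
        defined=False,
    )


def fit_class_trends(
    x: Sequence[float],
    y: Sequence[float],
    class_labels: Sequence[str],
    exclusions: Iterable[str] = (),
    names: Optional[Sequence[str]] = None,
) -> List[TrendFit]:
    """Per-class OLS fits of y on x after dropping excluded names.

    Parameters
    ----------
    x, y : sequences of float
        Paired observations; NaNs in either drop the pair.
    class_labels : sequence of str
        Class of each point (e.g. ``"mono"`` / ``"di"``); one fit is
        returned per distinct label, in first-appearance order.
    exclusions : iterable of str
        Point names to remove before fitting (case-insensitive).
    names : sequence of str, optional
        Point names; required for exclusions to have any effect.

    A class left with fewer than two points, or with constant x, yields
    an undefined fit (NaN coefficients) with a warning, not an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = list(class_labels)
    if not (len(x) == len(y) == len(labels)):
        raise ValueError("x, y and class_labels must have equal length")
    if names is not None and len(names) != len(x):
        raise ValueError("names must match x in length")

    excluded_set = {_normalize(e) for e in exclusions}
    fits: List[TrendFit] = []
    seen: Dict[str, None] = {}
    for label in labels:
        if label not in seen:
            seen[label] = None

    for label in seen:
        dropped: List[str] = []
        xs: List[float] = []
        ys: List[float] = []
        for i, lab in enumerate(labels):
            if lab != label:
                continue
            if names is not None and _normalize(names[i]) in excluded_set:
                dropped.append(names[i])
                continue
            if np.isnan(x[i]) or np.isnan(y[i]):
                continue
            xs.append(x[i])
            ys.append(y[i])

        excluded = tuple(dropped)
        if len(xs) < 2:
            fits.append(_undefined_fit(label, len(xs), excluded, "fewer than 2 points"))
            continue
        xa, ya = np.array(xs), np.array(ys)
        if np.ptp(xa) == 0.0:
            fits.append(_undefined_fit(label, len(xs), excluded, "constant x"))
            continue
        if np.ptp(ya) == 0.0:
            # no variance to explain: flat line, zero R², flagged
            fits.append(
                TrendFit(
                    class_label=label,
                    slope=0.0,
                    intercept=float(ya.mean()),
                    r_squared=0.0,
                    n=len(xs),
                    excluded=excluded,
                    stderr=0.0,
                    degenerate=True,
                )
            )
            continue

        res = stats.linregress(xa, ya)
        fits.append(
            TrendFit(
                class_label=label,
                slope=float(res.slope),
                intercept=float(res.intercept),
                r_squared=float(res.rvalue**2),
                n=len(xs),
                excluded=excluded,
                stderr=float(res.stderr),
            )
        )
    return fits


def sign_diagnostic(fits: Sequence[TrendFit]) -> dict:
    """Report whether the mono and di class slopes have opposite signs.

    Opposite mono/di trends of solubility advantage against the complex
    exponent are the qualitative signature of the two cocrystallization
    mechanisms (closed 1:1 pairs vs bridged superstructures).
    """
    by_label = {f.class_label: f for f in fits}
    mono = by_label.get("mono")
    di = by_label.get("di")
    complete = (
        mono is not None
        and di is not None
        and mono.defined
        and di.defined
        and not np.isnan(mono.slope)
        and not np.isnan(di.slope)
    )
    report = {
        "mono_slope": None if mono is None or not mono.defined else mono.slope,
        "di_slope": None if di is None or not di.defined else di.slope,
        "complete": complete,
        "opposite_signs": None,
    }
    if complete:
        report["opposite_signs"] = bool(mono.slope * di.slope < 0)
    return report


def plot_class_trends(
    x: Sequence[float],
    y: Sequence[float],
    class_labels: Sequence[str],
    fits: Sequence[TrendFit],
    path: str,
    xlabel: str = "x",
    ylabel: str = "y",
) -> None:
    """Scatter plot with per-class fitted lines, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(class_labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    markers = {"mono": "o", "di": "s"}
    for fit in fits:
        mask = labels == fit.class_label
        ax.scatter(
            x[mask], y[mask], marker=markers.get(fit.class_label, "^"),
            label=f"{fit.class_label}"
            + (f" (R²={fit.r_squared:.2f})" if fit.defined else " (undefined)"),
        )
        if fit.defined and not fit.degenerate:
            grid = np.linspace(np.nanmin(x[mask]), np.nanmax(x[mask]), 50)
            ax.plot(grid, fit.slope * grid + fit.intercept, lw=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
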