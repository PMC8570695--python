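"""Closed-form lattice organisation laws and the CV → class-distribution model.

Polygonal cell layers that minimise their lateral cell-cell contact surface
energy organise according to a small set of laws: the mean neighbour number
is six (Euler), the neighbours of an n-sided cell have on average
m(n) = 5 + 8/n neighbours (Aboav-Weaire), and the mean area of the n-sided
class relates to n either linearly (Lewis' law, (n−2)/4) or, at higher area
variability, quadratically ((n/6)·tan(π/6)/tan(π/n)).  Given a cell-area
coefficient of variation, either law induces a predicted polygon-class
distribution; its hexagon fraction declines as the CV grows.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from epi3d.datatypes import TheoryTable

LAWS = ("lewis_linear", "quadratic")
N_MIN, N_MAX = 3, 16  # supported polygon classes


def _check_n(n: int) -> int:
    n = int(n)
    if n < 3:
        raise ValueError(f"polygon class n must be >= 3, got {n}")
    return n


def lewis_linear(n: int) -> float:
    """Lewis' law: normalised mean area (n − 2) / 4 of the n-sided class."""
    return (_check_n(n) - 2) / 4.0


def lewis_quadratic(n: int) -> float:
    """Quadratic area-class law (n/6)·tan(π/6)/tan(π/n), ≈ (n/6)² for large n.

    Expected instead of the linear law when area variability is high; it is
    the relation under which all cell side lengths become equal.
    """
    n = _check_n(n)
    return (n / 6.0) * np.tan(np.pi / 6.0) / np.tan(np.pi / n)


def aw_prediction(n: int) -> float:
    """Aboav-Weaire's law: mean neighbour number m(n) = 5 + 8/n of neighbours."""
    return 5.0 + 8.0 / _check_n(n)


def regular_angle(n: int) -> float:
    """Internal angle of a regular n-gon, (n − 2)/n · 180, in degrees."""
    n = _check_n(n)
    return (n - 2) / n * 180.0


def class_area(n: int, law: str) -> float:
    if law == "lewis_linear":
        return lewis_linear(n)
    if law == "quadratic":
        return lewis_quadratic(n)
    raise ValueError(f"unknown law {law!r}; expected one of {LAWS}")


def predict_class_distribution(
    cv: float,
    law: str = "lewis_linear",
    family: str = "truncnorm",
    max_outside: float = 0.2,
) -> TheoryTable:
    """Predicted polygon-class distribution at a given area CV.

    Normalised cell areas A/Ā are modelled by a positive-support
    distribution with mean 1 and standard deviation ``cv`` (truncated
    normal renormalised to unit mean by default; a gamma alternative via
    ``family='gamma'``).  Each cell adopts the class n whose law-predicted
    area A_n/Ā is nearest: bin edges lie at the arithmetic midpoints of
    consecutive class areas, and the boundary classes (n = 3 and n = 16)
    absorb the distribution tails.  Because the distribution has unit mean
    and every cell is assigned a class, the mean cell area over classes is
    self-consistently equal to the population mean by construction, so no
    further rescaling is required.

    Parameters
    ----------
    cv
        Coefficient of variation of cell areas within the layer (std/mean).
    law
        'lewis_linear' or 'quadratic'.
    family
        Distribution family for normalised areas: 'truncnorm' or 'gamma'.
    max_outside
        Maximum tolerated probability mass outside the supported classes
        [3, 16]; beyond this the prediction is refused.

    Returns
    -------
    TheoryTable with class areas, class fractions (summing to 1) and the CV.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if law not in LAWS:
        raise ValueError(f"unknown law {law!r}; expected one of {LAWS}")

    ns = np.arange(N_MIN, N_MAX + 1)
    areas = np.array([class_area(int(n), law) for n in ns])

    if cv == 0.0:
        # all mass at A/Ā = 1, which is exactly the hexagon class area
        fractions = {int(n): (1.0 if n == 6 else 0.0) for n in ns}
        return TheoryTable(
            law=law, cv=0.0, class_areas=dict(zip(ns.tolist(), areas.tolist())),
            class_fractions=fractions,
        )

    if family == "truncnorm":
        a = (0.0 - 1.0) / cv  # truncate at zero area
        dist = stats.truncnorm(a, np.inf, loc=1.0, scale=cv)
        mean = float(dist.mean())  # renormalise to unit mean
    elif family == "gamma":
        k = 1.0 / cv**2
        dist = stats.gamma(k, scale=1.0 / k)
        mean = 1.0
    else:
        raise ValueError(f"unknown family {family!r}")

    def _cdf(x: np.ndarray) -> np.ndarray:
        return dist.cdf(np.asarray(x, dtype=float) * mean)

    # feasibility: the model must keep most mass within the supported
    # classes, measured against outer edges that extrapolate the class
    # spacing one half-step beyond the support
    inner = 0.5 * (areas[:-1] + areas[1:])
    lo = max(0.0, areas[0] - (inner[0] - areas[0]))
    hi = areas[-1] + (areas[-1] - inner[-1])
    outside = float(_cdf([lo])[0] + 1.0 - _cdf([hi])[0])
    if outside > max_outside:
        raise ValueError(
            f"cv={cv:g}: {outside:.1%} of area mass falls outside polygon "
            f"classes {N_MIN}..{N_MAX}; prediction undefined"
        )

    edges = np.concatenate([[0.0], inner, [np.inf]])
    frac = np.diff(_cdf(edges))
    frac = frac / frac.sum()
    return TheoryTable(
        law=law,
        cv=float(cv),
        class_areas=dict(zip(ns.tolist(), areas.tolist())),
        class_fractions={int(n): float(f) for n, f in zip(ns, frac)},
    )


def theory_curves(cvs, laws=LAWS, family: str = "truncnorm"):
    """Tidy table of predicted class fractions over a CV grid.

    Returns a list of dict rows (law, cv, n, fraction) suitable for CSV
    export and overlay on observed hexagon-fraction plots.
    """
    rows = []
    for law in laws:
        for cv in cvs:
            table = predict_class_distribution(float(cv), law=law, family=family)
            for n, f in table.class_fractions.items():
                rows.append({"law": law, "cv": float(cv), "n": n, "fraction": f})
    return rows
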