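"""Pseudo-ternary representation of two-bottle choice behavior.

For each mouse and condition the percent drug consumption with the drug on
the left (%c1) and on the right (%c2) is reduced to:

* ``a = min(c1, c2)``, ``b = max(c1, c2)``,
* consumption index ``x = (a + b) / 2`` (0–100, the triangle base), and
* side-bias index ``y = b - a`` (0–100, the triangle height axis).

A mouse that drinks the drug bottle on both sides sits near the 100% apex;
one that avoids it on both sides near the 0% apex; one that drinks a single
physical side regardless of content has ``c1 + c2 ≈ 100`` and sits near the
top apex. Before computing Euclidean apex distances the side-bias axis is
scaled by √3/2 so the three apices — (0, 0), (100, 0) and (50, 100·√3/2) —
form an equilateral triangle and distances are comparable across apices
(``side_scale=1.0`` disables the scaling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SIDE_SCALE",
    "TernaryPoint",
    "ternary_point",
    "points_table",
    "trajectory",
    "group_apex_distances",
    "reconstruct_xy",
]

SIDE_SCALE = math.sqrt(3.0) / 2.0

APEX_ZERO = "zero"  # 0% drug consumption (bottom left)
APEX_FULL = "full"  # 100% drug consumption (bottom right)
APEX_SIDE = "side"  # 100% side preference (top)


@dataclass
class TernaryPoint:
    mouse_id: str
    condition_id: str
    c1: float
    c2: float
    a: float
    b: float
    x: float  # consumption index, 0-100
    y: float  # side-bias index, 0-100 (unscaled)
    d_zero: float
    d_full: float
    d_side: float
    defined: bool = True


def ternary_point(
    c1: float,
    c2: float,
    *,
    mouse_id: str = "",
    condition_id: str = "",
    side_scale: float = SIDE_SCALE,
) -> TernaryPoint:
    """Map side-wise percent consumption to the pseudo-ternary plane.

    An undefined side component (NaN — e.g. a fully side-biased schedule
    segment that never sampled one side) yields a flagged point with NaN
    coordinates and no distances.
    """
    if not (np.isfinite(c1) and np.isfinite(c2)):
        nan = float("nan")
        return TernaryPoint(mouse_id, condition_id, c1, c2, nan, nan, nan, nan,
                            nan, nan, nan, defined=False)
    a, b = float(min(c1, c2)), float(max(c1, c2))
    if not (0.0 <= a <= b <= 100.0):
        raise ValueError(f"percent consumption out of range: ({c1}, {c2})")
    x = (a + b) / 2.0
    y = b - a
    px, py = x, y * side_scale
    d_zero = math.hypot(px - 0.0, py)
    d_full = math.hypot(px - 100.0, py)
    d_side = math.hypot(px - 50.0, py - 100.0 * side_scale)
    return TernaryPoint(mouse_id, condition_id, c1, c2, a, b, x, y,
                        d_zero, d_full, d_side)


def points_table(summaries: pd.DataFrame, *, side_scale: float = SIDE_SCALE) -> pd.DataFrame:
    """One ternary point per row of a condition-summary table (pct_c1/pct_c2)."""
    rows = []
    for r in summaries.itertuples():
        p = ternary_point(
            float(r.pct_c1), float(r.pct_c2),
            mouse_id=str(r.mouse_id), condition_id=str(r.condition_id),
            side_scale=side_scale,
        )
        d = p.__dict__.copy()
        if hasattr(r, "concentration"):
            d["concentration"] = r.concentration
        rows.append(d)
    return pd.DataFrame(rows)


def trajectory(points: pd.DataFrame) -> dict:
    """Summary displacement of one mouse's ordered condition points.

    Returns the ordered defined points plus the signed first-to-last change
    in each apex distance (negative = the mouse moved toward that apex).
    """
    pts = points[points["defined"]]
    if len(pts) < 2:
        raise ValueError("trajectory needs at least 2 defined condition points")
    first, last = pts.iloc[0], pts.iloc[-1]
    return {
        "mouse_id": pts["mouse_id"].iloc[0],
        "points": pts.reset_index(drop=True),
        "d_zero_change": float(last.d_zero - first.d_zero),
        "d_full_change": float(last.d_full - first.d_full),
        "d_side_change": float(last.d_side - first.d_side),
    }


def group_apex_distances(
    points: pd.DataFrame,
    group_col: str | None = None,
) -> pd.DataFrame:
    """Tidy mean ± sem apex distances per (group, condition, apex)."""
    pts = points[points["defined"]].copy()
    keys = ([group_col] if group_col else []) + ["condition_id"]
    rows = []
    for key, sub in pts.groupby(keys, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        for apex, col in ((APEX_ZERO, "d_zero"), (APEX_FULL, "d_full"), (APEX_SIDE, "d_side")):
            v = sub[col].to_numpy(float)
            rows.append(
                {
                    **dict(zip(keys, key)),
                    "apex": apex,
                    "mean": float(v.mean()),
                    "sem": float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0,
                    "n": len(v),
                }
            )
    return pd.DataFrame(rows)


def reconstruct_xy(d_zero: float, d_full: float) -> tuple[float, float]:
    """Invert two apex distances back to plane coordinates (x, y_scaled).

    The zero and full apices sit at (0,0) and (100,0), so the two circles
    intersect at a unique upper-half-plane point; used as an oracle that the
    three distances determine the point.
    """
    x = (d_zero**2 - d_full**2 + 100.0**2) / 200.0
    y2 = d_zero**2 - x**2
    return x, math.sqrt(max(y2, 0.0))
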